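"""Train a small inverse surrogate and inspect its held-out errors.

A deliberately small configuration so the example runs in about a minute;
the full study uses a larger corpus, network and epoch budget (see
docs/methods.md).
"""

from myostiff import (SurrogateConfig, build_dataset, lhs_sample,
                      make_parent_library, metrics, predict, split, train)

parents = make_parent_library(25, seed=11)
ds = build_dataset(parents, lhs_sample(300, seed=22, n_parents=25))
split(ds, n_test=50, seed=33)

cfg = SurrogateConfig(hidden_layers=2, units=128, epochs=400, seed=0)
model = train(ds, cfg)

X_test = ds.subset_X(ds.test_indices)
Y_test = ds.subset_Y(ds.test_indices)
m = metrics(Y_test, predict(model, X_test), model.output_scaler)
print(f"best checkpoint at epoch {model.best_epoch}")
print(m.to_frame().round(2))
# NMAE is the mean absolute error as a percentage of each target's observed
# range; R^2 is the coefficient of determination in percent.  a_f (overall
# stiffness scale) is consistently easier to recover than b_f (curvature).
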