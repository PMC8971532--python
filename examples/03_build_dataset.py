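"""Sample the design space and assemble a small training corpus.

Latin hypercube sampling over the six design dimensions (LV/RV resize
factors, endo/epi helix angles, a_f, b_f), one forward simulation per
sample, round-robin assignment to a 25-parent geometry library.
"""

from myostiff import build_dataset, lhs_sample, make_parent_library, split

parents = make_parent_library(25, seed=11)
samples = lhs_sample(60, seed=22, n_parents=len(parents))
ds = build_dataset(parents, samples)
split(ds, n_test=10, seed=33)

print(f"corpus: {len(ds)} examples, input width {ds.X.shape[1]}, "
      f"{len(ds.train_indices)}/{len(ds.test_indices)} train/test")
print(f"a_f spans {ds.Y[:, 0].min():.3g} .. {ds.Y[:, 0].max():.3g} kPa, "
      f"b_f spans {ds.Y[:, 1].min():.3g} .. {ds.Y[:, 1].max():.3g}")
# Each 114-wide input row = 12 geometric features + 2 fiber angles +
# 100 EDPVR volumes; the targets are the (a_f, b_f) that generated the curve.
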