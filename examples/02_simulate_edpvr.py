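"""Forward-simulate an end-diastolic pressure-volume relationship (EDPVR).

Builds an idealized rat-scale biventricular geometry, reduces the LV wall to
an equivalent thick-walled cylinder, assigns a four-layer transmural fiber
rule, and inflates the chamber to 30 mmHg in 100 equal pressure steps.
"""

import numpy as np

from myostiff import (MaterialParams, equivalent_cylinder, fiber_layers,
                      geometric_features, inflate, make_parent, resize)

parent = make_parent(seed=1)
geom = resize(parent, f_LV=1.1, f_RV=1.0)
features = geometric_features(geom)
cyl = equivalent_cylinder(geom, features)
fibers = fiber_layers(np.deg2rad(60.0), np.deg2rad(-60.0))

curve = inflate(cyl, fibers, MaterialParams(a_f=5.0, b_f=2.0))
print(f"LV cavity volume (unloaded) V0 = {curve.V0:7.1f} ul")
for p in (6.0, 15.0, 30.0):
    print(f"V({p:4.1f} mmHg) = {curve.volume_at(p):7.1f} ul")
# The volumes are the 100 EDPVR input features the surrogate consumes;
# stiffer fibers (larger a_f) shift every loaded volume downward.
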