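"""Calibrated default parameters of the lever model.

The zero-calcium anchors (mean pore radius ~0.9 nm, mean height ~9 nm,
a several-kT resistance to dilation from 1 to 2.5 nm) pin this
parameter set; the with-calcium behaviour of the model is then
parameter-free.  Values were selected by a grid search within
literature ranges (bending modulus 10-50 kT, tension
0.01-0.5 kT/nm^2, zippering gain 10-40 kT, complex length 10-16 nm,
diameter 2-5 nm) and are frozen here.

kappa = 10 kT and gamma = kappa/13^2 ~ 0.059 kT/nm^2 set the membrane
length scale sqrt(kappa/gamma) = 13 nm; the SNARE-C2B rod is a
14 x 4 nm capsule with a 3.7 nm crowding footprint on the waist.
"""

from .membrane import MembraneParams, ScaffoldParams
from .snares import C2BParams, SnareParams

CALIBRATED = dict(
    mem=MembraneParams(kappa=10.0, gamma=10.0 / 13.0**2),
    scaf=ScaffoldParams(),
    snares=SnareParams(N=4, dG_zip=18.0, rod_footprint=3.7, trans_area=450.0),
    c2b=C2BParams(
        complex_length=14.0,
        complex_diameter=4.0,
        untilted_sets_separation=False,
    ),
)
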