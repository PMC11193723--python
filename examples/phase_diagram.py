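"""A small substrate phase diagram: glucose x lactate at low demand.

Sweeps the kinetic model over a coarse grid of extracellular glucose
and lactate, prints steady glucose influx, signed lactate flux
(negative = uptake) and cytosolic ATP per cell, and saves a heatmap.
"""
from neuroenergetics.kinetics import default_parameters
from neuroenergetics.sweep import (SweepGrid, phase_map_to_csv,
                                   plot_phase_map, run_sweep)

params = default_parameters()
grid = SweepGrid(glc_values=(0.0, 0.25, 1.0, 5.0),
                 lac_values=(0.0, 1.0, 5.0))

pmap = run_sweep(grid, params, "intermediate")
df = phase_map_to_csv([pmap], None)
print(df.to_string(index=False,
                   formatters={"j_glc": "{:.4f}".format,
                               "j_lac": "{:+.4f}".format,
                               "atp": "{:.2f}".format}))
plot_phase_map(pmap, "atp", path="phase_atp_intermediate.png")
print("saved phase_atp_intermediate.png")

# Cells with deficit=True have steady ATP < 1 mM.  Note lactate flux
# switching sign: release (+) when glucose is plentiful, uptake (-)
# when the lactate/glucose ratio is raised by removing glucose.
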