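"""Briggs plume rise: where do elevated stack emissions enter the column?

A buoyant power-plant-like stack injects well above its physical height;
a passive vent does not.  The injection layer determines which grid cell
receives the emission flux.
"""

import numpy as np

from steadypm import EmissionRecord, StackParams, plume_rise
from steadypm.emissions import briggs_rise
from steadypm.fields import CellFields, SynthesisParams, synthesize_archive
from steadypm.grid import GridConfig, RasterPopulation, build_static_grid
from shapely.geometry import Point

cfg = GridConfig(domain_bounds=(0, 0, 8000.0, 8000.0), base_size=4000.0,
                 divisors=(2,), pop_threshold=1e30,
                 layer_tops=(50.0, 150.0, 350.0, 700.0, 1500.0, 3000.0))
grid = build_static_grid(RasterPopulation(np.zeros((2, 2)), 0, 0, 4000.0), cfg)
fields = synthesize_archive(grid, seed=3, params=SynthesisParams(n_hours=120))

cases = {
    "ground-level source (no stack)": None,
    "passive vent, 40 m": StackParams(40.0, 1.0, 288.0, 0.5),
    "warm stack, 80 m": StackParams(80.0, 2.5, 350.0, 10.0),
    "hot buoyant stack, 120 m": StackParams(120.0, 5.0, 450.0, 20.0),
}
for name, stack in cases.items():
    rec = EmissionRecord(Point(4000.0, 4000.0), {"SOx": 100.0}, stack)
    layer = plume_rise(rec, grid, fields)
    if stack is not None:
        i = grid.locate(4000.0, 4000.0)
        dh = briggs_rise(stack, fields.plume_wind_inv[i],
                         fields.plume_wind_m13[i], fields.plume_T[i],
                         fields.plume_s1[i], bool(fields.plume_unstable[i]))
        print(f"{name:32s} rise {dh:7.1f} m -> injection layer {layer}")
    else:
        print(f"{name:32s} {'':14s} -> injection layer {layer}")
print("Layer interfaces (m):", cfg.layer_tops)
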