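"""End-to-end run: 100 short tons/yr of primary PM2.5 from one point source.

Builds the bundled synthetic demo (population-refined grid, synthetic
annual-average field archive, single ground-level point source in the urban
cluster), iterates the solver to steady state, and summarizes the exposure
change.
"""

import tempfile
import os

from steadypm import RunConfig, make_demo, run

with tempfile.TemporaryDirectory() as tmp:
    cfg_path = make_demo(seed=1, outdir=tmp)
    config = RunConfig.from_yaml(cfg_path)
    summary = run(config)

    d = summary["diagnostics"]
    print(f"converged: {d['converged']} after {d['iterations']} iterations "
          f"(dt = {d['dt']:.1f} s)")
    print(f"population-weighted mean total PM2.5 change: "
          f"{summary['population_weighted_total_pm25']:.3e} ug m^-3")
    print(f"area-weighted mean total PM2.5 change:       "
          f"{summary['area_weighted_total_pm25']:.3e} ug m^-3")
    print("The population-weighted change exceeds the area-weighted one "
          "because the source sits in the populated, finely gridded cluster.")
    print("outputs written:", ", ".join(
        os.path.basename(p) for p in summary["outputs"].values()))
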