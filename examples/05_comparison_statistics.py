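"""Model-comparison statistics with area and population weighting.

Compares a 'model' field against a reference using the standard bundle:
mean bias/error, mean fractional bias/error (reported in percent), model
ratio, regression slope/intercept and squared Pearson correlation --
unweighted and population-weighted, as used for exposure-oriented
evaluation.
"""

import numpy as np

from steadypm import compare, normalize_for_comparison

rng = np.random.default_rng(7)
reference = rng.lognormal(mean=0.0, sigma=0.6, size=400)       # "truth"
model = 0.85 * reference + rng.normal(0, 0.12, 400)            # biased model
model = np.clip(model, 1e-3, None)
population = rng.pareto(2.0, 400) * 1e4                        # skewed weights

for label, w in (("unweighted        ", None),
                 ("population-weight.", population)):
    s = compare(reference, model, weights=w)
    print(f"{label} MFB {100 * s.MFB:+6.1f}%  MFE {100 * s.MFE:5.1f}%  "
          f"MR {s.MR:.2f}  S {s.S:.2f}  R2 {s.R2:.3f}")
print("A negative MFB means the model under-predicts the reference on "
      "average; weighting shifts the statistics toward populated locations.")

norm = normalize_for_comparison(model)
print(f"normalized field max = {norm.max():.1f} (largest value scaled to 1, "
      "as used when plotting scenario comparisons)")
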