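"""Paired-comparison statistics and exposure-weighted aggregation.

The bundle of statistics used throughout model evaluation: mean bias and
error, mean fractional bias and error (per-pair denominators), model ratio,
least-squares slope/intercept and squared Pearson correlation, all
optionally weighted (e.g. by population for exposure-relevant comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VariableGrid


class EvaluateError(ValueError):
    pass


@dataclass
class ComparisonStats:
    """Statistics for paired values Y (model) vs X (reference).

    MB/ME are in the units of the data; MFB/MFE are stored as fractions
    (multiply by 100 for the conventional percent rendering); MR is the mean
    per-pair ratio Y/X.  ``n_excluded_fractional`` / ``n_excluded_ratio``
    count pairs dropped from the fractional metrics (X + Y = 0) and from MR
    (X = 0).  With n = 1 the regression fields are NaN and
    ``regression_defined`` is False.  When weights are given, R2 is the
    weighted squared Pearson correlation and ``R2_unweighted`` the plain one.
    """

    MB: float
    ME: float
    MFB: float
    MFE: float
    MR: float
    S: float
    I: float
    R2: float
    n: int
    n_excluded_fractional: int = 0
    n_excluded_ratio: int = 0
    R2_unweighted: float = float("nan")
    regression_defined: bool = True

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("MB", "ME", "MFB", "MFE", "MR", "S", "I", "R2", "n")}

    def __str__(self):
        if not np.isfinite(self.S):
            reg = "regression undefined (n < 2)"
        else:
            reg = f"S={self.S:.3g} I={self.I:.3g} R2={self.R2:.3g}"
        return (f"MB={self.MB:.3g} ME={self.ME:.3g} "
                f"MFB={100 * self.MFB:.1f}% MFE={100 * self.MFE:.1f}% "
                f"MR={self.MR:.3g} {reg} (n={self.n})")


def _wmean(v, w):
    return float(np.sum(w * v) / np.sum(w))


def compare(X, Y, weights=None) -> ComparisonStats:
    """Compute the comparison statistics bundle for Y (model) vs X (reference).

    Pairs with X + Y = 0 are excluded from the fractional metrics and pairs
    with X = 0 from the model ratio; exclusions are tallied on the result.
    When weights are given all means are weighted and the regression is
    weighted least squares.
    """
    x = np.asarray(X, dtype=float).ravel()
    y = np.asarray(Y, dtype=float).ravel()
    if x.size != y.size or x.size < 1:
        raise EvaluateError("X and Y must be equal-length, non-empty")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.size != x.size or np.any(w < 0) or w.sum() <= 0:
            raise EvaluateError("weights must be non-negative with positive sum")
    n = x.size
    mb = _wmean(y - x, w)
    me = _wmean(np.abs(y - x), w)
    denom = y + x
    keep_f = denom != 0
    if np.any(keep_f):
        mfb = _wmean(2.0 * (y - x)[keep_f] / denom[keep_f], w[keep_f])
        mfe = _wmean(2.0 * np.abs(y - x)[keep_f] / denom[keep_f], w[keep_f])
    else:
        mfb = mfe = float("nan")
    keep_r = x != 0
    mr = _wmean(y[keep_r] / x[keep_r], w[keep_r]) if np.any(keep_r) else float("nan")
    if n >= 2:
        xm, ym = _wmean(x, w), _wmean(y, w)
        sxx = float(np.sum(w * (x - xm) ** 2))
        syy = float(np.sum(w * (y - ym) ** 2))
        sxy = float(np.sum(w * (x - xm) * (y - ym)))
        slope = sxy / sxx if sxx > 0 else float("nan")
        intercept = ym - slope * xm
        r2 = sxy ** 2 / (sxx * syy) if sxx > 0 and syy > 0 else float("nan")
        if weights is None:
            r2u = r2
        else:
            xmu, ymu = float(np.mean(x)), float(np.mean(y))
            su = float(np.sum((x - xmu) * (y - ymu)))
            sxxu = float(np.sum((x - xmu) ** 2))
            syyu = float(np.sum((y - ymu) ** 2))
            r2u = su ** 2 / (sxxu * syyu) if sxxu > 0 and syyu > 0 else float("nan")
        reg_def = True
    else:
        slope = intercept = r2 = r2u = float("nan")
        reg_def = False
    return ComparisonStats(
        MB=mb, ME=me, MFB=mfb, MFE=mfe, MR=mr, S=slope, I=intercept, R2=r2,
        n=n, n_excluded_fractional=int(np.sum(~keep_f)),
        n_excluded_ratio=int(np.sum(~keep_r)), R2_unweighted=r2u,
        regression_defined=reg_def)


def weighted_mean(values, grid: VariableGrid, mode: str = "population") -> float:
    """Area- or population-weighted mean of a ground-layer field.

    ``values`` may cover all cells (the ground layer is selected) or just
    the ground-layer cells.  Weights are renormalized over cells with finite
    values.
    """
    v = np.asarray(values, dtype=float).ravel()
    g = grid.ground_cells
    if v.size == grid.n_cells:
        v = v[g]
    elif v.size != g.size:
        raise EvaluateError("values must cover all cells or the ground layer")
    if mode == "area":
        w = grid.area[g]
    elif mode == "population":
        w = grid.population[g]
    else:
        raise EvaluateError(f"unknown weighting mode {mode!r}")
    ok = np.isfinite(v)
    if np.sum(w[ok]) <= 0:
        raise EvaluateError(f"all-zero {mode} weights over defined values")
    return float(np.sum(w[ok] * v[ok]) / np.sum(w[ok]))


def normalize_for_comparison(values) -> np.ndarray:
    """Scale so the largest absolute value equals one (idempotent)."""
    v = np.asarray(values, dtype=float)
    m = float(np.max(np.abs(v)))
    if m == 0:
        raise EvaluateError("cannot normalize an all-zero vector")
    return v / m
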