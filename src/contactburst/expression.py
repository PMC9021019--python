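"""Expression-side computations of the mobilization screen.

Normalization of flow-cytometry eGFP intensities, the smFISH
intensity-to-mRNA calibration line, 20 kb binned genomic trends with a
cross-validated smoothing spline, cell-to-cell variability (CV and
Fano) versus contact probability, and percentage fold-change curves
between genetic backgrounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import UnivariateSpline, interp1d
from scipy.stats import linregress, spearmanr

__all__ = [
    "FlowRecord",
    "CalibrationModel",
    "TrendCurve",
    "normalize_egfp",
    "calibrate_mrna",
    "bin_trend",
    "cv_curve",
    "fano_curve",
    "fold_change_curve",
]

TREND_BIN_BP = 20_000
NORM_WINDOW_BP = 40_000


@dataclass
class FlowRecord:
    """Per-line flow-cytometry record: replicate mean eGFP intensities
    measured on separate days, plus the matched background (reporter-
    free) intensity."""

    line_id: str
    position: int
    orientation: str
    intensities: np.ndarray          # per-day means, length >= 1
    background: float = 0.0
    include: bool = True             # False for control / failed lines

    def __post_init__(self):
        self.intensities = np.atleast_1d(np.asarray(self.intensities, float))
        if self.intensities.size < 1:
            raise ValueError("need >= 1 replicate intensity")
        if np.any(self.intensities < 0):
            raise ValueError("raw intensities must be >= 0")

    @property
    def mean_intensity(self) -> float:
        return float(self.intensities.mean())

    @property
    def median_intensity(self) -> float:
        return float(np.median(self.intensities))


@dataclass
class CalibrationModel:
    """OLS line mapping mean eGFP intensity to mean mRNA count."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def predict(self, intensity):
        return self.slope * np.asarray(intensity, float) + self.intercept


@dataclass
class TrendCurve:
    """Equally spaced binned means with a spline interpolant."""

    bin_centers: np.ndarray
    bin_means: np.ndarray
    bin_sds: np.ndarray
    bin_counts: np.ndarray
    spline: object = field(repr=False, default=None)
    kind: str = "spline"

    def __call__(self, x):
        return self.spline(np.asarray(x, float))

    @property
    def support(self):
        good = self.bin_counts > 0
        return float(self.bin_centers[good].min()), \
            float(self.bin_centers[good].max())


def normalize_egfp(records: Sequence[FlowRecord], promoter_coord: int,
                   window: int = NORM_WINDOW_BP,
                   common_factor: float = 1.0,
                   statistic: str = "mean") -> np.ndarray:
    """Background-subtracted, promoter-window-normalized expression.

    Each line's replicate-average intensity is corrected by subtracting
    the background intensity, divided by the average corrected
    intensity of all lines whose insertion lies within ``window`` bp
    centred on the promoter, and multiplied by ``common_factor``.
    ``statistic`` selects the per-line summary ("mean" or "median"
    across replicate days); the pipeline default is the mean.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    summ = np.array([
        r.mean_intensity if statistic == "mean" else r.median_intensity
        for r in records])
    bg = np.array([r.background for r in records])
    corrected = summ - bg
    if np.any(corrected < 0):
        warnings.warn("negative background-subtracted intensities clipped to 0")
        corrected = np.clip(corrected, 0.0, None)
    pos = np.array([r.position for r in records])
    half = window / 2
    in_window = np.abs(pos - promoter_coord) <= half
    if not in_window.any():
        raise ValueError(f"no lines within {window} bp of the promoter")
    ref = corrected[in_window].mean()
    if ref == 0:
        raise ValueError("window-average intensity is zero")
    return corrected / ref * common_factor


def calibrate_mrna(intensities, fish_means) -> CalibrationModel:
    """Least-squares line predicting mean mRNA per cell from mean eGFP
    intensity, fitted on paired smFISH/flow measurements."""
    x = np.asarray(intensities, float)
    y = np.asarray(fish_means, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired calibration points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: constant intensities")
    res = linregress(x, y)
    return CalibrationModel(res.slope, res.intercept, res.rvalue ** 2, x.size)


def _cv_spline(x, y, w=None):
    """Cubic smoothing spline with the smoothing parameter chosen by
    leave-one-out cross-validation over a log grid."""
    n = x.size
    var = max(y.var(), 1e-12)
    grid = var * n * np.logspace(-4, 1, 12)
    best, best_err = None, np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in grid:
            err = 0.0
            ok = True
            for i in range(n):
                idx = np.arange(n) != i
                try:
                    sp = UnivariateSpline(x[idx], y[idx], k=3,
                                          s=s * (n - 1) / n)
                    err += (sp(x[i]) - y[i]) ** 2
                except Exception:
                    ok = False
                    break
            if ok and err < best_err:
                best_err, best = err, s
    s_opt = best if best is not None else var * n
    return UnivariateSpline(x, y, k=3, s=s_opt)


def bin_trend(positions, values, region: tuple,
              bin_bp: int = TREND_BIN_BP) -> TrendCurve:
    """Equally spaced genomic bins with per-bin mean/s.d./count and a
    smoothing-spline interpolant through the nonempty bin means.  With
    fewer than 4 nonempty bins the interpolant falls back to piecewise
    linear."""
    positions = np.asarray(positions, float)
    values = np.asarray(values, float)
    lo, hi = region
    if np.any((positions < lo) | (positions >= hi)):
        raise ValueError("positions outside region")
    edges = np.arange(lo, hi + bin_bp, bin_bp)
    centers = edges[:-1] + bin_bp / 2
    nb = centers.size
    means = np.full(nb, np.nan)
    sds = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    which = np.clip(((positions - lo) // bin_bp).astype(int), 0, nb - 1)
    for b in range(nb):
        sel = which == b
        counts[b] = sel.sum()
        if counts[b]:
            means[b] = values[sel].mean()
            sds[b] = values[sel].std(ddof=1) if counts[b] > 1 else 0.0
    good = counts > 0
    x, y = centers[good], means[good]
    if good.sum() >= 4:
        spline = _cv_spline(x, y)
        kind = "spline"
    else:
        spline = interp1d(x, y, kind="linear", bounds_error=False,
                          fill_value=(y[0], y[-1])) if good.sum() > 1 else \
            (lambda q, y0=y[0]: np.full_like(np.asarray(q, float), y0))
        kind = "linear"
    return TrendCurve(centers, means, sds, counts, spline, kind)


def cv_curve(p_c, distributions, histogram: bool = True):
    """Per-line coefficient of variation against contact probability.

    ``distributions`` is a list (parallel to ``p_c``) of either count
    histograms (``histogram=True``: index = mRNA count, value = number
    of cells) or raw per-cell count arrays.  Returns ``(p_c, cv,
    rank_corr, p_value)`` with zero-mean lines dropped (warned).
    """
    p_c = np.asarray(p_c, float)
    cvs = np.full(p_c.size, np.nan)
    for i, dist in enumerate(distributions):
        dist = np.asarray(dist, float)
        if histogram:
            tot = dist.sum()
            m = np.arange(dist.size)
            mean = (dist @ m) / tot
            var = (dist @ (m - mean) ** 2) / tot
        else:
            mean = dist.mean()
            var = dist.var(ddof=0)
        if mean > 0:
            cvs[i] = np.sqrt(var) / mean
    keep = np.isfinite(cvs)
    if not keep.all():
        warnings.warn(f"{(~keep).sum()} zero-mean lines excluded from CV curve")
    if keep.sum() >= 3 and np.unique(cvs[keep]).size > 1:
        rho, pval = spearmanr(p_c[keep], cvs[keep])
    else:
        rho, pval = 0.0, 1.0
    return p_c[keep], cvs[keep], float(rho), float(pval)


def fano_curve(p_c, distributions, histogram: bool = True):
    """Per-line Fano factor (variance/mean) against contact probability;
    the sign of its trend separates on-rate modulation (Fano falls with
    contact) from initiation-rate modulation (Fano rises).  Returns
    ``(p_c, fano, rank_corr)``."""
    p_c = np.asarray(p_c, float)
    fanos = np.full(p_c.size, np.nan)
    for i, dist in enumerate(distributions):
        dist = np.asarray(dist, float)
        if histogram:
            tot = dist.sum()
            m = np.arange(dist.size)
            mean = (dist @ m) / tot
            var = (dist @ (m - mean) ** 2) / tot
        else:
            mean = dist.mean()
            var = dist.var(ddof=0)
        if mean > 0:
            fanos[i] = var / mean
    keep = np.isfinite(fanos)
    if keep.sum() >= 3 and np.unique(fanos[keep]).size > 1:
        rho, _ = spearmanr(p_c[keep], fanos[keep])
    else:
        rho = 0.0
    return p_c[keep], fanos[keep], float(rho)


def fold_change_curve(trend_a: TrendCurve, trend_b: TrendCurve,
                      grid) -> np.ndarray:
    """Percentage fold change ``100 * (b - a) / a`` between two trend
    interpolants on ``grid``; NaN where the reference trend is <= 0."""
    grid = np.asarray(grid, float)
    a = np.asarray(trend_a(grid), float)
    b = np.asarray(trend_b(grid), float)
    out = np.full(grid.shape, np.nan)
    ok = a > 0
    out[ok] = 100.0 * (b[ok] - a[ok]) / a[ok]
    return out
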