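"""Maximum-likelihood fitting of the bursting models to screen data.

The phenomenological (Hill-modulated) and apparent (reduced
mechanistic) two-state models are fitted *simultaneously* to per-line
mean expression levels and to per-line smFISH mRNA-count distributions:
the composite log-likelihood is the sum of a Gaussian term for the
replicate means (standard error = replicate s.d. / sqrt(replicates))
and a multinomial term for each count histogram under the model's
stationary pmf.  Profile likelihoods give confidence intervals, and
nested model variants are compared with likelihood-ratio tests.

All rates are fitted on a log scale with delta fixed to 1 (time unit =
mRNA lifetime); optimization is multi-start Nelder-Mead and fully
deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .mechanistic import apparent_kon
from .params import HillParams, ParameterError, TelegraphParams
from .telegraph import hill_response, telegraph_pmf

__all__ = [
    "ScreenDataset",
    "FishLine",
    "FishDataset",
    "PhenomModel",
    "ApparentModel",
    "FitResult",
    "composite_loglik",
    "fit_phenomenological",
    "fit_apparent",
    "fit_variant",
    "profile_ci",
    "lrt_compare",
    "predict_weak_enhancer",
    "VARIANT_FREE_PARAMS",
]


# ---------------------------------------------------------------------------
# datasets

@dataclass
class ScreenDataset:
    """Per-line screen table: insertion position, orientation, contact
    probability, replicate-mean mRNA estimate and its spread."""

    line_id: list
    position: np.ndarray
    orientation: np.ndarray
    p_c: np.ndarray
    mean: np.ndarray
    rep_sd: np.ndarray
    n_rep: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, int)
        self.orientation = np.asarray(self.orientation)
        self.p_c = np.asarray(self.p_c, float)
        self.mean = np.asarray(self.mean, float)
        self.rep_sd = np.asarray(self.rep_sd, float)
        self.n_rep = np.asarray(self.n_rep, int)
        if np.any((self.p_c < 0) | (self.p_c > 1)):
            raise ValueError("contact probabilities must lie in [0, 1]")
        if np.any(self.n_rep < 1):
            raise ValueError("replicate count must be >= 1")

    def __len__(self):
        return len(self.line_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "line_id": self.line_id, "position": self.position,
            "orientation": self.orientation, "p_c": self.p_c,
            "mean": self.mean, "rep_sd": self.rep_sd, "n_rep": self.n_rep})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.8g")

    @classmethod
    def from_tsv(cls, path) -> "ScreenDataset":
        df = pd.read_csv(path, sep="\t")
        return cls(df["line_id"].tolist(), df["position"].to_numpy(),
                   df["orientation"].to_numpy(), df["p_c"].to_numpy(),
                   df["mean"].to_numpy(), df["rep_sd"].to_numpy(),
                   df["n_rep"].to_numpy())


@dataclass
class FishLine:
    """smFISH histogram for one line: ``histogram[m]`` = number of cells
    with ``m`` mRNAs (technical replicates pooled)."""

    line_id: str
    p_c: float
    histogram: np.ndarray

    def __post_init__(self):
        self.histogram = np.asarray(self.histogram, float)
        if self.histogram.sum() < 1:
            raise ValueError(f"line {self.line_id}: need >= 1 cell")
        if np.any(self.histogram < 0):
            raise ValueError("cell counts must be >= 0")

    @property
    def n_cells(self) -> float:
        return float(self.histogram.sum())


@dataclass
class FishDataset:
    lines: list = field(default_factory=list)

    def __len__(self):
        return len(self.lines)

    def to_cells_csv(self, path) -> None:
        """Per-cell CSV (line_id, cell_id, count), the acquisition-level
        format."""
        rows = []
        for ln in self.lines:
            cell = 0
            for m, k in enumerate(ln.histogram):
                for _ in range(int(k)):
                    rows.append((ln.line_id, cell, m))
                    cell += 1
        pd.DataFrame(rows, columns=["line_id", "cell_id", "count"]).to_csv(
            path, index=False)

    @classmethod
    def from_cells_csv(cls, path, p_c_by_line: dict) -> "FishDataset":
        df = pd.read_csv(path)
        lines = []
        for lid, grp in df.groupby("line_id", sort=True):
            counts = grp["count"].to_numpy(int)
            hist = np.bincount(counts)
            lines.append(FishLine(str(lid), float(p_c_by_line[lid]), hist))
        return cls(lines)


# ---------------------------------------------------------------------------
# models

@dataclass(frozen=True)
class PhenomModel:
    """Phenomenological two-state model: k_on(p) is a Hill function of
    contact probability; k_off, mu, delta are shared across lines."""

    kon0: float
    kon1: float
    k_off: float
    mu: float
    c: float
    h: float
    delta: float = 1.0
    model_id = "phenomenological"

    def kon(self, p):
        return hill_response(p, HillParams(self.kon0, self.kon1,
                                           self.c, self.h))

    def mean(self, p):
        k = np.asarray(self.kon(p), float)
        return self.mu * k / (self.delta * (k + self.k_off))

    def pmf(self, p, m_min: int = 0, tail_mass: float = 1e-8):
        tp = TelegraphParams(float(self.kon(p)), self.k_off, self.mu,
                             self.delta)
        return telegraph_pmf(tp, tail_mass, m_min=m_min)


@dataclass(frozen=True)
class ApparentModel:
    """Apparent two-state model reduced from the mechanistic chain:
    k_on(p) interpolates between kon_basal and kon_enh through the
    completed-step occupancy of an n-step chain with forward/backward
    ratio beta."""

    kon_basal: float
    kon_enh: float
    beta: float
    n: int
    k_off: float
    mu: float
    delta: float = 1.0
    model_id = "apparent"

    def kon(self, p):
        return apparent_kon(p, self.beta, self.n, self.kon_basal,
                            self.kon_enh)

    def mean(self, p):
        k = np.asarray(self.kon(p), float)
        return self.mu * k / (self.delta * (k + self.k_off))

    def pmf(self, p, m_min: int = 0, tail_mass: float = 1e-8):
        tp = TelegraphParams(float(self.kon(p)), self.k_off, self.mu,
                             self.delta)
        return telegraph_pmf(tp, tail_mass, m_min=m_min)


def _model_params(model) -> dict:
    keys = (("kon0", "kon1", "k_off", "mu", "c", "h")
            if isinstance(model, PhenomModel)
            else ("kon_basal", "kon_enh", "beta", "n", "k_off", "mu"))
    return {k: getattr(model, k) for k in keys}


# ---------------------------------------------------------------------------
# composite likelihood

@dataclass
class LoglikParts:
    total: float
    gaussian: float
    multinomial: float


def _screen_se(screen: ScreenDataset, error_model: str,
               se_floor: float) -> np.ndarray:
    """Standard error of each line's replicate mean.

    ``pooled`` (default): a single relative day-to-day noise level is
    estimated by pooling the replicate CVs of all expressing lines and
    applied as ``se = cv_pool * mean / sqrt(n_rep)``.  ``per_line``
    uses each line's own replicate s.d.; with few replicates this makes
    the standardized residuals heavy-tailed (chance low-s.d. lines get
    enormous weight), so pooling is the calibrated default under
    multiplicative replicate noise.
    """
    if error_model == "per_line":
        se = screen.rep_sd / np.sqrt(screen.n_rep)
    elif error_model == "pooled":
        ok = screen.mean > 0
        rel2 = np.zeros(0)
        if ok.any():
            rel2 = (screen.rep_sd[ok] / screen.mean[ok]) ** 2
        cv_pool = np.sqrt(rel2.mean()) if rel2.size else 0.0
        se = cv_pool * np.abs(screen.mean) / np.sqrt(screen.n_rep)
    else:
        raise ValueError(f"unknown error model {error_model!r}")
    # relative floor keeps noise-free data well-conditioned for the
    # optimizer (0.1% of the observed mean) without affecting real noise
    return np.maximum(se, np.maximum(1e-3 * np.abs(screen.mean), se_floor))


def composite_loglik(model, screen: Optional[ScreenDataset],
                     fish: Optional[FishDataset],
                     fish_weight: float = 1.0,
                     se_floor: float = 1e-6,
                     tail_mass: float = 1e-8,
                     error_model: str = "pooled") -> LoglikParts:
    """Joint log-likelihood of screen means and smFISH histograms.

    Gaussian component: each line's observed mean given the model mean
    at its contact probability, with standard error from
    :func:`_screen_se` (pooled relative replicate noise by default).
    Multinomial component: each histogram under the model pmf, extended
    automatically to cover the largest observed count.  ``fish_weight``
    rescales the multinomial term (1 = the natural equally weighted
    composition).
    """
    gauss = 0.0
    if screen is not None and len(screen):
        mu_model = np.asarray(model.mean(screen.p_c), float)
        se = _screen_se(screen, error_model, se_floor)
        resid = screen.mean - mu_model
        gauss = float(np.sum(-0.5 * np.log(2 * np.pi * se ** 2)
                             - 0.5 * (resid / se) ** 2))
    multi = 0.0
    if fish is not None and len(fish):
        for ln in fish.lines:
            pmf = model.pmf(ln.p_c, m_min=ln.histogram.size - 1,
                            tail_mass=tail_mass)
            logp = np.log(np.maximum(pmf[: ln.histogram.size], 1e-300))
            multi += float(ln.histogram @ logp)
    total = gauss + fish_weight * multi
    return LoglikParts(total, gauss, multi)


# ---------------------------------------------------------------------------
# optimization

_BOUNDS = {
    "kon0": (1e-3, 1e3), "kon1": (1e-3, 1e3),
    "kon_basal": (1e-3, 1e3), "kon_enh": (1e-3, 1e3),
    "k_off": (1e-3, 1e3), "mu": (1e-3, 1e3),
    "c": (0.01, 1.0), "h": (0.5, 10.0),
    "beta": (1e-2, 1e3),
}

PHENOM_FREE = ("kon0", "kon1", "k_off", "mu", "c", "h")
APPARENT_FREE = ("kon_basal", "kon_enh", "beta", "k_off", "mu")

VARIANT_FREE_PARAMS = {
    "beta_only": ("beta",),
    "kon_enh_only": ("kon_enh",),
    "both": ("beta", "kon_enh"),
    "all_free": APPARENT_FREE,
}


@dataclass
class FitResult:
    """Outcome of a multi-start fit; ``params`` holds every model
    parameter (free and fixed), ``extras`` any model-specific
    diagnostics (e.g. the per-n likelihood profile)."""

    model_id: str
    params: dict
    free_names: tuple
    loglik: float
    converged: bool
    n_starts: int
    seed: int
    start_logliks: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def build(self):
        if self.model_id == "phenomenological":
            return PhenomModel(**{k: self.params[k] for k in PHENOM_FREE})
        return ApparentModel(
            **{k: self.params[k] for k in APPARENT_FREE}, n=self.params["n"])

    def report(self) -> dict:
        out = {"model": self.model_id, "loglik": self.loglik,
               "converged": self.converged, "seed": self.seed,
               "n_starts": self.n_starts}
        out.update({f"param_{k}": v for k, v in self.params.items()})
        return out


def _neg_loglik_factory(model_id, free_names, fixed, screen, fish,
                        fish_weight, error_model="pooled"):
    def build(x_log):
        vals = dict(fixed)
        vals.update({k: float(np.exp(v)) for k, v in zip(free_names, x_log)})
        if model_id == "phenomenological":
            return PhenomModel(kon0=vals["kon0"], kon1=vals["kon1"],
                               k_off=vals["k_off"], mu=vals["mu"],
                               c=vals["c"], h=vals["h"])
        return ApparentModel(kon_basal=vals["kon_basal"],
                             kon_enh=vals["kon_enh"], beta=vals["beta"],
                             n=int(vals["n"]), k_off=vals["k_off"],
                             mu=vals["mu"])

    def neg_ll(x_log):
        try:
            model = build(x_log)
            return -composite_loglik(model, screen, fish, fish_weight,
                                      error_model=error_model).total
        except (ParameterError, RuntimeError, FloatingPointError):
            return 1e12

    return build, neg_ll


def _multistart_minimize(neg_ll, free_names, x0s, maxfev):
    log_bounds = [tuple(np.log(_BOUNDS[k])) for k in free_names]
    best = None
    traces = []
    for x0 in x0s:
        simplex = np.vstack([x0, x0 + 0.4 * np.eye(len(x0))])
        simplex = np.clip(simplex, [b[0] for b in log_bounds],
                          [b[1] for b in log_bounds])
        res = minimize(neg_ll, x0, method="Nelder-Mead", bounds=log_bounds,
                       options={"maxfev": maxfev, "xatol": 1e-3,
                                "fatol": 1e-5,
                                "initial_simplex": simplex})
        traces.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    # polish the winner with a fresh local simplex
    res = minimize(neg_ll, best.x, method="Nelder-Mead", bounds=log_bounds,
                   options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-7})
    if res.fun <= best.fun:
        best = res
    return best, traces


def _draw_starts(rng, free_names, n_starts, extra=()):
    starts = [np.array(e) for e in extra]
    for _ in range(n_starts):
        starts.append(np.array([
            rng.uniform(*np.log(_BOUNDS[k])) for k in free_names]))
    return starts


def _heuristic_start_phenom(screen):
    """Data-driven start: saturating mean sets mu/k_off scale, low-p
    lines set the basal level."""
    top = np.percentile(screen.mean, 95) if len(screen) else 10.0
    top = max(top, 0.1)
    return np.log(np.clip(
        [0.02, 1.0, 1.0, 2.0 * top, 0.2, 2.0],
        [_BOUNDS[k][0] for k in PHENOM_FREE],
        [_BOUNDS[k][1] for k in PHENOM_FREE]))


def fit_phenomenological(screen: ScreenDataset, fish: FishDataset,
                         n_starts: int = 32, seed: int = 0,
                         fish_weight: float = 1.0,
                         error_model: str = "pooled",
                         maxfev: int = 2000) -> FitResult:
    """Multi-start ML fit of the phenomenological two-state model over
    (kon0, kon1, k_off, mu, c, h) with delta fixed to 1.

    Starts are log-uniform within bounds plus one data-driven start;
    the best start is polished and returned.  Deterministic given
    ``seed``.  ``extras['h_identifiable']`` is False when the fitted
    Hill response is essentially flat (kon1 ~ kon0), in which case the
    exponent is meaningless.
    """
    if len(screen) < 6:
        warnings.warn("fewer than 6 lines: Hill parameters are likely "
                      "unidentifiable")
    rng = np.random.default_rng(seed)
    build, neg_ll = _neg_loglik_factory(
        "phenomenological", PHENOM_FREE, {}, screen, fish, fish_weight,
        error_model)
    x0s = _draw_starts(rng, PHENOM_FREE, n_starts,
                       extra=[_heuristic_start_phenom(screen)])
    best, traces = _multistart_minimize(neg_ll, PHENOM_FREE, x0s, maxfev)
    model = build(best.x)
    params = _model_params(model)
    flat = (params["kon1"] - params["kon0"]) <= 1e-3 * max(
        params["kon1"], 1e-12)
    if not flat:
        # flat h-profile probe: vary h alone around the optimum
        base = -best.fun
        lls = []
        for fac in (0.5, 2.0):
            h_try = float(np.clip(params["h"] * fac, *_BOUNDS["h"]))
            x_try = best.x.copy()
            x_try[PHENOM_FREE.index("h")] = np.log(h_try)
            lls.append(-neg_ll(x_try))
        flat = max(abs(base - ll) for ll in lls) < 1e-3
    if flat:
        warnings.warn("Hill exponent unidentifiable: response is flat")
    return FitResult("phenomenological", params, PHENOM_FREE,
                     -best.fun, bool(np.isfinite(best.fun)),
                     len(x0s), seed, traces,
                     extras={"h_identifiable": not flat,
                             "fish_weight": fish_weight,
                             "error_model": error_model})


def fit_apparent(screen: ScreenDataset, fish: FishDataset,
                 n_grid: Iterable[int] = range(1, 11),
                 n_starts: int = 8, seed: int = 0,
                 fish_weight: float = 1.0,
                 error_model: str = "pooled",
                 maxfev: int = 1200) -> FitResult:
    """ML fit of the apparent two-state model: for each integer step
    count n in ``n_grid`` the continuous parameters (kon_basal,
    kon_enh, beta, k_off, mu) are maximized; the best n wins.  The
    per-n log-likelihood profile is kept in ``extras['n_profile']`` for
    the integer confidence set on n."""
    n_grid = [int(n) for n in n_grid]
    if any(n < 1 for n in n_grid):
        raise ValueError("n_grid must contain integers >= 1")
    rng = np.random.default_rng(seed)
    top = np.percentile(screen.mean, 95) if len(screen) else 10.0
    heuristic = np.log(np.clip(
        [0.02, 1.0, 2.0, 1.0, 2.0 * max(top, 0.1)],
        [_BOUNDS[k][0] for k in APPARENT_FREE],
        [_BOUNDS[k][1] for k in APPARENT_FREE]))
    base_starts = _draw_starts(rng, APPARENT_FREE, n_starts,
                               extra=[heuristic])
    n_profile = {}
    per_n = {}
    warm = None
    for n in n_grid:
        build, neg_ll = _neg_loglik_factory(
            "apparent", APPARENT_FREE, {"n": n}, screen, fish, fish_weight,
            error_model)
        x0s = list(base_starts) + ([warm] if warm is not None else [])
        best, traces = _multistart_minimize(neg_ll, APPARENT_FREE, x0s,
                                            maxfev)
        n_profile[n] = -best.fun
        per_n[n] = (best, traces, neg_ll)
        warm = best.x.copy()
    # refine the leading candidates so the n-selection is not decided by
    # an under-converged inner optimization
    leaders = sorted(n_profile, key=n_profile.get, reverse=True)[:3]
    for n in leaders:
        bst, traces, neg_ll = per_n[n]
        res = minimize(neg_ll, bst.x, method="Nelder-Mead",
                       bounds=[tuple(np.log(_BOUNDS[k]))
                               for k in APPARENT_FREE],
                       options={"maxfev": 2 * maxfev, "xatol": 1e-5,
                                "fatol": 1e-9})
        if res.fun < bst.fun:
            per_n[n] = (res, traces, neg_ll)
            n_profile[n] = -res.fun
    n_best = max(n_profile, key=n_profile.get)
    best, traces, _ = per_n[n_best]
    build, _ = _neg_loglik_factory("apparent", APPARENT_FREE,
                                   {"n": n_best}, screen, fish, fish_weight,
                                   error_model)
    model = build(best.x)
    params = _model_params(model)
    return FitResult("apparent", params, APPARENT_FREE, -best.fun,
                     bool(np.isfinite(best.fun)), len(base_starts), seed,
                     traces, extras={"n_profile": n_profile,
                                     "fish_weight": fish_weight,
                                     "error_model": error_model})


def fit_variant(screen: ScreenDataset, fish: Optional[FishDataset],
                full_params: dict, variant: str,
                n_starts: int = 8, seed: int = 0,
                fish_weight: float = 1.0,
                error_model: str = "pooled",
                maxfev: int = 1200) -> FitResult:
    """Refit the apparent model to a new dataset with only the
    ``variant`` parameters free and the rest pinned to ``full_params``
    (the best fit to the full-length-enhancer data); ``n`` stays fixed
    throughout."""
    if variant not in VARIANT_FREE_PARAMS:
        raise ValueError(f"unknown variant {variant!r}")
    free = VARIANT_FREE_PARAMS[variant]
    fixed = {k: full_params[k] for k in APPARENT_FREE if k not in free}
    fixed["n"] = int(full_params["n"])
    rng = np.random.default_rng(seed)
    build, neg_ll = _neg_loglik_factory("apparent", free, fixed, screen,
                                        fish, fish_weight, error_model)
    extra = [np.array([np.log(full_params[k]) for k in free])]
    x0s = _draw_starts(rng, free, n_starts, extra=extra)
    best, traces = _multistart_minimize(neg_ll, free, x0s, maxfev)
    model = build(best.x)
    params = _model_params(model)
    return FitResult("apparent", params, free, -best.fun,
                     bool(np.isfinite(best.fun)), len(x0s), seed, traces,
                     extras={"variant": variant,
                             "fish_weight": fish_weight,
                             "error_model": error_model})


# ---------------------------------------------------------------------------
# profile likelihood and model comparison

def profile_ci(best: FitResult, param: str, screen: ScreenDataset,
               fish: Optional[FishDataset], level: float = 0.95,
               step_factor: float = 1.08, max_steps: int = 80,
               maxfev: int = 500):
    """Profile-likelihood confidence interval.

    For a continuous parameter the profile walks multiplicatively away
    from the MLE, re-optimizing all other free parameters (warm-started
    from the neighbouring profile point), until twice the log-likelihood
    drop exceeds the chi-square(1) threshold; the crossing is located
    by linear interpolation.  For the integer step count ``n`` the
    interval is the set of n whose profile likelihood is within the
    threshold.  Ends that hit a parameter bound are returned at the
    bound (half-open interval) with a warning.
    """
    if not best.converged:
        raise ValueError("cannot profile a non-converged fit")
    thr = chi2.ppf(level, 1)
    fish_weight = best.extras.get("fish_weight", 1.0)
    error_model = best.extras.get("error_model", "pooled")
    if param == "n":
        prof = best.extras.get("n_profile")
        if not prof:
            raise ValueError("fit carries no per-n profile")
        llmax = max(prof.values())
        inside = [n for n, ll in prof.items() if 2 * (llmax - ll) <= thr]
        return (min(inside), max(inside))

    free = tuple(k for k in best.free_names if k != param)
    fixed_base = {k: v for k, v in best.params.items()
                  if k not in free and k != param}
    mle = best.params[param]
    llmax = best.loglik
    lo_b, hi_b = _BOUNDS[param]

    def profile_ll(value, warm_x):
        fixed = dict(fixed_base, **{param: value})
        build, neg_ll = _neg_loglik_factory(best.model_id, free, fixed,
                                            screen, fish, fish_weight,
                                            error_model)
        if not free:          # nothing left to re-optimize
            return -neg_ll(np.empty(0)), warm_x
        log_bounds = [tuple(np.log(_BOUNDS[k])) for k in free]
        simplex = np.vstack([warm_x, warm_x + 0.1 * np.eye(len(warm_x))])
        simplex = np.clip(simplex, [b[0] for b in log_bounds],
                          [b[1] for b in log_bounds])
        res = minimize(neg_ll, warm_x, method="Nelder-Mead",
                       bounds=log_bounds,
                       options={"maxfev": maxfev, "xatol": 1e-5,
                                "fatol": 1e-9,
                                "initial_simplex": simplex})
        return -res.fun, res.x

    ends = []
    for direction in (-1, 1):
        x_warm = np.array([np.log(best.params[k]) for k in free])
        prev_val, prev_drop = mle, 0.0
        bound = lo_b if direction < 0 else hi_b
        end = bound
        hit_bound = True
        for _ in range(max_steps):
            val = prev_val * step_factor ** direction
            if (direction < 0 and val <= lo_b) or \
               (direction > 0 and val >= hi_b):
                val = bound
            ll, x_warm = profile_ll(val, x_warm)
            drop = max(2 * (llmax - ll), 0.0)
            if drop >= thr:
                # the drop is locally quadratic in the log parameter, so
                # interpolate the crossing linearly in sqrt(drop)
                s0, s1 = np.sqrt(prev_drop), np.sqrt(drop)
                t = (np.sqrt(thr) - s0) / (s1 - s0) if s1 > s0 else 1.0
                end = float(np.exp(np.log(prev_val)
                                   + t * (np.log(val) - np.log(prev_val))))
                hit_bound = False
                break
            prev_val, prev_drop = val, drop
            if val == bound:
                break
        if hit_bound:
            warnings.warn(
                f"profile for {param} reached the parameter bound "
                f"{bound:g} without crossing: interval is half-open")
        ends.append(end)
    return (min(ends), max(ends))


def lrt_compare(reference: FitResult, variants: Sequence[FitResult],
                alpha: float = 0.05, tol: float = 1e-3) -> pd.DataFrame:
    """Likelihood-ratio comparison of nested variants against the
    all-parameters-free reference fit.

    Returns one row per variant with the statistic
    ``2*(ll_ref - ll_variant)``, its degrees of freedom (difference in
    free-parameter count) and chi-square p-value; the selected variant
    is the most constrained one not rejected at ``alpha``.
    """
    rows = []
    for v in variants:
        stat = 2.0 * (reference.loglik - v.loglik)
        if stat < -tol:
            raise RuntimeError(
                f"variant {v.extras.get('variant')} exceeds the reference "
                f"likelihood by {-stat/2:.4g}: reference optimizer failure")
        stat = max(stat, 0.0)
        df = len(reference.free_names) - len(v.free_names)
        pval = float(chi2.sf(stat, df)) if df > 0 else 1.0
        rows.append({"variant": v.extras.get("variant", "?"),
                     "n_free": len(v.free_names), "loglik": v.loglik,
                     "statistic": stat, "df": df, "p_value": pval})
    table = pd.DataFrame(rows)
    accepted = table[table["p_value"] > alpha]
    selected = (accepted.sort_values(["n_free", "p_value"],
                                     ascending=[True, False])
                .iloc[0]["variant"] if len(accepted) else "all_free")
    table.attrs["selected"] = selected
    table["selected"] = table["variant"] == selected
    return table


def predict_weak_enhancer(full_fit, mode: str, factor: float,
                          p_grid=None):
    """Predicted mean-expression curve for a weakened enhancer.

    ``mode='scale_kon_enh'`` multiplies the enhanced on rate by
    ``factor`` (conserves the shape of the response, lowers its
    plateau); ``mode='scale_beta'`` multiplies the regulatory
    forward/backward ratio (shifts the sensitive region of contact
    probabilities).  Returns ``(p_grid, mean_curve)``.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    model = full_fit.build() if isinstance(full_fit, FitResult) else full_fit
    if not isinstance(model, ApparentModel):
        raise ValueError("weak-enhancer prediction requires the apparent "
                         "two-state model")
    if p_grid is None:
        p_grid = np.linspace(0.0, 1.0, 101)
    p_grid = np.asarray(p_grid, float)
    if mode == "scale_kon_enh":
        scaled = replace(model, kon_enh=model.kon_enh * factor)
    elif mode == "scale_beta":
        scaled = replace(model, beta=model.beta * factor)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return p_grid, np.asarray(scaled.mean(p_grid), float)
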