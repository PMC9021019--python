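"""Steady state of the two-state (telegraph) promoter model and the
Hill-function coupling of its on rate to enhancer contact probability.

The promoter switches OFF -> ON at ``k_on`` and ON -> OFF at ``k_off``;
transcription initiates at ``mu`` while ON and mRNA decays at ``delta``.
The stationary mRNA-count distribution is obtained by solving the
truncated chemical master equation as a banded linear system, which is
exact up to truncation and fast enough to sit inside a likelihood.  The
classical beta-Poisson closed form (a confluent-hypergeometric series)
is provided purely as an independent cross-check.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
from numba import njit
from scipy.special import gammaln, hyp1f1

from .params import HillParams, ParameterError, TelegraphParams

__all__ = [
    "hill_response",
    "telegraph_mean",
    "telegraph_variance",
    "telegraph_fano",
    "telegraph_pmf",
    "telegraph_pmf_closed_form",
    "telegraph_cv",
    "apply_variant",
    "total_variation",
    "ModulationVariant",
]

ModulationVariant = Literal["on_rate", "off_rate", "initiation_rate"]


def hill_response(p, hp: HillParams):
    """On rate as a Hill function of contact probability ``p``:
    ``kon0 + (kon1 - kon0) * p**h / (c**h + p**h)``.

    Accepts scalars or arrays; continuous and non-decreasing in ``p``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ParameterError("contact probability must lie in [0, 1]")
    ph = np.power(p, hp.h)
    out = hp.kon0 + (hp.kon1 - hp.kon0) * ph / (hp.c ** hp.h + ph)
    return float(out) if out.ndim == 0 else out


def telegraph_mean(tp: TelegraphParams) -> float:
    """Analytic stationary mean: ``mu * k_on / (delta * (k_on + k_off))``."""
    s = tp.k_on + tp.k_off
    if s == 0:
        if tp.mu == 0:
            return 0.0
        raise ParameterError("k_on + k_off = 0 with mu > 0: promoter state "
                             "is frozen and the mean is initial-state "
                             "dependent")
    return tp.mu * tp.k_on / (tp.delta * s)


def telegraph_fano(tp: TelegraphParams) -> float:
    """Stationary Fano factor ``1 + mu*k_off / ((k_on+k_off)*(k_on+k_off+delta))``."""
    s = tp.k_on + tp.k_off
    if s == 0:
        return 1.0
    return 1.0 + tp.mu * tp.k_off / (s * (s + tp.delta))


def telegraph_variance(tp: TelegraphParams) -> float:
    return telegraph_mean(tp) * telegraph_fano(tp)


@njit(cache=True)
def _gth_banded(band: np.ndarray, b: int) -> np.ndarray:
    """Stationary vector of a banded CTMC generator by GTH elimination.

    ``band[u, i] = Q[i, i + u - b]`` holds the rate from state ``i`` to
    state ``i + u - b`` (the diagonal row ``u = b`` is unused).  GTH is
    subtraction-free, hence unconditionally stable, and its fill-in
    stays inside the band.  Requires every state ``k > 0`` to have a
    positive total rate toward lower-indexed states.
    """
    N = band.shape[1]
    S = np.empty(N)
    for k in range(N - 1, 0, -1):
        lo = max(0, k - b)
        s = 0.0
        for j in range(lo, k):
            s += band[b + j - k, k]
        S[k] = s
        for i in range(lo, k):
            qik = band[b + k - i, i]
            if qik > 0.0:
                for j in range(lo, k):
                    if j != i:
                        band[b + j - i, i] += qik * band[b + j - k, k] / s
    x = np.zeros(N)
    x[0] = 1.0
    total = 1.0
    for k in range(1, N):
        lo = max(0, k - b)
        acc = 0.0
        for i in range(lo, k):
            acc += x[i] * band[b + k - i, i]
        xk = acc / S[k]
        x[k] = xk
        total += xk
        if total > 1e280:          # renormalize to dodge overflow
            inv = 1.0 / total
            for i in range(k + 1):
                x[i] *= inv
            total = 1.0
    return x / total


def _stationary_banded(tp: TelegraphParams, M: int) -> np.ndarray:
    """Stationary distribution of the truncated telegraph CME via GTH.

    States are interleaved as ``idx = 2*m + s`` (s=0 OFF, s=1 ON),
    m = 0..M, giving a banded generator of bandwidth 2.  When
    ``k_off = 0`` the OFF layer is transient and the recurrent chain is
    the ON-only birth-death process, solved with the same routine.
    """
    k_on, k_off, mu, delta = tp.k_on, tp.k_off, tp.mu, tp.delta
    m = np.arange(M + 1, dtype=float)
    if k_off == 0.0:
        band = np.zeros((3, M + 1))
        band[2, :-1] = mu            # birth, reflected at M
        band[0, 1:] = m[1:] * delta  # death
        pmf = _gth_banded(band, 1)
        joint = np.zeros(2 * (M + 1))
        joint[1::2] = pmf
        return joint
    N = 2 * (M + 1)
    band = np.zeros((5, N))
    off_idx = 2 * np.arange(M + 1)
    on_idx = off_idx + 1
    band[3, off_idx] = k_on          # OFF(m) -> ON(m), offset +1
    band[1, on_idx] = k_off          # ON(m) -> OFF(m), offset -1
    band[4, on_idx[:-1]] = mu        # ON(m) -> ON(m+1), offset +2
    band[0, off_idx[1:]] = m[1:] * delta
    band[0, on_idx[1:]] = m[1:] * delta
    return _gth_banded(band, 2)


def telegraph_pmf(tp: TelegraphParams, tail_mass: float = 1e-8,
                  m_min: int = 0, max_states: int = 1 << 20) -> np.ndarray:
    """Stationary mRNA-count pmf over ``0..M``.

    ``M`` starts from a moment-based guess and doubles until the mass in
    the top three states falls below ``tail_mass``; ``m_min`` forces the
    returned support to cover at least that count (used when evaluating
    observed histograms).
    """
    if not (0 < tail_mass <= 1e-4):
        raise ParameterError("tail_mass must lie in (0, 1e-4]")
    if tp.mu == 0 or tp.k_on == 0:
        out = np.zeros(max(1, m_min + 1))
        out[0] = 1.0
        return out
    if tp.k_on + tp.k_off == 0:
        raise ParameterError("degenerate promoter: k_on + k_off = 0")
    mean = telegraph_mean(tp)
    sd = math.sqrt(telegraph_variance(tp))
    M = max(16, m_min + 4, int(mean + 10 * sd + 25))
    while True:
        if 2 * (M + 1) > max_states:
            raise RuntimeError(
                f"telegraph_pmf truncation did not converge below "
                f"{max_states} states (tail mass target {tail_mass})")
        joint = _stationary_banded(tp, M)
        pmf = joint[0::2] + joint[1::2]
        if pmf[-3:].sum() < tail_mass:
            return pmf
        M *= 2


def telegraph_pmf_closed_form(tp: TelegraphParams, m_max: int) -> np.ndarray:
    """Beta-Poisson closed form of the telegraph stationary pmf.

    ``P(m) = lam^m/m! * (a)_m/(a+b)_m * 1F1(a+m; a+b+m; -lam)`` with
    ``a = k_on/delta``, ``b = k_off/delta``, ``lam = mu/delta``.  Used
    only as a numerical cross-check of the master-equation solve; the
    hypergeometric series can overflow for large rates, so values are
    computed in log space where possible and invalid results raised.
    """
    a = tp.k_on / tp.delta
    b = tp.k_off / tp.delta
    lam = tp.mu / tp.delta
    m = np.arange(m_max + 1)
    with np.errstate(over="raise", invalid="raise"):
        logpref = (m * np.log(lam) - gammaln(m + 1)
                   + gammaln(a + m) - gammaln(a)
                   + gammaln(a + b) - gammaln(a + b + m))
        hyp = hyp1f1(a + m, a + b + m, -lam)
        if np.any(~np.isfinite(hyp)) or np.any(hyp <= 0):
            raise FloatingPointError("hypergeometric term overflowed")
        pmf = np.exp(logpref) * hyp
    return pmf


def telegraph_cv(tp: TelegraphParams, tail_mass: float = 1e-8) -> float:
    """Coefficient of variation (sd/mean) of the stationary pmf."""
    mean = telegraph_mean(tp)
    if mean == 0:
        raise ParameterError("CV undefined: stationary mean is zero")
    pmf = telegraph_pmf(tp, tail_mass)
    m = np.arange(pmf.size)
    mu1 = float(pmf @ m)
    var = float(pmf @ (m - mu1) ** 2)
    return math.sqrt(var) / mu1


def apply_variant(p, hp: HillParams, base: TelegraphParams,
                  variant: ModulationVariant) -> TelegraphParams:
    """Return telegraph parameters with one rate replaced by the Hill
    response to contact probability ``p``.

    ``on_rate`` is the model retained by the analysis; ``off_rate``
    (with the Hill response inverted so k_off decreases with contact)
    and ``initiation_rate`` are the alternatives it rejects on CV
    grounds.
    """
    if variant == "on_rate":
        return base.replace(k_on=hill_response(p, hp))
    if variant == "off_rate":
        # swap roles of kon0/kon1 so the response is non-increasing in p
        flipped = HillParams(hp.kon0, hp.kon1, hp.c, hp.h)
        val = flipped.kon1 + flipped.kon0 - hill_response(p, flipped)
        return base.replace(k_off=val)
    if variant == "initiation_rate":
        return base.replace(mu=hill_response(p, hp))
    raise ParameterError(f"unknown modulation variant {variant!r}")


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """TV distance between two pmfs on 0..inf, padding the shorter with
    zeros."""
    n = max(len(p), len(q))
    pp = np.zeros(n)
    qq = np.zeros(n)
    pp[: len(p)] = p
    qq[: len(q)] = q
    return 0.5 * float(np.abs(pp - qq).sum())
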