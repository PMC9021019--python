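"""Parameter containers for the promoter-bursting models.

Rates are expressed in units of the mRNA degradation rate ``delta``
(i.e. one time unit = one mRNA lifetime), the natural scale on which
steady-state mRNA-count distributions are invariant.  ``MRNA_LIFETIME_H``
converts to wall-clock hours for display.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

__all__ = [
    "TelegraphParams",
    "HillParams",
    "MechanisticParams",
    "MRNA_LIFETIME_H",
    "rates_in_hours",
]

#: Default eGFP mRNA lifetime (hours) used only to convert fitted rates to
#: per-hour values in reports; all computations stay in lifetime units.
MRNA_LIFETIME_H = 1.5


class ParameterError(ValueError):
    """Raised when a model parameter violates its admissible range."""


def _check_nonneg(obj, names):
    for name in names:
        v = getattr(obj, name)
        if not (v >= 0):  # catches NaN too
            raise ParameterError(f"{name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class TelegraphParams:
    """Two-state (telegraph) promoter: OFF <-> ON switching at ``k_on`` /
    ``k_off``, initiation at ``mu`` while ON, first-order mRNA decay at
    ``delta``."""

    k_on: float
    k_off: float
    mu: float
    delta: float = 1.0

    def __post_init__(self):
        _check_nonneg(self, ("k_on", "k_off", "mu"))
        if not (self.delta > 0):
            raise ParameterError(f"delta must be > 0, got {self.delta!r}")

    def replace(self, **kw) -> "TelegraphParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class HillParams:
    """Hill-function modulation of the promoter on rate by contact
    probability: ``kon0`` and ``kon1`` are the minimum and maximum on
    rates, ``c`` the critical threshold (contact-probability units) and
    ``h`` the sensitivity (Hill) exponent."""

    kon0: float
    kon1: float
    c: float
    h: float

    def __post_init__(self):
        _check_nonneg(self, ("kon0", "kon1"))
        if self.kon1 < self.kon0:
            raise ParameterError(
                f"kon1 ({self.kon1}) must be >= kon0 ({self.kon0})"
            )
        if not (self.c > 0):
            raise ParameterError(f"c must be > 0, got {self.c!r}")
        if not (self.h > 0):
            raise ParameterError(f"h must be > 0, got {self.h!r}")


@dataclass(frozen=True)
class MechanisticParams:
    """Full enhancer-promoter communication model.

    The enhancer toggles between a *far* and a *close* state with rates
    ``k_close`` (far->close) and ``k_far`` (close->far).  While close, up
    to ``n`` reversible regulatory steps advance at ``k_forward``; steps
    revert one at a time at ``k_back`` in either contact state.  The
    promoter runs a basal two-state regime with on rate ``kon_basal``
    unless all ``n`` steps are complete, in which case the on rate is
    ``kon_enh``; ``k_off``, ``mu`` and ``delta`` are shared between the
    two regimes.
    """

    k_close: float
    k_far: float
    k_forward: float
    k_back: float
    n: int
    kon_basal: float
    kon_enh: float
    k_off: float
    mu: float
    delta: float = 1.0

    def __post_init__(self):
        _check_nonneg(
            self,
            ("k_close", "k_far", "k_forward", "k_back", "kon_basal",
             "kon_enh", "k_off", "mu"),
        )
        if not (self.delta > 0):
            raise ParameterError(f"delta must be > 0, got {self.delta!r}")
        if int(self.n) != self.n or self.n < 1:
            raise ParameterError(f"n must be an integer >= 1, got {self.n!r}")
        if self.kon_enh < self.kon_basal:
            raise ParameterError("kon_enh must be >= kon_basal")

    @property
    def beta(self) -> float:
        """Forward/backward ratio of the regulatory steps."""
        if self.k_back == 0:
            return float("inf")
        return self.k_forward / self.k_back

    def replace(self, **kw) -> "MechanisticParams":
        return replace(self, **kw)


def params_to_dict(p) -> dict:
    return {f.name: getattr(p, f.name) for f in fields(p)}


def rates_in_hours(p, lifetime_h: float = MRNA_LIFETIME_H) -> dict:
    """Convert a rate-parameter container to per-hour rates.

    ``delta = 1`` in lifetime units corresponds to ``1/lifetime_h`` per
    hour; every other rate scales by the same factor.  ``n`` (a count) is
    passed through unchanged.
    """
    out = {}
    for name, v in params_to_dict(p).items():
        out[name] = v if name == "n" else v / lifetime_h
    return out
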