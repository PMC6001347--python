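"""The net-present-value engine.

Real base-year age profiles are projected forward under GDP growth and
inflation, discounted back at the nominal discount rate, accumulated into
a cumulative net-position curve, and searched for the break-even age.

Growth scheme
-------------
The default ``nominal_product`` scheme projects a real base-year flow at
age ``t`` by ``((1+g)(1+i))**t`` and discounts by ``(1+r)**t``; with the
base-case ``r == i`` this leaves an effective per-year compounding of
``1+g``.  The alternative ``real_only`` scheme grows flows by ``(1+g)**t``
alone and is exposed as a configuration switch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .errors import InvalidInputError
from .profiles import AgeProfile

__all__ = [
    "MacroParams",
    "FiscalResult",
    "growth_factor",
    "discount_factor",
    "present_value",
    "npv",
    "break_even_age",
]

GROWTH_SCHEMES = ("nominal_product", "real_only")


@dataclass(frozen=True)
class MacroParams:
    """Macroeconomic assumptions of the base-case scenario (2006 Spain)."""

    discount_rate: float = 0.035
    gdp_growth: float = 0.0408
    inflation: float = 0.035
    unemployment: float = 0.1061
    retirement_age: int = 65
    life_expectancy: int = 78
    base_year: int = 2006
    growth_scheme: str = "nominal_product"

    def __post_init__(self) -> None:
        if self.discount_rate < 0 or self.inflation < 0 or self.gdp_growth < 0:
            raise InvalidInputError("discount_rate, gdp_growth and inflation must be >= 0")
        if not 0 <= self.unemployment < 1:
            raise InvalidInputError("unemployment must lie in [0, 1)")
        if not 0 < self.retirement_age < self.life_expectancy:
            raise InvalidInputError("retirement_age must lie strictly inside (0, life_expectancy)")
        if self.growth_scheme not in GROWTH_SCHEMES:
            raise InvalidInputError(f"growth_scheme must be one of {GROWTH_SCHEMES}")

    def replace(self, **overrides) -> "MacroParams":
        return _dc_replace(self, **overrides)


@dataclass(frozen=True)
class FiscalResult:
    """Discounted lifetime totals and the cumulative net-position curve.

    ``cumulative[a]`` is the discounted net flow summed over ages ``<= a``
    minus the upfront treatment cost; it equals ``nfc`` at the final age.
    """

    pv_taxes: float
    pv_transfers: float
    nfc: float
    cumulative: AgeProfile
    break_even_age: int | None


def growth_factor(t: float, params: MacroParams) -> float:
    """Projection factor applied to a real base-year flow at age ``t``."""
    if t < 0:
        raise InvalidInputError("t must be >= 0")
    if params.growth_scheme == "real_only":
        return (1.0 + params.gdp_growth) ** t
    return ((1.0 + params.gdp_growth) * (1.0 + params.inflation)) ** t


def discount_factor(t: float, params: MacroParams) -> float:
    """``(1+r)**(-t)``."""
    if t < 0:
        raise InvalidInputError("t must be >= 0")
    return (1.0 + params.discount_rate) ** (-t)


def _pv_weights(n_ages: int, params: MacroParams) -> np.ndarray:
    t = np.arange(n_ages, dtype=float)
    if params.growth_scheme == "real_only":
        grow = (1.0 + params.gdp_growth) ** t
    else:
        grow = ((1.0 + params.gdp_growth) * (1.0 + params.inflation)) ** t
    disc = (1.0 + params.discount_rate) ** (-t)
    return grow * disc


def present_value(profile: AgeProfile, params: MacroParams) -> float:
    """Σ_t profile[t] · growth_factor(t) · discount_factor(t) over ages 0..N."""
    _require_life_axis(profile, params)
    return float(np.sum(profile.values * _pv_weights(profile.values.size, params)))


def _require_life_axis(profile: AgeProfile, params: MacroParams) -> None:
    if profile.max_age != params.life_expectancy:
        raise InvalidInputError(
            f"profile covers ages 0..{profile.max_age}, expected 0..{params.life_expectancy}"
        )


def npv(
    taxes: AgeProfile,
    transfers: AgeProfile,
    upfront_cost: float,
    params: MacroParams,
) -> FiscalResult:
    """Lifetime fiscal balance: PV(taxes) − PV(transfers) − upfront cost.

    The upfront cost is paid once at ``t = 0``, undiscounted.  The returned
    cumulative curve carries the running discounted net position including
    that cost, from which the break-even age is read off.
    """
    taxes._check_axis(transfers)
    _require_life_axis(taxes, params)
    if upfront_cost < 0:
        raise InvalidInputError("upfront_cost must be >= 0")
    w = _pv_weights(taxes.values.size, params)
    pv_taxes = float(np.sum(taxes.values * w))
    pv_transfers = float(np.sum(transfers.values * w))
    net = (taxes.values - transfers.values) * w
    cumulative = AgeProfile(np.cumsum(net) - upfront_cost)
    nfc = pv_taxes - pv_transfers - upfront_cost
    return FiscalResult(
        pv_taxes=pv_taxes,
        pv_transfers=pv_transfers,
        nfc=nfc,
        cumulative=cumulative,
        break_even_age=_first_nonnegative(cumulative),
    )


def _first_nonnegative(cumulative: AgeProfile) -> int | None:
    hits = np.nonzero(cumulative.values >= 0)[0]
    return int(hits[0]) if hits.size else None


def break_even_age(result: FiscalResult) -> int | None:
    """Smallest age at which the cumulative net position reaches zero.

    Returns the first crossing; the post-retirement decline of the curve
    never retracts an earlier crossing.  ``None`` if the curve stays
    negative for life.
    """
    return _first_nonnegative(result.cumulative)
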