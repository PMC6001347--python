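"""One-way deterministic sensitivity analysis.

Eight named macro scenarios vary the discount rate (to 1% or 5%), the GDP
growth rate (±100%), the inflation rate (±100%) and the unemployment rate
(±100%), alone or combined; −100% sets a parameter to zero and +100%
doubles it.  Unemployment changes also re-weight the employment-conditional
profiles (see :func:`adjust_unemployment`).  The calibrated real profiles
themselves are never re-calibrated per scenario — only re-projected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .art_costs import ARTParams, evaluate
from .errors import InvalidInputError
from .lifecycle import MacroParams, npv, present_value
from .profiles import AgeProfile, TaxProfileSet, TransferProfileSet, sum_taxes, sum_transfers

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "TABLE_SCENARIOS",
    "apply_scenario",
    "adjust_unemployment",
    "run_sensitivity",
    "tornado",
]

_OVERRIDABLE = ("discount_rate", "gdp_growth", "inflation", "unemployment")


@dataclass(frozen=True)
class ScenarioSpec:
    """A label plus parameter overrides.

    Override values are either absolute numbers or the relative strings
    ``"+100%"`` (double the base value) and ``"-100%"`` (set to zero).
    """

    label: str
    overrides: Mapping[str, float | str]


@dataclass(frozen=True)
class ScenarioResult:
    label: str
    expected_nfc: float
    net_contribution: float
    break_even_age: int | None
    roi: float
    expected_cost: float
    nfc_natural: float


#: The built-in eight-scenario set of the deterministic sensitivity design.
TABLE_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec("1: g -100%; i -100%", {"gdp_growth": "-100%", "inflation": "-100%"}),
    ScenarioSpec("2: g +100%; i +100%", {"gdp_growth": "+100%", "inflation": "+100%"}),
    ScenarioSpec("3: d = 1%", {"discount_rate": 0.01}),
    ScenarioSpec("4: d = 5%", {"discount_rate": 0.05}),
    ScenarioSpec("5: U -100%", {"unemployment": "-100%"}),
    ScenarioSpec("6: U +100%", {"unemployment": "+100%"}),
    ScenarioSpec(
        "7: g -100%; i -100%; U +100%",
        {"gdp_growth": "-100%", "inflation": "-100%", "unemployment": "+100%"},
    ),
    ScenarioSpec(
        "8: g +100%; i +100%; U -100%",
        {"gdp_growth": "+100%", "inflation": "+100%", "unemployment": "-100%"},
    ),
)


def _resolve(base_value: float, override: float | str) -> float:
    if isinstance(override, str):
        key = override.replace(" ", "")
        if key == "-100%":
            return 0.0
        if key == "+100%":
            return 2.0 * base_value
        raise InvalidInputError(f"unsupported relative override {override!r}")
    return float(override)


def apply_scenario(base: MacroParams, spec: ScenarioSpec) -> MacroParams:
    """Return a copy of ``base`` with the scenario's overrides applied."""
    changes = {}
    for name, override in spec.overrides.items():
        if name not in _OVERRIDABLE:
            raise InvalidInputError(
                f"scenario {spec.label!r}: parameter {name!r} cannot be overridden"
            )
        changes[name] = _resolve(getattr(base, name), override)
    return base.replace(**changes)


def _scale_clip(profile: AgeProfile, factor: float) -> AgeProfile:
    return AgeProfile(np.clip(profile.values * factor, 0.0, 1.0))


def adjust_unemployment(
    transfers: TransferProfileSet,
    taxes: TaxProfileSet,
    u_new: float,
    u_base: float,
    adjust_employment_side: bool = True,
) -> tuple[TransferProfileSet, TaxProfileSet]:
    """Re-weight profiles for a counterfactual unemployment rate.

    Unemployment-benefit participation scales by ``u_new/u_base`` and the
    employment-conditional series (public-wage participation and the Social
    Security and income-tax expected amounts) scale by
    ``(1−u_new)/(1−u_base)``; participation results are clipped to [0, 1].
    Consumption taxes are unchanged.  The employment-side effect can be
    switched off with ``adjust_employment_side=False``.
    """
    if not 0 <= u_new < 1:
        raise InvalidInputError("u_new must lie in [0, 1)")
    if not 0 <= u_base < 1:
        raise InvalidInputError("u_base must lie in [0, 1)")
    if u_base == 0:
        if u_new > 0:
            raise InvalidInputError("cannot scale unemployment up from a zero base rate")
        benefit_factor = 1.0
    else:
        benefit_factor = u_new / u_base
    employment_factor = (1.0 - u_new) / (1.0 - u_base)

    new_transfers = replace(
        transfers, unemp_part=_scale_clip(transfers.unemp_part, benefit_factor)
    )
    new_taxes = taxes
    if adjust_employment_side:
        new_transfers = replace(
            new_transfers, wages_part=_scale_clip(new_transfers.wages_part, employment_factor)
        )
        new_taxes = replace(
            taxes,
            ss=taxes.ss * employment_factor,
            income=taxes.income * employment_factor,
        )
    return new_transfers, new_taxes


def evaluate_scenario(
    params: MacroParams,
    transfers: TransferProfileSet,
    taxes: TaxProfileSet,
    art: ARTParams,
    label: str = "scenario",
) -> ScenarioResult:
    """Run the full pipeline for one parameterisation."""
    tax_profile = sum_taxes(taxes)
    transfer_profile = sum_transfers(transfers)
    nfc_natural = present_value(tax_profile, params) - present_value(transfer_profile, params)
    outcome = evaluate(art, nfc_natural)
    fiscal = npv(tax_profile, transfer_profile, outcome.expected_cost, params)
    return ScenarioResult(
        label=label,
        expected_nfc=outcome.expected_nfc,
        net_contribution=outcome.net_contribution,
        break_even_age=fiscal.break_even_age,
        roi=outcome.roi,
        expected_cost=outcome.expected_cost,
        nfc_natural=nfc_natural,
    )


def run_sensitivity(
    base_params: MacroParams,
    transfers: TransferProfileSet,
    taxes: TaxProfileSet,
    art: ARTParams,
    specs: Sequence[ScenarioSpec],
    adjust_employment_side: bool = True,
) -> list[ScenarioResult]:
    """Evaluate every scenario through the same pipeline as the base case."""
    if not specs:
        raise InvalidInputError("at least one scenario is required")
    results = []
    for spec in specs:
        params = apply_scenario(base_params, spec)
        t_set, x_set = transfers, taxes
        if params.unemployment != base_params.unemployment:
            t_set, x_set = adjust_unemployment(
                transfers,
                taxes,
                params.unemployment,
                base_params.unemployment,
                adjust_employment_side=adjust_employment_side,
            )
        results.append(evaluate_scenario(params, t_set, x_set, art, label=spec.label))
    return results


def tornado(
    results: Sequence[ScenarioResult], base: ScenarioResult
) -> list[tuple[str, float, float]]:
    """Scenario ROI spans ordered for a tornado diagram.

    Each entry is ``(label, roi_low, roi_high)`` with the span anchored at
    the base-case ROI, sorted by descending ``|roi − base.roi|``.
    """
    rows = [
        (res.label, min(res.roi, base.roi), max(res.roi, base.roi), abs(res.roi - base.roi))
        for res in results
    ]
    rows.sort(key=lambda r: r[3], reverse=True)
    return [(label, lo, hi) for label, lo, hi, _ in rows]
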