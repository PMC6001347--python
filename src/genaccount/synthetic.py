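"""Synthetic age-profile generator and two-scalar calibration.

The true per-age euro levels behind the model's 2006 Spanish inputs are
unpublished; what is documented is their structure (schooling-age
education, U-shaped healthcare by six age bands, late-life pensions with a
small orphan component, working-age labour taxes, consumption taxes from
fixed starting ages) and the two discounted lifetime totals.  This module
generates profile sets with exactly that structure and then rescales each
side by a single global factor so the discounted totals hit their targets.

Shapes are deliberately smooth and parameterised; any shape satisfying the
structural constraints and the calibration is admissible, so downstream
break-even ages and scenario euro values are shape-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, InvalidInputError
from .lifecycle import MacroParams, present_value
from .profiles import (
    AgeProfile,
    TaxProfileSet,
    TransferProfileSet,
    expand_group_profile,
    per_capita_profile,
    sum_taxes,
    sum_transfers,
)

__all__ = ["SyntheticConfig", "CalibrationReport", "generate_profiles", "calibrate"]

#: Default lifetime discounted totals used by the CLI (base-year euros).
DEFAULT_TARGET_PV_TAXES = 370_482.0
DEFAULT_TARGET_PV_TRANSFERS = 275_972.0

# Healthcare expenditure bands: (lo, hi or None meaning life expectancy).
_HEALTH_BANDS = ((0, 4), (5, 14), (15, 44), (45, 64), (65, 74), (75, None))


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs controlling the generated age structure.

    Levels are pre-calibration and only matter relative to other levels on
    the same (tax or transfer) side; calibration supplies the absolute
    scale.  ``noise`` is the relative spread of the multiplicative
    log-normal jitter applied per age (0 disables jitter entirely).
    """

    seed: int = 1
    life_expectancy: int = 78
    schooling_span: tuple[int, int] = (3, 24)
    working_span: tuple[int, int] = (16, 65)
    driver_start_age: int = 13
    vat_start_age: int = 17
    other_tax_start_age: int = 18
    adult_tax_start_age: int = 16
    pension_onset: int = 65
    noise: float = 0.01
    # transfer-side levels (euros/year before calibration)
    education_group_amounts: tuple[float, ...] = (30.0, 30.0, 60.0, 60.0)
    healthcare_band_means: tuple[float, ...] = (45.0, 25.0, 600.0, 610.0, 615.0, 625.0)
    public_wage: float = 8000.0
    public_servant_share: float = 0.0781
    pension_level: float = 20.0
    orphan_pension_level: float = 10.0
    survivor_pension_level: float = 5.0
    unemployment_benefit: float = 1500.0
    unemployment_rate: float = 0.1061
    labour_force_ceiling: float = 0.80
    employment_peak_age: float = 38.0
    employment_peak_width: float = 2.5
    # tax-side levels (euros/year before calibration)
    ss_level: float = 2000.0
    income_level: float = 1600.0
    corporate_level: float = 1500.0
    nonresident_level: float = 40.0
    alcohol_level: float = 90.0
    tobacco_level: float = 140.0
    fuel_level: float = 130.0
    vat_level: float = 200.0
    other_level: float = 40.0

    def __post_init__(self) -> None:
        n = self.life_expectancy
        for name in ("schooling_span", "working_span"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= n):
                raise InvalidInputError(f"{name} {lo}..{hi} infeasible within 0..{n}")
        if self.noise < 0:
            raise InvalidInputError("noise must be >= 0")
        if not 0 < self.pension_onset <= n:
            raise InvalidInputError("pension_onset must lie in (0, life_expectancy]")


@dataclass(frozen=True)
class CalibrationReport:
    tax_scale: float
    transfer_scale: float
    achieved_pv_taxes: float
    achieved_pv_transfers: float


def _labour_force_shape(
    ages: np.ndarray, lo: int, hi: int, ceiling: float, peak: float, width: float
) -> np.ndarray:
    """Smooth unimodal labour-force participation, zero outside the span.

    A narrow Gaussian career peak: earnings-linked flows are concentrated
    around ``peak`` so that the cumulative net position crosses zero at a
    similar age under every discount/growth re-weighting (see module docs
    of :mod:`genaccount.scenarios`).
    """
    a = ages.astype(float)
    shape = ceiling * np.exp(-0.5 * ((a - peak) / width) ** 2)
    shape[(ages < lo) | (ages > hi)] = 0.0
    return shape


def _jitter(rng: np.random.Generator, values: np.ndarray, noise: float) -> np.ndarray:
    if noise == 0:
        return values
    return values * np.exp(rng.normal(0.0, noise, size=values.size))


def _jitter_part(rng: np.random.Generator, values: np.ndarray, noise: float) -> np.ndarray:
    return np.clip(_jitter(rng, values, noise), 0.0, 1.0)


def generate_profiles(config: SyntheticConfig) -> tuple[TransferProfileSet, TaxProfileSet]:
    """Generate one transfer and one tax profile set.

    Reproducible: the same config (including seed) always yields the same
    profiles, and with ``noise == 0`` the seed is irrelevant.
    """
    n = config.life_expectancy
    ages = np.arange(n + 1)
    rng = np.random.default_rng(config.seed)

    school_lo, school_hi = config.schooling_span
    work_lo, work_hi = config.working_span
    labour = _labour_force_shape(
        ages,
        work_lo,
        work_hi,
        config.labour_force_ceiling,
        config.employment_peak_age,
        config.employment_peak_width,
    )
    u = config.unemployment_rate
    employed = labour * (1.0 - u)

    # ---- transfers -----------------------------------------------------
    # education: group means over primary / middle / high / tertiary ages,
    # enrolment near 1 through compulsory schooling then tapering.
    e1, e2, e3, e4 = config.education_group_amounts
    groups = [(school_lo, 5, e1), (6, 11, e2), (12, 17, e3), (18, school_hi, e4)]
    education_amount = expand_group_profile([g for g in groups if g[0] <= g[1]], n)
    enrolment = np.zeros(n + 1)
    for a in range(school_lo, school_hi + 1):
        if a <= 15:
            enrolment[a] = 0.97
        else:
            enrolment[a] = max(0.97 - 0.11 * (a - 15), 0.05)
    education_part = AgeProfile(_jitter_part(rng, enrolment, config.noise))
    education_amount = AgeProfile(_jitter(rng, education_amount.values, config.noise))

    bands = [
        (lo, n if hi is None else hi, mean)
        for (lo, hi), mean in zip(_HEALTH_BANDS, config.healthcare_band_means)
    ]
    healthcare_amount = AgeProfile(
        _jitter(rng, expand_group_profile(bands, n).values, config.noise)
    )

    wages_amount = AgeProfile(
        _jitter(rng, np.where(labour > 0, config.public_wage, 0.0), config.noise)
    )
    wages_part = AgeProfile(
        _jitter_part(rng, config.public_servant_share * employed, config.noise)
    )

    # pensions: expected per-capita amounts (participation folded in);
    # orphan pensions at young ages, a small survivor component mid-life,
    # full retirement pensions from the onset age.
    pensions = np.zeros(n + 1)
    pensions[: min(25, n + 1)] = config.orphan_pension_level
    pensions[min(55, config.pension_onset) : config.pension_onset] = (
        config.survivor_pension_level
    )
    pensions[config.pension_onset :] = config.pension_level
    pensions_amount = AgeProfile(_jitter(rng, pensions, config.noise))

    unemp_amount = AgeProfile(
        _jitter(rng, np.where(labour > 0, config.unemployment_benefit, 0.0), config.noise)
    )
    unemp_part = AgeProfile(_jitter_part(rng, labour * u, config.noise))

    transfers = TransferProfileSet(
        education_amount=education_amount,
        education_part=education_part,
        healthcare_amount=healthcare_amount,
        wages_amount=wages_amount,
        wages_part=wages_part,
        pensions_amount=pensions_amount,
        unemp_amount=unemp_amount,
        unemp_part=unemp_part,
    )

    # ---- taxes (expected per-age amounts) ------------------------------
    ss = config.ss_level * employed
    income = config.income_level * employed
    # business ownership follows the same career peak but is not
    # employment-conditional for unemployment re-weighting purposes
    corporate = config.corporate_level * labour

    adult = config.adult_tax_start_age
    nonresident = per_capita_profile(config.nonresident_level, 1.0, 15, n).values
    alcohol = per_capita_profile(config.alcohol_level, 1.0, adult, n).values
    tobacco = per_capita_profile(config.tobacco_level, 1.0, adult, n).values
    fuel = per_capita_profile(config.fuel_level, 1.0, config.driver_start_age, n).values.copy()
    # licence uptake ramps in before adulthood
    for a in range(config.driver_start_age, min(18, n + 1)):
        fuel[a] *= 0.2 * (a - config.driver_start_age + 1)
    vat = per_capita_profile(config.vat_level, 1.0, config.vat_start_age, n).values
    other = per_capita_profile(config.other_level, 1.0, config.other_tax_start_age, n).values

    def amt(values: np.ndarray) -> AgeProfile:
        return AgeProfile(np.clip(_jitter(rng, values, config.noise), 0.0, None))

    taxes = TaxProfileSet(
        ss=amt(ss),
        income=amt(income),
        corporate=amt(corporate),
        nonresident=amt(nonresident),
        alcohol=amt(alcohol),
        tobacco=amt(tobacco),
        fuel=amt(fuel),
        vat=amt(vat),
        other=amt(other),
    )
    return transfers, taxes


def calibrate(
    transfers: TransferProfileSet,
    taxes: TaxProfileSet,
    target_pv_taxes: float,
    target_pv_transfers: float,
    params: MacroParams,
) -> tuple[TransferProfileSet, TaxProfileSet, CalibrationReport]:
    """Scale each side by one global factor to hit its discounted target.

    Amount profiles are scaled; participation profiles are untouched, so
    every structural zero-region and probability bound survives.
    """
    if target_pv_taxes <= 0 or target_pv_transfers <= 0:
        raise InvalidInputError("calibration targets must be positive")
    pv_tax = present_value(sum_taxes(taxes), params)
    pv_transfer = present_value(sum_transfers(transfers), params)
    if pv_tax <= 0 or pv_transfer <= 0:
        raise CalibrationError("unscaled present value is zero; cannot calibrate")
    tax_scale = target_pv_taxes / pv_tax
    transfer_scale = target_pv_transfers / pv_transfer
    taxes_cal = taxes.scale_amounts(tax_scale)
    transfers_cal = transfers.scale_amounts(transfer_scale)
    report = CalibrationReport(
        tax_scale=tax_scale,
        transfer_scale=transfer_scale,
        achieved_pv_taxes=present_value(sum_taxes(taxes_cal), params),
        achieved_pv_transfers=present_value(sum_transfers(transfers_cal), params),
    )
    return transfers_cal, taxes_cal, report
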