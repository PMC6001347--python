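"""Age-profile data model and the imputation operations that build per-age,
participation-weighted amounts from aggregate statistics.

Everything downstream works on :class:`AgeProfile` objects: a value per
single year of age on a contiguous integer axis ``0..max_age``.  Amount
profiles are real (base-year) euros per year; participation profiles are
probabilities in ``[0, 1]``.  Growth, inflation and discounting are applied
only in :mod:`genaccount.lifecycle`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "AgeProfile",
    "TransferProfileSet",
    "TaxProfileSet",
    "TRANSFER_COMPONENTS",
    "TAX_COMPONENTS",
    "TAX_START_AGES",
    "expand_group_profile",
    "per_capita_profile",
    "weight_by_participation",
    "sum_transfers",
    "sum_taxes",
]

#: Transfer components; each has an amount and a participation profile.
TRANSFER_COMPONENTS = ("education", "healthcare", "wages", "pensions", "unemp")

#: Tax components; stored as already participation-weighted expected amounts.
TAX_COMPONENTS = (
    "ss",
    "income",
    "corporate",
    "nonresident",
    "alcohol",
    "tobacco",
    "fuel",
    "vat",
    "other",
)

#: First age at which per-capita consumption-tax imputations apply.
TAX_START_AGES = {"fuel": 13, "vat": 17, "other": 18}


@dataclass(frozen=True)
class AgeProfile:
    """A per-age series on the integer age axis ``0..max_age`` inclusive.

    The array is copied and frozen on construction; values must be finite.
    Sign conventions are enforced by callers via :meth:`require_amount` /
    :meth:`require_participation` because some derived series (cumulative
    net positions) are legitimately signed.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.array(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidInputError("AgeProfile requires a 1-D series with at least one age")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("AgeProfile values must be finite")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def zeros(cls, max_age: int) -> "AgeProfile":
        return cls(np.zeros(int(max_age) + 1))

    @classmethod
    def full(cls, max_age: int, value: float) -> "AgeProfile":
        return cls(np.full(int(max_age) + 1, float(value)))

    # ------------------------------------------------------------------ #
    # axis

    @property
    def max_age(self) -> int:
        return self.values.size - 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.values.size)

    def same_axis(self, other: "AgeProfile") -> bool:
        return self.values.size == other.values.size

    # ------------------------------------------------------------------ #
    # flavour checks

    def require_amount(self, name: str = "profile") -> "AgeProfile":
        if np.any(self.values < 0):
            raise InvalidInputError(f"{name}: amount values must be non-negative")
        return self

    def require_participation(self, name: str = "profile") -> "AgeProfile":
        if np.any((self.values < 0) | (self.values > 1)):
            raise InvalidInputError(f"{name}: participation values must lie in [0, 1]")
        return self

    # ------------------------------------------------------------------ #
    # arithmetic (axis-checked)

    def _check_axis(self, other: "AgeProfile") -> None:
        if not self.same_axis(other):
            raise InvalidInputError(
                f"age-axis mismatch: {self.max_age} vs {other.max_age}"
            )

    def __add__(self, other: "AgeProfile") -> "AgeProfile":
        self._check_axis(other)
        return AgeProfile(self.values + other.values)

    def __sub__(self, other: "AgeProfile") -> "AgeProfile":
        self._check_axis(other)
        return AgeProfile(self.values - other.values)

    def __mul__(self, scalar: float) -> "AgeProfile":
        return AgeProfile(self.values * float(scalar))

    __rmul__ = __mul__

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, age: int) -> float:
        return float(self.values[age])


def _check_shared_axis(profiles: Iterable[tuple[str, AgeProfile]]) -> int:
    sizes = {name: p.values.size for name, p in profiles}
    if len(set(sizes.values())) != 1:
        raise InvalidInputError(f"profiles do not share one age axis: {sizes}")
    return next(iter(sizes.values())) - 1


@dataclass(frozen=True)
class TransferProfileSet:
    """The five government-to-individual transfer components.

    Education, public wages and unemployment benefits carry explicit
    participation profiles; healthcare and pensions enter as expected
    per-capita amounts, so their participation defaults to 1 at every age.
    """

    education_amount: AgeProfile
    education_part: AgeProfile
    healthcare_amount: AgeProfile
    wages_amount: AgeProfile
    wages_part: AgeProfile
    pensions_amount: AgeProfile
    unemp_amount: AgeProfile
    unemp_part: AgeProfile
    healthcare_part: AgeProfile | None = None
    pensions_part: AgeProfile | None = None

    def __post_init__(self) -> None:
        n = self.education_amount.max_age
        if self.healthcare_part is None:
            object.__setattr__(self, "healthcare_part", AgeProfile.full(n, 1.0))
        if self.pensions_part is None:
            object.__setattr__(self, "pensions_part", AgeProfile.full(n, 1.0))
        _check_shared_axis(self.items())
        for name in TRANSFER_COMPONENTS:
            getattr(self, f"{name}_amount").require_amount(f"{name}_amount")
            getattr(self, f"{name}_part").require_participation(f"{name}_part")

    @property
    def max_age(self) -> int:
        return self.education_amount.max_age

    def items(self) -> list[tuple[str, AgeProfile]]:
        out = []
        for name in TRANSFER_COMPONENTS:
            out.append((f"{name}_amount", getattr(self, f"{name}_amount")))
            out.append((f"{name}_part", getattr(self, f"{name}_part")))
        return out

    def component(self, name: str) -> tuple[AgeProfile, AgeProfile]:
        """Return ``(amount, participation)`` for one component."""
        if name not in TRANSFER_COMPONENTS:
            raise InvalidInputError(f"unknown transfer component {name!r}")
        return getattr(self, f"{name}_amount"), getattr(self, f"{name}_part")

    def scale_amounts(self, factor: float) -> "TransferProfileSet":
        """Multiply every amount profile by ``factor``; participation untouched."""
        if factor < 0:
            raise InvalidInputError("scale factor must be non-negative")
        kw = {f"{c}_amount": getattr(self, f"{c}_amount") * factor for c in TRANSFER_COMPONENTS}
        return replace(self, **kw)


@dataclass(frozen=True)
class TaxProfileSet:
    """The nine individual-to-government tax components.

    Values are already participation-weighted expected per-age amounts.
    Consumption-tax imputations start at fixed ages: fuel from 13, VAT
    from 17, other taxes from 18; those profiles must be zero below.
    """

    ss: AgeProfile
    income: AgeProfile
    corporate: AgeProfile
    nonresident: AgeProfile
    alcohol: AgeProfile
    tobacco: AgeProfile
    fuel: AgeProfile
    vat: AgeProfile
    other: AgeProfile

    def __post_init__(self) -> None:
        _check_shared_axis(self.items())
        for name, prof in self.items():
            prof.require_amount(name)
        for name, start in TAX_START_AGES.items():
            prof = getattr(self, name)
            lead = prof.values[: min(start, prof.values.size)]
            if np.any(lead != 0):
                raise InvalidInputError(f"{name} tax must be zero below age {start}")

    @property
    def max_age(self) -> int:
        return self.ss.max_age

    def items(self) -> list[tuple[str, AgeProfile]]:
        return [(name, getattr(self, name)) for name in TAX_COMPONENTS]

    def scale_amounts(self, factor: float) -> "TaxProfileSet":
        if factor < 0:
            raise InvalidInputError("scale factor must be non-negative")
        return replace(self, **{n: p * factor for n, p in self.items()})


# ---------------------------------------------------------------------- #
# imputation operations


def expand_group_profile(
    group_means: Sequence[tuple[int, int, float]], max_age: int
) -> AgeProfile:
    """Spread age-group average amounts onto single years of age.

    Each ``(age_lo, age_hi, amount)`` triple assigns ``amount`` to every age
    in the closed interval ``[age_lo, age_hi]``.  Ages covered by no group
    get 0.  Groups must be disjoint and lie within ``[0, max_age]``.
    """
    values = np.zeros(int(max_age) + 1)
    covered = np.zeros(int(max_age) + 1, dtype=bool)
    for lo, hi, amount in group_means:
        lo, hi = int(lo), int(hi)
        if lo > hi:
            raise InvalidInputError(f"group ({lo}, {hi}) has age_lo > age_hi")
        if lo < 0 or hi > max_age:
            raise InvalidInputError(f"group ({lo}, {hi}) outside [0, {max_age}]")
        if covered[lo : hi + 1].any():
            raise InvalidInputError(f"group ({lo}, {hi}) overlaps a previous group")
        covered[lo : hi + 1] = True
        values[lo : hi + 1] = float(amount)
    return AgeProfile(values)


def per_capita_profile(
    aggregate: float, population: float, start_age: int, max_age: int
) -> AgeProfile:
    """Impute ``aggregate / population`` to every age from ``start_age`` on."""
    if population <= 0:
        raise InvalidInputError("population must be positive")
    start_age = int(start_age)
    if not 0 <= start_age <= max_age:
        raise InvalidInputError(f"start_age {start_age} outside [0, {max_age}]")
    values = np.zeros(int(max_age) + 1)
    values[start_age:] = float(aggregate) / float(population)
    return AgeProfile(values)


def weight_by_participation(amount: AgeProfile, participation: AgeProfile) -> AgeProfile:
    """Expected per-age amount: element-wise ``amount × participation``."""
    amount._check_axis(participation)
    participation.require_participation("participation")
    return AgeProfile(amount.values * participation.values)


def sum_transfers(ts: TransferProfileSet) -> AgeProfile:
    """Total expected transfer at each age: Σ component amount × participation."""
    total = np.zeros(ts.max_age + 1)
    for name in TRANSFER_COMPONENTS:
        amount, part = ts.component(name)
        total += amount.values * part.values
    return AgeProfile(total)


def sum_taxes(ts: TaxProfileSet) -> AgeProfile:
    """Total expected tax at each age: Σ over the nine components."""
    total = np.zeros(ts.max_age + 1)
    for _, prof in ts.items():
        total += prof.values
    return AgeProfile(total)
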