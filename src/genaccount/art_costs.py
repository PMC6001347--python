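"""Assisted-reproduction treatment economics.

Cycles to first pregnancy follow a geometric distribution with per-cycle
success probability ``p``, so the expected number of cycles is ``1/p`` and
the expected cost per pregnancy is ``c/p`` for a per-cycle cost ``c``.
Under a capped funding policy the state pays at most ``k`` cycles, which
yields an expected outlay of ``(c/p)·(1 − (1−p)**k)`` and a pregnancy
probability of ``1 − (1−p)**k``; failed-but-funded cycles of couples who
never conceive within the cap are included in that expectation.

Only 75% of achieved pregnancies result in a live birth by default, which
scales the expected lifetime net fiscal contribution but not the outlay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import InvalidInputError

__all__ = [
    "ARTParams",
    "ARTOutcome",
    "expected_cycles",
    "cost_per_pregnancy",
    "expected_capped_cost",
    "preg_prob_within",
    "expected_nfc",
    "evaluate",
    "default_params",
    "IVF_SUCCESS_PROB",
    "IVF_COST_PER_PREGNANCY",
    "AI_CYCLES_NEEDED",
    "AI_COST_PER_PREGNANCY",
    "DEFAULT_LIVE_BIRTH_PROB",
]

# Published base-case figures (2006 euros).  Per-cycle costs are not
# published; they are back-solved as cost_per_pregnancy × success_prob so
# that both the per-pregnancy and the capped three-cycle expected costs
# are reproduced.
IVF_SUCCESS_PROB = 0.287
IVF_COST_PER_PREGNANCY = 4173.0
AI_CYCLES_NEEDED = 6.53
AI_COST_PER_PREGNANCY = 3629.0
DEFAULT_LIVE_BIRTH_PROB = 0.75


@dataclass(frozen=True)
class ARTParams:
    """One assisted-reproduction technique under one funding policy.

    ``funded_cycles is None`` means the state funds as many cycles as are
    needed to obtain a pregnancy.
    """

    technique: str
    cycle_cost: float
    success_prob: float
    funded_cycles: int | None = None
    live_birth_prob: float = DEFAULT_LIVE_BIRTH_PROB

    def __post_init__(self) -> None:
        if not 0 < self.success_prob <= 1:
            raise InvalidInputError("success_prob must lie in (0, 1]")
        if not 0 < self.live_birth_prob <= 1:
            raise InvalidInputError("live_birth_prob must lie in (0, 1]")
        if self.cycle_cost < 0:
            raise InvalidInputError("cycle_cost must be >= 0")
        if self.funded_cycles is not None and self.funded_cycles < 1:
            raise InvalidInputError("funded_cycles must be >= 1 (or None for unlimited)")

    @classmethod
    def from_config(cls, cfg: Mapping) -> "ARTParams":
        """Build parameters from a config mapping.

        Accepts ``success_prob`` or its reciprocal ``cycles_needed``, and
        ``cycle_cost`` or ``cost_per_pregnancy`` (back-solved).  The key
        ``funded_cycles`` may be an integer or the string ``"unlimited"``.
        """
        technique = str(cfg.get("technique", "ART"))
        if "success_prob" in cfg:
            p = float(cfg["success_prob"])
        elif "cycles_needed" in cfg:
            needed = float(cfg["cycles_needed"])
            if needed <= 0:
                raise InvalidInputError("cycles_needed must be positive")
            p = 1.0 / needed
        else:
            raise InvalidInputError("config needs success_prob or cycles_needed")
        if "cycle_cost" in cfg:
            c = float(cfg["cycle_cost"])
        elif "cost_per_pregnancy" in cfg:
            c = float(cfg["cost_per_pregnancy"]) * p
        else:
            raise InvalidInputError("config needs cycle_cost or cost_per_pregnancy")
        funded = cfg.get("funded_cycles", "unlimited")
        if isinstance(funded, str):
            if funded.lower() != "unlimited":
                raise InvalidInputError("funded_cycles must be an integer or 'unlimited'")
            funded = None
        elif funded is not None:
            funded = int(funded)
        lam = float(cfg.get("live_birth_prob", DEFAULT_LIVE_BIRTH_PROB))
        return cls(technique, c, p, funded, lam)


def default_params(
    technique: str,
    funded_cycles: int | None = None,
    live_birth_prob: float = DEFAULT_LIVE_BIRTH_PROB,
) -> ARTParams:
    """Base-case parameters for ``"IVF"`` or ``"AI"``."""
    key = technique.strip().upper()
    if key == "IVF":
        p = IVF_SUCCESS_PROB
        c = IVF_COST_PER_PREGNANCY * p
    elif key == "AI":
        p = 1.0 / AI_CYCLES_NEEDED
        c = AI_COST_PER_PREGNANCY * p
    else:
        raise InvalidInputError(f"unknown technique {technique!r} (expected IVF or AI)")
    return ARTParams(key, c, p, funded_cycles, live_birth_prob)


@dataclass(frozen=True)
class ARTOutcome:
    """Expected economics of one technique/policy against a lifetime NFC."""

    expected_cycles: float
    cost_per_pregnancy: float
    expected_cost: float
    preg_prob: float
    expected_nfc: float
    net_contribution: float
    roi: float


def expected_cycles(p: float) -> float:
    """Mean number of cycles to the first success: ``1/p``."""
    if p <= 0:
        raise InvalidInputError("success probability must be positive")
    if p > 1:
        raise InvalidInputError("success probability must be <= 1")
    return 1.0 / p


def cost_per_pregnancy(c: float, p: float) -> float:
    """Expected cost of obtaining one pregnancy: ``c/p``."""
    if c < 0:
        raise InvalidInputError("cycle cost must be >= 0")
    return c * expected_cycles(p)


def expected_capped_cost(c: float, p: float, k: int | None) -> float:
    """Expected outlay when at most ``k`` cycles are funded.

    ``c · Σ_{j<k} (1−p)**j = (c/p)·(1 − (1−p)**k)``; unlimited ⇒ ``c/p``.
    """
    cpp = cost_per_pregnancy(c, p)
    if k is None:
        return cpp
    if k < 1:
        raise InvalidInputError("funded cycle cap must be >= 1")
    return cpp * (1.0 - (1.0 - p) ** int(k))


def preg_prob_within(p: float, k: int | None) -> float:
    """Probability of achieving a pregnancy within ``k`` funded cycles."""
    if not 0 < p <= 1:
        raise InvalidInputError("success probability must lie in (0, 1]")
    if k is None:
        return 1.0
    if k < 1:
        raise InvalidInputError("funded cycle cap must be >= 1")
    return 1.0 - (1.0 - p) ** int(k)


def expected_nfc(nfc_natural: float, live_birth_prob: float, preg_prob: float) -> float:
    """Live-birth-adjusted expected lifetime contribution."""
    for name, value in (("live_birth_prob", live_birth_prob), ("preg_prob", preg_prob)):
        if not 0 <= value <= 1:
            raise InvalidInputError(f"{name} must lie in [0, 1]")
    return nfc_natural * live_birth_prob * preg_prob


def evaluate(art: ARTParams, nfc_natural: float) -> ARTOutcome:
    """Compose the expectation operations for one technique/policy."""
    cycles = expected_cycles(art.success_prob)
    cpp = cost_per_pregnancy(art.cycle_cost, art.success_prob)
    cost = expected_capped_cost(art.cycle_cost, art.success_prob, art.funded_cycles)
    pp = preg_prob_within(art.success_prob, art.funded_cycles)
    enfc = expected_nfc(nfc_natural, art.live_birth_prob, pp)
    net = enfc - cost
    if cost <= 0:
        raise InvalidInputError("return on investment undefined: expected cost is zero")
    return ARTOutcome(
        expected_cycles=cycles,
        cost_per_pregnancy=cpp,
        expected_cost=cost,
        preg_prob=pp,
        expected_nfc=enfc,
        net_contribution=net,
        roi=net / cost,
    )
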