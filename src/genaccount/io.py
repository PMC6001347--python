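"""Profile CSV I/O, result-table rendering and the end-to-end pipeline.

The profile CSV contract is long-format with columns
``age,component,kind,value``: transfer components carry both an ``amount``
and a ``participation`` row per age; tax components carry ``amount`` rows
only (they are already participation-weighted).  UTF-8, dot decimal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .art_costs import ARTOutcome, ARTParams, default_params, evaluate
from .errors import InvalidInputError, ProfileParseError
from .lifecycle import FiscalResult, MacroParams, npv
from .profiles import (
    TAX_COMPONENTS,
    TRANSFER_COMPONENTS,
    AgeProfile,
    TaxProfileSet,
    TransferProfileSet,
    sum_taxes,
    sum_transfers,
)
from .scenarios import TABLE_SCENARIOS, evaluate_scenario, run_sensitivity, tornado
from .synthetic import (
    DEFAULT_TARGET_PV_TAXES,
    DEFAULT_TARGET_PV_TRANSFERS,
    SyntheticConfig,
    calibrate,
    generate_profiles,
)

__all__ = [
    "round_half_up",
    "read_profiles",
    "write_profiles",
    "render_base_table",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("genaccount")

_CSV_COLUMNS = ("age", "component", "kind", "value")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (display only; the pipeline never pre-rounds)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------- #
# profile CSV


def write_profiles(
    path: str | Path, transfers: TransferProfileSet, taxes: TaxProfileSet
) -> None:
    """Emit both profile sets in the long-format CSV contract."""
    rows = []
    for name in TRANSFER_COMPONENTS:
        amount, part = transfers.component(name)
        for age in range(amount.max_age + 1):
            rows.append((age, name, "amount", repr(amount[age])))
            rows.append((age, name, "participation", repr(part[age])))
    for name, prof in taxes.items():
        for age in range(prof.max_age + 1):
            rows.append((age, name, "amount", repr(prof[age])))
    frame = pd.DataFrame(rows, columns=list(_CSV_COLUMNS))
    frame.to_csv(path, index=False)


def _series_to_profile(
    sub: pd.DataFrame, component: str, kind: str, n_expected: int | None
) -> AgeProfile:
    sub = sub.sort_values("age")
    ages = sub["age"].to_numpy()
    if ages.size == 0:
        raise ProfileParseError(f"no rows for component {component!r} kind {kind!r}")
    expected = np.arange(ages.size)
    if not np.array_equal(ages, expected):
        missing = sorted(set(expected) - set(ages))
        row = int(sub.iloc[0]["_row"])
        raise ProfileParseError(
            f"non-contiguous ages for {component}/{kind} (first gap near age "
            f"{missing[0] if missing else ages[0]})",
            row=row,
        )
    if n_expected is not None and ages.size != n_expected:
        raise ProfileParseError(
            f"{component}/{kind} covers {ages.size} ages, expected {n_expected}"
        )
    values = sub["value"].to_numpy(dtype=float)
    if kind == "participation":
        bad = np.nonzero((values < 0) | (values > 1))[0]
        if bad.size:
            raise ProfileParseError(
                f"participation outside [0, 1] for {component} at age {ages[bad[0]]}",
                row=int(sub.iloc[bad[0]]["_row"]),
            )
    else:
        bad = np.nonzero(values < 0)[0]
        if bad.size:
            raise ProfileParseError(
                f"negative amount for {component} at age {ages[bad[0]]}",
                row=int(sub.iloc[bad[0]]["_row"]),
            )
    return AgeProfile(values)


def read_profiles(path: str | Path) -> tuple[TransferProfileSet, TaxProfileSet]:
    """Read and validate both profile sets from the CSV contract.

    Raises :class:`ProfileParseError` naming the first offending row.
    """
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (OSError, pd.errors.ParserError) as exc:
        raise ProfileParseError(f"cannot read profile CSV {path}: {exc}") from exc
    missing = set(_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ProfileParseError(f"missing columns: {sorted(missing)}")
    frame = frame.copy()
    frame["_row"] = frame.index + 2  # 1-based, after the header line

    known = set(TRANSFER_COMPONENTS) | set(TAX_COMPONENTS)
    unknown = set(frame["component"]) - known
    if unknown:
        row = int(frame.loc[frame["component"].isin(unknown), "_row"].iloc[0])
        raise ProfileParseError(f"unknown component {sorted(unknown)[0]!r}", row=row)

    n_ages: int | None = None
    transfer_kw = {}
    for name in TRANSFER_COMPONENTS:
        sub = frame[frame["component"] == name]
        amount = _series_to_profile(sub[sub["kind"] == "amount"], name, "amount", n_ages)
        n_ages = amount.values.size
        part = _series_to_profile(
            sub[sub["kind"] == "participation"], name, "participation", n_ages
        )
        transfer_kw[f"{name}_amount"] = amount
        transfer_kw[f"{name}_part"] = part
    tax_kw = {}
    for name in TAX_COMPONENTS:
        sub = frame[frame["component"] == name]
        tax_kw[name] = _series_to_profile(sub[sub["kind"] == "amount"], name, "amount", n_ages)
    try:
        return TransferProfileSet(**transfer_kw), TaxProfileSet(**tax_kw)
    except InvalidInputError as exc:
        raise ProfileParseError(str(exc)) from exc


# ---------------------------------------------------------------------- #
# rendering


def _fmt_euro(x: float) -> str:
    return f"{round_half_up(x):,.0f}"


def render_base_table(
    natural: FiscalResult,
    outcomes: Mapping[str, Mapping[str, tuple[ARTOutcome, int | None]]],
    fmt: str = "csv",
) -> str:
    """Base-case results table: natural conception plus one column per policy.

    ``outcomes`` maps technique label → policy label → (outcome, break-even
    age).  Euro amounts are shown half-up to whole euros; ROI and cycle
    counts to two decimals.  Rendering only reformats in-memory values.
    """
    if not outcomes:
        raise InvalidInputError("no results to render")
    policies: list[str] = []
    for by_policy in outcomes.values():
        if not by_policy:
            raise InvalidInputError("no results to render")
        for pol in by_policy:
            if pol not in policies:
                policies.append(pol)

    rows: list[tuple[str, ...]] = []

    def add(label: str, values: Sequence[str]) -> None:
        rows.append((label, *values))

    add("Taxes received (EUR)", [_fmt_euro(natural.pv_taxes)] * len(policies))
    add("Transfers to individual (EUR)", [_fmt_euro(natural.pv_transfers)] * len(policies))
    add("NFC (EUR)", [_fmt_euro(natural.nfc)] * len(policies))
    for technique, by_policy in outcomes.items():
        def cell(fn) -> list[str]:
            out = []
            for pol in policies:
                pair = by_policy.get(pol)
                out.append("" if pair is None else fn(*pair))
            return out

        add(f"{technique}: expected cycles", cell(lambda o, b: f"{o.expected_cycles:.2f}"))
        add(f"{technique}: expected cost (EUR)", cell(lambda o, b: _fmt_euro(o.expected_cost)))
        add(f"{technique}: expected NFC (EUR)", cell(lambda o, b: _fmt_euro(o.expected_nfc)))
        add(
            f"{technique}: expected NFC minus cost (EUR)",
            cell(lambda o, b: _fmt_euro(o.net_contribution)),
        )
        add(f"{technique}: break-even age (years)", cell(lambda o, b: "" if b is None else str(b)))
        add(f"{technique}: return on investment (EUR)", cell(lambda o, b: f"{o.roi:.2f}"))

    frame = pd.DataFrame(rows, columns=["quantity", *policies])
    if fmt == "csv":
        return frame.to_csv(index=False)
    if fmt == "markdown":
        header = "| " + " | ".join(frame.columns) + " |"
        sep = "| " + " | ".join("---" for _ in frame.columns) + " |"
        body = ["| " + " | ".join(str(v) for v in row) + " |" for row in frame.itertuples(index=False)]
        return "\n".join([header, sep, *body]) + "\n"
    raise InvalidInputError(f"unknown table format {fmt!r}")


# ---------------------------------------------------------------------- #
# pipeline


def _parse_policy(policy: str) -> int | None:
    policy = policy.strip().lower()
    if policy == "unlimited":
        return None
    if policy.startswith("capped:"):
        k = int(policy.split(":", 1)[1])
        if k < 1:
            raise InvalidInputError("capped policy needs at least one funded cycle")
        return k
    raise InvalidInputError(f"unknown funding policy {policy!r} (unlimited or capped:k)")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    macro: MacroParams = field(default_factory=MacroParams)
    techniques: tuple[str, ...] = ("IVF", "AI")
    policies: tuple[str, ...] = ("unlimited", "capped:3")
    art_overrides: tuple[Mapping, ...] = ()
    profile_csv: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    calibrate_taxes: float = DEFAULT_TARGET_PV_TAXES
    calibrate_transfers: float = DEFAULT_TARGET_PV_TRANSFERS
    output_dir: str = "out"
    table_format: str = "csv"
    scenario_technique: str = "IVF"
    scenario_policy: str = "capped:3"

    def __post_init__(self) -> None:
        if not self.techniques:
            raise InvalidInputError("at least one technique is required")
        if not self.policies:
            raise InvalidInputError("at least one funding policy is required")
        for policy in self.policies + (self.scenario_policy,):
            _parse_policy(policy)

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "RunConfig":
        kw: dict = {}
        if "macro" in cfg:
            kw["macro"] = MacroParams(**cfg["macro"])
        if "techniques" in cfg:
            kw["techniques"] = tuple(cfg["techniques"])
        if "policies" in cfg:
            kw["policies"] = tuple(cfg["policies"])
        if "art" in cfg:
            kw["art_overrides"] = tuple(cfg["art"])
        profiles = cfg.get("profiles", {})
        if "csv" in profiles:
            kw["profile_csv"] = str(profiles["csv"])
        if "synthetic" in profiles:
            syn = dict(profiles["synthetic"])
            kw["calibrate_taxes"] = float(syn.pop("calibrate_taxes", DEFAULT_TARGET_PV_TAXES))
            kw["calibrate_transfers"] = float(
                syn.pop("calibrate_transfers", DEFAULT_TARGET_PV_TRANSFERS)
            )
            kw["synthetic"] = SyntheticConfig(**syn)
        for key in ("output_dir", "table_format", "scenario_technique", "scenario_policy"):
            if key in cfg:
                kw[key] = cfg[key]
        return cls(**kw)


def _art_for(config: RunConfig, technique: str, funded: int | None) -> ARTParams:
    for override in config.art_overrides:
        if str(override.get("technique", "")).upper() == technique.upper():
            merged = dict(override)
            merged["funded_cycles"] = "unlimited" if funded is None else funded
            return ARTParams.from_config(merged)
    return default_params(technique, funded_cycles=funded)


def load_run_profiles(config: RunConfig) -> tuple[TransferProfileSet, TaxProfileSet]:
    """Resolve the run's profile source (CSV beats synthetic)."""
    if config.profile_csv is not None:
        return read_profiles(config.profile_csv)
    transfers, taxes = generate_profiles(config.synthetic)
    transfers, taxes, _ = calibrate(
        transfers, taxes, config.calibrate_taxes, config.calibrate_transfers, config.macro
    )
    return transfers, taxes


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full base-case + sensitivity pipeline and write artifacts.

    Writes ``base_table.csv`` (or ``.md``), ``sensitivity.csv``,
    ``tornado.csv``, ``cumulative.csv`` and ``run.log`` under the output
    directory; returns the paths.  Deterministic for a fixed config.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # validate every technique/policy before any computation
    arts: dict[str, dict[str, ARTParams]] = {}
    for technique in config.techniques:
        arts[technique] = {
            policy: _art_for(config, technique, _parse_policy(policy))
            for policy in config.policies
        }

    transfers, taxes = load_run_profiles(config)
    tax_profile = sum_taxes(taxes)
    transfer_profile = sum_transfers(transfers)
    natural = npv(tax_profile, transfer_profile, 0.0, config.macro)

    outcomes: dict[str, dict[str, tuple[ARTOutcome, int | None]]] = {}
    cumulative = {"natural": natural.cumulative}
    for technique, by_policy in arts.items():
        outcomes[technique] = {}
        for policy, art in by_policy.items():
            outcome = evaluate(art, natural.nfc)
            fiscal = npv(tax_profile, transfer_profile, outcome.expected_cost, config.macro)
            outcomes[technique][policy] = (outcome, fiscal.break_even_age)
            cumulative[f"{technique}:{policy}"] = fiscal.cumulative

    table = render_base_table(natural, outcomes, fmt=config.table_format)
    suffix = "md" if config.table_format == "markdown" else "csv"
    table_path = out_dir / f"base_table.{suffix}"
    table_path.write_text(table)

    scen_art = _art_for(
        config, config.scenario_technique, _parse_policy(config.scenario_policy)
    )
    base_result = evaluate_scenario(
        config.macro, transfers, taxes, scen_art, label="base"
    )
    results = run_sensitivity(config.macro, transfers, taxes, scen_art, TABLE_SCENARIOS)
    sens_frame = pd.DataFrame(
        [
            {
                "label": r.label,
                "expected_nfc": round_half_up(r.expected_nfc, 2),
                "net_contribution": round_half_up(r.net_contribution, 2),
                "break_even_age": r.break_even_age,
                "roi": round_half_up(r.roi, 2),
            }
            for r in results
        ]
    )
    sens_path = out_dir / "sensitivity.csv"
    sens_frame.to_csv(sens_path, index=False)

    torn_frame = pd.DataFrame(
        tornado(results, base_result), columns=["label", "roi_low", "roi_high"]
    )
    torn_path = out_dir / "tornado.csv"
    torn_frame.to_csv(torn_path, index=False)

    cum_frame = pd.DataFrame(
        {"age": np.arange(natural.cumulative.values.size)}
        | {name: prof.values for name, prof in cumulative.items()}
    )
    cum_path = out_dir / "cumulative.csv"
    cum_frame.to_csv(cum_path, index=False)

    log_path = out_dir / "run.log"
    resolved = {
        "macro": asdict(config.macro),
        "techniques": list(config.techniques),
        "policies": list(config.policies),
        "profile_source": config.profile_csv or "synthetic",
        "synthetic": asdict(config.synthetic) if config.profile_csv is None else None,
        "calibration_targets": {
            "pv_taxes": config.calibrate_taxes,
            "pv_transfers": config.calibrate_transfers,
        },
        "natural_nfc": natural.nfc,
    }
    log_path.write_text(json.dumps(resolved, indent=2, default=str) + "\n")
    logger.info("pipeline artifacts written to %s", out_dir)

    return {
        "base_table": table_path,
        "sensitivity": sens_path,
        "tornado": torn_path,
        "cumulative": cum_path,
        "log": log_path,
    }
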