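"""Configuration, CSV round-trips and the end-to-end trial driver.

One declarative config (YAML) holds every convention and every prior;
all randomness in a run descends from its single seed.  The driver runs
simulation -> isotope-dilution inversion -> summary statistics and
writes plain UTF-8 CSV tables plus a human-readable report that echoes
the conventions in force.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import syncohort, tracer_core, trial_stats
from .syncohort import CohortSpec, ConditionTruth, condition_id, default_condition_truths
from .tracer_core import DEFAULT_TRACER_PATTERNS, AbsorptionModelConfig, IsotopePattern

logger = logging.getLogger(__name__)

DEFAULT_COMPARISONS = [
    (condition_id("OatNF-SA-Fe", "water"), condition_id("FeSO4", "water")),
    (condition_id("OatNF-NaOH-Fe", "water"), condition_id("FeSO4", "water")),
    (condition_id("OatNF-SA-Fe", "acai"), condition_id("FeSO4", "acai")),
    (condition_id("OatNF-NaOH-Fe", "acai"), condition_id("FeSO4", "acai")),
]


class RunConfig(BaseModel):
    """Complete, serializable description of one synthetic trial run."""

    seed: int = 1
    cohort: CohortSpec = Field(default_factory=CohortSpec)
    truths: dict[str, ConditionTruth] = Field(default_factory=dict)
    tracer_patterns: dict[str, tuple[float, float, float, float]] = Field(
        default_factory=lambda: {
            k: tuple(v.as_array()) for k, v in DEFAULT_TRACER_PATTERNS.items()
        }
    )
    noise_sd_rel: float = Field(default=syncohort.DEFAULT_NOISE_SD_REL, ge=0)
    n_replicates: int = Field(default=syncohort.DEFAULT_N_REPLICATES, ge=1)
    fe_mass_mg: float = Field(default=syncohort.DEFAULT_DOSE_MG, gt=0)
    model: AbsorptionModelConfig = Field(default_factory=AbsorptionModelConfig)
    comparisons: list[tuple[str, str]] = Field(default_factory=lambda: list(DEFAULT_COMPARISONS))
    outdir: str | None = None

    def resolved_truths(self) -> dict[str, ConditionTruth]:
        return dict(self.truths) or default_condition_truths(self.cohort.n_participants)

    def resolved_patterns(self) -> dict[str, IsotopePattern]:
        return {k: IsotopePattern(*v) for k, v in self.tracer_patterns.items()}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# CSV schemas and validated round-trips
# ---------------------------------------------------------------------------


def _fraction(s: pd.Series) -> pd.Series:
    return (s < 0) | (s > 1)


def _negative(s: pd.Series) -> pd.Series:
    return s < 0


#: name -> (columns, {numeric column -> invalid-row predicate})
TABLE_SCHEMAS: dict[str, tuple[list[str], dict[str, Callable[[pd.Series], pd.Series]]]] = {
    "cohort": (
        ["participant_id", "age_y", "height_cm", "weight_kg", "hb_g_l", "sf_ug_l", "crp_mg_l"],
        {c: _negative for c in ["age_y", "height_cm", "weight_kg", "hb_g_l", "sf_ug_l", "crp_mg_l"]},
    ),
    "design": (
        ["participant_id", "phase", "day", "compound", "matrix", "condition_id", "tracer", "fe_mass_mg"],
        {"fe_mass_mg": _negative},
    ),
    "truth": (
        ["participant_id", "phase", "day", "compound", "matrix", "condition_id", "tracer",
         "fe_mass_mg", "true_fia"],
        {"true_fia": _fraction},
    ),
    "measurements": (
        ["participant_id", "day", "a54", "a56", "a57", "a58"],
        {c: _fraction for c in ["a54", "a56", "a57", "a58"]},
    ),
    "fia": (
        ["participant_id", "condition_id", "tracer", "phase", "q_mol", "fia", "flags"],
        {"q_mol": _negative, "fia": _negative},
    ),
    "summary": (["condition_id", "gm", "ci_lo", "ci_hi", "n"], {"gm": _negative}),
    "rbv": (
        ["pair", "gm_ratio", "ci_lo", "ci_hi", "ratio_of_gms", "n", "t", "p_raw", "p_adj"],
        {"gm_ratio": _negative},
    ),
}

_STRING_COLUMNS = {"participant_id", "compound", "matrix", "condition_id", "tracer", "flags", "pair"}


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write a schema-checked table as UTF-8 CSV with a header row."""
    columns, _ = TABLE_SCHEMAS[schema]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{schema} table missing column(s) {missing}")
    df[columns].to_csv(path, index=False, encoding="utf-8")


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table; errors name the file, row and column."""
    columns, checks = TABLE_SCHEMAS[schema]
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in columns:
        if col in _STRING_COLUMNS:
            df[col] = df[col].fillna("")  # empty strings round-trip as NaN
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {row}")
        df[col] = numeric
        if col in checks:
            invalid = checks[col](df[col]).fillna(False)
            if invalid.any():
                row = int(invalid.idxmax())
                raise ValueError(
                    f"{path}: column {col!r}, row {row}: value {df[col].iloc[row]!r} "
                    "violates the schema constraint"
                )
    return df[columns]


def roundtrip_tables(outdir: str | Path, tables: Mapping[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Write every table and read it back validated (write-then-read equality
    within CSV float precision)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        write_table(df, path, name)
        out[name] = read_table(path, name)
    return out


# ---------------------------------------------------------------------------
# End-to-end driver
# ---------------------------------------------------------------------------


def run_end_to_end(config: RunConfig) -> dict:
    """Simulate, invert and summarize one full cross-over trial.

    Returns the bundle of tables; if config.outdir is set, also writes
    cohort/design/truth/measurements/fia/summary/rbv CSVs and report.txt.
    """
    truths = config.resolved_truths()
    patterns = config.resolved_patterns()
    missing = sorted(
        {condition_id(c, m) for c in syncohort.COMPOUNDS for m in ("water", "acai")} - set(truths)
    )
    if missing:
        raise ValueError(f"config missing condition truth(s): {missing}")

    spec = config.cohort.model_copy(update={"seed": config.seed})
    tables = syncohort.simulate_trial(
        spec, truths, config.noise_sd_rel,
        fe_mass_mg=config.fe_mass_mg, tracer_patterns=patterns,
        config=config.model, n_replicates=config.n_replicates,
    )
    fia, skipped = tracer_core.process_trial(
        tables["measurements"], tables["design"], tables["cohort"], patterns, config.model
    )
    summary = trial_stats.summarize_fia(fia)
    rbv = trial_stats.rbv_table(fia, config.comparisons)
    bundle = {**tables, "fia": fia, "summary": summary, "rbv": rbv, "skipped": skipped}

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        roundtrip_tables(outdir, {k: bundle[k] for k in
                                  ("cohort", "design", "truth", "measurements", "fia", "summary", "rbv")})
        (outdir / "report.txt").write_text(_report_text(config, bundle))
    return bundle


def _report_text(config: RunConfig, bundle: Mapping) -> str:
    fia = bundle["fia"]
    flagged = fia[fia["flags"] != ""]
    lines = [
        "ferrotrace end-to-end run report",
        "=" * 34,
        f"seed: {config.seed}",
        f"participants: {config.cohort.n_participants}",
        f"absorption records: {len(fia)}",
        "",
        "conventions in force:",
        f"  blood-volume formula: {config.model.bv_formula}",
        f"  erythrocyte incorporation factor F: {config.model.incorporation_factor}",
        f"  iron per haemoglobin: {config.model.fe_per_hb} mg/g",
        f"  inversion solver space: {config.model.solver_space}",
        f"  isotope-ratio noise sd (relative): {config.noise_sd_rel}",
        f"  replicate measurements averaged: {config.n_replicates}",
        f"  dose per condition: {config.fe_mass_mg} mg Fe",
        f"  true-FIA truncation: {syncohort.FIA_TRUNCATION}",
        "  summaries: geometric means, t-based 95% CIs on the ln scale",
        "  paired tests: two-sided t on ln FIA, Bonferroni over comparisons",
        "",
        f"flags raised: {len(flagged)}",
    ]
    for _, row in flagged.iterrows():
        lines.append(f"  {row['participant_id']} {row['condition_id']}: {row['flags']}")
    lines.append(f"participant phases skipped: {len(bundle['skipped'])}")
    for pid, reason in bundle["skipped"]:
        lines.append(f"  {pid}: {reason}")
    lines.append("")
    lines.append("condition summaries (GM FIA, 95% CI):")
    for _, row in bundle["summary"].iterrows():
        lines.append(
            f"  {row['condition_id']}: {100 * row['gm']:.1f}% "
            f"({100 * row['ci_lo']:.1f}-{100 * row['ci_hi']:.1f}%), n={int(row['n'])}"
        )
    lines.append("")
    lines.append("relative bioavailability (GM of individual ratios, 95% CI):")
    for _, row in bundle["rbv"].iterrows():
        lines.append(
            f"  {row['pair']}: {row['gm_ratio']:.2f} "
            f"({row['ci_lo']:.2f}-{row['ci_hi']:.2f}), p_adj={row['p_adj']:.4g}"
        )
    return "\n".join(lines) + "\n"
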