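"""Isotope-dilution core: invert erythrocyte iron isotope patterns into
per-tracer incorporated iron and fractional iron absorption (FIA).

The measurement model is a two-pool mixing model.  A participant's
circulating iron pool (``N`` mol, isotope pattern ``baseline``) receives
``q_i`` mol of each enriched tracer ``i`` (pattern ``t_i``).  The measured
erythrocyte pattern two weeks after dosing is the mole-weighted mixture

    measured = (N * baseline + sum_i q_i * t_i) / (N + sum_i q_i)

with ``N + sum_i q_i`` fixed to the total circulating iron estimated from
blood volume (height/weight regression) and haemoglobin.  Because only a
fraction ``F`` (default 0.80) of absorbed iron is incorporated into
erythrocytes by the sampling day, the fractional absorption of dose ``d``
is ``FIA = q / (F * d_mol)``.

Both the ratio-space formulation (ratios to 56Fe, matching how the mass
spectrometer reports and how noise enters) and the abundance-space
formulation are linear in ``q`` and solved by non-negative least squares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

ISOTOPE_LABELS = ("54Fe", "56Fe", "57Fe", "58Fe")

# Atomic masses (g/mol) of the four stable iron isotopes.
ISOTOPE_MASSES = np.array([53.9396, 55.9349, 56.9354, 57.9333])

#: Indices of the three abundances that are independent once the pattern
#: is normalized (54, 57, 58; 56Fe is the reference isotope).
_FREE = np.array([0, 2, 3])

_PATTERN_SUM_TOL = 1e-9


@dataclass(frozen=True)
class IsotopePattern:
    """Fractional molar abundances of 54Fe/56Fe/57Fe/58Fe. Must sum to 1."""

    a54: float
    a56: float
    a57: float
    a58: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("isotope abundances must be finite")
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"abundances must lie in [0, 1], got {arr}")
        if abs(arr.sum() - 1.0) > _PATTERN_SUM_TOL:
            raise ValueError(
                f"abundances must sum to 1 within {_PATTERN_SUM_TOL}, got {arr.sum()!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.a54, self.a56, self.a57, self.a58], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float], renormalize: bool = False) -> "IsotopePattern":
        a = np.asarray(arr, dtype=float)
        if a.shape != (4,):
            raise ValueError("expected 4 abundances (54, 56, 57, 58)")
        if renormalize:
            s = a.sum()
            if s <= 0:
                raise ValueError("cannot renormalize a non-positive pattern")
            a = a / s
        return cls(*a)

    def ratios_to_56(self) -> np.ndarray:
        """Ratios 54/56, 57/56, 58/56 (the instrument-facing representation)."""
        if self.a56 <= 0:
            raise ValueError("ratios to 56Fe undefined for a56 <= 0")
        return self.as_array()[_FREE] / self.a56

    @classmethod
    def from_ratios_to_56(cls, ratios: Sequence[float]) -> "IsotopePattern":
        r = np.asarray(ratios, dtype=float)
        if r.shape != (3,):
            raise ValueError("expected 3 ratios (54/56, 57/56, 58/56)")
        if np.any(r < 0):
            raise ValueError("ratios must be non-negative")
        a = np.array([r[0], 1.0, r[1], r[2]])
        return cls.from_array(a / a.sum())


#: IUPAC representative natural iron isotopic composition.
NATURAL_ABUNDANCE = IsotopePattern(0.05845, 0.91754, 0.02119, 0.00282)

#: Default enrichment patterns of the three tracers.  Synthetic defaults
#: (commercial enriched iron varies batch to batch); configurable wherever
#: a pattern is consumed, never baked into the mixing math.
DEFAULT_TRACER_PATTERNS: dict[str, IsotopePattern] = {
    "54Fe": IsotopePattern(0.998, 0.002, 0.0, 0.0),
    "57Fe": IsotopePattern(0.001, 0.049, 0.948, 0.002),
    "58Fe": IsotopePattern(0.001, 0.040, 0.020, 0.939),
}


def pattern_molar_mass(pattern: IsotopePattern) -> float:
    """Molar mass (g/mol) of iron with the given isotopic composition."""
    return float(pattern.as_array() @ ISOTOPE_MASSES)


# ---------------------------------------------------------------------------
# Anthropometry-based circulating iron
# ---------------------------------------------------------------------------

# Height/weight blood-volume regressions, BV in litres, height in metres.
BLOOD_VOLUME_FORMULAS = {
    "nadler-female": lambda h_m, w_kg: 0.3561 * h_m**3 + 0.03308 * w_kg + 0.1833,
    "nadler-male": lambda h_m, w_kg: 0.3669 * h_m**3 + 0.03219 * w_kg + 0.6041,
}

DEFAULT_BV_FORMULA = "nadler-female"


def blood_volume(height_cm: float, weight_kg: float, formula: str = DEFAULT_BV_FORMULA) -> float:
    """Estimate total blood volume (L) from height and weight."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    try:
        f = BLOOD_VOLUME_FORMULAS[formula]
    except KeyError:
        raise ValueError(
            f"unknown blood-volume formula {formula!r}; "
            f"choose from {sorted(BLOOD_VOLUME_FORMULAS)}"
        ) from None
    return f(height_cm / 100.0, weight_kg)


class AbsorptionModelConfig(BaseModel):
    """Conventions of the erythrocyte-incorporation absorption model.

    incorporation_factor
        Fraction of absorbed iron incorporated into circulating
        erythrocytes by the sampling day (study assumption 0.80).
    fe_per_hb
        Iron stoichiometry of haemoglobin, mg Fe per g Hb.
    bv_formula
        Named blood-volume regression (adult-female default).
    solver_space
        ``"ratio"`` solves the mixing model on the three ratios to 56Fe
        (default; noise enters on ratios), ``"abundance"`` on abundances.
    """

    incorporation_factor: float = Field(default=0.80, gt=0, le=1)
    fe_per_hb: float = Field(default=3.47, gt=0)
    bv_formula: str = DEFAULT_BV_FORMULA
    solver_space: str = "ratio"

    @model_validator(mode="after")
    def _check_names(self) -> "AbsorptionModelConfig":
        if self.bv_formula not in BLOOD_VOLUME_FORMULAS:
            raise ValueError(f"unknown blood-volume formula {self.bv_formula!r}")
        if self.solver_space not in ("ratio", "abundance"):
            raise ValueError("solver_space must be 'ratio' or 'abundance'")
        return self


def circulating_iron(bv_l: float, hb_g_l: float, config: AbsorptionModelConfig | None = None) -> float:
    """Total circulating iron (mg) from blood volume (L) and Hb (g/L)."""
    if bv_l < 0 or hb_g_l < 0:
        raise ValueError("blood volume and haemoglobin must be non-negative")
    fe_per_hb = (config or AbsorptionModelConfig()).fe_per_hb
    return bv_l * hb_g_l * fe_per_hb


def circulating_iron_mol(
    height_cm: float,
    weight_kg: float,
    hb_g_l: float,
    baseline: IsotopePattern,
    config: AbsorptionModelConfig | None = None,
) -> float:
    """Circulating iron in moles.

    Convention: the mass-to-mole conversion uses the molar mass of the
    phase baseline pattern (the mixture's molar mass differs by < 1e-4
    relative at tracer doses of a few mg).  The forward simulator uses the
    identical convention so a noiseless round trip is exact.
    """
    cfg = config or AbsorptionModelConfig()
    bv = blood_volume(height_cm, weight_kg, cfg.bv_formula)
    mg = circulating_iron(bv, hb_g_l, cfg)
    return mg / 1000.0 / pattern_molar_mass(baseline)


# ---------------------------------------------------------------------------
# Doses and inversion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TracerDose:
    """One administered tracer dose."""

    label: str
    fe_mass_mg: float
    pattern: IsotopePattern
    day: int
    condition_id: str

    def __post_init__(self) -> None:
        if self.fe_mass_mg <= 0:
            raise ValueError("dose iron mass must be positive")

    @property
    def fe_mol(self) -> float:
        return self.fe_mass_mg / 1000.0 / pattern_molar_mass(self.pattern)


class TracerSolve(NamedTuple):
    q_mol: dict[str, float]
    residual: float
    condition_number: float


def _mix(baseline: np.ndarray, tracers: np.ndarray, q: np.ndarray, total_mol: float) -> np.ndarray:
    """Forward mixing model on abundance vectors. tracers: (k, 4)."""
    n_prior = total_mol - q.sum()
    return (n_prior * baseline + q @ tracers) / total_mol


def solve_tracer_increments(
    measured: IsotopePattern,
    baseline: IsotopePattern,
    tracer_patterns: Mapping[str, IsotopePattern],
    total_circulating_mol: float,
    *,
    space: str = "ratio",
    cond_threshold: float = 1e8,
) -> TracerSolve:
    """Solve the isotope-dilution mixing model for incorporated tracer moles.

    With the pool size constrained to ``total_circulating_mol`` the mixture
    abundances are affine in q, so both formulations reduce to a small
    non-negative linear least-squares problem:

    * ``space="ratio"`` (default): residuals r_k*a56(q) - a_k(q) on the
      three independent ratios to 56Fe;
    * ``space="abundance"``: residuals a_meas,k - a_k(q) on abundances
      54, 57, 58.

    Non-negativity (q >= 0) is enforced by the active-set NNLS solver;
    a tiny negative increment from measurement noise is unphysical.

    Returns estimated moles per tracer label, the residual norm, and the
    condition number of the design matrix.
    """
    if total_circulating_mol <= 0:
        raise ValueError("total circulating iron must be positive")
    if not 1 <= len(tracer_patterns) <= 3:
        raise ValueError("between 1 and 3 tracers supported")
    if space not in ("ratio", "abundance"):
        raise ValueError("space must be 'ratio' or 'abundance'")

    labels = list(tracer_patterns)
    b = baseline.as_array()
    t = np.stack([tracer_patterns[lb].as_array() for lb in labels])  # (k, 4)
    c = (t - b).T  # (4, k): abundance shift per mole fraction of tracer

    if space == "ratio":
        r = measured.ratios_to_56()  # 54/56, 57/56, 58/56
        # r_k * a56(q) - a_k(q) = 0, affine in x = q / total_mol:
        #   A[k, i] = r_k * c56_i - c_k_i ;  y_k = b_k - r_k * b56
        a_mat = np.outer(r, c[1]) - c[_FREE]
        y = b[_FREE] - r * b[1]
    else:
        m = measured.as_array()
        a_mat = c[_FREE]
        y = m[_FREE] - b[_FREE]

    cond = float(np.linalg.cond(a_mat))
    if cond > cond_threshold:
        raise ValueError(
            f"ill-conditioned mixing system (condition number {cond:.3g} > "
            f"{cond_threshold:.3g}); tracer patterns too close to baseline"
        )
    x, resid = nnls(a_mat, y)
    q = x * total_circulating_mol
    if q.sum() >= total_circulating_mol:
        raise ValueError("solved tracer moles exceed the circulating pool (unphysical)")
    return TracerSolve(dict(zip(labels, q.tolist())), float(resid), cond)


class FiaEstimate(NamedTuple):
    fia: float
    out_of_range: bool


def fia_from_increment(
    q_mol: float, dose: TracerDose, config: AbsorptionModelConfig | None = None
) -> FiaEstimate:
    """Fractional iron absorption from incorporated tracer moles.

    FIA = q / (F * dose_mol).  Values above 1 indicate a mass-balance or
    model failure and are flagged, never clipped.
    """
    if q_mol < 0:
        raise ValueError("incorporated moles must be non-negative")
    cfg = config or AbsorptionModelConfig()
    dose_mol = dose.fe_mol
    if dose_mol <= 0:
        raise ValueError("dose must contain iron")
    fia = q_mol / (cfg.incorporation_factor * dose_mol)
    return FiaEstimate(fia, fia > 1.0)


# ---------------------------------------------------------------------------
# Whole-trial processing
# ---------------------------------------------------------------------------

SAMPLING_DAYS = (1, 19, 37)
PHASE_OF_BASELINE_DAY = {1: 1, 19: 2}  # baseline day -> phase it baselines


def _pattern_from_row(row: pd.Series) -> IsotopePattern:
    return IsotopePattern.from_array(
        [row["a54"], row["a56"], row["a57"], row["a58"]], renormalize=True
    )


def process_trial(
    measurements: pd.DataFrame,
    doses: pd.DataFrame,
    cohort: pd.DataFrame,
    tracer_patterns: Mapping[str, IsotopePattern] | None = None,
    config: AbsorptionModelConfig | None = None,
) -> tuple[pd.DataFrame, list[tuple[object, str]]]:
    """Invert a full cross-over trial into absorption records.

    Parameters
    ----------
    measurements
        One row per participant per sampling day (1, 19, 37) with columns
        participant_id, day, a54, a56, a57, a58.  Duplicate rows for the
        same (participant, day) are treated as replicate measurements and
        averaged on the ratio scale before inversion.
    doses
        participant_id, phase, day, condition_id, tracer, fe_mass_mg.
    cohort
        participant_id, height_cm, weight_kg, hb_g_l.

    Phase 1 is inverted against the day-1 baseline using the day-19
    pattern; phase 2 against the day-19 pattern (sequential baselining)
    using day 37.  Participants missing a sampling day are skipped with a
    logged reason.  Returns (records, skipped).
    """
    cfg = config or AbsorptionModelConfig()
    patterns = dict(tracer_patterns or DEFAULT_TRACER_PATTERNS)
    cohort_ix = cohort.set_index("participant_id")

    records: list[dict] = []
    skipped: list[tuple[object, str]] = []
    for pid, meas in measurements.groupby("participant_id", sort=True):
        if pid not in cohort_ix.index:
            skipped.append((pid, "missing anthropometry"))
            logger.warning("participant %s skipped: missing anthropometry", pid)
            continue
        anthro = cohort_ix.loc[pid]
        day_patterns: dict[int, IsotopePattern] = {}
        for day, rows in meas.groupby("day"):
            ratios = np.stack([_pattern_from_row(r).ratios_to_56() for _, r in rows.iterrows()])
            day_patterns[int(day)] = IsotopePattern.from_ratios_to_56(ratios.mean(axis=0))

        pdoses = doses[doses["participant_id"] == pid]
        for baseline_day, phase in PHASE_OF_BASELINE_DAY.items():
            sample_day = 19 if phase == 1 else 37
            if baseline_day not in day_patterns or sample_day not in day_patterns:
                missing = baseline_day if baseline_day not in day_patterns else sample_day
                skipped.append((pid, f"missing day {missing}"))
                logger.warning("participant %s phase %d skipped: missing day %d", pid, phase, missing)
                continue
            phase_doses = pdoses[pdoses["phase"] == phase]
            if phase_doses.empty:
                skipped.append((pid, f"no doses for phase {phase}"))
                continue
            baseline = day_patterns[baseline_day]
            measured = day_patterns[sample_day]
            total_mol = circulating_iron_mol(
                float(anthro["height_cm"]), float(anthro["weight_kg"]),
                float(anthro["hb_g_l"]), baseline, cfg,
            )
            tr = {row["tracer"]: patterns[row["tracer"]] for _, row in phase_doses.iterrows()}
            sol = solve_tracer_increments(
                measured, baseline, tr, total_mol, space=cfg.solver_space
            )
            for _, drow in phase_doses.iterrows():
                dose = TracerDose(
                    label=drow["tracer"],
                    fe_mass_mg=float(drow["fe_mass_mg"]),
                    pattern=patterns[drow["tracer"]],
                    day=int(drow["day"]),
                    condition_id=drow["condition_id"],
                )
                est = fia_from_increment(sol.q_mol[dose.label], dose, cfg)
                records.append(
                    {
                        "participant_id": pid,
                        "condition_id": dose.condition_id,
                        "tracer": dose.label,
                        "phase": phase,
                        "q_mol": sol.q_mol[dose.label],
                        "fia": est.fia,
                        "flags": "fia>1" if est.out_of_range else "",
                    }
                )
    out = pd.DataFrame.from_records(
        records,
        columns=["participant_id", "condition_id", "tracer", "phase", "q_mol", "fia", "flags"],
    )
    return out, skipped


# ---------------------------------------------------------------------------
# Eligibility screening
# ---------------------------------------------------------------------------


class EligibilityCriteria(BaseModel):
    """Screening thresholds for the absorption study population."""

    sf_max_ug_l: float = 50.0
    hb_min_g_l: float = 120.0
    bmi_min: float = 18.5
    bmi_max: float = 24.9
    weight_max_kg: float = 70.0
    age_min_y: float = 18.0
    age_max_y: float = 45.0
    crp_max_mg_l: float = 5.0

    @model_validator(mode="after")
    def _ranges(self) -> "EligibilityCriteria":
        if not (self.bmi_min < self.bmi_max and self.age_min_y < self.age_max_y):
            raise ValueError("range minima must be below maxima")
        return self


class EligibilityDecision(NamedTuple):
    eligible: bool
    reasons: list[str]


_SCREEN_FIELDS = ("sf_ug_l", "hb_g_l", "height_cm", "weight_kg", "age_y", "crp_mg_l")


def check_eligibility(
    record: Mapping[str, float], criteria: EligibilityCriteria | None = None
) -> EligibilityDecision:
    """Apply the screening rules; reasons list every failed rule.

    Rules: SF < 50 ug/L, Hb >= 120 g/L (failure is 'anaemia'),
    BMI in [18.5, 24.9], weight < 70 kg, age 18-45 y, CRP <= 5 mg/L.
    """
    crit = criteria or EligibilityCriteria()
    missing = [f for f in _SCREEN_FIELDS if f not in record or record[f] is None]
    if missing:
        raise ValueError(f"record missing screened fields: {missing}")
    bmi = record["weight_kg"] / (record["height_cm"] / 100.0) ** 2
    reasons = []
    if not record["sf_ug_l"] < crit.sf_max_ug_l:
        reasons.append("SF")
    if record["hb_g_l"] < crit.hb_min_g_l:
        reasons.append("anaemia")
    if not crit.bmi_min <= bmi <= crit.bmi_max:
        reasons.append("BMI")
    if not record["weight_kg"] < crit.weight_max_kg:
        reasons.append("weight")
    if not crit.age_min_y <= record["age_y"] <= crit.age_max_y:
        reasons.append("age")
    if record["crp_mg_l"] > crit.crp_max_mg_l:
        reasons.append("CRP")
    return EligibilityDecision(not reasons, reasons)
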