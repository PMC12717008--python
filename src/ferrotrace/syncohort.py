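"""Synthetic cohort and forward measurement simulator.

Emulates a 52-participant, three-tracer, two-matrix cross-over iron
absorption study: participant screening variables, the randomized
condition order (each tracer once per phase, days 1/3/5 and 19/21/23),
lognormal per-condition true absorption with a shared within-person
effect, and forward-simulated erythrocyte isotope patterns on the three
blood-draw days (1, 19, 37) with multiplicative isotope-ratio noise.

Every downstream stage (inversion, statistics) is testable against the
known generating truth without any external data.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.stats import norm

from .tracer_core import (
    DEFAULT_TRACER_PATTERNS,
    NATURAL_ABUNDANCE,
    AbsorptionModelConfig,
    IsotopePattern,
    blood_volume,
    circulating_iron,
    pattern_molar_mass,
)

COMPOUNDS = ("OatNF-SA-Fe", "OatNF-NaOH-Fe", "FeSO4")

#: Fixed compound <-> tracer labelling used throughout the study.
COMPOUND_TRACER = {
    "OatNF-SA-Fe": "57Fe",
    "OatNF-NaOH-Fe": "58Fe",
    "FeSO4": "54Fe",
}

MATRIX_OF_PHASE = {1: "water", 2: "acai"}
PHASE_DAYS = {1: (1, 3, 5), 2: (19, 21, 23)}
DEFAULT_DOSE_MG = 4.0


def condition_id(compound: str, matrix: str) -> str:
    return f"{compound}:{matrix}"


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


class CohortSpec(BaseModel):
    """Priors of the screened study population.

    Defaults describe young, non-anaemic, iron-deficient (SF < 50 ug/L)
    women of the study's region: height/weight/Hb normal priors, serum
    ferritin and CRP lognormal (GM, GSD) priors, age uniform in range.
    """

    n_participants: int = Field(default=52, ge=1)
    seed: int = 0
    height_prior: tuple[float, float] = (157.0, 6.0)   # mean cm, sd cm
    weight_prior: tuple[float, float] = (54.0, 6.0)    # mean kg, sd kg
    hb_prior: tuple[float, float] = (131.0, 9.0)       # mean g/L, sd g/L
    sf_prior: tuple[float, float] = (22.0, 1.8)        # GM ug/L, GSD
    crp_prior: tuple[float, float] = (0.8, 2.2)        # GM mg/L, GSD
    age_range: tuple[float, float] = (18.0, 45.0)

    @model_validator(mode="after")
    def _positive_dispersion(self) -> "CohortSpec":
        for name in ("height_prior", "weight_prior", "hb_prior"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"{name} sd must be strictly positive")
        for name in ("sf_prior", "crp_prior"):
            if getattr(self, name)[1] <= 1:
                raise ValueError(f"{name} GSD must be > 1")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be increasing")
        return self


class ConditionTruth(BaseModel):
    """Generating truth for one compound-matrix condition.

    true FIA of participant p in condition c:
        FIA_pc = gm_fia * exp(person_effect_sd * z_p + e_pc),
        z_p ~ N(0,1) shared across conditions, e_pc ~ N(0, ln(gsd_fia)^2),
    truncated above at 0.95 to keep the tracer mass balance physical.
    """

    condition_id: str
    gm_fia: float = Field(gt=0, lt=1)
    gsd_fia: float = Field(ge=1)
    person_effect_sd: float = Field(ge=0)


def lognormal_sd_from_ci(ci_lo: float, ci_hi: float, n: int, level: float = 0.95) -> float:
    """Back-derive the ln-scale sample sd from a printed GM confidence interval.

    A two-sided CI for a geometric mean at confidence ``level`` spans
    exp(+-z * sd/sqrt(n)) around the GM, so sd = ln(hi/lo)/(2 z) * sqrt(n).
    """
    if not 0 < ci_lo < ci_hi:
        raise ValueError("need 0 < ci_lo < ci_hi")
    z = norm.ppf(0.5 + level / 2)
    return math.log(ci_hi / ci_lo) / (2 * z) * math.sqrt(n)


# Dispersion decomposition for the default generating truths.
#
# The within-person residual ln-sd comes from the reported sd of paired
# differences of log10 FIA (0.223) observed in the predecessor study:
#   sd_diff(ln) = 0.223 * ln(10), and for two independent residuals
#   sd_diff = sqrt(2) * sigma_e  =>  sigma_e = 0.223 * ln(10) / sqrt(2).
# The shared person-effect sd is then fixed so that the *total* ln-sd of
# the reference condition (GM 46.2%, 95% CI 38.9-55.0%, n = 52) matches
# its CI-implied dispersion: person_sd = sqrt(total^2 - sigma_e^2).
_SIGMA_E_REF = 0.223 * math.log(10.0) / math.sqrt(2.0)
_TOTAL_SD_REF = lognormal_sd_from_ci(0.389, 0.550, 52)
DEFAULT_PERSON_EFFECT_SD = math.sqrt(_TOTAL_SD_REF**2 - _SIGMA_E_REF**2)

# Printed geometric means and 95% CIs (fractions) of the six conditions.
_CONDITION_GM_CI = {
    condition_id("OatNF-SA-Fe", "water"): (0.462, 0.389, 0.550),
    condition_id("OatNF-NaOH-Fe", "water"): (0.203, 0.161, 0.257),
    condition_id("FeSO4", "water"): (0.263, 0.214, 0.324),
    condition_id("OatNF-SA-Fe", "acai"): (0.134, 0.098, 0.183),
    condition_id("OatNF-NaOH-Fe", "acai"): (0.063, 0.049, 0.081),
    condition_id("FeSO4", "acai"): (0.081, 0.061, 0.106),
}


def default_condition_truths(n: int = 52) -> dict[str, ConditionTruth]:
    """Generating truths centred on the study's printed GMs and CIs.

    Each condition's residual GSD is what remains of its CI-implied total
    ln-sd after removing the shared person effect.
    """
    truths = {}
    for cid, (gm, lo, hi) in _CONDITION_GM_CI.items():
        total = lognormal_sd_from_ci(lo, hi, n)
        ln_gsd = math.sqrt(max(total**2 - DEFAULT_PERSON_EFFECT_SD**2, 1e-12))
        truths[cid] = ConditionTruth(
            condition_id=cid,
            gm_fia=gm,
            gsd_fia=math.exp(ln_gsd),
            person_effect_sd=DEFAULT_PERSON_EFFECT_SD,
        )
    return truths


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_participants(spec: CohortSpec) -> pd.DataFrame:
    """Draw a screened cohort table from the spec's priors.

    Deterministic under spec.seed; BMI is derivable from the height and
    weight columns.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    width = max(3, len(str(n)))
    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:0{width}d}" for i in range(n)],
            "age_y": np.floor(rng.uniform(*spec.age_range, size=n)),
            "height_cm": rng.normal(*spec.height_prior, size=n),
            "weight_kg": rng.normal(*spec.weight_prior, size=n),
            "hb_g_l": rng.normal(*spec.hb_prior, size=n),
            "sf_ug_l": spec.sf_prior[0] * np.exp(rng.normal(0, math.log(spec.sf_prior[1]), size=n)),
            "crp_mg_l": spec.crp_prior[0] * np.exp(rng.normal(0, math.log(spec.crp_prior[1]), size=n)),
        }
    )


def assign_crossover_design(
    participant_ids: Sequence, seed: int, fe_mass_mg: float = DEFAULT_DOSE_MG
) -> pd.DataFrame:
    """Randomize the condition order per participant per phase.

    Each tracer (hence compound) is used exactly once per phase; the
    compound-to-day assignment is an independent uniform permutation for
    each participant and phase.  Matrix is water in phase 1, acai puree
    in phase 2.
    """
    ids = list(participant_ids)
    if not ids:
        raise ValueError("participant id list is empty")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids")
    rng = np.random.default_rng(seed)
    rows = []
    for pid in ids:
        for phase, days in PHASE_DAYS.items():
            order = rng.permutation(len(COMPOUNDS))
            matrix = MATRIX_OF_PHASE[phase]
            for day, ci in zip(days, order):
                compound = COMPOUNDS[ci]
                rows.append(
                    {
                        "participant_id": pid,
                        "phase": phase,
                        "day": day,
                        "compound": compound,
                        "matrix": matrix,
                        "condition_id": condition_id(compound, matrix),
                        "tracer": COMPOUND_TRACER[compound],
                        "fe_mass_mg": fe_mass_mg,
                    }
                )
    return pd.DataFrame(rows)


FIA_TRUNCATION = 0.95  # keeps the tracer mass balance physical


def generate_true_fia(
    design: pd.DataFrame, truths: Mapping[str, ConditionTruth], seed: int
) -> pd.DataFrame:
    """Attach a lognormal true FIA to every design row.

    One standard-normal person draw is shared across a participant's
    conditions (within-person correlation), scaled by each condition's
    person-effect sd; the condition residual uses ln(gsd_fia).
    """
    missing = sorted(set(design["condition_id"]) - set(truths))
    if missing:
        raise KeyError(f"no ConditionTruth for condition(s): {missing}")
    rng = np.random.default_rng(seed)
    pids = pd.unique(design["participant_id"])
    z_person = dict(zip(pids, rng.standard_normal(len(pids))))
    out = design.copy()
    fia = np.empty(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        t = truths[row.condition_id]
        e = rng.normal(0.0, math.log(t.gsd_fia)) if t.gsd_fia > 1 else 0.0
        fia[i] = t.gm_fia * math.exp(t.person_effect_sd * z_person[row.participant_id] + e)
    out["true_fia"] = np.minimum(fia, FIA_TRUNCATION)
    return out


# ---------------------------------------------------------------------------
# Forward measurement model
# ---------------------------------------------------------------------------

DEFAULT_NOISE_SD_REL = 5e-4  # typical isotope-ratio relative precision
DEFAULT_N_REPLICATES = 2     # duplicate measurements, averaged


def _noisy_pattern(
    true_pattern: IsotopePattern, noise_sd_rel: float, rng: np.random.Generator, n_replicates: int
) -> IsotopePattern:
    """Measurement model: each ratio to 56Fe perturbed multiplicatively,
    replicates averaged on the ratio scale, pattern renormalized."""
    ratios = true_pattern.ratios_to_56()
    if noise_sd_rel > 0:
        factors = rng.normal(1.0, noise_sd_rel, size=(n_replicates, 3))
        ratios = (ratios * factors).mean(axis=0)
    return IsotopePattern.from_ratios_to_56(ratios)


def forward_simulate_measurements(
    cohort: pd.DataFrame,
    truth: pd.DataFrame,
    noise_sd_rel: float = DEFAULT_NOISE_SD_REL,
    seed: int = 0,
    *,
    tracer_patterns: Mapping[str, IsotopePattern] | None = None,
    config: AbsorptionModelConfig | None = None,
    natural: IsotopePattern = NATURAL_ABUNDANCE,
    n_replicates: int = DEFAULT_N_REPLICATES,
) -> pd.DataFrame:
    """Simulate erythrocyte isotope patterns on the three blood-draw days.

    For each phase the circulating pool (moles from that day's blood
    volume and Hb, converted with the phase-baseline molar mass) absorbs
    q_i = FIA_i * dose_mol_i * F moles of each tracer; the new pool
    pattern is the mole-weighted mixture of the previous draw's (true)
    pattern and the tracer patterns.  Measurements add multiplicative
    ratio noise and average duplicates.

    ``truth`` is a design table carrying ``true_fia`` (from
    :func:`generate_true_fia`).
    """
    if noise_sd_rel < 0:
        raise ValueError("noise_sd_rel must be non-negative")
    cfg = config or AbsorptionModelConfig()
    patterns = dict(tracer_patterns or DEFAULT_TRACER_PATTERNS)
    unknown = sorted(set(truth["tracer"]) - set(patterns))
    if unknown:
        raise KeyError(f"no IsotopePattern for tracer(s): {unknown}")
    rng = np.random.default_rng(seed)

    rows = []
    for _, person in cohort.iterrows():
        pid = person["participant_id"]
        bv = blood_volume(person["height_cm"], person["weight_kg"], cfg.bv_formula)
        circ_mg = circulating_iron(bv, person["hb_g_l"], cfg)
        ptruth = truth[truth["participant_id"] == pid]

        pool = natural  # true pool pattern before any tracer
        rows.append({"participant_id": pid, "day": 1,
                     **_pattern_row(_noisy_pattern(pool, noise_sd_rel, rng, n_replicates))})
        for phase, draw_day in ((1, 19), (2, 37)):
            total_mol = circ_mg / 1000.0 / pattern_molar_mass(pool)
            phase_rows = ptruth[ptruth["phase"] == phase]
            q = []
            tr = []
            for r in phase_rows.itertuples(index=False):
                pat = patterns[r.tracer]
                dose_mol = r.fe_mass_mg / 1000.0 / pattern_molar_mass(pat)
                q.append(r.true_fia * dose_mol * cfg.incorporation_factor)
                tr.append(pat.as_array())
            q = np.asarray(q)
            if q.size and q.sum() >= total_mol:
                raise ValueError(
                    f"participant {pid} phase {phase}: incorporated tracer "
                    f"({q.sum():.3g} mol) exceeds circulating iron ({total_mol:.3g} mol)"
                )
            if q.size:
                mixed = ((total_mol - q.sum()) * pool.as_array() + q @ np.stack(tr)) / total_mol
                pool = IsotopePattern.from_array(mixed, renormalize=True)
            rows.append({"participant_id": pid, "day": draw_day,
                         **_pattern_row(_noisy_pattern(pool, noise_sd_rel, rng, n_replicates))})
    return pd.DataFrame(rows)


def _pattern_row(p: IsotopePattern) -> dict[str, float]:
    return {"a54": p.a54, "a56": p.a56, "a57": p.a57, "a58": p.a58}


def simulate_trial(
    spec: CohortSpec,
    truths: Mapping[str, ConditionTruth] | None = None,
    noise_sd_rel: float = DEFAULT_NOISE_SD_REL,
    *,
    fe_mass_mg: float = DEFAULT_DOSE_MG,
    tracer_patterns: Mapping[str, IsotopePattern] | None = None,
    config: AbsorptionModelConfig | None = None,
    n_replicates: int = DEFAULT_N_REPLICATES,
) -> dict[str, pd.DataFrame]:
    """Convenience driver: cohort -> design -> truth -> measurements.

    All randomness descends from spec.seed via spawned child seeds
    (cohort, design, truth, measurements, in that order).
    """
    truths = dict(truths or default_condition_truths(spec.n_participants))
    children = np.random.SeedSequence(spec.seed).spawn(4)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    cohort = generate_participants(spec.model_copy(update={"seed": seeds[0]}))
    design = assign_crossover_design(cohort["participant_id"], seeds[1], fe_mass_mg)
    truth = generate_true_fia(design, truths, seeds[2])
    measurements = forward_simulate_measurements(
        cohort, truth, noise_sd_rel, seeds[3],
        tracer_patterns=tracer_patterns, config=config, n_replicates=n_replicates,
    )
    return {"cohort": cohort, "design": design, "truth": truth, "measurements": measurements}
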