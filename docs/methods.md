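# Methods

`ferrotrace` implements the quantitative machinery of a multi-tracer
stable-isotope iron-absorption cross-over trial, together with the
companion desk computations such a study reports: iron speciation
ratios, EELS white-line valence estimation, CIELAB colour difference and
R-Index sensory discrimination. Because no participant-level data from
such trials are public, the package is built around a synthetic-data
generator whose defaults encode the study conditions, so every stage of
the analysis can be exercised and validated against a known truth.

## The absorption model

The core measurement principle is erythrocyte incorporation of oral
stable iron isotopes. A participant's circulating iron pool is treated
as well mixed: if the pool holds `N` mol of iron with isotope pattern
**b** (fractional abundances of ⁵⁴Fe/⁵⁶Fe/⁵⁷Fe/⁵⁸Fe) and `q_i` mol of
enriched tracer `i` (pattern **t**_i) are incorporated, the measured
erythrocyte pattern about two weeks after dosing is

    m = (N·b + Σ_i q_i·t_i) / (N + Σ_i q_i),

with the total `N + Σ q_i` pinned to the circulating iron estimated from
blood volume and haemoglobin:

  - blood volume (L) from the adult-female height–weight regression
    `BV = 0.3561·H(m)³ + 0.03308·W(kg) + 0.1833` (selectable by name;
    a male variant ships as well);
  - circulating iron (mg) = `BV × Hb(g/L) × 3.47 mg Fe per g Hb`.

Only a fraction `F = 0.80` of absorbed iron is assumed to be
incorporated into circulating erythrocytes by the sampling day, so
fractional iron absorption is `FIA = q / (F · dose_mol)`, where
`dose_mol` converts the administered elemental iron mass (4 mg per
condition by default) with the molar mass of the *tracer's own* isotope
pattern.

Because the total pool size is constrained, the mixture abundances are
affine in `q` and the inversion is a small linear non-negative
least-squares problem. Two formulations are available and agree to
better than 1e-6 in the noiseless limit:

  - **ratio space** (default): residuals `r_k·a56(q) − a_k(q)` on the
    three independent ratios to ⁵⁶Fe, matching how the mass spectrometer
    reports and how noise is modelled;
  - **abundance space**: residuals on the ⁵⁴/⁵⁷/⁵⁸ abundances.

Non-negativity is enforced by the active-set NNLS solver — a tiny
negative increment from noise is unphysical and is clipped to zero with
the remaining tracers refit. Ill-conditioned systems (condition number
above 1e8, e.g. a tracer pattern indistinguishable from the baseline)
are refused. FIA values above 1 are flagged, never clipped: they are
evidence of a mass-balance or model failure and must stay visible.

The cross-over trial is processed sequentially: phase-1 absorption is
inverted from the day-19 pattern against the day-1 (natural) baseline;
phase-2 from the day-37 pattern against the measured day-19 pattern,
which already contains the phase-1 labels. Duplicate measurements of
the same day are averaged on the ratio scale before inversion.

**Mole convention.** Converting the circulating iron mass to moles
requires a molar mass; the package uses the molar mass of the relevant
phase's baseline pattern, identically in the forward simulator and the
inversion. The mixture's true molar mass differs by under 1e-4
relatively at mg-scale tracer doses; using one shared convention makes
the noiseless forward–invert round trip exact (observed < 1e-12
relative), which is the property the test suite leans on.

## The synthetic cohort

`syncohort` emulates the study design: 52 women, three tracer-labelled
compounds (a ⁵⁷Fe-labelled ascorbate-reduced oat-nanofibril iron hybrid,
a ⁵⁸Fe-labelled hydroxide-reduced hybrid, and ⁵⁴Fe-labelled ferrous
sulfate as reference), each given once per phase in randomized order on
days 1/3/5 (in water) and 19/21/23 (in a polyphenol-rich açai meal),
with blood draws on days 1, 19 and 37. Screening variables (height,
weight, Hb, serum ferritin, CRP, age) are drawn from priors chosen to
describe a screened, non-anaemic, iron-deficient young-adult female
population (defaults: height 157 ± 6 cm, weight 54 ± 6 kg, Hb 131 ± 9
g/L, SF GM 22 µg/L GSD 1.8, CRP GM 0.8 mg/L GSD 2.2, age uniform
18–45). Eligibility screening (SF < 50 µg/L, Hb ≥ 120 g/L, BMI
18.5–24.9, weight < 70 kg, age 18–45, CRP ≤ 5 mg/L) is implemented as a
separate, monotone rule set.

True absorption is lognormal with a shared person effect:

    FIA_pc = GM_c · exp(s_c·z_p + e_pc),   z_p ~ N(0,1),  e_pc ~ N(0, ln²GSD_c),

truncated above at 0.95 to keep the tracer mass balance physical. The
default generating GMs are the six study-condition values (46.2 / 20.3 /
26.3 % in water; 13.4 / 6.3 / 8.1 % with the meal). Dispersion is
decomposed as follows: the within-person residual ln-sd is
`0.223·ln10/√2 ≈ 0.363`, taken from the reported sd of paired
differences of log₁₀ FIA in the predecessor study; the shared
person-effect sd (`≈ 0.524`) is fixed so the reference condition's total
ln-sd matches the value implied by its printed 95 % CI at n = 52
(`ln(0.550/0.389)/(2·1.96)·√52 ≈ 0.637`); each condition's residual GSD
absorbs what remains of its own CI-implied total. (The study text and
figure caption print two slightly different CIs for the same GM; the
text version is used here.)

Measurements apply independent multiplicative Gaussian noise (relative
sd 5e-4, typical of multi-collector ICP-MS ratio precision) to each
ratio-to-⁵⁶Fe, average two replicates, and renormalize. Natural
abundances default to the standard reference composition (0.05845,
0.91754, 0.02119, 0.00282); tracer enrichment patterns are synthetic
defaults declared in configuration, never hard-coded in the math.

**What the generator does not emulate:** ferritin/inflammation
kinetics, menstrual blood loss, dropout, Hb or weight drift between
draws, isotope fractionation, or instrument drift. Passing tests
therefore demonstrate the *pipeline's* fidelity (inversion, statistics,
bookkeeping) under the stated noise model, not robustness to every
feature of real clinical data.

Two consequences of the generating conditions are worth knowing:

  - With total ln-sd 0.637 around GM 0.462, roughly 13 % of draws in the
    highest-absorption condition exceed the 0.95 truncation, so the
    *realized* GM of that condition sits near 44.3 % rather than 46.2 %.
    The pipeline recovers what was generated; recovery checks against
    the realized truth are exact to numerical precision.
  - The ⁵⁴Fe tracer rides on the large natural ⁵⁴Fe background, so at
    ratio noise 5e-4 the small-FIA ferrous-sulfate conditions recover
    noisily and the non-negativity constraint occasionally clips an
    increment to zero. Geometric summaries exclude non-positive records
    (their logarithm is undefined) and report the remaining n.

## Trial statistics

All summaries are geometric means with t-based CIs on the ln scale;
paired comparisons are two-sided t-tests on ln FIA with Bonferroni
adjustment over the prespecified comparisons (both hybrids vs ferrous
sulfate in each matrix, k = 4 by default). Relative bioavailability is
reported both as the GM of per-participant ratios (with CI) and as the
ratio of condition GMs; the two are identical on complete pairs and
diverge under missingness, which is why neither is privileged.

The sample-size operation solves the paired log-scale design (detectable
ratio 1.30, power 0.80, α 0.05, sd of log differences 0.223) with either
the closed-form normal approximation or an iterative noncentral-t
solver. These stated inputs under-determine the published planning n of
44: natural-log and base-10 conventions give 6–8 and 31–33 respectively,
while base-10 with α/4 gives 43–46. `power_convention_sweep` documents
the full grid rather than asserting any convention as the original
intent. Dropout inflation multiplies then floors (44 × 1.2 → 52);
division by (1 − rate) is available behind a flag.

## Speciation

`ferrous_fraction(r) = r/(1+r)` converts a colorimetric Fe²⁺/Fe³⁺ ratio
into the ferrous share of total iron (5.6:1 → 84.8 %, i.e. 85 %).

The EELS white-line analysis auto-detects the Fe L₃ and L₂ maxima (the
two most prominent peaks), subtracts a configurable continuum — default
a double-arctan step anchored just below each edge with heights set by
the pre-edge, inter-edge and post-edge levels; a straight-line fit and
"none" are alternatives — and integrates ±2 eV windows by the trapezoid
rule. Peak positions are refined on the background-subtracted signal
because a sloping continuum shifts the raw maxima enough to bias the
windows. The L₃/L₂ ratio is mapped to a ferric fraction through a
calibration supplied as monotone anchor points; the shipped default is a
synthetic curve with the shape of the published universal calibrations
and is configuration data, not a claim. No reported ferric percentage
is asserted, since the underlying spectra and calibration of any given
instrument are not reproducible from printed values.

## Sensometrics

ΔE*ab is the Euclidean distance in CIELAB (the occasionally printed
"(Δb²)²" form is read as the standard (Δb*)²). The R-Index of a
4-category confidence table is the pairwise win proportion with ties
counted half, ×100. Critical values come from the exchangeable null in
which all pooled ratings are randomly reassigned to the test/reference
labels; the default tie-free (distinct-rank) variant matches the
construction of the published tables (Monte-Carlo with 200 000 draws by
default, exact enumeration for small panels), and a table is declared
perceptibly different only if R strictly exceeds the critical value.
For 30 + 30 pooled comparisons at one-sided α = 0.05 the permutation
critical value is ≈ 62.4, within the ±1.5 band of the tabulated 61.9
(the tables' exact construction, enumeration vs corrected normal
approximation, is not published).

## Numerical and design choices

  - Single-seed determinism: every random draw descends from the run
    config's one seed through spawned child sequences (cohort, design,
    truth, measurements, in that order); repeated runs are byte-identical.
  - Isotope masses: 53.9396 / 55.9349 / 56.9354 / 57.9333 g/mol.
  - Patterns must sum to 1 within 1e-9 at construction; simulated
    patterns renormalize after noise and sum to 1 within 1e-12.
  - Degenerate statistics (zero-variance differences, all-identical
    ANOVA groups) are resolved explicitly (t = 0, p = 1 when the shift
    is exactly null; an error when variance is zero but the shift is not)
    rather than surfacing NaN.
  - Problem sizes in the test suite (200 replicate trials for the
    recovery-coverage property, 2000 null replicates for test
    calibration, 1000 for CI coverage, 200 000 permutation draws) were
    chosen to keep Monte-Carlo error well inside each asserted band.
  - The acceptance script pools 10 replicate n = 52 trials for the
    recovered-GM target: a single cohort's GM has log-scale sampling sd
    ≈ 0.63/√52 (± ~4 percentage points), which would measure cohort
    sampling noise rather than pipeline fidelity.

## Known limitations

  - The mixing model assumes an instantaneously well-mixed circulating
    pool and ignores erythrocyte lifespan and iron turnover between
    draws.
  - The blood-volume regression and the 3.47 mg/g haemoglobin iron
    stoichiometry are conventions; both are configurable and echoed in
    the run report for audit.
  - Cross-over period and carry-over effects are not modelled (paired
    tests only), matching the analysis style the pipeline reproduces.
  - The valence calibration and the sensory critical-value tables are
    external data in the field; the package ships reasonable defaults
    and treats them as inputs.
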