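# ferrotrace

Simulation and analysis pipeline for multi-tracer stable-isotope iron
absorption trials, written for nutrition researchers who design or
re-analyse erythrocyte-incorporation bioavailability studies and want
every calculation — from raw isotope patterns to the fold-change table —
reproducible and testable without access to participant data.

## What it computes

**Fractional iron absorption by isotopic dilution.** An oral dose of an
isotopically enriched iron compound shifts the isotope ratios of the
circulating iron pool once the label is incorporated into erythrocytes.
With a pool of `N` mol (pattern **b**) receiving `q_i` mol of tracer `i`
(pattern **t**_i), the measured pattern is

    m = (N·b + Σ q_i·t_i) / (N + Σ q_i),

where the total is fixed by circulating iron estimated from a
height–weight blood-volume regression and haemoglobin (3.47 mg Fe per g
Hb). Solving this constrained mixing model by non-negative least
squares on the ratios to ⁵⁶Fe yields each `q̂_i`, and

    FIA_i = q̂_i / (F · dose_mol_i),   F = 0.80,

the assumed erythrocyte incorporation of absorbed iron. A full
cross-over trial (three tracers × two matrices × 52 participants, blood
draws on days 1, 19 and 37 with sequential baselining) yields 312
absorption records.

**Trial statistics** on the log scale: geometric means with t-based 95 %
CIs, per-participant relative bioavailability (GM of ratios and ratio of
GMs), two-sided paired t-tests on ln FIA with Bonferroni adjustment, a
paired log-scale sample-size solver with a documented convention sweep,
and one-way ANOVA with Bonferroni pairwise comparisons.

**Synthetic cohort generator**: lognormal per-condition true absorption
with a shared within-person effect, randomized cross-over design (each
tracer once per phase), natural-abundance baselines, enriched-tracer
patterns and multiplicative isotope-ratio measurement noise — the
ground truth that validates the inversion.

**Speciation**: ferrous fraction `r/(1+r)` from a colorimetric
Fe²⁺/Fe³⁺ ratio, and EELS Fe L₂,₃ white-line integration (configurable
continuum model, auto-detected peaks) with an anchor-point calibration
from the L₃/L₂ ratio to the ferric fraction.

**Sensometrics**: CIELAB ΔE*ab colour difference and the R-Index
multiple-difference test with exact/Monte-Carlo permutation critical
values under the exchangeable null.

## Worked example

```python
import ferrotrace as ft

cfg = ft.RunConfig(seed=1, outdir="demo")
bundle = ft.run_end_to_end(cfg)
print(open("demo/report.txt").read())
```

abridged output (one seed of the default 52-participant trial):

```
seed: 1
participants: 52
absorption records: 312
...
condition summaries (GM FIA, 95% CI):
  FeSO4:water: 28.3% (23.0-34.6%), n=52
  OatNF-SA-Fe:water: 54.1% (46.0-63.7%), n=52
  ...
relative bioavailability (GM of individual ratios, 95% CI):
  OatNF-SA-Fe:water vs FeSO4:water: 1.92 (1.60-2.30), p_adj=1.216e-08
  ...
```

Reading this: 52 simulated participants each contribute six absorption
measures (312 records). In this realization the ascorbate-reduced
oat-nanofibril hybrid given in water shows a geometric-mean fractional
absorption of 54.1 % against 28.3 % for ferrous sulfate — a 1.92-fold
relative bioavailability whose Bonferroni-adjusted paired test is
strongly significant. Each seed draws a new cohort around the same
generating geometric means, so single-trial summaries scatter with the
cohort sampling error the CIs describe. The report also echoes every
convention in force (blood-volume formula, incorporation factor,
solver space, noise model) for audit.

The same steps are available from the shell:

```
ferrotrace simulate --seed 1 --out demo
ferrotrace compute-fia --measurements demo/measurements.csv \
    --doses demo/design.csv --cohort demo/cohort.csv --out demo/fia.csv
ferrotrace stats --fia demo/fia.csv --out demo
ferrotrace report --seed 1 --out demo
```

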