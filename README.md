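# cogbattery

Simulator and psychometric analysis pipeline for a remote, self-administered
battery of 29 adaptive brain-health assessments.

Remote cognitive batteries hand each participant a set of short adaptive
tasks — each one tracking a threshold on a single stimulus dimension
(display exposure duration, memory set size, stimulus similarity, or sweep
speed) — and face a common set of evaluation questions: do the scores hit
ceilings or floors, do they scale with age but stay agnostic to gender,
race and education, what latent structure do they share, and which subset
would make a sound core battery?  This package gives researchers working
on such batteries a fully synthetic but statistically faithful test bed
plus the complete analysis chain, so every rule and statistic can be
exercised, calibrated and regression-tested without any participant data.

## What's inside

* **registry** — a reviewable CSV catalog of the 29 assessments: modality,
  score direction and bounds, adaptive-dimension kind, calibration targets,
  generative factor loadings, and the reference study's printed outcomes.
* **staircase** — a 3-down-1-up transformed up-down engine with logistic
  observers p(x) = γ + (1−γ−λ)·F(±s·(x−θ) + c), parametrized so that
  p(θ) equals the rule's stationary accuracy 0.5^(1/3) ≈ 0.794 exactly;
  exits on asymptotic performance, 3 consecutive best-bound (ceiling) or
  worst-bound (floor) trials, or a trial cap.
* **cohort** — synthetic registrants: demographic marginals of the
  reference deployment, a 4-factor latent ability model (z_j = Λ_j·f +
  modality and age terms + uniqueness), and an engagement mixture
  reproducing the published completion bins.
* **descriptives** — means/SD/median/mode/skew/kurtosis per assessment,
  the inclusive ≥10%-at-a-bound ceiling/floor flag, completion and
  demographic summaries.
* **associations** — Spearman screens for age and years of education,
  Wilcoxon rank-sum screens for gender (male vs female) and race (White
  vs people of color), exact small-sample null distributions.
* **profiles** — completer z-scores (raw or higher-is-better aligned),
  unweighted composites, and the a-priori four-class profile labels
  (high > 0.40, low < −0.40, modality-strong at a half-SD gap).
* **factors** — Bartlett sphericity, KMO, PCA with varimax rotation
  (retention by parallel analysis; Kaiser and fixed-k available), signed
  ≥0.40 loading flags, and the four-criterion core-battery selection with
  documented judgment-call overrides.
* **pipeline** — one seeded, hash-stamped run: simulate (or load CSVs) →
  descriptives → associations → profiles → factors → selection → report.

## Worked example

```python
import cogbattery as cb

dataset = cb.generate_study_dataset(cb.CohortConfig(seed=42))
registry = cb.load_registry()

completion = cb.completion_summary(dataset, registry, n_contacted=365_782)
print(completion.pct_completed_any, completion.pct_completed_all)

wide = cb.completer_score_matrix(dataset, registry)
ztable = cb.zscore_transform(wide, registry, "aligned_higher_better")
composites, summary = cb.composite_scores(ztable)
profiles = cb.profile_table(ztable, registry)
```

With seed 42 this prints a cohort of 414 simulated registrants of whom
376 (90.8%) start at least one assessment and 105 (25.4%) finish all 29
(the reference deployment observed 88.6% and 25.1%).  The 105 completers'
composite z-scores average exactly 0 (they are means of column-centered
z-scores) with SD 0.49, and the profile labels split into 21 high and 20
low performers, 7 auditory-strong, 13 visual-strong and 44 unclassified.
Running the selection stage on the reference study's printed tables
(`cb.select_core_battery(cb.reference_selection_inputs(registry))`)
retains the 14-assessment core battery, from Divided Attention through
To-Do List Training.  The `examples/` directory walks through each
capability as a short narrative script; `examples/07_full_pipeline.py`
writes a complete run directory with a markdown report.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the reported acceptance quantity from scratch: it generates
z-score tables for 104 synthetic completers from the default generative
latent configuration, fits the factor solution under the default
retention rule across 20 seeded replicates, and writes the majority
retained-factor count (with the sample size used) as JSON.  See
`docs/methods.md` for what the factor count does and does not establish
at this sample size.
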