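# Methods

This note documents the models, parameter choices and numerical
conventions behind cogbattery, and states what its synthetic world does
and does not establish.

## The staircase engine

Each assessment is a transformed up-down staircase on a single adaptive
dimension.  The 3-down-1-up rule (three consecutive correct responses →
one step harder; any error → one step easier) has its stationary point at
the stimulus level where P(correct) = 0.5^(1/3) ≈ 0.794, the standard
"approximately 80% criterion accuracy" of adaptive psychophysics.

A simulated participant on a task is a logistic psychometric function

    p(x) = γ + (1 − γ − λ) · F(d · s · (x − θ) + c)

with guess rate γ (default 0), lapse rate λ (default 0.02), slope s,
and d = +1 when numerically larger levels are easier (lower-is-better
dimensions) and −1 otherwise.  The offset c = logit((0.794 − γ)/(1 − γ − λ))
pins p(θ) to the convergence accuracy exactly, so θ ("theta80") *is* the
level a perfectly run staircase estimates — this makes the analytic
convergence point available as an oracle for tests.  For dimensions that
span orders of magnitude (exposure durations, sweep speeds) levels are
compared on the log scale and the staircase steps multiplicatively
(×/÷ 1.2); set sizes and similarity steps move additively (step 1.0,
halving per reversal to 0.5).  Slopes are expressed per population SD of
the trait for additive dimensions (default 1.5/SD, an IRT-style
discrimination: a fixed per-raw-unit slope is dimensionally arbitrary
across tasks whose score ranges differ 30-fold) and per log-unit
(default 6) for multiplicative ones.

Exit rules: (1) *asymptote* — 8 reversals, or ≥6 reversals whose last six
levels have SD below 5% of the score range; (2) *ceiling* — 3 consecutive
correct trials clamped at the best score bound; (3) *floor* — 3
consecutive errors at the worst bound; (4) a 120-trial safety cap,
flagged on the run.  The score is the mean of the last 6 reversal levels
on the staircase's working scale (geometric mean for multiplicative
dimensions — averaging raw levels would carry a ~6% Jensen bias), or the
bound value for bound exits.  Duration is trials × a per-assessment
per-trial time calibrated so a typical ~40-trial run matches the
published mean assessment durations (all 29 land within ±50%).

## The synthetic cohort

Demographics are independent draws from the reference deployment's
questionnaire marginals: age by decade bin (13–107, uniform within bin),
gender (64% female), education (79.5% degree holders) and race (84.3%
White, 11.6% people of color, 4.1% declined).

Ability follows a 4-factor linear model.  For assessment j with
generative loadings Λⱼ (the published rotated loadings, kept in raw
printed orientation so simulated raw-orientation z-scores reproduce the
printed sign structure), direction sign dⱼ and modality sign sⱼ = ±½:

    uⱼ = Λⱼ·f + dⱼ·(sⱼ·m − β·(age − 60)·[age-sensitive]) + √ψⱼ·εⱼ
    theta80ⱼ = calib_meanⱼ + calib_sdⱼ · uⱼ / SD(uⱼ)

with f ~ N(0, I₄), modality offset m ~ N(0, 0.3²) (auditory-minus-visual
skill; 0.3 SD produces a realistic minority of modality-strong profiles),
uniqueness ψⱼ = max(1 − ‖Λⱼ‖², 0.05), and age slope β = 0.03 ability-SD
per year on the 21 age-sensitive tasks (zero on the 8 published
exceptions).  Dividing by the closed-form SD(uⱼ) calibrates the threshold
spread to the published per-assessment score SDs.  At the reference age
60 the age term vanishes by construction.

Engagement is completely at random (independent of ability): with
probability 47/414 a registrant never starts; otherwise a completion
count is drawn from the published bins (46.6% finish 1–5, …, 29.4% finish
26–29), uniform within bins except the top bin, where P(29 | 26–29) =
104/108 to match the published full-completion count — the published
counts show that participants who reach the top bin almost always finish,
so a uniform top bin would halve the completer pool.  The attempted set
is the first m tasks of one of four fixed rotations of the registry
order.  The engagement propensity acts as the mixture quantile, making
the stopping point a deterministic monotone function of one uniform draw.

What the generator does *not* emulate: practice/tutorial trials, reaction
times, device heterogeneity, ability-dependent dropout (available as a
config switch in spirit — the mixture parameters are configurable — but
not modeled by default), household assistance, or the audiovisual content
of the tasks themselves.  A green test on this world shows the analysis
chain is correct and calibrated, not that the real battery has these
properties.

## Analysis conventions

* Sample SD (ddof = 1) throughout; skew and excess kurtosis are the
  adjusted Fisher–Pearson versions (scipy `bias=False`).  The mode is
  taken after snapping scores to the staircase grid (half-units for
  additive dimensions, the ×1.2 geometric grid for multiplicative ones).
* Ceiling/floor flag: at least 10% of takers exactly at a numeric score
  bound, inclusive, on either side.  Bound counts use numeric extremes,
  not performance-best extremes.
* Printed-style percentages round half away from zero to one decimal.
* Association screens: Spearman ρ (tie-corrected p) for age and for years
  of education (levels mapped 0/1/6/8/12/13/14/16/18/20, declined →
  missing, pairwise deletion); two-sided Wilcoxon rank-sum for gender
  (male vs female) and race (White vs people of color, where any selected
  minority option — including multiracial-excluding-White — counts as a
  person of color).  Exact null distribution for untied samples with
  combined n ≤ 25, otherwise normal approximation with tie and continuity
  corrections.  α = .05, no multiplicity correction, no outlier exclusion
  (the reference analysis is deliberately exploratory).
* z-scores are computed over completers only (composites and the profile
  classes are defined for completers).  Profiles and composites use the
  higher-is-better aligned orientation — "high performer" is meaningless
  across mixed-direction tasks otherwise — while the factor stage
  defaults to raw orientation, which reproduces the published loading
  sign pattern.  Both policies are recorded in output metadata.
* Profile precedence: high (composite > 0.40, strict), low (< −0.40,
  strict), then modality-strong (|auditory mean z − visual mean z| ≥ 0.5,
  inclusive; each task z has SD 1, so 0.5 is "half an SD"), else
  unclassified.  A composite of exactly 0.40 falls through to the
  modality rule.
* Factor stage: PCA of the completer correlation matrix; retention by
  Horn's parallel analysis (95th percentile of 100 simulated
  eigenvalue spectra).  The Kaiser eigenvalue > 1 rule is available but
  not the default: at p = 29 variables and n of order 100–500, pure noise
  puts 5–9 sample eigenvalues above 1 (the null spectrum's upper edge is
  (1 + √(p/n))² ≈ 2.3 at n = 104), so Kaiser systematically over-factors.
  Varimax rotation (Kaiser-normalized, via statsmodels' gradient
  projection) preserves communalities to 1e−8; factors are ordered by
  explained variance and sign-oriented so the dominant loading mass is
  positive.  Loading flags use the signed ≥ +0.40 rule — the published
  table leaves a −0.58 loading unmarked — with an absolute-value mode
  available.
* Bartlett's statistic is −(n − 1 − (2p + 5)/6)·ln|R| on p(p−1)/2 = 406
  degrees of freedom for the full battery (the reference report prints
  df = 28, which is not the standard convention for 29 variables).
* Core-battery selection is the conjunction of: usable bounds (no
  ceiling/floor flag, or modifiable bounds), age scaling, demographic
  agnosticism (non-significant on gender, education and race), and a
  distinct factor loading.  The reference selection involved judgment
  calls; they are reproduced as explicit override lists (data, not code):
  Syllable Stacks retained without age scaling; Mixed Signals and Target
  Tracker retained despite unmodifiable floor effects; six assessments
  retained for coverage without a flagged loading.  Relaxing any
  criterion (adding overrides) can only grow the retained set.

## Known limitations and honest disagreements with the reference values

* **Factor count at n = 104.**  The published rotated loadings are
  sample-attenuated: as a generative truth with unit-variance variables
  they imply population correlation eigenvalues 7.24, 1.91, 1.61, 1.48.
  At the study's own completer count (n = 104, p = 29) factors 2–4 sit
  below the detectability threshold, and *no* standard automatic
  retention rule recovers 4 factors from such data (Kaiser retains 8–9,
  parallel analysis 1–3, MAP ~3).  The same configuration yields 4
  factors essentially always at n ≈ 500, which is what the test suite
  asserts as the structural control.  The acceptance script reports the
  honestly computed majority count at n = 104 (typically 2).
* **Composite SD.**  The direction-aligned mean of the published loadings
  is ≈ 0.24 on every factor, so any generator faithful to those loadings
  produces completer composite SDs near 0.5, far above the published
  0.19; the two published quantities are mutually inconsistent under a
  4-factor reconstruction.  The test suite therefore checks the composite
  SD against its closed-form model implication rather than the printed
  value.
* The modality split of the 29 tasks is not published; five
  mixed-modality tasks are classified by judgment and flagged
  `ambiguous_modality` in the registry CSV, and the published
  modality-profile composites cannot all be made consistent with any
  single split under plain averaging, so no numerical reproduction of the
  per-user profile figures is attempted.
* Score bounds not fixed by the published tables are set to bracket the
  printed mean ± 3 SD; only the ceiling/floor logic is sensitive to them,
  and all published flag cases are pinned by printed modes/extremes.
* The deployed product's exact adaptive and scoring algorithms are
  proprietary; the engine reproduces the described contract (criterion
  accuracy, exit rules, threshold score), not the product.
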