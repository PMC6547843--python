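# Methods

## The generative model

The synthetic cohort reproduces the design of a two-strain, cage-housed
behavioural phenotyping study. Defaults (all overridable through
`SimulationParams` / the YAML run config):

| parameter | default | meaning |
|---|---|---|
| `n_pairs_per_time` | 8 | matched B6/D2 cage pairs (16 cages, 48 animals) |
| strains | B6, D2 | coded s = +½ / −½, so δ is the B6−D2 contrast |
| time groups | morning, noon, afternoon | one animal per cage per group |
| `cage_sd` | 0.5 | SD of the random cage effect (analysis-scale units) |
| `residual_sd` | 1.0 | residual SD; the analysis scale is standardised to it |
| `animal_sd` | 0.5 | between-animal SD for the two-trial (repeated) measures |
| δ (state measures) | (±1.8, ±1.8, 0) | strain contrast at (morning, noon, afternoon) |
| δ (FE measures) | constant ±1.8 | trait-type contrast, no time dependence |
| time effect τ | (0.4, 0, −0.4) | main effect of testing time (0 for FE) |
| trial effect θ | −0.5 | trial-2 shift for labyrinth-maze measures |
| `dropout` | none (`reference_study_params`: D2/afternoon) | one absent animal |

Measures are generated directly on the analysis (transformed) scale,
`y = μ + δ_t·s + τ_t + c_cage + a_animal + θ·1[trial 2] + ε`, with one cage
effect per cage per measure and independent residuals. A raw-scale column
is derived by the inverse transform (clipped to each measure's bounds).
Generating on the analysis scale makes the ANOVA's normality assumptions
hold *by construction*: tests of the statistical machinery are then not
confounded by transform distortion. The flip side is that the simulator
does **not** emulate raw-scale skew, floor/ceiling effects, count
discreteness, or cross-measure correlation within animals (each measure is
drawn independently); passing tests therefore validate the inference
machinery and design logic, not robustness to real-data pathologies.

The effect sizes are deliberately large (|δ|/σ = 1.8): the emulated study
was powered (n = 8 per cell, 80%) for large effects, and the default must
put the post hoc contrasts in a regime where "flagged in the morning and
noon, not in the afternoon" is the typical outcome, not a coin flip.

### The 20-measure catalogue

The catalogue lists six elevated-plus-maze, three dark-light, four
open-field and three free-exploration measures, plus the labyrinth-maze
error count and exit time at each of two trials (4 entries) — 20 in total.
The two LM readouts are *repeated* measures: their two trial entries share
a `base_id`, the measure table stores them as one measure with a trial
column, and the replicate analysis treats each trial as its own measure.
Transforms (angular for proportions, square root for counts/times, log for
latencies, offset 1 where zeros occur) are field-standard defaults and are
marked provisional in the config; the exact per-measure assignment in the
emulated study is not public in its main text.

## Split-plot ANOVA

Fitting is **stratified least squares** with the classical
expected-mean-squares F-tests, not iterative REML. For the balanced
split-plot the two coincide; the stratified fit is exactly deterministic,
reproduces the textbook degrees of freedom — with 2 strains, 8 cages per
strain, 3 times and 47 present animals the sub-plot residual has
47 − 1 − (1 + 14 + 2 + 2) = 27 df — and is verifiable against a
sums-of-squares partition computed directly from group means (the test
suite does exactly that, and additionally cross-checks F statistics
against R's `aov` with an `Error(cage)` stratum).

* Whole-plot stratum: strain vs cage-within-strain (df 1, 14).
* Sub-plot stratum: time, time×strain vs the within-cage residual.
* Sum-to-zero contrast coding throughout; under imbalance each term's SS
  is **Type III** (residual-SS increase from dropping the term's columns
  from the full model), which equals the sequential partition on balanced
  data — asserted as a property test.
* η²p = SS_term / (SS_term + SS_error-of-its-own-stratum).
* Degenerate inputs (all observations equal) yield a flagged result with
  zero SS and undefined F, never a silent zero.

### Repeated measures (labyrinth maze)

The two trials per animal are decomposed orthogonally into the animal mean
(between-animal stratum, analysed exactly as above with SS scaled by 2)
and the trial-2 − trial-1 difference (within-animal stratum, SS scaled by
½). The within stratum carries trial, trial×strain, trial×time and
trial×time×strain. Its error term is a modelling choice the data cannot
settle: by default (`trial_error="cage"`) the trial×cage-within-strain
interaction stays in the model and trial-level effects are tested against
the trial-by-animal residual with 27 df — mirroring the (2, 27) convention
of the emulated analysis — while `trial_error="pooled"` pools trial×cage
into the residual (41 df with 47 animals). Both are exposed; the default
follows the reported convention.

### Post hocs

Strain contrasts within a time group compare animals in *different* cages,
so the standard error mixes strata:
`Var = (1/n₁+1/n₂)·(MS_cage + (t−1)·MS_resid)/t` with t = 3 time levels.
The t statistic is referred to the whole-plot df (14) — the conservative
classical choice; Satterthwaite-style interpolated df are deliberately out
of scope. Time contrasts within a strain are pure sub-plot contrasts
(cage effects cancel) and use MS_resid with its residual df. Holm
adjustment is applied per family, one family per measure per contrast
direction. Holm and Shapiro-Wilk are delegated to statsmodels and scipy
respectively; their contracts are pinned by worked-example tests.

## Replicate designs

The sampling unit is the matched animal pair (cage pair × time): 24 units
by default. Standardised replicates are the three time groups verbatim —
the design is deterministic, and a dropout leaves one replicate an animal
short. Heterogenised replicates mix exactly two times each under the
cyclic scheme {morning+noon, noon+afternoon, afternoon+morning} — the only
symmetric pairing that uses each time group twice; the split of each time
group's units between its two replicates is balanced (4+4 by default) and
seed-driven. An incomplete unit (the dropout's unmatched animal) is
excluded from the heterogenised design because its analysis unit is the
matched pair, so one replicate holds 7 pairs. Designs serialise to CSV
and re-load with full invariant validation, so a specific documented draw
can be replayed.

## Reproducibility statistics

Per measure and design, a fixed-effects 2×3 ANOVA (strain × replicate)
gives the strain-by-replicate interaction F (Type III, df (2, N−6)); under
the standardised design "replicate" coincides with testing time, so this F
is large exactly when the strain contrast is time-dependent. The paired
F-ratios are compared with the one-tailed Wilcoxon signed-rank test of
"heterogenised < standardised": zeros discarded, midranks for ties,
W = sum of positive-difference ranks, and
`Z = (W − n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 − Σ(t³−t)/48)` with one-tailed
p = Φ(Z); no continuity correction. The direction is fixed a priori and
the API refuses to flip it post hoc. An exact mode computes the null
distribution of W by dynamic programming over (doubled) midranks —
equivalent to enumerating all 2ⁿ sign assignments — and anchors the
normal approximation in tests; descriptive per-replicate strain
differences use pooled-t 95% intervals on the raw scale, while F-ratios
are computed on the analysis scale.

## Problem sizes and numerical choices

The statistical checks run at deliberately chosen sizes: oracle
equivalence over 220 random small balanced designs at 1e-8 relative
tolerance; type-I calibration of the interaction F-test with 2000
simulated measures (band 0.05 ± 0.01); contrast-recovery and post hoc
flag rates over 40 simulated studies; and the design comparison over 500
simulated studies (300 in the acceptance script), where the one-tailed
test rejects in a large majority of runs with a time-varying contrast and
at roughly the nominal 5% with a constant one. Least-squares fits use
`numpy.linalg.lstsq` on exact contrast matrices; drop-term SS are clamped
at zero against negative rounding. All randomness flows through
`numpy.random.default_rng` seeded from three named seeds (cohort,
measures, heterogenisation), and every artefact re-run with the same
config is byte-identical (CSV ingestion uses round-trip float parsing).

## Known limitations

* The replicate analysis is purely fixed-effects by design; no mixed-model
  variant, no multi-laboratory extension, no >3 replicates or >2 mixed
  times per replicate.
* Transforms are assigned per measure by configuration; there is no
  automatic transform selection.
* The simulator draws measures independently; real behavioural batteries
  are cross-correlated within animals, so multivariate properties are out
  of scope.
* The exact published subsampling draw of the emulated study lives in its
  external data deposit; `load_assignment` exists so such a draw can be
  replayed, but the package ships only synthetic stand-ins.
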