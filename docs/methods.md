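# Methods

`cfsdecode` implements an image-computable analysis of breaking
continuous flash suppression (bCFS): on each trial two face-like stimuli
are suppressed, one in each visual hemifield, and the observer reports
which one reaches awareness first. The package asks whether that first
percept is predictable from the stimuli's spatial-frequency and
orientation contrast energy, whether the same spectral features carry
the stimuli's expression category, and whether expression category per
se predicts behavior. Because face photographs are not redistributable,
a first-class synthetic generator produces stimuli with exactly
controlled spectral content and simulated responses; real data enter as
grayscale PNGs plus a trial-table CSV.

## Spectral features

An N x N grayscale image (N even, default 128) is mean-subtracted and
Fourier transformed; the centered magnitude spectrum (absolute value,
not power) is partitioned into `n_sf` x `n_ori` wedges — 24 annular
spatial-frequency bands crossed with 16 orientation sectors by default,
giving 384 features per image and 768 per two-image trial. A feature is
the *sum* of magnitudes in its wedge. Orientation refers to the
propagation direction of the waveform: sector 0 is centered on the
horizontal Fourier axis and captures light–dark change from left to
right, i.e. vertical contours in the image.

Spatial-frequency band edges run from 1 cycle/image to Nyquist (N/2).
They are log-spaced with a minimum band width of one cycle/image:
attainable radii on the integer frequency lattice are sparse below ~2
cycles/image (1, √2, 2, …), so bands narrower than one cycle there would
be structurally empty. The result is linear (one band per cycle) at low
frequencies and log-spaced above the crossover; pure linear spacing is
available via `sf_spacing="linear"`. The DC term and radii above Nyquist
are excluded; conjugate-symmetric coefficients always share a wedge.
Some low-frequency wedges still contain no lattice point (32 of 384 at
defaults); their features are identically zero and classifiers drop them
as zero-variance columns.

Design choices: no windowing before the transform (mean subtraction
only) and no per-image energy normalization — the stimuli are assumed
contrast-controlled at presentation, and raw contrast energy is the
quantity under study. Scaling an image's pixel contrast by c scales
every feature by c.

## Synthetic stimuli and responses

A stimulus is phase-randomized noise with prescribed wedge energies: the
target summed magnitude of each wedge (base energy + per-class
"expression" delta, times per-wedge lognormal identity jitter,
sd 0.2 by default) is spread uniformly over the wedge's coefficients;
phases come from a seeded white-noise field, so the spectrum is
Hermitian and the image real. Pixels are finally mapped linearly onto
[(1−M)/2, (1+M)/2], fixing the Michelson contrast at M = 0.176 (the
scale of contrast-ramped suppression stimuli). The rescale multiplies
all wedge energies by one image-specific factor, so absolute energy
units are not preserved — only the relative wedge pattern is, which is
what the round-trip tests check (normalized energies within 10% in
coefficient-rich bands).

One subtlety matters for planted-signal experiments: the rescale factor
depends on the image's realized total energy, so *unbalanced* class
signatures (one class adding more total energy or RMS than another)
leak class information into every wedge through the shared factor. The
default class signatures are therefore energy-balanced: each class adds
the same amount (0.25 of base per wedge) over one full SF column in its
own orientation sector — happy at 90° (horizontal image contours), angry
at 45°, neutral at 135° — disjoint from the horizontal-axis sector that
drives behavior. The amount 0.25 puts per-feature class separation at
d′ ≈ 0.7 against the identity jitter: expressions are widely but
modestly decodable, which is the regime real face classes occupy.

The trial design is the study's: six conditions pairing the three
classes (HA-HA, HA-NE, HA-AN, AN-NE, AN-AN, NE-NE), 48 trials each (288
total), left/right placement counterbalanced within condition, image
identities sampled per trial. Responses come from a lapse-logistic
stand-in (the analysis target, not a claim about mechanism):

    P(left first) = (1 − λ) · σ(β (E_L − E_R)) + λ/2

with E the summed feature energy over a configurable set of driver
wedges (default: the horizontal-axis sector, i.e. vertical-contour
energy — the direction of the effect this kind of analysis detects), β
calibrated so that β·(E_L − E_R) has standard deviation 2 logits over
the stimulus set (P(first) mostly in 0.1–0.9: predictable but
stochastic; invariant to image size and contrast units), and lapse
λ = 0.05. Reaction times are lognormal with median ≈ 3 s and carry no
signal; they are stored but never analyzed. A multi-subject option draws
per-subject β multiplicatively (lognormal, sd 0.5) to exercise the
group-level statistics.

## The ensemble decoding engine

Per stratified fold (10 by default), four selection methods each
contribute 10 linear-SVM models (cost 1, features standardized by
training mean/SD, one-vs-one for 3 classes):

* **filter** — disjoint blocks of a chi-square ranking of the training
  split: model r takes ranks 3r−2 … 3r (block size 3, top 30 covered).
  Chi-square scores discretize each feature into 10 quantile bins and
  compute Σ(O−E)²/E of the bin × class table. Disjoint blocks, rather
  than nested top-k sets, keep each model's performance attributable to
  its own features; with nested sets every tail feature co-selected
  with the top-ranked ones inherits their models' performance, and the
  per-feature weight (below) loses its selectivity entirely.
* **wrapper** — forward stepwise inclusion judged by inner
  cross-validated accuracy (2 inner folds), run on a bootstrap resample
  of the training split per model for diversity. Candidates are
  pre-screened to the top `wrapper_pool` (20) chi-square ranks of the
  resample — a filter-wrapper hybrid; an unscreened scan of all 768
  candidates per step is computationally disproportionate and the
  pre-screen rarely excludes a feature stepwise inclusion would take.
  Inclusion stops when accuracy stops improving or at `wrapper_cap` (8).
* **random** — uniform draws, sizes matched to the filter blocks.
* **pseudo-random** — draws from features *unused* by the fold's filter
  and wrapper selections; if that pool runs short the remainder comes
  from wrapper-unused features, then (tiny feature spaces only) from
  any features, logged.

For each fold × method, 25 control models re-run the method's selection
and fit under a shuffled labeling of the whole dataset — 10 × 4 × 25 =
1000 chance performances. Three details of the control design matter,
and each was forced by a failure mode observed during development:

* Controls re-select rather than reuse the real selections, so that
  selection optimism is present in the null; for the random and
  pseudo-random methods, whose selection ignores labels, re-running
  means a fresh seeded draw.
* Controls are *tested under their own shuffled labeling*, not the true
  labels. A finite dataset offers chance feature–label associations
  that transfer from training to test splits; a control tested on true
  labels measures pure guessing and misses that transfer entirely.
  The shuffled labelings are class-balanced within every fold
  (permuting within the stratified fold blocks): an unconstrained
  global permutation anti-correlates training and test class
  proportions and deflates the null.
* The 25 labelings are *shared* across folds and methods, so each
  labeling spans a full parallel control pipeline. This is what lets
  the null capture how one realized chance association propagates
  through all of a feature's models at once.

A feature's **weight** is the mean test performance of the real models
containing it (0 if never tested). Features are tested unequal numbers
of times, and means of few performances are noisier — regression to the
mean. The matched null therefore respects the feature's test count m,
the provenance of those tests (filter models matched at the rank-block
level, other methods at the method level — selection-favored models run
above the pool average under the null), and the sharing of one labeling
across a feature's models: each of 10,000 resampled null means picks
one control labeling and draws, per real model of the feature, a
performance from that labeling's matching stratum. The feature is
significant iff its weight exceeds the *maximum* of its matched null
(empirical per-feature level 1e-4, comfortably below the nominal
0.001); untested features are never significant. This is what makes
the engine's false-flag rate essentially zero at the family level: on
label-shuffled inputs the significant-feature count is zero in ≥ 95% of
seeded runs, which a count-only iid null does not achieve.

## Weight correlations

Left-eye vs right-eye: positions 1–384 of the 768-feature awareness
weights are the left image's wedges, 385–768 the right's, in identical
wedge order; Pearson r on the pairs, excluding pairs where either weight
is exactly 0 (the marker of a never-tested feature). Awareness vs
expression: the awareness weights are first averaged across sides, then
paired with the 384 expression weights in wedge order; a subset variant
restricts to the features significant for expression decoding
(side-averaged awareness weights are used there too, for consistency).
p-values come from the exact t transform with n−2 df; a permutation
option exists in the API.

## Behavioral statistics

First-percept fractions count, per class, the different-class trials
containing it in which it was reported first (same-class pairings are
excluded; with equal trial counts the three fractions of one subject
average to 0.5). The group test is a Friedman ANOVA over the three
classes (within-subject midranks, tie-corrected, df = 2; fully tied
data return χ² = 0, p = 1), with pairwise Wilcoxon signed-rank
follow-ups: zero differences discarded, midranks for ties, W = sum of
positive-difference ranks, z from the tie-corrected normal
approximation without continuity correction, two-tailed p. Both match
exhaustive permutation oracles on small panels in the test suite. No
multiple-comparison correction is applied to the three pairwise tests.

Bias-based prediction asks whether expression *category* predicts the
first percept: 10 folds stratified by condition; per fold, the class
most often reported first for each pair in the 90% training split is
predicted for all test trials of that pair (an exactly tied training
bias falls back to a seeded coin flip; a pair absent from a training
split falls back to the global training bias, logged). Significance
comes from 10,000 permutations that shuffle the response *sides* within
each condition: sides are exchangeable within a condition when behavior
is class-blind, and because the left/right placement of the classes is
counterbalanced across trials, shuffled sides decouple outcome from
class while preserving the response-side marginals. Shuffling the
class-outcomes within condition instead would be degenerate — it
preserves each pair's marginal bias, the very thing the predictor uses.
The fixed-class variant (always predict one class, optionally within
one pairing) uses the same null. p = (1 + #{perm ≥ observed}) /
(n_permutations + 1).

## Orchestration and reproducibility

`run_all` (or the `cfsdecode run-all` CLI) executes synthesis →
extraction → three decodes (first percept on different-expression
trials; expression per image; first percept on same-expression trials)
→ weight correlations → behavioral statistics → bias prediction, writing
seven declared result files under `<out>/results/`, the model-run pools
under `<out>/intermediate/`, and a config echo plus run log at the top
level. One master seed fans out to named sub-streams (synthesis, folds,
shuffles, permutations) via `SeedSequence`, so stages can be re-run in
isolation and identical configs produce byte-identical outputs. With
multiple simulated subjects, decoding uses the first subject's session
and the group statistics use all subjects.

## Problem sizes in the test suite and acceptance script

The structural checks (384/768 features, 288 trials, 400 model runs,
1000 controls), the planted-recovery experiment and the type-I control
run at the default fold/model/control counts; type-I uses an 8 × 16
grid on 64 px images (the null-calibration property depends on model
coverage, so it is checked at the engine's real operating point). The
driver-recovery check uses the same reduced grid with a 5-fold ×
10-model × 10-control engine, and the left-right weight correlation
check an 8 × 8 grid. The planted-recovery fixture
confines class deltas to 12 wedges (4 per class) in SF bands 14–15 of
the default grid, where every sector holds exactly 6 coefficients, so
the three signatures are balanced in both total energy and RMS (see the
rescale subtlety above). Throughout, the stepwise wrapper uses cap 4 /
pool 8 in tests; the library defaults are cap 8 / pool 20.

## What the synthetic data do and do not show

The generator emulates the study's *structure* — contrast-controlled
stimuli with class-specific spectral signatures, a counterbalanced
six-condition design, energy-driven responses — not face photographs.
Passing tests show that the pipeline recovers planted spectral structure
selectively, controls its false-positive rate under label shuffling, and
that its statistics match exact oracles. They do not show that real
faces have class-balanced spectra (they do not; that is partly the
point of the original analysis), nor do they reproduce the empirical
effect sizes of any particular stimulus set: with class-blind response
defaults the Friedman test is null by construction, whereas a real
happy-superiority effect would appear here only if happy faces carried
more driver energy. Phase structure, spatial layout, and natural-image
1/f spectra are absent; analyses that depend on them are out of scope.

## Known limitations

* The per-feature weight (mean performance of containing models) is
  vulnerable to co-selection: any feature that rides in
  high-performing models inherits their performance. Disjoint filter
  blocks and the provenance-matched, labeling-clustered null contain
  this, but residual false positives concentrate near strong planted
  features when signal is near-deterministic.
* The wrapper's chi-square pre-screen can in principle exclude features
  that only help in combination (XOR-like structure); none of the
  analyses here depend on such interactions.
* The exact regression-to-the-mean correction of the original
  feature-selection toolbox is not published; the matched-resample null
  implements the stated criterion but may differ in detail.
* With a single simulated subject the Friedman/Wilcoxon group tests are
  undefined and are skipped with a log entry.
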