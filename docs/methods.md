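# Methods

This note documents the models inside `biasloop`, the parameter choices
that matter, and what the synthetic test bed does and does not show.

## Stimuli

An emotion-aggregation stimulus is 12 integer emotion ranks drawn i.i.d.
uniform on {1..50} (resampled in the measure-zero event that the mean is
exactly 25.5). The objective class is *more sad* iff the mean rank is below
25.5. Balanced sets pair each array with its mirror (rank → 51 − rank),
which flips the class and makes the set exactly class-balanced; mirroring
is an involution and mean(a) + mean(mirror(a)) = 51 always.

Faces are rendered as schematic grayscale glyphs: fixed head ring and eyes
plus a parabolic mouth whose curvature is linear in rank (frown ↔ smile).
The arc is drawn with a Gaussian pen (width 2/size) so curvature survives
rasterisation sub-pixel; the amplitude (0.16 of tile height) was chosen so
that a cold-started CNN learns the continuum reliably — smaller amplitudes
made training erratic. Twelve 16-pixel (default 24-pixel) tiles are laid
out row-major on a 4×3 grid padded to a square image. Rendering is
bit-deterministic in (ranks, tile size).

Consequence worth knowing: the glyph continuum is *cleaner* than morphed
photographs. A trained judge reaches ~97–98 % held-out accuracy on
objective labels (real-stimulus analogue: 96 %), so effects that depend on
residual stimulus ambiguity are smaller here (see "Label regimes" below).

## Simulated labellers

A labeller perceives the array's mean rank corrupted by late Gaussian noise
(`sensitivity_sd`, rank units), compares it against a shifted boundary
(`criterion`, positive = more "more sad" answers) and lapses to a coin flip
with probability `lapse`:

    P(more sad) = (1 − lapse) · Φ((25.5 + criterion − mean)/sd) + lapse/2.

Late noise on the aggregate (rather than per-face noise) is the simplest
model that a single accuracy/bias target can constrain. Calibration solves
for (sd, criterion) on the expected (not sampled) rates over a given array
set by nested bisection — both maps are monotone — and raises with
diagnostics when a target is unattainable (e.g. below-chance accuracy).
The 63 %-accuracy / 3 pp-bias target used for "human-like" labels lands
near sd ≈ 9.7 ranks, criterion ≈ +0.8.

## Label regimes and the judge

Four label regimes on a balanced array set: `objective`;
`objective_bias3` (flip uniformly chosen more-happy labels to more-sad
until exactly 53 % of labels are more-sad); `sim_human` (calibrated
labeller draws); `random_bias3` (fair-coin labels, then driven to exactly
53 % — downward flips if the coin overshoots). 53 % is the normative end
state; round-to-nearest sets the flip count.

The judge is a binary CNN: per stage 3×3 conv, batch normalisation, ReLU,
then 2×2 max pooling (default) or stride-2 convolution (desk scale,
`pool="none"`); then two dense hidden layers with 0.5 dropout and a 2-way
softmax. The default architecture keeps five stages with widths
(32, 64, 128, 256, 512) on 96×96 input. The desk-scale configuration —
used by `run_table1_experiment` and the acceptance script so that fifteen
CPU trainings fit in minutes — keeps the five-stage/three-dense shape at
64×64 input with widths (8, 16, 32, 32, 32). Training is mini-batch Adam
(lr 1e-3, batch 64, 12 epochs desk scale) with step decay (×0.3 at 50 %,
×0.1 at 75 % of epochs), a 10 % validation split, and early stopping that
restores the best-validation-loss weights. All stochastic pieces (init,
shuffling, dropout, splits) draw from one stream seeded by the config.

Expected desk-scale behaviour, averaged over five seeds on a 300-array
balanced held-out set:

* `objective` — accuracy ~97 %, |bias| ≲ 2 pp.
* `objective_bias3` — bias ~0–2 pp. Because the 3 % flips are independent
  of the stimulus, the Bayes rule under this regime is still the objective
  boundary; a near-Bayes judge therefore passes the label bias through
  *attenuated*. On harder, more ambiguous stimuli (softer decision
  boundaries) the pass-through is larger; the attenuation here is a
  property of the clean glyph continuum, not of the mechanism.
* `sim_human` — bias well above 3 pp (typically 10–25 pp): with heavy
  label noise the learned boundary shifts by the labellers' criterion and
  overshoots — bias amplification.
* `random_bias3` — the judge collapses to the majority class: ~100 %
  more-sad calls, bias ~50 pp, ~50 % accuracy vs objective classes, ~53 %
  vs the training-label rule.

Bias amplification is thus monotone in label noise at fixed 3 pp label
bias, which is the claim the acceptance tests check; exact interior
magnitudes are stimulus-dependent.

## Interaction protocols and agents

**Emotion change-of-mind.** Baseline blocks alone (default 3×50 trials),
then interaction blocks (default 6×50): classify, see the partner's class,
decide whether to change (Bernoulli policy with the empirical switch rates
as constants: 32.72 % on disagreement with an "AI"-labelled partner,
11.27 % with a "human"-labelled one, 0.3 % on agreement), then update the
criterion by a delta rule, c ← c + η(z_partner − z_own)/2 with z = ±1.
The expected drift per trial is η(P_partner(sad) − P_agent(sad)), so the
agent's sad rate converges toward the partner's. Default η = 0.1 with
sensitivity 9.7 produces a first→last interaction-block rise of roughly
51 % → 59 % against a 65 %-sad partner, the directional analogue of the
human feedback-loop effect; η is a design constant chosen for visible
within-session drift, not a fitted quantity.

**RDK advice weighting.** One baseline block then one block per partner
(each block presents the full 30-trial schedule, shuffled). Trial order:
independent estimate (evidence + offset + N(0, noise_sd), clipped to
[0, 100]) → commit w (default fixed 0.4) → partner response revealed →
joint response w·own + (1−w)·partner → delta-rule offset update
b ← b + η(partner − own). Expected dynamics: E[b_t] relaxes geometrically
to the partner's mean systematic offset (24.5 pp for the biased partner, 0
for the accurate one), at rate (1 − η) per trial. Defaults: η = 0.005
(gradual, non-saturating drift across five 30-trial blocks), noise_sd = 12,
per-agent baseline offsets ~ N(0, 8 pp) so an accurate partner has
idiosyncratic bias to remove. The committed w never depends on the current
trial's partner response — the session logger records w before the reveal,
and the tests verify the joint response reconstructs exactly from the
logged pre-reveal components.

The delta-rule agents are this package's own minimal learning model,
deliberately the simplest family that yields gradual block-wise drift with
the right fixed points; no claim of mechanistic fidelity to human learning
is made, and the learning rate is exactly recoverable from session logs by
least squares on the update recursion (the parameter-recovery test).

## Statistics

* Emotion bias: mean coded classification − 0.5. RDK bias/error: mean
  signed / absolute deviation of the agent's *independent* estimates from
  the evidence; induced bias = interaction − baseline bias; induced
  accuracy change = baseline − interaction error.
* Permutation tests: two-sided, sign flips (one-sample/paired) or label
  shuffles (two-sample); exhaustive enumeration whenever all 2^n sign
  patterns (n ≤ 14) or C(n, k) ≤ 15 000 splits fit, otherwise seeded Monte
  Carlo with add-one smoothing, default 10⁵ shuffles. Cohen's d; 95 %
  percentile-bootstrap CI of the mean (difference), 10⁴ resamples (the CI
  method is a package choice — the analysis tradition reports CIs without
  naming one).
* Block trends: one OLS slope per agent on block index, then a one-sample
  permutation test of the slopes against zero. This replaces mixed-effects
  trend models on purpose: it tests the same directional claim with no
  random-effects machinery, at some loss of efficiency.
* Influence comparison: per agent, z-score each induced metric across the
  three partner algorithms and compare the biased partner's bias z-score
  with the accurate partner's accuracy z-score (paired permutation test);
  alternatively relative change (induced bias / baseline bias, induced
  accuracy change / baseline error). The relative-change ratio is unstable
  for agents with near-zero baseline bias; the z-scoring method is the
  robust one and is what the equality test uses.
* Benjamini–Hochberg FDR correction is available as post-processing over a
  run's test family (α = 0.05 default).

## Problem sizes and numerical choices

Desk-scale defaults throughout: 4,000 training / 300 held-out arrays and
five seeds for the label-regime experiment; 50 agents × (1 + 5) × 30
trials for RDK trend experiments; 51 agents for the influence comparison
(divisible by the three Latin-square orders); 10⁵ shuffles for headline
tests, 2×10⁴ in the heavier simulation tests. The acceptance script runs
in ~5 minutes on one CPU. Degenerate inputs are defined: empty datasets
and out-of-range ranks/evidence raise; single-class training labels are
allowed but flagged; an all-identical permutation sample returns p = 1;
mean-rank-25.5 arrays are resampled at generation and rejected at
construction.

## Known limitations

* Glyph stimuli are cleaner than photographs; absolute bias magnitudes in
  the minor-bias regime are attenuated relative to the human-stimulus
  experiment (see above), and the sim-human amplification magnitude is
  stimulus-dependent. Directional and extreme-regime results are the
  robust quantities.
* The labeller and agents share one late-noise psychometric family; no
  per-face perceptual model, confidence model, or reaction times.
* The change-of-mind policy affects only the reported final class, not
  learning; the learning update uses the agent's own pre-advice answer.
* Human-subject effect sizes (switch rates aside, which are used as
  calibration constants) are not reproduction targets.
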