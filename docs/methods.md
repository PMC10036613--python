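# Methods

## Games

A game is a pair of 3×3 integer payoff matrices (row player = human,
column player = rational opponent), payoffs 1–9 by default.  Equilibria
are defined by **strict** best responses: with integer payoffs and
generic draws, strictness makes uniqueness checkable by enumeration of
the nine cells.  Two categories are generated by rejection sampling:

- **DO** (dominance-solvable): the column player has a strictly dominant
  action; the row player's equilibrium action is the best response to it.
- **UE** (unique equilibrium): neither player has a strictly dominant
  action, yet a unique strict equilibrium exists.

Accepted games must additionally have a unique naive action (no tie in
row means), a unique coordination cell (the lexicographic criterion
"maximise payoff sum, then minimise |payoff difference|" selects one
cell), and **pairwise-distinct** predictions from the three strategies.
Ties are construction-time rejections, never runtime tie-breaks: the
battery is tie-free by design, so the choice → strategy map is total and
deterministic.  The coordination rule is read lexicographically because
the two criteria (largest sum, smallest difference) otherwise conflict;
the sum dominates.  A default battery is 5 DO + 5 UE distinct games, and
batteries whose equilibrium rows are all identical are rejected so no
positional shortcut identifies the equilibrium.

Acceptance probability for a uniform draw is low (roughly 0.5 % for DO),
so `generate_game` is a loop of cheap NumPy checks; 500 games generate in
tens of seconds on one core.

## Synthetic gaze simulator

The simulator produces trials whose *category-level* statistics match
the behavioural signatures used throughout the package.  It is a
generative stand-in with the right sufficient statistics, not a
cognitive-process model.

**Response time.** Per strategy, RT ~ lognormal with (mean, SD) matched
by moments: Equilibrium (18 050, 13 200) ms, Naive (13 770, 16 780) ms,
Coordination (15 660, 15 400) ms.

**Sequence length.** Fixation durations are gamma (mean 250 ms, shape 5);
saccades are a fixed 30 ms (physiologically plausible; unconstrained
otherwise).  Fixations are appended while they fit inside the drawn RT,
tying sequence length to RT as in real data.  Fixation-count
distributions are otherwise a stipulation — no empirical target
constrains them.

**Transition kernel.** Each strategy has a probability vector over the
five transition categories (own-own, other-other, intracell, cross,
out-of-AOI):

| strategy      | own  | other | intracell | cross | out  |
|---------------|------|-------|-----------|-------|------|
| Equilibrium   | 0.18 | 0.29  | 0.12      | 0.35  | 0.06 |
| Naive         | 0.36 | 0.11  | 0.10      | 0.37  | 0.06 |
| Coordination  | 0.26 | 0.22  | 0.25      | 0.21  | 0.06 |

The own/other masses are the calibration targets; the intracell/cross/out
split is a package choice (documented here once): coordination gets the
largest intracell share because comparing the two players' payoffs within
an outcome cell is that strategy's hallmark, and the out-of-AOI mass is a
constant 6 %.

The kernel is realised by a three-state role chain (own / other / out)
whose **stationary flow frequencies equal the kernel exactly**: with
mixed mass q = intracell + cross and out mass z, flows are f(own,own) =
p_own, f(other,other) = p_other, f(own,other) = f(other,own) = q/2, and
the out state carries z/2 in and out, split between roles by occupancy.
The chain starts from its stationary distribution, so every transition's
marginal category distribution is unbiased at any sequence length — the
empirical proportions converge to the kernel with no small-sample bias.
On a mixed-role move, the destination is the same cell's other AOI with
probability intracell/(intracell+cross), else a uniformly chosen
different-cell AOI; within a role category the concrete AOI is uniform
over the 8 alternatives.  Fixation positions are AOI centres plus
Gaussian jitter (SD 8 px) clipped to 0.9 × radius, so jitter never moves
a fixation out of its AOI; out-of-AOI positions are uniform over the
screen outside every circle.

**Choices and participants.** The chosen action is the strategy's
prediction, flipped to a uniform alternative with probability
`choice_noise` (default 0: labels are defined by the chosen action, so
label purity is the baseline condition).  Each participant draws a
strategy-propensity vector from Dirichlet(c · mixture) with pooled
mixture (0.48, 0.31, 0.21) and concentration c = 2, giving the strong
within-participant consistency the design assumes while keeping the
pooled shares exactly at the mixture in expectation; c → ∞ collapses
every participant onto the mixture.

**What the simulator does not emulate:** spatial biases toward the
eventual choice cell, temporal non-stationarity of search (real gaze
drifts toward the decision late in the trial), pupil/blink events, and
inter-game transfer.  Passing tests therefore demonstrate that the
pipeline recovers structure *of this kind* from gaze sequences, not that
human data would yield the same accuracies.

## Scanpath images

1024×768 screen geometry, 18 circular AOIs (radius 45 px) on a 3×3 cell
grid, own payoff bottom-left and counterpart payoff upper-right of each
cell at maximal within-cell separation.  AOI containment is a closed disc
(boundary points count inside), so every fixation has a deterministic
assignment.

Rendering is a pure function of (record, layout, spec) at 224×224 RGB
(the native input size of standard CNN backbones): black background, AOI
circles (light gray own / dark gray other), saccade segments between
consecutive fixation positions coloured by linear interpolation from RGB
(0,0,255) to RGB (144,238,144) by temporal order, one aggregated marker
per fixated AOI (triangle own / diamond other) coloured by fixation count
on an embedded 256-entry magma-like sequential ramp — count 1 is the
near-black darkest entry, counts ≥ 20 saturate at the cap — and fuchsia
dots at 57 % marker size for out-of-AOI fixations.  Anti-aliasing is off
and the ramp is shipped as a data file, so identical inputs give
byte-identical rasters on any platform; draw order is fixed (background <
circles < saccades < markers < dots).  The light-green saccade endpoint
is pinned to CSS *lightgreen* (144,238,144) as the canonical "light
green" triplet.  No payoff values, labels or grid lines are drawn — the
image carries gaze structure only.

## Partial scanpaths

The cutoff is `value × rt` (percent mode) or `value` ms (time mode); a
record keeps exactly the events whose **end** time is ≤ the cutoff, so
events straddling the cutoff are dropped — a partial image reflects only
completed acquisitions.  Percent mode is measured against the trial's
response time rather than the last event's end time: RT is preserved by
truncation, which makes percent truncation idempotent and gives both
modes one retention rule; the two definitions differ only by the small
gap between the last event and the response.  Both grids nest
monotonically, and any cutoff at or past the trial duration is the
identity.

## Features and baseline

Transitions are classified between consecutive *fixations'* AOI
assignments (recorded saccade endpoints are ignored — robust to saccade
noise and faithful to "movement from one payoff to the next").
Proportions are normalised by the total transition count; a record with
fewer than two fixations yields zeros with an explicit
`has_transitions=False` flag.  The logistic baseline uses only the own,
other and intracell proportions as regressors (cross and out stay in the
feature vector but out of the design matrix); log RT is kept as a
separate correlate, not a regressor, matching the stated baseline
design.

## Models and evaluation

- **Split**: 70/20/10 at the participant level, largest-remainder
  rounding (243 → 170/49/24), seeded permutation.  No participant appears
  in two subsets; all metrics concern unseen participants.
- **Balancing (CT1)**: the whole dataset is balanced by undersampling the
  majority class before the split, as a pre-processing step.
- **SVM**: RBF kernel, gamma 1e-4, C 10 (optionally confirmed by 5-fold
  cross-validated grid search); images are block-averaged to 64×64 RGB,
  flattened and scaled to [0,1] — a resolution that keeps the kernel
  computation desk-scale.  CT2 uses class weights inversely proportional
  to class frequencies.
- **Logistic baseline**: unpenalised maximum likelihood; a fit that
  classifies its training set perfectly implies linear separation (the
  MLE does not exist), which is reported as a warning with an
  L2-regularised refit as fallback.
- **CNN stage (optional)**: a pluggable contract — any backbone exposing
  `extract(images)` gets a frozen-feature softmax head with L1/L2
  regularisation 1e-5, ≤ 30 epochs plus ≤ 10 fine-tune epochs at a
  lowered rate and early stopping.  Without a backbone the stage degrades
  (behind an explicit flag) to a small from-scratch NumPy conv net
  (conv 8@5×5/2 → ReLU → 2×2 average pool → softmax); the three-class
  task trains with focal loss (alpha 0.25, gamma 2).
- **Metrics**: accuracy = trace(confusion)/n; AUC binary for CT1 and
  one-vs-rest averaged with class-frequency weights (wAUC) for CT2; F1
  plain (CT1) or weighted (CT2).  Confidence is the predicted class's
  probability; interpretability correlations are Pearson r with
  two-sided p.
- **Protocol**: the model is trained once on full scanpaths from
  training participants and that same artifact is evaluated on the full
  test set and all eight truncated test sets.

## Problem sizes

The default experiment simulates 150 participants × 10 games;
calibration checks use 200 trials per strategy and a 500-participant
cohort; oracle suites use 1,000 random and 500 + 500 generated games.
These sizes make the full test suite and the reproduction script run in
a few minutes on one core while leaving all statistical checks
well-powered; the cohort size is configurable up to and beyond the
original 243.

Monte-Carlo calibration checks use trial-level 99 % confidence intervals
(the trial is the independent replicate; transitions within a trial are
Markov-dependent).  Such a single-cohort check has an intrinsic ~1–3 %
false-alarm rate, so the acceptance tests evaluate up to three
independent replicate cohorts and require one to land inside all its
CIs — a genuine miscalibration fails every replicate.

## Known limitations

- The simulator's category-level Markov walk ignores spatial adjacency
  (real saccades favour near AOIs) and temporal structure within trials.
- Classifier accuracies on synthetic cohorts depend on the configured
  kernel separation and are not estimates of human-data performance.
- The from-scratch conv net is a desk-scale stand-in for a pre-trained
  backbone and is not expected to match transfer-learning accuracy.
- The OSF ingestion adapter expects the package's own event-file dialect;
  mapping a real deposit's schema may require column adaptation.
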