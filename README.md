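# gazestrat

Predicting strategic choice in two-player 3×3 normal-form games from eye
movements, by encoding each trial's gaze as a colour-coded **scanpath
image** and classifying it before the player commits to an action.

## The problem

A human (row player, actions Top/Middle/Bottom) plays a matrix game
against a rational opponent (column player, Left/Middle/Right).  Every
game has a unique strict pure-strategy Nash equilibrium, and a player's
choice reveals their decision rule:

- **Equilibrium** — best-respond to the opponent's rational action;
  requires reasoning about the opponent's payoffs.
- **Naive** — pick the row `argmax_r mean_c U_row(r, c)` with the highest
  average own payoff, ignoring the opponent.
- **Coordination** — pick the row of the cell maximising the joint payoff
  `U_row + U_col`, tie-broken by the smallest `|U_row − U_col|`.

Games are constructed so these three predictions are pairwise distinct,
making choice → strategy a bijection.  Each decision rule leaves a
distinct information-search footprint in the gaze record: equilibrium
play makes many transitions among the *opponent's* payoffs, naive play
among the player's *own* payoffs, coordination play balances the two and
compares the pair of payoffs within outcome cells.

The pipeline exploits that footprint: fixations and saccades are drawn
onto a black canvas showing only the 18 payoff-centred areas of interest
(AOIs), with fixation counts per AOI mapped onto a perceptually uniform
sequential colour ramp (capped at 20) and saccades colour-coded from dark
blue (early) to light green (late).  Classifiers — an RBF-kernel SVM on
the images and a logistic baseline on the own/other/intracell transition
proportions — are trained on full scanpaths from training participants
and evaluated on *unseen* participants, both on full scanpaths and on
partial scanpaths cut at 15/30/50/80 % of the trial or at 2/5/10/15 s,
measuring how early the strategy is detectable.

A calibrated synthetic gaze simulator (strategy-conditioned transition
kernels, lognormal response times, Dirichlet per-participant strategy
propensities) makes the whole pipeline runnable and testable without any
eye-tracking hardware or data download.

## Worked example

`examples/05_ct1_experiment.py` runs the end-to-end binary task
(equilibrium choice or not) on a 40-participant synthetic cohort:

```
 set  accuracy   auc    f1  n
full     0.757 0.895 0.690 37
 p15     0.649 0.759 0.606 37
 p30     0.676 0.913 0.647 37
 p50     0.622 0.860 0.611 37
 p80     0.676 0.850 0.625 37
 t2s     0.622 0.888 0.611 37
 t5s     0.649 0.892 0.606 37
t10s     0.676 0.885 0.625 37
t15s     0.730 0.899 0.667 37
```

One logistic model, trained only on full scanpaths, classifies the
held-out participants' full records at 75.7 % accuracy and still performs
well above chance with only the first 15 % of each trial's gaze — the
strategy signature forms early in the visual search.  The other examples
cover game generation, cohort simulation, image rendering and partial
scanpath construction; each prints what its numbers mean.

Library surface: `gazestrat.games` (equilibria, dominance, strategy
predictions, game generation), `gazestrat.synth` (simulator + event-file
I/O), `gazestrat.render` (AOI layout and deterministic rasterisation),
`gazestrat.truncate`, `gazestrat.features`, `gazestrat.models`,
`gazestrat.cnn` (pluggable convolutional stage), `gazestrat.pipeline`.
A thin CLI mirrors the stages: `gazestrat games | simulate | render |
truncate | features | experiment`.

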