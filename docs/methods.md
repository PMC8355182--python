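# Methods

This note documents the analysis pipeline and the generative model behind
the synthetic data, including the numerical conventions and the design
decisions that were genuinely open.

## Analysis pipeline

### Pattern similarity

All similarity is the Fisher z-transform of the Pearson correlation
between per-stimulus voxel patterns (t-statistic-like response
estimates), computed only across scans — never within one scan, so that
estimation noise is independent between the two patterns entering a
correlation.  Correlations are clamped to |r| ≤ 1 − 1e−7 before the
z-transform so degenerate identities (a pattern correlated with a copy
of itself) stay finite; the clamp only ever acts on such constructed
cases.

The pairmate similarity score at an unordered round pair {i, j} averages
the two directional pairmate correlations and subtracts the mean of the
2 × 2 × 34 cross-item correlations between either pairmate and every
non-pairmate scene.  Self-correlations (the same scene across rounds)
are excluded from the baseline: self-similarity is a different construct
from item-item confusability.  Because the score is baseline-subtracted
it is comparable across regions with different overall signal levels,
and its sign is meaningful: negative means pairmates are farther apart
than unrelated scenes.

### Behavioral alignment

The learned round (LR) of a pair is the smallest k such that in round k
and every later round, both scenes' target objects were chosen with high
confidence.  A no-response trial counts as not-high-confidence-correct —
the definition demands positive evidence of retrieval, so a lapse resets
the candidate round.  The inflection point (IP) is the score at
{LR−1, LR}; pre-IP at {LR−2, LR−1}; LR±k at {LR, LR±k}.  Eligibility is
purely structural (IP needs LR ≥ 2, pre-IP needs LR ≥ 3, LR±k needs the
round to exist); ineligible cells are absent, never zero-filled, and all
participant means are taken over available pairmates only.

Participant-level behavioral exclusion is exposed as an optional
threshold on the final-round high-confidence rate and is off by default;
no principled cutoff is implied by the design, so the choice is left to
the analyst.

### Inference

* One-sample and paired t-tests report Cohen's d (mean/SD) and a 95% CI.
  A zero-variance sample exactly at the null value is reported as t = 0,
  p = 1 (vanishing-effect limit); zero variance elsewhere is an error.
* The repeated-measures ANOVA uses the classical sums-of-squares
  decomposition for 1–3 fully crossed within-participant factors, each
  effect tested against its interaction with participant, with classical
  η² = SS_effect / SS_total.  No sphericity correction is applied; for
  the 2×2 designs used here sphericity is automatic, and for larger
  designs the uncorrected classical test is the reported convention.
* The permutation test shuffles, within each participant, the assignment
  of IP round pairs across that participant's IP-eligible pairmates
  (uniform permutations, fixed points allowed), recomputes the group
  mean 1000 times, and reports the one-tailed p as k/n (an add-one
  (k+1)/(n+1) rule is available behind a flag).  Restricting the shuffle
  to eligible pairmates keeps every permuted assignment measurable by
  construction.  Participants contributing a single eligible pair add a
  constant to every permuted mean; participants with none are dropped.
* No multiple-comparison correction is applied anywhere; every p in the
  report is labeled uncorrected.

### Representational dynamics

Timepoint t carries the per-pairmate scores at consecutive round pair
{t, t+1}.  Structure correlations use Spearman's rho with average ranks
on ties, Fisher-z transformed, and average exactly three timepoint pairs
per lag — (1,2), (2,3), (3,4) for lag 1 and (1,3), (2,4), (3,5) for
lag 2 — so the two lags rest on the same number of comparisons.

The quartile analysis bins pairmates within participant by pre-IP score.
The default uses quartile (quantile) breaks on ranks, so bins are
equally populated; an equal-width-interval mode is available behind a
flag because base-R's `cut(x, 4)` — a common choice in this literature —
produces equal-width bins and the two conventions genuinely differ on
skewed score distributions.  Participants with fewer than four pairmates
holding both a pre-IP and an IP score are omitted.

A deterministic control distinguishes inversion from regression to the
mean: if every score partially shrinks toward the mean with no new
noise, ranks are preserved and the lag-1 rank correlation is +1; if
variance collapses entirely and is replaced by fresh noise, it is 0 in
expectation.  Neither mechanism can produce the negative correlation the
repulsion account predicts.

### Scene-object similarity

Object patterns are averaged voxelwise across the two object-exposure
rounds before correlation (a per-round mode exists behind a flag).  For
every pair with LR ≥ 2, scenes at LR−1 (pre-learned) and LR (learned)
are correlated with their target object (own associate) and competitor
object (pairmate's associate), both expressed relative to the mean
correlation with the 34 across-pairmate objects and averaged over the
two scenes of the pair.

## Generative model

Each scene's latent pattern is a unit-variance mixture over voxels of a
pairmate-shared component, a scene-unique component, and an
object-association component; all components are iid standard normal
across voxels and an observed round adds fresh Gaussian noise of scale
σ.  Learning is a single absorbing transition per pair with constant
per-round hazard; with the default degenerate response model
(high-confidence-correct with probability 1 from the LR, never before)
the behaviorally derived LR equals the generative one exactly, so
alignment error is zero by construction and can be studied separately by
relaxing those probabilities.

Three region types reproduce the qualitative regional dissociation:

* **remap** (hippocampal CA3/dentate-gyrus-like): from a pair's LR
  onward the shared component's sign is flipped for both pairmates and
  scaled by κ·(1 + γ·overlap), where overlap is that pair's *realized*
  noiseless pairmate similarity score at rounds (LR−2, LR−1) — repulsion
  is a reaction to the overlap that was actually there.  The flipped
  loading then decays geometrically (factor `kappa_decay` per round):
  repulsion peaks at the transition and the two codes relax toward
  independence, the classic remapping endpoint.  Without this decay the
  per-pair repulsion magnitude would impose a *permanent* ordering on
  all post-learning timepoints and the lag-1 structure correlation would
  be positive no matter how strong the repulsion — the transient form is
  what makes an inversion observable.  The object-association loading
  switches from the competitor's object (pre) to the target object
  (post), which also reproduces the pre-learned competitor > target
  scene-object effect.
* **stable** (CA1-like): no flip; structure persists apart from drift.
* **sensory** (early-visual-like): larger shared covariance, fully
  time-invariant; pairmate scores stay positive at every alignment.

In the hippocampal region types, the shared and unique components evolve
as stationary AR(1) processes across rounds (representational drift);
the sensory type is time-invariant.  Pairs also genuinely differ in
similarity: each pair's shared covariance is drawn uniformly from
c_pre·[1−s, 1+s].  After the flip, loadings are renormalized so every
voxel keeps unit marginal variance; a consequence worth knowing is that
the effective repulsion saturates for very large κ·(1+γ·overlap), which
bounds how steep the overlap→repulsion gradient can be made.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| n_participants / n_pairmates / n_voxels | 31 / 18 / 300 | study dimensions |
| c_pre | 0.15 | mean pre-learning pairmate covariance (unitless, fraction of voxel variance) |
| c_pre_spread | 0.15 | relative half-width of the per-pair covariance draw |
| c_pre_sensory | 0.5 | shared covariance in the sensory region |
| sigma | 0.55 | run-noise SD relative to unit signal SD |
| kappa | 1.1 | repulsion strength at the transition |
| kappa_decay | 0.3 | per-round decay of the flipped loading after the LR |
| gamma | 22 | overlap → repulsion coupling (per z-unit of realized overlap) |
| rho_drift / rho_unique | 0.6 / 0.15 | AR(1) round-to-round autocorrelation of shared / unique components |
| beta_comp_pre / beta_target_post | 0.15 | object-association loadings before / after learning |
| hazard | 0.25 | per-round learning probability |

The defaults were fixed by forward calibration against the qualitative
pattern the pipeline is meant to recover — pre-IP scores small-positive,
IP scores negative with a significant within-participant permutation
test, LR-versus-preceding below LR-versus-succeeding, lag-1 structure
correlation negative with lag-2 near zero in the remapping region,
lag-1 positive with lag-2 near zero in the stable region, and the
highest pre-IP quartile lowest at the IP — and then frozen.  Two
mechanistic constraints shaped them: the renormalization saturation
above (favoring moderate κ over extreme γ), and the fact that κ controls
both the global lag-1 inversion and the offsetting of persistent
pre-learning structure at lag 2, so it cannot be made small even though
a small κ would sharpen the quartile gradient.

### What the generator does and does not emulate

It emulates: pre-learning pairmate pattern overlap with true per-pair
heterogeneity, per-pair learning-round heterogeneity, abrupt
learning-locked decorrelation whose magnitude grows with realized prior
overlap, representational drift, run-wise measurement noise, and
scene-object associative structure that switches at learning.  It does
not emulate: BOLD dynamics or GLM estimation (patterns are generated at
the t-map level the analysis consumes), spatial autocorrelation across
voxels (Pearson correlation is the only consumer, and iid noise spans
the same null space), non-Gaussian noise, response-time structure,
session-level nuisance (motion, scanner drift), or attention/strategy
effects.  Passing tests therefore show the pipeline is correct and
well-calibrated and that the effect pattern is recoverable under this
model — not that real hippocampal data must show the effect.

Recognition (old/new) responses are generated with fixed hit and
false-alarm probabilities (0.99 / 0.02) solely to exercise the d′
summary; no learning dynamics are attached to them.

## Numerical conventions

* Fisher-z clamp at |r| ≤ 1 − 1e−7 (z ≈ 8.1); Spearman values clamped
  identically.
* Spearman ties: average ranks.
* Learned-round scan is a vectorized suffix-conjunction; "never" is NaN
  and all eligibility comparisons treat NaN as false.
* Missing cells propagate as missing; participant means use available
  pairmates; nothing is imputed.
* Quartile binning on ranks (`method="first"`) so exact ties cannot
  create unbalanced quantile bins.
* On-disk matrices are written at %.17g, so write → load is exact for
  IEEE doubles; repeated runs of the pipeline with one master seed are
  byte-identical (per-stage sub-seeds are spawned deterministically from
  it and every seed stays below 2³¹).

## Problem sizes used in validation

The acceptance suite validates oracle equivalence on ≥100 random small
fixtures per statistic (1e−10 agreement); null calibration on 200
structureless datasets of 31 × 18 × 100 voxels (aligned scores and
lagged structure correlations centered on zero within 3 SEM, permutation
false-positive rate in [0.02, 0.09] at α = 0.05); and effect recovery on
100 datasets at the default 31 × 18 × 300 size, requiring the full
remapping signature in ≥90% of runs (and in ≤10% in the stable region),
the lag-1 inversion plus lowest fourth quartile in ≥80%, "lag-2 near
zero" as |mean| ≤ 0.05 z (the magnitude range this literature reports as
null), and the scene-object state × relevance interaction in ≥90%.

## Known limitations

* The constant learning hazard yields a geometric learned-round
  distribution; empirical learning curves accelerate over rounds, so the
  synthetic distribution has more round-1 learners and more
  never-learners than a typical study.
* The overlap → repulsion coupling is linear in realized overlap with a
  floor at zero; non-monotonic (inverted-U) plasticity rules are not
  modeled, and the quartile analysis here can only exhibit monotone
  orderings.
* Regions are opaque voxel sets: no searchlight, no spatial maps, no
  cross-region voxel correspondence.
* The cross-region structure-correlation control (sensory at timepoint
  N against remap at N+lag) is expected near zero by construction, since
  regional latents are drawn independently; it validates bookkeeping,
  not anatomy.
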