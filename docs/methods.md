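# Methods

## The metric

Pairwise Fairness (PF) of subgroup G_i under scorer f is

PF(G_i) = P( f(x) > f(x′) | (x,y) ∈ G_i, y = 1, (x′,y′) ∈ G, y′ = 0 ),

estimated by pair counting with half credit for tied scores, computed
via midranks (`scipy.stats.rankdata`) in O(N log N). The half-tie
convention is chosen so PF of the trivial one-group partition equals
the Mann–Whitney AUC exactly; a strict-inequality convention would make
the two diverge on tied scores for no benefit. The negative pool is
**global**: it includes the subgroup's own negatives. Subgroups with no
positive have undefined PF and are excluded from the PFD
(max PF − min PF) rather than scored 0; a PFD needs at least two
eligible subgroups, otherwise it is an error. A brute-force O(n·m)
pair-counting oracle ships alongside the rank-based path and the test
suite requires exact agreement between the two.

Because PF depends only on the ordering of scores it is invariant to
any strictly increasing transform and never consults a classification
threshold; both properties are regression-tested.

## The training objective

Per batch: scores are positive-class probabilities (sigmoid of the
scorer's logit, the two-neuron softmax collapsed to its equivalent
single-logit form), so the ranking margin lives on [0, 1]. PF is
estimated for every subgroup with at least one positive in the batch,
against all batch negatives; the subgroup attaining the minimum is
selected (ties → lexicographically first category, so reruns are
deterministic) and the marginal ranking loss

L = (1/n) Σ_pairs max(0, −x_p + x_n + margin)

is minimised over its batch positives versus all batch negatives. The
exact definition pools negatives over the whole training set, which is
infeasible per step; the batch negatives are the unbiased minibatch
estimate. An optional FIFO buffer of recent negative scores is
available for a larger pool, but it is off by default: buffered scores
were produced by stale parameters, and in benchmark measurements the
buffer degraded both AUC and PFD.

Batches with no positives or no negatives yield a *skip* signal — no
parameter update, no cross-entropy fallback (the objective replaces,
not mixes, the losses). Skips are counted per epoch in the training
history, and every executed step is logged (epoch, batch, selected
category, its batch PF) for audit.

The default margin is 0.1. The hinge must stay active while positives
and negatives are still interleaved but deactivate once the worst
group's positives clear the negatives; on the probability scale, where
typical score spreads are a few tenths, 0.1 achieves this. There is no
principled unique value; it is exposed in `TrainConfig`.

## Trainer

Three loss modes share one loop: `bce` (baseline), `proposed` (above),
and `oversample` (bce on a multiset where minority-*class* indices are
resampled with replacement to equal class counts — class-level, not
subgroup-level, resampling). Optimisation is Adam; defaults are
learning rate 1e-4, batch 96, 20 epochs — the protocol values for
large pretrained backbones. The reference scorers are a linear model
and a one-hidden-layer tanh MLP in numpy with hand-written gradients
(verified against finite differences); for these small scorers the
*benchmark* configuration overrides the learning rate to 1e-2, the
knee of a decade sweep at which the baseline's dev AUC reaches its
plateau within 20 epochs (at 1e-4 the baseline is undertrained by
~0.1 AUC and mode comparisons would be meaningless).

Model selection: a dev set of 10% of training *patients* is carved
from the training split (never from test), dev AUC is evaluated each
epoch, and the parameters of the best epoch are returned. With
`epochs=0` the initialised scorer is returned with empty history. All
randomness (dev split, init, batch order, oversampling) derives from
one seed via `numpy.random.SeedSequence`; identical config + data +
seed gives bitwise-identical history.

## Synthetic biased cohorts

The generator emulates three bias mechanisms documented in real
diagnostic cohorts: per-group prevalence imbalance, per-group sample
size imbalance, and per-group class-separability disparity. Per group
g a patient is positive with probability π_g; each of their
1 + Poisson(1) images carries the informative signal d_g·(label) on
the first feature (or a unit-norm centred disc scaled by d_g in the
32×32 toy-image modality) plus unit Gaussian noise, so the
matched-filter scorer attains within-group AUC Φ(d_g/√2) — the basis
of the closed-form recovery tests. Labels are drawn at patient level;
all images of a patient share its label and group.

A nuisance *group-marker* channel (one feature per group, or a corner
patch in image mode) encodes group membership at a configurable
strength. This is the analogue of the group-identifying proxies real
medical images carry (anatomy, positioning, equipment), and it is
load-bearing: a scorer with no access to group information cannot move
one group's scores relative to another's, so neither the baseline's
demographic shortcut nor the fair model's correction could occur.
Default strength in the benchmark scenario is 1.0 (the same order as
the feature noise), fixed before any benchmark was run.

The `paperlike` benchmark scenario has three race-like groups with
image counts 1,282 / 1,008 / 306 (proportional to a real cohort's
38,457 : 30,239 : 9,191 at 1/30 scale), prevalences 0.37 / 0.70 /
0.40, and separabilities 1.8 / 1.8 / 1.0 — the smallest group is also
the hardest, so both imbalance mechanisms and the separability
disparity are present at once. ~2,600 images from ~1,300 patients keep
the full five-repeat benchmark under ten seconds on one CPU.

What passing tests on this generator do **not** show: real
radiographs' covariate shift, label noise, site effects, or any
mechanism where group membership is only partially recoverable from
the image; conclusions about the method's behaviour on real cohorts
require real cohorts.

## Evaluation protocol

Repeated holdout at patient level: each repeat shuffles patients with
its own derived seed and holds out round(0.2 × patients); no patient
appears on both sides. Within a repeat, all loss modes share the split
*and* the training seed, so initialisation and batch order are
identical — mode comparisons are paired, which at this scale roughly
halves the variance of the PFD difference. Reported tables carry mean
± sample standard deviation (ddof = 1) over repeats; relative changes
(x_proposed − x_baseline)/x_baseline are computed on the means, one
value per cell. Intersectional audits cross the two groupings with the
largest baseline mean PFD (ties broken by name) and re-audit the
already-scored test sets; only observed category combinations appear.

## Numeric and degenerate-input choices

- Numeric attribute bins are half-open [lo, hi) with the last bin
  closed above, so bins always partition the domain; a value equal to
  a threshold belongs to the upper bin. Published cohort tables print
  overlapping-looking labels ("65–75", "≥75"); exactly 75 goes up.
- Unknown or missing attribute values are errors listing the offending
  sample ids — never a silent "Other" bin, which would corrupt audits.
- Cohort-table percentages are rounded half-up to two decimals
  (`decimal.Decimal`), matching how such tables are printed; Python's
  bankers' rounding would differ on exact .005 boundaries.
- Hinge subgradient at exactly zero is taken as 0.
- Radiograph polarity ("invert so air is white") is decided by a
  border-versus-centre mean heuristic with a 10% frame — the border of
  an air-white image is brighter than its centre. Histogram
  equalisation is global, via the integer cumulative histogram over
  256 levels; re-equalising an equalised image moves pixels at most
  one level. Constant images pass through unchanged. Augmentation
  draws |angle| ~ U[0°, 10°] with a random sign (the protocol states
  only the magnitude range) and independent fair-coin horizontal and
  vertical flips; rotation fills exposed corners with black.
- JPG re-encoding (quality 95) exists only in the conversion utility,
  never in the training loader, to keep loading deterministic.

## Known limitations

- The reference scorers are deliberately small; plugging in a deep
  backbone means supplying an object with the same `logits/backward`
  surface (there is no autograd here).
- PF estimates in small batches are high-variance, so worst-group
  selection is noisy early in training; this is inherent to the
  per-batch protocol.
- On cohorts where subgroup separabilities genuinely differ, PFD
  equalisation necessarily spends some overall AUC (the demographic
  prior the baseline exploits); the benchmark shows ~1–2% at its
  scale. Probability calibration is out of scope: scores are ranking
  scores, not calibrated risks.
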