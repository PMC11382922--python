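# Methods

## Model

The core learner is a second-order gradient-boosted tree ensemble on additive
margins with binary logistic loss. With `p = σ(margin)` the per-sample
derivatives are `g = p − ỹ` and `h = p(1−p)`; margins are clipped to ±36 so
`h` stays strictly positive. Features are discretized once per training set
into quantile bins (default 32); when a feature has at most `n_bins` distinct
values the distinct values themselves become the bins, so binning is lossless
there. Split search scans every (feature, bin-boundary) candidate with the
regularized gain

    gain = ½ [ G_L²/(H_L+λ) + G_R²/(H_R+λ) − (G_L+G_R)²/(H_L+H_R+λ) ] − γ

and leaf weights are `w = −G/(H+λ)`; each tree contributes
`learning_rate · w`. Trees grow breadth-first to a fixed depth with full
expansion while a positive-gain split exists. Ties in the split search break
lexicographically by (global feature index, bin index); the global order is
guest features first, then each host's features in party order. This
deterministic tie-break is what lets the federated trainer reproduce the
centralized one bit-for-bit. Missing values are rejected — the dense
functional-feature tables this targets have none, and it keeps the histogram
protocol simple.

Defaults: depth 3, learning rate 0.3, λ = 1, γ = 0, `min_child_samples` = 1,
base margin 0. Depth and the stage tree counts (10/20/30) are the
configuration that performed best in the study this emulates; loss and
regularization are this package's own choices from the XGBoost family's
standard settings.

## Federated protocol

The simulator runs guest and hosts in one process, with every cross-party
exchange an explicit `Message` on a transport whose transcript is append-only.
Per tree: the guest seals the gradient vector and sends it to each host
(`gradients`); per level it announces frontier sample spaces
(`leaf_assignment`); hosts aggregate sealed gradients into per-feature bin
histograms and return them (`histogram`, sealed sums + public counts); the
guest unseals, scans, and either splits locally or notifies the owning host
(`split_broadcast` carrying feature name, bin index, gain and cover — all
aggregates), which records the threshold privately and answers with the left
child's sample ids (`split_answer`); right children are inferred. Prediction
routes through `routing_query`/`routing_answer` pairs, so the guest sees
left/right decisions but never thresholds or feature values. Host bin edges
are quantiles of host-local data (each party bins its own features) — with
per-feature binning this is identical to centralized binning of the same
columns, which the equivalence tests rely on.

Encryption is modeled as a *sealing contract*: hosts hold opaque objects whose
only interface is additive aggregation into histograms; a backend (default:
plaintext-with-audit) is the sole unsealing authority. The privacy guarantees
of the default backend come from the interface plus the transcript audit, not
from cryptography; a homomorphic backend can implement the same two-method
interface. The audit declares a transcript clean iff no host-bound message
carries label-like fields or unsealed gradients, no guest-bound message
carries raw feature values or thresholds, and host→guest traffic consists only
of histogram aggregates, split answers and routing answers.

Exact federated≡centralized equality is engineered, not approximate: both
trainers share the histogram, split-search and leaf-weight code, so every
floating-point accumulation happens in the same order. Leaf weights are
computed from the sample→leaf assignment with a single `bincount` in both
paths for the same reason.

## PU loop

Working labels initialize to the PU flags (unlabeled = negative). A relabel
stage ranks all training samples by the preceding model's probability
(descending, ties by ascending sample index) and sets the top
`round(proportion × n)` plus every observed positive to 1. The quota is over
*all* samples, not only unlabeled ones: on balanced data the final proportion
of 0.5 then drives the labels toward the balanced split, which is the
rationale for the default schedule's 0.3 → 0.5 progression. The alternative
(quota over unlabeled only) is a deliberate non-feature; it would change the
meaning of the published proportions. Every boost stage trains from scratch —
no margin carryover — because each stage is conceptually a new classifier
trained on a new labeling. Final hard predictions threshold at 0.5, the
symmetric default for balanced data; the harness also reports the
transductive accuracy of the final working labels against the hidden training
labels, since both readings of "accuracy" exist for PU pipelines.

`estimate_c` implements the Elkan–Noto e1 estimator: the mean nontraditional
score over labeled positives, clipped to (0,1]. It should be fed *held-out*
scores: in-sample tree scores are overfit-inflated (≈0.49 vs ≈0.20 at true
c = 0.2 in our measurements). The loop itself never uses the estimate; it is
a diagnostic of the SCAR constant-factor relationship.

## Synthetic data

The generator stands in for high-dimensional acoustic functional features. Its
default mirrors the emulated study's shape at desk scale: n = 1,330 balanced
samples (the corpus's 665+665 after undersampling), 200 features of which 165
carry signal — 15 informative plus 150 redundant — and 35 pure noise, with
labels Bernoulli(0.5) and SCAR flags at c = 0.2 ("20% of positives labeled").
Informative features are class-conditional unit-variance Gaussians with means
±class_sep/2 (default class_sep = 2). Redundant features are unit-norm random
linear combinations of the informative block plus Gaussian noise (sd 0.5),
emulating the strong cross-correlation of real functional features. The
mixing matrix is drawn from a separate `structure_seed` so that every draw —
train, test, validation — describes the same population; only the samples
vary with `seed`, which drives independent sub-streams for labels, features
and masking.

Because the informative block is Gaussian with known means, the true posterior
is available in closed form: `logit p(y=1|x) = class_sep · Σ_k x_k +
logit(pos_fraction)` over the informative columns. Tests use this oracle for
ranking and calibration checks; ranking comparisons use the log-odds rather
than the probability because at high separation the probability saturates to
exactly 0/1 in float64, creating artificial rank ties.

What the generator does *not* emulate: temporal structure, recording-length
effects, inter-institution distribution shift, label noise, and non-SCAR
labeling mechanisms. Passing tests therefore demonstrate protocol and
algorithm correctness and the PU loop's behavior under SCAR — not clinical
performance on real heart-sound corpora, whose absolute numbers depend on the
external audio features and are out of scope here.

A note on separation scale: class_sep acts per informative feature, so the
total Mahalanobis separation grows with √d_informative. At the defaults the
task is strongly separable (both PU and supervised pipelines exceed 99%
held-out accuracy, with a supervised-minus-PU gap of ~0.1–0.3 points, the same
order as the published corpus-scale gap). At class_sep = 3 roughly half the
population has a float-saturated posterior; within those regions
`g = c·f` varies below 1e-10 and no finite-sample estimator carries ranking
signal, which caps rank correlations against the true posterior near 0.85
regardless of model class. This is a property of the data regime, not of the
trainer.

## Importance

The five tree metrics all derive from the per-split records (feature, gain,
cover), where cover is the Hessian sum over the splitting node's samples; for
federated models each party contributes the records of the nodes it owns and
the guest aggregates, so no feature data crosses parties. Sums are primary;
the mean is sum/weight and the reported total is mean × weight, which makes
the `gain × weight = total_gain` and `cover × weight = total_cover` identities
hold exactly in floating point (the raw sum may differ from the reported total
by ≤1 ulp). SHAP is the path-dependent tree-Shapley variant: the value
function is the cover-weighted conditional expectation (training sample counts
as weights), computed exactly by enumerating subsets of each tree's used
features — at most 2^depth − 1 of them, so 2^7 subsets at the default depth;
trees using more than 16 features are rejected rather than approximated. The
global score is mean |φ| over a reference set (mean φ would cancel signed
effects); local accuracy `base + Σφ = margin` holds to machine precision.
Top-k selection (default k = 165) sorts descending with name-ascending
tie-break for stability.

## Evaluation harness

`repeat_experiment` redraws, masks, balances, partitions, trains and scores
once per repetition, with per-repetition seeds derived deterministically from
a master seed (all below 2³¹). Defaults: 1,330 training samples, 570 held-out
test samples (the 7:3 protocol ratio), two parties with a contiguous half/half
feature assignment, 50 repetitions in the API default; the acceptance script
uses 10 repetitions, a problem size chosen to keep a full from-scratch rerun
in the minutes range while leaving Monte-Carlo error well below the effects
of interest. Metrics are reported in percent with three decimals, mirroring
the result-table convention. UAR/UF1 raise on empty classes rather than
silently scoring zero.

## Known limitations

- The plaintext sealing backend protects against honest-but-curious *logging*
  analysis only; it is an interface for a cryptographic backend, not one.
- Sample-id sets travel in cleartext, as in the emulated protocol; id-level
  privacy (PSI, differential privacy on histograms) is out of scope.
- No column/row subsampling, early stopping, multiclass, sparse or
  missing-value handling in the booster.
- SHAP for federated models is computed on the merged (simulator-side) model;
  a deployment would need a federated attribution protocol.
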