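# Methods

## Problem setting

Protein function prediction is a multilabel classification problem over the
Gene Ontology (GO): each protein may carry many GO terms, experimentally
confirmed annotations exist only for a small minority of proteins, and an
*absent* annotation does not mean the function is absent — it is simply
unlabeled. Training a binary classifier that treats every unlabeled
protein–term pair as a negative therefore teaches the model to suppress
exactly the annotations one hopes to discover. `pufun` implements the
positive–unlabeled (PU) alternative: empirical risk minimization from
positives and unlabeled data only, with class priors derived from the GO
hierarchy, a pairwise ranking risk for the unlabeled side, and the
protein-centric / class-centric evaluation suite used by CAFA-style
benchmarks.

## Risk estimators

For a score function g and logistic loss l(z) = −ln σ(z), the
positive–negative risk π·RP⁺ + (1−π)·RN⁻ cannot be computed without
negatives. Using (1−π)RN⁻ = RU⁻ − π·RP⁻, the unbiased PU (uPU) estimator is

    R̂ = π·R̂P⁺ − π·R̂P⁻ + R̂U⁻ ,

with R̂P⁺ = −mean_{x∈P} ln σ(g(x)), R̂P⁻ = −mean_{x∈P} ln σ(−g(x)),
R̂U⁻ = −mean_{x∈U} ln σ(−g(x)). Flexible models can drive the estimated
negative-risk part below zero (overfitting the hidden positives), so the
non-negative (nnPU) estimator clamps it:

    R̂ = π·R̂P⁺ + max{0, R̂U⁻ − π·R̂P⁻ + β},   β = γ·π,  γ ∈ [0, 1].

The multilabel risk sums the clamped per-class risks over the k indexed GO
classes. Per class i the prior is

    π_i = π_o · S_i / S_max ,

where S_i is the fraction of training proteins annotated (after true-path
propagation) with class i and S_max the largest such fraction. Two details
matter:

- **β is per-class**, β_i = γ·π_i. The constraint 0 ≤ β ≤ π must hold for
  every class once priors vary; a single global β would violate it for rare
  classes.
- **π_o is a small tunable weight, not a literal class probability.** Its
  default search range is [1e−4, 1e−3] even though the most frequent
  (near-root) class is annotated in most proteins. With π_o that small the
  clamp essentially never engages and the per-class priors act as
  frequency-proportional weights on the positive-risk terms. Setting π_o
  near the true marginal rate of the most frequent class instead makes
  the inner term permanently negative for uniform-prior variants and
  freezes their unlabeled-side gradient; this configuration is supported
  but is not what the method is designed around.

The **ranking variant** replaces the per-class sigmoid unlabeled risk with
a pairwise logistic ranking risk over the batch's positive × unlabeled
pairs,

    R̂U⁻_rank = −(1/|P||U|) Σ_{x∈P} Σ_{y∈U} ln σ(g(x) − g(y)),

which only asks positives to outrank unlabeled samples instead of pushing
every unlabeled score to zero. It is invariant to adding a constant to all
logits (the sigmoid variant is not), and decreasing an unlabeled logit can
never increase it.

Four loss variants are exposed: `pn_bce` (treat unlabeled as negative,
mean binary cross-entropy), `pu_basic` (sigmoid unlabeled risk, uniform
π_o), `pu_ranking` (ranking risk, uniform π_o), and `pu_go` (ranking risk,
hierarchical per-class priors).

All risks are estimated **per minibatch**: P_i and U_i are the batch's rows
for class i; a class whose batch lacks one side is skipped and counted in
the batch report. Ranking pairs are enumerated exhaustively within the
batch (feasible at batch sizes of 30–200); there is no pair subsampling.
The clamp is the literal max{0, ·} — no gradient-ascent correction step is
applied when the inner term is negative. −ln σ(z) is computed as
softplus(−z) via log-sum-exp for numerical safety.

## Ontology handling

The OBO parser (backed by `obonet`) keeps obsolete terms flagged but
edge-free, resolves `alt_id`s to canonical accessions, and rejects cyclic
graphs naming a cycle member. Propagation follows `is_a` and `part_of`
edges (configurable to `is_a` only) and never crosses namespaces; each
subontology is modelled separately. Propagation is idempotent and produces
upward-closed annotation sets, which guarantees count monotonicity
(N_child ≤ N_parent) along every edge.

Information content is conditional on the full parent set:
IC(c) = −ln(N_c / N_{P(c)}), where N_{P(c)} counts training proteins
annotated with *every* propagation parent of c (the whole training set for
a root). Natural log is used throughout; Smin comparisons are internally
consistent under any fixed base. Propagation guarantees N_c ≤ N_{P(c)},
hence IC ≥ 0, and a root annotated everywhere has IC 0.

Class vocabularies are built per namespace from the propagated training
table with a configurable minimum annotation count (default 1), in
lexicographic accession order for determinism.

## Dataset construction

Evidence filtering retains the 13 experimental/curated codes (EXP, IDA,
IPI, IMP, IGI, IEP, TAS, IC, HTP, HDA, HMP, HGI, HEP) by default.
Similarity grouping reads DIAMOND/BLAST tabular output, keeps hits with
e-value ≤ 0.001, treats them as undirected edges, and takes connected
components as groups; proteins without retained hits are singletons.
Splitting assigns whole groups: 10% of groups to test, then 10% of the
remaining training groups to validation (≈ 81/9/10 of groups). Group-count
proportions are enforced; protein-count proportions drift with group sizes
and are only reported. No retained hit can cross a split boundary by
construction, and the whole assignment is a deterministic function of the
seed.

## Classifier

A residual MLP over precomputed protein-language-model embeddings
(5120-dimensional in the intended use). One block computes
Dropout(BatchNorm(ReLU(Wx + b))) — normalization deliberately *after* the
activation, which a regression test pins down — and the network is
h₁ = Block₁(x), h = h₁ + Block₂(h₁), logits = W₃h + b₃. Prediction applies
a plain sigmoid to eval-mode logits; scores are not propagated up the
hierarchy by default (an optional cumulative-max step is provided).

The network, Adam, and the triangular cyclic learning-rate schedule are
implemented directly on numpy arrays with hand-written backpropagation.
The loss gradient with respect to the logits has a closed form for every
variant (including the pairwise ranking term and the clamp's subgradient,
taken as zero when the inner term is non-positive), verified by central
finite differences to 1e−4 and backpropagated through the network.
Batch-normalization uses eps 1e−5 and running-statistic momentum 0.1
(biased variance for normalization, unbiased for the running estimate);
dropout is inverted. Eval-mode inference is a pure function of
(parameters, input), and training is bit-reproducible from
(config, seed): initialization, shuffling and dropout masks all derive
from the run seed.

Default hyperparameter search ranges: batch size 30–200, γ ∈ [0.01, 0.1],
max learning rate ∈ [5e−6, 1e−2], min-lr factor ∈ [1e−4, 1e−1],
π_o ∈ [1e−4, 1e−3]. A seeded random search over these ranges is provided
as the tuner; early stopping (patience 10 by default) and
best-validation-checkpoint selection are the stopping rule.

## Evaluation

Protein-centric Fmax, Smin and AUPR scan thresholds t ∈ [0, 1] in steps of
0.01; a class is predicted when its score ≥ t *and* positive (a zero score
is never a prediction, matching prediction files that list only scored
terms). AvgPr averages per-protein precision over proteins with ≥ 1
prediction; AvgRc averages recall over proteins with ≥ 1 true annotation.
Fmax is the maximum harmonic mean over defined thresholds (smallest
maximizing threshold reported); Smin = min_t √(ru² + mi²) with ru/mi the
IC-weighted missed/wrong annotation masses averaged over all evaluated
proteins; AUPR integrates the defined (AvgRc, AvgPr) points by trapezoid
after anchoring the curve at recall 0 with the most-stringent defined
precision, with no extrapolation toward recall 1. Class-centric AUC is the
rank-based (Mann–Whitney, ties 0.5) ROC AUC averaged over classes having
both positives and negatives in the evaluation set; one-sided classes are
skipped and counted.

Baselines: the naive classifier scores every query with the class's
training annotation frequency; the homology baseline transfers propagated
annotations from similar training sequences weighted by normalized
bitscore over hits at e ≤ 0.001 (queries without hits score zero); score
combination is the cellwise arithmetic mean over the union of protein
universes, with an absent operand contributing zero — conservative for
homology-free proteins.

## Synthetic data

The generator emulates the pipeline's real inputs without downloads. A
random single-namespace DAG is built by giving term j (j ≥ 1) one to
`max_parents` parents among terms 0..j−1 (acyclic by construction; a
fraction of edges are `part_of` to exercise typed-edge handling).
Embeddings are i.i.d. standard normal; every non-root term carries a
weight vector scaled so the per-term logistic score has standard deviation
`weight_scale` (default 2.0) and a bias logit(`target_rate`) (default
0.15), and direct annotations are Bernoulli draws from that logistic
model, closed upward to give the complete "true" matrix. Observation
follows SCAR: each true *direct* annotation survives independently with
probability c (default 0.25), and survivors are re-propagated — mirroring
curators adding leaf annotations whose ancestors follow automatically.
Because x is isotropic, each column's expected direct rate has a
one-dimensional closed form conditionally on its drawn weights, which the
Monte-Carlo tests exploit.

What the generator does *not* emulate: real embedding geometry (cluster
structure, anisotropy), correlated annotation noise, homology structure in
the similarity hits (the random-hit writer is a plumbing smoke test only),
and annotation biases that violate SCAR. Passing tests therefore certify
the estimators and their implementation under the model's own assumptions,
not performance on real proteomes.

## Recovery experiment

The headline simulation check: 3000 proteins, 32-dimensional embeddings, a
32-term ontology (≈ 30 usable classes after requiring ≥ 5 observed training
positives, a non-saturated true rate, and both label values in the test
split), label frequency c = 0.25, five paired seeds. Each seed draws one
dataset, splits proteins 80/10/10, and trains all four variants on the same
observed PU labels (hidden width 64, batch 128, 100 epochs, max lr 3e−3
cycling down to 3e−4, γ = 0.05, π_o = 1e−3 — the method's own magnitude, see
above). Held-out proteins are scored against the *complete* true labels
with class-centric mean AUC. The asserted outcome is directional: the full
variant beats the treat-unlabeled-as-negative baseline in the mean, and the
ranking variant is at or above the sigmoid variant. Problem sizes were
chosen so the whole experiment runs in a few minutes on one CPU;
the comparisons are paired across variants, which is what makes five seeds
statistically meaningful.

## Numerical and design choices

- Dropout default 0.1 (unstated upstream; configurable).
- Duplicate similarity hits: retention decided by the most significant
  copy; direction and self-hits ignored.
- Tie-breaks: smallest threshold attaining the Fmax/Smin optimum; stable
  lexicographic class ordering everywhere.
- Degenerate inputs: empty vocabulary, empty validation split, zero
  evaluable AUC classes, and fully-degenerate batches raise; single-class
  skips inside a batch are reported, not raised.
- Oracle tolerances in tests: exact for set counts, 1e−10 for ratios,
  1e−4 for finite-difference gradients.
- The γ search range is read as [0.01, 0.1] and the learning-rate ranges
  as [5e−6, 1e−2] / [1e−4, 1e−1] (ascending).

## Known limitations

- The per-minibatch ranking risk sees only within-batch pairs; very rare
  classes contribute gradients infrequently (they are skipped when a batch
  has no positive).
- Priors derived from observed frequencies inherit the SCAR bias of the
  observation process; the package does not attempt label-frequency (c)
  estimation.
- True negatives, ontology-embedding losses, and Gaussian-process
  hyperparameter optimization are out of scope; the random search stub
  covers the stated ranges only.
- The numpy training loop is single-threaded BLAS-bound and intended for
  embedding dimensions in the hundreds, not for full 5120-d × 20k-class
  production runs.
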