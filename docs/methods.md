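# Methods

## The model

`hinadr` learns low-dimensional drug representations from a heterogeneous
information network (HIN) with five object types — drugs (D), chemical
substructures (C), target proteins (P), side effects (SE), diseases (DI) —
and six binary relations (drug–drug interaction occurrence, drug–chemical,
drug–protein, drug–side effect, drug–disease, protein–protein interaction),
and uses those representations for three adverse-drug-reaction (ADR)
prediction tasks: side effects of a single drug (multi-label), occurrence
of a drug–drug interaction (binary), and the event types of an interaction
(multi-label).

The pipeline has four stages.

### 1. Meta-path proximities

Every meta-path starts and ends at drugs, so each one induces a symmetric
drugs × drugs proximity matrix S(p):

* **DD** — Jaccard similarity of interaction neighbourhoods,
  `S[i,j] = |D_i ∩ D_j| / |D_i ∪ D_j|` over rows of the (type-collapsed)
  interaction matrix; 0 when both neighbourhoods are empty.
* **DCD, DPD, DDID, DSED** — PathSim over the corresponding bipartite
  incidence M: with path-instance counts `C = M Mᵀ`,
  `S[i,j] = 2 C[i,j] / (C[i,i] + C[j,j])`, and 0 when the denominator
  vanishes.  The diagonal is 1 exactly for drugs with ≥ 1 attribute.
* **DP(n)D (n ≥ 2), "target propagation"** — drugs are proximate when the
  targets of one can reach the targets of the other through the PPI graph.
  With P the row-stochastic random-walk matrix of the PPI graph (zero rows
  for isolated proteins) and damping μ, the walk kernel is the Katz series

      K = Σ_{m≥1} (μP)^m = (I − μP)⁻¹ − I,

  which excludes the zero-hop term: shared-target similarity is already
  DPD's job, and the meta-path semantics require at least one PPI hop.
  The raw proximity is `R = M_dp K M_dpᵀ`; because row normalization makes
  P (hence R) asymmetric, the returned matrix is `(R + Rᵀ)/2`.

**Numerical choices.**  The kernel is computed by sparse LU solve of
`(I − μP) X = I`, restricted to the columns belonging to proteins that are
actually targeted; a truncated-series backend exists purely as an
independent cross-check (the two agree to ≤ 1e−8 at μ ≤ 0.9 in the tests).
μ defaults to 0.98, the conventional damping for this kernel.  Jaccard and
PathSim already lie in [0,1]; the unbounded propagation proximity is
min–max scaled to [0,1] so that all six matrices share one supervision
scale.  A PathSim/Jaccard denominator of zero yields 0, never NaN.

### 2. Per-sub-network embedding (semi-supervised SDAE)

Each proximity matrix is a homogeneous drug sub-network; each is encoded by
its own stacked denoising auto-encoder.  The input of drug i is row i of
the normalized proximity matrix (the SDNE convention; the choice of encoder
input is otherwise open).  Input neurons are zeroed independently with
probability `corruption_p`; all neurons use the sigmoid activation; the
loss is

    L = Σ_i ‖x̂_i − x_i‖² + α Σ_{i,j} S_ij ‖e_i − e_j‖² + β Σ_k (‖W(k)‖²_F + ‖Ŵ(k)‖²_F)

— reconstruction of the *clean* input, pairwise proximity preservation on
the embedding layer, and a Frobenius penalty on all encoder/decoder weight
matrices (biases unpenalized).  Training is full batch (the drug axis is
small) with Adam and hand-derived gradients; the supervision term enters
the embedding layer as `4αLE` with `L = diag(S·1) − S` (the pairwise sum
equals `2 tr(EᵀLE)` for symmetric S, an identity the tests check against a
literal double loop).  A minibatch mode subsamples drugs and rescales the
supervision by the inverse pair-sampling fraction; greedy layer-wise
pre-training is available behind a flag but off by default (end-to-end
training is simpler and the schedule of the layer-wise variant is
unspecified).

**Why α defaults to 1e−3.**  The two loss pieces are *sums*: reconstruction
over n drugs, supervision over all n² ordered pairs of a dense matrix with
typical entries ~0.3.  At n ≈ 120 the supervision term therefore outweighs
reconstruction by roughly two orders of magnitude per unit of α; with
α ≳ 0.005 the optimum collapses every embedding to a single point (the
pull term has no opposing spread term — only reconstruction pushes
embeddings apart).  α = 1e−3 leaves between-cluster distances intact while
visibly contracting within-cluster distances, which is the intended
semi-supervised effect.  Validation sweeps at desk scale put the usable
range at roughly 1e−4–1e−3.

Other defaults: layers n → 256 → 64 (encoder; decoder mirrored),
`corruption_p = 0.2`, β = 1e−4, learning rate 5e−3, 500 epochs.  All
randomness (weight init, corruption, minibatch sampling) derives from one
explicit seed; corruption masks are keyed by drug ID rather than row
position, which makes embeddings exactly equivariant to a consistent
permutation of the drugs.

### 3. Secondary embedding (fusion)

The per-meta-path embeddings e(p) are concatenated in canonical meta-path
order (DD, DCD, DPD, DPnD, DDID, DSED) and passed through a second SDAE of
the same form, whose supervision is the weighted average

    S̄ = Σ_p α(p) S(p) / Σ_p α(p).

The secondary encoder reconstructs the concatenated vector e_i (not the
original proximity rows).  The fusion weights α(p) ∈ {0.1, …, 0.5} can be
selected by cross-validated ROC-AUC of a downstream head on a small
labeled drug subset (10% by default, 10 folds); the full 5^6 grid is
combinatorial, so the default strategy is coordinate ascent with two
sweeps (exhaustive enumeration is available for ≤ 3 meta-paths).  With the
search disabled every weight is 0.3, the grid midpoint — the average is
then uniform, and Eq.-level behaviour is unchanged under rescaling of a
single weight.  Final dimension defaults to 64.

### 4. Prediction heads

Every task uses one fully-connected sigmoid layer
`y′ = σ(W_P e + b)` trained on the summed binary cross-entropy plus
`λ‖W_P‖²_F`, fit by L-BFGS on the exact loss with analytic gradients and
zero initialization (hence deterministic).  Multi-label tasks are fit
jointly — with no shared hidden layer this is mathematically identical to
independent per-label logistic models, and a `per_label` flag runs the
literal one-by-one protocol.  Pair tasks concatenate the two drug
embeddings; since an interaction is an unordered pair, training presents
both orders and prediction averages them, making scores symmetric.
Negative pairs are sampled uniformly from the non-interacting universe at a
1:1 ratio by default.

**Why λ defaults to 1.0.**  At desk scale a training fold holds ~85 drugs
while features are 64-dimensional and outputs multi-label; λ = 1e−4 is
effectively unregularized there and the head interpolates noise directions
(validation ROC-AUC ~0.53 versus ~0.75 at λ = 1 on synthetic runs).  λ is
exposed everywhere and should be re-tuned on validation data for other
regimes.

## Evaluation protocol

Hold-out is at the *drug* level: 10% of drugs form the test set and all of
their side-effect and interaction entries are zeroed in the training
network before proximities are computed ("scrubbing"), so no test label can
leak through any training-side artifact — a property the tests assert by
poisoning test-drug labels with sentinels.  The remaining drugs split 95/5
into train and validation.  Split sizes use half-up rounding (100 drugs →
10/85/5; 548 → 55/468/25).  The whole cycle (split → scrub → proximities →
embeddings → heads → metrics) repeats R times; reports carry
per-repetition rows and mean/std aggregates.  R defaults to 5 at desk
scale; a protocol-faithful configuration uses 30.

Metrics: **AP@K** defaults to the standard definition — precision
accumulated at the relevant ranks, normalized by `min(L, K)` — which keeps
MAP in [0, 1]; a literal mode (`as_printed=True`) accumulates Precision(k)
at *every* rank k ≤ K and can exceed 1 (L = 1, K = 3 gives 11/6 on a
perfect ranking), so both readings of the printed formula are available.
Instances with no relevant item return 0 with a warning and are excluded
from MAP.  Ranking ties break by ascending item index (stable sort), so
MAP is deterministic.  **ROC-AUC** is the Mann–Whitney statistic with
midrank tie handling (scikit-learn's implementation; the tests pin it to a
brute-force pairwise oracle, ties included).

## The synthetic HIN generator

Real integrated pharmacovigilance datasets are licence-encumbered, so the
generator emulates the *schema* at configurable scale with two planted,
exactly recoverable signals:

* **Drug clusters** (default 120 drugs, 4 clusters): each cluster has
  prototype chemical-fingerprint and disease vectors (bits drawn at rate
  0.3); per-drug vectors flip each bit independently with
  `bit_flip_noise = 0.1`.  Targets (3 per drug) are drawn from the
  cluster's protein community, rewired to a random protein with the same
  flip probability.  Within-cluster drug pairs interact with probability
  0.35 versus a 0.05 background.
* **Mechanistic side effects** (default 40): the PPI graph is a stochastic
  block model over 150 proteins whose communities align with cluster
  target pools (within/between edge probability 0.08 / 0.005).  Each side
  effect is anchored at one protein; a drug carries it (noise-free) iff
  some target lies within `propagation_hops = 2` PPI hops of the anchor;
  observed labels flip with `se_noise = 0.05`.  DDI event types reuse the
  same mechanism on the union of the pair's targets.  Hop-bounded
  reachability (rather than diffusion weights) keeps the ground truth
  exactly computable by breadth-first search, which is the independent
  oracle for the propagation machinery.

These defaults were chosen once as a realistic desk-scale regime — large
enough for stable AUC estimates, small enough for minutes-scale runs — and
are the conditions under which the acceptance properties are stated.  What
the generator deliberately does **not** emulate: the heavy-tailed degree
distributions of real PPI and DDI data, ADR co-occurrence structure,
correlated label noise, and the order-of-magnitude larger vocabularies of
the real databases.  Passing tests therefore demonstrate that the
machinery recovers planted structure of the intended kind, not that the
method attains any particular accuracy on real pharmacovigilance data.

Because side-effect labels are a function of *multi-hop* PPI reachability,
the DP(n)D meta-path is the proximity that observes that signal most
directly; ablating it ("no-target-propagation" variant, which simply drops
DPnD from the meta-path set) lowers Task-1 test ROC-AUC in the majority of
repeated splits — the qualitative counterpart of the full-versus-ablated
comparison the method is designed around.  The advantage is modest and
split-dependent at desk scale: the DPD meta-path (shared targets) carries
much of the same community-level information, since per-drug targets are
drawn from small cluster pools, so DP(n)D's *marginal* value is the
drug-specific reachability component only.

## Degenerate inputs and edge cases

Proteins appearing only as drug targets are retained as isolated PPI nodes
(zero transition rows, no kernel mass).  Drugs with no targets have
all-zero propagation rows.  μ ≥ 1 is rejected (series divergence).
Single-class label columns fit with a warning (the bias absorbs them);
single-class ROC-AUC raises.  A non-finite training loss aborts with the
epoch and loss components.  Empty relations are legal and yield all-zero
matrices.

## Problem sizes

Default test-suite and acceptance runs use the 120-drug generator
configuration, 5 seeds or repeated splits, and the default 500-epoch
training schedule; unit tests run far smaller instances (8–40 drugs,
25–60 epochs).  These sizes are the package's desk-scale choices and are
stated in the report metadata of every run.

## Known limitations

* The SDAE is plain NumPy on one CPU; it is sized for hundreds of drugs,
  not tens of thousands (the drugs × drugs proximities are dense).
* The α(p) grid search retrains the secondary encoder per candidate and is
  costly; coordinate ascent is a heuristic and is not guaranteed to find
  the grid optimum.
* ADR event probabilities are intentionally out of scope (labels are
  binarized), as is any acquisition or ID-mapping of real databases; no
  calibration of head probabilities is attempted.
* The min–max normalization of the propagation proximity and the SDNE-style
  choice of encoder input are documented design choices, not uniquely
  determined by the method's description.
* The DDI-occurrence head is a single linear layer on concatenated pair
  embeddings; it cannot represent equality-type interactions ("drugs
  interact iff they share a latent group"), which is exactly the structure
  the synthetic generator plants — so DDI-occurrence ROC-AUC sits near
  chance on the synthetic benchmark even when the embeddings encode the
  groups perfectly.  Richer pair features (e.g. elementwise products)
  would fix this but are outside the method's formulation.
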