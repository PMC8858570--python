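# Methods

## Problem and model

`ganlink` treats link prediction in a protein–protein interaction (PPI)
network as image-to-image translation. The known interactome is assumed
to be a uniformly under-sampled snapshot of a denser true network, so a
model that learns to reverse one step of uniform edge removal — mapping
a network at 81% of its edges to the same network at 90% — can be
applied one level up (90% → 100%, or 100% → beyond) to propose new
links.

Whole-interactome adjacency matrices are far too large and sparse to
train on, so the network is cut into fixed-size pieces: from every node
a modified breadth-first search collects whole neighbor layers while
the running node count (start node included) stays below the limit
l = 36, then fills the remainder with nodes drawn uniformly from the
first overflowing layer. Every emitted subgraph has exactly l nodes;
start nodes whose connected component is smaller than l yield nothing.
Each subgraph contributes an l×l binary adjacency matrix at the lower
connectivity level (the condition) paired with the matrix of the same
node group at the higher level (the target).

The translator is a conditional Wasserstein GAN with gradient penalty:

* **Generator** — a U-Net: the 36×36 condition is zero-padded to 40×40,
  encoded by three stride-2 convolutions (channel widths c, 2c, 4c with
  c = 64 by default), decoded by mirrored transposed convolutions with
  skip concatenation at matching depths, squashed by a sigmoid and
  cropped back to 36×36. There is no noise input: the map from
  condition to confidence matrix is deterministic.
* **Critic** — three stride-2 convolutions over the channel-concatenated
  (condition, candidate) pair, flattened into one linear score. No
  squashing activation and no batch normalization (per-sample gradient
  penalties require per-sample scores).
* **Losses** — critic: E[D(c, G(c))] − E[D(c, x)] + λ·E[(‖∇x̂ D(c, x̂)‖₂ − 1)²]
  with λ = 10 and x̂ a per-sample uniform interpolate between target and
  generated candidate; the gradient is taken with respect to the
  candidate only. Generator: −E[D(c, G(c))], optionally plus a weighted
  L1 reconstruction term (below). Optimization uses Adam
  (lr = 2·10⁻⁴, β₁ = 0.9, β₂ = 0.99), batch size 64, 3 epochs, and 5
  critic updates per generator update — all defaults, all configurable.

Confidence matrices from all subgraphs of the input level are
aggregated per unordered node pair by taking the maximum over every
occurrence and both matrix orientations; pairs already present in the
input network are pruned; the remainder is ranked by descending
confidence with lexicographic tie-breaks.

## Numerical core

No deep-learning framework is used: the models run on a small
reverse-mode automatic-differentiation engine over float32 numpy
arrays (`ganlink.nn`). Every vector–Jacobian product is itself built
from differentiable primitives, so the engine supports double
backprop; this is load-bearing, because the gradient penalty puts the
norm of an input gradient inside the critic loss and its parameter
gradient must flow through that inner backward pass. Convolutions are
im2col/col2im index maps plus batched matrix products; correctness of
first- and second-order gradients is pinned by finite-difference tests.

## The balanced reconstruction term

The optional pix2pix-style L1 term exists because pure Wasserstein
feedback converges slowly at small step budgets. Adjacency targets at
realistic sparsity are ≈ 95% zeros, and a plain pixel-mean L1 through a
sigmoid collapses the output to all-zeros: the majority class saturates
the sigmoid and the sparse positive entries then receive vanishing
gradient. The implementation therefore reweights present-edge pixels by
the batch zero/one ratio (`l1_balanced`, on by default) so both classes
exert equal total pressure; the term is normalized by the total weight
so its scale stays comparable to the unweighted mean. With balancing,
a single-pair overfit run drives held-out edge positions to confidence
≈ 1 while never-edge positions stay near 0; without it the same run
saturates to zero everywhere. The library default remains
`l1_weight = 0` (pure adversarial objective); pipeline profiles that
must learn within a small step budget enable it.

A related scale effect is worth knowing: the Wasserstein critic's
score is unbounded, so unlike the bounded discriminator loss the
pix2pix weight of 100 was calibrated against, a fixed `l1_weight` can
be overwhelmed by the adversarial gradient as the critic sharpens.
At small scale this can compress all confidences toward zero while
leaving their ordering — and hence ranking metrics — intact. Where
interpretable absolute confidence levels matter, raise `l1_weight`
until the reconstruction term dominates (the training examples use
1000 for this).

## Evaluation

Positives are held-out edges that received a confidence; negatives are
all other scored candidate pairs. Held-out edges whose endpoints never
co-occur in any subgraph cannot be scored; they are reported as the
`unpredictable_fraction` of the coverage report rather than silently
dropped, and a strict mode appends them at confidence 0 so they count
against the curves. AUROC is the Mann–Whitney statistic (ties ½),
AUPRC the non-interpolated average precision, and NDCG uses binary
gain, log₂ discount and no truncation — the metric trio's exact
variants are reconstructions, pinned against brute-force oracles in
the tests. Cross-validation summaries are arithmetic means of fold
metrics.

## Synthetic fixtures

Three generators emulate the high-confidence interactome regime
(densities of order 0.2–0.8% of all pairs, one giant component, small
isolated components below l, heavy-tailed degrees):
scale-free (preferential attachment), planted-partition (stochastic
block model) and duplication–divergence. The planted-partition model is
the end-to-end benchmark because recoverability is tunable: with
within-block density ≫ between-block density, uniformly removed
within-block edges are statistically recoverable from topology, and a
common-neighbors heuristic certifies each scenario is learnable before
the GAN is credited or blamed. What fixtures do **not** reproduce:
real interactomes' degree-correlation structure, study bias, or any
molecular signal — passing tests demonstrate correct mechanics and
topological recoverability, not wet-lab validity of predictions.

## Scaled-down run profiles

Full-scale training (thousands of subgraphs, default widths, 10-fold
cross-validation) is a GPU-scale workload. Tests and examples use a
scaled profile chosen by problem size: base channel width 8–16,
`critic_steps = 1`, `l1_weight = 100` with balancing, batch size
16–32, learning rate 1–2·10⁻³, and epoch counts that give the
generator on the order of a thousand updates —
comparable total parameter displacement to the full recipe, whose
3 epochs over far more batches yield a similar update count at
lr 2·10⁻⁴. The end-to-end benchmark uses a 600-node, 8-block
planted-partition fixture at 2% density with a 25× within/between
ratio and 10% edge holdout.

## Degenerate inputs and tie-breaking

Self-pairs in input files are dropped (and counted in the log); the
diagonal of every matrix is fixed at zero and self-interactions are
never predicted. Edges are canonical sorted pairs; all orderings
(edge lists, spec enumeration, prediction ties) are lexicographic, so
every artifact is byte-reproducible for a fixed master seed. Each
start node draws its subgraph-fill randomness from a stream keyed by
(seed, hash of node id), making specs independent of enumeration
order. K-fold and holdout splits canonicalize and shuffle the edge
list before splitting so results do not depend on input file order —
a deliberate choice in favor of reproducibility over replaying any
particular file ordering.

## Known limitations

* Node coverage and therefore recall are structurally bounded: links
  whose endpoints never share a subgraph are invisible (reported, not
  scored).
* The conv prior assumes informative local structure in BFS-ordered
  adjacency matrices; orderings that scatter communities weaken it.
* CPU-scale profiles trade model capacity and training length for
  runtime; reported synthetic benchmarks are scaled-down analogues,
  not reproductions of full-scale results.
* The critic is a reconstruction: the original layer table is not
  published, so no bit-compatibility is claimed.
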