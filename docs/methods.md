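# Methods

## The model

`foldembed` embeds a protein domain — an ordered Cα trace — into a
128-dimensional unit vector such that cosine similarity between vectors
reflects structural relatedness. The network operates on a graph whose
nodes are Cα atoms and whose edges connect Cα pairs within 10 Å.

### Node features (69 per residue)

| feature | dims | definition |
|---|---|---|
| packing density | 1 | neighbour count within 10 Å (self excluded), divided by the maximum count in the domain |
| N-/C-terminus flags | 2 | one-hot marks on the first and last residue |
| τ pseudo-torsion | 2 | (sin τ, cos τ) of the dihedral through Cα(i−1), Cα(i), Cα(i+1), Cα(i+2) |
| positional encoding | 64 | transformer-style sinusoids of the 0-based position in the domain, base 10000 |

Every feature is a function of inter-atomic distances, dihedral angles,
or sequence indices, so the representation — and hence the embedding —
is SE(3)-invariant by construction. Choices the feature list leaves
open, decided here and isolated behind `featurize` so they can be
swapped:

* τ is fed as (sin, cos) rather than raw radians, removing the ±180°
  discontinuity; residues without a complete quadruple (the first node,
  the last two, chains shorter than 4) and geometrically degenerate
  quadruples get (0, 0);
* density excludes the residue itself (self-inclusion would only shift
  all counts by one before normalization);
* the edge cutoff is a closed ball: pairs at exactly 10 Å are edges;
* the positional encoding uses position within the domain, not author
  residue numbering, so renumbered copies of a structure embed
  identically.

### Architecture

A message-passing network in the E(n)-GNN family configured without
coordinate updates, which reduces it to a standard GNN whose edge
operation also receives the squared inter-node distance:

1. a one-layer MLP lifts the 69 features to the 128-wide hidden state;
2. six residual message-passing layers: per directed edge (i, j) an
   edge MLP — Linear(2·128+1 → 256), SiLU, Linear(256 → 64), SiLU —
   consumes (h_i, h_j, ‖x_i − x_j‖²); messages are sum-aggregated at
   node i; a node MLP — Linear(128+64 → 128), SiLU, Linear(128 → 128) —
   maps (h_i, m_i) to an update added to h_i;
3. a two-layer node MLP, sum-pooling over nodes, a final two-layer MLP
   to 128 dimensions, and L2 normalization.

Squared distances enter the edge MLP raw. There are no dropout or
normalization layers, so training and inference behaviour are
identical. Weights are initialized uniform fan-in, U(−1/√d, 1/√d),
from a recorded seed; the default model has 817 280 parameters. The
residual is added after the node update (the reference configuration of
the cited GNN family). The whole network, including reverse-mode
gradients and the Adam optimizer, is implemented in float64 NumPy;
at these model sizes a vectorized CPU implementation is fast enough,
and float64 arithmetic makes every pipeline stage bit-reproducible for
a fixed seed.

Graphs are batched block-diagonally (index-offset edge lists, segmented
pooling), so batched and single-graph embeddings agree to round-off.

## Training

Supervised contrastive learning on domains labeled with a four-level
hierarchical classification (class.fold.superfamily.family, sccs-style
strings such as `a.1.1.2`).

* **Batches.** Each epoch cycles over the training families in seeded
  shuffled order. Per anchor family, five other families are drawn at
  random; each of the six families contributes six domains (drawn
  without replacement until exhausted, then duplicated), giving 36
  domains with six unique labels per batch and one Adam step per batch.
* **Loss.** The multi-positive supervised contrastive loss in its
  "positives averaged outside the log" form (the variant the loss's
  originating work recommends), temperature τ = 0.1:
  L_i = −(1/|P(i)|) Σ_{p∈P(i)} log[ exp(z_i·z_p/τ) / Σ_{a≠i} exp(z_i·z_a/τ) ].
* **Augmentation.** During training only, zero-mean Gaussian noise of
  variance 1.0 Å² is added independently to every coordinate component
  before featurization, resampled at every appearance of a domain (so
  within-batch duplicates are not bit-identical inputs).
* **Optimizer.** Adam, learning rate 5e-5, weight decay 1e-16 (classic
  L2 coupling), no gradient clipping; defaults follow the published
  training protocol, and the small-scale runs below override the
  learning rate.
* **Model selection.** After every epoch the family-level retrieval
  sensitivity is computed on the validation set, used as both queries
  and database with the self-hit included; the checkpoint from the best
  epoch is returned. Ties keep the later epoch: a small validation set
  saturates at sensitivity 1.0 while the loss is still falling, and the
  most-trained of the tied checkpoints is the better model.

## Search

Embeddings are stored as Float16 rows ("half precision") with per-entry
metadata and a fingerprint of the producing model; rounding to Float16
changes any pairwise score by under 1e-3 and is re-measured by the test
suite. Search widens the rows to float64, renormalizes, and computes
every cosine in one matrix–vector product — exhaustive, no approximate
index. The reported score is (1 + cos)/2 ∈ [0, 1]; 1 means identical
embeddings, and a score ≥ 0.8 conventionally indicates the same fold.
Ties are broken by database insertion order (stable sort).

## Retrieval benchmark

Every query is ranked against the full database (query included). The
per-query metric is the fraction of true positives detected up to the
first hit from a different fold, with TPs defined per level: family =
same family; superfamily = same superfamily and not same family; fold =
same fold and not same superfamily. The stopping rule is purely
fold-based at every level, so the self-hit (same fold by definition)
never stops the scan, and hits that are not TPs at the evaluated level
pass through silently unless their fold differs. Also reported: the
fraction of the top-20 hits sharing the query's fold, and summaries
stratified by class, length bins and contact-order bins.

Contact order — used for stratification — counts all residue pairs
whose Cβ atoms (Cα where Cβ is absent, e.g. glycine) lie within 8 Å,
with no minimum sequence separation, and divides the mean sequence
separation of contacting pairs by the chain length:
CO = Σᵢ Sᵢ / (L·N).

## Synthetic study conditions

Real benchmarks need curated classifications of experimental
structures; the synthetic generator reproduces the *statistical shape*
of that setting so the full pipeline runs from nothing. Defaults,
chosen once: 2 classes × 2 folds × 2 superfamilies × 2 families × 6
members (16 families, 96 domains, so every query has TPs at all three
levels), chain lengths 40–100 residues. Fold templates are independent
persistent self-avoiding walks with the 3.8 Å consecutive-Cα spacing of
real backbones and a 3.0 Å excluded-volume threshold; helix and strand
template styles with ideal α-helix (2.3 Å radius, 1.5 Å rise, 100°
twist) and extended-zigzag geometry are available. Superfamily
templates perturb the fold template by 2.0 Å i.i.d. Gaussian noise,
family templates perturb superfamily templates by 1.5 Å, and members
add 0.5 Å noise, giving within-family RMSD ≈ 0.5·√6 ≈ 1.2 Å, well
separated (> 3×) from between-family spread — the separability the
contrastive objective assumes.

What the generator does **not** emulate: real secondary-structure
statistics, side chains, sequence signal of any kind, length variation
within a fold, domain discontinuity frequencies, or the long-tailed
family-size distribution of curated classifications. Tests passing on
these conditions therefore demonstrate correctness of the machinery
and recoverability of a planted hierarchy, not retrieval accuracy on
experimental structure databases, which requires the full-scale
training protocol (500 epochs over thousands of families, about a week
on a GPU) and curated data.

## Scaled-down run sizes

The bundled verification runs use deliberately small problem sizes,
chosen as the smallest sets that still exercise every code path: the
training/benchmark run uses the default 96-domain hierarchy, a model
with hidden width 32, embedding width 32, edge MLP 64 → 32, and 30
epochs at learning rate 1e-3 (the published 5e-5 suits millions of
steps; a ~500-step run needs a proportionally larger step). On these
conditions the trained model reaches mean family sensitivity 1.0 with
every self-hit at rank 1, versus ≈ 0.5–0.6 for a random-weight model.

## Numerical notes and limitations

* Features and model run in float64; SE(3)-invariance of the embedding
  holds to ~1e-15 under random rigid motions. The sin/cos τ columns are
  continuous functions of rotated floating-point coordinates and so are
  reproduced to ~1e-12 rather than bit-identically; all discrete-origin
  feature columns and the edge list are bit-identical.
* Degenerate inputs: single-residue domains embed (both terminus flags
  set, no edges); zero-edge graphs aggregate a zero message; chains
  with no contacts get contact order 0 with a warning; domains outside
  the 20–500 residue training band warn but still embed and search.
* An anchor family must have ≥ 2 members and a training set ≥ 6
  families, or batch construction fails by contract.
* The model is domain-level: multi-domain chains should be split before
  searching (the CLI exposes a hook for an external splitter); there is
  no structural alignment output.
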