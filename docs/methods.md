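# Methods note

This note records the model implemented by `loopclust`, the assumptions
and parameter choices baked into it, and its limitations. Nothing here is
an empirical claim beyond what the test suite and the worked example in
the README actually compute.

## 1. Loop model

A loop is identified by a location string
`PDBID_CHAIN:start1-end1[_start2-end2...]` (one segment = hairpin, two =
internal loop, more = multiloop). Each nucleotide carries a residue
number, a base identity (A/C/G/U; anything else is treated as
"other" and encodes as an all-zero one-hot), and up to six backbone atom
coordinates (C3', C4', C5', O3', O5', P). Base-pair annotations use the
18 directional Leontis–Westhof classes (`cWW … tSS`); reversing a pair's
direction swaps its edge letters (`cWH` ↔ `cHW`). Stacking annotations
use four orientations; reversal maps upward ↔ downward and leaves
inward/outward fixed.

## 2. Graph encoding

Each loop of N nucleotides becomes a complete directed graph: N nodes
with 4-dim one-hot features and N(N−1) edges with 23-dim features
`[distance, 18 LW one-hot, 4 stacking one-hot]`. Distances default to
Euclidean distance between nucleotide centers (mean of available backbone
atoms); a `kabsch_backbone` mode instead uses per-pair Kabsch RMSD over
the common backbone atom set. Duplicate identical annotations collapse;
two different classes on the same ordered edge are an error.

## 3. Embedding model

A 3-layer GIN classifier. Layer update on the complete digraph:

    h_v' = MLP( (1+ε)·h_v + Σ_{u≠v} (h_u + P·e_uv) )

with ε = 0 (optionally learnable), a per-layer linear projection P of the
23-dim edge feature added to the neighbour message (`project_add` mode;
`ignore` gives the plain sum-aggregation update), and MLP = Linear →
LeakyReLU(α = 0.01) → Linear with hidden width 128. Readout: per-layer
node mean, summed over layers, LeakyReLU, linear projection to the
128-dim embedding; a softmax head over families is trained with
categorical cross-entropy.

Implementation is pure NumPy: graphs are padded into batch tensors with
masks, and the in-neighbour aggregation uses the identity
Σ_{u≠v}(h_u + P·e_uv) = (colsum(H) − h_v) + Ein_v·P, where Ein_v is the
precomputed column sum of incoming edge features — O(N·d) per graph
instead of O(N²·d). Gradients are hand-derived and verified against
central finite differences in the test suite. Optimization: Adam
(lr 1e-3, β = 0.9/0.999), batch size 32, 200 epochs, stratified 80/10/10
split. The checkpoint with the highest validation accuracy is retained;
**ties are broken by the latest such epoch**. This matters: validation
accuracy typically saturates early while the embedding geometry keeps
tightening, and keeping the earliest saturated epoch yields visibly less
separable embeddings.

All randomness (initialization, batching, splits) flows from a single
seed, so training is bit-deterministic.

## 4. Two-stage clustering

Stage 1: seeded K-means (`n_init=10`). K is chosen by sweeping a
candidate grid — every K from 2 to 10 plus a geometric tail up to n/4 —
and, among candidates whose Single Motif Cluster Ratio (fraction of
singleton clusters) is below 5%, taking the highest silhouette, ties
broken by lower Davies–Bouldin index, then smaller K. The dense low-K
range is deliberate: silhouette landscapes are sharp at small K and a
purely geometric grid can skip the true family count. If no candidate
meets the SMCR constraint the minimum-SMCR candidate is returned, flagged
`constraint_met=False`.

Stage 2: each K-means cluster is refined independently with
agglomerative clustering (average linkage, Euclidean metric) cut at
distance threshold 6.0 in embedding space. Tight clusters stay whole;
heterogeneous ones split into subclusters.

## 5. Q-score

Each subcluster i is summarized by averages over all C(M,2) member pairs
under two backends — an interaction alignment (greedy matching of
base pairs with equal LW class; score = 2·matched pairs + 0.5·matched
stackings; RMSD over matched-pair nucleotide centers) and a structure
alignment (sequence-order center superposition; score =
mean 1/(1+(d/d₀)²) with d₀ = 4 Å). With maxima over all subclusters:

    SXQ_i = SXsc_i/SXsc_max + SXal_i/SXal_max + M_i/M_max − SXd_i/SXd_max
    TMQ_i analogous;  Q_i = (SXQ_i + TMQ_i)/2

Any ratio with a zero maximum contributes 0. Singletons get zeroed
statistics and a flag. An external backend reads per-pair
score/RMSD/length values from a TSV, so outputs of dedicated alignment
tools can replace the internal backends without code changes.

## 6. Evaluation

Subclusters map to families either by strict majority (> 0.60 of
labelled members, else "unassigned") or by one-to-one Hungarian
assignment maximizing member overlap. From the induced per-loop
predictions: per-family precision/recall/F1 (unassigned counts as an
error), weighted averages, accuracy, confusion matrix, ARI/AMI against
the family partition, per-family Motif Clustering Accuracy (fraction of
a family's known loops landing in that family's subclusters), and a
purity analysis (fraction of multi-member subclusters whose mean
pairwise RMSD stays below a mean + 2 SD bound from known-family pairs).

## 7. Synthetic generator (and its realism limits)

Eight built-in family templates (SR, KT, TS, HT, EL, CL internal; TL, GL
hairpin) each combine a distinct base-pair/stacking signature with a
distinct parametric backbone: per-strand helices (rise 2.2–3.6 Å, twist
0.40–1.30 rad, radius 3.0–5.0 Å), antiparallel second strand at a 9 Å
gap, optional kink. Six backbone atoms sit at fixed zero-mean offsets
around each nucleotide center. Sampling adds isotropic Gaussian jitter
per nucleotide (default σ = 0.3 Å; atoms of a nucleotide move rigidly)
and drop/flip noise on the base-pair pattern (default 5%/5%).

These are geometric stand-ins, **not** physical RNA: no ribose/phosphate
stereochemistry, no sequence realism, no correlated backbone noise, and
inter-family separation (center-RMSD well above the jitter scale) is far
cleaner than in real corpora. The generator's job is to exercise every
code path deterministically and to give the pipeline a recoverable
ground truth; perfect scores on it are a correctness check, not a
performance claim about real structures. Generator defaults are study
conditions and are never tuned against pipeline outcomes.

## 8. Numerical choices

- Kabsch superposition via SVD with determinant-sign correction
  (proper rotations only); verified against an independent
  Wahba-problem solver (`scipy Rotation.align_vectors`).
- Softmax/cross-entropy computed with max-shift and a 1e-12 floor.
- K-means/agglomerative/silhouette/DBI/ARI/AMI/Hungarian come from
  scikit-learn and scipy rather than re-implementations.
- Deterministic RNG streams: `default_rng([noise_seed, instance_seed])`
  per sampled loop, a single seeded generator per training run.
- Zero-max Q-score ratios define 0/0 = 0; majority threshold is strict
  (exactly 0.60 does not assign).

## 9. Limitations

- The GIN is NumPy-based and CPU-bound; it is comfortable at
  hundreds-to-thousands of loops but not at large-corpus scale, and has
  no GPU path.
- Complete-digraph message passing costs O(N²) edge features per loop;
  fine for loops (N ≲ 30), wasteful for long chains.
- The internal alignment backends are deliberately lightweight (greedy
  pair matching, sequence-order superposition); for publication-grade
  Q-scores plug in external alignment tools via the pair-table backend.
- Loop extraction from full structures (secondary-structure parsing,
  helix detection) is out of scope; loops enter through the documented
  loop-file dialect plus coordinates (TSV or PDB/mmCIF).
- Reported perfect recovery numbers apply to the synthetic corpus at the
  problem sizes actually run here (6 families × 50 loops; selector grids
  2–10 plus geometric tail) and do not transfer to real corpora.
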