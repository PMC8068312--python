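# Methods

## The model

`phytonet` analyses a **tripartite network** of medicinal plants, chemicals,
and protein targets. Nodes fall into three disjoint layers; edges are
unweighted and exist only between a plant and a chemical (the chemical is a
constituent of the plant) or between a chemical and a target (the chemical
is predicted active on the target). Plants and targets never touch
directly: every plant–target relationship is mediated by shared chemistry.
Throughout, `w_mn ∈ {0,1}` is the adjacency indicator, `d_m` a node degree,
and `E` the total edge count.

A chemical–target *interaction* is declared when the activity-prediction
probability exceeds a cut-off `p_min`, default 0.9, with a **strict**
inequality: a prediction at exactly 0.9 is discarded. Duplicate
(chemical, target) prediction rows collapse to the maximum probability
before thresholding — the most permissive reading consistent with declaring
an interaction whenever *some* prediction clears the bar.

### Preprocessing cascade

Five stages, each closed by a report of per-layer node counts, per-relation
edge counts, and the multipartite density

    density = E / (Np·Nc + Nc·Nt),

the realized edge count over the number of edges the layer constraint
permits:

1. **raw** — every record and every (unthresholded) prediction;
2. **non-plant filter** — minerals and animals are removed, fungi kept;
   detection is driven by the explicit `category` column, because the
   manual curation behind such labels cannot be replicated by name
   heuristics;
3. **deduplication** — records identical on (scientific name, Latin name,
   use target) collapse to the *first* occurrence in file order (a
   deterministic choice); the removed duplicates' plant–chemical edges are
   unioned into the survivor, so information is merged, not dropped;
4. **probability threshold** — strict `> p_min`; targets left with no
   surviving prediction leave the network at this stage, while the chemical
   registry is carried forward (a chemical stripped of its edges lingers,
   deliberately, until the next stage);
5. **pruning** — degree-zero nodes of every layer are removed. Pruning
   removes nodes only; one pass suffices since deleting an unconnected node
   deletes no edges.

The cascade is idempotent and node/edge counts are non-increasing across
stages — both are asserted as properties in the test suite.

### Spectral co-clustering and model selection

Since plants and targets both attach only to chemicals, the whole graph is
bipartite between rows = plants ∪ targets and columns = chemicals. That
incidence orientation is this package's design choice: it keeps the two
"outer" layers in a single row space so that a row cluster and the column
cluster with the same index jointly form one plant–chemical–target
subnetwork.

Partitioning uses bipartite spectral graph partitioning in Dhillon's
formulation (degree-normalized incidence, truncated SVD, joint row/column
embedding, k-means with 10 restarts), via scikit-learn's
`SpectralCoclustering`. All randomness (SVD initialization and k-means
restarts) is driven by one seed, so a fixed seed gives a reproducible
partition. `k = 1` short-circuits to the trivial partition. `k` may not
exceed the number of nonzero incidence rows/columns, and co-clustering
refuses networks with degree-zero nodes (run pruning first).

Partition quality:

* **normalized cut** `(1/k) Σ_i cut(V_i, V̄_i)/vol(V_i)` — the quantity the
  spectral method approximately minimizes; 0 exactly when no edge crosses
  clusters. Zero-volume clusters contribute 0 with a logged warning rather
  than dividing by zero.
* **modularity** `(1/2E) Σ_i Σ_{m,n∈V_i} (w_mn − d_m d_n/2E)`, the Newman
  form with the double sum over *ordered* pairs including the diagonal.
  This convention makes the one-cluster partition score exactly 0 — used as
  a sanity identity in the tests — and gives the closed form
  `Σ_i [E_in,i/E − (vol_i/2E)²]` used by the implementation; an exhaustive
  pair-sum oracle checks it to 1e−12 on small random graphs.

The number of clusters is chosen by scanning k (default 2–20) and taking
the modularity maximum, ties broken toward smaller k (parsimony).

### Plant dendrogram

Each plant is its binary chemical profile; pairwise distances are
Bray–Curtis,

    d(u, v) = |profile symmetric difference| / (deg u + deg v)
            = 1 − Dice similarity,

computed with scipy's `pdist(braycurtis)` on the dense indicator matrix and
cross-checked in the tests against the independent set-arithmetic form. The
metric is scale-free (chemicals connected to neither plant cancel out —
padding the chemical universe never changes a distance) and bounded in
[0, 1], with `d < 1` iff the plants share a chemical. Two empty profiles
would give 0/0; this cannot arise after pruning and raises otherwise.

Agglomeration is complete linkage (cluster distance = farthest pair), so
cutting the tree at height `h_max ≤ 1` yields clusters in which *every*
within-cluster plant pair shares at least one chemical — the
shared-chemical guarantee, exhaustively verified on random networks in the
tests. The default cut is `1 − 1e−9`, the largest cut preserving the
guarantee; it is exposed as a flag. The cut is strict (`merge height <
h_max`), except that merges at height exactly 0 — identical profiles, e.g.
the same species catalogued with different used parts — are always applied,
so even `h_max = 0` aggregates exact duplicates at the bottom level.
Leaves are sorted lexicographically before agglomeration and scipy's
deterministic nearest-neighbor-chain algorithm does the merging, so trees
are bitwise reproducible for a given distance matrix; residual tie-breaks
among exactly equal distances follow scipy's index order over the sorted
leaves rather than an explicit lexicographic-pair rule, a simplification
that affects none of the package's guarantees.

### Target Potency Score

For a plant cluster P and target T,

    TPS(P, T) = |C_P ∩ C_T| / |C_T|,

with C_P the union of the cluster's chemical profiles and C_T the target's
chemical set. TPS ∈ [0, 1]; it is 1 iff C_T ⊆ C_P, 0 iff the overlap is
empty, and monotone non-decreasing as plants are added to P — which is why
cluster retrieval evaluates the fixed clusters from the dendrogram cut, not
nested supersets, and why ties in `best_cluster_for_target` break toward
the *smaller* cluster. When ranking targets for a cluster, targets with
|C_T| below a reliability floor (default 20 chemicals) are excluded before
the TPS threshold is applied; small denominators make the fraction noisy.
There is no single canonical TPS threshold — practical screens use values
from 0.05 to 0.5 depending on how permissive a shortlist is wanted — so
`tps_min` is a required argument rather than a default. TPS is a
connectivity fraction and nothing more; it carries no pharmacological
effect size.

## Synthetic data: what it emulates, and what it does not

The generator emits the same four tables a real analysis would start from
(plants, plant–chemical edges, predictions, chemical classifications),
with planted structure and an exact ground-truth record:

* **5 planted blocks of 20 plants**, each with a disjoint 40-chemical
  profile; a block plant carries each profile chemical with probability
  0.5 and other blocks' chemicals with probability 0.02 (the separation
  the co-clustering recovery properties are stated at);
* **one designated target per block**, predicted active on the block's
  profile with probability drawn from `0.95 + 0.05·Beta(2,2)`, plus ten
  decoy targets whose predictions come from `0.8·Beta(2,2)`. The supports
  are disjoint around the 0.9 cut, so "every designated edge survives the
  threshold and every decoy edge is removed" holds exactly by
  construction, not just with high probability;
* **50 background chemicals** with plant-degrees drawn from a discrete
  power law (exponent 2.5, capped at half the plant count), echoing the
  heavy-tailed degree spread of real plant–chemical networks, plus one
  ubiquitous chemical connected to ~60% of plants across blocks — a
  β-sitosterol-like compound that blurs family-level clustering the way
  widely shared phytosterols do in real data (complete linkage keeps the
  blocks separate regardless, because *some* cross-block pair always has
  distance 1);
* **preprocessing fodder**: 5 mineral/animal decoy records with edges, 5%
  duplicated records carrying a random half of their source's edges, and
  2 edgeless records.

Sizes were chosen as the smallest network at which the five blocks are
unambiguous to the spectral method yet the whole 20-seed recovery study
runs in seconds; they are roughly 1/10 the plant count of a national
medicinal-plant inventory and keep the same order-of-magnitude sparsity.

What the generator does **not** emulate: correlated chemistry between
blocks (real plant families share biosynthetic pathways), annotation noise,
probability calibration error in the activity model, and the long tail of
plants with a single catalogued chemical. Passing recovery tests therefore
show that the pipeline's machinery is correct and well-conditioned at a
realistic sparsity — not that five clean clusters exist in any real
inventory.

## Numerical choices and degenerate inputs

* Density with a zero denominator (no chemicals, or no plants and no
  targets) reports 0 with a warning.
* Modularity on an edgeless network raises; normalized cut of a
  zero-volume cluster contributes 0 with a warning.
* Degree assortativity is the Pearson correlation of endpoint degrees over
  edges; with zero degree variance (e.g. a single edge) it is reported as
  an explicit undefined marker (`None`/null), never an exception.
* The bipartite clustering coefficient of node u averages
  `|N(u)∩N(v)|/|N(u)∪N(v)|` over u's second neighbors v (networkx's
  `bipartite.clustering`, dot mode); nodes without second neighbors score
  0; the network value is the mean over all nodes.
* Empty TPS rankings are legitimate results; an unknown target or a target
  with empty C_T is an error.
* All pipeline randomness flows from one root seed recorded in the output
  manifest; rerunning a config reproduces identical content hashes.

## Known limitations

* The incidence orientation (targets sharing the row space with plants) is
  one reasonable adaptation of bipartite co-clustering to the tripartite
  case; alternatives (e.g. clustering the plant–chemical and
  chemical–target bipartite graphs separately) would weight the small
  target layer differently.
* Power-law fidelity of the generated degree distributions is not asserted
  — the generator aims at a heavy tail, not at a calibrated exponent.
* Chemical classification labels are consumed as given; no ontology
  reasoning, synonym resolution, or structure handling is attempted.
* `select_k` refits the spectral embedding per k; for networks orders of
  magnitude larger than the defaults, caching the SVD across k would be
  the first optimization.
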