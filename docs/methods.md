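# Methods

## Problem setting

The package infers *temporal phenotypes* — recurring disease-progression
patterns — from encounter-level clinical tables whose temporal structure is
deliberately not used for model building. Each row is one encounter:
subject id, days since the subject's first visit, a binary stage label
(1 = complication present; the motivating label is microvascular
complication in type 2 diabetes) and a fixed-order feature vector. Time
and label enter only to *orient* structures discovered from the features
(trajectory roots, pseudo-time endpoints), which is what lets the method
run on cross-sectional data.

## Mapper topology

Features are min-max normalized to [−1, +1] per feature
(`x' = 2(x − min)/(max − min) − 1`); binary features land on {−1, +1} and
constant features pass through at 0. The Mapper construction then:

1. computes a pairwise distance matrix (cosine by default; Euclidean in
   benchmark mode);
2. projects rows through two lenses — by default the projection onto the
   first right singular vector of the column-centred feature matrix (sign
   fixed so the vector's largest-magnitude component is positive) and
   L∞-centrality, the distance to the farthest point; benchmark mode uses
   the two observed variables directly;
3. covers the lens plane with `n²` closed rectangles. Per dimension the
   interval length is `ℓ = R/(n − (n−1)g)` with step `ℓ(1−g)` over the lens
   range `R`, so adjacent intervals overlap by exactly the gain fraction
   `g` and their union is exactly the range. A boundary point belongs to
   both bins, which preserves connectivity;
4. clusters each bin's rows by single linkage. The default cut is the
   canonical histogram-gap heuristic: merge heights are histogrammed into
   `clusters_per_bin` bins up to the bin diameter and the dendrogram is cut
   at the first empty histogram bin, so the cluster count adapts to the
   data (a dense blob stays whole). A fixed-count variant (`cluster_bin`,
   exactly `min(k, |bin|)` clusters) is provided; it is not the default
   because forcing extra clusters shaves distribution tails into singleton
   satellite components, which makes fully connected topologies — the
   first selection criterion of the validation study — unattainable;
5. links clusters sharing rows; the edge payload is the member-set
   intersection. Clusters whose member set is wholly contained in another
   cluster's are pruned by default (`prune_nested`): rectangular covers
   slice the margins of dense regions into such nested clusters, which add
   nothing to the cover's union and would dangle off the spanning tree as
   spurious dead-end leaves.

Node attributes (mean encounter time, majority hidden state, community)
are aggregated over member rows; majority ties break toward the smaller
value. All tie-breaks in the package are deterministic so identical
configurations give byte-identical outputs.

## Communities, trajectories, assignment

Communities maximize unweighted Newman modularity. Graphs with ≤ 10 nodes
are solved exactly by enumerating all set partitions (the Bell number
B(10) ≈ 1.2 × 10⁵ keeps this near-instant; beyond ~12 nodes enumeration is
infeasible). Larger graphs use a deterministic greedy portfolio —
Clauset–Newman–Moore, Louvain (fixed seed), and all-singletons starts,
each refined by single-node moves, community merges and a merge-then-refine
lookahead — and the result is flagged approximate. The exact branch doubles
as the oracle for the greedy one in the tests.

Trajectories come from a minimum spanning tree (Kruskal, ties broken by
(weight, min id, max id)) over the topology, weighted either by the mean
encounter time of each edge's shared rows (cohort mode: time orients the
tree along follow-up) or by node-index distance |u − v| (benchmark mode:
ids follow the bin traversal, so index distance reflects topological
proximity). The root is the cluster accounting for the first observations:
the node holding the most rows at the dataset's earliest time value,
restricted to tree leaves when the tree is available, because the origin of
root-to-leaf paths should itself be an extremity — the naive
minimal-mean-time rule can select a tiny node of early-but-late-stage rows.
One trajectory per leaf (root-to-leaf tree path); mined trajectories are
grouped automatically by their terminal node's community.

Each subject's encounters are mapped to nodes (an encounter in several
overlapping nodes goes to the node whose other members are closest on
average), ordered by time, and compressed (consecutive duplicates
collapsed). Assignment is to the mined trajectory maximizing set-Jaccard
similarity, ties toward the lowest index.

## Pseudo-time-series and the ARHMM

One bootstrap iteration draws `sample_size` rows uniformly without
replacement (default min(200, n): small enough that the complete-graph MST
stays cheap, large enough to span both label classes), builds the complete
cosine-distance graph, takes its MST, and returns the unique tree path
from a uniformly chosen label-0 row to a uniformly chosen label-1 row.
Draws missing a label class are retried (bounded), failing iterations are
skipped and counted, and the ensemble (default B = 1000) is reproducible
from a base seed (iteration i uses seed base + i).

The state-space model is an order-1 autoregressive Gaussian HMM: hidden
chain (π, A); first observation of a sequence `x₁ | z₁=k ~ N(μ_k, diag σ²₀ₖ)`;
then `x_t | z_t=k, x_{t−1} ~ N(c_k + Φ_k x_{t−1}, diag σ²ₖ)`. Inference is
the scaled forward–backward recursion (exact on a chain). EM uses
closed-form M-steps — responsibility-weighted least squares for (c_k, Φ_k)
with a 1e-10 ridge, weighted moments for the rest, variance floor 1e-8 —
with k-means-initialized restarts (uniform π, A = 0.8 I + 0.2/K; default 5
restarts), discarding restarts that starve a state of responsibility mass,
and relabelling states by ascending first emission-mean component for
identifiability. Viterbi decoding breaks ties toward the lower state.
K defaults to 5 but is a free parameter; no model selection over K is
attempted.

## Synthetic generators

**Benchmark.** 750 sequences × 10 steps = 7,500 observations of (X, Y)
from a 5-state ARHMM with the hand-coded transition matrix

| from\to | 1 | 2 | 3 | 4 | 5 |
|---|---|---|---|---|---|
| 1 | .80 | .05 | .05 | .05 | .05 |
| 2 | .10 | .80 | 0 | .10 | 0 |
| 3 | .10 | 0 | .80 | 0 | .10 |
| 4 | 0 | 0 | 0 | 1 | 0 |
| 5 | 0 | 0 | 0 | 0 | 1 |

Every sequence starts in state 1; states 4 and 5 are absorbing. Many
short sequences (rather than one long chain) keep the state distribution
mixed despite absorption. The emission parameters are hand-coded — like
the transitions — to realize a clean progression from state 1 to the two
endpoints: state means trace an axis-aligned "L" in the (X, Y) plane
((0,0), (5,0), (0,5), (10,0), (0,10)); each state's AR matrix has long
memory (0.7) along its arm and short memory (0.15) across it, with noise
variance 0.25 along / 0.04 across (state 1: 0.6 isotropic memory, 0.04
noise). The long along-arm memory fills the corridors between state blobs
with transition observations, so the data form a connected V-shaped
filament; short transverse memory and small transverse noise keep the
arms thin and suppress diagonal cross-arm strays. Axis alignment matters:
a rectangular lens cover slices diagonal filaments into stair-step
fragments with spurious dead-end nodes, whereas the Mapper graph of an
axis-aligned filament is a clean path from tip 4 through the state-1 elbow
to tip 5. All of these are ordinary `BenchmarkSpec` parameters.

**Cohort.** Subjects accrue 2 + Poisson-distributed encounters
(~14.7 mean) at irregular 120–420-day gaps (follow-up up to ~4,000 days).
Seven features (age, smoking, HbA1c, BMI, SBP, total cholesterol,
triglycerides) start at clinically plausible baselines and drift along a
latent progression score `severity × t/4000`; 60 % of subjects develop the
complication at a random onset in (0.3, 0.9) of their follow-up, after
which the label stays 1, and progressing subjects drift faster — so label
prevalence rises with follow-up time from zero at baseline. What the
generator does **not** emulate: missing data, measurement batch effects,
treatment feedback, informative visit schedules, or label noise — so
passing tests demonstrate the machinery's correctness and the method's
behaviour under its own assumptions, not robustness to real EHR artifacts.

## Validation study

The benchmark topology is selected by grid search (resolutions 5–8, gains
0.4–0.6, geometric scale 6–10; Euclidean metric, raw X/Y lenses) under
three criteria: fully connected network; per-node hidden-state incidence
distribution correlating (Pearson) with the data's state distribution;
average shortest-path length near the state count. Ranking is by
correlation, descending. Resolutions above 8 are excluded by default
because the cover's rows become thinner than the emission filament and
slice artifacts reappear; 5–8 brackets the stable regime. The headline
end-to-end property — asserted over three seeds — is that the top-ranked
topology's MST trajectories all start at a majority-state-1 node and
terminate at majority-state-4 or -5 nodes, i.e. the hidden progression is
recovered from shape alone.

## Numerical and scale choices

- Exhaustive modularity only to 10 nodes; greedy beyond (flagged).
- Variance floors (1e-8) and a 1e-10 least-squares ridge keep EM stable;
  the log-likelihood trace is monotone to 1e-8.
- Test and acceptance runs use scaled-down problem sizes chosen as
  representative: 50–120-subject cohorts (the generator's default remains
  924), 200-sequence EM recovery, a 16-point acceptance grid over three
  seeds. The full 36-point default grid runs in ~25 s per seed.
- Degenerate inputs are defined, not errors: empty bins yield no clusters,
  an edgeless graph gets singleton communities with Q = 0, a single-node
  tree yields one length-1 trajectory, constant features normalize to 0.

## Known limitations

- The Mapper graph depends on cover geometry; only rectangle covers over
  two lenses are implemented.
- Greedy modularity carries no optimality guarantee above 10 nodes.
- The ARHMM assumes diagonal Gaussian noise and AR order 1; K is fixed by
  the user.
- Pseudo-time endpoints use a single binary stage label; no severity
  weighting of start/end selection.
- Subjects whose encounters all fall outside the lens cover (impossible
  with the default closed cover, possible when applying a trained
  normalization to out-of-range data) are dropped with a warning.
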