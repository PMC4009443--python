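# Methods

This note records the models, the defaults and their rationale, the
numerical choices, and what the synthetic benchmark does and does not
establish.

## Synthetic study design

The generator emulates a single-group resting-state experiment at desk
scale: 18 subjects, 196 volumes at TR = 3 s, 25 network nodes plus 6
designated noise regions.  The 25 nodes comprise three positive modules
of sizes 6/5/5 (within-module correlation target 0.5, between-module
0.1) and a 9-node block anticorrelated with all positive nodes (target
−0.3).  The first node is a *bridge*: its correlation with every
positive node outside its own module is raised to 0.35, planting a
high-degree, high-betweenness connector whose recovery the tests check.
Within the anticorrelated block nodes correlate at the within-module
level, matching the empirical observation that anticorrelated regions
are positively coupled among themselves.

Per subject, the group target matrix receives symmetric Gaussian jitter
(sd 0.05), is repaired to the nearest positive semi-definite correlation
matrix (eigenvalue floor 1e−8, diagonal rescaled; a repair that moves
any entry beyond a tolerance of 0.1 is an error naming the worst entry),
and is imposed by the symmetric matrix square root on independent
Gaussian series whose spectrum is confined to the 0.008–0.08 Hz band by
hard masking of the real FFT.  The mask normalization keeps unit
expected variance, so empirical correlations converge to the targets;
at 20 000 time points the maximum deviation is below 0.05.  The
anticorrelated block is specified directly as negative pairwise targets
rather than through a latent factor with negative loadings: at the
default levels the direct target matrix is already comfortably PSD
(minimum eigenvalue ≈ 0.18), so the extra construction would buy
nothing.

Nuisance consists of a node-specific linear drift (slope scale 0.5 in
signal units per scan) and a per-subject physiological source — a
unit-variance sinusoid at 0.03 Hz plus 10% broadband noise — loaded on
every node (loadings uniform in 0.5–1.5 times the amplitude, default
0.5) and three times more strongly on the noise regions, which carry
almost no neural signal (scale 0.05).  The amplitude ratio of neural to
physiological signal is not an empirically constrained quantity; the
defaults are chosen so that cleaning is demonstrably necessary (raising
the amplitude to 3 drives node–source correlations above 0.9) and
demonstrably sufficient (residual correlations ≈ 0.01).

What the generator does *not* emulate: hemodynamic convolution, scanner
noise physics, head motion, slice timing, spatial autocorrelation of
voxels within a region.  Passing tests therefore show that the
*statistical machinery* recovers planted covariance structure under
realistic sample sizes and band-limited autocorrelation — not that any
particular preprocessing choice is optimal for real scanner data.

## Preprocessing

Band-pass filtering is zero-phase: a 4th-order Butterworth applied
forward and backward (the effective amplitude response is the squared
magnitude), so correlations are not distorted by phase lag.  At TR 3 s
this passes 0.04 Hz within 0.1%, and attenuates 0.004 Hz and the alias
of 0.2 Hz by more than 99%.  A linear-phase FIR realization (Hamming
window) is selectable.  Filtering is idempotent for signals in the
passband interior; content at the band edges is re-attenuated on every
pass, which is inherent to any finite-order filter.

Nuisance correction is CompCor-style: noise-region signals are
detrended (default polynomial order 1), z-scored, and their top
principal components (default 5, requiring at least 5 noise signals)
are regressed out of every node signal together with the trend basis.
Component signs follow a deterministic convention (largest-magnitude
loading positive).  The default stage order is nuisance regression
before filtering, so regression cannot re-introduce stop-band energy;
the reverse order is available behind a flag since the original
ordering convention is not fixed by common practice.

The Fisher transform `z = arctanh r` is used throughout; degenerate
correlations |r| ≥ 1 (which occur on noiseless toys) raise unless a
clipping flag maps them to ±(1 − 1e−7).

## Seed correlation analysis

Seed signals are means over all units within a spherical region (radius
default 4 mm); geometry is a table of unit positions in mm, which
covers both node tables and regular voxel grids.  Per-subject maps are
Pearson correlations Fisher-transformed; zero-variance units become
flagged missing values.  Group inference is a one-sample t-test of the
per-subject z values against zero — for a one-group design this has the
same null behaviour as the heavier covariance-component machinery of
the big toolboxes, with far less machinery.  Height thresholds use
Benjamini–Hochberg FDR (default q = 0.01) or a raw p cutoff; cluster
extent uses either a fixed minimum size or a sign-flip permutation null
of the maximum cluster size (default, 999 permutations, p = 0.01).  The
permutation flips per-unit *demeaned* maps: flipping raw maps that
carry a strong common effect in many units would inflate the null
cluster sizes and swallow genuine clusters, whereas demeaning estimates
the noise-only cluster-size distribution.
Connectivity for clustering is distance-based: units within a link
radius (default 15 mm, chosen so that nodes of one synthetic module
form a connected cloud while module centres 60 mm apart stay separate)
are neighbours; on a voxel grid a radius of √3 times the voxel size
reproduces 26-connectivity.  Cluster peaks are maximum-|t| units, ties
broken by lexicographically smallest coordinate for determinism.
Cluster peaks become spherical network nodes; a node whose sphere
contains an original seed centre is replaced by the seed(s).

Talairach↔MNI conversion uses the standard piecewise-linear transform
(two published 3×3 matrices above/below the AC plane).  The inverse
direction selects its branch self-consistently — each inverse matrix is
tried and the branch whose output z sign matches is kept, above-AC
winning ties — giving round-trip identity to 1e−9 mm over the sampled
coordinate range.

## Network construction and threshold selection

The group adjacency is the subject-mean (median selectable) of the
per-subject Fisher-z correlation matrices, diagonal zero.  Thresholded
graphs keep edges with weight ≥ τ over the grid 0.20–0.27 in steps of
0.01.  Three criteria are evaluated at every τ: (a) full connectivity,
read literally as minimum degree ≥ 1, with the stricter single-component
reading reported alongside; (b) small-worldness — global efficiency
ratio vs degree-preserving rewirings ≥ γ_g (default 0.8) and local
efficiency ratio ≥ γ_l (default 1.5); (c) wiring cost (edge density)
≤ 0.5, with cost efficiency = global efficiency − cost reported.  The
"equivalent random network" is a degree-sequence-preserving edge-swap
randomization (100·|E| attempted swaps, seeded), not an Erdős–Rényi
graph, so the comparison is not confounded by the degree distribution.

The selected range is the maximal contiguous run of thresholds passing
(a) and (c); criterion (b) is treated as a soft preference — if any
admissible threshold also passes the small-world flag the run is
restricted to flagged thresholds, otherwise the relaxation is logged.
Rationale: on small dense networks (16 nodes at density ≈ 0.4) rewired
graphs retain local efficiency ≈ 0.75, so no threshold can reach a 1.5
ratio even for a strongly modular graph; a hard small-world gate would
make the criterion vacuous exactly where the analysis is meant to run.
The γ cutoffs quantify "approximates" and "clearly surpasses", which
are otherwise untestable; both are configurable and recorded in the
report.

## Graph metrics and hubs

All metrics are computed on the binarized suprathreshold graph (the
modularity objective is the only consumer of weights): binary degree,
normalized betweenness (division by (n−1)(n−2)/2), characteristic path
length as the mean over connected ordered pairs with the unreachable
count reported, global/nodal efficiency with 1/∞ = 0, local efficiency
as the global efficiency of each neighbour subgraph, and triangle-based
clustering.  This matches the scale of typical reported values (e.g.
mean degrees of 5–7 on 16 nodes).  Hub classification uses the sample
standard deviation (n−1): a hub must exceed mean + 1 sd in *both*
degree and betweenness, with a strict ">" against the mean so that
zero-variance regular graphs yield no hubs rather than all hubs.
Threshold-averaged summaries report, per metric, an "above mean" tier
and a "≥ mean + 1 sd" tier.

## Signed modularity, consensus, null models

Q* is implemented exactly as the asymmetric combination of the positive
and negative modularity terms; with no negative weights it equals
standard Newman–Girvan weighted modularity (cross-checked against an
independent implementation to 1e−12).  The Louvain optimizer alternates
greedy single-node moves with module aggregation (self-loops carry
internal weight through levels); vacated label slots remain available
so nodes can split off, and a finest-level refinement pass runs after
the hierarchy converges.  Each "run" takes the best of 4 random-order
restarts: single-start greedy ascent lands in a dominant suboptimal
basin on a noticeable fraction of dense random signed matrices, and the
consensus rule (below) amplifies the dominant basin, not the best one.
With restarts, consensus attains the exhaustive-search optimum on 99 of
100 random signed test matrices with n ≤ 8 and never exceeds it.

Consensus repeats the optimizer (default 100 runs) with seeds derived
from one master seed, canonicalizes labels (modules numbered by
smallest member), and keeps the most frequent partition; ties break by
higher Q*, then lexicographic order.  The co-assignment frequency
matrix is reported, and a post-hoc rule flags nodes as "unassigned"
when their consensus module has fewer than 2 members or their
co-assignment with every module peer is below 50% — an explicit,
testable stand-in for the reporting category of nodes that belong to no
stable module.

Null networks randomize topology by double edge swaps performed within
the positive and within the negative edge sets.  Swaps are
collision-aware: a move whose target pair already carries an edge of
either sign is rejected, so the two edge sets stay disjoint and node
count, signed edge counts, signed degree sequences, and each sign's
weight multiset are preserved exactly.  Weights are then placed on the
rewired edges in random order within each sign (default).  A
rank-matching variant that sorts weights onto edges by the product of
original endpoint strengths is available, but it is *not* the default:
concentrating large weights on high-strength pairs systematically
lowers the attainable null Q*, which made the significance test reject
essentially every structureless input in calibration experiments,
whereas random placement leaves an i.i.d.-weight network exchangeable
with its nulls (measured rejection rate ≈ 3–7% at nominal 5%).

Significance of the empirical Q* reports three p-values side by side,
since no single convention is canonical: the empirical quantile
(1 + #{null ≥ empirical})/(n_null + 1), which is the primary value; a
parametric one-sided p treating the empirical Q* as a draw from the
null distribution (t, n_null − 1 df, on the standardized exceedance);
and a bootstrap p comparing the observed standardized exceedance
against its distribution under resampling of the null values.  A
zero-variance null ensemble leaves only the quantile p, flagged.
Null networks receive the same consensus treatment (same number of
runs) as the empirical network.

Node roles: the participation coefficient uses binary edge counts on
the thresholded graph (k_i = 0 gives P = 0); the within-module z-score
standardizes within-module degree against the module's members with the
population standard deviation, and modules of size 1 or zero variance
yield z = 0 with a flag.

## Problem sizes and determinism

The default problem sizes are those of the synthetic study design (18
subjects, 196 time points, 25 + 6 nodes); the validation suite uses 20
replicates for recovery, 100 nulls for the planted significance test,
39 nulls × 100 repeats (5-run consensus, 12 nodes) for calibration, 50
draws for small-world discrimination, 200 random graphs for the metric
oracles, and ~30 signed matrices with n ≤ 8 for exhaustive-search
comparison — sizes at which every experiment is exactly reproducible
from a single master seed.  All randomness flows through
`numpy.random.SeedSequence` spawns of explicit seeds; repeated
invocations are bit-identical.

## Known limitations

- The volumetric (image) code path is represented by the generic
  distance-based geometry; native neuroimaging file formats are out of
  scope and node/voxel tables are the interface.
- ICA decomposition and reverse-inference database queries that would
  corroborate a network's identity on real data are out of scope; only
  the spatial template-matching correlation is provided.
- Weighted variants of path-based metrics are not defaults and the
  binary choice on thresholded graphs, while matching the reported
  scales, is a declared interpretation.
- The calibration guarantee of the null-model test is established for
  i.i.d.-weight matrices; heavy-tailed or strength-heterogeneous
  networks may still show mild miscalibration, which the three reported
  p-values help diagnose.
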