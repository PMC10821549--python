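# Methods

`essprot` predicts essential proteins by combining the dynamics of a
protein–protein interaction (PPI) network with subcellular localization.
This note describes the model, its assumptions, the tunable parameters, what
the synthetic benchmark does and does not emulate, and the numerical choices
made where the design was open.

## Dynamic network construction (3-sigma activity rule)

For each protein *p* with temporal expression EV₁(p)…EVₙ(p) (n ≥ 2):

- μ(p) = Σᵢ EVᵢ(p) / n — arithmetic mean,
- σ²(p) = Σᵢ (EVᵢ(p) − μ(p))² / (n − 1) — sample variance,
- F(p) = 1 / (1 + σ²(p)) — fluctuation index in (0, 1],
- t(p) = μ(p) + 3·σ(p)·(1 − F(p)) — activity threshold.

Protein *p* is *active* at time *i* when EVᵢ(p) ≥ t(p). The comparison is
non-strict: a constant series has σ = 0, hence t = μ = EVᵢ, and a strict
comparison would mark constitutively expressed proteins inactive everywhere,
severing most of the network for no biological reason. Proteins with no
expression row are treated as always active — discarding their interactions
would shrink the network for a data-availability reason only.

Snapshot Eₜ of the dynamic network keeps exactly the static edges whose two
endpoints are both active at *t*. By default the first snapshot is replaced
by the full static edge set (`first_snapshot_static=True`), so the event
stream opens by generating every static interaction; the pure
activity-driven first snapshot is available by flag.

A property of the rule worth knowing: the threshold margin
t − μ = 3σ³/(1 + σ²) grows without bound in σ, so a protein whose
active/baseline swing is large relative to 1 (in the units of the input
matrix) is *never* called active — its own peak falls below its threshold.
The rule implicitly assumes expression on a normalized, roughly
unit-variance scale (log-like intensities), and it only detects *sparse*
peaks: a protein "active" half the time has too much variance to be called.
Users feeding raw wide-range intensities should normalize first.

Consecutive snapshots are differenced into an interaction stream of
birth/death triplets (u, v, t). Within one timestep deaths are ordered
before births (pair-canonical order breaks remaining ties) so that replaying
the stream never transiently duplicates an edge; replay reconstructs every
snapshot exactly, which the tests assert on randomized fixtures.

An optional cycle-averaging preprocessor (`cycle_average`) collapses a time
course made of repeated experimental cycles into one representative cycle by
arithmetic mean; it is off by default.

## Streaming community discovery

Communities are maintained online over the event stream, with two membership
levels. A **core** member lies in at least one triangle whose three vertices
are all cores of the same community; a **peripheral** member is a one-hop
neighbor of a core. Only cores propagate membership.

On the birth of (u, v), for each common neighbor z (each new triangle):

1. if two of {u, v, z} are cores of a common community, the third is
   promoted to core there (leaving that community's periphery if present);
2. if no community holds any two of them as core, a new community with core
   {u, v, z} is created.

Promotions cascade to a fixpoint: a newly promoted core re-triggers rule 1
on its incident triangles, but only within the community it just joined —
membership never travels through non-core members. An edge with no common
neighbor only extends peripheries. On a death, cores that lose their last
all-core triangle are demoted (iterated to fixpoint); if the core-induced
subgraph disconnects, each component becomes its own community (the
component containing the lexicographically smallest member keeps the old
community id — ids must be assigned deterministically and components carry
no id of their own); a community whose core shrinks below three members
dissolves. Communities whose core sets become identical are collapsed onto
the smaller id to prevent unbounded duplicate features. Edge aging (TTL) is
deliberately not implemented: deaths arrive explicitly from the snapshot
differences, which already encode vanishing interactions.

Live communities are recorded at observation-window boundaries (default:
every timestep, one observation per snapshot transition — the window is
tunable but there is no canonical value) and once after the final event if
it does not land on a boundary. The recorded member sets, deduplicated
exactly (first occurrence kept, ordered by first window then community id),
become candidate features. Membership for the feature matrix counts
core ∪ peripheral by default (core-only is a config option): entry (n, m)
is 1 iff protein n belongs to candidate m.

Note that label propagation through shared members can merge planted modules
that are densely cross-linked: two cross-promoted cores inside a foreign
module absorb that whole module through the triangle rule. This is inherent
to the algorithm, visible on the dense first static snapshot, and is why the
candidate set keeps *every* distinct observed member set rather than only
final communities.

## SVM-RFE feature selection

Candidate communities are ranked by recursive feature elimination with a
linear soft-margin SVM. The dual problem is

  min over α: ½ Σₕₖ yₕ yₖ αₕ αₖ (xₕ·xₖ + λδₕₖ) − Σₖ αₖ
  s.t. 0 ≤ αₖ ≤ C, Σₖ αₖ yₖ = 0,

with w = Σₖ αₖ yₖ xₖ. The quadratic program is solved by libsvm on the
precomputed kernel X Xᵀ + λI; the kernel assembly, weight-vector recovery,
ranking loop and KKT verification are this package's code. Each round trains
on the surviving features, scores feature i by cᵢ = wᵢ², removes the argmin
(ties → smallest column index) and records it; features are ranked
best-first by reverse removal order. One feature is removed per round;
chunked removal is an explicit non-default speed option that changes the
ranking. RFE runs on the full (imbalanced) training split — per-round
resampling would make the ranking seed-dependent. Binary 0/1 features are
not standardized: they share a scale, so weight magnitudes are comparable.

Defaults C = 1, λ = 1e−6, tol = 1e−6. λ is a tiny ridge keeping the dual
strictly concave without materially moving the linear-kernel optimum.
libsvm's stopping rule tracks but does not strictly bound the margin
residual we verify, so `train_linear_svm` checks the KKT residual after
solving and retries with a 10× and then 100× tighter solver tolerance in the
rare case the residual exceeds tol; starting directly at a tighter tolerance
is much slower on the degenerate kernels RFE produces (binary membership
matrices have many duplicated rows).

The top 64 ranked communities are retained (saturating with a warning when
fewer exist), returned in original column order for matrix assembly.

Subcellular localization terms are ranked by annotated-protein count
(descending, ties lexicographic); of the top 1024 terms, ranks 11–64 are
excluded as low-contribution, leaving at most 970 binary columns. RFE is
*not* applied to localization features.

## Two-branch classifier

One fully connected branch per feature family:

- community branch: input → 32 → 16,
- subcellular branch: input → 256 → 64 → 16,

each layer followed by batch normalization and ReLU, both branches ending in
a length-16 representation. The concatenated vector (32) feeds a head
32 → 16 → 1 with ReLU and a sigmoid output; the loss is binary cross
entropy. Input widths are read from the data, so desk-scale fixtures with
narrow feature blocks work unchanged; a zero-width block simply drops that
branch (used by the ablation harness). The network is implemented directly
in numpy (explicit forward/backward passes, Adam optimizer) — it is small
enough that this is simpler and more transparent than a framework
dependency, and it makes bit-reproducibility under a single seed trivial.

Essential proteins are rare, so each epoch trains on a balanced subset: all
M positives plus M negatives drawn uniformly without replacement from the N
training negatives, a fresh draw per epoch. The minimum epoch count that
bounds the probability of any given negative never being drawn by
P (default 0.001) is the smallest k with (1 − M/N)^k ≤ P; the default epoch
count is max(that bound, 200).

Optimizer settings: full-batch Adam on the balanced subset, learning rate
0.01, one step per epoch. With one full-batch step per epoch, a learning
rate of 1e−3 over a few hundred epochs moves the parameters too little to
fit even cleanly separable data; 0.01 with at least 200 epochs reliably
drives the balanced-subset loss below 0.05 on separable fixtures while
remaining stable on the synthetic benchmark. Classification threshold for
accuracy/precision/recall/F is 0.5. The train/test split is a stratified
80/20 (stratification protects the tiny positive class in small datasets;
it requires at least 5 samples per class).

## Evaluation

Average precision (step-wise, non-interpolated area under the
precision-recall curve) is the primary metric under class imbalance; ROC AUC
(tie credit ½) and threshold metrics (accuracy, precision, recall,
F-measure = harmonic mean of precision and recall) are also reported. Both
ranking metrics are computed via scikit-learn and are cross-checked in the
tests against hand-written O(n²) pair-counting and rank-accumulation
oracles. The top-fraction protocol labels the top ⌈fraction·n⌉ proteins by
score as positive (ceiling, with score ties broken by protein ID) — the
protocol under which degree-like centrality baselines are traditionally
scored, using the species' essential-protein proportion as the fraction.

Two ablation harnesses reuse a single split and seed per comparison so that
only the manipulated factor varies: branch ablation trains community-only,
subcellular-only and combined models; snapshot detachment removes one
snapshot, rebuilds stream → communities → features, retrains with unchanged
parameters, and evaluates (a sweep covers every timepoint).

## Synthetic benchmark

The generator plants K communities as dense blocks of a planted-partition
graph (edge probability `p_in` within a block, `p_out` between; block
assignment is a seeded permutation of the protein IDs, so different seeds
plant genuinely different modules). Each block receives a contiguous active
phase of the time course; member expression is `active_expr` (default 3.0)
in phase and `baseline_expr` (default 1.0) outside, plus Gaussian noise
(sd 0.1), truncated at zero. The two-level profile makes the 3-sigma stage
analytically checkable: with the default levels and a phase covering at most
a quarter of the timepoints, the in-phase level exceeds the protein's own
threshold and the baseline falls below it (asserted in the tests in the
zero-noise limit). The phase length is capped at ⌈T/4⌉ for exactly this
reason; larger active/baseline swings or longer phases push the threshold
above the active level — see the 3-sigma note above — so "more signal" in
raw units would paradoxically erase the dynamics.

Labels are planted by an explicit generative rule, never by degree (degree
would conflate the benchmark with centrality baselines): `community-linked`
draws 90% of essentials from designated essential-rich blocks (the first
⌈K/2⌉); `localization-linked` draws essentials uniformly but attaches each
of 3 enriched localization terms with probability 0.9 to essentials versus
0.05 to background proteins; `mixed` (default) does both. Defaults:
200 proteins, 12 timepoints, 5 blocks of 20–36 members, p_in 0.9,
p_out 0.02, essential fraction 0.2, 30 localization terms. All randomness
derives from one seed through per-component substreams, so identical
configurations emit byte-identical files.

What the benchmark does *not* emulate: scale-free degree structure of real
PPI networks, false-positive interaction noise, probe-to-protein ID mapping
artifacts, realistic GEO noise models, or correlated localization terms.
Passing tests therefore demonstrate that the machinery recovers structure it
assumes, not performance on real databases.

## Degenerate inputs and numerical details

- Variance is clamped at zero against floating-point negatives before the
  square root.
- A run that observes no community yields a zero-width community branch
  (logged); an empty localization table yields zero subcellular columns.
- All matrices and tie-breaks use the lexicographic protein order; community
  ids are assigned in creation order with sorted iteration everywhere, so
  identical streams give identical catalogs.
- Pipeline stages are cached by content hash of their inputs plus the
  configuration keys they depend on; reruns with identical inputs and config
  produce byte-identical artifacts.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline at
n = 200 proteins, 12 timepoints, 5 planted blocks (about 2,000–2,500 edges
and 5,000–7,000 stream events), with 10-seed sweeps for the stochastic
claims and 100–1,000 replicates for the oracle comparisons — sizes at which
every stage's invariants can be verified exhaustively.
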