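# Methods

This note documents the models, procedures and numerical choices
implemented in `netbin`, in the package's own terms.  Everything stated
here is computed by the code and exercised by the test suite; nothing is
asserted that the tests or `scripts/acceptance.py` do not measure.

## The weighted complex hierarchy (WCH) model

`netbin.wch` generates complete weighted networks that emulate the
hierarchical hub structure of EEG phase-based functional connectivity.
For `n` nodes, every unordered pair receives a base weight
`w_ij ~ Uniform(0, 1)` i.i.d.  A level count `h` is drawn uniformly from
{2, 3, 4, 5} (or fixed by the caller), each node is independently
assigned a level `h(i) = min(G, h)` with `G` geometric on {1, 2, ...}
(success probability `level_param`, default 0.6; excess mass is lumped
into level `h` rather than renormalised, so level-1 occupancy is exactly
`level_param`), and the final weight is

    w̄_ij = w_ij + (h(i) − 1)·s + (h(j) − 1)·s .

The strength parameter `s ≥ 0` (default study grid 0–0.30 in steps of
0.05) tunes the rigidity of the hierarchy: `s = 0` is a uniformly
weighted random network; large `s` produces strict class-based topology
with pronounced hubs.  Matrices are exactly symmetric (the two level
contributions are summed before being added to the base, which matters
at the last floating-point ulp), zero-diagonal and nonnegative; weights
are *not* rescaled at generation, so the additive definition above holds
verbatim.  Banks derive per-realisation generators from a master seed by
spawn keys, so member `k` of a bank is identical for any bank size.

Empty levels are permitted.  The model produces no volume-conduction
structure, no electrode geometry, no frequency content and no weight
ties — features of real PLI matrices that passing tests therefore do not
speak to.

## Binarisation strategies

All five strategies are stateless scikit-learn transformers over stacks
of weight matrices, with plain functions as wrappers.  Edge selection is
always by descending weight with a deterministic (weight, i, j)
lexicographic tie rule; counts are rounded half-to-even.

* **Proportional threshold** keeps the `round(f · n(n−1)/2)` strongest
  edges.
* **MST** is the maximum-total-weight spanning tree (computed as the
  minimum spanning tree of the negated weights), n−1 edges, density 2/n.
* **ECO** keeps the `round(1.5 n)` strongest edges (density ≈ 3/(n−1)),
  the efficiency-cost optimum; for n ≤ 4 it clamps to the complete graph
  with a warning.
* **CST** scans integer density percentages 15–85 (duplicate edge counts
  collapsed), computes the global clustering coefficient (transitivity,
  3·triangles / connected triples, maintained incrementally while edges
  are inserted in rank order) and returns the network minimising
  |C − 0.5| — the balance point of open and closed triples.  Ties break
  toward the lower density; the signed form would degenerately select
  the sparsest network.
* **USP** maps weights to distances `ŵ_ij = −ln(w_ij)/α`, with `α` the
  smallest positive integer making every distance strictly less than 1,
  and returns the union of one shortest path per node pair, taken from
  per-source Dijkstra predecessor trees (deterministic tie handling;
  ties have measure zero for continuous weights).  A flag switches to
  the union over *all* shortest paths.  Off-diagonal weights outside
  (0, 1) are first linearly rescaled to (ε, 1−ε), ε = 10⁻⁶ (logged);
  `α` itself never affects path structure — only the weight-to-(0,1)
  map does, which is why that map is stated explicitly here.

## Metrics

Ten metrics, three per network type: CST (P, L, V), MST (LF, D, MD),
USP (C, P, V), ECO and proportional thresholds (C, L, V), weighted
networks (C_W, Eff, μ_W).  Notation: P edge density 2m/n(n−1); L
characteristic path length (mean shortest-path length over *connected*
ordered pairs — infinite distances are excluded with a logged warning, a
flag restricts to the largest component instead); D diameter (errors on
disconnected input); C mean local (Watts–Strogatz) clustering, degree-<2
nodes contributing 0; V population variance of the degree sequence
(divide by n); LF leaf fraction; MD maximum degree; μ_W mean
upper-triangle weight.

C_W is the Onnela geometric-mean weighted clustering.  Weights already
in [0, 1] are used as-is (a triangle of 0.5-weights scores 0.5, and 0/1
matrices reduce exactly to C); only weights exceeding 1 are rescaled by
the maximum, with a warning.

Weighted efficiency defaults to the canonical inverse lengths
`d = 1/w`.  The log-distance alternative is available as a flag but is
not the default: on unit-normalised matrices the strongest edge's log
distance approaches 0, making mean(1/d) heavy-tailed and dominated by a
single entry.

## The population-contrast harness

Banks of WCH realisations are generated per (size, strength) condition.
**Each bank matrix is divided by its own maximum** before any analysis —
the standard weight-conversion normalisation.  This is a substantive
choice, made for three reasons: it places weights in the log transform's
domain so the USP applies directly; it makes the weighted metrics
scale-free, so contrasts reflect topology rather than the trivial mean
shift `E[w̄]` inherits from `s` (with raw scales, mean weight alone
separates conditions in essentially every trial, which contradicts the
known mediocre performance of weighted metrics on this task); and it
makes Uniform(0, 1) attack replacements commensurate with the weights.
Rank-based binarisations (CST, MST, ECO, proportional) are provably
unaffected by it.

Each trial samples `pop_size = 20` networks per population without
replacement (independently across trials), reduces each network to its
metric triple, and applies a two-sided Welch t-test per metric (a pooled
Student variant is a flag).  The *best* metric is the one with the most
p-values below α = 0.05 over the 50 trials, ties broken by the lowest
mean natural log p-value; a method's accuracy in a cell is the best
metric's percentage of significant trials.  Trials with non-finite
metric values are dropped and the denominator adjusted.  No
multiple-testing correction is applied across the three metrics — the
best metric is selected post hoc, exactly as in the procedure this
harness replicates; treat per-cell accuracies accordingly.  Advisory
normality z-tests (D'Agostino–Pearson) are available and never gate.

Grand averages are unweighted means over all sizes (16, 32, 64, 128) and
all six adjacent strength pairs.  The study size used by the acceptance
script and the acceptance tests — banks of 200 realisations, 50 trials —
is the package's reference configuration; accuracies are means over 50
Bernoulli trials, so per-cell Monte-Carlo error is ≈ 7 percentage points
at 50% accuracy.

## Topological attacks

Two granularities are provided and they are *not* the same operation:

* `random_attack` / `targeted_attack` operate on a single network:
  `round(density · #pairs)` pairs (for targeted, pairs adjacent to hub
  nodes — nodes whose mean adjacent weight exceeds the across-node mean
  by more than one SD, recomputed per network) are replaced with fresh
  independent Uniform(0, 1) draws.  Targeted density is a fraction of the
  hub-adjacent pair set by default (density 1 = all hub edges), with a
  global-denominator flag.
* `attack_sweep` implements the *parallel population attack* used by the
  robustness analysis: one sparse random attack matrix is drawn per
  density and its entries are substituted into every network of both
  populations.  Attacked positions then carry no between-network
  variance, so discriminability degrades only through the loss of
  surviving structure.  This reading reproduces the characteristic
  robustness profile — the cluster-span threshold degrades gracefully
  and leads the binarisations, spanning-tree and efficiency-cost
  thresholds collapse immediately, weighted metrics are nearly flat —
  whereas independent per-network attacks destroy every method's
  accuracy at once and, applied on the raw scale, even inject a
  spurious normalisation artifact that *raises* accuracy with attack
  density.  For targeted sweeps the shared mask is filtered per network
  to hub-adjacent pairs.

## PLI front-end

Order-70 Hamming-window FIR bandpass (α 8–13 Hz, β 13–32 Hz presets;
band edges snapped to a 0.5 Hz design grid), applied as a single forward
pass with the order/2-sample group delay compensated (forward–backward
filtering is a flag).  Instantaneous phase is the angle of the analytic
(Hilbert) signal.  The phase lag index is

    PLI_ij = | ⟨ sgn(φ_i(t) − φ_j(t)) ⟩ |,

with the phase difference wrapped to (−π, π) (the sign of its sine) so a
2π wrap of one channel cannot flip the sign, and differences within
10⁻⁹ of zero lag contributing 0 — this makes the PLI of exact or scaled
channel copies exactly 0, the measure's defining insensitivity to
volume conduction, and the self-PLI 0.  The first and last `order`
samples are excluded from the averaging in the pipeline entry point.
Per-trial matrices are averaged entrywise.

## Known limitations

* The mean USP density on WCH banks is ≈ 0.3 at (n = 16, s = 0.1) under
  the per-network unit normalisation, noticeably sparser than reported
  elsewhere for this model class; the USP is the one strategy sensitive
  to the exact weight-to-(0,1) map, and no principled map we tested
  (empirical max, model ceilings, clipping, inverse or linear distances,
  exponential transforms) reproduces both the published density level
  and the weighted-metric behaviour simultaneously.  Conclusions about
  the USP should be read with that sensitivity in mind.
* The sparse binarisations (MST, ECO) are *more* discriminative in this
  implementation than published comparisons suggest: at a strength step
  of 0.05 the maximum-weight tree's leaf fraction shifts by several
  standard deviations at n = 128.  The qualitative ordering (CST above
  USP/ECO, far above MST at equal tolerance) is stable; absolute sparse-
  method accuracies are not directly comparable across implementations.
* Real EEG analyses (re-referencing, artifact handling, epoch selection)
  are out of scope; the PLI front-end expects clean multichannel text
  matrices.
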