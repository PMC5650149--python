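# netbin

Binarisation of weighted functional-connectivity networks, with the
simulation machinery to evaluate binarisation strategies on a known
ground truth.

Network analyses of EEG functional connectivity start from a full
symmetric matrix of coupling weights (here, the phase lag index) and
must decide which edges constitute "the network".  That thresholding
choice is consequential and usually arbitrary.  `netbin` implements the
non-arbitrary strategies in current use and a simulation harness to
compare them:

* **CST** — cluster-span threshold: the proportional threshold at which
  the global clustering coefficient C_Glob = 3·triangles/triples is
  closest to 0.5, balancing open against closed triples (typical
  density 0.3–0.5);
* **MST** — maximum-weight spanning tree (n−1 edges, density 2/n);
* **USP** — union of shortest paths on log-transformed distances
  ŵ_ij = −ln(w_ij)/α, α = min{N ∈ ℕ : max ŵ_ij < 1};
* **ECO** — efficiency-cost optimum, the strongest round(1.5 n) edges
  (density ≈ 3/(n−1));
* arbitrary proportional thresholds, and direct weighted-network
  analysis for comparison.

Ground truth comes from the **weighted complex hierarchy (WCH) model**:
base weights w_ij ~ U(0,1) plus level boosts,
w̄_ij = w_ij + (h(i)−1)s + (h(j)−1)s, where nodes occupy 2–5 hierarchy
levels (truncated-geometric assignment) and the strength s controls how
rigid the hub hierarchy is.  Two populations whose s differs by 0.05 are
contrasted by Welch t-tests on three per-method graph metrics (e.g.
density P, path length L, degree variance V for the CST) over 50 trials
of 20-vs-20 samples; the best metric's significant-trial percentage is
the method's *accuracy* at discovering the known topological difference.
Size-preserving topological attacks (randomising a fraction of weights,
uniformly or restricted to hub-adjacent edges) probe robustness, and a
PLI front-end (order-70 FIR bandpass → Hilbert phase →
PLI_ij = |⟨sgn(φ_i−φ_j)⟩|) turns multichannel recordings into weight
matrices.

Intended users: researchers in EEG/MEG network neuroscience comparing
thresholding choices, and methodologists benchmarking new binarisation
rules against a controllable hierarchical ground truth.

## Worked example

```python
from netbin import WchSpec, generate_wch, cst, mst, metric_triple
from netbin.experiment import TrialDesign, run_design, grand_average

net, levels = generate_wch(WchSpec(n=32, s=0.15, seed=42))
bn = cst(net)
print("CST density:", round(bn.density, 3), "| transitivity:", round(bn.params["transitivity"], 3))
t = metric_triple(bn, "CST")
print("triple:", t.names, [round(v, 3) for v in t.values])
print("MST density:", mst(net).density)

design = TrialDesign(n_trials=20, pop_size=20, bank_size=60, sizes=(16, 32),
                     s_values=(0.10, 0.15), methods=("CST", "MST"), seed=1)
results, table = run_design(design)
print(table.to_string(index=False))
```

prints

```
CST density: 0.49 | transitivity: 0.505
triple: ('P', 'L', 'V') [0.49, 1.51, 12.652]
MST density: 0.0625
 size  s_a  s_b method best_metric  accuracy
   16  0.1 0.15    CST           V      95.0
   16  0.1 0.15    MST          LF     100.0
   32  0.1 0.15    CST           V      95.0
   32  0.1 0.15    MST          LF      90.0
```

The CST lands at density 0.49 with transitivity 0.505 — the scan point
closest to the open/closed-triple equilibrium 0.5 — and its (P, L, V)
triple summarises that network.  In the mini-design, the CST's degree
variance V distinguishes s = 0.10 from s = 0.15 populations in 95% of
trials at both sizes.  (At this short 0.05 strength step the spanning
tree is also highly discriminative; differences between methods emerge
over the full size/strength grid.)

The binarisers are scikit-learn transformers, so they compose with
pipelines: `ClusterSpanThreshold().fit_transform(stack_of_matrices)`
returns a stack of 0/1 adjacency matrices.

A command-line interface mirrors the library:

```bash
netbin wch-generate --n 32 --s 0.15 --bank 10 --seed 7 --out bank/
netbin binarise --method cst --in bank/wch_0000.csv --out adj.csv
netbin metrics --in adj.csv --method cst --out metrics.csv
netbin attack --kind random --density 0.35 --seed 3 --in bank/wch_0000.csv --out attacked.csv
netbin pli --in signals.csv --fs 250 --band 8 13 --out W.csv
netbin experiment --config design.yaml --out results/
```

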