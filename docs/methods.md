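# Methods

## Deposition model

A simulated nanowire network is a random arrangement of `n` straight 1D
segments on a rectangular plane (default 30 × 30 µm). Midpoints are
uniform on the plane; orientations uniform on `[0, 2π)`; lengths are
`Normal(ℓ̄, d·ℓ̄)` with the dispersion `d = sd/mean ∈ [0, 1]` and
non-positive draws rejected (at `d = 0` every wire has exactly length
`ℓ̄`). Only midpoints are constrained to the plane: wires may overhang
the boundary and are not clipped. Every pairwise crossing is recorded as
a junction — the simplifying assumption being that any physical contact
forms a working junction — and the network is the undirected simple
graph on wires with one edge per crossing pair.

Geometric conventions: coordinates are floats in µm with the origin at
the lower-left corner; endpoints touching within 1e-9 µm count as a
crossing; collinear overlapping segments (a measure-zero configuration)
produce no junction and log a warning, since a contact *line* has no
unique intersection point.

The expected junction count is the Buffon-type estimate
`E[J] = n(n−1) ℓ̄²/(π A)` (two random segments cross with probability
`2ℓ̄²/(πA)`). Measured counts run ~10–15 % below it because partners for
wires near the boundary are missing; the simulator's ensemble means stay
within ±15 % of the estimate for `n ∈ {100, 500}`.

### Density regime

At the default geometry the reduced density `n ℓ̄² / A` crosses the 2D
stick-percolation threshold (≈ 5.6) between `ℓ̄ = 6` and `ℓ̄ = 9` µm for
`n = 100`: the sparsest 100-wire depositions fragment into components of
a few dozen wires, while 500-wire depositions are fully connected with
mean degree ~11–25. Ensemble statistics over the full parameter grid at
`n = 100` therefore mix sub- and super-critical networks and carry much
higher variance than at `n = 500`; global metrics are always computed on
the largest connected component (LCC) with the excluded fraction
reported, so they remain finite either way. Published densities for
comparable simulators are substantially higher than this geometry
admits (e.g. mean degrees near 40 at 500 wires would require more
junctions than the 30 × 30 µm plane can host at these lengths), so
ensemble summaries that depend on absolute density — mean path length,
100-wire propensity, matched Watts–Strogatz `k` — are sensitive to that
calibration; the simulator deliberately keeps the stated geometry rather
than re-scaling the plane to meet any particular summary value.

## Reference families

* **Watts–Strogatz**: ring lattice with `N` nodes, `k` neighbours per
  side (mean degree `2k`, requiring `2k < N`); each lattice edge is
  rewired with probability β to a uniformly chosen node, rejecting
  self-loops and duplicates, so the edge count `N·k` is invariant.
  Degree matching to another graph uses `k = round(mean degree / 2)`
  (ties to even, floor 1). The default sweep is β = 0, 0.05, …, 1
  (21 graphs).
* **Layered ANN**: consecutive layers joined completely bipartitely, no
  within-layer edges; triangle-free by construction, so clustering is
  identically zero. Default layers 10-160-160-160-10 (500 nodes, 54,400
  edges). It is a topology object only; nothing is trained.
* **Connectomes**: external edge lists or adjacency-matrix CSVs are
  symmetrized, binarized, self-loops dropped and parallel entries
  merged. Weights are never used by the metrics. The bundled
  `synthetic_connectome` generator is a labelled synthetic stand-in, not
  anatomical data: modules wired as random paths and chained (forcing
  connectivity), remaining edges sampled 75 % within-module with
  endpoint weights 8:1 toward a configurable hub minority. It matches a
  small nervous system's gross statistics (277 nodes, 2,105 edges,
  modularity, hubs) but not its specific wiring motifs, neuron identities
  or spatial layout — passing on it shows the code paths are exercised,
  not that biological conclusions transfer.

## Metrics

* **Path length**: mean/SD of BFS hop counts over all unordered LCC
  pairs (SciPy sparse all-pairs shortest paths). Per-source profiles and
  all-pairs histograms support path-distribution plots.
* **Clustering**: local triangle fraction per node, degree < 2 scoring
  0, averaged over LCC nodes (the node-wise mean, not the transitivity
  ratio).
* **Small-world propensity**: nulls are (i) the ring lattice with
  matched `N` and `k = round(mean degree/2)` and (ii) the mean over
  `n_null = 10` seeded `G(N, M)` draws with matched edge count (each
  reduced to its LCC for path length). Deltas are ordering-aware: a
  non-positive deviation (e.g. the observed graph is *more* clustered
  than its lattice null, which happens whenever the matched lattice has
  `k = 1` and hence no triangles) counts as 0; coincident or inverted
  null denominators set the delta to 0 with a warning; otherwise the
  ratio is clamped to 1. This keeps the two analytic anchors exact: a
  ring lattice scores ΔC = 0, ΔL = 1 and an Erdős–Rényi graph ΔC ≈ 1,
  ΔL ≈ 0, both giving φ = 1 − 1/√2 ≈ 0.293.
* **Cartography**: Louvain modularity maximisation (resolution 1.0,
  explicit seed) on the LCC; participation coefficient
  `P_i = 1 − Σ_s (k_is/k_i)²` with isolated nodes scoring 0;
  within-module degree z-score with population SD and the zero-variance
  convention `z = 0` (so every module's mean z is exactly 0). Region
  boundaries are half-open with the boundary value in the upper region:
  non-hubs (`z < 2.5`) split at participation 0 / 0.62 / 0.80 into
  ultra-peripheral, peripheral, non-hub connector and non-hub kinless;
  hubs (`z ≥ 2.5`) split at 0.30 / 0.75 into provincial, connector and
  kinless hubs. `z = 2.5` itself counts as hub. These choices make the
  classifier a total, deterministic tiling of the plane.

## Pipeline and statistics

`run_sweep` takes a declarative config (YAML via the CLI), generates or
loads every configured network, runs the full battery and emits one
summary record per network plus tidy CSVs (summary table,
clustering-vs-path-length plane, propensity per family, per-node
cartography) and a manifest recording config and seed. Failures skip a
single network with a logged diagnostic. Group comparisons use one-way
ANOVA with Bonferroni-corrected pairwise t-tests; propensity comparisons
operate on per-network values, participation/z comparisons on per-node
values. Zero-variance inputs raise rather than returning an undefined F.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed; ensemble members get
counter-derived seeds (`SeedSequence([master, index])`, reduced below
2³¹) so any single network can be regenerated from its recorded
parameters. The test suite and the acceptance script use ensembles of
16 networks per size (the 4 mean-lengths × 4 dispersions grid at fixed
`n`), 10-draw Watts–Strogatz ensembles and 10 random-null draws per
propensity evaluation; these sizes give ensemble-mean standard errors
well below the comparison tolerances while keeping a full run under a
minute.

## Known limitations

* All metrics are binary-graph metrics; weights, junction conductances
  and any electrical dynamics are out of scope.
* The Louvain partition is one local optimum of modularity; participation
  means shift by a few hundredths across reasonable partitioning choices,
  which is why partition-dependent comparisons carry wide tolerances.
* The exhaustive-search modularity oracle used in tests is feasible only
  for graphs of ≤ ~8 nodes.
* Wires are ideal 1D segments: no curvature, thickness, or electrical
  screening between nearby parallel wires.
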