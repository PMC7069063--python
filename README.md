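# nwtopo

Structural graph analysis of **self-assembled nanowire networks** — the
neuromorphic substrates in which metallic nanowires act as synthetic
neurons and the wire–wire junctions as synthetic, atomic-switch-like
synapses. Because the hardware self-assembles, its wiring diagram cannot
be read off a micrograph; `nwtopo` simulates the deposition instead and
asks the questions a network neuroscientist would ask of a connectome:
is the wiring small-world? how modular is it? where are its hubs?

The package is aimed at researchers in neuromorphic hardware and network
neuroscience who want reproducible, seed-controlled comparisons between
simulated nanowire networks, Watts–Strogatz references, layered
feed-forward (ANN) topologies and biological connectomes such as
*C. elegans*.

## What it computes

**Deposition model.** Each nanowire is a 1D segment: midpoint uniform on
a `W x H` µm plane, orientation uniform on `[0, 2π)`, length drawn from
`Normal(ℓ̄, σ)` with dispersion `σ/ℓ̄ ∈ [0, 0.5]` (non-positive draws
rejected). Every crossing of two segments is a junction; the network is
the undirected simple graph with one node per wire and one edge per
crossing pair. The expected junction count follows the Buffon-type
estimate `n(n−1) ℓ̄² / (π A)`.

**Small-world propensity.** With `C` the node-averaged local clustering
and `L` the mean shortest-path length over the largest connected
component, observed values are compared against a degree-matched ring
lattice (`latt`) and an edge-matched Erdős–Rényi ensemble (`rand`):

    ΔC = (C_latt − C_obs) / (C_latt − C_rand)
    ΔL = (L_obs − L_rand) / (L_latt − L_rand)
    φ  = 1 − sqrt((ΔC² + ΔL²) / 2),    ΔC, ΔL clamped to [0, 1]

A graph lying on either null line scores `1 − 1/√2 ≈ 0.293`; small-world
graphs (cluster like a lattice, route like a random graph) score higher.

**Functional cartography.** Louvain modularity maximisation assigns
modules; each node then gets a participation coefficient
`P_i = 1 − Σ_s (k_is / k_i)²` and a within-module degree z-score, and is
classified into one of the seven Guimerà–Amaral regions
(ultra-peripheral … kinless hub; hubs at `z ≥ 2.5`).

## Worked example

```sh
$ nwtopo generate --n-wires 500 --mean-length 8 --dispersion 0.2 --seed 42 --out demo
500 wires, 4518 junctions, mean degree 18.07 -> demo

$ nwtopo swp --in demo/edges.tsv --seed 1
{ "c_obs": 0.4149, "c_latt": 0.7059, "c_rand": 0.0362,
  "l_obs": 4.1029, "l_latt": 14.3647, "l_rand": 2.4652,
  "delta_c": 0.4345, "delta_l": 0.1376, "phi": 0.6777, ... }
```

The 500-wire deposition at mean length 8 µm yields 4,518 junctions,
close to the Buffon estimate `500·499·64/(900π) ≈ 5,648` minus boundary
losses. Its clustering (0.41) sits far above the random null (0.04)
while its path length (4.10) stays near the random null (2.47) and far
below the lattice null (14.4) — a small-world propensity of 0.68.

```sh
$ nwtopo cartography --in demo/edges.tsv --seed 1 --out demo/nodes.csv
{ "mean_pcoeff": 0.205, "sd_pcoeff": 0.211, "mean_mz": 0.0, "sd_mz": 1.0,
  "region_counts": { "ultra-peripheral": 191, "peripheral": 297,
                     "non-hub connector": 10, "provincial hub": 2 },
  "modularity_q": 0.700, "n_modules": 7, ... }
```

The deposition is highly modular (Q = 0.70, 7 modules) and dominated by
peripheral, within-module nodes with a low mean participation
coefficient (0.21) — segregated modules with sparse inter-module wiring
and almost no hubs.

Library use mirrors the CLI (`nwtopo.generate_ensemble`,
`nwtopo.small_world_propensity`, `nwtopo.cartographic_profile`,
`nwtopo.run_sweep`); see the module docstrings and `docs/methods.md`.

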