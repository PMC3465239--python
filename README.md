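# spokenet

Tools for asking where the falling clustering-coefficient curve
C(k) ~ k⁻¹ of biological networks actually comes from.

A node of degree *k* with *N* triangles through it has clustering
coefficient C = 2N / (k(k−1)); the curve C(k) averages this over all
nodes of degree *k*. A power-law decline of C(k) is widely read as the
signature of *hierarchical modularity* — small dense modules nested
inside larger ones, as in the deterministic recursive 5-clique model.
`spokenet` implements the machinery needed to test that reading:

* **Generators** — the deterministic hierarchical model (5ᴸ nodes),
  scale-free configuration graphs with P(k) ~ k^(−γ), preferential
  injection of *super-hubs* (nodes far above the power-law cutoff,
  playing the role of currency metabolites such as ATP or H₂O), and a
  heuristic *spoke* model in which hubs touch only low-degree leaves.
* **Attachment theory** — closed forms for the triangles a newly wired
  node of degree k_j creates through an existing node of degree k_i:
  ΔN_i = k_i · m_ij · m_j⟨k⟩ with m_ij = min(k_i k_j / 2M, 1).
  The min() is just the simple-graph constraint, and it splits the
  world in two: while the cap is slack ΔN ~ k² and C(k) stays flat;
  once it binds (a super-hub) ΔN ~ k and C(k) ~ 1/k — the hierarchical
  signature, produced by a single hub in an otherwise random graph.
* **Null models** — degree-preserving rewiring; joint-degree-matrix
  preserving random seeds (which reproduce the assortativity r
  exactly); a Metropolis simulated-annealing null that additionally
  drives the triangle count to the real network's value by minimizing
  E = |N_random − N| / N; and a stringent null that keeps ≥30% of the
  original edges in place.
* **Profiles** — Maslov–Sneppen-style correlation profiles
  P(k_i,k_j)/⟨P_r(k_i,k_j)⟩ with z-scores against a rewired ensemble,
  C(k) ensemble envelopes, and tail-probability super-hub detection.
* **Co-expression** — gene co-expression networks from expression
  matrices (array/gene missingness filters, pairwise-complete Pearson
  correlation, |r| > 0.65 edges).
* **Synthetic data** — seeded generators for every input the pipeline
  needs: super-hub graphs, assortativity-steered graphs,
  planted-partition modular graphs, block-correlated expression
  matrices with missing values.

## Worked example

The deterministic hierarchical model is exactly reproducible:

```python
>>> import spokenet as sn
>>> g = sn.hierarchical_model(6)
>>> g.number_of_nodes(), g.number_of_edges()
(15625, 64866)
>>> round(sn.assortativity(g), 4)
-0.0768
```

so even the "pure hierarchy" benchmark is disassortative: its wiring
rule (peripheral nodes to central nodes, never center–center) builds
hub repulsion in. Its C(k) indeed falls like 1/k (the level-4 model
fits a log–log slope of −1.11).

The attachment theory, tabulated for a degree-2,000 node entering a
10,000-node, 8,500-edge random graph (`spokenet theory --s 10000
--m 8500 --kj 2000 --k-values 2,5,10,20,50,100`):

```
<k> = 1.7000; cap binds at k_i >= 8.50
k_i   m_ij     dN_i     C'(k_i)
2     0.2353   0.09412  0.03137
5     0.5882   0.5882   0.03922
10    1        2        0.03636
20    1        4        0.01905
50    1        10       0.007843
100   1        20       0.00396
```

Above the cap (k_i ≥ 8.5) the gain ΔN is exactly linear in k_i and the
predicted clustering C′(k_i) = 2ΔN/(k_i(k_i+1)) halves every time the
degree doubles — the k⁻¹ law, with no hierarchy anywhere.

Experiments are driven from the CLI, e.g.

```sh
spokenet generate hierarchical --levels 3 -o hier.tsv
spokenet anneal -i graph.tsv --tol 0.05 --seed 1 -o null.tsv --log traj.tsv
spokenet experiment superhub --outdir out/
```

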