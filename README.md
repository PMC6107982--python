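# muxcom

Community detection in **multiplex biological networks** by randomized
optimization of a multiplex modularity.

Biological interactions come in layers — protein–protein interaction,
co-expression, signaling, homology — each an undirected weighted graph over
an overlapping set of genes. When the layers are partial views of one
underlying modular organization, clustering them *jointly* recovers that
organization better than clustering any single network or a merged one.
`muxcom` is for researchers who want to extract such shared gene/protein
modules from several networks at once and validate the procedure on
simulated networks with a known community structure.

## The score and the algorithm

A partition assigning each vertex *i* a community *c<sub>i</sub>* is scored by
the multiplex modularity

```
Q = Σ_g  w⁽ᵍ⁾/(2m⁽ᵍ⁾) · Σ_{ {i,j}, i≠j }  ( X_ij⁽ᵍ⁾ − γ S_i⁽ᵍ⁾S_j⁽ᵍ⁾ / (2m⁽ᵍ⁾) ) δ_{c_i,c_j}
```

where per layer *g*: `X_ij` is the edge weight, `m` the total edge weight,
`S_i` the vertex strength, `w` a user-defined layer weight, and γ the
resolution parameter. Each layer contributes its own Newman–Girvan
null-model comparison; a vertex missing from a layer simply has strength 0
there, so layers with different vertex sets pose no problem.

Q is optimized with a multiplex-adapted **Louvain** heuristic: local
single-vertex moves followed by contraction of communities into
super-vertices, iterated to a local optimum. In the **randomized** variant
each vertex move is drawn uniformly among *all* strictly improving moves
rather than the single best one; running N such randomized searches and
keeping the best-scoring partition escapes many of the poor local optima
the greedy search falls into — most visibly on dense, noisy multiplexes.

Two more pieces make the output usable as gene modules:

* **Recursive re-clustering** — communities larger than a size cap
  (default 100) are extracted as sub-multiplexes and re-clustered with the
  same settings until every community fits or is provably unsplittable
  (e.g. a large clique), followed by a size-range filter (default 7–100).
* **Validation tooling** — a stochastic-block-model simulator that plants a
  known community structure across layers (sparse/dense/mixed regimes,
  optional missing vertices), and the adjusted Rand index (ARI) to compare
  detected with planted communities.

## Worked example

Simulate a 3-layer dense multiplex with 6 planted communities of 50 genes,
cluster it with 5 randomized runs, and compare with the truth:

```sh
$ muxcom simulate --n 300 --k 6 --layers 3 --regime dense --seed 7 --out toy
$ muxcom cluster --layer toy.layer1.tsv --layer toy.layer2.tsv \
    --layer toy.layer3.tsv --runs 5 --seed 42 --filter-min 3 --out run
communities	6
modules_in_range	6
multiplex_modularity	0.244138
$ muxcom evaluate run.partition.tsv toy.planted.tsv
1.000000
```

The clustering found 6 communities, all within the requested size range,
with multiplex modularity 0.244; the ARI of 1.0 against the planted
partition means the 6 blocks were recovered exactly. `run.partition.tsv`
holds the vertex → community map, `run.modules.tsv` one module per line,
and `run.manifest.txt` every parameter needed to reproduce the run
byte-for-byte. `muxcom summary FILE...` prints node/edge counts and edge
density per layer, and `muxcom study` runs the full planted-recovery
experiment grid.

The same operations are available as a library:

```python
from muxcom import (read_edge_list, MultiplexNetwork, OptimizerConfig,
                    run_louvain, ari_on_overlap)
net = MultiplexNetwork([read_edge_list(p) for p in paths])
res = run_louvain(net, OptimizerConfig(n_runs=10, seed=1))
print(res.score, res.partition.n_communities)
```

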