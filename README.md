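# kassembly

Graph-theoretic tools for studying associative memory through *k-assemblies*:
threshold activation dynamics on networks of neurons, maximum-k-core peeling,
and exact enumeration of **all minimal k-cores** of an undirected graph, with
a seeded simulation harness over random graphs.

## The model

A network of neurons is a simple undirected graph `G = (V, E)`: vertices are
neurons, edges are unit-strength synapses. A set `S ⊆ V` of active neurons
excites, in one synchronous step, every vertex with at least `k` active
neighbors:

    f_k(S) = { v ∈ V : |N(v) ∩ S| ≥ k }.

Iterating `f_k` from `S` either reaches a fixed point — the **closure**
`cl_k(S)`, a self-sustaining activation pattern — dies out at `∅` (`S` is
*weak*), or cycles (the closure is then undefined). A set with `S ⊆ f_k(S)`
is *persistent*: once lit, it never loses members.

A **k-core** is a nonempty vertex set inducing minimum degree ≥ k (neither
maximality nor connectedness is required); a **minimal k-core** is one with
no proper subset inducing a k-core. Minimal k-cores are exactly the minimal
ignition sites: the **k-assembly** `cl_k(M)` of a minimal k-core `M` is the
memory pattern recalled by exciting `M`. Finding them all is NP-hard (a
(k+1)-clique is a minimal k-core), which is why the enumerator is a
Bron–Kerbosch-style backtracking search rather than anything polynomial:

* `maximum_kcore(G, k)` — greedy minimum-degree peel; returns the unique
  maximum k-core (the union of all k-cores) plus the removal order.
* `enumerate_minimal_kcores(G, k)` — backtracking over
  `(kcore, not, candidates)` states; reports every minimal k-core exactly
  once. Two independent baselines, `subset_oracle` (exhaustive, ≤ 20
  vertices) and `naive_enumerate` (branch on every single-vertex deletion),
  are shipped for cross-validation.
* `run_experiment(config)` — replicated counts over Bernoulli `G(n, p)` or
  random d-regular graphs, aggregated with the conditional-mean convention
  (replicates without any core are counted, not averaged in).

## Worked example

```python
>>> import networkx as nx
>>> from kassembly import enumerate_minimal_kcores, k_assembly, make_graph
>>> G = make_graph(4, [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3)])  # triangle + vertex 3
>>> result = enumerate_minimal_kcores(G, 2)
>>> result.cores
[(0, 1, 2), (0, 1, 3)]
>>> k_assembly(G, {0, 1, 2}, 2)
frozenset({0, 1, 2, 3})
```

The graph contains two minimal 2-cores (the two triangles). Exciting either
one recruits the fourth vertex — both vertices 2 and 3 see two active
neighbors — so the closure, the 2-assembly, is the whole graph: overlapping
minimal cores ignite the same stored pattern.

The same is available from the shell:

```sh
kassembly enumerate --graph graph.txt --k 2
kassembly dynamics --graph graph.txt --seed-set "0,1,2" --k 2
kassembly experiment --model bernoulli --n 10 --p 0.5 --k 2,3 \
    --replicates 100 --seed 7 --out summary.csv
```

Edge lists are plain text, one `u v` pair per line, `#` comments allowed.

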