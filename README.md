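# gestnet

Psychometric network analysis of schizotypal personality traits and
speech-gesture processing.

Schizotypy — the continuum of schizophrenia-liability traits in the general
population — is linked to altered processing of co-speech gestures. To study
*which* facets of schizotypy connect to *which* aspects of gesture processing,
nine variables measured by three instruments are analyzed jointly as a
network: three SPQ-B schizotypy facets (cognitive-perceptual, interpersonal,
disorganization), four BAG self-report gesture subscales (perception,
production, social perception, social production), and two speech-gesture
matching performance indices (iconic/concrete and metaphoric/abstract).

`gestnet` implements that full analysis as a reproducible, tested pipeline:

1. **Scoring** — SPQ-B and BAG subscale sums (reverse-keyed items recoded),
   gesture-matching indices `mean(related) − mean(unrelated)` per sentence
   type, attention-check exclusion.
2. **Bivariate associations** — Spearman rank correlations with t-based
   p-values.
3. **Network estimation** — non-regularized partial correlation network on
   rank-based (Spearman, copula-corrected) correlations: with precision
   matrix `P = R⁻¹`, edge weight `ρ̂ᵢⱼ = −Pᵢⱼ/√(Pᵢᵢ Pⱼⱼ)`. Edges are kept by
   a nonparametric bootstrap decision rule: resample participants, re-estimate
   all partials, include an edge iff the 95% percentile CI of its bootstrap
   distribution excludes zero (default B = 5000, α = 0.05).
4. **Community detection** — deterministic fast-greedy (Clauset–Newman–Moore)
   modularity maximization on |weights|, with a pinned lexicographic
   tie-break.
5. **Bridge centrality** — bridge expected influence, bridge closeness, and
   bridge betweenness of every node given the communities (edge length
   `1/|w|`), with percentile-bootstrap tests of all pairwise differences.
6. **Controllability** — average controllability (trace of the infinite-
   horizon Gramian of `x(t+1) = A x(t) + Bu(t)`, `A` scaled by
   `1 + |λ_max|`) and modal controllability `φᵢ = Σⱼ (1 − λⱼ²) vᵢⱼ²`.
7. **Predictability** — per-node R² from regressing each node on its selected
   neighbors (on ranks).

Because studies of this design rarely deposit raw data, the package ships a
first-class synthetic-data generator: a known ground-truth partial-correlation
network over the nine variables (three instrument blocks plus a handful of
signed cross-block bridge edges concentrated on BAG social production), latent
Gaussian sampling, and quantile-threshold discretization into item-level
Likert responses. Every downstream stage is validated against this known
truth.

## Worked example

```python
import gestnet as gn

gt = gn.make_ground_truth()                            # known 9-node truth
items = gn.simulate_item_responses(gt, n=1139, seed=42)
scored, report = gn.score_responses(items)
print(f"retained {report.n_retained} of {report.n_input}")

net = gn.bootstrap_edge_selection(scored, n_boot=1000, seed=43)
part = gn.fast_greedy(net)
print("communities:", part.n_communities, "Q = %.3f" % part.Q)
for g in part.groups():
    print("  ", g)

bridge = gn.bridge_scores(net, part.membership)
ctrl = gn.controllability_scores(net)
```

Output:

```
retained 1101 of 1139
communities: 3 Q = 0.256
   ('CogPerc', 'Disorg', 'Interp')
   ('Icon', 'Metaph')
   ('Perc', 'Prod', 'SocPerc', 'SocProd')
```

The three detected communities coincide exactly with the three instruments —
the schizotypy facets, the task indices, and the self-report subscales — which
is the data-driven sanity check the community step exists for. In
`bridge.sort_values("bei")` the BAG social-production node sits at or near the
top: it carries the generating cross-block edges, i.e. it is the node through
which self-reported gesturing, schizotypal traits, and task performance are
connected. Average controllability values fall in the ~1.04–1.13 range typical
of partial-correlation networks of this density; nodes with stronger total
coupling score higher on average and lower on modal controllability.

The same analysis is available from a shell:

```sh
gestnet run --n 1094 --nboot 5000 --seed 1 --out results/run1
```

which writes the subscale table, correlation tables, edge list + GraphML,
community partition, bridge and controllability and predictability tables,
and a manifest with per-stage seeds and checksums (re-running with the same
seed reproduces every file byte-for-byte).

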