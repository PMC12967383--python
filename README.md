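# shapeclust

Shape-based clustering of cancer-incidence time series.

Cancer registries publish yearly incidence rates per 100,000 person-years,
stratified by sex, cancer site and 10-year age band. Asking which cancers'
*trends* resemble each other — rather than which cancers are similarly
common — requires a dissimilarity between rate curves that ignores the
baseline level and, if desired, the scale of a curve. `shapeclust`
implements such a proximity measure, the standardization that extends its
invariance, and the average-linkage agglomerative clustering used to find
groups of cancers with similar incidence trajectories. It is aimed at
epidemiologists and biostatisticians working with long-format registry
exports (e.g. the Finnish Cancer Registry's 1963–2023 statistics export).

## The measure

For two series X = [x₁, …, x_k] and Y = [y₁, …, y_k] on the same yearly
axis,

    D(X, Y) = (1/k) Σᵢ [ d(xᵢ, yᵢ) − d(T(X), T(Y)) ],

with distance kernel d(a, b) = (a − b)² and location T(X) = x̄ by default.
Under this default, D(X, Y) equals the population variance of the
difference series x − y, so D ≥ 0, D is symmetric, and D(X, X + b) = 0 for
any vertical shift b. Standardizing each series to

    x̂ᵢ = (xᵢ − x̄) / s(X),    s(X) = √( (1/k) Σᵢ (xᵢ − x̄)² )

(population standard deviation, divide-by-k) makes D additionally
invariant under positive scaling: D(std(X), std(aX + b)) = 0 for a > 0.
On standardized input D reduces to 2(1 − r) with r the Pearson
correlation. Alternative kernels (absolute distance, median location, MAD
scatter) are available but forfeit the non-negativity guarantee.

Clusters are built bottom-up: the pair of clusters Q, R minimizing the
average linkage d_A(Q, R) = (1/|Q||R|) Σ D(X, Y) over cross pairs is
merged until the requested number of clusters (typically 2, 3 and 4)
remains. The linkage is recomputed definitionally from the distance
matrix at every step, and cuts at successive k are nested.

## Worked example

Generate a synthetic panel with four planted trend shapes (three curves
each, 5 % relative noise), then cluster the standardized curves:

```python
from shapeclust import (SyntheticSpec, generate_panel, pairwise_distance_matrix,
                        agglomerate, cut, recovery_score, standardize, shape_distance)

spec = SyntheticSpec(templates=("linear-increase", "decline", "u-shape", "late-jump"),
                     series_per_template=3, noise_sd=0.05, seed=1)
panel, planted = generate_panel(spec)

x, y = panel.get("linear-increase-01"), panel.get("decline-01")
print("raw D = %.3f" % shape_distance(x, y))
print("std D = %.3f" % shape_distance(standardize(x), standardize(y)))

assignment = cut(agglomerate(pairwise_distance_matrix(panel, standardized=True)), 4)
for c, sites in sorted(assignment.groups().items()):
    print(f"cluster {c}: {', '.join(sites)}")
print("ARI vs planted templates:", recovery_score(assignment, planted))
```

Output:

```
raw D = 1009.366
std D = 3.944
cluster 1: linear-increase-01, linear-increase-02, linear-increase-03
cluster 2: decline-01, decline-02, decline-03
cluster 3: u-shape-01, u-shape-02, u-shape-03
cluster 4: late-jump-01, late-jump-02, late-jump-03
ARI vs planted templates: 1.0
```

The raw proximity (≈ 1009) is dominated by the two curves' different
scales; after standardization it reflects only the opposing trends
(≈ 3.944, close to the anti-correlation maximum of 4). The k = 4 cut
recovers the planted shapes exactly (adjusted Rand index 1.0).

The same pipeline is available from the shell:

```sh
shapeclust simulate --seed 1 --out sim/
shapeclust cluster --input sim/panel.csv --sex female --age-group 50-59 \
    --standardize --k 2,3,4 --out run/
shapeclust trends --input sim/panel.csv --sex female --age-group 50-59 \
    --site decline-01 --from 1990 --to 2023 --out trends/
```

`cluster` writes the distance matrix (CSV), the dendrogram (Newick) and
the per-k cluster assignments (CSV + JSON); `trends` writes percentage
changes between two years and the extreme yearly changes in the window.

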