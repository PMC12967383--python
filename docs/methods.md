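# Methods

## The proximity measure

The dissimilarity between two rate curves X = [x₁, …, x_k] and
Y = [y₁, …, y_k] observed on the same yearly axis is

    D(X, Y) = (1/k) Σᵢ [ d(xᵢ, yᵢ) − d(T(X), T(Y)) ],

the discrete (Riemann-sum) form of the analogous integral over continuous
curves, with the 1/k normalization kept exactly as in the discrete
definition (no year-span rescaling: an alternative 1/(span) constant
would only multiply all distances by a common factor and leave every
clustering decision unchanged).

With the default kernels — squared distance and the mean as location —
the measure expands to

    D(X, Y) = (1/k) Σᵢ (xᵢ − yᵢ)² − (x̄ − ȳ)²,

which is the population variance of the pointwise difference series.
Three consequences follow and are asserted as tests:

* **Non-negativity and symmetry** (variance of a real series).
* **Shift invariance**: D(X, X + b) = 0 for any constant b, so two
  cancers whose rates differ by a constant offset are "the same trend".
* **Standardized closed form**: on z-scored input, D = 2(1 − r) with r
  the Pearson correlation of the raw curves. This identity is used only
  as an independent test oracle; the implementation always evaluates the
  defining sum.

### Standardization

Each series is standardized separately, over its own full year span:

    x̂ᵢ = (xᵢ − T(X)) / s(X),

with T the mean and s the **population** standard deviation
(divide by k, not k − 1) by default. The divide-by-k convention is kept
deliberately and differs from the `ddof=1` default of many statistics
libraries; with k = 61 yearly points the numerical difference is below
1 %, but the unit-population-variance invariant of the standardized
output (checked to 1e−12) holds only under this convention.
Standardization makes D invariant under y = a·x + b with a > 0, so
clustering standardized curves groups by trend shape regardless of how
common a cancer is.

A series with zero scatter carries no shape information and cannot be
standardized; it raises `ConstantSeriesError` (naming the site) rather
than being silently dropped. "Zero" means s(X) < 1e−12 · max(1, |T(X)|),
a relative guard against catastrophic cancellation in nearly-constant
series.

### Alternative kernels

Absolute distance, median location and MAD scatter are selectable for
robustness experiments. The invariance algebra above holds only for the
default combination: with absolute distance and median location the mean
pointwise gap can undershoot the median gap and the proximity goes
negative (the test suite carries a concrete counterexample:
x = [0, 0, 10], y = [5, 5, 10] gives D = 10/3 − 5 < 0). Negative values
are returned unmodified with a warning — clamping would silently change
the method.

## Clustering

Agglomerative hierarchical clustering with average linkage:

    d_A(Q, R) = (1/|Q||R|) Σ_{X∈Q, Y∈R} D(X, Y),

merging the globally minimal pair until one cluster remains. The linkage
of every candidate pair is recomputed definitionally from the original
distance matrix at each step rather than via Lance–Williams update
recurrences. This is O(n³)-ish in the number of curves, but registry
panels hold ~10–20 curves, and the definitional form makes "each merge
attains the brute-force minimum" true by construction instead of by
algebraic equivalence. Average linkage is reducible, so merge heights
never decrease (asserted over random matrices).

Ties between candidate pairs (exact equality of d_A, which genuinely
occurs when shift-copies produce zero distances) are broken by the
smallest member index in input label order, then the second index —
determinism is required for reproducible outputs, and the choice is
otherwise arbitrary.

Cutting the merge sequence when k clusters remain yields the k-partition;
cuts at successive k are nested by construction. Cluster indices follow
the order of each cluster's first leaf in the input label order so that
assignment files diff cleanly across runs.

Dendrograms are exported as Newick with the ultrametric convention: a
cluster merged at linkage height h sits at height h/2, so the
cophenetic distance between two leaves equals their merge height and a
two-leaf tree merged at h has two branches of length h/2. Labels
containing Newick metacharacters are single-quoted.

## Registry input

Input is a long-format CSV (one row per sex × site × age-band × year
with case count and rate per 100,000 person-years), the export dialect
of registry statistics applications. Column names, the excluded-site
list and the year span are configuration (YAML), not code, because
export vocabularies differ between registries. Exclusions (basal-cell
carcinomas, in-situ/borderline/non-invasive categories — neoplasms that
rarely metastasize) are matched exactly but case-insensitively.

Rates are used as provided; the package never recomputes them from case
counts because the export carries no population denominators. Series
must cover the full declared span: an incomplete series is dropped with
a warning naming it, never imputed, since no defensible imputation rule
exists for registry rates.

"Most common cancers" defaults to the top 10 sites by case count in the
final year of the span; the selection rule is configurable because
different reference years give different rankings in young age groups.

### Trend statistics

Percentage change between two years is 100 · (v_to − v_from)/|v_from|.
The absolute-value denominator is a deliberate convention: standardized
series cross zero, and without it the sign of a change from a negative
baseline would invert its meaning. Yearly extremes report the largest
rise and largest drop of the consecutive-year changes inside a window;
year-steps starting at an exactly zero value are skipped with a warning
(the relative change is undefined there).

## Synthetic panels

The generator emulates one registry subgroup: each curve is
a·f(t) + b + ε on the 1963–2023 axis (61 points), where f is one of six
template shapes on the unit interval — linear increase, accelerating
(quadratic) increase, decline, a decline-then-rise U shape (as seen for
cervical cancer where screening first suppressed and HPV-era incidence
later raised rates), a late logistic jump (as produced by the
introduction of PSA testing for prostate cancer), and flat. Scaling
a ~ U(10, 100) spans the order-of-magnitude spread of real per-100,000
rates across sites; shifts b ~ U(0, 20) create nonzero baselines; and
ε is i.i.d. Gaussian with standard deviation

    σ = noise_sd · a · (max f − min f),

i.e. *relative to the realized series amplitude*. Scaling noise by the
drawn amplitude a makes `noise_sd` the exact relative noise level of
every series, so "well-separated at 5 % noise" means the same thing for
every seed and scale; noise fixed to the unit template amplitude would
make the effective shape perturbation depend on the random a. The
default `noise_sd = 0.05` produces panels whose standardized curves are
visually noisy but unambiguous, comparable to mid-age registry series.

An optional Poisson mode draws cases ~ Poisson(rate · PY/100,000) and
derives the rate, emulating the count noise that dominates the youngest
age bands; it is off by default because additive Gaussian noise keeps
the invariance algebra exact in the σ → 0 limit.

Seeding: one root seed; each (template, replicate) series draws from its
own `SeedSequence(seed, spawn_key=(template_idx, series_idx))`
substream, so appending a template or replicates never perturbs
previously generated series, and identical spec + seed is bit-identical.

What the generator does *not* emulate: age–period–cohort structure,
serial correlation of registry noise, reporting-delay artefacts, or
fitted real incidence curves. Passing recovery tests therefore show that
the pipeline recovers planted affine-disguised shapes under i.i.d.
noise — not that real registry panels contain k well-separated clusters.

## Problem sizes and numerics

The test and acceptance workloads use 61-point series (the full
1963–2023 axis), panels of 10–20 curves, 8-leaf random matrices for the
linkage oracle (100 replicates), 1,000 random pairs for the invariance
and identity checks, and 10–20 seeds for recovery statistics — sizes at
which every check is definitional and exhaustive. Invariance identities
are asserted to 1e−10 absolute and the variance identity to ~1e−12
(relative for large rate scales, where squared terms near 1e4 leave a
few ulps of cancellation error). Distance matrices are validated
symmetric to 1e−12 with an exactly zero diagonal.

## Known limitations

* No missing-value handling beyond rejection; aligning panels with
  gaps is the caller's responsibility.
* Negative proximities from non-default kernels flow into the linkage
  minimization unmodified; the resulting dendrogram heights can then be
  non-monotone and the Newick export can contain negative branch
  lengths (both logged, neither an error).
* Automatic choice of the number of clusters is out of scope; k is
  always user-specified (defaults 2, 3, 4).
* Single/complete linkage and Ward's method are not provided.
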