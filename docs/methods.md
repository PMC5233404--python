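# Methods

This note records the modelling assumptions, parameter choices and known
limitations of `padnet`. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pathway enrichment

Genes are ranked by the signal-to-noise ratio
`(mean_case − mean_control) / (sd_case + sd_control)` with sample (ddof = 1)
standard deviations, each floored at `max(sd, 0.2·|mean|, 1e-8)`. The floor
is the canonical GSEA guard against genes whose within-class variance is
essentially zero, which would otherwise dominate the ranking; the `0.2`
fraction is the GSEA default. Ranking ties are broken lexicographically by
gene id, so a ranking is a pure function of the data.

The enrichment score of a gene set is the signed maximal deviation of the
weighted Kolmogorov–Smirnov running sum: walking the ranking, a set member
("hit") adds `|r|^p / Σ_hits |r|^p` and a non-member subtracts `1/(N − k)`.
The weight exponent `p` defaults to 1 (the GSEA default) and is configurable
over {0, 1, 1.5, 2}; at `p = 0` the statistic depends on ranks only, which
the tests verify as invariance under strictly increasing metric transforms.
Set genes absent from the dataset are ignored (counted and logged); a set
with no overlap raises an error rather than scoring 0, because "no evidence"
and "balanced evidence" are different outcomes. If every hit has metric
exactly 0 (possible only in degenerate fixtures) the hit increments fall
back to equal steps `1/k`.

**Permutation null.** The null distribution permutes phenotype labels
(class sizes preserved), re-ranks, and re-scores every set against each
permuted ranking. When the smaller class has fewer than 7 samples the null
switches to gene-set permutation (random relabelling of the membership
vector), the usual GSEA fallback for tiny cohorts, because the space of
distinct label permutations becomes too small. The nominal p-value uses the
add-one estimator restricted to same-sign permutation scores:
`p = (1 + #{|ES_perm| ≥ |ES|, sign match}) / (1 + #{sign match})`, so `p` is
never 0 — published tables that print `p = 0` are outside what a permutation
estimate can produce. NES divides ES by the mean absolute same-sign
permutation score and is reported as NaN when no same-sign permutation
exists (in which case `p = 1/(1 + n_perm)`). Default `n_perm = 1000`; a seed
is mandatory. All sets of a dataset share one set of permutations, which is
both much faster and the statistically standard choice.

**Integration.** Per dataset, pathways with nominal `p < 0.01` are selected;
the disease-specific pathway set is their union across datasets, with
per-pathway provenance retained. `min_overlap = 5` genes (a common GSEA
floor) gates which pathways are scored at all.

## Bipartite network and propagation

The pathway × drug enrichment matrix becomes a weighted bipartite graph.
Negative enrichment is evidence of association in either direction of
perturbation, so the default edge weight is `|ES|` (`abs` transform); a
`positive-only` transform is available for workflows that trust only
upregulated pathway activity. The sparsification threshold defaults to 0
(dense), matching the dense matrix the method is defined on. Nodes left
isolated are dropped with a warning because the degree normalization is
undefined at degree 0.

Normalization is symmetric, `B = D_u^{-1/2} W D_v^{-1/2}`, which bounds the
spectral norm of `B` by 1 (verified on random instances in the tests). With
restart weight `α ∈ (0, 1)` the Jacobi update

```
f_v(t) = (1 − α) y_v + α Σ_u B[u,v] f_u(t−1)
f_u(t) = (1 − α) y_u + α Σ_v B[u,v] f_v(t−1)
```

is a contraction with factor ≤ α, so any start converges to the unique
fixed point `f = (1 − α)(I − αM)^{-1} y`, `M = [[0, B], [Bᵀ, 0]]`, which
`propagate_closed_form` computes by direct solve and which doubles as the
test oracle for the iteration. Both updates read the previous iterate
(Jacobi, not Gauss–Seidel) — that is what the update equations state, and it
makes the iteration order-independent. Defaults: `α = 0.8` (the method
itself does not fix α; 0.8 weights network structure strongly while keeping
fast convergence — the value is recorded in every run's resolved config),
`tol = 1e-6` on the maximum absolute change, `max_iter = 1000`.
Initialization is `f⁰ = y`; the fixed point does not depend on it.
Binary labels give scores in [0, 1], monotone in the label set.

Label matching is exact string equality after lower-casing (configurable to
strict case). Unmatched names are returned and logged, never silently
dropped — with real drug vocabularies most known drugs fail to map, and
that loss must be visible.

## Scoring

Propagated drug scores are standardized with the **population** standard
deviation (divisor n; at panel sizes in the hundreds the n vs n−1
distinction is far below reporting precision, but the choice is fixed).
P-values are the **one-sided upper tail** of the standard normal, computed
through the complementary error function; one-sided is the variant that
reproduces the case study's printed (Z, p) pairs, which the acceptance
tests verify to the precision the printed four-digit Z supports (~0.2%
relative — half a unit in Z's last printed digit moves the tail by about
that much). Candidates are drugs with `p < 0.001`, sorted by z descending
with lexicographic tie-break; removing the known drugs leaves the novel
candidates.

## Validation network

Edge lists carry `(node_a, node_b, edge_type, weight)` with
`edge_type ∈ {drug-drug, drug-gene, gene-gene}`; in drug–gene rows the
drug is `node_a`. Weights must lie in [0, 1]; integer interaction scores
(e.g. 0–900) must be rescaled via an explicit divisor — the filter
`w > 0.4` presumes a unit scale. Assembly order: rescale, deduplicate
(maximum weight wins), drop `w ≤ weight_min` (strict, default 0.4), then
cap each drug at its `neighbor_cap = 40` strongest incident edges (ties by
neighbor id; a drug–drug edge must fit inside both caps). Gene–gene edges
survive only when both genes remain anchored to some retained drug edge,
since the network exists to characterize drug neighborhoods.

Metrics: degree centrality `deg/(n−1)` on the unweighted graph;
betweenness unnormalized with each unordered pair counted once and
fractional credit across tied shortest paths (the convention that yields
small-integer bottleneck tallies); weighted PageRank at damping 0.85 by
power iteration (tolerance 1e-10), reported raw (sums to 1) and min–max
scaled over all nodes. When every PageRank value coincides the scaled
version is undefined and returned as NaN with a warning. networkx provides
the graph algorithms; the tests check them against independent brute-force
oracles (all-pairs BFS accumulation; dense power iteration).

## Synthetic studies

The generator emulates the statistical structure the method assumes, not
any particular organism or platform:

* **Expression:** control expression is i.i.d. Normal(0, 1) per gene
  (log-scale microarray intensities after normalization are roughly
  Gaussian); genes in the planted disease pathways gain `+δ` (default
  δ = 2 sd) in cases; each of the 4 cohorts draws independent noise, so
  integration across cohorts is informative. 30 samples per arm, 2000
  genes, 200 pathways of 15–40 members.
* **Drug matrix:** background ES ~ Normal(0, 0.05) truncated to [−1, 1];
  the 5 planted candidates and 5 known drugs carry |ES| ≈ 0.9 (random
  sign) on the planted pathways — drugs treating the same phenotype
  perturb the same pathways.
* **Validation network:** planted hub drugs wire to every known drug and
  ~90% of target genes at Uniform(0.7, 0.99); background edges are
  Erdős–Rényi with Uniform(0.2, 0.6) weights, so the 0.4 cutoff removes
  half of them (asserted by simulation).

**Sizing of the drug panel.** With k drugs carrying planted signal among a
panel of n, population z-scores obey `Σz² = n` and `Σz = 0`, so the largest
z any of k comparable outliers can attain is near `√((n−k)/k)`. Ten signal
drugs in a panel of 100 cap z at 3.0 — below the 3.09 needed for
`p < 0.001` — and the known drugs' `(1−α)` self-label offset inflates the
variance further. The default panel is therefore 1000 drugs (the order of
magnitude of real perturbation panels), with planted enrichment 0.9 over
noise sd 0.05; at these defaults the smallest planted-candidate z across
20 seeded studies lies between 3.4 and 3.8, and the tests assert full
recovery (mean AUC ≥ 0.95 and all planted candidates selected).

**What passing does not show.** The generator's planted effects are clean,
additive shifts with independent genes and exact membership; real cohorts
have correlated genes, batch effects, heterogeneous effect sizes, partial
pathway annotation, and drug signatures averaged over cell lines and doses.
Recovery at the defaults demonstrates the machinery is correct and
calibrated, not that real studies will separate candidates this sharply.
Signal also leaks into non-planted pathways that share members with planted
ones — visible as unions much larger than the planted count — exactly as
overlapping pathway collections behave on real data.

## Problem sizes used by the batteries

The 20-seed recovery battery (tests and acceptance script) runs the GSEA
stage at 250 permutations per dataset: selection happens at `p < 0.01`,
which needs resolution no finer than 1/251, and the planted effects sit at
the permutation floor regardless. The null-uniformity battery uses 200
datasets × 500 permutations (KS distance to uniform, asserted < 0.1); the
propagation and running-sum oracle batteries use 100 random instances each.

## Known limitations

* Nominal p-values only — no FDR/FWER control and no NES-based
  multiple-testing correction; the union is deliberately permissive.
* The p-value floor `1/(1 + n_same_sign)` ties strongly enriched pathways;
  ordering below the floor is not meaningful.
* Raw CEL/array preprocessing (RMA etc.) and probe annotation are out of
  scope; the package consumes preprocessed matrices and a generic
  probe→gene map.
* The propagation α and the published GSEA settings of the original case
  study are not recoverable from its report, so paper-scale score tables
  are not reproducible desk-side; the acceptance quantities are the
  printed-value round-trips and the synthetic recovery batteries.
* Betweenness and PageRank reporting conventions vary across tools; the
  conventions here (unnormalized pair counts; min–max scaling) are fixed
  and documented rather than inferred.
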