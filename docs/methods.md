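# Methods

## The two models

Let `y ∈ R^n` be one per-sample ecosystem property and `X ∈ N^{n×p}` the
sample × family count table at a common sequencing depth.

**Linear route.** Ordinary least squares of `y` on the family relative
abundances with intercept and no interaction terms. Model quality is the
least-squares AICc

```
AICc(RSS, n, k) = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)
```

with `k = (number of families) + 1` for the intercept. The Gaussian constant
and the error-variance parameter are deliberately omitted from `k`; only
within-route comparisons of AICc are meaningful. Backward stepwise selection
tentatively removes each remaining family, accepts the removal with the
lowest AICc when it strictly improves the current one, and stops otherwise;
ties are broken by family input order, so the procedure is deterministic.
The route requires `n > p + 1`; when the input violates that, the families
with the smallest column totals are dropped first, down to `p = n − 2`
(recorded in the trace as `predropped`).

When `k` is so large that the correction is undefined (`n − k − 1 ≤ 0`) the
AICc is treated as `+∞` rather than an error inside the selection loops: the
saturated starting models of the study regime (p = 55, n = 57) live in this
zone, and the first accepted removal brings the criterion back into its
domain. A perfect fit (RSS = 0) maps to `−∞`.

**Clustering route.** Families are discretized into relative-abundance
classes: a family observed at frequency `f` gets
`clamp(round_half_up(f / 0.30), 1, 3)` classes, so ubiquitous families get
three and families near 30% keep one. Present samples are rank-ordered by
relative abundance (raw counts when depths are equal) and cut into
contiguous blocks whose sizes differ by at most one, larger blocks at the
low-abundance end; ties keep input order. The per-family class system is
exhaustive and exclusive over the presence vector by construction.

A partition of classes into groups defines each sample's **assembly motif**:
the set of groups with at least one present class (the empty motif is a
legitimate motif with its own mean). The model predicts each sample by the
mean of `y` over its motif; R² = 1 − RSS/TSS is the inter-motif variance
fraction and the F-ratio is the one-way ANOVA F across observed motifs.

## Partition search

The search is a greedy divisive hierarchy. Level 1 puts all classes in one
group. Level g+1 seeds a new group by relocating a single class and refines
with first-improvement local moves (any class to any group, input order,
repeated until no move strictly increases R²; moves that would empty their
source group are skipped), optionally extended with pairwise class swaps.
Because a single seeded start can stall in a local optimum, the level keeps
the best refined result over the five best-scoring seed classes plus ten
deterministic random initial partitions (fixed internal stream, so the
algorithm remains deterministic). Seeding splits one group, so the motif
partition of samples refines across levels and R² is non-decreasing in the
group count.

The group count is selected by AICc with `k` = number of observed motifs.
An exhaustive oracle enumerates set partitions into exactly `g` nonempty
groups via restricted growth strings (guarded at 10⁶ partitions) and is used
in tests to audit the greedy search: on random instances with ≤ 8 classes
and ≤ 3 groups the greedy level matches the oracle's maximal R² in ≥ 95% of
instances and never exceeds it.

The motif structure itself regularizes the search on large encodings: moving
an irrelevant class into a signal group usually merges its samples into
existing motif cells with wrong means, sharply lowering R², so pure
in-sample maximization rarely pollutes signal groups. Splitting moves can
still overfit at high group counts; the family-level pruning and the
AICc-over-motifs level selection are the counterweights.

## Group ordering and the residual group

Groups are ordered by explanatory contribution. The residual group is the
one whose dissolution (merging its classes into the best-absorbing other
group) costs the least R²; since merging G into H and H into G yield the
same partition, such drops tie, and ties are broken by the variance
explained by the group's own presence/absence split (lowest first), then by
input order. Non-residual groups are then sorted by the R² drop when merged
into the residual, classes within a group by the R² drop when the single
class moves to the residual; residual classes keep input order. Labels are
reassigned A, B, … with the residual last. Groups whose distinction is below
the noise floor (e.g. a very weak effect next to a dominant one) are not
reliably separable from no-effect groups by any of these criteria; the
ordering is then arbitrary among them.

## Family selection on the clustering route

Only families whose every class sits in the residual group are candidates.
A candidate is removed when dropping all its classes leaves every sample's
motif unchanged (which also guarantees the non-residual groups are
untouched) and the AICc improves, where `k` is the number of remaining
families — a different `k` convention from level selection, kept
deliberately. Because qualifying removals leave RSS unchanged, fewer
families always improves this AICc; when both values sit in the
undefined-correction zone the comparison is decided by `k` alone. The final
fit reports `reported_df = p_initial − families_kept` alongside the
conventional residual df, mirroring the two degrees-of-freedom conventions
found in published summary tables without asserting which is canonical.

## Group effects and route comparison

Per-group percent effects are
`100 × (mean(y | G present) − median(y)) / |median(y)|`; pairwise
interactions use the double difference over the four exclusive presence
cells. Significance comes from a sequential (Type-I) ANOVA of `y` on the
binary group-presence factors in explanatory order, main effects before all
pairwise interactions, at the study-wide threshold p < 0.001. Groups present
in all or no samples carry no contrast and are dropped with a warning; a
zero median switches effects to raw units. The percent-effect and
interaction definitions are explicit package choices validated against
synthetic truth, not a reconstruction of any particular published ANOVA
formula.

`compare_key_families` crosses the kept sets of the two routes into
both / linear_only / clustering_only / neither, with the coefficient sign
and t-test significance on the linear side and the best group letter plus
its ANOVA significance on the clustering side. `median_abundance_check` is a
tie-corrected Kruskal–Wallis comparison of per-family total reads between
key and non-key sets.

## Synthetic data

`simulate_abundance_table` draws, per family, a target observation frequency
`f_j ~ Uniform(0.3, 1)` and a log-abundance location `μ_j ~ N(ln 3, 1.8)`
once; presence is Bernoulli(f_j) per sample, positive counts are rounded
log-normals `exp(N(μ_j, σ))` with dispersion σ = 1 by default, and each
sample is multinomially resampled to a fixed depth (3000 reads by default),
mirroring rarefaction by random read selection. Families drawn present but
allotted zero reads get one read back from the largest cell so realized
presence matches the Bernoulli draw. The defaults reproduce the target
regime qualitatively — depths exactly 3000, frequencies 30–100%, abundances
spanning roughly 1 to ~2000 reads with low medians — but the generator does
not emulate compositional correlations between families, phylogenetic
structure, or community dynamics over incubation; passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
regime, not fidelity to any particular real survey.

`plant_partition_property` assigns key classes to groups and sets
`y_i = mean(motif_i) + N(0, noise_sd)`, with motif means given directly or
additively (baseline + group effects + pairwise interaction terms), plus an
optional linear per-family component. `simulate_study` plants one middling
class from each of the first `groups × 2` families, round-robin, with
additive effects (4, 2, −1, …) chosen so all motif means are distinct, and
noise defaulting to 5% of the motif-mean spread. One integer seed drives all
draws through a single generator stream.

**Recovery metric.** The planted partition defines group identities only
over the key classes — every other class is residual by construction — so
recovery is scored as the adjusted Rand index between planted and recovered
group labels restricted to the key classes, with the tree fit at the planted
group count + 1. At the default noise this ARI is 1.0 in essentially all
seeds; at zero noise the refit is exact (ARI = 1, R² = 1).

## Numerical choices

* R² in the search loop uses the fast formula `Σy² − Σ(cell sums²/counts)`;
  final fits recompute RSS from residuals, so a cell-constant `y` yields
  R² = 1.0 exactly. The two routes agree to 1e−10 (tested).
* "Strictly increases" in the local search means by more than 1e−12.
* All ties (seeding, moves, removals, ordering) break by input order.
* Problem sizes in tests and in the acceptance script (100 random search
  instances at n = 30, 20 recovery simulations at 60 × 20, one study-scale
  run at 57 × 60) were chosen as the smallest sizes at which each property
  is statistically meaningful.
* Serialized floats carry 12 significant digits, making identical runs
  byte-identical.

## Known limitations

* The greedy hierarchy is audited, not exact, above the oracle guard; at
  high group counts on large encodings its AICc-selected level may be finer
  than the generative truth (splitting moves fit noise), which family
  pruning only partly undoes.
* Backward selection on the linear route prunes a pure-noise predictor only
  when the AICc penalty relief exceeds its spurious fit (~85% of draws per
  predictor); this is a property of AICc selection itself.
* Unobserved motifs at prediction time would be mapped to the grand mean;
  the package currently only fits in-sample.
* Percent effects require a nonzero median property.
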