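# funcmotif

Attribution of soil ecosystem functions — basal respiration, straw
mineralization and the priming effect — to the composition of microbial
communities, by two deliberately contrasted statistical routes:

* **Linear (composition-effect) route.** The property *y* is modeled as
  `y = β₀ + Σⱼ βⱼ xⱼ + ε`, a multi-linear combination of family relative
  abundances *xⱼ*, without interactions. Irrelevant families are pruned by
  backward stepwise selection under the small-sample Akaike criterion
  `AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)` with *k* = families + 1
  (intercept). This route captures effects that accumulate linearly with
  abundance.

* **Clustering (interaction-effect) route.** Each family's abundances are
  discretized into 1–3 equally-populated relative-abundance classes
  (`family|c/k`, centered on ~30% observation frequency). Classes are
  partitioned into functional groups A, B, … so that the **assembly motif**
  of a sample — the set of groups with at least one present class — explains
  *y* by motif means; R² is the inter-motif variance fraction. The partition
  is searched by a greedy divisive hierarchy audited against an exhaustive
  set-partition oracle, the group count is selected by AICc over observed
  motifs, and families whose classes all sit in the residual group are
  pruned under an AICc whose *k* is the remaining family count. This route
  captures non-linear effects of co-occurrence.

Post-fit, each group's effect is expressed as a percentage of the median
property via sequential (Type-I) ANOVA with pairwise interactions, the two
routes' key-family sets are crossed, and a Kruskal–Wallis test checks that
being key is unrelated to total abundance.

A first-class synthetic-data generator emulates the target regime (57
samples × 60 families rarefied to 3000 reads, family frequencies 30–100%,
heavy-tailed abundances) and plants a known class→group partition so that
parameter recovery can be measured by adjusted Rand index.

## Worked example

```sh
python examples/clustering_route.py
```

```
level  groups  motifs  R^2      AICc
    1       1       1  0.0000     107.7
    2       2       2  0.7996      18.3
    3       3       4  0.9366     -42.8
    4       4       8  0.9812    -101.9
    5       5      16  0.9937    -137.7
    6       6      26  0.9982    -156.2 <- selected

groups (most to least explanatory): ['A', 'B', 'C', 'D', 'E', 'F'], residual = F
  group A: ['fam01|2/2', 'fam04|2/3']
  group B: ['fam02|2/3', 'fam05|2/2']
  group C: ['fam06|2/2', 'fam03|1/1']
  ...
family selection removed 45, kept 15 of 60
R^2 = 0.998, F = 692.8, AICc = -213.3 (k = 15 families), reported df = 45
adjusted Rand index vs planted partition: 1.00
```

Reading: on a synthetic 57×60 community whose property was generated from
three planted groups (each two abundance classes) plus 5% noise, the greedy
hierarchy's R² rises with the number of groups, the AICc picks the finest
level, ordering puts the three planted groups first (A, B, C exactly match
the planted classes), and family pruning discards the 45 families that never
influence any assembly motif. An ARI of 1.00 against the planted partition
means the functional structure was recovered exactly.

The other scripts in `examples/` walk through dataset simulation,
discretization, the linear route, and the cross-route effects report.

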