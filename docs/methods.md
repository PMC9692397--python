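# Methods

This note documents the models, decision rules, numerical choices and
known limitations of `hormonet`. It describes what the code computes;
every number quoted here is produced by the test suite or
`scripts/acceptance.py`.

## Differential expression

The DE stage is a deliberately simple negative-binomial Wald test, not a
re-implementation of any particular DESeq-era tool. Its job in this
pipeline is to supply a sound DE gene list; the scientific contribution
lives downstream.

* **Normalization.** Median-of-ratios size factors: the reference is the
  per-gene geometric mean over samples, restricted to genes positive in
  every sample; a sample's factor is the median count-to-reference ratio.
  Factors are rescaled to geometric mean 1 for identifiability. If no
  gene is positive everywhere, the function errors and tells the caller
  to supply factors externally rather than silently switching reference.
* **Dispersion.** One α per gene (variance μ + αμ²), method of moments
  pooled over all four conditions: within-condition residual sums of
  squares, corrected by n_c/(n_c−1) and with the size-factor (Poisson)
  term subtracted, divided by Σ n_c μ_c². Floor α ≥ 10⁻⁸. No shrinkage
  across genes.
* **Test.** Wald statistic on the difference of condition log-means with
  the NB delta-method variance, referred to a **t distribution with
  N − 4 degrees of freedom** (the pooled within-condition df, 8 at the
  default 3 replicates). The t reference was chosen at design time: with
  a moment dispersion estimated from 8 residual df, a normal reference is
  anti-conservative. Measured on a 5000-gene null simulation the
  raw-p < 0.05 rate is ≈ 0.048–0.057, within three binomial SEs of
  nominal.
* **Zero handling.** Condition means are clamped at 0.5 normalized counts
  inside the test statistic only when below that value; the displayed
  log2 fold change uses a pseudo-count of 0.5 throughout. The pseudo-count
  affects display, not the decision to call a gene DE.
* **Multiplicity.** Benjamini–Hochberg within each contrast
  (statsmodels' step-up implementation); a gene is DE at FDR ≤ 0.05,
  and "DE overall" means DE in at least one of the three contrasts.
* A precomputed DE table can be passed to `CrosstalkModel.fit`, which
  then skips this stage entirely.

## Response-type classification

Condition values entering the classifier are **means of size-factor
normalized replicate counts**, one value per condition. Each gene's four
means are standardized to mean 0 and **population** SD 1 (denominator 4).
Standardization makes the classification invariant under affine
transformations of the raw means; constant profiles are skipped with a
warning.

Letters for T₃, CORT and T₃+CORT are called from Δ_X = z_X − z_CTRL at
threshold τ = 0.9: "u" above, "d" below −τ, else "n". All inequalities
are strict, so boundary values take the weaker call ("n", "N",
lowercase) — a deterministic tie-break.

The fourth (crosstalk) letter is assigned by a decision tree on
d_T = |z_TC − z_T3|, d_G = |z_TC − z_CORT| at threshold t = 0.9, with
X = #{distances > t}:

* **Both hormones act, opposite directions** → antagonism: "A" if X = 2
  else "a".
* **Both act, same direction** → compare the cotreatment with the
  additive prediction Δ_add = Δ_T3 + Δ_CORT: "N" if
  |Δ_TC − Δ_add| ≤ t; else "P" if |Δ_TC| > |Δ_add| (potentiation);
  otherwise antagonism ("A"/"a" by X).
* **Exactly one hormone acts** (effect Δ_H, distance d_H): "N" if
  d_H ≤ t; else synergy ("S" if the cotreatment amplifies the effect —
  same sign, |Δ_TC| ≥ |Δ_H| — with X = 2, "s" with X = 1); a diminished
  or sign-reversed cotreatment is antagonism ("A"/"a" by X).
* **Neither hormone acts alone but the cotreatment does** → strict
  synergy: "S" if X = 2 else "s".

τ is not independently documented for the original analysis; it defaults
to t (single-threshold parsimony) and is separately configurable.

Two geometric facts about this rule system, both consequences of the
SD-1 constraint, are worth knowing:

* An all-"n" letter triple is **impossible** at τ = 0.9 (three values
  within 0.9 of z_CTRL cap the sum of squares at 3.24 < 4), so every
  standardizable profile receives a call at default thresholds. The
  "unclassified" path exists for constant profiles and for larger τ.
* Some response types occupy **slivers of z-space**. For `nnds` the
  constraints (|Δ_T3| ≤ τ, d_T ≤ t, |Δ_TC| > t, SD = 1) admit solutions
  only within ~0.006 of the thresholds; `dddP`/`uuuP` are pinned within
  ~0.01–0.02. These types are intrinsically fragile to replicate noise —
  a property of the rule system, not of any implementation.

The category lookup (A: T₃ only; B: CORT only; C: both, independently;
D: T₃-regulated, influenced by CORT; E: CORT-regulated, influenced by
T₃; F: both regulate, with crosstalk; G: regulated only jointly) is a
fixed table. `duna` and `uuna` are absent from the original category
table; this package places them in F (both hormones regulate) and flags
them. Four-letter patterns outside the 26 observed types can arise under
noise; they are tallied under their own name with category "other"
rather than forced into a canonical cluster.

## Archetypes

`make_archetypes()` returns one canonical z-quadruple per response type,
each verified to classify to its own name (round-trip property). The
constants were found by numerically maximizing the minimum
**noise-normalized** decision margin — each compared quantity's distance
from its threshold divided by that quantity's sampling SD under NB
replicate noise at the planted means — so each representative sits where
the classifier is best protected. The plain geometric margin is stored
on each profile (0.17–0.9 for 23 types; the three boundary-pinned types
above have margins < 0.02).

## Synthetic data

* **Counts.** NB(μ, α) with variance μ + αμ², default dispersion
  α = 0.1, four conditions × 3 replicates. Per-sample size factors are
  drawn uniform on [0.7, 1.4] and rescaled to geometric mean 1. One RNG
  stream per dataset plus a deterministic child stream per gene, so a
  fixed seed reproduces counts byte-for-byte.
* **Planting.** A planted gene's condition means are **affine in its
  archetype z-profile**: μ_c = M(1 + κ z_c). This is the unique shape
  (up to affine maps) whose z-transformation recovers the archetype
  exactly in the noise-free limit — the classification is
  affine-invariant, so any non-affine embedding (e.g. multiplicative on
  the log scale) distorts the planted type and makes some labels
  unrecoverable in principle. κ is solved from
  (1 + κ z_max)/(1 + κ z_min) = 2^(e·(z_max − z_min)), so the
  effect-size parameter e is the planted log2 fold change between the
  archetype's extreme conditions per unit of z-spread; the construction
  keeps every mean positive for any e, and e = 0 gives flat profiles.
* **Composition.** Default 1000 genes, 85% unregulated — matching the
  regulated fraction of the liver study this design emulates (~3k DE of
  ~20k genes) and preserving the non-DE majority that median-of-ratios
  normalization assumes. Planted types are drawn, by default, with the
  study's observed abundances (category totals 2180/27/416/324/20/35/85
  spread evenly over each category's clusters): response types are very
  unevenly populated in real data, with ~70% of DE genes regulated by T₃
  alone. Uniform planting over the 26 types is available via
  `planted_type_weights` and is the harder recovery benchmark: with it,
  full-label recovery at effect 3, α = 0.05, n = 3 measures ~68%,
  because NB noise (~0.2–0.4 z-units on high-mean conditions) exceeds the
  geometric margin ceilings of roughly ten types (see above). Under the
  study-abundance default the measured recovery is ~94–95% of 3-letter
  patterns and ~92–93% of full labels among DE-called planted genes.
* **Pathways.** Poisson-sized random gene sets with Bernoulli
  intra-pathway edges (density 1 ⇒ complete graph). `focus_genes` with
  `focus_weight` > 1 over-samples chosen genes into membership,
  emulating the co-occurrence of functionally related regulated genes in
  curated collections; uniform placement carries no enrichment signal,
  so neighborhood permutation z-scores on unfocused collections are
  correctly near 0.
* **What the generator does not emulate:** read-level artifacts
  (sequencing error, mapping), batch effects, gene-length or GC bias,
  correlated genes, and count outliers. Passing recovery tests therefore
  demonstrate correctness of the pipeline's logic under its own model,
  not robustness to those real-data pathologies.

## Network analysis

Edges are undirected, unweighted, deduplicated; self-loops are dropped at
load; gene identifiers are matched case-insensitively (inputs are
pre-mapped orthologs). The merged network is the union of pathways whose
member set intersects the DE genes. Hubs are nodes with degree ≥ 20.
Chains are connected components (size ≥ 2) of the subgraph induced on
crosstalk genes (`crosstalk_only`) or all DE genes (`all_de`) — the
switch exists because a chain reported in the original analysis contains
one T₃-only gene, so the published rule is ambiguous; components are
sorted by size, ties by smallest member.

The permutation test statistic is the number of labeled (by default
crosstalk-DE) nodes among the first and second BFS neighbors, jointly, of
the seed set. The null re-assigns the labeled set (same cardinality)
uniformly over non-seed nodes; the null statistic is hypergeometric, and
sampled null moments are verified against that expectation. When the
number of possible assignments is ≤ 10⁴ the null is enumerated
exhaustively and the p-value is exact (#{null ≥ obs}/#assignments);
otherwise the empirical p is (1 + #{null ≥ obs})/(1 + B). A
degree-preserving rewiring null (`null_model="degree_rewire"`) is
available as a sensitivity check; it is much slower and intended for
small permutation counts. Degenerate cases (no labeled nodes, zero null
SD) are flagged rather than yielding an undefined z.

## Problem sizes

The test suite and acceptance script run at desk scale by design:
recovery uses ten datasets of 500 genes (425 null), calibration one
dataset of 5000 null genes, the end-to-end network run 2000 genes and 60
pathways with 10⁴ permutations. The pipeline itself is vectorized per
stage and handles genome-scale matrices (~20k genes) in seconds.

## Known limitations

* The DE stage omits dispersion shrinkage, independent filtering and
  fold-change shrinkage; at n = 3 its per-gene dispersion estimates are
  noisy, which the t reference compensates for on average but not per
  gene.
* The crosstalk tree is a rule system with hard thresholds; genes near
  boundaries flip between adjacent types under replicate noise, and the
  three sliver types (`dddP`, `uuuP`, `nnds`) cannot be called reliably
  at realistic noise levels.
* Orthology mapping, GO enrichment, KGML parsing and graph layout are
  out of scope; inputs are pre-mapped identifiers in GMT/SIF/TSV form.
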