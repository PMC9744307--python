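# Methods

`tadcoord` implements the statistical layer of a cohesin-perturbation
experiment: given a TAD partition, a transcript annotation,
differential-expression tables, nascent-transcription 3′-end signal,
chromatin-loop calls and per-allele FISH geometries, it asks whether
misexpressed genes cluster and change coordinately within TADs, whether
they sit near loop anchors, whether a co-depletion rescues them, and
whether domain contacts change in single cells. This note records the
models, conventions and numerical choices; it states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and the DEG threshold

All intervals are BED-convention 0-based half-open `[start, end)`;
annotation tables carry 0-based TSS positions. A gene is a DEG when its
adjusted p-value satisfies `padj ≤ α` with α = 0.01 **inclusive** (the
threshold is described as a *minimum* adjusted p-value, which we read as
≤). Missing `padj` never counts as significant but the record is kept —
the rescue classifier needs genes that drop out of the significance
call. TADs must form a non-overlapping partition per chromosome;
overlap is a hard error because every per-TAD statistic assumes each
gene has at most one home.

## Dominant-TSS calling

Promoter signal for a transcript is the sum of 3′-end counts in the
strand-aware window from the TSS to +150 nt downstream. The window is
taken inclusive of both the TSS base and the +150 base (151 positions),
mirrored toward lower coordinates on the minus strand; the literature
phrase "TSS to +150 nt downstream" does not fix the endpoints, so this
convention is fixed here and configurable (`AnalysisConfig.tss_window`).
A TSS with ≤ 9 window counts is inactive (active ⇔ count ≥ 10). Among a
gene's active transcripts the dominant TSS is chosen by a total order:
highest count, then furthest-upstream TSS (strand-aware), then longest
transcript, then lowest numeric portion of the gene identifier — so the
call is invariant to input order, which the suite checks by shuffling.
Dominant TSSs of *different* genes sharing a start position are each
kept (one call per gene) and flagged in the log; dropping one of them is
not well defined from the published description. Counts are pooled
across samples *before* calling via `SignalTrack.sum_tracks`.

## Clustering statistic and its null

The clustering statistic is the unweighted mean over TADs of the
percentage of each TAD's genes carrying the positive label — DEG among
active genes, or active among all genes, depending on the analysis.
TADs with zero assigned genes are dropped; genes outside every TAD are
excluded from the statistic but participate in the shuffle (in the real
data ~95% of active genes fall inside a TAD). The null permutes labels
uniformly across the gene universe keeping category counts fixed; the
p-value is the raw fraction of null draws at or above the observed value
(ties count toward the tail; p can be exactly 0, and a `(r+1)/(n+1)`
estimator is available as an option).

**Degeneracy.** When all TADs contain the same number of genes, the
mean of per-TAD percentages equals the global positive fraction for
*every* labeling — the statistic is constant and the test has no power.
Sensitivity comes from covariance between label placement and per-TAD
gene count: DEGs packed into gene-sparse TADs push the observed mean
above the null. The strong-clustering acceptance scenario therefore
confines DEGs to the gene-sparsest 10% of TADs (20 genes each, fully
DEG, against 90 TADs of 40 genes), where the observed statistic exceeds
every one of 1,000 shuffles and p = 0. A degenerate label set (all
genes positive) is an error rather than a trivial p = 1.

## Coordination score and its null

The coordination score of a TAD is the majority fraction of its DEG
directions, `100 × max(#up, #down) / #DEGs` — the unique affine score
with 50% = even split and 100% = unanimous. It is computed over TADs
with ≥ 2 DEGs (the score is undefined below that; the eligibility
threshold is configurable). The profile reports the unweighted mean and
counts in five upper-inclusive 10-point bins (50–60 … 90–100). The null
shuffles directions among DEG slots only, keeping TAD membership and
per-TAD DEG counts fixed; the binwise comparison reports observed
count, null mean, and percentile-rank p in both directions. If every
DEG shares one direction the permutation cannot vary and p = 1 with a
warning.

## Enrichment and overlap tests

Anchor distance is TSS-to-interval-edge with inside = 0 — the strictest
reading of "within N kb of a loop anchor"; a TSS on a chromosome with
no loops has missing distance and counts as "far" when dichotomized.
Proximity enrichment is a Fisher exact test on near/far counts at 5 kb
(and 200 kb), reporting the one-tailed (enrichment) and two-sided p.
The distance–fold-change correlation is Spearman's rank correlation of
anchor distance against |log2FC| by default (plots of "fold change"
versus distance are unsigned; a signed mode exists). Set-overlap tests
use the upper hypergeometric tail on a fixed 20,000-gene universe; the
supplied group totals back the proximity tables, the fixed universe only
the set-overlap tests. The published worked examples — p = 3.93×10⁻²⁶
for a 578-gene overlap of 1,876 vs 4,195 and p = 0.51 for 405 of 1,931
vs 4,195 — reproduce to printed precision and are frozen in the suite.

## Rescue classification

For each single-knockdown DEG: **fully rescued** ⇔ `padj_double > α` or
missing (a gene absent from the double table also passed no
significance call and is fully rescued, with a warning; configurable to
an error); **partially rescued** ⇔ still significant, same sign, and
|log2FC| *strictly* smaller ("diminished" is read strictly — equality is
not rescued); everything else is **not rescued**, with significant sign
flips flagged rather than merged. The three categories always partition
the DEG set.

## FISH statistics

Alleles are post-segmentation summaries: each domain a sphere (centroid
+ radius in nm) or precomputed volumes. Contact ⇔ boundary gap ≤ 250 nm
(inclusive; overlapping signals always contact). The published methods
text defines contact as "> 250 nm signal colocalization", which
contradicts the results' "contact cutoff of 250 nm"; the ≤ reading is
used because it is the only one under which cohesin loss reduces
contact, matching the reported deltas. Overlap fraction is the
closed-form sphere-intersection (lens) volume over the **smaller**
domain volume (union / fixed-domain denominators selectable; no
published choice is asserted). Distributions are compared by two-sided
Mann–Whitney with tie correction, cross-checked against exhaustive rank
enumeration at 3-vs-3. The gene-vs-domains configuration call is
"interacting" when a strict majority (> 0.5) of the gene sphere's volume
lies in the union of the two flanking domains — exactly half is
"exclusion". The union volume uses closed-form inclusion–exclusion when
the domains (or their gene overlaps) are disjoint and a deterministic
midpoint-grid quadrature (default 48³ cells over the gene sphere) when a
triple overlap exists, accurate to ~1–2% which comfortably supports a
0.5 threshold away from the knife edge.

## Synthetic data: what it emulates and what it does not

The generator is the stated world the tests run in. Defaults: TADs of
1 Mb (the scale of the worked example TAD) tiled on one synthetic
chromosome; Poisson(5) genes per TAD on a 1 kb grid (so promoter
windows never straddle genes); 1–3 transcripts per gene with ~40% of
extra transcripts sharing the base TSS to exercise tie-breaking.
DEG tables place `round(deg_rate × n)` DEGs, drawn with weight
`clustering_weight` inside a designated `hot_tad_fraction` (default
10%) of TADs; each TAD has a latent majority direction matched with
probability `coordination`; `padj` is log-uniform on (0, α] for DEGs and
uniform on (α, 1] otherwise — only threshold crossings matter
downstream. Promoter counts are negative-binomial (shape 10) for active
genes and ≤ 9 for inactive ones, multinomially scattered at single-base
resolution. FISH alleles draw the boundary gap at or below the cutoff
with probability `contact_prob`, else cutoff + Exp(mean 500 nm), with
±10% radius jitter around 400 nm (roughly the scale of a ~1 Mb domain
under the imaging resolution). Loops place an upstream anchor within
2 kb of a tunable fraction of DEG (and non-DEG) TSSs with the partner
anchor 200 kb away.

Under null settings (`clustering_weight = 1`, `coordination = 0.5`) both
permutation p-values are uniform on [0, 1]; the suite verifies this by
Kolmogorov–Smirnov at the 1% level over 200 replicate simulations
(n_perm = 100 per replicate to stay inside the CI time budget; the
lattice bias of the percentile-rank p at that resolution is ~0.005,
far below the KS critical value).

What a green test does **not** establish: the generator draws gene
positions independently of expression (no gene-density/GC structure), a
single chromosome, no covariance between anchor distance and fold-change
magnitude (so the distance–|log2FC| Spearman analysis is a null
demonstration on synthetic data), spherical segmented domains (no
irregular voxel masks), and no read-level noise — alignment,
differential-expression fitting and image segmentation are upstream of
this package by design.

## Known limitations

* The clustering test is powerless on equal-gene-count TAD partitions
  (see above); with real, size-heterogeneous TADs the statistic behaves
  as intended.
* Percentile-rank p-values are granular at 1/n_perm; use the add-one
  estimator for downstream multiple-testing corrections that dislike
  exact zeros.
* Permutation loops are plain (not vectorized across permutations);
  at genome scale (~20k genes, n_perm = 1000) they run in seconds,
  which is the intended regime.
* The grid quadrature for triple sphere overlaps is O(grid³); keep the
  default grid unless configurations sit near the 0.5 boundary.
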