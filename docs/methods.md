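# Methods

This note documents the models and procedures `snpannot` implements, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic-data tests do and do not establish.

## Variant-to-gene mapping

Variants are resolved to 1-based coordinates through a plain rsID→(chrom,
pos) index table; coordinate queries pass through with a synthesized
`chrom:pos` identifier (chromosome names canonicalized by stripping any
`chr` prefix).  Mapping applies three rules with strict precedence — a
variant's gene set comes only from the winning tier:

1. **Coding.**  Match against the coding-consequence table by rsID first,
   then by exact chromosome + position.  All coding genes at the position
   are kept.
2. **eQTL.**  Match by rsID against the eQTL table restricted to the
   user-selected tissues; the mapped set is the union of target genes over
   those tissues.  eQTL records are assumed pre-thresholded (significant
   pairs); no additional P-value filter is applied.
3. **Positional.**  Scan windows d = 50, 100, …, 500 kb and stop at the
   first d with at least one gene whose distance to the variant is ≤ d.
   *All* genes within that d are returned, together with the window size.
   Distance is to the nearest gene-body boundary (start/end), zero inside
   the body, strand- and TSS-agnostic.

No gene within 500 kb ⇒ tier `unmapped`: a value, not an error.  Unmapped
variants are excluded from gene-based statistics but retained in direct
rsID catalog lookups and SV proximity, and always reported.

## Sampling correction

A variant mapped to k genes would contribute k times to any gene-level
statistic.  Both downstream analyses therefore draw, per iteration, one
gene uniformly at random from each variant's mapped set (`iterations`
default 500) and average the per-iteration statistic.  The draw stream is
shared: trait fractions and enrichment called with the same seed see the
same gene assignments.  All randomness flows from a single master seed;
per-stage streams are derived from the seed plus a stage-name hash, so any
stage can be re-run in isolation with identical results.

## Trait-catalog fractions

The catalog is filtered at load time to associations with P < 9×10⁻⁶
(strict), the inclusion rule of the curated association registry the table
emulates.  Per iteration, an input SNP supports a trait if (a) its rsID
appears in the catalog for that trait, or (b) its sampled gene is among
the union of the trait's reported genes — OR-ed, so a SNP counts once.
The fraction is supporters / (all input SNPs, including unmapped).  The
mean and population SD over iterations are reported; traits with zero
support are omitted.  Supporter counts are accumulated as integers and
divided once, so the degenerate all-single-gene case is exactly seed- and
iteration-count-invariant.

## Gene-set over-representation

Per iteration the deduplicated sampled gene set is tested per term with the
one-sided hypergeometric upper tail P(X ≥ k) (survival function evaluated
in log space; k = 0 returns exactly 1).  The universe is the source's
annotation corpus — the union of its term gene sets — matching the
"annotated genes" default of standard over-representation services; it is
stated in the output header.  Term-size bounds default to 3–1000.
Per-term P-values are averaged arithmetically across iterations
(equivalently: a weighted mean over distinct sampled gene sets, which is
faster and exact in the degenerate case), and Benjamini–Hochberg FDR is
applied once, per source, to the averaged values.  Results are sorted by
mean P, ties by term id.  The FDR threshold for the "significant" table
and for condensation input defaults to 10% and is configurable.

## Term condensation

**Information content.**  Annotation counts are propagated to all is_a
ancestors; p(t) = count(t)/count(namespace root), IC = −ln p(t), computed
per namespace over the bundle's full annotation corpus (not just the
enriched genes).  Terms with zero propagated count have infinite IC and
raise a defined error on access.  Only is_a edges are traversed.

**Lin similarity.**  2·IC(MICA)/(IC(t1)+IC(t2)) with MICA the common
ancestor of maximal IC; 0 by convention when both ICs are 0; cross-
namespace pairs are an error.  The matrix is exactly symmetric with unit
diagonal for terms of positive IC.

**Redundancy masking.**  Terms are processed by ascending P-value (ties by
term id); a term is masked when its similarity to an already-kept term
reaches the cutoff (default 0.7, the "medium" setting of the standard
redundancy-reduction tool); the most similar keeper becomes its
representative, so a representative's P-value never exceeds its masked
term's.  Masked terms remain in all tables, flagged.  Kept terms are
embedded in 2-D by classical (Torgerson) MDS: double-center the squared
distance matrix (distance = 1 − similarity), eigen-decompose, scale the
top two eigenvectors by √eigenvalue.  On an exactly Euclidean 2-D input
this reproduces the distances to machine precision.

**Clustering.**  Ward-D2 agglomeration on the Lin distance matrix (scipy's
Lance–Williams update on a precomputed distance input, matching `ward.D2`
behavior in the R ecosystem).  The cut is adaptive rather than a single
height: recursive descent from the root splits a branch when its own merge
height exceeds the mean + 1 SD of the merge heights strictly below it
(with an ulp-level relative slack so exactly-tied heights do not split);
clusters smaller than `min_cluster_size` (default 3) are merged into the
cluster with the highest average inter-cluster similarity.  This is a
deliberately simple member of the dynamic-tree-cut family: it recovers
clean block structure exactly (see the acceptance suite) but does not
implement the published hybrid algorithm's PAM-like reassignment stage, so
on noisy dendrograms the published algorithm and this one can differ.

**Wordclouds.**  Term names are lowercased, split on non-alphanumerics,
and counted per cluster after removing a small built-in stopword list
(function words plus near-universal ontology fillers like "process" and
"regulation"; configurable).

## Regional statistics

**P-value profile.**  The region is divided into `n_bins` equal-width bins
(default 20); each non-empty bin contributes its maximum −log10 P point
(ties → leftmost position); a least-squares polynomial of `degree` is fit
through the maxima on a rescaled predictor for conditioning, sampled on an
even grid, and clipped below at 0.  Fewer non-empty bins than
max(degree+1, 2) is an error advising fewer bins or a lower degree.  The
default degree 3 gives a smooth display curve; localizing an
asymmetrically placed peak needs degree ≥ 4 (a cubic cannot represent a
bump placed off-center), which is what the acceptance checks use.

**LD.**  r² is the squared Pearson correlation of dosage vectors over
pairwise-complete samples — invariant to allele-coding swaps (g → 2−g) and
symmetric.  Monomorphic comparators yield missing values; a monomorphic
target is an error.  r² was chosen over D′ as the field-standard measure
for regional display.

**Expression heatmap preparation.**  Per-gene z-scaling (population SD;
constant genes become all-zero rows and are flagged, not dropped), then
average-linkage hierarchical clustering on Euclidean distances for both
genes and tissues; the leaf orders are returned for rendering.  "Scaled"
and the linkage method are not pinned down by convention anywhere, so
z-score + average linkage is this package's choice.

## Association-file recognition

Name-based matching first (case-insensitive): chromosome ∈ {CHR, CHROM,
#CHROM, CHROMOSOME}, position ∈ {BP, POS, POSITION, BP_HG19}, P ∈ {P,
PVAL, P_VALUE, PVALUE, P_BOLT_LMM}; CHR+BP+P ⇒ PLINK 1.x dialect,
#CHROM+POS ⇒ PLINK 2.x.  Roles still open fall back to content heuristics
over sample rows, filled in a fixed order (chromosome: values within the
human chromosome vocabulary; position: integer column with the largest
range; P: float column within (0,1]).  Two equally plausible candidates
for a role abort with an ambiguity error — no silent guessing.

## Synthetic bundles and what the tests show

The generator divides each chromosome into fixed-width slots (≥ 1.2 Mb),
one gene (sometimes a tight pair) per slot, spaced so a variant's nearest
gene is always its own slot's gene.  That geometry lets it plant, exactly:

- coding variants (inside gene bodies, with decoy eQTLs on some to
  exercise tier precedence), eQTL variants (1–3 target genes in the
  configured tissues), positional variants at exact distances inside
  chosen 50 kb window rings, and variants with no gene within 500 kb;
- enriched terms whose gene sets are over-sampled from the mapped genes;
- catalog traits supported directly (rsID rows) and via reported genes;
- structural variants within 10 kb of chosen variants, the rest far away.

Defaults (4 chromosomes × 120 Mb, 300 genes, 80 variants, 15% coding, 25%
eQTL, 40 ontology terms per namespace, 3–12 genes per term, 500-iteration
sampling) were chosen so the query-to-universe ratio resembles a real
annotation corpus at desk scale: ~80 query genes against a 300-gene
universe gives planted terms hypergeometric P-values around 10⁻⁴–10⁻⁷,
comfortably separated from null terms without being trivial.  One integer
seed drives fixed per-component child streams, so bundles are
byte-reproducible and adding a fixture component never perturbs existing
ones.

The generator makes no attempt at biological realism beyond what the
statistics require: no LD structure between variants, no realistic MAF
spectrum or gene-length distribution, uniform annotation instead of the
real ontology's heavy-tailed term sizes, and a catalog far smaller than
the real registry.  Passing tests therefore demonstrate *correctness of
the computations and contracts* (tier precedence, window law, statistical
exactness, calibration, determinism) — not that any particular biological
discovery would replicate on real resources, which depend on specific
database releases.

## Known limitations

- Coordinates are single-build; no liftOver between genome versions.
- rsID resolution is a plain index table, not a dbSNP query.
- Enrichment is over-representation only (no ranked/GSEA statistics, no
  depletion), with BH correction rather than the multiple-testing scheme
  some hosted services use (stated in output metadata).
- Term condensation uses Lin similarity only, is_a edges only.
- The dynamic tree cut is the simplified variant described above.
- No plotting: the package emits the tables a renderer would consume.
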