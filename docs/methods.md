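# Methods

This note documents the models and procedures implemented in
`druggability`, the choices made where the design was genuinely open, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Problem setting

Given a pan-cancer tumor cohort with somatic mutations, mRNA expression,
and protein/phosphoprotein panels, the pipeline asks: which tumors carry a
biomarker that links them to a drug, with what quality of evidence, and is
that link on-label for the tumor's own cancer type or a repurposing
candidate?  The driver of every match is a curated variant/drug
knowledgebase in which each entry ties a molecular event in a gene to a
drug, a tumor-type context, a direction of effect (*sensitive* or
*resistant*), and an ordinal evidence tier

    preclinical < case report < clinical trial < FDA approved.

## Knowledgebase resolution

Entries identical in (gene, variant class, variant spec, drug, tumor type,
effect) are duplicates; only the highest-evidence one is retained.  The
sources behind such tables do not define a tie-break at equal evidence, so
the first entry in file order wins and a warning is logged.  Tumor-type
codes are free-form uppercase tokens, optionally validated against a
vocabulary; `UNSPECIFIED` marks preclinical entries whose cell-line or
xenograft context names no cancer type.

Variant classes cover exact missense changes (`V600E`), ambiguous
single-residue changes (`V600`, any substitution of that valine), codon
ranges for class-restricted events (`729-761:inframe_del`), loose
frameshift/nonsense categories with an optional position (`*` = any), exact
in-frame indels, and spec-less expression/copy-number/fusion flags.
Copy-number entries are representable but match only when a copy-number
call channel is supplied; none is wired by default.

## Mutation matching and call resolution

Matching is hash-table based: exact (gene, protein change) lookups,
(gene, reference amino acid, position) lookups for ambiguous specs, and a
per-gene linear scan of codon ranges.  Three deliberate conventions:

- Position-only matching requires the **reference** amino acid to agree:
  `V600` matches V600K but not A600K.
- Range matching uses the mutation's **start codon** only; a deletion
  partially overlapping a range counts iff its start lies inside.
- Frameshift/nonsense entries match by (gene, class, position), position
  optional.

Resolution per (sample, mutation): if any sensitive interaction exists, the
call is sensitive (sensitive-over-resistant); among effect-consistent
matches, the drug with the globally maximal evidence tier — any tumor
type — is chosen; the call is *cancer-type-specific* when the sample's own
cancer type appears among the matches at that maximal tier, otherwise the
drug is off-label (*non-specific*, the repurposing setting).  `UNSPECIFIED`
tumor types never confer specificity, since specificity is defined over
named cancer types attaining the top tier.  Equal-evidence drug ties keep
every drug on the call and designate the alphabetically first as chosen.

Cumulative tier summaries count a sample once, at its best tier, and only
sensitive calls count toward druggable fractions; resistant calls flow to
the co-occurrence report.

## Cohort quality control

Three filters, applied in order:

1. **Large/complex indels** — indels > 100 bp (strict) and any mutation
   class in a configurable complex-indel token list are dropped.
2. **Duplicate samples** — sample pairs with > 60% variant concordance are
   collapsed unless both have ≤ 5 variants.  The concordance denominator is
   not defined by convention, so the smaller sample's variant count is used
   (conservative: a contained duplicate is always flagged).  Of a flagged
   pair the sample with fewer variants is dropped; at equal counts the
   lexicographically later barcode goes.  Both choices are logged.
3. **Common variants** — population allele frequency > 0.05% *and* not
   pathogenic; a missing frequency is treated as rare.

## Expression outliers

For each knowledgebase expression-linked feature (gene, or `GENE:pSNNN`
phosphosite, which inherits its parent gene's direction by default), cohort
quartiles Q1/Q3 are computed across the post-exclusion pan-cancer cohort —
not per cancer type — with linear interpolation between order statistics
(the default of mainstream numeric stacks; all oracles use the same
convention).  The outlier score is

    score = (x − Q3) / IQR        (high direction)
    score = (Q1 − x) / IQR        (low direction)

and a sample is an outlier iff score > 1.5 (strict).  Features observed in
fewer than 10 samples are skipped; IQR = 0 suppresses calls with a warning;
missing values are ignored (protein panels are sparse by design).  Acute
myeloid leukemia samples are removed before quartiles by default.  Scores
are location-scale free, so calls are invariant to affine rescaling of a
feature.  Within each sample, calls get a dense rank (1 = highest score,
ties share).

## Proximity clustering

On each structure, the empirical pair p-value of two mutated residues is
the proportion of **all** residue-pair distances on that structure that are
≤ their distance; the background is per-structure, computed once, and not
refreshed between recursion rounds.  Pairs need p < 0.05 and distance < 5 Å
(both strict).  Residue–residue distance from a PDB chain is the minimum
inter-atomic distance; a precomputed distance table bypasses parsing.  No
sequence-separation filter is applied: adjacent residues are eligible.

Single-link agglomeration (connected components of the significant-pair
graph) forms initial clusters.  The centroid is the most recurrent member;
the "close to highly recurrent mutations" tie-break is operationalized as
the minimal recurrence-weighted sum of shortest-path distances to the other
members, with the smallest residue number as the final tie-break.  Members
within a 5 Å graph radius of the centroid form the focused cluster; the
remainder re-enters single-link clustering restricted to pairs among
itself, generation incrementing per round, until no significant pair
remains.  Singleton leftovers are discarded.

Label propagation is mutation-level: any cohort mutation at a member
residue of a sensitive-containing cluster that the knowledgebase does not
itself catalogue becomes *putative sensitive* (this deliberately includes
uncatalogued changes at a residue that also hosts a known mutation);
resistant-only clusters yield *putative resistant* calls only when they
share no member with any sensitive-containing cluster.  Putative calls
enter downstream summaries at a pseudo-tier (`hotspot3d`) strictly below
preclinical.  When a gene has several structures, each is clustered
independently and putative calls are unioned.

## Multi-omics integration

A sample has *complete profiling* when it appears in the mutation table and
both expression matrices (configurable).  A complete-profile tumor is
multi-omics druggable when sensitive calls support ≥ 2 of
{mutation, mRNA, protein}; phosphoprotein calls count as protein.  Sector
tables map tumors into exactly ten drug classes via the chosen drug's class
labels; within-class (multiple genes, one class) and cross-class links are
tabulated per tumor.  The co-occurrence report lists all unordered
within-sample alteration pairs, flagging sensitive+resistant pairs
(potential therapy failure) and sensitive+sensitive pairs across disjoint
drug classes (combination candidates).  A resistant call does not veto a
same-pathway sensitive sector entry; both are reported and the veto is left
to the user.

## Screen validation

Knowledgebase drugs map onto screen compounds by case-insensitive
name/synonym match or by gene-target agreement.  The global test compares
pooled LN(IC50) of (mutant line, mapped drug) measurements against the full
background — every (line, drug) measurement, mutant or not, including the
tested points themselves (the literal reading of the background
definition).  Per (mutation, drug) tests require ≥ 5 mutant lines and use
that drug's own background.  The Mann-Whitney U test is two-sided: exact
for tie-free groups of ≤ 8, otherwise the tie-corrected normal
approximation with continuity correction.

Expression validation computes per-probe outlier scores using the cell-line
panel itself as the reference cohort, then fits ordinary least squares
LN(IC50) = B·score + a per probe/drug with ≥ 5 lines, skipping
zero-variance scores.  A gene is *validated* iff at least one probe has
p < 0.05 and B < 0.  No multiple-testing correction is applied across this
combination family — deliberately, to mirror the screening analyses this
emulates; consumers should treat per-combination p-values accordingly.

## Demographics

Per (cancer type, druggable gene) cell, between trait categories A and B:

    log2( (druggable A / A) / (druggable B / B) ),

±∞ clamped to ±3.  Eligibility: ≥ 20 tumors per category per cancer type;
a gene druggable in ≥ 40 tumors (race) or ≥ 150 (sex) cohort-wide; ≥ 10
carriers of the gene in the cancer type for a cell to be computed.  The sex
analysis excludes sex-specific cancer types (BRCA, CESC, PRAD, OV, UCEC,
UCS by default).  With more than two categories the two largest anchor the
contrast (A = larger), configurable.  Two-sided Fisher exact tests per cell
with Benjamini-Hochberg FDR across all cells of the matrix at q < 0.05.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, with
ground truth recorded for every planted effect.  Defaults (the study
conditions for all end-to-end checks):

- **Cohort**: 7 cancer types × 150 tumors (SKCM, THCA, COADREAD, LUAD,
  BRCA, GBM, LAML).  Driver frequencies follow the classic melanoma/thyroid
  scenario — BRAF V600E in 40% of SKCM and 60% of THCA, NRAS Q61K in 12% of
  SKCM, PIK3CA E545K in 5.2% of COADREAD, EGFR exon-19-like in-frame
  deletions in 10% of LUAD — plus uncatalogued hotspot neighbours (BRAF
  G596D/K601E/W604L, RAC1 P29L/C18Y) at 2–3%.
- **Passengers**: Poisson(8) random missense mutations per tumor.  Real
  tumors carry tens to hundreds of somatic variants; at much lower burdens
  two unrelated tumors sharing only a recurrent hotspot mutation would be
  spuriously flagged as duplicates under the smaller-denominator
  concordance convention.
- **QC plants**: duplicate twins at 80% concordance, one ≤ 5-variant
  identical pair (must survive), common variants at AF 0.2% in 2% of
  samples, 150 bp indels (must be removed) and 100 bp indels (must be
  kept).
- **Expression**: normal baselines (mRNA μ=8, σ=1, already log-scale;
  protein μ=0, σ=1 with 10% missingness); 90%/80% sample coverage at the
  mRNA/protein level; outliers planted in 3% of covered non-LAML samples at
  Q3 + (3 + jitter)·IQR — comfortably beyond the 1.5 fence so recovery is
  deterministic.  An optional t(3) mode stress-tests the fence under heavy
  tails.
- **Structures**: hotspot residues uniformly inside a ball of diameter 4 Å,
  decoys on a line at 15 Å spacing; with ~40 decoys the hotspot pairs are
  the only pairs below both the 5 Å and p < 0.05 thresholds.
- **Screen**: 60 cell lines; background LN(IC50) ~ N(3, 1); sensitive
  mutant lines shifted by −2; expression-linked drugs respond linearly with
  slope −0.8 and noise σ = 0.5.
- **Traits**: sex 50/50; race 60/20/15/5; a 4:1 odds enrichment of BRAF
  carriage in one sex category is planted as the demographic effect.

All randomness flows from one integer seed through numpy's PCG64
(`default_rng`); identical seeds give byte-identical files (fixed float
formatting throughout).

What the generator does **not** emulate: mutational signatures and
realistic passenger hotspots, copy-number variation, batch effects,
cancer-type-specific expression programs, correlated multi-level expression
for the same gene, dose–response curve noise structure, and linkage between
cohort tumors and cell lines.  Passing tests therefore demonstrate that the
procedures are implemented correctly and recover planted effects under
their stated assumptions — not that those assumptions hold in any real
cohort.

## Numerical choices and problem sizes

- Quantiles: linear interpolation (`numpy.percentile` default), everywhere.
- Mann-Whitney: exact only for tie-free groups ≤ 8; asymptotic path is
  tie-corrected with continuity correction (scipy).
- OLS p-values: two-sided t-test on the slope (scipy `linregress`).
- Fisher: scipy exact two-sided; FDR: statsmodels Benjamini-Hochberg.
- Degenerate inputs: IQR = 0 features, < 4-value features, < 10-sample
  features, zero-variance regression scores, and empty backgrounds are
  skipped or raised as documented per module, never silently imputed.
- Test and acceptance problem sizes were chosen to keep the full suite in
  seconds on one CPU while leaving planted effects unambiguous: cohorts of
  ~1000 tumors, 100-replicate oracle sweeps, 1000-replicate type-I checks,
  500-replicate slope-recovery checks, 200-replicate enrichment checks.

## Known limitations

- Quartiles are pan-cancer by default; outliers in cancer types with low
  overall expression can be missed (a per-cancer-type mode exists, off by
  default).
- The duplicate-sample concordance denominator and drop choice are
  conventions, not published definitions; both are logged and configurable.
- Cluster-derived putative calls indicate co-location, not direction of
  drug response; they are reported at the lowest tier for that reason.
- The screen's regression family is uncorrected for multiplicity by
  design; interpret per-combination significance with care.
- No germline variants, clonal heterogeneity, toxicity, fusion calling, or
  copy-number calling.
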