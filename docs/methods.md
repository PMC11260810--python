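# Methods

## Scope and data model

cubkit analyses collections of assembled-transcriptome ORFs from multiple
yeasts. Each ORF carries a nucleotide sequence (frame 0, length a multiple
of 3), an RPKM expression value, and optional annotations: one of 22
cellular-pathway categories, a regulation log2 fold-change, and
per-residue secondary-structure (H/E/T/C = helix/strand/turn/coil) and
subcellular-localization (c/e/t = cytoplasmic/extracellular/transmembrane)
label strings aligned 1:1 with codons. Each yeast carries an optimal
temperature of growth (OTG, °C; validated to 0–45 °C, never clamped).
Upstream steps that produce these inputs — assembly, read mapping,
ORF annotation, structure/topology prediction — are out of scope; their
outputs are consumed as FASTA/TSV tables.

## RSCU and preferred codons

RSCU for codon *i* in a family of size *k* is `n_i / (n_fam / k)`. Design
choices that the definition alone does not fix:

* **Stop codons** are excluded from counts, RSCU, and all content
  denominators. **ATG and TGG** (single-codon families) carry no RSCU and
  can never be preferred, but they do count in content denominators —
  they are real codons of the ORF.
* A family with zero occurrences in an ORF yields *missing* RSCU for all
  its codons (excluded pairwise from tests, never imputed as 0); a codon
  absent from a *present* family has a true RSCU of 0.
* Codons containing N (assembly ambiguity) are skipped and tallied, not
  treated as errors.
* Preferred codons are called from **pooled** L5 counts per yeast
  (robust to short ORFs); mean-of-per-ORF RSCU is selectable. A yeast
  with no L5 ORF gets an UNDEFINED preferred set, distinct from an empty
  one. The calling boundary RSCU ≥ 1.5 is inclusive.

## Filtering and stratification

Inclusion: length ≥ 210 nt AND RPKM ≥ 10 (both inclusive); when a yeast
has several transcriptome runs, each ORF keeps its maximum RPKM across
runs. Expression groups: L1 [10, 100], L2 (100, 300], L3 (300, 500],
L4 (500, 1000], L5 (> 1000) — lower-exclusive/upper-inclusive throughout.
%GC groups: gc1 (0, 20], gc2 (20, 40], gc3 (40, 60], gc4 (60, 80];
values above 80 are flagged UNGROUPED rather than binned.

## Nonparametric comparison machinery

Every group comparison is a Kruskal–Wallis omnibus test plus Dunn's
pairwise z-tests on mean ranks with tie correction,

    z = (R̄_a − R̄_b) / sqrt((N(N+1)/12 − ΣT/(12(N−1))) (1/n_a + 1/n_b)),

two-sided normal p-values adjusted within each omnibus family (Bonferroni
default; Holm and Benjamini–Hochberg selectable). Two-group comparisons
use the same machinery for uniformity; without continuity correction the
two-group Dunn p equals the asymptotic Mann–Whitney p, which the tests
use as an independent cross-check. p-values are adjusted within one
omnibus family only, not across codons; the alternative (additional
across-codon correction) would change only the family-wise
interpretation of the significant-codon counts. Groups with fewer than 2
observations are dropped with a warning; alpha defaults to 0.05.

The normality battery (Lilliefors, Kolmogorov–Smirnov on standardized
data, Anderson–Darling with Stephens' p-value approximation for the
estimated-parameters case, D'Agostino K²) is diagnostic only — the
pipeline is nonparametric regardless of its outcome.

## Correlation screening

Per-yeast, per-expression-group RSCU summaries (per-codon **median**
across the group's ORFs; mean selectable) feed a difference matrix with
one record per codon per ordered combination: between-yeast records for
every yeast pair × every group-of-a/group-of-b combination (same or
different), and within-yeast records for every group pair (d_otg = 0).
Expression differences use group rank indices (L1=1 … L5=5), since the
groups are ordinal bins. Correlations are Spearman by default (the data
reject normality); reporting thresholds are |rho| ≥ 0.4 for OTG
(between-yeast) and |rho| ≥ 0.5 for expression, with the within-yeast
pass additionally summarized as the number of yeasts in which each codon
clears the threshold. Each context is reported separately plus pooled.
A centered, unscaled PCA of the difference matrix is an auxiliary output;
the correlations are the primary quantity.

## Clustering

Yeast profiles are pooled L5 RSCU over the fixed 59-codon index; codons
missing in one yeast are imputed with the cross-yeast median (flagged).
Default distance is correlation distance (1 − Pearson r; profile shape,
not magnitude, is the object of comparison) with average linkage;
Euclidean/Ward are selectable. The tree is cut into k groups (default 9),
profiles are sorted by yeast id before distance computation so equal
merge heights resolve deterministically, and the dendrogram is serialized
to Newick. Per-group OTG distributions (n, median, range) accompany the
cut. The cut count k is a free parameter; no claim is made that any
particular k is optimal.

## Content analyses

Per-ORF preferred-codon content is compared across the 22 pathway
categories within each yeast (all-pairs Dunn; the pathway-vs-pathway
median differences and the count of significant pairs are the summary
quantities) and between up- (log2FC ≥ 1) and down-regulated (≤ −1) ORF
sets, overall and per pathway ("% up-down" median differences). Both
regulation bounds are closed. The pathway vocabulary is locked to the 22
abbreviations; unknown labels raise a validation error naming the allowed
set. ORFs without the relevant annotation are skipped.

## Positional analyses

ORFs are fragmented 5′→3′ into non-overlapping 30-nt segments (10 codons,
frame 0); a trailing partial segment is dropped to keep denominators at
10 codons. The ramp summary is, for segment position s ≤ 20 and offset
j ≤ 20, the median over ORFs (per expression group and pooled) of
content(s) − content(s+j), using only ORFs with ≥ s+j segments; cells
supported by fewer than 10 ORFs are reported MISSING. Two numerical
caveats are inherent to the definition and documented rather than
corrected: (i) segment 1 contains the start codon ATG, which counts in
the denominator but can never be preferred, so segment-1 deltas carry a
deficit of roughly one tenth of the typical content even without any
ramp; (ii) per-segment content is quantized in 10-point steps, so
per-cell medians sit on a 5-point lattice and single cells are noisy —
aggregate signals (row means across offsets) are the stable readout.

Structure/localization content scores, per ORF and category, the codons
whose residue carries that label; categories are compared all-pairs per
expression group, and the number of yeasts with significant category
pairs is the cross-yeast summary. Whole-ORF localization labels are
accepted and broadcast per-residue with a flag.

## Synthetic corpus generator

The generator produces the corpus structure every stage assumes, with
every recoverable effect planted explicitly and recorded in a
ground-truth ledger. Amino-acid sequences are i.i.d. draws from a fixed
yeast-proteome-like composition (first residue always Met); synonymous
codon choice per position carries all signal. Defaults (chosen once as
realistic study conditions): ORF lengths lognormal around 450 nt
(≥ 210 nt, multiple of 3); RPKM lognormal (median ≈ 120, log-sd 1.3)
truncated at the ≥ 10 filter, spanning all five L-groups, with explicit
per-group proportions available when a test needs specific strata; OTG
uniform on 10–30 °C; per-family codon preference profiles Dirichlet(0.6),
which yields per-yeast preferred sets of ~12–25 codons — the range
reported for real yeast transcriptome collections.

Planted effects: per-family probability mass on a designated codon
(ground-truth preferred = codons whose *expected* RSCU, mass × k, clears
the threshold — note mass 0.6 on a 2-fold family gives expected RSCU 1.2
and is deliberately *not* ground-truth preferred); OTG and expression
couplings as log-linear tilts of family profiles (an OTG slope of −0.2
per °C produces true |rho| ≈ 0.5 at 80 yeasts, the magnitude band the
reporting threshold targets); the 5′ ramp as a position-dependent mixture
toward non-top codons with depth in percentage points of content;
structure/pathway biases as odds multipliers on the family's top codon;
regulation offsets as additive content shifts. `simulate_null` zeroes
every planted effect for type-I calibration. A fixed seed makes the
corpus byte-reproducible.

What the generator does **not** emulate: real gene structure (introns,
UTRs), codon autocorrelation along genes, amino-acid composition
differences between pathways or structure classes, phylogenetic
correlation between yeasts, and assembly/mapping noise. Passing recovery
tests therefore demonstrate that the estimators detect the effects they
target at realistic sizes — not that real corpora contain those effects.

## Validation scales

Study sizes used by the acceptance tests (chosen as the package's own
desk-scale conditions): brute-force RSCU oracle on 1,000 random ORFs;
type-I calibration over 200 two-group null replicates (rate within 3
Monte-Carlo SE of 0.05); preferred-codon recovery at 300 ORFs/yeast
(Jaccard ≥ 0.9); two-archetype clustering over 80 yeasts (ARI = 1.0);
OTG-correlation recovery over 80 yeasts × 50 ORFs (Jaccard ≥ 0.8 at the
|0.4| threshold); ramp detection over 20 replicates of 250 ORFs
(detection in ≥ 95%); strand-bias detection at 220 labelled ORFs; and a
byte-identity rerun of the full pipeline on a 4-yeast corpus.

## Known limitations

* Corpus-scale headline quantities of real 89-yeast studies (median
  significant-codon counts between yeast pairs, specific dendrogram group
  structure, pathway content medians) are corpus-specific and not
  reproduced at desk scale; the package validates the machinery, not any
  particular corpus.
* Dunn p-values use the normal approximation; very small groups (n < 5)
  have conservative-to-erratic tail behaviour, which the minimum-n floor
  only partly mitigates.
* The segment-1 ramp deficit partially reflects start-codon (and, in real
  data, signal-peptide) composition; it is flagged, not modelled.
* Correlation screening treats yeast pairs as exchangeable; no
  phylogenetic correction is attempted.
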