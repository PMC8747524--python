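# Methods

## The mapping strategy

A near-isogenic line (NIL) is bred by crossing a donor parent carrying a
target trait to a recurrent parent, backcrossing the progeny to the
recurrent parent for *n* generations with selection for the trait, and
selfing for *m* generations to fix the line (BCnFm). Each backcross
halves the expected donor-genome fraction, so an unselected BCn plant
carries (1/2)^(n+1) donor genome; selection forces one donor block to
survive and drags linked flanking sequence with it. Comparing NILs bred
from *different* recurrent parents cancels the incidental blocks: only
a region introgressed in *all* NILs — a common introgressed region
(CIR) — is a credible location for the trait gene. `nilscan` locates
CIRs from whole-genome variant calls, annotates the SNPs inside them,
converts suitable SNPs to CAPS markers and quantifies marker–trait
association.

## Genotype classification

Input is a multi-sample VCF with per-sample allele depths (AD) and
total depth (DP). Sites are retained when biallelic with mapping
quality strictly greater than `min_mq` (default 30; records lacking MQ
pass with a warning, tolerating caller dialects). Classification is
per cell, not per site: a sample is classified only where its DP ≥
`min_depth` (default 3), so one shallow sample never discards a site
for the others. With p = AD_alt/(AD_ref+AD_alt):

| class | rule |
|---|---|
| alt-homozygous (h) | p ≥ 0.90 |
| ref-homozygous (l) | AD_ref/(AD_ref+AD_alt) ≥ 0.90 |
| heterozygous (e) | 0.40 ≤ p ≤ 0.60 |
| unclassified (u) | anything else, incl. zero depth |

The homozygous band is evaluated on each allele's own proportion so the
p = 0.10 boundary is exact in floating point. The 10–40 % and 60–90 %
bands are deliberately unclassified: at depth ~25 they are dominated by
barely-covered heterozygotes and contaminated calls, and leaving them
out of window denominators is safer than forcing a class. The depth
rule is ≥ 3 (not > 3): with a mean coverage near 25× the choice moves
<1 % of cells, and the inclusive form matches the analysis-stage
convention; it is configurable.

## Informative loci and the window scan

An informative locus is a site where donor and recurrent parent are
classified as opposite homozygotes; every other site (heterozygous,
unclassified or concordant in a parent) is discarded with a tally. At
informative loci the NIL's call reveals local ancestry: the
donor-allele homozygous class is donor-derived, the recurrent-allele
class is background, heterozygous calls count as non-donor evidence
(a finished NIL should be fixed; the residual-het fraction is
reported), unclassified calls are excluded from denominators.

Each chromosome is cut into non-overlapping windows `[k·w, (k+1)·w)`
(default w = 1 Mb). A window is donor-flagged when

* it holds ≥ `min_donor_loci` donor-homozygous calls (default 5), and
* those calls are ≥ `min_donor_frac` of its classified informative
  calls (default 0.8).

The two thresholds replace visual reading of graphical genotypes with
an explicit rule: the count suppresses isolated miscalls, the fraction
suppresses windows whose few donor calls sit in a recurrent background.
Runs of flagged windows, bridging at most `max_gap_windows` unflagged
windows (default 1), merge into segments whose bounds are then refined
inward to the first and last donor-homozygous locus — segment
coordinates are SNP-resolution, not window-resolution. CIRs are the
per-chromosome interval intersections of the NILs' segment sets; a
CIR's common SNPs are the informative loci at which *every* NIL is
donor-homozygous, so the common count can never exceed the smallest
per-NIL count.

Window size must be read relative to chromosome length: 1 Mb on a
~34 Mb chromosome is ~34 windows per chromosome. The truth-set
evaluation (below) simulates 5 Mb chromosomes and therefore scales the
window to `chrom_length/34` (~150 kb) to preserve that resolution;
running desk-scale genomes with full-size windows tests a much coarser
regime in which sub-window segments dilute below the 0.8 fraction and
are systematically missed.

## Annotation

Gene models come from GFF3 (1-based inclusive coordinates, converted
internally where needed). The promoter is the 1 kb upstream of the
strand-aware gene start (transcription start, not the literal lower
coordinate; a flag restores the literal reading). A SNP inside an exon
is EXON, inside the gene but outside exons INTRON, within the promoter
window PROMOTER, else INTERGENIC; a SNP hitting several genes reports
every association, and single-context tallies use the precedence
EXON > INTRON > PROMOTER. Coding effects extract the affected codon
strand- and frame-aware from the spliced CDS, substitute the alt base
(complemented on minus-strand genes), translate both codons with the
standard genetic code, and call SYNONYMOUS exactly when the amino acids
match. CDS lengths not divisible by 3 are flagged, not rejected, and
effects are still computed for complete codons.

## CAPS design

Recognition sites are matched under IUPAC semantics on both strands
(minus-strand matches are positions of the reverse-complement pattern
in top-strand coordinates); palindromicity is derived from the
sequence — degenerate palindromes such as CTNAG count. An `N` in the
*query* sequence never matches, a conservative choice for marker
design. An enzyme is a CAPS candidate for a SNP when the site sets of
the ref- and alt-substituted flanks differ **and** a differing site
overlaps the variant (the polymorphism itself must cause the
difference), and the predicted digestion patterns of the two alleles
differ on the amplicon (default ±150 bp around the SNP; primer design
is out of scope). Fragment sizes use top-strand cut coordinates
(`cut_offset` from the site's 5′ end), descending, with the
heterozygote pattern the union of both allele patterns. Two exact
invariants hold and are tested: fragment sizes always sum to the
amplicon length, and the bottom-strand cut set of a sequence reflects
onto the top-strand cut set of its reverse complement. Full fragment-
multiset strand invariance holds exactly for blunt (centre-cutting)
enzymes; staggered cutters shift the two *end* fragments by the
overhang length (4 bp for EcoRI), which a gel cannot resolve but an
exact test must acknowledge. The packaged catalogue is ~35 common
double-strand cutters as a TSV (name, recognition, cut offset);
nicking and outside-cutting enzymes are excluded.

## Association statistics

Marker codes come from a closed vocabulary: hh (donor homozygote,
coded 2), hl (1), ll (0), m (failed PCR — cultivar dropped for that
marker), d (dominant scoring — donor homozygote and heterozygote
indistinguishable; the marker is reported NOT_ESTIMABLE rather than
half-analysed). R² is the squared Pearson correlation from ordinary
least squares of the cultivar trait **means** on the additive codes.
Means, not per-fruit replicates, are the regression unit: replicate
values are typically unpublished, and the additive/means convention is
the one whose results match published single-marker tables. R² is
invariant to the coding direction (x → 2−x) and to affine rescaling of
the trait, both property-tested.

One-way ANOVA and Duncan's multiple range test run from replicates or
from summary statistics — between- and within-group sums of squares
are exactly recoverable from (mean, sd, n) per group, so the
summary-based F equals the replicate-based F. Duncan's test sorts the
k group means and compares means r ranks apart against the least
significant range LSR_r = q(1−α_r; r, df_e)·√(MSE/n_h), with
protection level α_r = 1−(1−α)^(r−1), studentized-range quantiles
computed numerically (and cached — they are expensive), and n_h the
harmonic mean group size when groups are unbalanced (logged). A span
declared homogeneous protects all its sub-spans (Duncan's containment
rule); letters mark the maximal homogeneous runs, lettered from the
lowest mean upward as trait tables print them.

## Breeding simulator

Meiosis is Haldane: per chromosome the crossover count is Poisson with
mean cM/100, positions uniform, no interference — adequate for
segment-scale truth sets, where interference would sharpen block-length
distributions without changing any tested expectation. Pedigrees
advance one plant per generation, redrawing (cap 1000) until the
offspring carries the donor allele at the selected locus; the final
selfing generation selects a donor-*homozygous* plant, because a
finished NIL is a fixed line and is genotyped as such. Selfing is
simulated generation by generation, so residual heterozygosity away
from the selected locus persists at realistic rates ((1/2)^m per
locus) rather than being forced away. Default genome: 11 chromosomes
of 30–38 Mb at 5 cM/Mb (a ~360 Mb genome with a ~1800 cM map); default
divergence between parents ~214k SNPs + ~12k InDels genome-wide, both
scaled down proportionally in tests. Read sampling: per sample and
site DP ~ Poisson(mean depth), alt depth ~ Binomial(DP, g/2 adjusted
by the error rate), where g is the true alt dosage; the donor carries
alt alleles by construction. The default seed is 97103 (the reference
accession number), always overridable; identical seeds give
byte-identical VCF/BED output.

The simulator emulates: opposite-homozygous parents, mosaic NIL
genomes with realistic block lengths, selection drag, residual
heterozygosity, and binomial read-sampling noise. It does **not**
emulate: recurrent parents that differ from each other (both are the
reference haplotype here), alignment and calling artefacts
(mismapping, allele-specific bias, indel realignment), crossover
interference, or population-scale breeding with plant-number
bookkeeping (progeny counts per generation are unstated free
parameters). Passing truth-set tests therefore demonstrates the
*analysis* logic, not robustness to alignment artefacts in real data.

## Evaluation experiments and problem sizes

`nilscan.evaluation` packages two seeded experiments used by the tests
and the acceptance script:

* **Donor-fraction calibration** — 10,000 unselected BC1/BC2/BC3
  pedigrees on a 2 × 2 Mb (50 cM each) genome; means are compared to
  (1/2)^(n+1) within three standard errors. The expectation is
  layout-independent; the small genome just makes 30,000 pedigrees
  cheap.
* **Introgression recovery** — 20 NIL pairs (BC3F6, 2 × 5 Mb
  chromosomes, 500 informative loci, depth 25, error-free, both NILs
  selected at the same mid-chromosome locus), scanned end-to-end.
  Recall counts truth segments holding ≥ 5 informative loci that a
  detected segment overlaps; precision counts detected segments
  overlapping truth; the forced segment is recovered when a CIR
  overlaps the intersection of the pair's truth blocks around the
  selected locus. Windows scale with the chromosome as described
  above; flagging thresholds are the package defaults.

## Numerical and degenerate-input choices

Zero read depth is unclassified, never an error. Empty VCFs give empty
matrices with a zero-site report. Multi-allelic records are dropped
and counted; malformed records are logged and skipped, never silently.
Interval conventions: 1-based inclusive in VCF/GFF3, 0-based half-open
in BED and all in-memory intervals. Coordinates refined to loci use
the first/last donor locus, so a single-locus segment still has
positive width. Duncan's test with zero MSE is undefined (raises);
identical group means give all groups one letter. The studentized-
range quantile cache is keyed on (α, span, df) only — means and
variances never affect it.

## Known limitations

* Ancestry calls are rule-based, not probabilistic: no HMM smoothing,
  no per-locus posterior; very short introgressions below the window
  scale (relative to locus density) can be missed, and the published
  two-marker resolution of a CIR is the realistic floor.
* The regression reproduces published R² under the means/additive
  convention; two published values from markers with failed-PCR
  entries do not match this (or any plausible) recomputation and are
  judged likely table errors — the acceptance test reports them by
  name rather than hiding them.
* CAPS predictions ignore PCR thermodynamics, star activity and
  partial digestion; dCAPS (mismatch-primer) designs are out of scope.
* InDel coding effects are limited to single-base substitutions;
  frameshift annotation is out of scope.
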