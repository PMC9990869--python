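# Methods

This note documents the models, conventions and numerical choices behind
`editscan`, and what the synthetic studies used by the test suite do and do
not establish about real data.

## Data model and coordinates

The pipeline's entry point is per-site base-count evidence (REDItools-style
tables: chrom, 1-based position, reference base, strand hint, depth, mean
base quality, and A/C/G/T counts) for RNA and DNA of each sample.  Read
alignment and pileup generation are upstream of this package.  Internally
every interval is 0-based half-open; all emitted tables are 1-based closed.
Annotation comes from GFF3 (1-based closed) or BED12 (0-based half-open),
normalised to one internal representation; UTRs are taken from explicit
UTR features when present and otherwise derived from the CDS span.  When a
position hits several annotation classes the reported class follows the
precedence exonic > 3'UTR > 5'UTR > intronic > intergenic, with gene ties
broken lexicographically — a single label per site is needed for
region-distribution summaries, and the precedence is a documented package
convention.  The SNP mask matches on position only; conservative removal
without allele bookkeeping.

## Filter cascade

Candidates are positions with ≥ 1 non-reference RNA read whose DNA passes
a homozygous-reference check.  The cascade applies, in this fixed order:

| step | rule | default | rationale |
| --- | --- | --- | --- |
| quality | mean base quality > 30 | 30 | stringent-call convention |
| depth | RNA depth ≥ 10 | 10 | per sample ("each site in each sample") |
| multi-allelic | 2nd variant allele with ≥ 2 reads | 2 reads | one stray error read (P ≈ 3% per site-sample at depth 50, error 1e-3) must not discard a site |
| DNA variant | DNA alt fraction > 0.01 **or** alt count ≥ 2 | 0.01 / 2 | robust at low DNA depth; DNA depth ≥ 5 required for evidence at all |
| SNP | position in mask | — | known germline variation |
| level | 0.1 ≤ alt/(ref+alt) < 1 | [0.1, 1) | removes low-level overediting noise and fixed variants |

Each rejected candidate carries exactly its first-failing flag, so flag
counts partition the candidate set and the cascade is auditable.  The
thresholds actually applied are logged on every run.  Filtering is per
sample; the merged matrix keeps a cell missing (never zero) where a site
did not pass in a sample, because "not covered" and "not edited" are
different observations.

## Differential editing

Sample coverage is counted per condition over passing observations.
Classification uses `shared` = coverage ≥ 10 in *both* conditions
(inclusive reading; a strict `> 10` is selectable), `tumor_/normal_specific`
= coverage ≥ 4 in one condition and exactly 0 in the other; everything
else is dropped with a recorded reason, so the four groups always sum to
the matrix size.

The Fisher test pools read counts within each condition over the samples
where the site passes, producing one 2×2 table per site — the only
construction that yields a single p-value per site across a cohort.  The
two-sided p sums all hypergeometric probabilities not exceeding the
observed table's (relative tie tolerance 1e-7, the classical convention);
a zero-margin table is degenerate and reported as p = 1 with a flag.
Significance is unadjusted p < 0.05, and BH q-values over the shared-group
tests are emitted alongside for users who prefer FDR control.  Because
pooling ignores between-sample variation, the test is exact only under a
per-condition binomial model; with the default hierarchical level
variation its empirical type-I rate inflates from ~4% to ~10–15%, which is
why the q-column and the per-sample paired t-tests on mean level and site
count are part of the standard output.

The DRE heatmap export keeps missing cells missing by default
(zero-filling is an explicit flag); the 2-cluster average-linkage/Euclidean
cut used in tests to measure tumor/normal separation is a report-layer
convenience, not part of the model.

## Editing-frequency F_ST

Each sample contributes its editing level as the allele frequency of one
sampled unit.  For two groups with sizes n1, n2 and group mean frequencies
p1, p2:

    nbar = (n1+n2)/2
    nc   = n1+n2 − (n1²+n2²)/(n1+n2)
    pbar = (n1 p1 + n2 p2)/(n1+n2),  qbar = 1 − pbar
    s²   = [n1(p1−pbar)² + n2(p2−pbar)²] / nbar
    a    = (nbar/nc) [ s² − (pbar qbar − s²/2)/(nbar−1) ]
    b    = (nbar/(nbar−1)) (pbar qbar − s²/2)
    F_ST = a/(a+b)

These are the Weir–Cockerham two-population variance components with the
heterozygosity terms dropped: an editing fraction has no genotypes, so no
within-individual component exists.  The estimator is label-symmetric,
equals 0 (after clamping) for identical groups and 1 for fully diverged
0-vs-1 groups, and refuses groups with fewer than two samples.  Negative
raw estimates are preserved in `fst_raw` and clamped to 0 in the headline
column; thresholding (default 0.25, the conventional strong-differentiation
cut) is unaffected by clamping.  A Hudson-style ratio estimator on pooled
read counts is available as a cross-check, and sites can be exported as a
pseudo-genotype VCF for external F_ST tools.  The scan runs over any site
table carrying matrix site ids — typically the DRE table; sensitivity
analyses in the test suite run it over the full matrix.

## Sequence context

Strand-resolved ±k windows (default k = 5) around edited adenosines are
compared with *all* other gene-strand adenosines of the same genes whose
windows avoid edited sites; an optional cap triggers a seeded subsample.
The full background minimises estimator variance — with a count-matched
background of ~1000 the per-offset log2-ratio noise (sd ≈ 0.11) would
swamp enrichments of interest — and the window-avoidance rule keeps the
background window content distribution identical to the edited one under
the null.  Frequencies are reported raw; enrichments use a +0.5 pseudocount
per cell.  Minus-strand windows are reverse-complemented, making the whole
profile invariant under reverse-complementing the genome and flipping all
gene strands (a tested property).  MEME-style de novo motif discovery is
not reimplemented; ±25 nt windows are exported as FASTA for external tools.

## ADAR association

Per-sample mean editing level averages over the sites observed in that
sample (not zero-filled, consistent with per-sample filtering).  Global
association is Spearman's rho (ties mid-ranked) of that mean against each
deaminase's expression across all samples, refused below n = 3; per-site
association restricts to samples where the site passes (default minimum
10).  Differential ADAR expression between conditions uses a paired t-test
on log2(x+1).  Pairs split into ADAR1-up/downregulated by tumor-vs-normal
ADAR1 expression; within each stratum (≥ 3 pairs) mean level is correlated
with passing-site count across tumor samples, Spearman by default with
Pearson selectable.  All rank-based outputs are invariant under strictly
monotone transforms of expression (tested).

## Expression and splicing integration

The differential-expression stand-in computes, per gene, the median over
pairs of log2((tumor+1)/(normal+1)) and a paired t-test on log2(x+1) with
BH correction — a transparent paired fold-change procedure for studies
without an external DESeq2 table, not a DESeq2 reimplementation; external
DEG tables plug in through the same interface.  eDREs are DREs whose gene
passes |log2FC| ≥ 1 and padj < 0.05; the join is by gene id and a complete
namespace mismatch is an error rather than a silent empty result.

Splicing events arrive as rMATS-dialect rows.  The defining span per event
type includes flanking introns, because causal edits sit there: SE and MXE
span from the upstream exon start to the downstream exon end, A5SS/A3SS
span the alternative splice-site region plus its intron (same generic
block), RI is the retained block itself.  A DRE inside a span is an sDRE;
the fraction of events containing ≥ 1 DRE is reported.  No
direction-consistency constraint links the editing mode to the expression
or inclusion direction — the intersections are presence-based.

Edited/unedited window pairs (±250 or ±1000 nt, clipped at contig edges
with a warning) differ at exactly the center A→G and are written on the
edited strand for external RNAfold/MXfold2 runs; a harness ingests the
resulting MFE table and reports the fraction of sites with |ΔMFE| above a
user threshold.

## The simulator

`SimConfig` defines a complete paired study; all defaults together are the
desk-scale regime the tests run under:

* 10 tumor/normal pairs (a cohort-scale study would use ~40; 10 keeps every
  replicate-heavy test in seconds);
* a 2×150 kb genome, 40 genes with exon/intron/UTR structure, uniform base
  composition except at planted motif flanks;
* 300 shared + 150 tumor-specific + 150 normal-specific A-to-I sites placed
  region-weighted (78% intronic, 6% 3'UTR, 5% exonic, 4% 5'UTR, 7%
  intergenic, the shape of real editing catalogues), minimum separation
  12 nt; site-level means Beta(2, 8) (mean 0.2 — levels mostly in the
  10–30% band), per-sample levels drawn from a Beta around the site mean
  with concentration 1/`sample_dispersion` (default 100) so pooled-count
  tests face realistic overdispersion; a pure-binomial regime is
  `sample_dispersion = 0`;
* 60 shared sites carry a planted tumor−normal difference of 0.15 on a
  base of U(0.2, 0.4) (both conditions detectable by construction), and 30
  carry divergent frequencies 0.2 vs 0.8 for the selection scan;
* depth is negative binomial with mean 50 and dispersion 0.3 in the
  var = μ + αμ² convention; per-base error 0.001; mean qualities ~N(36, 1)
  with a few planted low-quality positions;
* confounders: 30 germline SNPs (heterozygous in the DNA of every sample
  and listed in the emitted VCF mask) and 30 DNA variants, both also
  showing an RNA signal so the cascade is genuinely exercised, plus 2000
  error-only background positions;
* each sample gets an ADAR1 activity multiplier `A ~ lognormal(0, 0.25)`
  (tumor samples shifted ×1.4); the editing multiplier is `A^coupling`
  (default coupling 0.5), so `coupling = 0` is the exact null;
* motif bias 0.8: a flagged site has a non-G at −1 and G at +1 on the
  edited strand;
* an expression matrix with 20 planted DE genes among the edited genes and
  4 among site-free genes (|log2FC| = 1.5), plus ADAR/ADARB1/ADARB2 rows;
  200 significant splicing events of which 40% are built to contain a
  planted site; Alu-like repeat intervals covering 60% of sites.

Everything derives from one seeded generator chain, so equal configurations
give byte-identical outputs, including all written files.

What the simulator does **not** emulate: alignment artifacts
(multi-mapping, splice-junction edge effects, hyper-edited read loss),
strand-specific library chemistry, position-dependent error profiles,
copy-number or purity variation in tumors, linkage between neighboring
sites, and real gene-expression covariance.  Passing tests therefore show
that the statistical machinery is correct under its stated model, not that
the cascade's thresholds are optimal for any particular real cohort.

## Numerical and testing choices

* Fisher p-values come from hypergeometric pmf summation; the test-suite
  oracle is an independent exact-integer enumeration (agreement ≤ 1e-9 on
  random tables), with `scipy.stats.fisher_exact` as a second cross-check.
* The W–C estimator is checked to 1e-9 against a separately coded
  transcription of the variance-component definitions.
* Type-I and power of the differential test are measured on sites that
  reach the shared-group test.  With 10 pairs, shared classification
  requires a passing observation in every sample of both conditions, so a
  site's chance of being testable at all (~0.2–0.5, dominated by depth and
  DNA-error tails) is a property of the coverage rule, which is tested
  separately at its boundaries; conflating it with the test's error rates
  would measure the product of two unrelated things.
* Replicate-heavy calibrations use deliberately small simulated studies
  (12–16 genes, 50–70 kb, 40–100 sites) so that 50–200 replicates run in
  tens of seconds; single-study checks use the full default configuration.
* The null context-profile calibration runs at 2500 planted sites: the
  max-|log2-enrichment| statistic spans 40 offset/base cells, and the
  < 0.2 bound needs the per-cell noise (≈ 0.25/√n relative) that size
  provides.

## Known limitations

* Pooled-count Fisher testing is anticonservative under overdispersion;
  treat unadjusted significance on real cohorts with care and prefer the
  BH column.
* The editing-frequency F_ST convention (one frequency observation per
  sample, no heterozygosity) is one of several defensible encodings;
  the pseudo-genotype VCF export exists so external tools can cross-check.
* Strand resolution relies on unambiguous gene annotation; sites under
  overlapping antisense genes stay unresolved and keep their raw mismatch
  class.
* The DEG stand-in is a paired fold-change screen; it does not model
  count dispersion and should be replaced by a dedicated DE tool's output
  when available.
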