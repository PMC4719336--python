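# Methods

This note documents the models and procedures implemented in `caprilnc`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical edge-case decisions.

## Coordinate model

All internal coordinates are 0-based half-open intervals; GTF/GFF3 and
RepeatMasker `.out` coordinates (1-based, fully closed) are converted at
read/write time only. This keeps every overlap and distance computation
free of ±1 corrections and makes the conversion trivially invertible
(`write ∘ read` and `read ∘ write` are identities on valid files, verified
by round-trip tests). Transcripts are assembled solely from `exon` feature
lines, since assembler GTFs vary in whether they emit `transcript` rows.
Strand `"."` is accepted for TE elements but rejected for any transcript
entering classification — subtype calls are strand-dependent.

## Identification cascade

Order: structural → known-class → coding-potential. The two structural
predicates (exon count ≥ 2, spliced length ≥ 200 nt, both inclusive) and
the known-class predicate are per-transcript, so the survivor set is
independent of filter order; the attrition report reconciles at every step
(`n_in = n_removed + n_out`, steps chain).

Known-class removal requires ≥ 1 bp **exon-against-exon** overlap, never
span overlap: an intronic lncRNA inside a coding gene must survive to be
classified. mRNA overlap removes only on the same strand (a same-strand
exonic overlap is treated as an mRNA isoform fragment); the small-RNA and
pseudogene classes remove on either strand. The reference annotation must
carry explicit biotype attributes — the package does not guess biotypes.

The coding-potential consensus keeps a transcript only when every supplied
caller votes noncoding; a transcript missing from any table is removed as
"unscored" by default (conservative; a policy flag upgrades this to an
error). External tools are deliberately not re-implemented. The built-in
stand-in is the longest complete ATG→stop ORF over the three forward
frames, threshold 300 nt (100 codons) — the conventional lncRNA cutoff.
Codons containing `N` are neither starts nor stops; an ATG without a
downstream in-frame stop is not an ORF.

An optional mean-FPKM floor exists but is off by default: no expression
filter is part of the standard cascade.

## Positional classification

Precedence antisense > intronic > lincRNA. Exonic overlap is the stronger,
less ambiguous positional signal, and the three classes must partition the
survivors; the tie rule matters only for transcripts that are
simultaneously exon-overlapping and intron-contained. "Intronic" admits
both strands: a sense-intronic transcript has no coding-exon overlap and
cannot be antisense, and the class carries no strand qualifier. A lincRNA
is span-disjoint from every coding span with no minimum distance (distance
0 allowed). A transcript whose span overlaps a coding span without exonic
overlap or single-intron containment (e.g. straddling a gene end) fits
none of the three geometries; it is reported as *ambiguous*, excluded from
the classified set, and logged — forcing it into a class would silently
distort every downstream contrast.

## Feature contrasts

Per-transcript features: spliced length; exon count; isoforms per locus
(transcripts sharing a `gene_id` within the class — the standard proxy for
alternative splicing); longest ORF; mean FPKM across **all** samples,
summarized as log₁₀(mean + 1); optional per-transcript conservation score.
The across-sample summary (mean, before the log) is a package decision and
is recorded in the output metadata. Expression rows are looked up by
transcript id first, then gene id, so gene-level FPKM tables work for
multi-isoform coding loci.

The Kolmogorov–Smirnov statistic is the sup-distance between the two
empirical CDFs evaluated on the pooled sample points; the two-sided
p-value uses the asymptotic Kolmogorov distribution at
√(n₁n₂/(n₁+n₂))·D. The exact small-sample distribution is not implemented:
intended class sizes are ≫ 30, where the asymptotic form is standard. The
suite verifies D against a brute-force ECDF oracle, the p-value against
the Kolmogorov series, invariance under monotone transforms, and a type-I
error of 0.03–0.07 at α = 0.05 (1000 null simulations at n = 100 vs 100;
the asymptotic p is mildly conservative, observed ≈ 0.04).

## TE landscape

Density is computed over transcript **spans** (introns included), not
spliced exons: repeat-annotation analyses of lncRNA loci conventionally
use the genomic locus. Same-family elements are merged before measuring,
so density is invariant to how an annotation splits an element, and class
density is Σcovered/Σspan. Family-presence contrasts use the two-sided
Fisher exact test on (with, without) × (class A, class B); the odds ratio
gets a 0.5 (Haldane) correction only when a cell is zero (flagged), and a
table with an all-zero margin returns p = 1 with a warning.

TSS profiles are per-transcript presence fractions: each transcript votes
0/1 at every offset in a ±W window (default W = 2000) oriented 5′→3′, so
fractions are bounded by 1 regardless of stacked elements and the curve is
comparable across classes of different size. The window is symmetric even
though the upstream side is the primary target of the bias analysis — a
peak "right at the TSS" needs the downstream side to be visible. Positions
off the chromosome count as uncovered.

## Target prediction

*Cis*: edge-to-edge distance between the lncRNA span and the gene span
(union of the gene's transcripts), overlap → 0, boundary inclusive,
strand-agnostic, with nested 10 kb / 100 kb tiers. Distance is signed by
the gene's position along the lncRNA's 5′→3′ orientation. Measuring from
span edges (rather than TSSs) is a package decision, flagged in output
metadata.

*Trans*: Pearson correlation on raw FPKM across all samples ("expression
levels", not their logs; a `--log` alternative exists and is recorded in
output metadata), strict inequalities at the threshold (r > 0.95 or
r < −0.95). Zero-variance rows have no defined correlation; their pairs
are skipped and logged. **Small-n caveat:** with n = 6 samples the null
probability of |r| > 0.95 for independent rows is
2·P(t₄ > 0.95·2/√(1−0.95²)) ≈ 0.0037, so a 92 × 200 pair scan yields ≈ 70
chance pairs. Trans lists at this sample size are enrichment inputs, not
individual discoveries; recovery tests therefore require the planted pairs
to be found and bound the extras by the null rate rather than demanding
exact equality.

Differential expression is a Welch t-test on log₁₀(FPKM + 1) — unequal
variances are the safe default at n = 3 per group — with Holm–Šidák
step-down correction: with raw p ascending, adjusted
p(i) = max over j ≤ i of 1 − (1−p(j))^(m−j+1), clipped to 1 (delegated to
`statsmodels`, which implements exactly this formula; an independent
implementation is cross-checked in the tests). Degenerate rows with zero
variance in both groups get p = 1 when means are equal and p = 0 otherwise
(the infinite-t limit).

EASE enrichment: one-tailed hypergeometric upper tail with the observed
overlap decremented by one, P(X ≥ k − 1); k ≤ 1 gives p = 1 by
construction. Term systems are user-supplied (term, gene) TSVs — no
ontology download.

## The synthetic generator

The generator emulates the *structure* of a small two-phenotype RNA-seq
study, not its sequence content: a two-chromosome 4-Mb toy genome; 200
spaced multi-exon coding genes; 60 lincRNAs placed in intergenic gaps with
clearance margins, 20 antisense transcripts with one exon over a host
coding exon on the opposite strand, 12 intronic transcripts strictly
inside roomy introns; 40 decoys, 10 per failure mode (single-exon,
< 200 nt, ORF ≥ 330 nt, housekeeping-RNA exon overlap), each engineered to
fail exactly that one filter; 10 housekeeping reference genes cycling
through the small-RNA/pseudogene biotypes. Five TE families (LINE/L1,
LINE/RTE-BovB, LTR/ERV1, LTR/ERVL, SINE/Core-RTE) are scattered at
realistic genome-coverage densities (1–4 %), and an ERV1 peak is planted
in the 500 bp upstream of every lincRNA TSS: one 200-bp element placed
uniformly inside the window, so the window-mean coverage excess equals the
configured 0.4 exactly per transcript, up to background.

Expression: 6 samples (dark/white × 3). Baseline rows are log-normal
(log₁₀FPKM ~ N(0.5, 0.6) row means with per-sample scatter 0.25) and
mutually independent. Planted correlated pairs are *linear* in a shared
uniform latent factor, so at zero noise the empirical r is exactly ±1;
otherwise pairs are resampled (bounded retries) until |r| ≥ 0.97. Planted
DE rows use a clean ×16 shift (log₂FC = 4) with small per-sample scatter
(0.03 in log₁₀): with 3 samples per group the Welch statistic has only
2–4 df, and a Holm–Šidák correction across the full ~330-row matrix
demands raw p below ~10⁻⁴, which a heavier-noise/weaker-shift design
cannot reliably deliver. Even so, draws where one group's sample variance
collapses the df to ≈ 2 can leave an occasional planted row above the
threshold — recovery of 90–100 % is the honest behaviour of a t-test at
n = 3, and the package reports it as measured.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: read-level artifacts and assembly errors,
fragmented or chimeric models, realistic sequence composition (transcript
sequences are random nucleotides with rejection-sampled ORF content), TE
sequence inside transcripts, overdispersed count noise, batch effects, and
correlated expression structure beyond the planted pairs. Planted-truth
recovery at 100 % demonstrates the pipeline's logic, not its accuracy on
noisy assemblies.

All randomness flows from one `numpy` generator seeded by the mandatory
config seed (the expression stage uses a child seed sequence), and a fixed
seed reproduces every output file byte for byte.

## Problem sizes

The standard bundle (200 genes, 132 candidates, ~1000 TE elements, 6
samples) runs the full pipeline in about a second. Calibration
simulations use 1000 replicates for the KS type-I error and Holm–Šidák
FWER and 40 000 row pairs for the spurious-correlation rate, sizes at
which the Monte-Carlo standard errors are comfortably below the effects
being checked.

## Known limitations

* The classifier assumes the upstream cascade removed same-strand exonic
  overlaps with coding genes; encountering one raises instead of guessing.
* The KS p-value is asymptotic; do not use it for classes of < ~20
  transcripts.
* Cis windows are span-edge based; TSS-anchored windows would shift pair
  sets for long genes.
* EASE/Fisher computations treat genes as exchangeable units; no
  gene-length or expression-level bias correction is applied.
* GFF3 support covers the gene/transcript/exon subset with
  `transcript_id`/`Parent` attributes, not the full feature ontology.
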