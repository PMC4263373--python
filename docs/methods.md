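# Methods

## Scope and coordinate model

All stages share one alignment model (`srio.AlignmentRecord`): 0-based
half-open genomic coordinates, a strand-aware 5′ end (leftmost base on
`+`, `start + length − 1` on `−`), collapsed read multiplicity
(`copies`), and the number of genomic alignments of the read sequence
(`n_hits`). Default retention filters keep reads of 18–26 nt with at
most 20 genomic alignments; reads overlapping a structural-RNA blacklist
(rRNA/tRNA/snRNA/snoRNA intervals) by ≥ 1 nt are removed. Abundance is
expressed in RPM, reads per million genome-matched reads of the library;
the denominator is the genome-matched total *before* structural-RNA
removal, since "genome-matched" is the natural definition of the
library size (the alternative, post-removal denominator differs only by
a per-library constant). Multimapped reads contribute their full
`copies` at every reported alignment; optional 1/n down-weighting is not
applied in the sRNA stages, where discarding multimapping reads is known
to delete bona fide miRNA and ta-siRNA loci.

## Windowed differential abundance

Reads of each size class (21, 22, 24 nt) are counted in non-overlapping
500-nt windows tiling each sequence from coordinate 0, assigned by
strand-aware 5′ end, strands pooled. Windows with fewer than 10 reads
summed over all libraries are removed. The genotype effect is tested
per window with the exact negative-binomial test for two groups under a
single common dispersion: counts are scaled to a common library size
(size factors = genome-matched totals, geometric-mean centred) and
rounded; group sums are compared conditionally on their total, summing
the probabilities of all splits no more likely than the observed one
(two-sided). The common dispersion is estimated by conditional maximum
likelihood on the scaled counts — exact when library sizes are equal,
a quantile-adjustment surrogate otherwise — and the scan is also usable
with a fixed dispersion. A unit test pins this construction to an
independent implementation of the same exact test (edgeR's
`exactTest` with fixed dispersion and equal library sizes), which agrees
to ~10 significant digits.

Fold change is `log2((mutant mean + 0.5) / (wildtype mean + 0.5))` on
size-factor-normalized means; the 0.5 pseudo-count keeps zero groups
finite. Positive values mean up in the mutant. Windows pass when
|log2FC| ≥ 1, BH-adjusted p < 0.05, and the window is outside any
excluded interval (e.g. a mutant introgression region); the failure
reason is recorded. Per-size-class library totals (18–26 nt) are
compared with a two-sided Welch t-test; two constant groups with equal
means return p = 1 by definition.

Numerical notes: the exact test's discreteness makes it slightly
conservative at small counts (the null simulation in the test suite
shows type-I error ≈ 0.04–0.05 at α = 0.05 with 2000 windows, 3 vs 3,
dispersion 0.1); a non-positive dispersion estimate is clamped to 1e-6
with a warning.

## Phased-cluster detection

Wild-type libraries are normalized to RPM and pooled. Plus-strand reads
contribute at their leftmost coordinate, minus-strand reads at leftmost
+2, so both strands of one DCL4 duplex share a phase position (the 2-nt
3′ overhang). For each 500-bp window (sliding step 250 bp, half-window
overlap; the step is configurable) and each register r ∈ [0, k), the
C = ⌊500/k⌋ phase positions `wstart + r + k·i` are evaluated: P is
their summed abundance, n the number occupied, U the remaining size-k
abundance in the window, and

    score = (n − 2) · ln(1 + 10·P/(1 + U))  for n ≥ 3, else 0.

C is 23, 22, and 20 for k = 21, 22, 24. The register maximizing the
score is reported (ties broken toward the smaller window offset; the
reported register is the genomic residue class mod k). A window is a
candidate when the best register carries ≥ 5 raw pooled in-register
reads — the read-count threshold is deliberately applied to raw counts
while the score uses normalized abundance — and qualifies at
score ≥ 25. Overlapping or abutting qualifying windows of one k merge
into clusters keeping the best window's score and register; clusters
overlapping a window called significantly down in the mutant are
flagged mutant-dependent (NA when no differential results are given).
U counts only same-size off-register reads, keeping the three size
classes independent. Positions beyond `wstart + k·C` within the window
are off-phase for every register by construction of C.

A brute-force register enumeration (walking every window offset) is
kept in the test suite as an independent oracle; scan and oracle agree
exactly on hundreds of random windows.

## Target-duplex scoring and two-hit detection

Duplexes are scored with the classic plant penalty scheme: mismatch 1,
G:U wobble 0.5, each bulged nucleotide 1, all doubled when the position
falls at sRNA positions 2–13 from the 5′ end (a bulged target base
anchors to the next sRNA position). The search slides the
reverse-complemented sRNA along the transcript exhaustively and
enumerates every single-nucleotide bulge placement on either strand
(at most one bulge per duplex, the practical regime of this scheme;
configurable). Scores for all configurations are computed as partial
diagonal sums of a position-penalty matrix in numpy; duplex states are
reconstructed only for reported hits, and only the best alignment per
site interval is kept. T and U are equivalent on input. The predicted
cleavage position is the transcript nucleotide paired to sRNA position
10, i.e. the first nucleotide of the 3′ cleavage fragment.

Two-hit detection returns the non-overlapping pair of qualifying sites
(score ≤ 4.5 by default) with the smallest combined score, ordered by
transcript coordinate; the phase-setting cleavage is the 3′ site's (the
5′ site need not be cleavable). An independent brute-force enumerator
of all ≤ 1-bulge alignments verifies the search exactly on 50-nt toys.

## PARE validation

5′-end tag counts are pooled across PARE libraries per transcript
position. For a predicted cleavage position c, `W_S` sums tags over
[c−2, c+2] (5 nt) and `W_L` over [c−15, c+15] (31 nt), truncated with a
warning at transcript ends (the denominator stays the truncated sum).
A site validates when `W_S/W_L ≥ 0.75` and `W_S ≥ 4`; thresholds apply
to raw tag counts, and `W_L = 0` leaves the ratio undefined and the
site unvalidated.

## TAS locus characterization

Cleavage at the 3′ miR390 site sets the register (cleavage mod 21).
D-indexed ta-siRNAs tile 5′-ward from the cut: D_i(+) occupies
[c − 21·i, c − 21·(i−1)) on the sense strand — D numbering is anchored
at the 3′ cleavage site, matching the register definition; the
5′-anchored literature convention is a straightforward re-indexing —
and D_i(−) is the duplex partner offset −2 nt. Enumeration stops at the
last complete cycle clearing the 5′ site, so a locus with m cycles
predicts 2m ta-siRNAs. A read is in phase iff its duplex-adjusted 5′
position is congruent with the register mod 21 (only 21-nt reads can be
in phase; all lengths enter the 18–26-nt size profile). ta-siRNAs with
a site of score ≤ 3.0 in any provided ARF3-like transcript are flagged
tasiR-ARF. The per-locus summary reports predicted ta-siRNA and
tasiR-ARF counts, the best phasing score, total raw pooled wild-type
reads in the locus (in- plus out-of-phase), and the
wild-type-over-mutant fold change of mean locus RPM with a 0.5
pseudo-count.

## Synthetic data: what it emulates and what it does not

The generator plants, in a 2 × 150-kb random genome, every structure the
pipeline assumes: 8 two-hit TAS loci (two miR390-complementary sites an
integer 8–13 phase cycles apart; the 5′ site carries one core-distal
mismatch, the 3′ site is perfect and cleaved; most loci carry the
canonical tasiR-ARF sequence at D7(+)), 5 miRNA loci, 5 22-nt
hairpin/antisense loci, 3 three-copy repeat families emitting
multimapped reads, 6 24-nt heterochromatic loci, and 60 unphased null
loci. Three replicates per genotype draw per-locus totals from a
negative binomial (dispersion 0.1) around class mean × genotype fold ×
size factor. Defaults: TAS 300 RPM at 0.02 mutant/wild-type fold
(≈ 50×, mid-range of the published per-locus fold changes),
hairpin/repeat 4× up, heterochromatic 4× down, null unchanged at
60 RPM; 10% of TAS reads are placed off register and 10% off size.
TAS duplex geometry is exact (minus partner at plus start − 2), so
strand merging is tested against geometry rather than convention.
Library size is 1e6 so RPM equals raw counts. Loci are placed ≥ 1.2 kb
apart, mirroring the genomic sparsity of real sRNA loci, so windowed
stages cannot merge two planted loci. PARE tags are Poisson(20) at each
truly cleaved position — the 3′ miR390 cut of each TAS locus and both
tasiR-ARF sites of each of 3 ARF3-like transcripts (sites ~200 nt
apart) — over a Poisson(0.02/nt) background; annotated decoy positions
receive background only.

Deliberately absent: sequencing error, adapter artifacts, position-level
overdispersion within loci, hierarchical locus structure, and genome-scale
repeat content. Passing recovery tests therefore demonstrates correctness
of the statistical machinery under its stated model, not performance on
real libraries, where dispersion, multimapping and annotation complexity
are far richer.

## Problem sizes and determinism

The end-to-end study (300 kb genome, ~100 loci, 6 libraries of ~3,000
alignment records, ~2,000 PARE positions) runs in about one second; the
acceptance script, including a 2,000-window null calibration, in a few
seconds. Every stochastic step flows from one integer seed through
`numpy.random.default_rng`; reruns are byte-identical and the pipeline
manifest records parameter values and output digests.

## Known limitations

* The exact NB test supports two groups only; no GLM designs or
  trended/tagwise dispersion.
* Target search allows at most one bulge and no G:U-aware thermodynamic
  refinement; no cap on hits per sRNA.
* The orchestrated `run_all` drives the self-contained synthetic study;
  external datasets are analyzed through the per-stage APIs/CLI rather
  than one config.
* Phase candidacy evaluates the ≥ 5-read rule at the best-scoring
  register only; a window whose best register is read-poor but whose
  runner-up register meets the read threshold is not a candidate.
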