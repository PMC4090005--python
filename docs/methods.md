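# Methods

## Coordinate and read conventions

All genomic coordinates are 0-based, half-open. Reads arrive as BED6
intervals; the scored position of a read is its first sequenced base —
`start` for plus-strand reads and `end − 1` for minus-strand reads (the
first sequenced base of a reverse alignment is the interval's last base).
This convention is exposed as `chromdiverge.io.REVERSE_READ_POSITION`.
Gene models store TSS and TTS per strand: plus genes have `tss < tts`,
minus genes `tss > tts`; a transcription-relative offset r maps to genomic
position `tss + r` (plus) or `tss − r` (minus), so metagene windows and
region definitions are strand-symmetric by construction.

## Track construction

Fragment length is estimated by the strand-shift method: forward and
reverse first-base profiles are correlated while the reverse profile is
shifted left one base at a time (profiles concatenated across
chromosomes), and the argmax shift over [0, max_shift] is the estimate.
The correlation is Spearman's rank correlation by default (with a Pearson
flag), because the characteristic quantity reported for such scans is the
rank correlation between strands; ties in the scan break toward the
smaller shift. For integer count profiles the ranks are computed exactly
via counting sort, which makes the full scan linear-time per shift and
bit-identical to `scipy.stats.spearmanr`.

Merging shifts the forward profile right by ⌊offset/2⌋ and the reverse
profile left by the remainder, then sums; counts shifted past a chromosome
edge are dropped and tallied (`meta["edge_lost"]`), so total mass is
conserved up to the counted losses. Note that for a planted constant
fragment length L, the reverse first base sits at `frag_start + L − 1`, so
the scan's optimum is L − 1; the estimator is therefore exact up to one
base, well inside the ±5 bp tolerance used throughout.

Samples are depth-normalized by scaling every linear track to the lowest
library total, then log2 transformed with a pseudocount of 1.0 (the choice
of pseudocount is exposed; the underlying reports are silent on zero
handling). The H3 occupancy control is smoothed with a centered moving
mean of 140 bases — widened to 141 to center it — with edge windows
truncated to available bases; smoothing is applied to the log2 H3 track by
default (the alternative order, smoothing the linear track before log2, is
a one-line change at the call site and does not alter any conclusion in
the test suite). H3 normalization is the elementwise subtraction
log2(mod) − log2(H3, smoothed).

## Metagene and region signals

Per-gene profiles are 20-bp bins laid out in transcription orientation;
given a linear track a bin is log2(mean linear + pseudocount) (the "log of
mean" reading), given a log2 track it is the mean of per-base log2 values;
the mode is recorded on the matrix. Bins that reach past a chromosome
edge are masked rather than truncated, to avoid biased means. Region
means tile the region with the same 20-bp bins and average the bin values,
so a region mean equals the mean of the corresponding profile-matrix
columns exactly; genes whose region leaves the chromosome are flagged
invalid and excluded from disparity and divergence, mirroring the
exclusion of genes lacking data for a modification. Nucleosome-level
signals are log2(mean + pseudocount) over each nucleosome interval.
Positional correlations (signal column vs a per-gene covariate) are
Pearson by default with a Spearman option, masked wherever fewer than
three genes have joint data.

## Disparity and enrichment

The disparity statistic is ac − me in log2 units (i.e.
log2(H3K9ac/H3K4me3)) from the per-mark peak regions; genes shorter than
700 bp or with an invalid signal are left unranked. Sectors are the top,
bottom, and middle `sector_size` genes of the descending ranking; the
middle window is centered on the median rank (the placement of the
intermediate sector is not otherwise pinned down, and a centered window is
the symmetric choice). All ties break by gene id so results are invariant
to input order. Enrichment is the one-sided hypergeometric tail
(P[X ≥ k] for enrichment, P[X ≤ k] for depletion, direction chosen by the
sign of the fold enrichment); raw p-values are reported without
multiple-testing correction, as is conventional for this display style.

## Divergence

Differences are oriented A − B throughout. The Lowess extraction fits
y = f(x) with span 0.3 and two robustness iterations (statsmodels
implementation), ranks residuals y − f(x), and takes the `n_per_side` most
negative and most positive; the exact-size sets with gene-id tie-breaks
make the operation equal to a brute-force residual ranking. Change
classification uses |d| > 0.4 log2 as significance; the five pair
categories and the six triple categories follow mechanically from the
significance flags and signs, with a residual `other` for triple
combinations outside the displayed five. Threshold-gated correlations
require both gated vectors to exceed the threshold; at small sample sizes
such gates are strongly selecting and the pipeline therefore also reports
ungated correlations — the gated figures are meaningful at the scale of a
few thousand orthologs, where hundreds of genes pass the gate.

## The synthetic-data generator

The generator is the package's stand-in for real two-species ChIP-seq /
RNA-seq data and defines the default study conditions (2000 genes, 10⁶
reads per ChIP sample). Genes of uniform length 800–2200 bp are tiled on
equal chromosomes with fixed spacing; every gene carries nucleosomes
−2..+6 at 165-bp spacing with +1 starting at the TSS. Both species share
this architecture; 90% of genes enter the one-to-one ortholog map. The
default length range sits above the 700-bp analysis filter so that
full-size sector analyses (3 × 1200 genes) are feasible at n = 4000; the
filter itself is exercised on explicit fixtures.

Per-nucleosome emission intensities are `shape[mark][nuc] · 2^(amplitude)`
with fixed shapes: acetylation peaked at +1 (with a −1 promoter component
at 30% of genes), methylation plateauing over +2/+3 and decaying
downstream, H3 dipping at −1/promoter. The amplitude is the gene's log2
expression (Normal(4, 1)) plus independent per-mark noise (SD 0.6) plus a
class effect: `disparity_effect` (default +1 log2) added to acetylation at
OPN genes and to methylation at DPN genes. Species B shifts expression by
Normal(0, 0.6) per gene, and each mark follows that shift with its
coupling weight: Δmark = k·Δexpr + (1 − k)·Normal(0, 0.5), k = 0.8 for
H3K4me3 and 0.1 for H3K9ac by default — so full coupling (k = 1) copies
the expression divergence exactly and k = 0 decouples it.

Reads are single-end: fragment midpoints are drawn multinomially over
(gene, nucleosome) cells proportionally to intensity, uniform within the
nucleosome; fragments have constant length (default 150 bp, within the
150–300 bp sonication range typical of such experiments); each fragment
emits a forward read at its start and a reverse read at its last base,
each with probability 0.5. RNA-seq counts are Poisson with rate
proportional to gene length × 2^expression at a configured depth, two
replicates. The condition compendium draws each gene's series with a
planted SD (2.0 responsive, 0.2 non-responsive, 0.8 background).

What this emulates: strand-shift geometry, depth-dependent shot noise,
expression-coupled signal amplitude, promoter occupancy dips, class-biased
disparity, and controlled expression–chromatin co-divergence. What it
does not: sequence content and mappability bias, GC effects, fragment-size
dispersion, overdispersed counts, nucleosome positioning variability, or
cis/trans regulatory structure. Passing tests therefore demonstrate that
the estimators recover planted effects through realistic sampling noise —
not that real libraries are free of the unmodeled artifacts. One visible
consequence of the simple error model: with a pseudocount of 1 and
moderate depth, small log2 differences are shrunk toward zero, so
co-change proportions at the 0.4 threshold are conservative relative to a
deep real dataset.

## Problem sizes and numerics

Default test and pipeline scales (300–2000 genes, 10⁵–2×10⁶ reads per
sample) were chosen so each analysis stage runs in seconds while keeping
every estimator in its well-behaved regime; the coupling-contrast analysis
uses ~3000 orthologs at 2×10⁶ reads per sample, where the 0.4-gate passes
hundreds of genes. All generators and the pipeline are pure functions of
their config (including the seed): per-stage RNG streams are derived from
the config seed, and reruns are byte-identical. Degenerate inputs raise
explicit errors: constant strand profiles in the shift scan, zero-total
tracks in normalization, empty classes or sectors in enrichment, gates
with fewer than three genes in correlations.
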