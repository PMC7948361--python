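# Methods

## Coordinate model

All in-memory coordinates are 0-based half-open on the forward genomic
axis; BED/bedGraph are written natively, GTF converts to 1-based inclusive
at the boundary. *Upstream* and *downstream* always mean transcription
direction: on the − strand, downstream is decreasing genomic coordinate.
This single convention is load-bearing — the cleavage-event definition
(1 nt downstream of a trimmed read 3′ end), the internal-priming
adjacency rule, the CSE search window and all profile offsets are
transcript-centric, and every coordinate operation is covered by a
strand-mirror test (reverse-complementing the genome and flipping strands
reproduces the identical result at mirrored coordinates).

## Poly(A) tail detection

Trailing adenosines are found by a 3′→5′ scan with a 5-nt sliding window
allowing one non-A per window; the scan stops at the first window that
would contain two or more non-A. Leading non-A bases of the accepted
region are returned to the read body (the tail proper starts at the
region's first A), so a read ending `…T` + 10×A keeps the T. The tail is
trimmed iff the region contains ≥10 A's; reads shorter than 5 nt after
trimming are flagged unusable. These exact semantics are frozen in the
unit tests so the independent hand-simulated oracle and the code cannot
drift apart.

## Internal-priming masking

Genomic A-stretches are found by a direct scan (every 10-nt window with
≤2 non-A forward, or ≤2 non-T for − strand stretches; overlapping windows
merged, merged intervals trimmed to their outermost matching base so a
stretch never starts or ends on a mismatch). The scan is equivalent to
aligning A₁₀ with two mismatches and merging, without the aligner
dependency, and is checked against a brute-force 10-mer enumeration
oracle. A cleavage event is discarded when a same-strand stretch overlaps
it or begins within 5 nt downstream of it (`adjacency_nt`, configurable):
internal priming leaves templated adenosines immediately downstream of
the false 3′ end. Events, not windows, are filtered — an artifact can
therefore never seed a cluster.

## Clustering and windows

Pooled events (all samples) are visited most-upstream-first per
contig/strand. A cluster extends to the next downstream position while it
is ≤25 nt from the running median; medians are computed over events with
multiplicity (not unique positions), with the even-size median the mean
of the central pair. The greedy pass is deliberately order-dependent —
that is the definition — and is fuzz-tested against an independently
coded step-by-step oracle on 1,000 random instances. Each cluster becomes
a 15-nt window centered on the modal event position; ties go to the most
upstream position.

## Quantification and the compound filter

CE_window recounts events per sample inside each window. PU divides by
all cleavage events of the window's gene — pinned as every retained
event within the gene span or ≤50 nt downstream of it, the same slack
used for window-to-gene assignment; this keeps Σ PU ≤ 100 per gene, an
invariant the suite asserts. TPM = CE / 0.015 / (library total / 10⁶),
with the library total taken after trimming, deduplication and artifact
filtering, i.e. the denominators are the events that can actually appear
in windows. Replicates are averaged per condition; the filter takes the
maximum across conditions of CE_average, PU_average and the gene-level
TPM_maximum, all strict inequalities (a window at CE_average exactly 4
fails). The filter is applied to per-condition CE_average rather than
single-replicate CE_window — the per-replicate reading would make the
threshold depend on replicate count; the averaged reading is the one
consistent with the PU/TPM clauses.

## Annotation choices

Gene assignment uses the window center and same-strand genes only;
centers in more than one gene are removed, and orphan centers are rescued
only when exactly one gene ends 1–50 nt upstream. Region precedence on
multi-region overlap is 3′UTR > intron > Other. The CSE is searched in
the 50 nt upstream of the cleavage site with the hexamer fully contained
in that window; hierarchy AAUAAA > AUUAAA > remaining hexamers by closest
start to the PAS, alphabetical on ties. The 18-hexamer list ships as an
editable TSV (`pascape/data/cse_hexamers.tsv`); the code treats it as
data and only insists that the five canonical variants are present.
Caller matching (pPAS↔pPAS, dPAS↔dPAS within −250..+50 nt of the atlas
cleavage site) resolves conflicts globally by ascending absolute
distance, each site matched at most once; distances are measured between
cleavage sites, not window edges.

## Profiles and statistics

Motif and crosslink metaprofiles are per-offset fractions/rates relative
to the cleavage site (negative = upstream). Smoothing is local quadratic
least squares on the uniform offset grid (Savitzky–Golay) with the span
as the fraction of the grid in each fit, default 0.1 — the loess-type
smoother appropriate for an equally spaced 1-nt grid. Smoothing is
display-level only; every statistic runs on raw profiles, and a test
bounds the smoothed-vs-raw integral drift at 5%.

The matched-background z-score resamples the background pool 100 times
without replacement at the target set size, standardizes the target
profile by the per-offset resample mean and standard deviation (ddof=1),
converts to two-sided normal P values and applies Benjamini–Hochberg
across offsets; offsets with zero background spread are excluded and
reported. The FDR threshold defaults to 0.01.

Library comparison is a pooled two-proportions z-test per offset on
summed anchor counts against library event totals, after scaling library
B's counts and total by f = positions-with-signal(A) /
positions-with-signal(B); BH across offsets, flags at FDR ≤ 0.01. The
closed form is verified against statsmodels' implementation to 1e-9.

Significant crosslink sites use a within-gene permutation: the gene's
event total is redistributed uniformly over its positions 100 times, and
a count height h is significant when the mean permuted number of
positions ≥h is under 5% of the observed number. This is a
reimplementation of the height-based permutation FDR idea, not a wrapper
around any external CLIP toolchain. k-mer enrichment counts each
occurrence once (unweighted) in the −30..−5 and +5..+30 nt flanks,
shuffles sites uniformly within their genes preserving per-gene counts,
and ranks by z. Under a uniform null the per-run *maximum* |z| over all
k-mers has heavier-than-normal tails (overlapping flank windows make
k-mer counts clumpy); the calibrated statement, asserted in the tests, is
that the pooled fraction of |z| > 4 stays ≤1% with a pooled 99th
percentile below 4.

## Synthetic data: what it emulates, what it does not

The generator writes multi-exon genes (5′UTR / CDS / intron / CDS /
3′UTR) on both strands separated by intergenic spacers, background
sequence scrubbed of accidental A/T homopolymer windows so the A-stretch
content is fully controlled by the truth set. Per gene it plants 1–4 PASs
in the 3′UTR (≥80 nt apart, Dirichlet usage weights bounded at 0.15 so
every planted site is quantifiable), a CSE drawn from a configurable
frequency table (start −30..−15 nt, C-guarded so planting cannot create
homopolymer artifacts, with all other listed hexamers scrubbed from the
−53..+2 nt neighbourhood so the planted signal is the unique occurrence),
optional UGUA elements at −70..−55, and A-stretches (Poisson per gene and
per spacer, default mean 1) at ≥40 nt from any PAS. Reads carry 8-nt
UMIs in the read name, constant Phred 30, non-templated tails of 12–20
A's, and rounded-Gaussian cleavage jitter (default sd 1 nt); internal-
priming reads terminate at planted stretches with templated adenosines;
duplicates repeat UMI and coordinates. Crosslink counts are Poisson with
a uniform background plus Gaussian bumps at −75 nt scaled by PAS usage.

Not emulated: sequencing errors outside the tail, quality-score
variation, fragment-length effects, expression-level dispersion between
replicates beyond multinomial/Poisson sampling, overlapping or nested
genes, and alternative transcript structures. Passing the recovery tests
therefore shows the *rules* are implemented correctly and are robust to
jitter, duplicates and artifact reads — not that the thresholds are
optimal for any particular real library.

## Problem sizes and determinism

The validation suite runs at desk scale: 4–10 gene genomes (~10 kb),
20–30 reads per PAS, 50-seed calibration loops, 100 permutations /
resamples / shuffles as the procedures specify. The full suite finishes
in well under a minute on one CPU; the acceptance script in seconds.
Every stochastic component takes a `numpy` `default_rng` seed, derived
seeds stay below 2³¹, and the pipeline manifest records SHA-256 of every
output so bit-identical reruns are machine-checkable (and asserted in the
tests).

## Known limitations

Atlas-scale numbers from real data (tens of thousands of PASs) require
real 3′ end libraries and an external aligner, both out of scope; the
BED-of-aligned-3′-ends input path replaces mapping. BAM input is not
implemented (convert to BED first); bigWig/CRAM are unsupported. The
two-proportions test uses library event totals as denominators with the
positions-based scaling factor — both choices are exposed as arguments.
DaPars/MISO internals are consumed as tables, never re-implemented.
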