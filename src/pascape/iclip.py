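"""Crosslink-track analytics downstream of iCLIP mapping.

A crosslink event marks the nucleotide where reverse transcription
truncated at the protein-RNA contact — one position upstream of the
aligned read start.  On top of the per-position count tracks this module
provides permutation-based significant-site calling, k-mer enrichment
against within-gene shuffles, PAS-anchored metaprofiles with the two-step
normalization (per anchor count, then per library positions-with-signal),
and two library-comparison statistics (nucleotide-wise two-proportions
z-tests with a depth scaling factor, and the resampled-background
z-score).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .coords import check_strand
from .io_formats import GeneModel, GenomeSequence
from .motifs import BackgroundZ, background_zscore
from .smoothing import loess_smooth

TRACK_COLUMNS = ["contig", "strand", "position", "count"]


@dataclass
class CrosslinkTrack:
    """Per-position crosslink-event counts for one iCLIP library."""

    library_id: str
    counts: pd.DataFrame  # contig, strand, position, count (count ≥ 1)

    def __post_init__(self):
        self.counts = (
            self.counts.groupby(["contig", "strand", "position"], as_index=False)["count"]
            .sum()
            .sort_values(["contig", "strand", "position"], kind="mergesort")
            .reset_index(drop=True)
        )
        if (self.counts["count"] < 1).any():
            raise ValueError("crosslink counts must be ≥ 1 at stored positions")
        for s in self.counts["strand"].unique():
            check_strand(s)

    @property
    def total_events(self) -> int:
        return int(self.counts["count"].sum())

    @property
    def n_positions(self) -> int:
        return int(len(self.counts))

    def gene_counts(self, gene: GeneModel) -> np.ndarray:
        """Count vector over the gene span (transcription order)."""
        m = (
            (self.counts["contig"] == gene.contig)
            & (self.counts["strand"] == gene.strand)
            & (self.counts["position"] >= gene.start)
            & (self.counts["position"] < gene.end)
        )
        vec = np.zeros(gene.end - gene.start, dtype=int)
        sub = self.counts.loc[m]
        vec[sub["position"].to_numpy() - gene.start] = sub["count"].to_numpy()
        return vec if gene.strand == "+" else vec[::-1]


def extract_crosslinks(
    read_starts: pd.DataFrame,
    library_id: str,
    genome: GenomeSequence | None = None,
) -> CrosslinkTrack:
    """Aggregate deduplicated read starts into a crosslink-event track.

    The crosslink sits 1 nt upstream (transcription direction) of the read
    start: start − 1 on the + strand, start + 1 on −.  ``read_starts``
    needs columns contig, strand, position (and optionally count).
    Positions falling off a contig are dropped with a warning.
    """
    df = read_starts.copy()
    if "count" not in df.columns:
        df["count"] = 1
    df["position"] = np.where(df["strand"] == "+", df["position"] - 1, df["position"] + 1)
    if genome is not None:
        ok = np.ones(len(df), dtype=bool)
        for i, row in enumerate(df.itertuples(index=False)):
            if row.position < 0 or row.position >= genome.length(row.contig):
                ok[i] = False
        if not ok.all():
            warnings.warn(f"{(~ok).sum()} crosslink positions off-contig; dropped")
            df = df.loc[ok]
    return CrosslinkTrack(library_id=library_id, counts=df[TRACK_COLUMNS])


# ---------------------------------------------------------------------------
# significant crosslink sites


def call_significant_xlinks(
    track: CrosslinkTrack,
    genes: dict[str, GeneModel],
    n_perm: int = 100,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation FDR for crosslink positions within co-transcribed regions.

    Per gene, the gene's total events are relocated uniformly over the gene
    positions ``n_perm`` times.  For an observed count height h,
    FDR(h) = mean permuted number of positions with count ≥ h divided by
    the observed number; positions whose height has FDR < ``fdr`` are
    significant.  Genes with fewer than 2 events yield no calls.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes.values():
        vec = track.gene_counts(gene)
        total = int(vec.sum())
        if total < 2:
            continue
        L = vec.size
        perm_counts = rng.multinomial(total, np.full(L, 1.0 / L), size=n_perm)
        heights = np.unique(vec[vec > 0])
        for h in heights:
            obs_n = int((vec >= h).sum())
            perm_n = (perm_counts >= h).sum(axis=1).mean()
            fdr_h = perm_n / obs_n
            if fdr_h < fdr:
                idx = np.flatnonzero(vec == h)
                for i in idx:
                    pos = gene.start + i if gene.strand == "+" else gene.end - 1 - i
                    rows.append(
                        (gene.contig, gene.strand, int(pos), int(h), float(fdr_h), gene.gene_id)
                    )
    return pd.DataFrame(
        rows, columns=["contig", "strand", "position", "count", "fdr", "gene_id"]
    ).sort_values(["contig", "strand", "position"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# k-mer enrichment


def _flank_kmers(
    genome: GenomeSequence,
    gene: GeneModel,
    contig: str,
    strand: str,
    position: int,
    k: int,
) -> Counter:
    """k-mers in the two crosslink flanks (txn offsets −30..−5 and +5..+30),
    truncated to the gene span; the ±4-nt core around the crosslink is
    excluded by construction."""
    out: Counter = Counter()
    for lo, hi in ((-30, -5), (5, 30)):
        # clip the offset interval to the gene extent
        if strand == "+":
            glo = max(gene.start, position + lo) - position
            ghi = min(gene.end - 1, position + hi) - position
        else:
            glo = max(lo, position - (gene.end - 1))
            ghi = min(hi, position - gene.start)
        if ghi - glo + 1 < k:
            continue
        seq, actual_lo = genome.fetch_offsets(contig, strand, position, glo, ghi)
        for i in range(len(seq) - k + 1):
            out[seq[i : i + k]] += 1
    return out


@dataclass
class KmerEnrichment:
    k: int
    table: pd.DataFrame  # kmer, observed, shuffle_mean, shuffle_sd, z, rank
    n_windows_scanned: int


def kmer_zscore(
    significant: pd.DataFrame,
    genome: GenomeSequence,
    genes: dict[str, GeneModel],
    k: int = 5,
    n_shuffles: int = 100,
    seed: int = 0,
) -> KmerEnrichment:
    """k-mer enrichment around significant crosslinks vs within-gene shuffles.

    k-mers are counted (unweighted, overlapping) in the flank intervals
    −30..−5 and +5..+30 nt around each significant crosslink.  Each of the
    ``n_shuffles`` controls relocates every crosslink uniformly within its
    gene, preserving per-gene site counts exactly; z = (observed − shuffle
    mean) / shuffle sd, ranked by z (ties and undefined z ranked last,
    alphabetical within ties).
    """
    if significant.empty:
        raise ValueError("no significant crosslink positions supplied")
    rng = np.random.default_rng(seed)
    sites = [
        (genes[row.gene_id], row.contig, row.strand, int(row.position))
        for row in significant.itertuples(index=False)
    ]
    observed: Counter = Counter()
    for gene, contig, strand, pos in sites:
        observed += _flank_kmers(genome, gene, contig, strand, pos, k)
    shuffle_counts: dict[str, np.ndarray] = {}
    for si in range(n_shuffles):
        cnt: Counter = Counter()
        for gene, contig, strand, _ in sites:
            p = int(rng.integers(gene.start, gene.end))
            cnt += _flank_kmers(genome, gene, contig, strand, p, k)
        for kmer, c in cnt.items():
            shuffle_counts.setdefault(kmer, np.zeros(n_shuffles))[si] = c
    kmers = sorted(set(observed) | set(shuffle_counts))
    rows = []
    for kmer in kmers:
        obs = observed.get(kmer, 0)
        arr = shuffle_counts.get(kmer, np.zeros(n_shuffles))
        mu, sd = arr.mean(), arr.std(ddof=1)
        z = (obs - mu) / sd if sd > 0 else np.nan
        rows.append((kmer, obs, mu, sd, z))
    df = pd.DataFrame(rows, columns=["kmer", "observed", "shuffle_mean", "shuffle_sd", "z"])
    df = df.sort_values(["z", "kmer"], ascending=[False, True], na_position="last").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return KmerEnrichment(k=k, table=df, n_windows_scanned=int(sum(observed.values())))


# ---------------------------------------------------------------------------
# PAS-anchored metaprofiles and library comparisons


@dataclass
class XlinkProfile:
    library_id: str
    offsets: np.ndarray
    raw: np.ndarray  # two-step normalized: per anchor, then per positions-with-signal
    smoothed: np.ndarray
    n_anchors: int
    n_library_positions: int


def _summed_anchor_counts(
    track: CrosslinkTrack, anchors, lo: int, hi: int
) -> np.ndarray:
    offsets = np.arange(lo, hi + 1)
    out = np.zeros(offsets.size, dtype=float)
    by_key = {
        key: grp.set_index("position")["count"]
        for key, grp in track.counts.groupby(["contig", "strand"])
    }
    for contig, strand, center in anchors:
        series = by_key.get((contig, strand))
        if series is None:
            continue
        if strand == "+":
            pos = center + offsets
        else:
            pos = center - offsets
        vals = series.reindex(pos).fillna(0.0).to_numpy()
        out += vals
    return out


def pas_metaprofile(
    track: CrosslinkTrack,
    anchors,
    lo: int = -400,
    hi: int = 100,
    span: float = 0.1,
) -> XlinkProfile:
    """Normalized crosslink metaprofile around a set of PASs.

    Two normalization steps: summed per-offset counts are divided by the
    number of anchor PASs (making PAS categories comparable) and then by
    the library's number of positions with crosslink signal (making
    libraries comparable).
    """
    anchors = list(anchors)
    if not anchors:
        raise ValueError("empty anchor set")
    summed = _summed_anchor_counts(track, anchors, lo, hi)
    raw = summed / len(anchors) / track.n_positions
    return XlinkProfile(
        library_id=track.library_id,
        offsets=np.arange(lo, hi + 1),
        raw=raw,
        smoothed=loess_smooth(raw, span),
        n_anchors=len(anchors),
        n_library_positions=track.n_positions,
    )


def two_proportions_z(x1: float, n1: float, x2: float, n2: float) -> float:
    """Pooled two-proportions z statistic for x1/n1 vs x2/n2."""
    p1, p2 = x1 / n1, x2 / n2
    p = (x1 + x2) / (n1 + n2)
    if p <= 0 or p >= 1:
        return 0.0
    se = np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    return float((p1 - p2) / se)


@dataclass
class ComparisonResult:
    offsets: np.ndarray
    z: np.ndarray
    pvals: np.ndarray
    qvals: np.ndarray
    flags: np.ndarray
    scaling_factor: float


def compare_profiles(
    track_a: CrosslinkTrack,
    track_b: CrosslinkTrack,
    anchors,
    lo: int = -400,
    hi: int = 100,
    fdr: float = 0.01,
) -> ComparisonResult:
    """Nucleotide-wise two-proportions z-test between two libraries.

    At each offset the summed anchor counts are compared as proportions of
    the library totals (total events).  Library B's counts and total are
    scaled by f = positions-with-signal(A) / positions-with-signal(B) to
    account for sequencing depth.  BH correction across offsets, flags at
    FDR ≤ ``fdr``.
    """
    anchors = list(anchors)
    if track_a.total_events == 0 or track_b.total_events == 0:
        raise ValueError("zero-event library")
    xa = _summed_anchor_counts(track_a, anchors, lo, hi)
    xb = _summed_anchor_counts(track_b, anchors, lo, hi)
    f = track_a.n_positions / track_b.n_positions
    na, nb = track_a.total_events, track_b.total_events * f
    z = np.array(
        [two_proportions_z(a, na, b * f, nb) for a, b in zip(xa, xb)]
    )
    pvals = 2 * norm.sf(np.abs(z))
    rej, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return ComparisonResult(
        offsets=np.arange(lo, hi + 1),
        z=z,
        pvals=pvals,
        qvals=qvals,
        flags=qvals <= fdr,
        scaling_factor=f,
    )


def profile_background_z(
    track: CrosslinkTrack,
    target_anchors,
    pool_anchors,
    lo: int = -400,
    hi: int = 100,
    n_resamples: int = 100,
    fdr: float = 0.01,
    seed: int = 0,
) -> BackgroundZ:
    """Resampling z-score of a target anchor set's crosslink profile.

    Same contract as the motif background z-score, but each resampled
    profile is the normalized crosslink metaprofile of a size-matched
    subset of unaffected PASs.
    """
    target_anchors = list(target_anchors)
    target = pas_metaprofile(track, target_anchors, lo, hi).raw
    return background_zscore(
        target,
        list(pool_anchors),
        lambda sub: pas_metaprofile(track, sub, lo, hi).raw,
        sample_size=len(target_anchors),
        n_resamples=n_resamples,
        fdr=fdr,
        seed=seed,
    )
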