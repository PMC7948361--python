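"""PAS discovery from 3' end sequencing reads.

The stages mirror how single-nucleotide cleavage sites are called from
poly(A)-anchored 3' end libraries (MACE-style):

1. quality trimming + UMI deduplication (:func:`prepare_reads`)
2. trailing poly(A) detection/trimming (:func:`trim_polya`)
3. cleavage events = 1 nt downstream of each trimmed read 3' end
4. internal-priming masking against genomic A-stretches
   (:func:`find_genomic_a_stretches`, :func:`filter_internal_priming`)
5. greedy median clustering of cleavage events (≤25 nt from the running
   cluster median) and 15-nt windows centered on the mode
6. CE / PU / TPM quantification with the compound filter
   CE_average > 4 AND PU_average > 5% AND TPM_maximum > 0.25
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coords import check_strand
from .io_formats import GeneModel, GenomeSequence, window_to_bed_interval

EVENT_COLUMNS = ["contig", "strand", "position", "sample_id", "count"]


# ---------------------------------------------------------------------------
# read preparation


@dataclass
class TrimResult:
    trimmed: str
    n_trailing_a: int
    is_polya: bool
    usable: bool


def trim_polya(seq: str, min_a: int = 10, window: int = 5, min_usable: int = 5) -> TrimResult:
    """Detect and trim a trailing poly(A) stretch from a read (given 5'->3').

    Scanning 3'->5', the accepted trailing region is the maximal suffix in
    which every complete 5-nt window contains at most one non-adenosine; the
    scan stops at the first window that would contain two or more.  Leading
    non-A bases of the accepted region belong to the read body, so the tail
    proper starts at the region's first A.  The tail is trimmed iff it
    contains at least ``min_a`` adenosines.
    """
    seq = seq.upper()
    n = len(seq)
    stop = n  # leftmost admissible suffix start found so far
    for p in range(n - 1, -1, -1):
        if p + window <= n:
            win = seq[p : p + window]
            if sum(1 for b in win if b != "A") >= 2:
                break
        stop = p
    # tail starts at the first A of the accepted region
    tail_start = stop
    while tail_start < n and seq[tail_start] != "A":
        tail_start += 1
    n_a = seq.count("A", tail_start)
    is_polya = n_a >= min_a
    trimmed = seq[:tail_start] if is_polya else seq
    usable = len(trimmed) >= min_usable
    return TrimResult(trimmed=trimmed, n_trailing_a=n_a, is_polya=is_polya, usable=usable)


def quality_trim(seq: str, quals: Sequence[int], cutoff: int = 16) -> tuple[str, list[int]]:
    """Trim low-quality bases (Phred < cutoff) from both ends of a read."""
    lo, hi = 0, len(seq)
    while lo < hi and quals[lo] < cutoff:
        lo += 1
    while hi > lo and quals[hi - 1] < cutoff:
        hi -= 1
    return seq[lo:hi], list(quals[lo:hi])


@dataclass
class PreparedRead:
    name: str
    umi: str
    seq: str
    quals: list[int]


def umi_from_name(name: str) -> str | None:
    """UMI = last colon-separated field of the read name (simulator convention)."""
    if ":" not in name:
        return None
    umi = name.rsplit(":", 1)[1]
    if umi and set(umi) <= set("ACGTN"):
        return umi
    return None


def prepare_reads(
    reads: Iterable[tuple[str, str, Sequence[int]]],
    phred_cutoff: int = 16,
    coordinates: dict[str, tuple] | None = None,
) -> tuple[list[PreparedRead], dict[str, int]]:
    """Quality-trim both read ends and collapse PCR duplicates.

    ``reads`` yields (name, sequence, phred qualities).  Duplicates share a
    UMI and — when ``coordinates`` maps read names to aligned coordinates —
    the same coordinate; the first occurrence survives.  Reads without a
    parseable UMI are dropped with a warning.
    """
    kept: list[PreparedRead] = []
    seen: set = set()
    log = {"n_in": 0, "n_no_umi": 0, "n_duplicates": 0, "n_kept": 0}
    for name, seq, quals in reads:
        log["n_in"] += 1
        umi = umi_from_name(name)
        if umi is None:
            log["n_no_umi"] += 1
            warnings.warn(f"read {name!r} has no UMI; dropped")
            continue
        key = (umi, coordinates.get(name)) if coordinates is not None else (umi,)
        if key in seen:
            log["n_duplicates"] += 1
            continue
        seen.add(key)
        tseq, tquals = quality_trim(seq, quals, cutoff=phred_cutoff)
        kept.append(PreparedRead(name=name, umi=umi, seq=tseq, quals=tquals))
    log["n_kept"] = len(kept)
    return kept, log


# ---------------------------------------------------------------------------
# genomic A-stretches and internal priming


def _stretches_one_sense(seq: str, base: str, window: int = 10, max_other: int = 2):
    """Merged intervals of 10-nt windows with ≤2 bases differing from ``base``."""
    n = len(seq)
    if n < window:
        return
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_other = (arr != ord(base)).astype(np.int32)
    csum = np.concatenate(([0], np.cumsum(is_other)))
    wsum = csum[window:] - csum[:-window]  # mismatches per window start
    ok = wsum <= max_other
    # merge overlapping passing windows
    starts = np.flatnonzero(ok)
    if starts.size == 0:
        return
    block_start = int(starts[0])
    prev = int(starts[0])
    for s in starts[1:]:
        s = int(s)
        if s <= prev + window:  # windows [prev,prev+10) and [s,s+10) overlap or touch
            prev = s
        else:
            yield block_start, prev + window
            block_start = prev = s
    yield block_start, prev + window


def find_genomic_a_stretches(genome: GenomeSequence, window: int = 10, max_mismatch: int = 2) -> pd.DataFrame:
    """Locate homopolymeric A-stretches on both strands of the genome.

    Every 10-nt window with at most two non-A (forward, + strand) or two
    non-T (forward, − strand, i.e. an A-stretch on the transcript) passes;
    overlapping windows are merged per strand and merged intervals trimmed
    to their outermost matching base, so a stretch never starts or ends on
    a mismatch.
    """
    rows = []
    for contig in genome:
        seq = genome[contig]
        for strand, base in (("+", "A"), ("-", "T")):
            for s, e in _stretches_one_sense(seq, base, window, max_mismatch):
                while s < e and seq[s] != base:
                    s += 1
                while e > s and seq[e - 1] != base:
                    e -= 1
                if e - s >= window:
                    rows.append((contig, strand, s, e))
    return pd.DataFrame(rows, columns=["contig", "strand", "start", "end"])


def events_from_bed(bed: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    """Cleavage events from aligned poly(A)-trimmed reads (BED6 intervals).

    The cleavage event sits 1 nt downstream (transcription direction) of the
    read 3' end: ``end`` on the + strand, ``start − 1`` on the − strand.
    """
    pos = np.where(bed["strand"] == "+", bed["end"], bed["start"] - 1)
    df = pd.DataFrame(
        {"contig": bed["contig"], "strand": bed["strand"], "position": pos}
    )
    grouped = (
        df.groupby(["contig", "strand", "position"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    grouped["sample_id"] = sample_id
    return grouped[EVENT_COLUMNS]


def filter_internal_priming(
    events: pd.DataFrame, stretches: pd.DataFrame, adjacency_nt: int = 5
) -> tuple[pd.DataFrame, int]:
    """Drop events adjacent to (or inside) a same-strand genomic A-stretch.

    An event is removed iff an A-stretch overlaps its position or begins
    within ``adjacency_nt`` nt downstream of it (transcription direction):
    internal priming leaves templated adenosines immediately downstream of
    the false 3' end.
    """
    if events.empty or stretches.empty:
        return events.copy(), 0
    removed = np.zeros(len(events), dtype=bool)
    for (contig, strand), sgrp in stretches.groupby(["contig", "strand"]):
        mask = (events["contig"] == contig) & (events["strand"] == strand)
        if not mask.any():
            continue
        pos = events.loc[mask, "position"].to_numpy()
        hit = np.zeros(pos.shape, dtype=bool)
        for s, e in zip(sgrp["start"], sgrp["end"]):
            inside = (pos >= s) & (pos < e)
            if strand == "+":
                near = (s >= pos) & (s - pos <= adjacency_nt)
            else:
                tstart = e - 1  # transcription-direction start of the stretch
                near = (tstart <= pos) & (pos - tstart <= adjacency_nt)
            hit |= inside | near
        removed[np.flatnonzero(mask.to_numpy())[hit]] = True
    kept = events.loc[~removed].reset_index(drop=True)
    n_removed_events = int(events.loc[removed, "count"].sum())
    return kept, n_removed_events


# ---------------------------------------------------------------------------
# clustering and windows


@dataclass
class PASCluster:
    contig: str
    strand: str
    positions: list[int] = field(default_factory=list)  # txn order, with multiplicity

    @property
    def median(self) -> float:
        srt = sorted(self.positions)
        m = len(srt)
        mid = m // 2
        return float(srt[mid]) if m % 2 else (srt[mid - 1] + srt[mid]) / 2.0

    def counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for p in self.positions:
            out[p] = out.get(p, 0) + 1
        return out


def cluster_cleavage_events(events: pd.DataFrame, max_dist: int = 25) -> list[PASCluster]:
    """Greedy clustering of pooled cleavage events along transcription.

    Events (with multiplicity) are visited most-upstream-first per
    contig/strand; the current cluster extends to the next downstream
    position while it lies within ``max_dist`` nt of the running median
    (median over events, not unique positions); otherwise the cluster is
    closed and reseeded.
    """
    clusters: list[PASCluster] = []
    pooled = (
        events.groupby(["contig", "strand", "position"], as_index=False)["count"].sum()
    )
    for (contig, strand), grp in pooled.groupby(["contig", "strand"]):
        check_strand(strand)
        grp = grp.sort_values("position", ascending=(strand == "+"))
        cur: PASCluster | None = None
        for row in grp.itertuples(index=False):
            for _ in range(int(row.count)):
                if cur is None:
                    cur = PASCluster(contig=contig, strand=strand, positions=[row.position])
                    continue
                if abs(row.position - cur.median) <= max_dist:
                    cur.positions.append(int(row.position))
                else:
                    clusters.append(cur)
                    cur = PASCluster(contig=contig, strand=strand, positions=[row.position])
        if cur is not None:
            clusters.append(cur)
    return clusters


@dataclass
class PASWindow:
    """A 15-nt cleavage-site window centered on the mode cleavage event."""

    contig: str
    strand: str
    center: int
    start: int
    end: int
    gene_id: str | None = None

    def __post_init__(self):
        if self.end - self.start != 15:
            raise ValueError("PAS window must be exactly 15 nt wide")


def define_pas_window(cluster: PASCluster) -> PASWindow:
    """Resize a cluster to the 15-nt window centered on its mode position.

    The center is the position carrying the most cleavage events; ties go to
    the most upstream position in transcription direction.
    """
    if not cluster.positions:
        raise ValueError("empty cluster")
    counts = cluster.counts()
    best = max(counts)
    best_n = -1
    for pos in sorted(counts, reverse=(cluster.strand == "-")):
        if counts[pos] > best_n:
            best, best_n = pos, counts[pos]
    start, end = window_to_bed_interval(best)
    return PASWindow(contig=cluster.contig, strand=cluster.strand, center=best, start=start, end=end)


# ---------------------------------------------------------------------------
# quantification and filtering


def _gene_event_total(gene: GeneModel, sample_events: pd.DataFrame, downstream_slack: int = 50) -> int:
    """All cleavage events of one sample assigned to the gene.

    Counts events inside the gene span or up to ``downstream_slack`` nt
    downstream of it (transcription direction) — the same slack used for
    window-to-gene assignment.
    """
    mask = (sample_events["contig"] == gene.contig) & (sample_events["strand"] == gene.strand)
    sub = sample_events.loc[mask]
    if sub.empty:
        return 0
    lo, hi = gene.start, gene.end
    if gene.strand == "+":
        hi += downstream_slack
    else:
        lo -= downstream_slack
    return int(sub.loc[(sub["position"] >= lo) & (sub["position"] < hi), "count"].sum())


def quantify_and_filter(
    windows: Sequence[PASWindow],
    events: pd.DataFrame,
    condition_map: dict[str, str],
    genes: dict[str, GeneModel],
    min_ce: float = 4.0,
    min_pu: float = 5.0,
    min_tpm: float = 0.25,
    window_kb: float = 0.015,
) -> pd.DataFrame:
    """Quantify 15-nt windows per sample and apply the compound usage filter.

    For every window and sample, CE_window recounts the cleavage events
    inside the window; PU = CE_window / all events of the gene × 100;
    TPM = CE_window / 0.015 / (library total / 10^6).  Replicates are
    averaged per condition; TPM_maximum is the per-gene maximum of
    TPM_average.  A window passes iff, taking the maximum across
    conditions, CE_average > ``min_ce`` AND PU_average > ``min_pu`` AND
    the gene-level TPM_maximum > ``min_tpm`` (all strict).

    Windows must carry a ``gene_id``; genes with zero assigned events are
    skipped with a warning.  Returns a tidy table with one row per window,
    per-condition statistics and a boolean ``passed`` column.
    """
    samples = sorted(condition_map)
    conditions = sorted(set(condition_map.values()))
    lib_totals = {
        s: int(events.loc[events["sample_id"] == s, "count"].sum()) for s in samples
    }
    rows = []
    skipped_genes: set[str] = set()
    by_sample = {s: events.loc[events["sample_id"] == s] for s in samples}
    for wi, w in enumerate(windows):
        if w.gene_id is None:
            raise ValueError("quantify_and_filter requires gene-assigned windows")
        gene = genes[w.gene_id]
        ce, pu, tpm = {}, {}, {}
        gene_zero = False
        for s in samples:
            sev = by_sample[s]
            m = (
                (sev["contig"] == w.contig)
                & (sev["strand"] == w.strand)
                & (sev["position"] >= w.start)
                & (sev["position"] < w.end)
            )
            ce_w = float(sev.loc[m, "count"].sum())
            gt = _gene_event_total(gene, sev)
            if gt == 0 and ce_w > 0:
                gene_zero = True
            ce[s] = ce_w
            pu[s] = (ce_w / gt * 100.0) if gt > 0 else np.nan
            tpm[s] = ce_w / window_kb / (lib_totals[s] / 1e6) if lib_totals[s] > 0 else np.nan
        all_gene_totals = [
            _gene_event_total(gene, by_sample[s]) for s in samples
        ]
        if all(t == 0 for t in all_gene_totals):
            if w.gene_id not in skipped_genes:
                warnings.warn(f"gene {w.gene_id} has zero cleavage events; windows skipped")
                skipped_genes.add(w.gene_id)
            continue
        row = {
            "window_index": wi,
            "contig": w.contig,
            "strand": w.strand,
            "center": w.center,
            "start": w.start,
            "end": w.end,
            "gene_id": w.gene_id,
        }
        for c in conditions:
            reps = [s for s in samples if condition_map[s] == c]
            row[f"ce_average_{c}"] = float(np.mean([ce[s] for s in reps]))
            row[f"pu_average_{c}"] = float(np.nanmean([pu[s] for s in reps]))
            row[f"tpm_average_{c}"] = float(np.nanmean([tpm[s] for s in reps]))
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    # gene-level TPM_maximum per condition
    for c in conditions:
        df[f"tpm_maximum_{c}"] = df.groupby("gene_id")[f"tpm_average_{c}"].transform("max")
    ce_max = df[[f"ce_average_{c}" for c in conditions]].max(axis=1)
    pu_max = df[[f"pu_average_{c}" for c in conditions]].max(axis=1)
    tpm_max = df[[f"tpm_maximum_{c}" for c in conditions]].max(axis=1)
    df["passed"] = (ce_max > min_ce) & (pu_max > min_pu) & (tpm_max > min_tpm)
    return df
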