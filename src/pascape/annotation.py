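"""Annotation of PAS windows: gene/region assignment, s/p/o/d typing,
CSE hexamer calling, matching to coverage-based APA callers, and gene-set
overlap statistics.

A gene with a single PAS carries an sPAS; a gene with two or more carries
exactly one proximal (pPAS, most upstream), one distal (dPAS, most
downstream) and any number of intermediate oPASs — upstream/downstream in
transcription direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .coords import txn_offset
from .discovery import PASWindow
from .io_formats import DaParsRecord, GeneModel, GenomeSequence

PAS_TYPES = ("sPAS", "pPAS", "oPAS", "dPAS")
REGION_OTHER = "Other"

REQUIRED_HEXAMERS = {"AAUAAA", "AUUAAA", "UAUAAA", "AAGAAA", "AAUAUA"}


def load_cse_hexamers(path=None) -> list[str]:
    """The configurable CSE hexamer list (RNA alphabet), shipped as data.

    The default table holds 18 poly(A)-signal variants commonly reported in
    genome-wide PAS compendia; users can point to their own single-column
    TSV.
    """
    if path is None:
        with resources.files("pascape.data").joinpath("cse_hexamers.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    hexamers = [h.strip().upper().replace("T", "U") for h in df["hexamer"]]
    missing = REQUIRED_HEXAMERS - set(hexamers)
    if missing:
        raise ValueError(f"hexamer list missing required members: {sorted(missing)}")
    return hexamers


@dataclass
class PASRecord:
    """An annotated polyadenylation site."""

    window: PASWindow
    gene_id: str
    region: str
    pas_type: str | None = None
    cse: str | None = None
    cse_offset: int | None = None
    distance_to_annotated_end: int | None = None
    cse_window_truncated: bool = False

    @property
    def center(self) -> int:
        return self.window.center

    @property
    def strand(self) -> str:
        return self.window.strand

    @property
    def contig(self) -> str:
        return self.window.contig


def assign_gene_and_region(
    window: PASWindow,
    genes: dict[str, GeneModel],
    downstream_slack: int = 50,
) -> PASRecord | None:
    """Assign a window to a gene by its center, or drop it.

    A window whose center overlaps more than one same-strand gene is
    removed (``None``).  Centers in no gene but 1–50 nt downstream of
    exactly one gene are assigned to that gene's 3'UTR.  Region calls
    follow overlap of the center with annotated subregions, with the
    precedence 3'UTR > intron > Other when several kinds overlap.
    """
    c = window.center
    hits = [
        g
        for g in genes.values()
        if g.contig == window.contig
        and g.strand == window.strand
        and g.start <= c < g.end
    ]
    if len(hits) > 1:
        return None
    if len(hits) == 1:
        gene = hits[0]
        kinds = {k for k, s, e in gene.regions if s <= c < e}
        if not kinds:
            region = REGION_OTHER
        elif len(kinds) == 1:
            region = kinds.pop()
        elif "3UTR" in kinds:
            region = "3UTR"
        elif "intron" in kinds:
            region = "intron"
        else:
            region = REGION_OTHER
    else:
        downstream = [
            g
            for g in genes.values()
            if g.contig == window.contig
            and g.strand == window.strand
            and 1 <= txn_offset(c, g.tes, g.strand) <= downstream_slack
        ]
        if len(downstream) != 1:
            return None
        gene = downstream[0]
        region = "3UTR"
    window.gene_id = gene.gene_id
    ends = gene.annotated_3p_ends or [gene.tes]
    dist = min(
        (txn_offset(c, e, gene.strand) for e in ends), key=abs
    )
    return PASRecord(
        window=window,
        gene_id=gene.gene_id,
        region=region,
        distance_to_annotated_end=int(dist),
    )


def classify_pas_types(records: Sequence[PASRecord]) -> list[PASRecord]:
    """Type every PAS as sPAS / pPAS / oPAS / dPAS within its gene."""
    by_gene: dict[str, list[PASRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    for gene_id, recs in by_gene.items():
        recs.sort(key=lambda r: r.center, reverse=(recs[0].strand == "-"))
        if len(recs) == 1:
            recs[0].pas_type = "sPAS"
        else:
            for r in recs:
                r.pas_type = "oPAS"
            recs[0].pas_type = "pPAS"
            recs[-1].pas_type = "dPAS"
    return list(records)


def assign_cse(
    record: PASRecord,
    genome: GenomeSequence,
    hexamers: Sequence[str],
    upstream_nt: int = 50,
) -> PASRecord:
    """Assign the CSE hexamer in the 50 nt upstream of the cleavage site.

    Hierarchy: AAUAAA beats AUUAAA beats everything else; among the
    remaining hexamers the one whose start is closest to the PAS wins,
    ties broken alphabetically.  Only hexamers fully contained in the
    upstream window count.  A window truncated by the contig edge is
    searched as far as available and flagged.
    """
    c, strand, contig = record.center, record.strand, record.contig
    if strand == "+":
        lo, hi = c - upstream_nt, c
    else:
        lo, hi = c + 1, c + 1 + upstream_nt
    seq = genome.fetch(contig, lo, hi, strand)  # 5'->3', ends just before the PAS
    record.cse_window_truncated = len(seq) < upstream_nt
    hits: list[tuple[str, int]] = []  # (hexamer RNA, start offset relative to PAS)
    n = len(seq)
    for hx in hexamers:
        dna = hx.replace("U", "T")
        start = seq.find(dna)
        while start != -1:
            hits.append((hx, start - n))
            start = seq.find(dna, start + 1)
    if not hits:
        record.cse, record.cse_offset = None, None
        return record
    for preferred in ("AAUAAA", "AUUAAA"):
        cand = [(hx, off) for hx, off in hits if hx == preferred]
        if cand:
            hx, off = max(cand, key=lambda t: t[1])  # closest to the PAS
            record.cse, record.cse_offset = hx, off
            return record
    # other hexamers: closest start to the PAS, alphabetical on ties
    hx, off = min(hits, key=lambda t: (-t[1], t[0]))
    record.cse, record.cse_offset = hx, off
    return record


def annotate_windows(
    windows: Iterable[PASWindow],
    genes: dict[str, GeneModel],
    genome: GenomeSequence | None = None,
    hexamers: Sequence[str] | None = None,
) -> tuple[list[PASRecord], int]:
    """Gene/region assignment, typing and (optionally) CSE calling.

    Returns the annotated records and the count of removed windows.
    """
    records, removed = [], 0
    for w in windows:
        rec = assign_gene_and_region(w, genes)
        if rec is None:
            removed += 1
        else:
            records.append(rec)
    classify_pas_types(records)
    if genome is not None:
        hexamers = hexamers if hexamers is not None else load_cse_hexamers()
        for rec in records:
            assign_cse(rec, genome, hexamers)
    return records, removed


def records_to_table(records: Sequence[PASRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [r.contig for r in records],
            "strand": [r.strand for r in records],
            "center": [r.center for r in records],
            "start": [r.window.start for r in records],
            "end": [r.window.end for r in records],
            "gene_id": [r.gene_id for r in records],
            "region": [r.region for r in records],
            "pas_type": [r.pas_type for r in records],
            "cse": [r.cse for r in records],
            "cse_offset": [r.cse_offset for r in records],
            "distance_to_annotated_end": [r.distance_to_annotated_end for r in records],
        }
    )


# ---------------------------------------------------------------------------
# integration with coverage-based APA callers


@dataclass(frozen=True)
class DaParsMatch:
    record: DaParsRecord
    pas: PASRecord
    coordinate: int  # the matched caller coordinate
    offset: int  # transcription-direction offset, caller − atlas site


def match_dapars(
    dapars: Sequence[DaParsRecord],
    records: Sequence[PASRecord],
    max_upstream: int = 250,
    max_downstream: int = 50,
) -> list[DaParsMatch]:
    """Match caller-predicted proximal/distal sites to atlas PASs.

    A caller site matches an atlas PAS of the same type (pPAS-pPAS or
    dPAS-dPAS) if it lies within ``max_upstream`` nt upstream to
    ``max_downstream`` nt downstream of the atlas cleavage site.  Conflicts
    are resolved globally by ascending absolute distance; each site on
    either side is matched at most once.
    """
    candidates = []
    for rec in records:
        if rec.pas_type not in ("pPAS", "dPAS"):
            continue
        for dp in dapars:
            if dp.contig != rec.contig or dp.strand != rec.strand:
                continue
            coord = dp.ppas if rec.pas_type == "pPAS" else dp.dpas
            off = txn_offset(coord, rec.center, rec.strand)
            if -max_upstream <= off <= max_downstream:
                candidates.append((abs(off), off, dp, rec, coord))
    candidates.sort(key=lambda t: (t[0], t[2].gene_id, t[3].center))
    used_dp, used_rec, matches = set(), set(), []
    for _, off, dp, rec, coord in candidates:
        kd = (id(dp), rec.pas_type)
        kr = id(rec)
        if kd in used_dp or kr in used_rec:
            continue
        used_dp.add(kd)
        used_rec.add(kr)
        matches.append(DaParsMatch(record=dp, pas=rec, coordinate=coord, offset=off))
    return matches


def threshold_apa(
    records: Sequence[DaParsRecord],
    fdr_max: float = 0.1,
    min_abs_dpdui: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Split genes into significantly shortened / lengthened 3'UTR sets.

    shortened: FDR ≤ ``fdr_max`` and ΔPDUI ≤ −``min_abs_dpdui``;
    lengthened: FDR ≤ ``fdr_max`` and ΔPDUI ≥ +``min_abs_dpdui``.
    Thresholds are inclusive; the two sets are disjoint by construction.
    """
    shortened = {
        r.gene_id for r in records if r.fdr <= fdr_max and r.delta_pdui <= -min_abs_dpdui
    }
    lengthened = {
        r.gene_id for r in records if r.fdr <= fdr_max and r.delta_pdui >= min_abs_dpdui
    }
    return shortened, lengthened


def overlap_fisher(
    set_a: set, set_b: set, universe: set
) -> tuple[int, float, float]:
    """Two-sided Fisher's exact test for the overlap of two gene sets.

    Returns (overlap count, odds ratio, P value) from the 2×2 table
    [[both, a only], [b only, neither]] over ``universe``.
    """
    if not universe:
        raise ValueError("empty universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    both = len(set_a & set_b)
    a_only = len(set_a - set_b)
    b_only = len(set_b - set_a)
    neither = len(universe) - both - a_only - b_only
    odds, p = fisher_exact([[both, a_only], [b_only, neither]], alternative="two-sided")
    return both, float(odds), float(p)
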