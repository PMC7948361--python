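"""Readers and writers for the formats the pipeline touches.

Internal convention: every coordinate in memory is 0-based half-open on the
forward genomic axis.  Conversion happens only at format boundaries: BED and
bedGraph are natively 0-based half-open; GTF is written/read as 1-based
inclusive.

Region kinds use the ASCII spellings ``5UTR``, ``CDS``, ``intron``, ``3UTR``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from pyfaidx import Fasta

from .coords import check_strand, revcomp

logger = logging.getLogger(__name__)

REGION_KINDS = ("5UTR", "CDS", "intron", "3UTR")

_GTF_KIND = {
    "5UTR": "five_prime_utr",
    "CDS": "CDS",
    "3UTR": "three_prime_utr",
}
_KIND_FROM_GTF = {
    "five_prime_utr": "5UTR",
    "5UTR": "5UTR",
    "UTR5": "5UTR",
    "CDS": "CDS",
    "three_prime_utr": "3UTR",
    "3UTR": "3UTR",
    "UTR3": "3UTR",
}

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised for malformed input files."""


class GenomeSequence:
    """A small in-memory genome: contig name -> uppercase DNA string."""

    def __init__(self, contigs: Mapping[str, str]):
        seen = {}
        for name, seq in contigs.items():
            if name in seen:
                raise FormatError(f"duplicate contig name {name!r}")
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r} contains letters outside A/C/G/T/N: {sorted(bad)}"
                )
            seen[name] = seq
        self._contigs = seen

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __getitem__(self, contig: str) -> str:
        return self._contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self._contigs

    def __iter__(self):
        return iter(self._contigs)

    def items(self):
        return self._contigs.items()

    def length(self, contig: str) -> int:
        return len(self._contigs[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end), clipped to the contig; reverse-complemented on −.

        On the minus strand the returned string reads 5'->3' in transcription
        direction.
        """
        check_strand(strand)
        seq = self._contigs[contig]
        start = max(0, start)
        end = min(len(seq), end)
        if end <= start:
            return ""
        sub = seq[start:end]
        return sub if strand == "+" else revcomp(sub)

    def fetch_offsets(
        self, contig: str, strand: str, center: int, lo: int, hi: int
    ) -> tuple[str, int]:
        """Sequence covering transcription-direction offsets ``lo..hi`` (inclusive)
        around ``center`` (offset 0 = the center nucleotide itself).

        Returns (sequence 5'->3' in transcription direction, actual first
        offset after clipping at contig edges).
        """
        check_strand(strand)
        n = self.length(contig)
        if strand == "+":
            gs, ge = center + lo, center + hi + 1
            clipped_lo = max(0, -gs)
        else:
            gs, ge = center - hi, center - lo + 1
            clipped_lo = max(0, ge - n)
        return self.fetch(contig, gs, ge, strand), lo + clipped_lo


@dataclass
class GeneModel:
    """One gene: span, strand and annotated subregions, all 0-based half-open."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    regions: list[tuple[str, int, int]] = field(default_factory=list)
    annotated_3p_ends: list[int] = field(default_factory=list)

    def __post_init__(self):
        check_strand(self.strand)
        if self.end <= self.start:
            raise FormatError(f"gene {self.gene_id}: empty span [{self.start},{self.end})")
        for kind, s, e in self.regions:
            if kind not in REGION_KINDS:
                raise FormatError(f"gene {self.gene_id}: unknown region kind {kind!r}")
            if not (self.start <= s < e <= self.end):
                raise FormatError(
                    f"gene {self.gene_id}: region {kind} [{s},{e}) outside span"
                )

    def regions_of_kind(self, kind: str) -> list[tuple[int, int]]:
        return [(s, e) for k, s, e in self.regions if k == kind]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Annotated transcription end (last transcribed nt), genomic coordinate."""
        return self.end - 1 if self.strand == "+" else self.start


def _validate_gtf_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 tab-separated fields")
            try:
                s, e = int(fields[3]), int(fields[4])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from None
            if s < 1 or e < s:
                raise FormatError(f"{path}: line {lineno}: invalid 1-based interval {s}-{e}")


def read_annotation(path: str | Path) -> dict[str, GeneModel]:
    """Parse a GTF/GFF annotation into GeneModels keyed by gene_id.

    Exons are used to derive introns (the gaps between consecutive exons) and
    transcript 3' ends; UTR/CDS features become region annotations.  Genes
    without a strand are rejected.
    """
    _validate_gtf_lines(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, dict] = {}

    def bucket(feat):
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise FormatError(f"{path}: feature without gene_id at {feat.seqid}:{feat.start}")
        return by_gene.setdefault(
            gid, {"gene": None, "exons": [], "regions": [], "tx_exons": {}}
        )

    for feat in db.all_features():
        entry = bucket(feat)
        if feat.featuretype == "gene":
            entry["gene"] = feat
        elif feat.featuretype == "exon":
            entry["exons"].append((feat.start - 1, feat.end))
            tid = feat.attributes.get("transcript_id", ["__na__"])[0]
            entry["tx_exons"].setdefault(tid, []).append((feat.start - 1, feat.end))
        elif feat.featuretype in _KIND_FROM_GTF:
            entry["regions"].append(
                (_KIND_FROM_GTF[feat.featuretype], feat.start - 1, feat.end)
            )

    genes: dict[str, GeneModel] = {}
    for gid, entry in by_gene.items():
        feat = entry["gene"]
        if feat is None:
            if not entry["exons"]:
                continue
            contig = None
            raise FormatError(f"{path}: gene {gid} has features but no gene record")
        if feat.strand not in ("+", "-"):
            raise FormatError(f"{path}: gene {gid} has no strand")
        regions = sorted(entry["regions"], key=lambda r: (r[1], r[2]))
        exons = sorted(set(entry["exons"]))
        introns = [
            (prev_end, nxt_start)
            for (_, prev_end), (nxt_start, _) in zip(exons, exons[1:])
            if nxt_start > prev_end
        ]
        regions += [("intron", s, e) for s, e in introns]
        ends = set()
        for tx in entry["tx_exons"].values():
            if feat.strand == "+":
                ends.add(max(e for _, e in tx) - 1)
            else:
                ends.add(min(s for s, _ in tx))
        genes[gid] = GeneModel(
            gene_id=gid,
            contig=feat.seqid,
            strand=feat.strand,
            start=feat.start - 1,
            end=feat.end,
            regions=sorted(regions, key=lambda r: (r[1], r[2])),
            annotated_3p_ends=sorted(ends),
        )
    return genes


def write_annotation(genes: Iterable[GeneModel], path: str | Path, source: str = "pascape") -> None:
    """Write GeneModels as GTF (1-based inclusive), one transcript per gene."""

    def line(contig, ftype, s0, e0, strand, attrs):
        return (
            f"{contig}\t{source}\t{ftype}\t{s0 + 1}\t{e0}\t.\t{strand}\t.\t{attrs}\n"
        )

    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.contig, g.start)):
            ga = f'gene_id "{g.gene_id}";'
            ta = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(line(g.contig, "gene", g.start, g.end, g.strand, ga))
            introns = sorted(g.regions_of_kind("intron"))
            # exons = span minus introns
            exons, cur = [], g.start
            for s, e in introns:
                if s > cur:
                    exons.append((cur, s))
                cur = e
            if g.end > cur:
                exons.append((cur, g.end))
            for s, e in exons:
                fh.write(line(g.contig, "exon", s, e, g.strand, ta))
            for kind, s, e in g.regions:
                if kind == "intron":
                    continue
                fh.write(line(g.contig, _GTF_KIND[kind], s, e, g.strand, ta))


@dataclass
class DaParsRecord:
    """One gene's APA quantification from a coverage-based caller.

    PDUI is the fraction of distal poly(A)-site usage; ``delta_pdui`` is
    condition minus control (negative = 3'UTR shortening).
    """

    gene_id: str
    contig: str
    strand: str
    ppas: int
    dpas: int
    pdui_control: float
    pdui_condition: float
    delta_pdui: float
    fdr: float

    def __post_init__(self):
        check_strand(self.strand)
        for v in (self.pdui_control, self.pdui_condition):
            if not (0.0 <= v <= 1.0):
                raise FormatError(f"gene {self.gene_id}: PDUI {v} outside [0,1]")


DAPARS_CANONICAL_COLUMNS = [
    "gene_id",
    "contig",
    "strand",
    "ppas",
    "dpas",
    "pdui_control",
    "pdui_condition",
    "fdr",
]

# Native DaPars-style headers accepted as aliases; canonical names win on conflict.
_DAPARS_ALIASES = {
    "Gene": "gene_id",
    "Chromosome": "contig",
    "Strand": "strand",
    "Proximal_APA": "ppas",
    "Predicted_Proximal_APA": "ppas",
    "Distal_APA": "dpas",
    "Loci_Distal_APA": "dpas",
    "PDUI_A": "pdui_control",
    "PDUI_Group_A": "pdui_control",
    "PDUI_B": "pdui_condition",
    "PDUI_Group_B": "pdui_condition",
    "adjusted.P_val": "fdr",
    "FDR": "fdr",
    "P_val_adj": "fdr",
}


def read_dapars_table(path: str | Path) -> list[DaParsRecord]:
    """Read an APA result table (TSV) into DaParsRecords.

    delta_PDUI is always recomputed from the two PDUI columns.  Rows with a
    missing FDR are dropped and rows with PDUI outside [0,1] rejected; both
    counts are logged.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {c: _DAPARS_ALIASES[c] for c in df.columns if c in _DAPARS_ALIASES}
    for native, canonical in list(rename.items()):
        if canonical in df.columns:
            del rename[native]  # canonical column present: it wins
    df = df.rename(columns=rename)
    missing = [c for c in DAPARS_CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    records, n_no_fdr, n_bad = [], 0, 0
    for row in df.itertuples(index=False):
        if pd.isna(row.fdr):
            n_no_fdr += 1
            continue
        try:
            rec = DaParsRecord(
                gene_id=str(row.gene_id),
                contig=str(row.contig),
                strand=str(row.strand),
                ppas=int(row.ppas),
                dpas=int(row.dpas),
                pdui_control=float(row.pdui_control),
                pdui_condition=float(row.pdui_condition),
                delta_pdui=float(row.pdui_condition) - float(row.pdui_control),
                fdr=float(row.fdr),
            )
        except (FormatError, ValueError) as exc:
            n_bad += 1
            warnings.warn(f"{path}: row rejected: {exc}")
            continue
        records.append(rec)
    if n_no_fdr:
        logger.info("%s: dropped %d rows with missing FDR", path, n_no_fdr)
    if n_bad:
        logger.info("%s: rejected %d invalid rows", path, n_bad)
    return records


def write_dapars_table(records: Iterable[DaParsRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "contig": r.contig,
            "strand": r.strand,
            "ppas": r.ppas,
            "dpas": r.dpas,
            "pdui_control": r.pdui_control,
            "pdui_condition": r.pdui_condition,
            "delta_pdui": r.delta_pdui,
            "fdr": r.fdr,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _sorted_or_warn(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    if not df[cols].apply(tuple, axis=1).is_monotonic_increasing:
        warnings.warn("records not sorted by contig/start; sorting internally")
        df = df.sort_values(cols, kind="mergesort").reset_index(drop=True)
    return df


def write_bedgraph(events: pd.DataFrame, path: str | Path) -> None:
    """Write per-position counts as bedGraph (0-based half-open).

    ``events`` needs columns contig, position, count; one line per position.
    """
    df = _sorted_or_warn(events[["contig", "position", "count"]].copy(), ["contig", "position"])
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.position}\t{row.position + 1}\t{row.count}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["contig", "start", "end", "count"]
    )
    out = []
    for row in df.itertuples(index=False):
        for pos in range(int(row.start), int(row.end)):
            out.append((row.contig, pos, row.count))
    return pd.DataFrame(out, columns=["contig", "position", "count"])


def write_bed6(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write BED6 (contig, start, end, name, score, strand), 0-based half-open."""
    cols = ["contig", "start", "end", "name", "score", "strand"]
    df = _sorted_or_warn(intervals[cols].copy(), ["contig", "start"])
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
        dtype={"contig": str, "name": str, "strand": str},
    )
    for s in df["strand"]:
        check_strand(s)
    return df


def window_to_bed_interval(center: int) -> tuple[int, int]:
    """15-nt window interval (0-based half-open) for a cleavage-site center."""
    return center - 7, center + 8
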