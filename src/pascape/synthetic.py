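"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the structure the downstream analyses assume:
multi-gene genomes on both strands with annotated 5'UTR/CDS/intron/3'UTR
regions; 1–4 true PASs per gene with planted CSE hexamers and UGUA
elements; reads carrying genuine non-templated poly(A) tails with
cleavage-site jitter; internal-priming reads terminating at planted
genomic A-stretches; PCR duplicates sharing UMIs; and crosslink tracks
with a position-dependent enrichment bump upstream of the PASs.

Background sequence is scrubbed of accidental A/T homopolymer windows
before planting, so the set of genomic A-stretches is controlled by the
truth set.  All outputs are byte-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coords import revcomp, shift_downstream
from .iclip import CrosslinkTrack
from .io_formats import GeneModel, GenomeSequence

DEFAULT_HEXAMER_FREQS = {
    "AAUAAA": 0.60,
    "AUUAAA": 0.16,
    "UAUAAA": 0.06,
    "AGUAAA": 0.06,
    "AAGAAA": 0.06,
    "AAUAUA": 0.06,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PASTruth:
    gene_id: str
    index: int  # transcription-order index within the gene (0 = most proximal)
    position: int  # genomic cleavage-site coordinate
    weight: float  # relative usage, weights sum to 1 per gene
    cse: str  # planted hexamer, RNA alphabet
    cse_offset: int  # planted start offset (transcription direction, negative)
    ugua_offsets: list[int] = field(default_factory=list)


@dataclass
class GeneTruth:
    gene_id: str
    contig: str
    strand: str
    pas: list[PASTruth] = field(default_factory=list)


@dataclass
class TruthSet:
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    a_stretches: pd.DataFrame | None = None  # contig, strand, start, end, gene_id
    xlink_profiles: dict[str, dict] = field(default_factory=dict)

    def all_pas(self) -> list[PASTruth]:
        return [p for g in self.genes.values() for p in g.pas]

    def anchors(self) -> list[tuple[str, str, int]]:
        return [
            (g.contig, g.strand, p.position)
            for g in self.genes.values()
            for p in g.pas
        ]


def _suppress_homopolymer_windows(seq: np.ndarray) -> None:
    """Break every 10-nt window with ≤2 non-A (or ≤2 non-T) in place.

    A-rich windows get a C planted mid-window, T-rich windows a G, until no
    window passes the internal-priming detector's criterion.
    """
    for base, repl in ((ord("A"), ord("C")), (ord("T"), ord("G"))):
        while True:
            other = (seq != base).astype(np.int32)
            csum = np.concatenate(([0], np.cumsum(other)))
            wsum = csum[10:] - csum[:-10]
            bad = np.flatnonzero(wsum <= 2)
            if bad.size == 0:
                break
            for s in bad:
                # mutate the middle matching base of the window
                win = seq[s : s + 10]
                idx = np.flatnonzero(win == base)
                if idx.size:
                    win[idx[idx.size // 2]] = repl


class _SeqEditor:
    """Transcription-direction writes into a mutable forward-strand sequence."""

    def __init__(self, seq: np.ndarray):
        self.seq = seq

    def write(self, strand: str, anchor: int, offset: int, text: str) -> None:
        """Write ``text`` (5'->3' in transcription direction) so its first
        character lands ``offset`` nt from ``anchor`` (txn direction)."""
        if strand == "+":
            start = anchor + offset
            self.seq[start : start + len(text)] = np.frombuffer(
                text.encode(), dtype=np.uint8
            )
        else:
            rc = revcomp(text)
            end = anchor - offset + 1
            self.seq[end - len(text) : end] = np.frombuffer(rc.encode(), dtype=np.uint8)

    def read(self, strand: str, anchor: int, lo: int, hi: int) -> str:
        if strand == "+":
            sub = self.seq[anchor + lo : anchor + hi + 1].tobytes().decode()
            return sub
        sub = self.seq[anchor - hi : anchor - lo + 1].tobytes().decode()
        return revcomp(sub)


def _scrub_hexamers(
    editor: _SeqEditor,
    strand: str,
    pas: int,
    hexamer_dna: list[str],
    keep_span: tuple[int, int],
    lo: int = -53,
    hi: int = 2,
) -> None:
    """Remove unplanned CSE-hexamer occurrences near the upstream window.

    The scrubbed range extends a few nt beyond the 50-nt search window on
    both sides so that a called cleavage site a few nt off the planted one
    still sees the planted hexamer as the only occurrence.
    """
    for _ in range(30):
        window = editor.read(strand, pas, lo, hi)
        dirty = False
        for hx in hexamer_dna:
            i = window.find(hx)
            while i != -1:
                off = i + lo  # start offset of the occurrence
                span = range(off, off + 6)
                if not (keep_span[0] <= off <= keep_span[1]):
                    # mutate a base outside the planted element
                    for o in span:
                        if not (keep_span[0] - 1 <= o <= keep_span[1] + 6):
                            editor.write(strand, pas, o, "C")
                            dirty = True
                            break
                    else:
                        i = window.find(hx, i + 1)
                        continue
                    break
                i = window.find(hx, i + 1)
            if dirty:
                break
        if not dirty:
            return


def simulate_genome(
    n_genes: int = 8,
    strand_mix: float = 0.5,
    utr_length_range: tuple[int, int] = (350, 650),
    n_pas_range: tuple[int, int] = (1, 4),
    a_stretch_rate: float = 1.0,
    seed: int = 0,
    contig: str = "chr1",
    hexamer_freqs: dict[str, float] | None = None,
    a_stretch_length: int = 18,
    min_pas_weight: float = 0.15,
) -> tuple[GenomeSequence, dict[str, GeneModel], TruthSet]:
    """Simulate a toy genome with annotated genes and a PAS truth set.

    ``strand_mix`` is the probability of a + strand gene;
    ``a_stretch_rate`` the Poisson mean of planted A-stretches per gene
    (one intergenic stretch per spacer at the same rate).  Each true PAS
    gets a CSE hexamer drawn from ``hexamer_freqs`` planted with its start
    15–30 nt upstream of the cleavage site, C-guarded so planting cannot
    create homopolymer artifacts, plus optional upstream UGUA elements.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be ≥ 1")
    rng = np.random.default_rng(seed)
    freqs = hexamer_freqs or DEFAULT_HEXAMER_FREQS
    hex_names = sorted(freqs)
    hex_p = np.array([freqs[h] for h in hex_names], dtype=float)
    hex_p = hex_p / hex_p.sum()
    hexamer_dna = [h.replace("U", "T") for h in hex_names]
    # scrub against the full configurable CSE list, not just the planted one,
    # so the planted hexamer is the only listed occurrence near each PAS
    from .annotation import load_cse_hexamers

    scrub_dna = sorted({h.replace("U", "T") for h in load_cse_hexamers()} | set(hexamer_dna))

    min_utr = 60 + (n_pas_range[0] - 1) * 80 + 10
    if utr_length_range[1] < min_utr:
        raise ValueError(
            f"3'UTR length range {utr_length_range} too short to host "
            f"{n_pas_range[0]} PASs (needs ≥ {min_utr} nt)"
        )

    # gene layouts
    layouts = []
    pos = 0
    spacers = []
    for gi in range(n_genes):
        spacer = int(rng.integers(300, 600))
        spacers.append((pos, pos + spacer))
        pos += spacer
        utr5 = int(rng.integers(80, 150))
        cds1 = int(rng.integers(150, 300))
        intron = int(rng.integers(100, 200))
        cds2 = int(rng.integers(150, 300))
        utr3 = int(rng.integers(utr_length_range[0], utr_length_range[1] + 1))
        glen = utr5 + cds1 + intron + cds2 + utr3
        strand = "+" if rng.random() < strand_mix else "-"
        layouts.append(
            dict(
                gene_id=f"gene{gi + 1:03d}",
                start=pos,
                end=pos + glen,
                strand=strand,
                parts=[("5UTR", utr5), ("CDS", cds1), ("intron", intron), ("CDS", cds2), ("3UTR", utr3)],
            )
        )
        pos += glen
    tail_spacer = int(rng.integers(300, 600))
    spacers.append((pos, pos + tail_spacer))
    total = pos + tail_spacer

    seq = _BASES[rng.integers(0, 4, size=total)].copy()
    _suppress_homopolymer_windows(seq)
    editor = _SeqEditor(seq)

    genes: dict[str, GeneModel] = {}
    truth = TruthSet()
    stretch_rows = []

    for lay in layouts:
        gid, strand = lay["gene_id"], lay["strand"]
        gstart, gend = lay["start"], lay["end"]
        # map parts (transcription order) to genomic intervals
        regions = []
        cursor = 0
        utr3_txn = None  # (txn start offset within gene, length)
        for kind, length in lay["parts"]:
            if strand == "+":
                iv = (gstart + cursor, gstart + cursor + length)
            else:
                iv = (gend - cursor - length, gend - cursor)
            regions.append((kind, iv[0], iv[1]))
            if kind == "3UTR":
                utr3_txn = (cursor, length)
            cursor += length
        gene = GeneModel(
            gene_id=gid,
            contig=contig,
            strand=strand,
            start=gstart,
            end=gend,
            regions=sorted(regions, key=lambda r: (r[1], r[2])),
            annotated_3p_ends=[gend - 1 if strand == "+" else gstart],
        )
        genes[gid] = gene
        gt = GeneTruth(gene_id=gid, contig=contig, strand=strand)
        truth.genes[gid] = gt

        utr_off, utr_len = utr3_txn
        k_req = int(rng.integers(n_pas_range[0], n_pas_range[1] + 1))
        k_fit = max(1, (utr_len - 70) // 80 + 1)
        k = min(k_req, k_fit)
        if k < n_pas_range[0]:
            raise ValueError(f"gene {gid}: 3'UTR too short for {n_pas_range[0]} PASs")
        # spaced txn offsets within the 3'UTR
        lo, hi = 60, utr_len - 10
        pas_offsets = None
        for _ in range(200):
            cand = np.sort(rng.integers(lo, hi, size=k))
            if k == 1 or np.diff(cand).min() >= 80:
                pas_offsets = cand
                break
        if pas_offsets is None:
            pas_offsets = np.linspace(lo, hi - 1, k).astype(int)
        # usage weights, bounded away from zero
        for _ in range(500):
            w = rng.dirichlet(np.full(k, 4.0))
            if w.min() >= min_pas_weight:
                break
        else:
            w = np.full(k, 1.0 / k)

        anchor_tss = gstart if strand == "+" else gend - 1
        for pi, (t_off, weight) in enumerate(zip(pas_offsets, w)):
            gene_off = utr_off + int(t_off)
            pas_pos = shift_downstream(anchor_tss, gene_off, strand)
            hx_i = int(rng.choice(len(hex_names), p=hex_p))
            cse_off = int(rng.integers(-30, -14))  # start offset, −30..−15
            editor.write(strand, pas_pos, cse_off - 1, "C")
            editor.write(strand, pas_pos, cse_off, hexamer_dna[hx_i])
            editor.write(strand, pas_pos, cse_off + 6, "C")
            _scrub_hexamers(editor, strand, pas_pos, scrub_dna, (cse_off, cse_off))
            ugua_offs: list[int] = []
            if rng.random() < 0.7:
                u1 = int(rng.integers(-70, -54))
                editor.write(strand, pas_pos, u1, "TGTA")
                ugua_offs.append(u1)
                if rng.random() < 0.5:
                    u2 = u1 + int(rng.integers(6, 13))
                    if u2 + 4 <= -50:
                        editor.write(strand, pas_pos, u2, "TGTA")
                        ugua_offs.append(u2)
            gt.pas.append(
                PASTruth(
                    gene_id=gid,
                    index=pi,
                    position=int(pas_pos),
                    weight=float(weight),
                    cse=hex_names[hx_i],
                    cse_offset=cse_off,
                    ugua_offsets=ugua_offs,
                )
            )

        # planted A-stretches inside the 3'UTR, away from every PAS
        n_in = int(rng.poisson(a_stretch_rate))
        placed = 0
        for _ in range(50):
            if placed >= n_in:
                break
            t = int(rng.integers(0, max(1, utr_len - a_stretch_length)))
            if all(
                abs((t + d) - int(p)) >= 40
                for p in pas_offsets
                for d in (0, a_stretch_length)
            ):
                gene_off = utr_off + t
                first = shift_downstream(anchor_tss, gene_off, strand)
                editor.write(strand, first, -1, "C")
                editor.write(strand, first, 0, "A" * a_stretch_length)
                editor.write(strand, first, a_stretch_length, "C")
                last = shift_downstream(first, a_stretch_length - 1, strand)
                s, e = (first, last + 1) if strand == "+" else (last, first + 1)
                stretch_rows.append((contig, strand, int(s), int(e), gid))
                placed += 1

    # intergenic stretches (forward strand) in the spacers
    for s_lo, s_hi in spacers:
        if rng.poisson(a_stretch_rate) < 1:
            continue
        if s_hi - s_lo < a_stretch_length + 80:
            continue
        t = int(rng.integers(s_lo + 40, s_hi - 40 - a_stretch_length))
        editor.write("+", t, -1, "C")
        editor.write("+", t, 0, "A" * a_stretch_length)
        editor.write("+", t, a_stretch_length, "C")
        stretch_rows.append((contig, "+", t, t + a_stretch_length, None))

    truth.a_stretches = pd.DataFrame(
        stretch_rows, columns=["contig", "strand", "start", "end", "gene_id"]
    )
    genome = GenomeSequence({contig: seq.tobytes().decode()})
    return genome, genes, truth


# ---------------------------------------------------------------------------
# MACE-like reads


@dataclass
class MaceLibrary:
    """One simulated 3' end sequencing library.

    ``reads`` are (name, sequence, phred qualities); ``bed`` holds the
    alignment truth of each poly(A)-trimmed read (BED6); ``log`` records
    per-read origin so downstream filters can be scored against truth.
    The UMI is the last colon-separated field of each read name.
    """

    sample_id: str
    reads: list
    bed: pd.DataFrame
    log: pd.DataFrame

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq, quals in self.reads:
                qstr = "".join(chr(q + 33) for q in quals)
                fh.write(f"@{name}\n{seq}\n+\n{qstr}\n")

    def write_bed(self, path) -> None:
        from .io_formats import write_bed6

        df = self.bed.sort_values(["contig", "start"], kind="mergesort").reset_index(drop=True)
        write_bed6(df, path)

    def coordinates(self) -> dict:
        """Read name -> aligned (contig, start, end, strand), for deduplication."""
        return {
            r.name: (r.contig, int(r.start), int(r.end), r.strand)
            for r in self.bed.itertuples(index=False)
        }


def _read_interval(event_pos: int, strand: str, read_len: int) -> tuple[int, int]:
    """Genomic interval of a poly(A)-trimmed read whose cleavage event is at
    ``event_pos`` (the event sits 1 nt downstream of the read 3' end)."""
    if strand == "+":
        return event_pos - read_len, event_pos
    return event_pos + 1, event_pos + 1 + read_len


def simulate_mace_reads(
    genome: GenomeSequence,
    truth: TruthSet,
    reads_per_pas: int = 30,
    tail_length_range: tuple[int, int] = (12, 20),
    tail_error_rate: float = 0.0,
    cleavage_jitter_sd: float = 1.0,
    internal_priming_fraction: float = 0.0,
    duplicate_rate: float = 0.0,
    read_length: int = 40,
    sample_id: str = "S1",
    seed: int = 0,
) -> MaceLibrary:
    """Simulate one poly(A)-anchored 3' end library from the truth set.

    Genuine reads end with ≥10 non-templated adenosines (length drawn from
    ``tail_length_range``) at a cleavage position jittered (rounded
    Gaussian) around a true PAS chosen by the gene's usage weights, with
    ``reads_per_pas`` reads per PAS on average.  Internal-priming reads
    terminate at planted genomic A-stretches with templated adenosines and
    make up ``internal_priming_fraction`` of the library.  PCR duplicates
    (same UMI and coordinates) are appended at ``duplicate_rate``.
    """
    if cleavage_jitter_sd < 0:
        raise ValueError("cleavage jitter sd must be ≥ 0")
    if reads_per_pas < 1:
        raise ValueError("reads_per_pas must be ≥ 1")
    rng = np.random.default_rng(seed)
    reads, bed_rows, log_rows = [], [], []

    def add_read(idx, contig, strand, event_pos, insert_len, tail_seq, origin, gene_id, pas_pos):
        umi = "".join("ACGT"[b] for b in rng.integers(0, 4, size=8))
        name = f"{sample_id}_r{idx:06d}:{umi}"
        s, e = _read_interval(event_pos, strand, insert_len)
        insert = genome.fetch(contig, s, e, strand)
        reads.append((name, insert + tail_seq, [30] * (len(insert) + len(tail_seq))))
        bed_rows.append((contig, s, e, name, 1, strand))
        log_rows.append((name, umi, origin, gene_id, pas_pos, event_pos, contig, strand, False))
        return name, (contig, s, e, strand), insert, tail_seq

    idx = 0
    uniques = []
    for gt in truth.genes.values():
        if not gt.pas:
            continue
        k = len(gt.pas)
        weights = np.array([p.weight for p in gt.pas])
        weights = weights / weights.sum()
        n_gene = reads_per_pas * k
        choices = rng.choice(k, size=n_gene, p=weights)
        for ci in choices:
            p = gt.pas[ci]
            jitter = int(round(rng.normal(0.0, cleavage_jitter_sd)))
            event = shift_downstream(p.position, jitter, gt.strand)
            tl = int(rng.integers(tail_length_range[0], tail_length_range[1] + 1))
            tail = list("A" * tl)
            if tail_error_rate > 0:
                for i in range(len(tail)):
                    if rng.random() < tail_error_rate:
                        window = tail[max(0, i - 4) : i]
                        if all(b == "A" for b in window):
                            tail[i] = "CGT"[int(rng.integers(0, 3))]
            uniques.append(
                add_read(idx, gt.contig, gt.strand, event, read_length, "".join(tail), "pas", gt.gene_id, p.position)
            )
            idx += 1

    n_genuine = idx
    if internal_priming_fraction > 0:
        in_gene = truth.a_stretches.dropna(subset=["gene_id"])
        if in_gene.empty:
            raise ValueError("internal_priming_fraction > 0 but no in-gene A-stretches planted")
        n_art = int(round(internal_priming_fraction / (1 - internal_priming_fraction) * n_genuine))
        picks = rng.integers(0, len(in_gene), size=n_art)
        for pi in picks:
            row = in_gene.iloc[int(pi)]
            strand = row["strand"]
            tstart = int(row["start"]) if strand == "+" else int(row["end"]) - 1
            stretch_len = int(row["end"]) - int(row["start"])
            tl = min(int(rng.integers(tail_length_range[0], tail_length_range[1] + 1)), stretch_len)
            # templated adenosines from the genome itself
            tail = genome.fetch(
                row["contig"],
                *(tstart, tstart + tl) if strand == "+" else (tstart - tl + 1, tstart + 1),
                strand,
            )
            uniques.append(
                add_read(idx, row["contig"], strand, tstart, read_length, tail, "artifact", row["gene_id"], None)
            )
            idx += 1

    # PCR duplicates: same UMI + same coordinates, fresh read name
    n_unique = idx
    for name, coords, insert, tail in list(uniques):
        if rng.random() < duplicate_rate:
            umi = name.rsplit(":", 1)[1]
            dname = f"{sample_id}_r{idx:06d}:{umi}"
            reads.append((dname, insert + tail, [30] * (len(insert) + len(tail))))
            contig, s, e, strand = coords
            bed_rows.append((contig, s, e, dname, 1, strand))
            orig = next(r for r in log_rows if r[0] == name)
            log_rows.append((dname, umi, orig[2], orig[3], orig[4], orig[5], contig, strand, True))
            idx += 1

    bed = pd.DataFrame(bed_rows, columns=["contig", "start", "end", "name", "score", "strand"])
    log = pd.DataFrame(
        log_rows,
        columns=["name", "umi", "origin", "gene_id", "true_pas", "event_position", "contig", "strand", "is_duplicate"],
    )
    return MaceLibrary(sample_id=sample_id, reads=reads, bed=bed, log=log)


# ---------------------------------------------------------------------------
# crosslink tracks


def simulate_crosslinks(
    genes: dict[str, GeneModel],
    truth: TruthSet,
    library_ids=("libA", "libB"),
    depth: float = 1.0,
    background_rate: float = 0.02,
    bump_offset: int = -75,
    bump_sd: float = 8.0,
    bump_height: float = 3.0,
    seed: int = 0,
) -> dict[str, CrosslinkTrack]:
    """Per-library crosslink tracks: uniform background plus per-PAS bumps.

    Counts at each transcribed position are Poisson with rate
    ``depth x (background_rate + bump_height x weight x
    exp(-(offset - bump_offset)^2 / 2 bump_sd^2))`` summed over the gene's
    PASs — emulating a protein with a binding peak ~75 nt upstream of the
    cleavage site.  Libraries are independent draws from the same rates.
    """
    if background_rate < 0 or bump_height < 0 or depth < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    tracks = {}
    for lib in library_ids:
        rows = []
        for gene in genes.values():
            gt = truth.genes.get(gene.gene_id)
            L = gene.end - gene.start
            gpos = np.arange(gene.start, gene.end)
            rate = np.full(L, background_rate * depth, dtype=float)
            if gt is not None:
                for p in gt.pas:
                    off = (gpos - p.position) if gene.strand == "+" else (p.position - gpos)
                    rate += (
                        depth
                        * bump_height
                        * p.weight
                        * np.exp(-((off - bump_offset) ** 2) / (2 * bump_sd**2))
                    )
            counts = rng.poisson(rate)
            nz = np.flatnonzero(counts)
            for i in nz:
                rows.append((gene.contig, gene.strand, int(gpos[i]), int(counts[i])))
        df = pd.DataFrame(rows, columns=["contig", "strand", "position", "count"])
        tracks[lib] = CrosslinkTrack(library_id=lib, counts=df)
        truth.xlink_profiles[lib] = dict(
            depth=depth,
            background_rate=background_rate,
            bump_offset=bump_offset,
            bump_sd=bump_sd,
            bump_height=bump_height,
        )
    return tracks
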