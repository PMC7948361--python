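"""Strand-aware coordinate arithmetic.

All internal coordinates are 0-based half-open on the forward genomic axis.
"Upstream" and "downstream" always refer to the direction of transcription:
on the minus strand, downstream means *decreasing* genomic coordinate.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def shift_downstream(pos: int, d: int, strand: str) -> int:
    """Genomic coordinate ``d`` nt downstream (transcription direction) of pos."""
    return pos + d if strand == "+" else pos - d


def txn_offset(pos: int, anchor: int, strand: str) -> int:
    """Signed offset of ``pos`` from ``anchor`` in transcription direction.

    Negative = upstream of the anchor.
    """
    return pos - anchor if strand == "+" else anchor - pos


def txn_sort_key(strand: str):
    """Sort key placing positions in transcription order (upstream first)."""
    if strand == "+":
        return lambda p: p
    return lambda p: -p


def check_strand(strand: str) -> str:
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return strand
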