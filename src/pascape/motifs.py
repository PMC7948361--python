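"""Motif geometry around polyadenylation sites.

Metaprofiles give, per offset from the cleavage site, the fraction of PASs
with a motif start at that offset (negative offsets = upstream in
transcription direction).  Significance against a matched background uses
the resampling z-score: the background pool is resampled 100 times at the
target set size, per-offset mean and standard deviation of the resampled
profiles standardize the target profile, and Benjamini-Hochberg controls
the FDR across offsets.

RNA motifs (e.g. the CFIm element UGUA) are matched as DNA on the coding
strand (UGUA -> TGTA).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomeSequence
from .smoothing import loess_smooth

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def pattern_to_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern into an overlap-reporting regex."""
    body = "".join(IUPAC[ch] for ch in pattern.upper())
    return re.compile(f"(?={body})")


def scan_motif(seq: str, pattern: str, anchor_index: int) -> list[int]:
    """All motif start offsets in ``seq`` relative to position ``anchor_index``.

    Overlapping matches are all reported.  ``seq`` is read 5'->3' in
    transcription direction; offsets are start − anchor.
    """
    rx = pattern_to_regex(pattern)
    return [m.start() - anchor_index for m in rx.finditer(seq.upper())]


def motif_offsets_around(
    genome: GenomeSequence,
    contig: str,
    strand: str,
    center: int,
    pattern: str,
    half_window: int,
) -> list[int]:
    """Motif start offsets within ±half_window of a cleavage site.

    The fetched sequence extends ``len(pattern) − 1`` nt past the downstream
    edge so a motif *starting* at +half_window still counts; windows
    truncated by contig edges are scanned as far as available.
    """
    overhang = len(pattern) - 1
    seq, lo = genome.fetch_offsets(contig, strand, center, -half_window, half_window + overhang)
    return [o for o in (s + lo for s in (m.start() for m in pattern_to_regex(pattern).finditer(seq))) if -half_window <= o <= half_window]


@dataclass
class MotifProfile:
    pattern: str
    offsets: np.ndarray  # −hw..+hw
    raw: np.ndarray  # fraction of anchors with ≥1 motif start per offset
    smoothed: np.ndarray
    n_anchors: int
    z: np.ndarray | None = None
    qvals: np.ndarray | None = None
    flags: np.ndarray | None = None  # significant at the configured FDR
    excluded: np.ndarray | None = None  # offsets with zero background sd
    background_mean: np.ndarray | None = None
    background_sd: np.ndarray | None = None


def metaprofile(
    anchors: Sequence[tuple[str, str, int]],
    genome: GenomeSequence,
    pattern: str,
    half_window: int = 300,
    span: float = 0.1,
) -> MotifProfile:
    """Fraction of anchor PASs with a motif start at each offset, loess-smoothed.

    ``anchors`` are (contig, strand, cleavage site) triples.
    """
    if not anchors:
        raise ValueError("empty anchor set")
    offsets = np.arange(-half_window, half_window + 1)
    hits = np.zeros(offsets.size, dtype=float)
    for contig, strand, center in anchors:
        found = set(
            motif_offsets_around(genome, contig, strand, center, pattern, half_window)
        )
        for o in found:
            hits[o + half_window] += 1
    raw = hits / len(anchors)
    return MotifProfile(
        pattern=pattern,
        offsets=offsets,
        raw=raw,
        smoothed=loess_smooth(raw, span),
        n_anchors=len(anchors),
    )


@dataclass
class BackgroundZ:
    z: np.ndarray
    pvals: np.ndarray
    qvals: np.ndarray
    flags: np.ndarray
    excluded: np.ndarray  # True where background sd == 0 (z undefined)
    background_mean: np.ndarray
    background_sd: np.ndarray


def background_zscore(
    target_profile: np.ndarray,
    pool: Sequence,
    profile_func: Callable[[Sequence], np.ndarray],
    sample_size: int,
    n_resamples: int = 100,
    fdr: float = 0.01,
    seed: int = 0,
) -> BackgroundZ:
    """Resampling z-score of a target profile against a matched background.

    ``pool`` is resampled ``n_resamples`` times without replacement at
    ``sample_size`` (size-matched to the target set); ``profile_func`` maps
    a subset of pool items to a per-offset profile.  z = (target − mean) /
    sd per offset, two-sided normal P values, BH correction across the
    offsets where sd > 0; offsets with sd == 0 are excluded and flagged.
    """
    if sample_size > len(pool):
        raise ValueError("background pool smaller than the target set size")
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    rng = np.random.default_rng(seed)
    pool = list(pool)
    profiles = np.empty((n_resamples, np.asarray(target_profile).size))
    for i in range(n_resamples):
        idx = rng.choice(len(pool), size=sample_size, replace=False)
        profiles[i] = profile_func([pool[j] for j in idx])
    mean = profiles.mean(axis=0)
    sd = profiles.std(axis=0, ddof=1)
    target = np.asarray(target_profile, dtype=float)
    excluded = sd == 0
    z = np.full(target.shape, np.nan)
    z[~excluded] = (target[~excluded] - mean[~excluded]) / sd[~excluded]
    pvals = np.full(target.shape, np.nan)
    pvals[~excluded] = 2 * norm.sf(np.abs(z[~excluded]))
    qvals = np.full(target.shape, np.nan)
    flags = np.zeros(target.shape, dtype=bool)
    if (~excluded).any():
        rej, q, _, _ = multipletests(pvals[~excluded], alpha=fdr, method="fdr_bh")
        qvals[~excluded] = q
        flags[~excluded] = q <= fdr
    return BackgroundZ(
        z=z, pvals=pvals, qvals=qvals, flags=flags, excluded=excluded,
        background_mean=mean, background_sd=sd,
    )


def metaprofile_background_z(
    target_anchors: Sequence[tuple[str, str, int]],
    pool_anchors: Sequence[tuple[str, str, int]],
    genome: GenomeSequence,
    pattern: str,
    half_window: int = 300,
    n_resamples: int = 100,
    fdr: float = 0.01,
    seed: int = 0,
) -> MotifProfile:
    """Motif metaprofile of a target PAS set with resampled-background z/FDR."""
    prof = metaprofile(target_anchors, genome, pattern, half_window)
    bz = background_zscore(
        prof.raw,
        pool_anchors,
        lambda sub: metaprofile(sub, genome, pattern, half_window).raw,
        sample_size=len(target_anchors),
        n_resamples=n_resamples,
        fdr=fdr,
        seed=seed,
    )
    prof.z, prof.qvals, prof.flags = bz.z, bz.qvals, bz.flags
    prof.excluded = bz.excluded
    prof.background_mean, prof.background_sd = bz.background_mean, bz.background_sd
    return prof


# ---------------------------------------------------------------------------
# tandem UGUA geometry


@dataclass
class TandemUGUAProfile:
    mode: str
    win_sizes: np.ndarray
    fraction: np.ndarray  # cumulative fraction of PASs qualifying at each Win_size
    min_distance: list  # per-PAS minimum distance between qualifying UGUA starts (nan if never)


def _min_winsize(mode: str, starts: Sequence[int], win_max: int) -> tuple[float, float]:
    """Smallest Win_size at which a PAS qualifies, plus the minimum pairwise
    distance among pairs that qualify at the maximal window.

    Range logic per mode, ``a``/``b`` being two distinct motif start offsets:
    enclosing — a in [−W, −4] and b in [−3, W−3];
    preceded  — both in [−W, −4];
    followed  — both in [1, W−3].
    """
    best = np.inf
    dists = []
    ss = sorted(set(starts))
    for i, a in enumerate(ss):
        for b in ss:
            if a == b:
                continue
            if mode == "enclosing":
                if a <= -4 and b >= -3:
                    w = max(-a, b + 3, 1)
                else:
                    continue
            elif mode == "preceded":
                if a <= -4 and b <= -4 and a != b:
                    w = max(-a, -b, 1)
                else:
                    continue
            elif mode == "followed":
                if a >= 1 and b >= 1 and a != b:
                    w = max(a, b) + 3
                else:
                    continue
            else:
                raise ValueError(f"unknown mode {mode!r}")
            best = min(best, w)
            if w <= win_max:
                dists.append(abs(b - a))
    return best, (min(dists) if dists else np.nan)


def tandem_ugua(
    anchors: Sequence[tuple[str, str, int]],
    genome: GenomeSequence,
    mode: str,
    pattern: str = "UGUA",
) -> TandemUGUAProfile:
    """Cumulative fraction of PASs with a tandem UGUA configuration.

    Modes: ``enclosing`` (UGUA-PAS-UGUA, Win_size 1–75), ``preceded``
    (UGUA-UGUA-PAS) and ``followed`` (PAS-UGUA-UGUA), both 1–150; windows
    on either side of the PAS grow in 1-nt steps and a PAS qualifies at a
    Win_size once two distinct UGUA starts satisfy the mode's ranges.  The
    cumulative fraction is non-decreasing because the ranges only grow.
    """
    win_max = 75 if mode == "enclosing" else 150
    win_sizes = np.arange(1, win_max + 1)
    half = win_max + len(pattern)
    min_w = []
    min_d = []
    for contig, strand, center in anchors:
        starts = motif_offsets_around(genome, contig, strand, center, pattern, half)
        w, d = _min_winsize(mode, starts, win_max)
        min_w.append(w)
        min_d.append(d)
    min_w = np.asarray(min_w)
    qualifies_at_max = min_w <= win_max
    fraction = np.array([(min_w <= W).mean() if anchors else 0.0 for W in win_sizes])
    min_distance = [
        d if ok else np.nan for d, ok in zip(min_d, qualifies_at_max)
    ]
    return TandemUGUAProfile(
        mode=mode, win_sizes=win_sizes, fraction=fraction, min_distance=min_distance
    )
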