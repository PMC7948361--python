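import statistics

import numpy as np
import pandas as pd
import pytest

from pascape import discovery as D
from pascape.io_formats import GenomeSequence


# ---------------------------------------------------------------------------
# poly(A) trimming


@pytest.mark.parametrize(
    "seq,exp_trimmed,exp_n,exp_polya",
    [
        ("ACGTACGT" + "A" * 10, "ACGTACGT", 10, True),
        ("ACGTACGT" + "A" * 9, "ACGTACGT" + "A" * 9, 9, False),
        # the G-interrupted tail is accepted by the 5-nt window rule (one
        # non-A per window); the T/G-crossing window has two and stops it
        ("ACGT" + "AAAAAGAAAAAA", "ACGT", 11, True),
        ("A" * 12, "", 12, True),
        ("ACGTACGTACGT", "ACGTACGTACGT", 1, False),
    ],
)
def test_trim_polya_window_rule(seq, exp_trimmed, exp_n, exp_polya):
    r = D.trim_polya(seq)
    assert (r.trimmed, r.n_trailing_a, r.is_polya) == (exp_trimmed, exp_n, exp_polya)


def test_trim_polya_flags_short_remainder():
    r = D.trim_polya("ACG" + "A" * 15)
    assert r.is_polya and not r.usable


def test_quality_trim_both_ends():
    seq, quals = D.quality_trim("AACGTT", [10, 10, 30, 30, 30, 12], cutoff=16)
    assert seq == "CGTT"[:-1] or seq == "CGT"
    assert seq == "CGT" and quals == [30, 30, 30]


def test_prepare_reads_dedup_rules():
    reads = [
        ("r1:ACGTACGT", "ACGT", [30] * 4),
        ("r2:ACGTACGT", "ACGT", [30] * 4),  # same UMI, same position -> dup
        ("r3:ACGTACGT", "ACGT", [30] * 4),  # same UMI, different position
        ("r4", "ACGT", [30] * 4),  # no UMI -> dropped
    ]
    coords = {"r1:ACGTACGT": 100, "r2:ACGTACGT": 100, "r3:ACGTACGT": 250}
    with pytest.warns(UserWarning, match="UMI"):
        kept, log = D.prepare_reads(reads, coordinates=coords)
    assert [r.name for r in kept] == ["r1:ACGTACGT", "r3:ACGTACGT"]
    assert log["n_duplicates"] == 1 and log["n_no_umi"] == 1


def test_prepare_reads_idempotent():
    reads = [("r1:AAAACCCC", "AACGTT", [10, 10, 30, 30, 30, 30])]
    once, _ = D.prepare_reads(reads)
    twice, _ = D.prepare_reads([(r.name, r.seq, r.quals) for r in once])
    assert [(r.name, r.seq, r.quals) for r in once] == [
        (r.name, r.seq, r.quals) for r in twice
    ]


# ---------------------------------------------------------------------------
# genomic A-stretches


def _oracle_stretches(seq: str, base: str):
    """Brute force: enumerate all 10-mers with ≤2 mismatches to base^10,
    merge overlaps, trim termini to the matching base."""
    passing = [
        (i, i + 10)
        for i in range(len(seq) - 9)
        if sum(1 for b in seq[i : i + 10] if b != base) <= 2
    ]
    merged = []
    for s, e in passing:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    out = []
    for s, e in merged:
        while s < e and seq[s] != base:
            s += 1
        while e > s and seq[e - 1] != base:
            e -= 1
        if e - s >= 10:
            out.append((s, e))
    return out


@pytest.mark.parametrize(
    "seq,expected_plus",
    [
        ("C" * 20 + "A" * 12 + "C" * 20, [(20, 32)]),
        ("G" * 10 + "AAAAACCAAAAA" + "G" * 10, [(10, 22)]),
    ],
)
def test_a_stretch_examples(seq, expected_plus):
    st = D.find_genomic_a_stretches(GenomeSequence({"c": seq}))
    plus = st.loc[st["strand"] == "+", ["start", "end"]].apply(tuple, axis=1).tolist()
    assert plus == expected_plus


def test_t_run_is_minus_strand_stretch():
    st = D.find_genomic_a_stretches(GenomeSequence({"c": "C" * 20 + "T" * 12 + "C" * 20}))
    assert st["strand"].tolist() == ["-"]
    assert st[["start", "end"]].values.tolist() == [[20, 32]]


def test_a_stretches_match_bruteforce_oracle():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(30, 120))
        seq = "".join("AACGT"[i] for i in rng.integers(0, 5, size=n))  # A-biased
        st = D.find_genomic_a_stretches(GenomeSequence({"c": seq}))
        got_plus = st.loc[st["strand"] == "+", ["start", "end"]].apply(tuple, axis=1).tolist()
        got_minus = st.loc[st["strand"] == "-", ["start", "end"]].apply(tuple, axis=1).tolist()
        assert got_plus == _oracle_stretches(seq, "A")
        assert got_minus == _oracle_stretches(seq, "T")


# ---------------------------------------------------------------------------
# cleavage events and internal priming


def test_events_one_nt_downstream_of_read_end():
    bed = pd.DataFrame(
        dict(contig=["c", "c"], start=[60, 200], end=[100, 240],
             name=["a", "b"], score=[1, 1], strand=["+", "-"])
    )
    ev = D.events_from_bed(bed, "s1")
    plus = ev.loc[ev["strand"] == "+", "position"].item()
    minus = ev.loc[ev["strand"] == "-", "position"].item()
    assert plus == 100 and minus == 199


@pytest.mark.parametrize(
    "strand,event,stretch,removed",
    [
        ("+", 100, (103, 115), True),   # starts 3 nt downstream
        ("+", 100, (105, 117), True),   # boundary: exactly 5 nt
        ("+", 100, (106, 118), False),
        ("+", 100, (120, 132), False),
        ("+", 110, (103, 115), True),   # overlap
        ("-", 100, (85, 97), True),     # txn start 96, 4 nt downstream on −
        ("-", 100, (80, 90), False),    # txn start 89, 11 nt away
    ],
)
def test_internal_priming_adjacency(strand, event, stretch, removed):
    ev = pd.DataFrame(
        dict(contig=["c"], strand=[strand], position=[event], sample_id=["s"], count=[1])
    )
    st = pd.DataFrame(dict(contig=["c"], strand=[strand], start=[stretch[0]], end=[stretch[1]]))
    kept, n = D.filter_internal_priming(ev, st, adjacency_nt=5)
    assert (n == 1) == removed


def test_internal_priming_strand_specific():
    ev = pd.DataFrame(dict(contig=["c"], strand=["+"], position=[100], sample_id=["s"], count=[1]))
    st = pd.DataFrame(dict(contig=["c"], strand=["-"], start=[100], end=[112]))
    kept, n = D.filter_internal_priming(ev, st)
    assert n == 0


# ---------------------------------------------------------------------------
# clustering


def _oracle_cluster(positions, strand, max_dist=25):
    """Independent step-by-step re-enactment of the greedy median rule."""
    order = sorted(positions, reverse=(strand == "-"))
    clusters, cur = [], []
    for p in order:
        if not cur:
            cur = [p]
        elif abs(p - statistics.median(cur)) <= max_dist:
            cur.append(p)
        else:
            clusters.append(sorted(cur))
            cur = [p]
    if cur:
        clusters.append(sorted(cur))
    return clusters


def test_cluster_example_step_by_step():
    ev = pd.DataFrame(
        dict(contig="c", strand="+", position=[100, 101, 101, 103, 150],
             sample_id="s", count=1)
    )
    got = [sorted(c.positions) for c in D.cluster_cleavage_events(ev)]
    assert got == [[100, 101, 101, 103], [150]]


def test_cluster_minus_strand_processed_downstream():
    ev = pd.DataFrame(
        dict(contig="c", strand="-", position=[500, 480, 479], sample_id="s", count=1)
    )
    got = [sorted(c.positions) for c in D.cluster_cleavage_events(ev)]
    assert got == [[479, 480, 500]]


def test_cluster_singleton():
    ev = pd.DataFrame(dict(contig=["c"], strand=["+"], position=[42], sample_id=["s"], count=[1]))
    cl = D.cluster_cleavage_events(ev)
    assert len(cl) == 1 and cl[0].positions == [42]


def test_clustering_matches_oracle_fuzz():
    """Exhaustive fuzz vs an independently coded oracle (≤20 events)."""
    rng = np.random.default_rng(7)
    for _ in range(1000):
        n = int(rng.integers(1, 21))
        strand = "+" if rng.random() < 0.5 else "-"
        pos = rng.integers(0, 120, size=n)
        ev = (
            pd.DataFrame(dict(contig="c", strand=strand, position=pos, sample_id="s", count=1))
        )
        got = [sorted(c.positions) for c in D.cluster_cleavage_events(ev)]
        want = _oracle_cluster(list(pos), strand)
        assert got == want


# ---------------------------------------------------------------------------
# windows


def test_window_mode_and_geometry():
    c = D.PASCluster("c", "+", [100] * 3 + [101] + [103] * 2)
    w = D.define_pas_window(c)
    assert (w.center, w.start, w.end) == (100, 93, 108)


def test_window_tie_breaks_upstream():
    assert D.define_pas_window(D.PASCluster("c", "+", [100, 100, 104, 104])).center == 100
    assert D.define_pas_window(D.PASCluster("c", "-", [100, 100, 104, 104])).center == 104


def test_window_singleton():
    assert D.define_pas_window(D.PASCluster("c", "+", [50])).center == 50


# ---------------------------------------------------------------------------
# quantification


def _toy_quant(ce_w, gene_total, lib_total):
    from pascape.io_formats import GeneModel

    gene = GeneModel("g", "c", "+", 0, 1000, regions=[("3UTR", 0, 1000)], annotated_3p_ends=[999])
    w = D.PASWindow(contig="c", strand="+", center=500, start=493, end=508, gene_id="g")
    rows = [("c", "+", 500, "s1", ce_w)]
    if gene_total > ce_w:
        rows.append(("c", "+", 100, "s1", gene_total - ce_w))
    pad = lib_total - gene_total
    if pad > 0:
        rows.append(("c", "+", 2000, "s1", pad))  # outside the gene
    ev = pd.DataFrame(rows, columns=D.EVENT_COLUMNS)
    return D.quantify_and_filter([w], ev, {"s1": "ctrl"}, {"g": gene})


def test_pu_arithmetic():
    df = _toy_quant(ce_w=10, gene_total=40, lib_total=40)
    assert df["pu_average_ctrl"].item() == pytest.approx(25.0)


def test_tpm_formula():
    df = _toy_quant(ce_w=6, gene_total=6, lib_total=2_000_000)
    assert df["tpm_average_ctrl"].item() == pytest.approx(200.0)


def test_ce_filter_is_strict():
    """A window with CE_average exactly 4 fails the strict > threshold."""
    df = _toy_quant(ce_w=4, gene_total=5, lib_total=5)
    assert df["ce_average_ctrl"].item() == 4.0
    assert not df["passed"].item()
    df2 = _toy_quant(ce_w=5, gene_total=6, lib_total=6)
    assert df2["passed"].item()


def test_pu_sums_below_100_per_gene(call_result):
    atlas = call_result.atlas
    for c in ("control", "knockdown"):
        sums = atlas.groupby("gene_id")[f"pu_average_{c}"].sum()
        assert (sums <= 100.0 + 1e-9).all()


def test_gene_with_zero_events_skipped():
    from pascape.io_formats import GeneModel

    gene = GeneModel("g", "c", "+", 0, 100, regions=[("3UTR", 0, 100)], annotated_3p_ends=[99])
    w = D.PASWindow(contig="c", strand="+", center=50, start=43, end=58, gene_id="g")
    ev = pd.DataFrame([("c", "+", 5000, "s1", 10)], columns=D.EVENT_COLUMNS)
    with pytest.warns(UserWarning, match="zero cleavage events"):
        df = D.quantify_and_filter([w], ev, {"s1": "ctrl"}, {"g": gene})
    assert df.empty
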