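import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportions_ztest

from pascape import iclip as I
from pascape import synthetic
from pascape.io_formats import GeneModel, GenomeSequence


def _track(rows, lib="L"):
    return I.CrosslinkTrack(
        library_id=lib,
        counts=pd.DataFrame(rows, columns=["contig", "strand", "position", "count"]),
    )


def _gene(gid="g", start=0, end=1000, strand="+"):
    return GeneModel(gid, "c", strand, start, end,
                     regions=[("3UTR", start, end)],
                     annotated_3p_ends=[end - 1 if strand == "+" else start])


# ---------------------------------------------------------------------------
# crosslink extraction


def test_crosslink_one_nt_upstream_of_read_start():
    starts = pd.DataFrame(dict(contig=["c", "c"], strand=["+", "-"], position=[100, 100]))
    tr = I.extract_crosslinks(starts, "L")
    plus = tr.counts.loc[tr.counts["strand"] == "+", "position"].item()
    minus = tr.counts.loc[tr.counts["strand"] == "-", "position"].item()
    assert plus == 99 and minus == 101


def test_crosslink_counts_aggregate():
    starts = pd.DataFrame(dict(contig=["c"] * 2, strand=["+"] * 2, position=[100, 100]))
    tr = I.extract_crosslinks(starts, "L")
    assert tr.counts["count"].item() == 2 and tr.total_events == 2 and tr.n_positions == 1


def test_crosslink_off_contig_dropped():
    g = GenomeSequence({"c": "ACGT" * 10})
    starts = pd.DataFrame(dict(contig=["c", "c"], strand=["+", "+"], position=[0, 10]))
    with pytest.warns(UserWarning, match="off-contig"):
        tr = I.extract_crosslinks(starts, "L", genome=g)
    assert tr.counts["position"].tolist() == [9]


# ---------------------------------------------------------------------------
# significant crosslink calling


def test_xlink_call_single_tower_significant():
    genes = {"g": _gene()}
    tr = _track([("c", "+", 500, 50)])
    sig = I.call_significant_xlinks(tr, genes, seed=0)
    assert sig["position"].tolist() == [500]


def test_xlink_call_uniform_counts_not_significant():
    genes = {"g": _gene()}
    tr = _track([("c", "+", p, 1) for p in range(100, 150)])
    sig = I.call_significant_xlinks(tr, genes, seed=0)
    assert sig.empty


def test_xlink_call_nperm_zero_errors():
    with pytest.raises(ValueError):
        I.call_significant_xlinks(_track([("c", "+", 1, 2)]), {"g": _gene()}, n_perm=0)


def test_xlink_call_null_fdr_calibration():
    """Under a uniform null, the fraction of called positions stays within
    1.5x the nominal FDR across 100 seeded genes."""
    rng = np.random.default_rng(8)
    called = considered = 0
    for trial in range(100):
        gene = _gene(gid=f"g{trial}", end=800)
        n_ev = int(rng.integers(30, 80))
        pos = rng.integers(0, 800, size=n_ev)
        rows = pd.DataFrame(dict(contig="c", strand="+", position=pos)).groupby(
            "position").size().reset_index(name="count")
        tr = _track([("c", "+", int(p), int(c)) for p, c in rows.values])
        sig = I.call_significant_xlinks(tr, {gene.gene_id: gene}, n_perm=100,
                                        fdr=0.05, seed=trial)
        called += len(sig)
        considered += len(rows)
    assert called / considered <= 0.05 * 1.5


# ---------------------------------------------------------------------------
# k-mer enrichment


def test_kmer_planted_motif_ranks_first():
    rng = np.random.default_rng(9)
    seqs, genes, rows = {}, {}, []
    for gi in range(12):
        contig = f"c{gi}"
        seq = list("".join("ACGT"[b] for b in rng.integers(0, 4, size=900)))
        site = 450
        seq[site + 6 : site + 11] = list("TGTAA")  # planted in the +5..+30 flank
        seqs[contig] = "".join(seq)
        genes[f"g{gi}"] = GeneModel(f"g{gi}", contig, "+", 0, 900,
                                    regions=[("3UTR", 0, 900)], annotated_3p_ends=[899])
        rows.append((contig, "+", site, 5, 0.01, f"g{gi}"))
    genome = GenomeSequence(seqs)
    sig = pd.DataFrame(rows, columns=["contig", "strand", "position", "count", "fdr", "gene_id"])
    enr = I.kmer_zscore(sig, genome, genes, k=5, n_shuffles=100, seed=1)
    assert enr.table.iloc[0]["kmer"] == "TGTAA"


def test_kmer_observed_total_matches_windows():
    rng = np.random.default_rng(10)
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=600))
    genome = GenomeSequence({"c": seq})
    genes = {"g": _gene(end=600)}
    sig = pd.DataFrame([("c", "+", 300, 3, 0.01, "g")],
                       columns=["contig", "strand", "position", "count", "fdr", "gene_id"])
    enr = I.kmer_zscore(sig, genome, genes, k=5, n_shuffles=5, seed=0)
    # two 26-nt flanks, fully inside the gene: 2 x (26 - 5 + 1) k-mer windows
    assert enr.n_windows_scanned == 2 * 22
    assert enr.table["observed"].sum() == enr.n_windows_scanned


def test_kmer_null_z_tails_calibrated():
    """Uniform random genome: pooled across 25 seeded runs, |z| > 4 occurs for
    ≤1% of k-mers and the pooled 99th percentile of |z| stays below 4.

    k-mer counts in 26-nt flanks are clumpy (overlapping windows repeat the
    same word), so the per-run maximum over all k-mers has heavier-than-
    normal tails; the pooled tail fraction is the calibrated quantity.
    """
    rng = np.random.default_rng(11)
    allz = []
    for trial in range(25):
        seqs, genes, rows = {}, {}, []
        for gi in range(8):
            contig = f"c{gi}"
            seqs[contig] = "".join("ACGT"[b] for b in rng.integers(0, 4, size=700))
            genes[f"g{gi}"] = GeneModel(f"g{gi}", contig, "+", 0, 700,
                                        regions=[("3UTR", 0, 700)], annotated_3p_ends=[699])
            for _ in range(8):
                rows.append((contig, "+", int(rng.integers(100, 600)), 3, 0.01, f"g{gi}"))
        genome = GenomeSequence(seqs)
        sig = pd.DataFrame(rows, columns=["contig", "strand", "position", "count", "fdr", "gene_id"])
        enr = I.kmer_zscore(sig, genome, genes, k=4, n_shuffles=100, seed=trial)
        allz.append(enr.table["z"].to_numpy(dtype=float))
    z = np.abs(np.concatenate(allz))
    z = z[~np.isnan(z)]
    assert np.mean(z > 4) <= 0.01
    assert np.quantile(z, 0.99) <= 4.0


# ---------------------------------------------------------------------------
# metaprofiles


def test_metaprofile_unit_impulse():
    tr = _track([("c", "+", 425, 1)])
    prof = I.pas_metaprofile(tr, [("c", "+", 500)])
    idx = np.flatnonzero(prof.offsets == -75)
    assert prof.raw[idx].item() == pytest.approx(1.0)  # 1 count / 1 anchor / 1 position
    assert prof.raw.sum() == pytest.approx(1.0)


def test_metaprofile_anchor_duplication_invariant():
    rng = np.random.default_rng(12)
    tr = _track([("c", "+", int(p), int(c)) for p, c in
                 zip(rng.integers(0, 2000, size=100), rng.integers(1, 5, size=100))])
    anchors = [("c", "+", 500), ("c", "+", 1500)]
    p1 = I.pas_metaprofile(tr, anchors)
    p2 = I.pas_metaprofile(tr, anchors * 3)
    assert np.allclose(p1.raw, p2.raw)


def test_metaprofile_two_step_normalization_algebra():
    """Splitting the same events over twice as many positions at half the
    counts scales the profile by (1/2) / 2 = 1/4."""
    anchors = [("c", "+", 500)]
    a = _track([("c", "+", 450, 4), ("c", "+", 460, 4)], lib="A")
    b = _track([("c", "+", 450, 2), ("c", "+", 455, 2),
                ("c", "+", 460, 2), ("c", "+", 465, 2)], lib="B")
    pa = I.pas_metaprofile(a, anchors)
    pb = I.pas_metaprofile(b, anchors)
    ia = np.flatnonzero(pa.offsets == -50)
    assert pb.raw[ia].item() == pytest.approx(pa.raw[ia].item() / 4)


def test_metaprofile_empty_anchors_error():
    with pytest.raises(ValueError):
        I.pas_metaprofile(_track([("c", "+", 1, 1)]), [])


def test_metaprofile_minus_strand_offsets():
    tr = _track([("c", "-", 575, 1)])
    prof = I.pas_metaprofile(tr, [("c", "-", 500)])
    idx = np.flatnonzero(prof.offsets == -75)  # upstream on − is higher coordinate
    assert prof.raw[idx].item() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# two-proportions comparison


def test_two_proportions_example():
    assert I.two_proportions_z(30, 1000, 10, 1000) == pytest.approx(3.1944, abs=1e-3)


def test_two_proportions_matches_independent_implementation():
    """Closed form agrees with statsmodels' pooled two-proportion z to 1e-9
    on 1,000 random count pairs."""
    rng = np.random.default_rng(13)
    for _ in range(1000):
        n1, n2 = (int(x) for x in rng.integers(50, 10_000, size=2))
        x1 = int(rng.integers(1, n1))
        x2 = int(rng.integers(1, n2))
        ours = I.two_proportions_z(x1, n1, x2, n2)
        ref, _ = proportions_ztest([x1, x2], [n1, n2])
        assert ours == pytest.approx(ref, abs=1e-9)


def test_compare_identical_tracks_no_flags():
    rows = [("c", "+", int(p), 3) for p in range(100, 900, 10)]
    a, b = _track(rows, "A"), _track(rows, "B")
    res = I.compare_profiles(a, b, [("c", "+", 500)], lo=-100, hi=50)
    assert np.allclose(res.z, 0.0)
    assert not res.flags.any()
    assert res.scaling_factor == pytest.approx(1.0)


def test_compare_zero_total_errors():
    a = _track([("c", "+", 1, 1)])
    with pytest.raises(ValueError):
        I.compare_profiles(a, I.CrosslinkTrack("B", pd.DataFrame(columns=I.TRACK_COLUMNS)),
                           [("c", "+", 5)])


def test_compare_null_calibration(sim_bundle):
    """Two libraries drawn from the same rates: ≤2% of offsets flagged at
    FDR ≤ 0.01 over 50 seeded simulations."""
    genome, genes, truth = sim_bundle
    anchors = truth.anchors()
    flagged = total = 0
    for seedling in range(50):
        tracks = synthetic.simulate_crosslinks(
            genes, truth, library_ids=("A", "B"), depth=1.0,
            background_rate=0.03, seed=1000 + seedling,
        )
        res = I.compare_profiles(tracks["A"], tracks["B"], anchors, lo=-150, hi=50)
        flagged += int(res.flags.sum())
        total += res.flags.size
    assert flagged / total <= 0.02


def test_bh_monotonicity():
    """Flags at q=0.01 are a subset of flags at q=0.05."""
    rng = np.random.default_rng(14)
    rows_a = [("c", "+", int(p), int(c)) for p, c in
              zip(np.arange(0, 1200), rng.poisson(2.0, 1200) + 1)]
    rows_b = [("c", "+", int(p), int(c)) for p, c in
              zip(np.arange(0, 1200), rng.poisson(2.4, 1200) + 1)]
    a, b = _track(rows_a, "A"), _track(rows_b, "B")
    anchors = [("c", "+", 600)]
    r1 = I.compare_profiles(a, b, anchors, lo=-400, hi=100, fdr=0.01)
    r5 = I.compare_profiles(a, b, anchors, lo=-400, hi=100, fdr=0.05)
    assert set(np.flatnonzero(r1.flags)) <= set(np.flatnonzero(r5.flags))


# ---------------------------------------------------------------------------
# background z over crosslink profiles


def test_profile_background_null_calibration(sim_bundle):
    """Target anchors drawn from the unaffected pool: ≤2% flagged over 50 seeds."""
    genome, genes, truth = sim_bundle
    anchors = truth.anchors()
    tracks = synthetic.simulate_crosslinks(genes, truth, library_ids=("A",),
                                           background_rate=0.05, seed=77)
    track = tracks["A"]
    rng = np.random.default_rng(15)
    flagged = total = 0
    for seedling in range(50):
        idx = rng.choice(len(anchors), size=8, replace=False)
        target = [anchors[i] for i in idx]
        bz = I.profile_background_z(track, target, anchors, lo=-150, hi=50,
                                    n_resamples=100, fdr=0.01, seed=seedling)
        flagged += int(bz.flags.sum())
        total += int((~bz.excluded).sum())
    assert flagged / total <= 0.02


def test_profile_background_detects_planted_bump(sim_bundle):
    """Anchors with a 5x crosslink bump at −75 nt produce a flagged block
    covering the bump in nearly all seeds."""
    genome, genes, truth = sim_bundle
    anchors = truth.anchors()
    ok = 0
    for seedling in range(10):
        tracks = synthetic.simulate_crosslinks(
            genes, truth, library_ids=("A",), background_rate=0.05,
            bump_height=5.0, seed=3000 + seedling,
        )
        track = tracks["A"]
        # background pool: synthetic anchors far from any true PAS (no bump)
        pool = [(g.contig, g.strand, g.start + 120) for g in genes.values()]
        pool += [(g.contig, g.strand, g.start + 180) for g in genes.values()]
        pool += [(g.contig, g.strand, g.start + 240) for g in genes.values()]
        bz = I.profile_background_z(track, anchors, pool, lo=-150, hi=0,
                                    n_resamples=60, fdr=0.01, seed=seedling)
        offsets = np.arange(-150, 1)
        bump = (offsets >= -85) & (offsets <= -65)
        if bz.flags[bump].mean() >= 0.5:
            ok += 1
    assert ok >= 9
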