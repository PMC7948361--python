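"""UGUA motif geometry around called polyadenylation sites.

Computes the UGUA (CFIm element) metaprofile around the planted PASs of a
synthetic genome, a resampled-background z-score against unaffected PASs,
and the cumulative fraction of PASs enclosed by tandem UGUAs.
"""

import numpy as np

from pascape import motifs, synthetic

genome, genes, truth = synthetic.simulate_genome(n_genes=10, seed=21)
anchors = truth.anchors()

prof = motifs.metaprofile(anchors, genome, "UGUA", half_window=150)
peak = prof.offsets[np.argmax(prof.smoothed)]
upstream = prof.raw[prof.offsets < 0].mean()
downstream = prof.raw[prof.offsets > 0].mean()
print(f"anchors: {prof.n_anchors} PASs")
print(f"smoothed UGUA profile peaks at offset {peak:+d} nt")
print(f"mean per-offset UGUA fraction upstream {upstream:.4f} vs downstream {downstream:.4f}")
print("(the generator plants UGUA elements 55-70 nt upstream of ~70% of PASs,")
print(" so the upstream flank is enriched over the 1/256 random expectation)")

rng = np.random.default_rng(5)
target = [anchors[i] for i in rng.choice(len(anchors), size=10, replace=False)]
bz = motifs.metaprofile_background_z(
    target, anchors, genome, "UGUA",
    half_window=150, n_resamples=100, fdr=0.01, seed=5,
)
print(f"\nbackground z-score: {int(bz.flags.sum())} of {bz.offsets.size} offsets flagged")
print("(the target is a random subset of the background pool -> ~0 expected;")
print(" a regulated PAS set would show a contiguous flagged block instead)")

tp = motifs.tandem_ugua(anchors, genome, mode="enclosing")
print(f"\ntandem UGUA (enclosing): fraction at Win_size 75 = {tp.fraction[-1]:.2f}")
dists = [d for d in tp.min_distance if not np.isnan(d)]
if dists:
    print(f"median minimum UGUA-UGUA distance among qualifying PASs: {np.median(dists):.0f} nt")
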