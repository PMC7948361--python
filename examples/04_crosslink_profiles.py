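"""Protein-RNA crosslink analytics around polyadenylation sites.

Simulates two iCLIP-like libraries whose binding peaks ~75 nt upstream of
every PAS, builds the doubly-normalized metaprofile, compares the two
libraries position-wise (two-proportions z-test with depth scaling) and
calls significant crosslink sites by within-gene permutation.
"""

import numpy as np

from pascape import iclip, synthetic

genome, genes, truth = synthetic.simulate_genome(n_genes=8, seed=31)
anchors = truth.anchors()

tracks = synthetic.simulate_crosslinks(
    genes, truth, library_ids=("protA", "protB"),
    background_rate=0.03, bump_offset=-75, bump_sd=8.0, bump_height=3.0, seed=31,
)

for lib, track in tracks.items():
    prof = iclip.pas_metaprofile(track, anchors, lo=-200, hi=50)
    peak = prof.offsets[np.argmax(prof.smoothed)]
    print(f"{lib}: {track.total_events} events at {track.n_positions} positions; "
          f"profile peak at {peak:+d} nt")

res = iclip.compare_profiles(tracks["protA"], tracks["protB"], anchors, lo=-200, hi=50)
print(f"\ntwo-proportions comparison: scaling factor {res.scaling_factor:.3f}, "
      f"{int(res.flags.sum())} of {res.flags.size} offsets flagged at FDR <= 0.01")
print("(both libraries share the same generating rates -> ~0 flags expected)")

sig = iclip.call_significant_xlinks(tracks["protA"], genes, n_perm=100, fdr=0.05, seed=3)
offs = []
for row in sig.itertuples(index=False):
    gt = truth.genes[row.gene_id]
    offs += [
        (row.position - p.position) if gt.strand == "+" else (p.position - row.position)
        for p in gt.pas
    ]
near_peak = sum(-110 <= o <= -40 for o in offs)
print(f"\nsignificant crosslink sites: {len(sig)}; "
      f"{near_peak}/{len(offs)} site-PAS offsets fall in the planted -110..-40 nt band")
print("The permutation FDR keeps only positions whose event pile-up cannot be")
print("explained by redistributing the gene's events uniformly.")
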