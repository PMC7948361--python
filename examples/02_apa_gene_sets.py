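"""Threshold an APA result table and test the overlap of two target sets.

Builds a small DaPars-style table (per-gene PDUI in control and condition,
FDR), extracts the significantly shortened / lengthened 3'UTR gene sets
(FDR <= 0.1, |dPDUI| >= 0.05) and runs Fisher's exact test on the overlap
of two such sets — the statistic used to ask whether two knockdowns
regulate a common APA target pool.
"""

import numpy as np

from pascape.annotation import overlap_fisher, threshold_apa
from pascape.io_formats import DaParsRecord

rng = np.random.default_rng(4)
universe = [f"gene{i:03d}" for i in range(200)]


def make_table(shift_genes, direction, seed):
    rng = np.random.default_rng(seed)
    records = []
    for g in universe:
        base = rng.uniform(0.2, 0.8)
        if g in shift_genes:
            delta = direction * rng.uniform(0.08, 0.3)
            fdr = rng.uniform(0.0, 0.05)
        else:
            delta = rng.normal(0.0, 0.01)
            fdr = rng.uniform(0.2, 1.0)
        cond = min(1.0, max(0.0, base + delta))
        records.append(DaParsRecord(g, "chr1", "+", 1000, 2000, base, cond, cond - base, fdr))
    return records

targets_a = set(rng.choice(universe, size=40, replace=False))
targets_b = set(rng.choice(sorted(targets_a), size=20, replace=False)) | set(
    rng.choice(universe, size=10, replace=False)
)

table_a = make_table(targets_a, direction=-1, seed=1)  # shortening regulator
table_b = make_table(targets_b, direction=-1, seed=2)

short_a, long_a = threshold_apa(table_a, fdr_max=0.1, min_abs_dpdui=0.05)
short_b, long_b = threshold_apa(table_b, fdr_max=0.1, min_abs_dpdui=0.05)
print(f"knockdown A: {len(short_a)} shortened, {len(long_a)} lengthened genes")
print(f"knockdown B: {len(short_b)} shortened, {len(long_b)} lengthened genes")

n, odds, p = overlap_fisher(short_a, short_b, set(universe))
print(f"\noverlap of shortened sets: {n} genes, odds ratio {odds:.1f}, P = {p:.3g}")
print("A small P value says the two factors share APA targets far beyond chance.")
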