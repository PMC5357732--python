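"""Broken boundary index: find which boundaries lost precision.

Injects spreading (30% of proximal reads displaced outward, 200-bp decay)
at 10 of 100 boundaries of a late-stage library, computes the BBI of every
boundary against an independent wild-type control, and shows that the
injected boundaries rise to the top of the ranking while the distribution
of untouched boundaries stays centered at 1.
"""

from dataclasses import replace

import numpy as np

from scnbound.bbi import bbi_table, summarize_bbi, top_n_heatmap
from scnbound.simulate import SimConfig, make_genome, simulate_scnrna, with_seed

cfg = SimConfig(seed=3, n_chrom=2, chrom_length=500_000, n_ies_A=25,
                n_ies_B=25, ies_length_range=(1000, 3000),
                n_reads=200_000, stage="late")
genome = make_genome(cfg)

keys = [(s.ies_id, side) for s in genome.ies_segments()
        for side in ("left", "right")]
rng = np.random.default_rng(99)
injected = sorted(tuple(keys[i])
                  for i in rng.choice(len(keys), size=10, replace=False))
sample = simulate_scnrna(
    replace(cfg, spread={k: (0.3, 200.0) for k in injected}), genome)
control = simulate_scnrna(with_seed(cfg, 4), genome)

table = bbi_table(sample, control, genome, pseudocount=1,
                  min_control_reads=10)
s = summarize_bbi(table)
print(f"BBI over {s['n']} eligible boundaries: median {s['median']:.3f} "
      f"(IQR {s['q1']:.3f}-{s['q3']:.3f})")

top10 = table[table["eligible"]].nsmallest(10, "rank")
hits = set(zip(top10["ies_id"], top10["side"])) & set(injected)
print(f"top 10 BBI ranks contain {len(hits)}/10 injected boundaries")
print(f"highest BBI: {top10['bbi'].iloc[0]:.1f} at "
      f"{top10['ies_id'].iloc[0]}/{top10['side'].iloc[0]} "
      "(vs ~1 for an undisturbed boundary)")

heatmap = top_n_heatmap(table, {"mutant": sample, "wt": control}, genome,
                        n=10, bin_size=50)
mut = heatmap["mutant"].values
outside_share = mut[:, :10].sum() / mut.sum()
print(f"top-10 heatmap (50-bp bins): {outside_share:.0%} of mutant RPM sits "
      "outside the boundary; the same rows in the control stay inside "
      f"({heatmap['wt'].values[:, :10].sum() / heatmap['wt'].values.sum():.0%})")
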