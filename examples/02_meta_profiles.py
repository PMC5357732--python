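"""Boundary meta-profiles of wild-type vs boundary-spreading libraries.

Compiles scnRNA 13th-nt anchors over the 500 bp outside/inside of every
type-B IES boundary (10-bp bins) for a clean late-stage library and for a
mutant-like library in which every boundary leaks 30% of its proximal
reads into flanking MDS.  In the wild type all signal sits at positive
offsets (inside the IES); in the mutant the outside half fills in.
"""

from dataclasses import replace

import numpy as np

from scnbound.profiles import meta_profile
from scnbound.simulate import SimConfig, make_genome, simulate_scnrna

cfg = SimConfig(seed=7, n_chrom=2, chrom_length=400_000, n_ies_A=15,
                n_ies_B=15, n_reads=100_000, stage="late")
genome = make_genome(cfg)
wt = simulate_scnrna(cfg, genome)

spread_all = {(s.ies_id, side): (0.3, 200.0)
              for s in genome.ies_segments()
              for side in ("left", "right")}
mutant = simulate_scnrna(replace(cfg, spread=spread_all), genome)

for name, lib in (("WT", wt), ("spreading mutant", mutant)):
    prof = meta_profile(lib, genome, "B", bin_size=10, window=500,
                        anchor_mode="nt13")
    total = prof.total()
    outside = total[prof.offsets() < 0].sum()
    inside = total[prof.offsets() >= 0].sum()
    print(f"{name}: type-B meta-profile over {prof.n_boundaries} boundaries; "
          f"RPM outside/inside = {outside:,.0f}/{inside:,.0f} "
          f"(ratio {outside / inside:.3f})")
print("the outside/inside RPM ratio is the meta-profile view of boundary "
      "precision: ~0 in WT, rising with spreading")
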