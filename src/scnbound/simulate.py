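"""Synthetic genomes and scnRNA/ChIP libraries with the structure the
analysis assumes.

The generator emulates, at coordinate level (no nucleotides), the
developmental small-RNA program of *Tetrahymena* conjugation:

* ``early_3h`` — Early-scnRNAs from type-A IES bodies plus flanking MDS,
  with flank density decaying exponentially away from the IES edge;
* ``post_selection_6h`` — the same, after "scnRNA selection" removes
  MDS-anchored reads with a configurable efficiency;
* ``late`` — Late-scnRNAs from type-A and type-B IES bodies only, except
  at boundaries given a spreading parameter, where a fraction of
  boundary-proximal reads is displaced across the edge into MDS with a
  one-sided exponential displacement kernel (the minimal one-parameter
  model of ectopic Late-scnRNA production).

Read lengths follow a 26-32 nt scnRNA distribution plus an out-of-range
contaminant fraction; strands are unbiased.  ChIP libraries are fragment
midpoint draws with uniform input and fold enrichment over IES bodies.
All randomness flows from a single integer seed; each operation derives
an independent stream from it, so libraries and genomes are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import IES_A, IES_B, MDS, Segment, SegmentedGenome
from .profiles import ChipPair
from .reads import BED6_COLUMNS, Library

# default scnRNA length distribution: unimodal, peaked at 28-29 nt
DEFAULT_LENGTH_DIST = {26: 0.08, 27: 0.15, 28: 0.25, 29: 0.22,
                       30: 0.15, 31: 0.09, 32: 0.06}
CONTAMINANT_LENGTHS = tuple(range(20, 26)) + tuple(range(33, 41))

STAGES = ("early_3h", "post_selection_6h", "late")


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    ``spread`` maps (ies_id, side) to (fraction, decay): at that boundary
    the given fraction of boundary-proximal reads (5' anchor within
    ``spread_proximal`` of the edge, inside the IES) is displaced outside
    with exponential decay length ``decay`` (bases).  ``global_scale``
    multiplies the library size (a ΔLIA5-like global elevation);
    ``chip_spread`` optionally applies the same displacement to ChIP
    fragments.
    """

    seed: int = 0
    n_chrom: int = 4
    chrom_length: int = 1_000_000
    n_ies_A: int = 30
    n_ies_B: int = 20
    ies_length_range: tuple[int, int] = (1000, 4000)
    mds_length_range: tuple[int, int] = (2000, 6000)
    stage: str = "late"
    n_reads: int = 200_000
    length_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST)
    )
    contaminant_fraction: float = 0.05
    spread: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    spread_proximal: int = 500
    selection_efficiency: float = 0.9
    early_flank_fraction: float = 0.5
    early_flank_lambda: float = 300.0
    late_type_b_fraction: float = 0.4
    chip_enrichment: float = 5.0
    chip_fragment_length: tuple[int, int] = (150, 250)
    chip_n_fragments: int = 500_000
    chip_spread: dict[tuple[str, str], tuple[float, float]] | None = None
    global_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        total = sum(self.length_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("length_dist probabilities must sum to 1")
        if not set(self.length_dist) <= set(range(26, 33)):
            raise ValueError("length_dist lengths must lie in 26..32")
        for p in (self.contaminant_fraction, self.selection_efficiency,
                  self.early_flank_fraction, self.late_type_b_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for count in (self.n_chrom, self.n_ies_A + self.n_ies_B, self.n_reads):
            if count <= 0:
                raise ValueError("counts must be positive")

    def rng(self, salt: int) -> np.random.Generator:
        """Independent stream for one operation, derived from the one seed."""
        return np.random.default_rng([self.seed, salt])


_SALT_GENOME, _SALT_SCN, _SALT_CHIP = 1, 2, 3


def make_genome(cfg: SimConfig) -> SegmentedGenome:
    """Alternating MDS/IES layout; IES types shuffled over positions.

    IESs are distributed round-robin over chromosomes; the final MDS of
    each chromosome is stretched to reach ``chrom_length``.  Infeasible
    packing (content longer than the chromosome) is a hard error.
    """
    rng = cfg.rng(_SALT_GENOME)
    n_ies = cfg.n_ies_A + cfg.n_ies_B
    types = np.array([IES_A] * cfg.n_ies_A + [IES_B] * cfg.n_ies_B)
    rng.shuffle(types)
    ies_lengths = rng.integers(*cfg.ies_length_range, endpoint=True, size=n_ies)
    per_chrom: dict[int, list[int]] = {i: [] for i in range(cfg.n_chrom)}
    for i in range(n_ies):
        per_chrom[i % cfg.n_chrom].append(i)
    segments: list[Segment] = []
    chrom_lengths: dict[str, int] = {}
    counter = 1
    for ci in range(cfg.n_chrom):
        chrom = f"chr{ci + 1}"
        pos = 0
        idxs = per_chrom[ci]
        mds_lens = rng.integers(*cfg.mds_length_range, endpoint=True,
                                size=len(idxs) + 1)
        for k, i in enumerate(idxs):
            mds_end = pos + int(mds_lens[k])
            segments.append(Segment(chrom, pos, mds_end, MDS))
            ies_end = mds_end + int(ies_lengths[i])
            segments.append(
                Segment(chrom, mds_end, ies_end, str(types[i]),
                        ies_id=f"ies_{counter:06d}")
            )
            counter += 1
            pos = ies_end
        tail = max(int(mds_lens[-1]), 1)
        if pos + tail > cfg.chrom_length:
            raise ValueError(
                f"{chrom}: segments need {pos + tail} bp but chrom_length "
                f"is {cfg.chrom_length}; packing infeasible"
            )
        segments.append(Segment(chrom, pos, cfg.chrom_length, MDS))
        chrom_lengths[chrom] = cfg.chrom_length
    return SegmentedGenome(chrom_lengths, segments)


def _draw_lengths(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    lengths = np.fromiter(cfg.length_dist.keys(), dtype=np.int64)
    probs = np.fromiter(cfg.length_dist.values(), dtype=float)
    out = rng.choice(lengths, size=n, p=probs / probs.sum())
    contam = rng.random(n) < cfg.contaminant_fraction
    out[contam] = rng.choice(np.array(CONTAMINANT_LENGTHS), size=int(contam.sum()))
    return out


def _ies_arrays(genome: SegmentedGenome, types: tuple[str, ...]):
    segs = [s for s in genome.ies_segments() if s.label in types]
    return segs, np.array([s.length for s in segs], dtype=float)


def _reads_frame(
    genome: SegmentedGenome,
    chrom: np.ndarray,
    anchor: np.ndarray,
    lengths: np.ndarray,
    plus: np.ndarray,
) -> pd.DataFrame:
    """Assemble BED6 from 5' anchors; shift intervals to stay in-chromosome."""
    start = np.where(plus, anchor, anchor + 1 - lengths)
    end = start + lengths
    # shift (never truncate: lengths are data) the rare interval poking out
    for c, clen in genome.chrom_lengths.items():
        m = chrom == c
        shift = np.maximum(0, -start) - np.maximum(0, end - clen)
        start[m] += shift[m]
        end[m] += shift[m]
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "name": [f"read_{i}" for i in range(len(start))],
            "score": 0,
            "strand": np.where(plus, "+", "-"),
        }
    )
    return df.sort_values(
        ["chrom", "start", "end", "strand"], kind="mergesort"
    ).reset_index(drop=True)


def _five_prime(anchor_start: np.ndarray) -> np.ndarray:
    return anchor_start


def simulate_scnrna(cfg: SimConfig, genome: SegmentedGenome) -> Library:
    """Simulate one scnRNA library for the configured stage.

    Returns a :class:`Library` whose reads are the 26-32 nt-filtered set
    (the RPM denominator); the full read table including contaminants is
    kept on ``Library.reads`` only after filtering — use
    :func:`simulate_scnrna_raw` for the unfiltered BED table.
    """
    return Library.from_reads(
        simulate_scnrna_raw(cfg, genome), name=f"sim_{cfg.stage}_seed{cfg.seed}"
    )


def simulate_scnrna_raw(cfg: SimConfig, genome: SegmentedGenome) -> pd.DataFrame:
    rng = cfg.rng(_SALT_SCN)
    n = int(round(cfg.n_reads * cfg.global_scale))

    if cfg.stage == "late":
        chrom, anchor = _late_anchors(cfg, genome, rng, n)
    else:
        chrom, anchor = _early_anchors(cfg, genome, rng, n)
        if cfg.stage == "post_selection_6h":
            keep = np.ones(len(anchor), dtype=bool)
            for c in np.unique(chrom):
                m = chrom == c
                labels = genome.label_at(str(c), anchor[m])
                in_mds = labels == MDS
                drop = in_mds & (rng.random(int(m.sum())) < cfg.selection_efficiency)
                idx = np.flatnonzero(m)
                keep[idx[drop]] = False
            chrom, anchor = chrom[keep], anchor[keep]

    m = len(anchor)
    lengths = _draw_lengths(cfg, rng, m)
    plus = rng.random(m) < 0.5
    return _reads_frame(genome, chrom, anchor, lengths, plus)


def _early_anchors(cfg, genome, rng, n):
    """Type-A bodies plus exponential flanks (Early-scnRNA geography)."""
    segs, weights = _ies_arrays(genome, (IES_A,))
    if not segs:
        raise ValueError("genome has no type-A IESs for an early-stage library")
    pick = rng.choice(len(segs), size=n, p=weights / weights.sum())
    in_flank = rng.random(n) < cfg.early_flank_fraction
    u = rng.random(n)
    starts = np.array([s.start for s in segs])
    ends = np.array([s.end for s in segs])
    body = starts[pick] + np.floor(u * (ends[pick] - starts[pick])).astype(np.int64)
    left = rng.random(n) < 0.5
    d = np.floor(rng.exponential(cfg.early_flank_lambda, size=n)).astype(np.int64)
    flank = np.where(left, starts[pick] - 1 - d, ends[pick] + d)
    anchor = np.where(in_flank, flank, body)
    chrom = np.array([segs[i].chrom for i in pick])
    anchor = _clip_anchors(genome, chrom, anchor)
    return chrom, anchor


def _late_anchors(cfg, genome, rng, n):
    """IES-body anchors (A and B) with per-boundary displacement spreading."""
    segs_a, w_a = _ies_arrays(genome, (IES_A,))
    segs_b, w_b = _ies_arrays(genome, (IES_B,))
    if not segs_a and not segs_b:
        raise ValueError("genome has no IESs")
    from_b = rng.random(n) < (
        cfg.late_type_b_fraction if segs_b else 0.0
    )
    if not segs_a:
        from_b[:] = True
    segs = segs_a + segs_b
    weights = np.concatenate([w_a, w_b]) if segs_a and segs_b else (
        w_a if segs_a else w_b
    )
    offset = len(segs_a)
    pick = np.empty(n, dtype=np.int64)
    n_b = int(from_b.sum())
    if segs_a:
        pick[~from_b] = rng.choice(len(segs_a), size=n - n_b, p=w_a / w_a.sum())
    if segs_b:
        pick[from_b] = offset + rng.choice(len(segs_b), size=n_b, p=w_b / w_b.sum())
    starts = np.array([s.start for s in segs])
    ends = np.array([s.end for s in segs])
    u = rng.random(n)
    anchor = starts[pick] + np.floor(u * (ends[pick] - starts[pick])).astype(np.int64)
    chrom = np.array([segs[i].chrom for i in pick])

    if cfg.spread:
        by_id = {s.ies_id: i for i, s in enumerate(segs)}
        for (ies_id, side), (frac, lam) in sorted(cfg.spread.items()):
            i = by_id.get(ies_id)
            if i is None:
                raise KeyError(f"spread references unknown IES {ies_id!r}")
            if side == "left":
                prox = (pick == i) & (anchor < starts[i] + cfg.spread_proximal)
            else:
                prox = (pick == i) & (anchor >= ends[i] - cfg.spread_proximal)
            move = prox & (rng.random(n) < frac)
            k = int(move.sum())
            d = np.floor(rng.exponential(lam, size=k)).astype(np.int64)
            if side == "left":
                anchor[move] = starts[i] - 1 - d
            else:
                anchor[move] = ends[i] + d
    anchor = _clip_anchors(genome, chrom, anchor)
    return chrom, anchor


def _clip_anchors(genome, chrom, anchor):
    anchor = anchor.copy()
    for c, clen in genome.chrom_lengths.items():
        m = chrom == c
        anchor[m] = np.clip(anchor[m], 0, clen - 1)
    return anchor


def simulate_chip(cfg: SimConfig, genome: SegmentedGenome) -> ChipPair:
    """Fragment-midpoint ChIP and matched uniform input libraries.

    ChIP midpoints are drawn with density proportional to
    ``chip_enrichment`` over IES bodies and 1 elsewhere; optional
    ``chip_spread`` displaces boundary-proximal ChIP fragments outward,
    emulating heterochromatin spreading across the edge.
    """
    if cfg.chip_enrichment < 1:
        raise ValueError("chip_enrichment must be >= 1")
    rng = cfg.rng(_SALT_CHIP)
    segs = [s for c in sorted(genome.segments) for s in genome.segments[c]]
    lens = np.array([s.length for s in segs], dtype=float)
    is_ies = np.array([s.is_ies for s in segs])
    starts = np.array([s.start for s in segs])
    chroms = np.array([s.chrom for s in segs])

    def draw(weights: np.ndarray, n: int):
        pick = rng.choice(len(segs), size=n, p=weights / weights.sum())
        u = rng.random(n)
        mid = starts[pick] + np.floor(u * lens[pick]).astype(np.int64)
        return chroms[pick], mid, pick

    n = cfg.chip_n_fragments
    in_chrom, in_mid, _ = draw(lens, n)
    w_chip = lens * np.where(is_ies, cfg.chip_enrichment, 1.0)
    ch_chrom, ch_mid, ch_pick = draw(w_chip, n)

    if cfg.chip_spread:
        by_id = {s.ies_id: i for i, s in enumerate(segs) if s.is_ies}
        ends = starts + lens.astype(np.int64)
        for (ies_id, side), (frac, lam) in sorted(cfg.chip_spread.items()):
            i = by_id[ies_id]
            if side == "left":
                prox = (ch_pick == i) & (ch_mid < starts[i] + cfg.spread_proximal)
            else:
                prox = (ch_pick == i) & (ch_mid >= ends[i] - cfg.spread_proximal)
            move = prox & (rng.random(n) < frac)
            k = int(move.sum())
            d = np.floor(rng.exponential(lam, size=k)).astype(np.int64)
            ch_mid[move] = (starts[i] - 1 - d) if side == "left" else (ends[i] + d)

    def frame(chrom, mid, tag):
        flen = rng.integers(*cfg.chip_fragment_length, endpoint=True, size=len(mid))
        plus = rng.random(len(mid)) < 0.5
        start = mid - flen // 2
        end = start + flen
        df = pd.DataFrame(
            {
                "chrom": chrom, "start": start, "end": end,
                "name": [f"{tag}_{i}" for i in range(len(mid))],
                "score": 0, "strand": np.where(plus, "+", "-"),
            }
        )
        for c, clen in genome.chrom_lengths.items():
            m = df["chrom"].to_numpy() == c
            shift = (np.maximum(0, -df["start"].to_numpy())
                     - np.maximum(0, df["end"].to_numpy() - clen))
            df.loc[m, "start"] += shift[m]
            df.loc[m, "end"] += shift[m]
        return df.sort_values(
            ["chrom", "start", "end", "strand"], kind="mergesort"
        ).reset_index(drop=True)

    chip = Library.from_reads(
        frame(ch_chrom, ch_mid, "chip"),
        name=f"sim_chip_seed{cfg.seed}", scnrna_filter=False,
    )
    inp = Library.from_reads(
        frame(in_chrom, in_mid, "input"),
        name=f"sim_input_seed{cfg.seed}", scnrna_filter=False,
    )
    return ChipPair(chip=chip, input=inp)


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Same study conditions, different random stream (replicate libraries)."""
    return replace(cfg, seed=seed)
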