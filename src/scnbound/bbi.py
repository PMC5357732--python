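"""Broken boundary index (BBI): per-boundary spreading statistic and ranking.

For one IES boundary, reads mapping to the 500-bp MDS window outside the
edge are compared with reads mapping to the 500-bp IES window inside it,
and that ratio is normalized by the same ratio in a matched wild-type
control library:

    BBI = (MDS_sample / IES_sample) / (MDS_control / IES_control)

A BBI near 1 means boundary precision equal to wild type; values above 1
mean small-RNA production has leaked across the edge into MAC-destined
sequence.  A pseudocount (default 1) is added to all four counts, and
boundaries whose control inside-count is below a threshold are flagged
ineligible, because the ratio of ratios is unstable at low coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import DEFAULT_WINDOW, BoundaryWindow, SegmentedGenome
from .profiles import HEATMAP_BIN
from .reads import Library, rpm

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_MIN_CONTROL_READS = 10

BBI_COLUMNS = [
    "ies_id", "side", "ies_type", "chrom", "boundary",
    "mds_sample", "ies_sample", "mds_control", "ies_control",
    "bbi", "eligible", "rank",
]


def boundary_counts(
    lib: Library, bw: BoundaryWindow, anchor_mode: str = "nt13"
) -> tuple[int, int]:
    """(MDS-window count, IES-window count) of anchors at one boundary.

    Both strands are pooled.  The window must be eligible; callers are
    expected to pre-filter ineligible (short-IES or chromosome-edge)
    boundaries.
    """
    if not bw.eligible:
        raise ValueError(
            f"boundary {bw.ies_id}/{bw.side} is ineligible (short IES or "
            "truncated window); filter before counting"
        )
    index = lib.anchors_by_chrom(anchor_mode)
    if bw.chrom not in index:
        return (0, 0)
    pos, _ = index[bw.chrom]
    o0, o1 = np.searchsorted(pos, bw.outside)
    i0, i1 = np.searchsorted(pos, bw.inside)
    return (int(o1 - o0), int(i1 - i0))


def compute_bbi(
    sample_counts: tuple[float, float],
    control_counts: tuple[float, float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Ratio-of-ratios BBI with a symmetric pseudocount on all four counts."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    mds_s, ies_s = sample_counts
    mds_c, ies_c = control_counts
    if pseudocount == 0 and (ies_s == 0 or mds_c == 0 or ies_c == 0):
        raise ValueError(
            "zero count in a denominator with pseudocount 0; use a positive "
            "pseudocount or filter the boundary"
        )
    return ((mds_s + pseudocount) / (ies_s + pseudocount)) / (
        (mds_c + pseudocount) / (ies_c + pseudocount)
    )


def bbi_table(
    sample: Library,
    control: Library,
    genome: SegmentedGenome,
    window: int = DEFAULT_WINDOW,
    anchor_mode: str = "nt13",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_control_reads: int = DEFAULT_MIN_CONTROL_READS,
    include_foreign_overlaps: bool = True,
    windows: list[BoundaryWindow] | None = None,
) -> pd.DataFrame:
    """BBI at every window-eligible boundary, ranked by descending BBI.

    ``eligible`` additionally requires the control inside-count to reach
    ``min_control_reads``; ranks (1 = highest BBI) are assigned among
    eligible boundaries only, with ties broken by (chrom, boundary
    position, side).
    """
    if windows is None:
        windows = genome.boundaries(window)
    use = [w for w in windows if w.eligible]
    if not include_foreign_overlaps:
        use = [w for w in use if not w.overlaps_foreign_ies]
    rows = []
    for bw in use:
        mds_s, ies_s = boundary_counts(sample, bw, anchor_mode)
        mds_c, ies_c = boundary_counts(control, bw, anchor_mode)
        rows.append(
            (
                bw.ies_id, bw.side, bw.ies_type, bw.chrom, bw.boundary,
                mds_s, ies_s, mds_c, ies_c,
                compute_bbi((mds_s, ies_s), (mds_c, ies_c), pseudocount),
                ies_c >= min_control_reads,
            )
        )
    df = pd.DataFrame(rows, columns=BBI_COLUMNS[:-1])
    df["rank"] = pd.array([pd.NA] * len(df), dtype="Int64")
    elig = df[df["eligible"]].sort_values(
        by=["bbi", "chrom", "boundary", "side"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    df.loc[elig.index, "rank"] = np.arange(1, len(elig) + 1)
    return df


def summarize_bbi(table: pd.DataFrame) -> dict:
    """Median/quartile summary of the eligible-boundary BBI distribution."""
    vals = table.loc[table["eligible"], "bbi"].to_numpy()
    if len(vals) == 0:
        return {"n": 0, "median": None, "q1": None, "q3": None}
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {"n": int(len(vals)), "median": float(med),
            "q1": float(q1), "q3": float(q3)}


@dataclass
class HeatmapMatrix:
    """Top-N boundaries (rank order) x 50-bp bins across the boundary axis."""

    strain: str
    row_ids: list[tuple[str, str]]  # (ies_id, side) in rank order
    values: np.ndarray  # n_rows x (2*window/bin_size), RPM
    bin_size: int
    window: int

    def to_frame(self) -> pd.DataFrame:
        offsets = np.arange(self.values.shape[1]) * self.bin_size - self.window
        df = pd.DataFrame(self.values, columns=[f"offset_{o}" for o in offsets])
        df.insert(0, "ies_id", [r[0] for r in self.row_ids])
        df.insert(1, "side", [r[1] for r in self.row_ids])
        return df


def _boundary_bins(
    lib: Library, bw: BoundaryWindow, window: int, bin_size: int, anchor_mode: str
) -> np.ndarray:
    """Strand-pooled raw anchor counts per bin on one boundary's axis."""
    n_bins = 2 * window // bin_size
    out = np.zeros(n_bins)
    index = lib.anchors_by_chrom(anchor_mode)
    if bw.chrom not in index:
        return out
    pos, _ = index[bw.chrom]
    b = bw.boundary
    i0, i1 = np.searchsorted(pos, [b - window, b + window])
    if bw.side == "left":
        off = pos[i0:i1] - b
    else:
        off = (b - 1) - pos[i0:i1]
    np.add.at(out, (off + window) // bin_size, 1)
    return out


def top_n_heatmap(
    table: pd.DataFrame,
    libs: dict[str, Library],
    genome: SegmentedGenome,
    n: int = 50,
    bin_size: int = HEATMAP_BIN,
    window: int = DEFAULT_WINDOW,
    anchor_mode: str = "nt13",
    windows: list[BoundaryWindow] | None = None,
) -> dict[str, HeatmapMatrix]:
    """RPM heatmaps of the reference strain's top-N boundaries in every strain.

    The row set comes once from ``table`` (the reference strain's BBI
    ranking) and the SAME rows are profiled in each library, so strains
    are directly comparable row by row.
    """
    if (2 * window) % bin_size:
        raise ValueError(f"bin size {bin_size} does not divide the 2x{window} axis")
    n_eligible = int(table["eligible"].sum())
    if n > n_eligible:
        raise ValueError(f"requested top {n} but only {n_eligible} eligible boundaries")
    top = table[table["eligible"]].sort_values("rank").head(n)
    if windows is None:
        windows = genome.boundaries(window)
    by_key = {(w.ies_id, w.side): w for w in windows}
    rows = [(r.ies_id, r.side) for r in top.itertuples(index=False)]
    out: dict[str, HeatmapMatrix] = {}
    for strain, lib in libs.items():
        values = np.vstack(
            [
                rpm(_boundary_bins(lib, by_key[key], window, bin_size, anchor_mode), lib)
                for key in rows
            ]
        )
        out[strain] = HeatmapMatrix(
            strain=strain, row_ids=rows, values=values,
            bin_size=bin_size, window=window,
        )
    return out


def per_ies_table(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse the boundary-level table to one row per IES (max-BBI side),
    re-ranked among eligible IESs."""
    elig = table[table["eligible"]]
    idx = elig.groupby("ies_id")["bbi"].idxmax()
    df = table.loc[sorted(idx)].copy()
    df = df.sort_values(
        by=["bbi", "chrom", "boundary", "side"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
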