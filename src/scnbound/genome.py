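"""Segmented germline-genome model.

The micronuclear (germline) genome of *Tetrahymena* is a tiling of
MAC-destined sequences (MDS) and internal eliminated sequences (IES),
the latter split into type A (source of Early-scnRNAs) and type B
(dependent on Late-scnRNAs).  This module represents that segmentation,
reads/writes it as BED, and derives the oriented 500-bp boundary windows
that every downstream meta-profile and boundary statistic is anchored to.

All coordinates are 0-based, half-open (BED convention).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MDS = "MDS"
IES_A = "IES_A"
IES_B = "IES_B"
IES_LABELS = (IES_A, IES_B)
VALID_LABELS = (MDS, IES_A, IES_B)

DEFAULT_WINDOW = 500


@dataclass(frozen=True)
class Segment:
    """One labeled interval of the germline genome (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    label: str
    ies_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")
        if not self.start < self.end:
            raise ValueError(
                f"empty/inverted segment {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_ies(self) -> bool:
        return self.label in IES_LABELS

    @property
    def ies_type(self) -> str:
        """'A' or 'B' for IES segments."""
        if not self.is_ies:
            raise ValueError("not an IES segment")
        return self.label[-1]


@dataclass(frozen=True)
class BoundaryWindow:
    """One IES edge with its paired inside(IES)/outside(MDS-side) windows.

    ``inside`` abuts the edge from within the IES; ``outside`` abuts it from
    the flanking sequence.  ``orientation_sign`` is +1 for a left edge and -1
    for a right edge: positive boundary-relative offsets always point INTO
    the IES once right edges are mirrored.
    """

    ies_id: str
    side: str  # 'left' | 'right'
    ies_type: str  # 'A' | 'B'
    chrom: str
    inside: tuple[int, int]
    outside: tuple[int, int]
    eligible: bool
    overlaps_foreign_ies: bool = False
    sides_overlap: bool = False

    @property
    def orientation_sign(self) -> int:
        return 1 if self.side == "left" else -1

    @property
    def boundary(self) -> int:
        """Genomic coordinate of the edge (the IES start or end)."""
        return self.inside[0] if self.side == "left" else self.inside[1]


class SegmentedGenome:
    """Ordered, gap-free, non-overlapping labeled segmentation per chromosome."""

    def __init__(self, chrom_lengths: dict[str, int], segments: list[Segment]):
        self.chrom_lengths = dict(chrom_lengths)
        self.segments: dict[str, list[Segment]] = {c: [] for c in self.chrom_lengths}
        for seg in sorted(segments, key=lambda s: (s.chrom, s.start)):
            if seg.chrom not in self.segments:
                raise ValueError(f"segment on unknown chromosome {seg.chrom!r}")
            self.segments[seg.chrom].append(seg)
        self._validate()

    def _validate(self) -> None:
        for chrom, segs in self.segments.items():
            length = self.chrom_lengths[chrom]
            if not segs:
                raise ValueError(f"chromosome {chrom} has no segments")
            if segs[0].start != 0:
                raise ValueError(f"{chrom}: first segment does not start at 0")
            if segs[-1].end != length:
                raise ValueError(
                    f"{chrom}: last segment ends at {segs[-1].end}, "
                    f"chromosome length is {length}"
                )
            for a, b in itertools.pairwise(segs):
                if a.end != b.start:
                    raise ValueError(
                        f"{chrom}: gap or overlap between "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )
                if a.label == MDS and b.label == MDS:
                    raise ValueError(
                        f"{chrom}: adjacent MDS segments at {a.end} "
                        "(should be merged)"
                    )

    # -- queries ---------------------------------------------------------

    def all_segments(self) -> list[Segment]:
        return [s for c in sorted(self.segments) for s in self.segments[c]]

    def ies_segments(self, ies_type: str | None = None) -> list[Segment]:
        """IES segments in genome order, optionally restricted to 'A' or 'B'."""
        out = [s for s in self.all_segments() if s.is_ies]
        if ies_type is not None:
            out = [s for s in out if s.ies_type == ies_type]
        return out

    def n_ies(self, ies_type: str | None = None) -> int:
        return len(self.ies_segments(ies_type))

    def label_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized segment-label lookup for anchor positions on one chromosome."""
        segs = self.segments[chrom]
        starts = np.array([s.start for s in segs])
        labels = np.array([s.label for s in segs])
        idx = np.searchsorted(starts, positions, side="right") - 1
        return labels[idx]

    # -- boundary windows ------------------------------------------------

    def boundaries(self, window: int = DEFAULT_WINDOW) -> list[BoundaryWindow]:
        """Derive the two oriented boundary windows of every IES.

        Windows are eligible only when both inside and outside intervals
        reach the full width ``window`` (short IESs and chromosome-end IESs
        are kept but flagged ineligible, never truncated silently).
        """
        if window <= 0:
            raise ValueError("window width must be positive")
        out: list[BoundaryWindow] = []
        for chrom in sorted(self.segments):
            clen = self.chrom_lengths[chrom]
            ies = [s for s in self.segments[chrom] if s.is_ies]
            ies_iv = np.array([[s.start, s.end] for s in ies]).reshape(-1, 2)
            for seg in ies:
                sides_overlap = seg.length < 2 * window
                for side in ("left", "right"):
                    if side == "left":
                        inside = (seg.start, min(seg.start + window, seg.end))
                        outside = (max(seg.start - window, 0), seg.start)
                    else:
                        inside = (max(seg.end - window, seg.start), seg.end)
                        outside = (seg.end, min(seg.end + window, clen))
                    eligible = (
                        inside[1] - inside[0] == window
                        and outside[1] - outside[0] == window
                    )
                    foreign = bool(
                        np.any(
                            (ies_iv[:, 0] < outside[1])
                            & (ies_iv[:, 1] > outside[0])
                            & ~(
                                (ies_iv[:, 0] == seg.start)
                                & (ies_iv[:, 1] == seg.end)
                            )
                        )
                    )
                    out.append(
                        BoundaryWindow(
                            ies_id=seg.ies_id,
                            side=side,
                            ies_type=seg.ies_type,
                            chrom=chrom,
                            inside=inside,
                            outside=outside,
                            eligible=eligible,
                            overlaps_foreign_ies=foreign,
                            sides_overlap=sides_overlap,
                        )
                    )
        return out


def boundaries(
    genome: SegmentedGenome, window: int = DEFAULT_WINDOW
) -> list[BoundaryWindow]:
    """Functional alias for :meth:`SegmentedGenome.boundaries`."""
    return genome.boundaries(window)


# ---------------------------------------------------------------------------
# BED / TSV serialization
# ---------------------------------------------------------------------------


def load_segmentation(bed_path, chrom_lengths: dict[str, int]) -> SegmentedGenome:
    """Load an IES annotation BED into a gap-free segmentation.

    Only IES records are required in the BED (name field ``IES_A`` /
    ``IES_B``, optionally ``IES_A:<id>`` to carry an identifier); the MDS
    segments between them are filled in automatically (explicit MDS records
    are accepted and ignored; the tiling is reconstructed).  Overlapping
    IESs or IESs running past the chromosome end are hard errors.
    """
    try:
        df = pd.read_csv(
            bed_path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "name"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "name"])

    ies_records: list[Segment] = []
    auto = itertools.count(1)
    for row in df.itertuples(index=False):
        label, _, ies_id = row.name.partition(":")
        if label == MDS:
            continue  # MDS tiling is reconstructed, not trusted
        if label not in IES_LABELS:
            raise ValueError(f"unrecognized BED name field {row.name!r}")
        if row.chrom not in chrom_lengths:
            raise ValueError(f"IES on unknown chromosome {row.chrom!r}")
        if row.end > chrom_lengths[row.chrom]:
            raise ValueError(
                f"IES {row.chrom}:{row.start}-{row.end} extends past "
                f"chromosome end ({chrom_lengths[row.chrom]})"
            )
        ies_records.append(
            Segment(row.chrom, int(row.start), int(row.end), label, ies_id)
        )

    ies_records.sort(key=lambda s: (s.chrom, s.start))
    for a, b in itertools.pairwise(ies_records):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(
                f"overlapping IES records {a.chrom}:{a.start}-{a.end} "
                f"({a.ies_id or a.label}) and {b.chrom}:{b.start}-{b.end} "
                f"({b.ies_id or b.label})"
            )

    # deterministic ids for records that carried none
    ies_records = [
        s if s.ies_id else replace(s, ies_id=f"ies_{next(auto):06d}")
        for s in ies_records
    ]

    segments: list[Segment] = []
    by_chrom: dict[str, list[Segment]] = {}
    for s in ies_records:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, clen in chrom_lengths.items():
        pos = 0
        for s in by_chrom.get(chrom, []):
            if s.start > pos:
                segments.append(Segment(chrom, pos, s.start, MDS))
            segments.append(s)
            pos = s.end
        if pos < clen:
            segments.append(Segment(chrom, pos, clen, MDS))
    return SegmentedGenome(chrom_lengths, segments)


def write_segmentation(genome: SegmentedGenome, bed_path) -> None:
    """Write the full tiling (MDS and IES) as BED6; IES names carry their ids."""
    rows = []
    for seg in genome.all_segments():
        name = f"{seg.label}:{seg.ies_id}" if seg.is_ies else MDS
        rows.append((seg.chrom, seg.start, seg.end, name, 0, "."))
    pd.DataFrame(rows).to_csv(bed_path, sep="\t", header=False, index=False)


def read_chrom_lengths(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64})
    return dict(zip(df["chrom"], (int(x) for x in df["length"])))


def write_chrom_lengths(chrom_lengths: dict[str, int], path) -> None:
    pd.DataFrame(sorted(chrom_lengths.items())).to_csv(
        path, sep="\t", header=False, index=False
    )


def boundary_table(windows: list[BoundaryWindow]) -> pd.DataFrame:
    """Flat TSV-ready table of boundary windows and their flags."""
    return pd.DataFrame(
        {
            "ies_id": [w.ies_id for w in windows],
            "side": [w.side for w in windows],
            "ies_type": [w.ies_type for w in windows],
            "chrom": [w.chrom for w in windows],
            "inside_start": [w.inside[0] for w in windows],
            "inside_end": [w.inside[1] for w in windows],
            "outside_start": [w.outside[0] for w in windows],
            "outside_end": [w.outside[1] for w in windows],
            "eligible": [w.eligible for w in windows],
            "overlaps_foreign_ies": [w.overlaps_foreign_ies for w in windows],
            "sides_overlap": [w.sides_overlap for w in windows],
        }
    )
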