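"""Binned coverage profiles: per-locus and boundary-anchored meta-profiles.

Meta-profiles compile, over all eligible IES boundaries of one type, the
anchors falling in the paired 500-bp outside/inside windows onto a common
offset axis running from -W (deep in the flanking MDS) to +W (deep in the
IES).  Right-hand boundaries are mirrored so positive offsets always point
into the IES, and the strand of mirrored reads is flipped so that the
sense/antisense split stays boundary-relative.  Counts are summed across
boundaries, then normalized (RPM for small-RNA libraries; per-bin RPM
ratio for ChIP over input, with zero-input bins masked as missing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import DEFAULT_WINDOW, BoundaryWindow, SegmentedGenome
from .reads import Library, rpm

LOCUS_BIN = 100
META_BIN = 10
HEATMAP_BIN = 50


@dataclass
class BinnedProfile:
    """Per-bin values over a genomic locus or a compiled boundary axis.

    Locus mode: ``chrom``/``start``/``end`` set, bins tile [start, end).
    Meta mode: ``window`` set; bin i covers boundary-relative offsets
    [i*bin_size - window, (i+1)*bin_size - window); offset 0 begins the
    inside (IES) half.  ``mask`` marks bins with no defined value
    (ChIP/input bins where the input had zero reads).
    """

    bin_size: int
    value_kind: str  # raw_count | RPM | chip_over_input
    sense: np.ndarray
    antisense: np.ndarray | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    window: int | None = None
    n_boundaries: int | None = None
    mask: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.sense)

    @property
    def is_meta(self) -> bool:
        return self.window is not None

    def offsets(self) -> np.ndarray:
        """Left edge of each bin (boundary-relative in meta mode)."""
        if self.is_meta:
            return np.arange(self.n_bins) * self.bin_size - self.window
        return self.start + np.arange(self.n_bins) * self.bin_size

    def total(self) -> np.ndarray:
        """Strand-pooled values (sense + antisense when stranded)."""
        if self.antisense is None:
            return self.sense
        return self.sense + self.antisense

    def to_frame(self) -> pd.DataFrame:
        col = "offset_bin" if self.is_meta else "bin_start"
        data = {col: self.offsets(), "sense": self.sense}
        if self.antisense is not None:
            data["antisense"] = self.antisense
        if self.n_boundaries is not None:
            data["n_boundaries"] = self.n_boundaries
        if self.mask is not None:
            data["masked"] = self.mask
        return pd.DataFrame(data)


@dataclass
class ChipPair:
    """A ChIP library with its matched input; both mapped-read filtered only."""

    chip: Library
    input: Library

    def __post_init__(self) -> None:
        for lib, role in ((self.chip, "ChIP"), (self.input, "input")):
            if lib.total_filtered <= 0:
                raise ValueError(f"{role} library {lib.name!r} is empty")


def _check_bins(window: int, bin_size: int) -> int:
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if (2 * window) % bin_size:
        raise ValueError(f"bin size {bin_size} does not divide the 2x{window} axis")
    return 2 * window // bin_size


def locus_profile(
    lib: Library,
    chrom: str,
    start: int,
    end: int,
    bin_size: int = LOCUS_BIN,
    anchor_mode: str = "five_prime",
    value_kind: str = "RPM",
    genome: SegmentedGenome | None = None,
) -> BinnedProfile:
    """Stranded binned profile of anchor counts over one genomic region."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if start < 0 or end <= start:
        raise ValueError(f"bad region {chrom}:{start}-{end}")
    if genome is not None:
        if chrom not in genome.chrom_lengths or end > genome.chrom_lengths[chrom]:
            raise ValueError(f"region {chrom}:{start}-{end} outside genome")
    n_bins = int(np.ceil((end - start) / bin_size))
    sense = np.zeros(n_bins)
    anti = np.zeros(n_bins)
    index = lib.anchors_by_chrom(anchor_mode)
    if chrom in index:
        pos, plus = index[chrom]
        i0, i1 = np.searchsorted(pos, [start, end])
        bins = (pos[i0:i1] - start) // bin_size
        p = plus[i0:i1]
        np.add.at(sense, bins[p], 1)
        np.add.at(anti, bins[~p], 1)
    if value_kind == "RPM":
        sense = rpm(sense, lib)
        anti = rpm(anti, lib)
    elif value_kind != "raw_count":
        raise ValueError(f"unsupported value_kind {value_kind!r}")
    return BinnedProfile(
        bin_size=bin_size, value_kind=value_kind, sense=sense, antisense=anti,
        chrom=chrom, start=start, end=end,
    )


def select_windows(
    windows: list[BoundaryWindow],
    ies_type: str,
    include_foreign_overlaps: bool = True,
) -> list[BoundaryWindow]:
    out = [w for w in windows if w.eligible and w.ies_type == ies_type]
    if not include_foreign_overlaps:
        out = [w for w in out if not w.overlaps_foreign_ies]
    return out


def meta_profile(
    lib: Library,
    genome: SegmentedGenome,
    ies_type: str,
    bin_size: int = META_BIN,
    window: int = DEFAULT_WINDOW,
    anchor_mode: str = "nt13",
    value_kind: str = "RPM",
    stranded: bool = True,
    include_foreign_overlaps: bool = True,
    windows: list[BoundaryWindow] | None = None,
) -> BinnedProfile:
    """Compiled boundary meta-profile for one IES type.

    For each eligible boundary, anchors in the outside/inside window pair
    are placed at boundary-relative offsets (right edges mirrored, strands
    flipped there); per-bin counts are summed across boundaries and then
    normalized.
    """
    n_bins = _check_bins(window, bin_size)
    if windows is None:
        windows = genome.boundaries(window)
    use = select_windows(windows, ies_type, include_foreign_overlaps)
    if not use:
        raise ValueError(f"no eligible type-{ies_type} boundaries")
    sense = np.zeros(n_bins)
    anti = np.zeros(n_bins)
    index = lib.anchors_by_chrom(anchor_mode)
    for bw in use:
        if bw.chrom not in index:
            continue
        pos, plus = index[bw.chrom]
        b = bw.boundary
        i0, i1 = np.searchsorted(pos, [b - window, b + window])
        if i0 == i1:
            continue
        p = plus[i0:i1]
        if bw.side == "left":
            off = pos[i0:i1] - b
            sense_mask = p
        else:  # mirror: offsets counted inward from the last inside base
            off = (b - 1) - pos[i0:i1]
            sense_mask = ~p
        bins = (off + window) // bin_size
        np.add.at(sense, bins[sense_mask], 1)
        np.add.at(anti, bins[~sense_mask], 1)
    if value_kind == "RPM":
        sense = rpm(sense, lib)
        anti = rpm(anti, lib)
    elif value_kind != "raw_count":
        raise ValueError(f"unsupported value_kind {value_kind!r}")
    if not stranded:
        sense = sense + anti
        anti = None
    return BinnedProfile(
        bin_size=bin_size, value_kind=value_kind, sense=sense, antisense=anti,
        window=window, n_boundaries=len(use),
    )


def chip_ratio(
    pair: ChipPair,
    mode: str = "meta",
    **request,
) -> BinnedProfile:
    """Per-bin (ChIP RPM)/(input RPM) profile.

    ``mode`` is ``meta`` (boundary-compiled, unstranded, midpoint anchor by
    default) or ``locus``; remaining keyword arguments are forwarded to the
    underlying profile call.  Bins where the input has zero reads are
    masked: reported as missing (NaN), never 0 or infinity.
    """
    request.setdefault("anchor_mode", "midpoint")
    if mode == "meta":
        request.setdefault("stranded", False)
        chip = meta_profile(pair.chip, value_kind="RPM", **request)
        inp = meta_profile(pair.input, value_kind="RPM", **request)
    elif mode == "locus":
        chip = locus_profile(pair.chip, value_kind="RPM", **request)
        inp = locus_profile(pair.input, value_kind="RPM", **request)
    else:
        raise ValueError(f"unknown chip_ratio mode {mode!r}")
    chip_v = chip.total()
    inp_v = inp.total()
    mask = inp_v == 0
    ratio = np.full_like(chip_v, np.nan)
    np.divide(chip_v, inp_v, out=ratio, where=~mask)
    return BinnedProfile(
        bin_size=chip.bin_size, value_kind="chip_over_input", sense=ratio,
        antisense=None, chrom=chip.chrom, start=chip.start, end=chip.end,
        window=chip.window, n_boundaries=chip.n_boundaries, mask=mask,
    )


def write_profile_tsv(profile: BinnedProfile, path, header_comment: str = "") -> None:
    """TSV export; a leading '#' header records bin size, kind and axis."""
    with open(path, "w") as fh:
        axis = (
            f"meta window={profile.window}"
            if profile.is_meta
            else f"locus {profile.chrom}:{profile.start}-{profile.end}"
        )
        fh.write(
            f"# scnbound profile | {axis} | bin_size={profile.bin_size} "
            f"| value_kind={profile.value_kind} | coords=0-based half-open\n"
        )
        if header_comment:
            fh.write(f"# {header_comment}\n")
        profile.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_bedgraph(profile: BinnedProfile, path, strand: str = "sense") -> None:
    """Locus-mode profile as bedGraph (one strand per file)."""
    if profile.is_meta:
        raise ValueError("bedGraph export is for locus profiles")
    values = profile.sense if strand == "sense" else profile.antisense
    starts = profile.offsets()
    ends = np.minimum(starts + profile.bin_size, profile.end)
    df = pd.DataFrame(
        {"chrom": profile.chrom, "start": starts, "end": ends, "value": values}
    )
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.10g")
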