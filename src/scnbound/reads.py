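"""Mapped-read layer: scnRNA length filter, anchor positions, RPM.

Reads are consumed as already-mapped BED6 records (alignment is out of
scope).  Bulk operations work on a pandas DataFrame with the BED6 columns
``chrom, start, end, name, score, strand``; :class:`AlignedRead` is the
single-record view used where per-read semantics matter.

scnRNAs are the 26-32 nt class; the filter bounds are inclusive.  Two
anchor conventions are supported: the 5' end (used for 100-bp locus
profiles) and the 13th nucleotide of the read (used for 10-bp meta and
50-bp heatmap bins); ChIP fragments are anchored at their midpoint.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCNRNA_MIN_NT = 26
SCNRNA_MAX_NT = 32

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
ANCHOR_MODES = ("five_prime", "nt13", "midpoint")


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read: a 0-based half-open interval plus strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("read interval must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def anchor(self, mode: str = "five_prime") -> int:
        """Anchor position of this read under the given convention.

        five_prime: the 5' terminal base (start on +, end-1 on -).
        nt13: the 13th nucleotide counted from the 5' end (start+12 on +,
        end-13 on -); requires length >= 13.
        midpoint: (start+end)//2, strand-agnostic (ChIP fragments).
        """
        if mode == "five_prime":
            return self.start if self.strand == "+" else self.end - 1
        if mode == "nt13":
            if self.length < 13:
                raise ValueError("nt13 anchor undefined for reads shorter than 13 nt")
            return self.start + 12 if self.strand == "+" else self.end - 13
        if mode == "midpoint":
            return (self.start + self.end) // 2
        raise ValueError(f"unknown anchor mode {mode!r}")


def read_bed6(path) -> pd.DataFrame:
    """Read a BED6 alignment file (strand required) into a DataFrame."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=BED6_COLUMNS,
            dtype={
                "chrom": str,
                "start": np.int64,
                "end": np.int64,
                "name": str,
                "score": np.int64,
                "strand": str,
            },
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            BED6_COLUMNS, [str, np.int64, np.int64, str, np.int64, str])})
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(
            f"{path}: {int(bad.sum())} records without +/- strand "
            "(strand is required for read input)"
        )
    return df


def write_bed6(reads: pd.DataFrame, path) -> None:
    reads[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def filter_scnrna(
    reads: pd.DataFrame,
    min_len: int = SCNRNA_MIN_NT,
    max_len: int = SCNRNA_MAX_NT,
) -> pd.DataFrame:
    """Keep reads whose length is in [min_len, max_len] (inclusive), order preserved."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    length = reads["end"] - reads["start"]
    return reads[(length >= min_len) & (length <= max_len)].reset_index(drop=True)


def anchor_positions(reads: pd.DataFrame, mode: str = "five_prime") -> np.ndarray:
    """Vectorized anchor positions for a read table (see AlignedRead.anchor)."""
    start = reads["start"].to_numpy()
    end = reads["end"].to_numpy()
    if mode == "midpoint":
        return (start + end) // 2
    plus = reads["strand"].to_numpy() == "+"
    if mode == "five_prime":
        return np.where(plus, start, end - 1)
    if mode == "nt13":
        if ((end - start) < 13).any():
            raise ValueError("nt13 anchor undefined for reads shorter than 13 nt")
        return np.where(plus, start + 12, end - 13)
    raise ValueError(f"unknown anchor mode {mode!r}")


@dataclass
class Library:
    """One sequencing library: filtered analysis reads plus its RPM denominator.

    ``reads`` are the records used for profiling (for scnRNA libraries,
    those passing the 26-32 nt filter; for ChIP/input, all mapped records).
    ``total_filtered`` is the RPM denominator; it always equals
    ``len(reads)`` when constructed through :meth:`from_reads`.
    """

    reads: pd.DataFrame
    total_filtered: int
    name: str = ""
    filter_bounds: tuple[int, int] | None = None
    raw_total: int | None = None
    _by_chrom: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def rpm_factor(self) -> float:
        if self.total_filtered <= 0:
            raise ValueError(
                f"library {self.name or '<unnamed>'} is empty: cannot normalize"
            )
        return 1e6 / self.total_filtered

    @classmethod
    def from_reads(
        cls,
        reads: pd.DataFrame,
        name: str = "",
        scnrna_filter: bool = True,
        min_len: int = SCNRNA_MIN_NT,
        max_len: int = SCNRNA_MAX_NT,
    ) -> "Library":
        raw_total = len(reads)
        bounds = None
        if scnrna_filter:
            reads = filter_scnrna(reads, min_len, max_len)
            bounds = (min_len, max_len)
        return cls(
            reads=reads,
            total_filtered=len(reads),
            name=name,
            filter_bounds=bounds,
            raw_total=raw_total,
        )

    @classmethod
    def from_bed6(cls, path, name: str = "", scnrna_filter: bool = True, **kw):
        return cls.from_reads(read_bed6(path), name=name,
                              scnrna_filter=scnrna_filter, **kw)

    def anchors_by_chrom(self, mode: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (sorted anchor positions, is-plus-strand) arrays.

        Cached: profiling and boundary statistics re-query the same index.
        """
        if mode in self._by_chrom:
            return self._by_chrom[mode]
        pos = anchor_positions(self.reads, mode)
        plus = self.reads["strand"].to_numpy() == "+"
        chroms = self.reads["chrom"].to_numpy()
        index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in np.unique(chroms):
            m = chroms == chrom
            p = pos[m]
            s = plus[m]
            order = np.argsort(p, kind="mergesort")
            index[str(chrom)] = (p[order], s[order])
        self._by_chrom[mode] = index
        return index

    def metadata(self) -> dict:
        md = {
            "name": self.name,
            "total_filtered": self.total_filtered,
            "raw_total": self.raw_total,
            "rpm_factor": self.rpm_factor if self.total_filtered else None,
            "filter_bounds": list(self.filter_bounds) if self.filter_bounds else None,
        }
        return md


def rpm(count: float | np.ndarray, lib: Library) -> float | np.ndarray:
    """Reads-per-million normalization against the library's filtered total."""
    return count * lib.rpm_factor


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_library_metadata(lib: Library, path) -> None:
    with open(path, "w") as fh:
        json.dump(lib.metadata(), fh, indent=2, sort_keys=True)
        fh.write("\n")
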