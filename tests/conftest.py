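import numpy as np
import pandas as pd
import pytest

from scnbound.genome import Segment, SegmentedGenome
from scnbound.reads import Library


def make_reads(records) -> pd.DataFrame:
    """Build a BED6 read table from (chrom, start, end, strand) tuples."""
    rows = [
        (c, s, e, f"r{i}", 0, st) for i, (c, s, e, st) in enumerate(records)
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def make_library(records, scnrna_filter=False, name="test") -> Library:
    return Library.from_reads(
        make_reads(records), name=name, scnrna_filter=scnrna_filter
    )


def reads_at_anchors(chrom, anchors, strand="+", length=28) -> list[tuple]:
    """Reads of fixed length whose 5' anchor sits at each given position."""
    out = []
    for a in anchors:
        if strand == "+":
            out.append((chrom, a, a + length, "+"))
        else:
            out.append((chrom, a + 1 - length, a + 1, "-"))
    return out


@pytest.fixture
def toy_genome() -> SegmentedGenome:
    """10-kb chromosome with one type-A and one type-B IES, both 2 kb."""
    segs = [
        Segment("chr1", 0, 1000, "MDS"),
        Segment("chr1", 1000, 3000, "IES_A", "iesA1"),
        Segment("chr1", 3000, 6000, "MDS"),
        Segment("chr1", 6000, 8000, "IES_B", "iesB1"),
        Segment("chr1", 8000, 10000, "MDS"),
    ]
    return SegmentedGenome({"chr1": 10000}, segs)
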