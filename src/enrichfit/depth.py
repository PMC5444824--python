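"""Per-position, strand-aware read-depth tables from BAM/SAM alignments.

Depth here is position-resolved: in ``start`` mode each read contributes one
count at its 5'-most aligned reference base (the biologically meaningful
position for transcript 5'-end enrichment protocols), in ``end`` mode at its
3'-most aligned base, and in ``all`` mode one count at every aligned reference
base (appropriate for internal-feature enrichment such as m6A-seq).
Coordinates are reported 1-based; soft-clipped bases have no reference
coordinate and never contribute. Duplicate reads are retained: reads sharing a
start may come from distinct RNA molecules, which is precisely the signal at
enriched positions.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
import pysam

from .errors import ConfigurationError, MissingIndexError

COUNT_MODES = ("start", "end", "all")


class GenomicPosition(NamedTuple):
    """A strand-aware 1-based genomic coordinate."""

    reference: str
    position: int
    strand: str


@dataclass
class DepthTable:
    """Read-depth counts for one library under one counting mode.

    ``counts`` maps :class:`GenomicPosition` to a positive depth; positions
    with zero depth are simply absent.
    """

    library_id: str
    count_mode: str
    counts: dict[GenomicPosition, int] = field(default_factory=dict)

    @property
    def total_depth(self) -> int:
        return sum(self.counts.values())

    @property
    def n_positions(self) -> int:
        return len(self.counts)

    def to_tsv(self, path: str | Path) -> None:
        """Write a 4-column TSV: reference, position, strand, depth."""
        rows = sorted(self.counts.items())
        frame = pd.DataFrame(
            [(k.reference, k.position, k.strand, d) for k, d in rows],
            columns=["reference", "position", "strand", "depth"],
        )
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, library_id: str, count_mode: str) -> "DepthTable":
        frame = pd.read_csv(path, sep="\t")
        counts = {
            GenomicPosition(str(r), int(p), str(s)): int(d)
            for r, p, s, d in zip(
                frame["reference"], frame["position"], frame["strand"], frame["depth"]
            )
        }
        return cls(library_id=library_id, count_mode=count_mode, counts=counts)


def _check_index(alignments: str | Path) -> None:
    path = Path(alignments)
    if path.suffix.lower() in {".bam", ".cram"}:
        with pysam.AlignmentFile(os.fspath(path), require_index=False) as af:
            if not af.has_index():
                raise MissingIndexError(
                    f"{path} is not indexed; run samtools index (or pysam.index) first"
                )


def compute_depth(
    alignments: str | Path | pysam.AlignmentFile,
    count_mode: str = "start",
    min_mapq: int = 0,
    library_id: str | None = None,
) -> DepthTable:
    """Count per-position read depth from a coordinate-sorted alignment file.

    Parameters
    ----------
    alignments
        Path to a SAM/BAM file (BAM must be indexed) or an open
        :class:`pysam.AlignmentFile`.
    count_mode
        ``start`` counts each read once at its 5'-most aligned base (in read
        orientation: leftmost reference base for forward alignments, rightmost
        for reverse), ``end`` the 3'-most base symmetrically, ``all`` every
        aligned reference base.
    min_mapq
        Minimum mapping quality; reads below it are skipped.

    Unmapped, secondary and supplementary records are always skipped;
    duplicates are retained. An empty input yields an empty table.
    """
    if count_mode not in COUNT_MODES:
        raise ConfigurationError(f"count_mode must be one of {COUNT_MODES}, got {count_mode!r}")
    if min_mapq < 0:
        raise ConfigurationError("min_mapq must be >= 0")

    own_handle = not isinstance(alignments, pysam.AlignmentFile)
    if own_handle:
        _check_index(alignments)
        handle = pysam.AlignmentFile(os.fspath(alignments))
        if library_id is None:
            library_id = Path(alignments).stem
    else:
        handle = alignments
        if library_id is None:
            library_id = Path(handle.filename.decode()).stem if handle.filename else "library"

    counts: Counter[GenomicPosition] = Counter()
    try:
        for read in handle.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            ref = read.reference_name
            strand = "-" if read.is_reverse else "+"
            if count_mode == "all":
                for pos0 in read.get_reference_positions():
                    counts[GenomicPosition(ref, pos0 + 1, strand)] += 1
                continue
            left = read.reference_start + 1          # first aligned base, 1-based
            right = read.reference_end               # last aligned base, 1-based
            if count_mode == "start":
                pos = right if read.is_reverse else left
            else:  # end
                pos = left if read.is_reverse else right
            counts[GenomicPosition(ref, pos, strand)] += 1
    finally:
        if own_handle:
            handle.close()

    return DepthTable(library_id=library_id, count_mode=count_mode, counts=dict(counts))


@dataclass(frozen=True)
class OverlapSummary:
    """Partition of the union of covered positions between two libraries."""

    both: int
    only_enriched: int
    only_control: int

    @property
    def total(self) -> int:
        return self.both + self.only_enriched + self.only_control

    @property
    def fractions(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            return {"both": 0.0, "only_enriched": 0.0, "only_control": 0.0}
        return {
            "both": self.both / tot,
            "only_enriched": self.only_enriched / tot,
            "only_control": self.only_control / tot,
        }


def library_overlap_summary(enriched: DepthTable, control: DepthTable) -> OverlapSummary:
    """Count covered positions shared by, or private to, the paired libraries."""
    if enriched.count_mode != control.count_mode:
        raise ConfigurationError(
            f"count modes differ: {enriched.count_mode!r} vs {control.count_mode!r}"
        )
    keys1 = enriched.counts.keys()
    keys2 = control.counts.keys()
    both = len(keys1 & keys2)
    return OverlapSummary(
        both=both,
        only_enriched=len(keys1) - both,
        only_control=len(keys2) - both,
    )


def depth_histogram(table: DepthTable) -> dict[int, int]:
    """Frequency table of depth values (e.g. read starts per position)."""
    return dict(Counter(table.counts.values()))
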