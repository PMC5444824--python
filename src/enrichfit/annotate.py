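"""Gene-context annotation of calls and recall against known feature positions.

Annotation is strand-aware: for a call on the + strand, downstream genes are
same-strand genes whose start lies at or beyond the call; on the - strand
the mirror holds (a gene's end coordinate is its 5' boundary there).
Distances are reported as nonnegative magnitudes together with an explicit
relation, avoiding sign-convention ambiguity. A call inside a same-strand
gene is labeled intragenic, otherwise intergenic.

Recall against a list of known feature positions (e.g. annotated
transcription start sites) uses a +/- ``window`` nucleotide rule on the same
strand: a known position is counted as detected if any significant call lies
within the window. Known positions with no enrichment record anywhere in the
window (no mapped reads) are excluded from the denominator, and both counts
are reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .depth import GenomicPosition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    reference: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive, >= start
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class RecallResult:
    n_known: int
    n_evaluable: int
    n_detected: int

    @property
    def recall_percent(self) -> float:
        if self.n_evaluable == 0:
            return float("nan")
        return 100.0 * self.n_detected / self.n_evaluable


def read_genes_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneRecord]:
    """Load gene records of one feature type from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type(feature_type):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneRecord(
                reference=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                gene_id=gene_id,
            )
        )
    return genes


def _gene_index(genes: Sequence[GeneRecord]):
    """Per (reference, strand): gene arrays sorted by start and by end."""
    index: dict[tuple[str, str], dict[str, np.ndarray | list]] = {}
    for ref_strand in {(g.reference, g.strand) for g in genes}:
        group = [g for g in genes if (g.reference, g.strand) == ref_strand]
        by_start = sorted(group, key=lambda g: g.start)
        by_end = sorted(group, key=lambda g: g.end)
        index[ref_strand] = {
            "starts": np.array([g.start for g in by_start]),
            "ends": np.array([g.end for g in by_end]),
            "by_start": by_start,
            "by_end": by_end,
            "group": group,
        }
    return index


def annotate_positions(
    calls: Iterable[GenomicPosition], genes: Sequence[GeneRecord]
) -> pd.DataFrame:
    """Annotate each call with gene context and nearest-gene distances.

    For each call: ``context`` (intragenic/intergenic relative to same-strand
    genes), the nearest downstream gene (whose 5' boundary the call may be
    upstream of — the promoter-candidate relation for TSS work) with its
    distance, and the nearest upstream gene with the distance past its 3'
    boundary. Distances are nonnegative; 0 means the call touches the
    boundary. Calls on references absent from the annotation are skipped with
    a warning.
    """
    index = _gene_index(genes)
    known_refs = {g.reference for g in genes}
    rows = []
    for call in calls:
        if call.reference not in known_refs:
            warnings.warn(
                f"no annotation for reference {call.reference!r}; call skipped",
                stacklevel=2,
            )
            continue
        entry = index.get((call.reference, call.strand))
        row = {
            "reference": call.reference,
            "position": call.position,
            "strand": call.strand,
            "context": "intergenic",
            "downstream_gene": None,
            "downstream_distance": None,
            "upstream_gene": None,
            "upstream_distance": None,
        }
        if entry is not None:
            pos = call.position
            for g in entry["group"]:
                if g.start <= pos <= g.end:
                    row["context"] = "intragenic"
                    break
            if call.strand == "+":
                # downstream: smallest gene start >= pos
                i = int(np.searchsorted(entry["starts"], pos, side="left"))
                if i < len(entry["by_start"]):
                    g = entry["by_start"][i]
                    row["downstream_gene"] = g.gene_id
                    row["downstream_distance"] = g.start - pos
                # upstream: largest gene end <= pos
                j = int(np.searchsorted(entry["ends"], pos, side="right")) - 1
                if j >= 0:
                    g = entry["by_end"][j]
                    row["upstream_gene"] = g.gene_id
                    row["upstream_distance"] = pos - g.end
            else:
                # on -, a gene's end is its 5' boundary: downstream genes end <= pos
                j = int(np.searchsorted(entry["ends"], pos, side="right")) - 1
                if j >= 0:
                    g = entry["by_end"][j]
                    row["downstream_gene"] = g.gene_id
                    row["downstream_distance"] = pos - g.end
                i = int(np.searchsorted(entry["starts"], pos, side="left"))
                if i < len(entry["by_start"]):
                    g = entry["by_start"][i]
                    row["upstream_gene"] = g.gene_id
                    row["upstream_distance"] = g.start - pos
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "reference", "position", "strand", "context",
            "downstream_gene", "downstream_distance",
            "upstream_gene", "upstream_distance",
        ],
    )


def recall_known_tss(
    calls: set[GenomicPosition],
    known: Sequence[GenomicPosition],
    enrichment_records: set[GenomicPosition],
    window: int = 5,
) -> RecallResult:
    """Recall of known feature positions within a same-strand window.

    A known position is evaluable iff some position within ``window``
    nucleotides of it (same reference and strand) has an enrichment record;
    it is detected iff a significant call lies within the window.
    """
    if len(known) == 0:
        raise ValueError("empty list of known positions")
    if window < 0:
        raise ValueError("window must be >= 0")
    n_eval = 0
    n_det = 0
    for k in known:
        neighborhood = [
            GenomicPosition(k.reference, k.position + off, k.strand)
            for off in range(-window, window + 1)
        ]
        if not any(p in enrichment_records for p in neighborhood):
            continue
        n_eval += 1
        if any(p in calls for p in neighborhood):
            n_det += 1
    return RecallResult(n_known=len(known), n_evaluable=n_eval, n_detected=n_det)


def read_known_sites_tsv(path: str | Path) -> list[GenomicPosition]:
    """Read a known-sites TSV with columns reference, position, strand."""
    frame = pd.read_csv(path, sep="\t")
    return [
        GenomicPosition(str(r), int(p), str(s))
        for r, p, s in zip(frame["reference"], frame["position"], frame["strand"])
    ]
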