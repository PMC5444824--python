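"""Position selection and normalized enrichment scores.

The enrichment score at position *i* compares the enriched library's depth
``d1`` to the control library's depth ``d2``, rescaled by the ratio of
library-wide totals so that a position with no differential enrichment scores
around 1 regardless of sequencing depth:

    score_i = (d1_i / d2_i) * (sum_j d2_j / sum_j d1_j)

By default every position with at least one mapped read in either library is
analyzed, with a unit pseudo-count added to both libraries at every selected
position so the ratio is always defined. The pseudo-count is applied before
the normalizing totals are taken, keeping the equation self-consistent on
exactly the analyzed position set. Both strands enter one global score set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .depth import DepthTable, GenomicPosition
from .errors import ConfigurationError, EnrichFitError


@dataclass(frozen=True)
class FilterConfig:
    """Position-selection filters.

    pseudo_count
        Add one count to both libraries at every selected position (default).
        May only be disabled when both per-library minimum depths are >= 1,
        which guarantees no division by zero.
    min_depth_enriched, min_depth_control
        Minimum raw depth required in the enriched / control library.
    min_depth_sum
        Minimum raw ``d1 + d2``.
    """

    pseudo_count: bool = True
    min_depth_enriched: int = 0
    min_depth_control: int = 0
    min_depth_sum: int = 0

    def __post_init__(self) -> None:
        if min(self.min_depth_enriched, self.min_depth_control, self.min_depth_sum) < 0:
            raise ConfigurationError("minimum depth filters must be >= 0")
        if not self.pseudo_count and (
            self.min_depth_enriched < 1 or self.min_depth_control < 1
        ):
            raise ConfigurationError(
                "disabling the pseudo-count requires a minimum depth of at "
                "least 1 in both libraries"
            )


@dataclass
class EnrichmentTable:
    """Per-position paired depths and enrichment scores.

    ``frame`` holds one row per analyzed position, sorted by
    (reference, position, strand), with columns ``reference``, ``position``,
    ``strand``, ``depth_enriched``, ``depth_control`` (post-pseudo-count
    values) and ``score``; downstream fitting adds ``transformed``,
    ``p_value``, ``q_value`` and ``called``.
    """

    frame: pd.DataFrame
    pseudo_count: bool = True

    @property
    def n_positions(self) -> int:
        return len(self.frame)

    @property
    def scores(self) -> np.ndarray:
        return self.frame["score"].to_numpy()

    def positions(self) -> list[GenomicPosition]:
        return [
            GenomicPosition(r, int(p), s)
            for r, p, s in zip(
                self.frame["reference"], self.frame["position"], self.frame["strand"]
            )
        ]

    def position_set(self) -> set[GenomicPosition]:
        return set(self.positions())

    def called_positions(self) -> set[GenomicPosition]:
        if "called" not in self.frame:
            raise EnrichFitError("no significance calls present; run the fit first")
        sub = self.frame[self.frame["called"]]
        return {
            GenomicPosition(r, int(p), s)
            for r, p, s in zip(sub["reference"], sub["position"], sub["strand"])
        }

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def select_positions(
    enriched: DepthTable,
    control: DepthTable,
    config: FilterConfig = FilterConfig(),
) -> set[GenomicPosition]:
    """Select positions for analysis under the configured depth filters.

    With defaults this is the union of covered positions of the two
    libraries; with the pseudo-count disabled (which forces per-library
    minima of >= 1) it reduces to their intersection.
    """
    if enriched.count_mode != control.count_mode:
        raise ConfigurationError(
            f"count modes differ: {enriched.count_mode!r} vs {control.count_mode!r}"
        )
    selected: set[GenomicPosition] = set()
    for key in enriched.counts.keys() | control.counts.keys():
        d1 = enriched.counts.get(key, 0)
        d2 = control.counts.get(key, 0)
        if d1 < config.min_depth_enriched or d2 < config.min_depth_control:
            continue
        if d1 + d2 < config.min_depth_sum:
            continue
        selected.add(key)
    return selected


def enrichment_scores(
    enriched: DepthTable,
    control: DepthTable,
    positions: Iterable[GenomicPosition] | None = None,
    config: FilterConfig = FilterConfig(),
) -> EnrichmentTable:
    """Compute normalized enrichment scores over the selected positions.

    The normalizing totals are taken over the selected set after any
    pseudo-count addition, so scores are invariant to rescaling either
    library's counts by a positive constant.
    """
    if positions is None:
        positions = select_positions(enriched, control, config)
    keys = sorted(positions)
    add = 1 if config.pseudo_count else 0
    d1 = np.array([enriched.counts.get(k, 0) + add for k in keys], dtype=np.float64)
    d2 = np.array([control.counts.get(k, 0) + add for k in keys], dtype=np.float64)
    if not config.pseudo_count and (d2 == 0).any():
        raise EnrichFitError(
            "selected position with zero control depth under non-pseudo-count "
            "configuration; tighten the minimum depth filters"
        )
    if len(keys) == 0:
        frame = pd.DataFrame(
            columns=["reference", "position", "strand", "depth_enriched", "depth_control", "score"]
        )
        return EnrichmentTable(frame=frame, pseudo_count=config.pseudo_count)
    scores = (d1 / d2) * (d2.sum() / d1.sum())
    frame = pd.DataFrame(
        {
            "reference": [k.reference for k in keys],
            "position": [k.position for k in keys],
            "strand": [k.strand for k in keys],
            "depth_enriched": d1.astype(np.int64),
            "depth_control": d2.astype(np.int64),
            "score": scores,
        }
    )
    frame.sort_values(["reference", "position", "strand"], inplace=True, ignore_index=True)
    return EnrichmentTable(frame=frame, pseudo_count=config.pseudo_count)
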