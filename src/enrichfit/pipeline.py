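"""End-to-end analysis: depths -> scores -> fit -> calls (-> meta-analysis).

One :func:`run_experiment` call handles a single enriched/control pair: it
computes strand-aware depths, selects positions, scores them, fits the
Box-Cox normal model, and calls significant positions on the transformed
scale (equivalently — the transform being strictly increasing — on the raw
scale). If the transformed scores fail the Q-Q R^2 normality gate the
model path is refused and the percentile-rank fallback is used, with no
p-values attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .depth import DepthTable, OverlapSummary, compute_depth, library_overlap_summary
from .distfit import (
    DEFAULT_ALPHA,
    DEFAULT_PERCENTILE,
    DEFAULT_R2_CUTOFF,
    NormalFit,
    boxcox_mle,
    boxcox_transform,
    percentile_cutoff,
    position_pvalues,
    qq_fit,
)
from .enrich import EnrichmentTable, FilterConfig, enrichment_scores, select_positions

logger = logging.getLogger(__name__)


@dataclass
class ExperimentResult:
    """Result of one enriched-vs-control analysis."""

    table: EnrichmentTable
    fit: NormalFit | None
    method: str  # "normal" or "percentile"
    cutoff_raw: float
    overlap: OverlapSummary
    alpha: float

    @property
    def n_called(self) -> int:
        return int(self.table.frame["called"].sum())

    def called_positions(self):
        return self.table.called_positions()


def _as_depth_table(
    source: DepthTable | str | Path | pysam.AlignmentFile,
    count_mode: str,
    min_mapq: int,
    library_id: str | None = None,
) -> DepthTable:
    if isinstance(source, DepthTable):
        return source
    return compute_depth(source, count_mode=count_mode, min_mapq=min_mapq, library_id=library_id)


def run_experiment(
    enriched: DepthTable | str | Path,
    control: DepthTable | str | Path,
    config: FilterConfig = FilterConfig(),
    alpha: float = DEFAULT_ALPHA,
    r2_cutoff: float = DEFAULT_R2_CUTOFF,
    percentile: float = DEFAULT_PERCENTILE,
    count_mode: str = "start",
    min_mapq: int = 0,
) -> ExperimentResult:
    """Analyze one enriched/control pair from BAM paths or depth tables."""
    enriched_depth = _as_depth_table(enriched, count_mode, min_mapq)
    control_depth = _as_depth_table(control, count_mode, min_mapq)
    overlap = library_overlap_summary(enriched_depth, control_depth)
    positions = select_positions(enriched_depth, control_depth, config)
    table = enrichment_scores(enriched_depth, control_depth, positions, config)
    logger.info("analyzing %d positions", table.n_positions)

    scores = table.scores
    lam = boxcox_mle(scores)
    transformed = boxcox_transform(scores, lam)
    fit = qq_fit(transformed, lam, alpha=alpha, r2_cutoff=r2_cutoff)
    table.frame["transformed"] = transformed

    if fit.passed_normality:
        pvals = position_pvalues(transformed, fit)
        table.frame["p_value"] = pvals
        try:
            from statsmodels.stats.multitest import multipletests

            table.frame["q_value"] = multipletests(pvals, method="fdr_bh")[1]
        except ImportError:  # pragma: no cover
            pass
        table.frame["called"] = transformed >= fit.critical_transformed
        logger.info(
            "normal model accepted (R^2=%.4f >= %.2f): lambda=%.4f, "
            "critical raw score %.4f, %d positions called at alpha=%g",
            fit.r_squared, r2_cutoff, lam, fit.critical_raw,
            int(table.frame["called"].sum()), alpha,
        )
        return ExperimentResult(
            table=table, fit=fit, method="normal",
            cutoff_raw=fit.critical_raw, overlap=overlap, alpha=alpha,
        )

    logger.warning(
        "normal model refused (R^2=%.4f < %.2f); falling back to the "
        "%gth-percentile rank cutoff (no p-values)",
        fit.r_squared, r2_cutoff, percentile,
    )
    cutoff, called = percentile_cutoff(scores, percentile)
    table.frame["called"] = called
    return ExperimentResult(
        table=table, fit=fit, method="percentile",
        cutoff_raw=cutoff, overlap=overlap, alpha=alpha,
    )


def run_replicates(
    enriched_sources: list,
    control: DepthTable | str | Path,
    config: FilterConfig = FilterConfig(),
    alpha: float = DEFAULT_ALPHA,
    r2_cutoff: float = DEFAULT_R2_CUTOFF,
    percentile: float = DEFAULT_PERCENTILE,
    count_mode: str = "start",
    min_mapq: int = 0,
) -> list[ExperimentResult]:
    """Analyze several enriched replicates against one shared control."""
    control_depth = _as_depth_table(control, count_mode, min_mapq)
    return [
        run_experiment(
            src, control_depth, config=config, alpha=alpha,
            r2_cutoff=r2_cutoff, percentile=percentile,
            count_mode=count_mode, min_mapq=min_mapq,
        )
        for src in enriched_sources
    ]
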