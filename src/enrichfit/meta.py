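"""Meta-analysis of per-position evidence across replicate experiments.

Two combining rules are offered. Fisher's combined probability test pools
the per-replicate p-values at a position: X = -2 * sum(ln p_i) follows a
chi-square distribution with 2k degrees of freedom under the joint null, and
the combined p-value is its upper-tail probability. The consensus rule calls
a position if it is individually significant in at least ``m`` replicates.

A position with no enrichment record in some replicate (no mapped reads
there) has no p-value to contribute; it receives no combined p-value and is
excluded from Fisher calling, but remains eligible for consensus calling
among the replicates where it is observed.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .depth import GenomicPosition
from .enrich import EnrichmentTable


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's combined probability over k independent tests.

    Exact p-values of 0 are clamped to the smallest positive float with a
    warning; values outside (0, 1] are rejected.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p == 0).any():
        warnings.warn("p-value of 0 clamped to smallest positive float", stacklevel=2)
        p = np.where(p == 0, np.nextafter(0.0, 1.0), p)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, df=2 * p.size))


def consensus_select(
    per_replicate_calls: Mapping[str, set[GenomicPosition]], m: int
) -> set[GenomicPosition]:
    """Positions individually significant in at least ``m`` replicates."""
    k = len(per_replicate_calls)
    if not 1 <= m <= k:
        raise ValueError(f"m must lie in [1, {k}], got {m}")
    tally: dict[GenomicPosition, int] = {}
    for calls in per_replicate_calls.values():
        for pos in calls:
            tally[pos] = tally.get(pos, 0) + 1
    return {pos for pos, c in tally.items() if c >= m}


def combine_replicates(
    tables: Sequence[EnrichmentTable],
    replicate_ids: Sequence[str] | None = None,
    alpha: float = 0.05,
    min_replicates: int | None = None,
) -> pd.DataFrame:
    """Merge replicate enrichment tables into one meta-analysis frame.

    Returns one row per position observed in any replicate, with per-replicate
    score and p-value columns, Fisher's ``combined_p`` (only where every
    replicate reports a p-value), ``n_significant`` (replicates whose own
    p-value is <= alpha among those observed), ``called_fisher`` and — when
    ``min_replicates`` is given — ``called_consensus``.
    """
    if not tables:
        raise ValueError("need at least one replicate table")
    k = len(tables)
    if replicate_ids is None:
        replicate_ids = [f"rep{i + 1}" for i in range(k)]
    if len(replicate_ids) != k:
        raise ValueError("replicate_ids length must match number of tables")

    merged: pd.DataFrame | None = None
    for rid, table in zip(replicate_ids, tables):
        cols = ["reference", "position", "strand", "score"]
        sub = table.frame[cols + (["p_value"] if "p_value" in table.frame else [])].copy()
        sub = sub.rename(
            columns={"score": f"score_{rid}", "p_value": f"p_{rid}"}
        )
        merged = sub if merged is None else merged.merge(
            sub, on=["reference", "position", "strand"], how="outer"
        )
    assert merged is not None

    p_cols = [f"p_{rid}" for rid in replicate_ids if f"p_{rid}" in merged]
    pmat = merged[p_cols].to_numpy(dtype=np.float64) if p_cols else np.empty((len(merged), 0))
    complete = ~np.isnan(pmat).any(axis=1) if pmat.shape[1] == k else np.zeros(len(merged), bool)

    combined = np.full(len(merged), np.nan)
    if complete.any():
        clamped = np.clip(pmat[complete], np.nextafter(0.0, 1.0), 1.0)
        x = -2.0 * np.log(clamped).sum(axis=1)
        combined[complete] = stats.chi2.sf(x, df=2 * k)
    merged["combined_p"] = combined
    merged["n_significant"] = (pmat <= alpha).sum(axis=1) if pmat.size else 0
    merged["called_fisher"] = np.where(complete, combined <= alpha, False)
    if min_replicates is not None:
        if not 1 <= min_replicates <= k:
            raise ValueError(f"min_replicates must lie in [1, {k}]")
        merged["called_consensus"] = merged["n_significant"] >= min_replicates
    merged.sort_values(["reference", "position", "strand"], inplace=True, ignore_index=True)
    return merged


def fisher_called_positions(meta_frame: pd.DataFrame) -> set[GenomicPosition]:
    """Positions called significant by the combined-p rule."""
    sub = meta_frame[meta_frame["called_fisher"]]
    return {
        GenomicPosition(r, int(p), s)
        for r, p, s in zip(sub["reference"], sub["position"], sub["strand"])
    }
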