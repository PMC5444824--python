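"""File and figure outputs for a completed analysis.

Outputs per run: a significant-positions TSV, a GFF3 of the called
positions (feature type ``enriched_site``, score column carrying the
enrichment score, attributes carrying p-value and depths), a plain-text
summary with library overlap counts and the fitted model parameters, and
PNG figures: normal Q-Q plots of the scores before and after transformation
with the critical value drawn as a horizontal line, a depth-frequency
density plot, and a pie chart of the both/only-enriched/only-control
position overlap.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .depth import DepthTable, depth_histogram
from .distfit import qq_points
from .pipeline import ExperimentResult


def write_gff3(result: ExperimentResult, path: str | Path, source: str = "enrichfit") -> Path:
    """Write called positions as single-base GFF3 features."""
    path = Path(path)
    frame = result.table.frame
    called = frame[frame["called"]]
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, row in enumerate(called.itertuples(index=False), start=1):
            attrs = [f"ID=enriched_site_{i}"]
            if hasattr(row, "p_value") and not np.isnan(getattr(row, "p_value", np.nan)):
                attrs.append(f"p_value={row.p_value:.6g}")
            attrs.append(f"depth_enriched={row.depth_enriched}")
            attrs.append(f"depth_control={row.depth_control}")
            fh.write(
                "\t".join(
                    [
                        str(row.reference), source, "enriched_site",
                        str(row.position), str(row.position),
                        f"{row.score:.6g}", str(row.strand), ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
    return path


def write_significant_tsv(result: ExperimentResult, path: str | Path) -> Path:
    path = Path(path)
    frame = result.table.frame
    frame[frame["called"]].to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def write_summary(result: ExperimentResult, path: str | Path) -> Path:
    """Key-value text block: totals, overlap partition, model parameters."""
    path = Path(path)
    ov = result.overlap
    lines = [
        f"n_positions_analyzed\t{result.table.n_positions}",
        f"positions_both_libraries\t{ov.both}",
        f"positions_only_enriched\t{ov.only_enriched}",
        f"positions_only_control\t{ov.only_control}",
        f"calling_method\t{result.method}",
        f"alpha\t{result.alpha}",
        f"n_called\t{result.n_called}",
        f"cutoff_raw_score\t{result.cutoff_raw:.6g}",
    ]
    if result.fit is not None:
        fit = result.fit
        lines += [
            f"boxcox_lambda\t{fit.lam:.6g}",
            f"mu\t{fit.mu:.6g}",
            f"sigma\t{fit.sigma:.6g}",
            f"qq_r_squared\t{fit.r_squared:.6g}",
            f"r2_cutoff\t{fit.r2_cutoff}",
            f"passed_normality\t{fit.passed_normality}",
            f"critical_transformed\t{fit.critical_transformed:.6g}",
        ]
    path.write_text("\n".join(lines) + "\n")
    return path


def _qq_axes(ax, values: np.ndarray, title: str, hline: float | None) -> None:
    theo, ordered = qq_points(values)
    ax.plot(theo, ordered, ".", ms=2, color="steelblue")
    r = np.corrcoef(theo, ordered)[0, 1]
    ax.set_title(f"{title} (R$^2$={r * r:.4f})")
    ax.set_xlabel("theoretical quantiles")
    ax.set_ylabel("score quantiles")
    if hline is not None:
        ax.axhline(hline, color="green", lw=1.2)


def plot_qq(result: ExperimentResult, out_dir: str | Path) -> list[Path]:
    """Q-Q plots of scores before and after transformation."""
    out_dir = Path(out_dir)
    frame = result.table.frame
    paths = []
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    _qq_axes(ax, frame["score"].to_numpy(), "raw scores", result.cutoff_raw)
    fig.tight_layout()
    p = out_dir / "qq_before.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)
    if "transformed" in frame:
        hline = result.fit.critical_transformed if result.fit is not None else None
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        _qq_axes(ax, frame["transformed"].to_numpy(), "transformed scores", hline)
        fig.tight_layout()
        p = out_dir / "qq_after.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths.append(p)
    return paths


def plot_depth_summaries(
    enriched: DepthTable, control: DepthTable, result: ExperimentResult, out_dir: str | Path
) -> list[Path]:
    """Depth-frequency density plot and library-overlap pie chart."""
    out_dir = Path(out_dir)
    fig, ax = plt.subplots(figsize=(5, 4))
    for table, color in ((enriched, "firebrick"), (control, "steelblue")):
        hist = depth_histogram(table)
        if not hist:
            continue
        depths = np.array(sorted(hist))
        freqs = np.array([hist[d] for d in depths], dtype=float)
        ax.plot(depths, freqs / freqs.sum(), label=table.library_id, color=color)
    ax.set_xscale("log")
    ax.set_xlabel("reads per position")
    ax.set_ylabel("fraction of positions")
    ax.legend()
    fig.tight_layout()
    density = out_dir / "depth_density.png"
    fig.savefig(density, dpi=110)
    plt.close(fig)

    ov = result.overlap
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.pie(
        [ov.both, ov.only_enriched, ov.only_control],
        labels=["both", "only_enriched", "only_control"],
        autopct="%1.1f%%",
        colors=["mediumpurple", "firebrick", "steelblue"],
    )
    fig.tight_layout()
    pie = out_dir / "overlap_pie.png"
    fig.savefig(pie, dpi=110)
    plt.close(fig)
    return [density, pie]


def write_outputs(
    result: ExperimentResult,
    out_dir: str | Path,
    enriched: DepthTable | None = None,
    control: DepthTable | None = None,
    prefix: str = "",
) -> dict[str, Path]:
    """Emit the full output set for one experiment into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = (prefix + "_") if prefix else ""
    paths = {
        "significant_tsv": write_significant_tsv(result, out_dir / f"{name}significant_positions.tsv"),
        "all_tsv": Path(out_dir / f"{name}all_positions.tsv"),
        "gff3": write_gff3(result, out_dir / f"{name}enriched_positions.gff3"),
        "summary": write_summary(result, out_dir / f"{name}summary.txt"),
    }
    result.table.to_tsv(paths["all_tsv"])
    for p in plot_qq(result, out_dir):
        paths[p.stem] = p
    if enriched is not None and control is not None:
        for p in plot_depth_summaries(enriched, control, result, out_dir):
            paths[p.stem] = p
    return paths
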