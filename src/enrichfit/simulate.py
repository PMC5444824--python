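"""Synthetic paired enriched/control libraries with planted enrichment.

The generator emulates the experimental design of 5'-end enrichment
protocols: a control library whose read 5' starts fall over transcribed
positions according to background weights, and an enriched library in which
a set of planted sites receives an elevated start probability (background
weight times an enrichment factor > 1). Read starts are drawn per position
from a multinomial over the transcribed positions of both strands; optional
gamma-distributed position weights inject the depth heterogeneity that
transcript-abundance variation produces in real libraries, which the global
distribution model must absorb.

Reads are error-free, full-length and uniquely placed by construction, so
alignment is bypassed and SAM records are written directly: this isolates
the statistical method under test from aligner behavior. All randomness sits
behind one seeded generator; output is byte-identical for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from scipy import stats

from .depth import DepthTable, GenomicPosition
from .distfit import boxcox_transform
from .errors import EnrichFitError

_BASES = np.array(list("ACGT"))


def make_genome(length: int, seed: int) -> str:
    """Deterministic random genome sequence with uniform base composition."""
    if length < 1000:
        raise ValueError(f"genome length must be >= 1000, got {length}")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(_BASES, size=length))


def write_fasta(sequence: str, path: str | Path, name: str = "sim1") -> Path:
    """Write a single-record FASTA file."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(Seq(sequence), id=name, description="synthetic genome")
    path = Path(path)
    SeqIO.write([record], str(path), "fasta")
    return path


@dataclass
class TruthTable:
    """Planted ground truth for one simulated paired-library experiment."""

    planted_sites: list[tuple[GenomicPosition, float]]
    background_depth_mean: float
    n_reads_enriched: int
    n_reads_control: int
    seed: int
    genome_length: int = 5049
    read_length: int = 50
    reference: str = "sim1"
    heterogeneity_shape: float | None = None

    def __post_init__(self) -> None:
        keys = {site for site, _ in self.planted_sites}
        if len(keys) != len(self.planted_sites):
            raise ValueError("planted sites must be unique")
        for site, factor in self.planted_sites:
            if factor <= 1:
                raise ValueError(f"enrichment factor must be > 1, got {factor}")

    def planted_positions(self) -> set[GenomicPosition]:
        return {site for site, _ in self.planted_sites}

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            [(s.reference, s.position, s.strand, f) for s, f in self.planted_sites],
            columns=["reference", "position", "strand", "factor"],
        ).to_csv(path, sep="\t", index=False)


def transcribed_keys(truth: TruthTable) -> list[GenomicPosition]:
    """All 5'-start positions at which a full-length read fits the genome.

    Forward reads start in [1, G - L + 1]; reverse reads (5' end = rightmost
    aligned base) start in [L, G]. Order is deterministic: all forward
    positions ascending, then all reverse positions ascending.
    """
    g, L = truth.genome_length, truth.read_length
    fwd = [GenomicPosition(truth.reference, p, "+") for p in range(1, g - L + 2)]
    rev = [GenomicPosition(truth.reference, p, "-") for p in range(L, g + 1)]
    return fwd + rev


def plant_sites(
    n_sites: int,
    factor: float,
    seed: int,
    genome_length: int = 5049,
    read_length: int = 50,
    reference: str = "sim1",
    depth_mean: float = 20.0,
    heterogeneity_shape: float | None = None,
) -> TruthTable:
    """Build a :class:`TruthTable` with ``n_sites`` uniform random planted sites.

    Read counts are set so the background depth per transcribed position
    equals ``depth_mean`` in both libraries.
    """
    stub = TruthTable(
        planted_sites=[],
        background_depth_mean=depth_mean,
        n_reads_enriched=0,
        n_reads_control=0,
        seed=seed,
        genome_length=genome_length,
        read_length=read_length,
        reference=reference,
        heterogeneity_shape=heterogeneity_shape,
    )
    keys = transcribed_keys(stub)
    n_reads = int(round(depth_mean * len(keys)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(keys), size=n_sites, replace=False) if n_sites else []
    sites = [(keys[int(i)], float(factor)) for i in chosen]
    return TruthTable(
        planted_sites=sites,
        background_depth_mean=depth_mean,
        n_reads_enriched=n_reads,
        n_reads_control=n_reads,
        seed=seed,
        genome_length=genome_length,
        read_length=read_length,
        reference=reference,
        heterogeneity_shape=heterogeneity_shape,
    )


def _position_counts(truth: TruthTable) -> tuple[list[GenomicPosition], np.ndarray, np.ndarray]:
    """Draw per-position read-start counts for (enriched, control)."""
    keys = transcribed_keys(truth)
    n = len(keys)
    for site, _ in truth.planted_sites:
        if site not in set(keys):
            raise ValueError(f"planted site {site} outside transcribed positions")
    rng = np.random.default_rng(truth.seed)
    if truth.heterogeneity_shape is not None:
        shape = truth.heterogeneity_shape
        weights = rng.gamma(shape, 1.0 / shape, size=n)
    else:
        weights = np.ones(n)
    index = {key: i for i, key in enumerate(keys)}
    w_enriched = weights.copy()
    for site, factor in truth.planted_sites:
        w_enriched[index[site]] *= factor
    counts_enriched = rng.multinomial(truth.n_reads_enriched, w_enriched / w_enriched.sum())
    counts_control = rng.multinomial(truth.n_reads_control, weights / weights.sum())
    return keys, counts_enriched, counts_control


def simulate_depth_tables(truth: TruthTable) -> tuple[DepthTable, DepthTable]:
    """Exact start-mode depth tables for the paired libraries.

    This is the sampling model of :func:`simulate_libraries` up to (but not
    including) SAM emission; it is the fast path for statistical studies
    where alignment-file round-tripping is not the property of interest.
    """
    keys, c1, c2 = _position_counts(truth)
    enriched = DepthTable(
        library_id="enriched",
        count_mode="start",
        counts={k: int(c) for k, c in zip(keys, c1) if c > 0},
    )
    control = DepthTable(
        library_id="control",
        count_mode="start",
        counts={k: int(c) for k, c in zip(keys, c2) if c > 0},
    )
    return enriched, control


def _write_sam(
    path: Path,
    genome: str,
    truth: TruthTable,
    keys: list[GenomicPosition],
    counts: np.ndarray,
    prefix: str,
) -> None:
    L = truth.read_length
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": truth.reference, "LN": truth.genome_length}],
    }
    # leftmost 1-based coordinate per key; emit in coordinate order
    lefts = np.array(
        [k.position if k.strand == "+" else k.position - L + 1 for k in keys]
    )
    order = np.argsort(lefts, kind="stable")
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        serial = 0
        for i in order:
            c = int(counts[i])
            if c == 0:
                continue
            key = keys[i]
            left = int(lefts[i])
            seq = genome[left - 1 : left - 1 + L]
            for _ in range(c):
                read = pysam.AlignedSegment(out.header)
                read.query_name = f"{prefix}_{serial}"
                serial += 1
                read.query_sequence = seq
                read.flag = 16 if key.strand == "-" else 0
                read.reference_id = 0
                read.reference_start = left - 1
                read.mapping_quality = 60
                read.cigarstring = f"{L}M"
                read.query_qualities = pysam.qualitystring_to_array("I" * L)
                out.write(read)


def simulate_libraries(
    genome: str, truth: TruthTable, out_dir: str | Path
) -> dict[str, Path]:
    """Write paired enriched/control SAM files plus the truth table.

    Returns paths under keys ``enriched_sam``, ``control_sam``, ``truth_tsv``.
    """
    if len(genome) != truth.genome_length:
        raise EnrichFitError(
            f"genome length {len(genome)} does not match truth table "
            f"({truth.genome_length})"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    keys, c1, c2 = _position_counts(truth)
    paths = {
        "enriched_sam": out_dir / "enriched.sam",
        "control_sam": out_dir / "control.sam",
        "truth_tsv": out_dir / "truth.tsv",
    }
    _write_sam(paths["enriched_sam"], genome, truth, keys, c1, "enr")
    _write_sam(paths["control_sam"], genome, truth, keys, c2, "ctl")
    truth.to_tsv(paths["truth_tsv"])
    return paths


def sam_to_indexed_bam(sam_path: str | Path, bam_path: str | Path | None = None) -> Path:
    """Sort a SAM file into an indexed BAM (coordinate order)."""
    sam_path = Path(sam_path)
    if bam_path is None:
        bam_path = sam_path.with_suffix(".bam")
    bam_path = Path(bam_path)
    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))
    return bam_path


def inverse_boxcox_normal_sample(
    lam: float,
    n: int,
    rng: np.random.Generator,
    low: float = 0.1,
    high: float = 30.0,
) -> np.ndarray:
    """Positive scores whose Box-Cox transform at ``lam`` is exactly normal.

    The transformed values are drawn as stratified normal deviates (one
    quantile-jittered draw per probability stratum, then shuffled), a
    variance-reduction scheme that makes exponent-recovery studies reflect
    estimator consistency rather than Monte-Carlo noise. The target normal
    is centered so raw scores span roughly [low, high]; for lam != 0 the
    range is narrowed geometrically until the transform's support boundary
    -1/lam lies at least 5 standard deviations from the mean, so no draw can
    leave the valid domain.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    lo, hi = float(low), float(high)
    if not 0 < lo < hi:
        raise ValueError("need 0 < low < high")
    while True:
        tlo = float(boxcox_transform([lo], lam)[0])
        thi = float(boxcox_transform([hi], lam)[0])
        mu, sigma = (tlo + thi) / 2.0, (thi - tlo) / 6.0
        if lam == 0 or abs(-1.0 / lam - mu) / sigma >= 5.0:
            break
        lo, hi = lo * 1.1, hi / 1.1
    u = (np.arange(n) + 0.01 + 0.98 * rng.random(n)) / n
    z = mu + sigma * stats.norm.ppf(u)
    rng.shuffle(z)
    if lam == 0:
        return np.exp(z)
    return np.power(1.0 + lam * z, 1.0 / lam)
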