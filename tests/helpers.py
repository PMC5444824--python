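"""Shared test utilities: hand-rolled SAM writing and a text-level depth oracle.

The oracle deliberately avoids pysam: it walks the SAM text and CIGAR
strings itself, so depth counting is checked by two independent routes.
"""

from __future__ import annotations

import re
from collections import Counter
from pathlib import Path

CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

SKIP_FLAGS = 4 | 256 | 2048  # unmapped, secondary, supplementary


def cigar_query_length(cigar: str) -> int:
    return sum(int(n) for n, op in CIGAR_RE.findall(cigar) if op in "MIS=X")


def write_sam(
    path: Path,
    reads: list[tuple[str, int, int, int, str, str]],
    ref: str = "chr1",
    length: int = 1000,
) -> Path:
    """Write SAM text from (name, flag, pos_1based, mapq, cigar, seq) tuples."""
    lines = ["@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:{ref}\tLN:{length}"]
    for name, flag, pos, mapq, cigar, seq in reads:
        qual = "I" * len(seq) if seq != "*" else "*"
        lines.append(
            f"{name}\t{flag}\t{ref}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def sam_depth_oracle(path: Path, mode: str, min_mapq: int = 0) -> Counter:
    """Brute-force per-read enumeration of aligned reference coordinates."""
    counts: Counter = Counter()
    for line in open(path):
        if line.startswith("@"):
            continue
        fields = line.rstrip("\n").split("\t")
        flag = int(fields[1])
        if flag & SKIP_FLAGS:
            continue
        if int(fields[4]) < min_mapq:
            continue
        ref, pos, cigar = fields[2], int(fields[3]), fields[5]
        strand = "-" if flag & 16 else "+"
        aligned: list[int] = []
        cursor = pos
        for n, op in CIGAR_RE.findall(cigar):
            n = int(n)
            if op in "M=X":
                aligned.extend(range(cursor, cursor + n))
                cursor += n
            elif op in "DN":
                cursor += n
            # I, S, H, P consume no reference
        if not aligned:
            continue
        if mode == "all":
            for p in aligned:
                counts[(ref, p, strand)] += 1
        elif mode == "start":
            p = max(aligned) if strand == "-" else min(aligned)
            counts[(ref, p, strand)] += 1
        else:  # end
            p = min(aligned) if strand == "-" else max(aligned)
            counts[(ref, p, strand)] += 1
    return counts


def random_sam(path: Path, rng, n_reads: int = 100, ref: str = "chr1", length: int = 500) -> Path:
    """A random SAM mixing strands, clips, indels and skippable records."""
    records = []
    for i in range(n_reads):
        pos = int(rng.integers(1, length - 60))
        flag = int(rng.choice([0, 0, 16, 16, 4, 256, 2048]))
        mapq = int(rng.integers(0, 61))
        a, b = int(rng.integers(5, 20)), int(rng.integers(5, 20))
        k = int(rng.integers(1, 5))
        cigar = [
            f"{a + b}M",
            f"{k}S{a}M",
            f"{a}M{k}S",
            f"{a}M{k}D{b}M",
            f"{a}M{k}I{b}M",
        ][int(rng.integers(0, 5))]
        if flag & 4:
            cigar = "*"
            seq = "*"
        else:
            seq = "".join(rng.choice(list("ACGT"), cigar_query_length(cigar)))
        records.append((f"r{i}", flag, pos, mapq, cigar, seq))
    records.sort(key=lambda r: r[2])
    return write_sam(path, records, ref=ref, length=length)
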