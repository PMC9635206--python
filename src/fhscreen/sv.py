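"""Structural-variant consensus calling by reciprocal overlap.

Two callers' per-sample call sets are merged into consensus records when a
pair of same-sample, same-chromosome, same-type calls overlaps reciprocally
by strictly more than a threshold (default 80%). Reciprocal overlap of
intervals a, b is min(|a n b| / |a|, |a n b| / |b|) on 1-based inclusive
coordinates. Size filtering keeps calls of 50 bp to 10 Mb. Per-individual
consensus records can then be clustered across samples and intersected with
gene intervals to flag gene-disrupting events.

Matching is greedy best-overlap-first, each call used at most once, ties
broken by larger overlap then smaller start. The consensus interval averages
the two callers' breakpoints (rounded half up); the multi-sample cluster
representative uses median breakpoints.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import groupby

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SVCall",
    "ConsensusSV",
    "reciprocal_overlap",
    "size_filter",
    "merge_callers",
    "multi_sample_consensus",
    "gene_disruption",
    "read_sv_table",
    "read_sv_vcf",
    "read_genes_bed",
    "write_sv_table",
]

SV_TYPES = ("DEL", "DUP", "INV", "INS")


@dataclass(frozen=True)
class SVCall:
    """One caller's SV interval; 1-based inclusive start/end."""

    sample: str
    chrom: str
    start: int
    end: int
    sv_type: str
    caller: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start for {self}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ConsensusSV:
    sample: str
    chrom: str
    start: int
    end: int
    sv_type: str
    callers: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def as_call(self, caller: str = "consensus") -> SVCall:
        return SVCall(self.sample, self.chrom, self.start, self.end, self.sv_type, caller)


def reciprocal_overlap(a: SVCall, b: SVCall) -> float:
    """min of the mutual overlap fractions; 0 when disjoint, off-chromosome,
    or of different SV type."""
    if a.chrom != b.chrom or a.sv_type != b.sv_type:
        return 0.0
    ovl = min(a.end, b.end) - max(a.start, b.start) + 1
    if ovl <= 0:
        return 0.0
    return min(ovl / a.length, ovl / b.length)


def size_filter(calls, min_size: int = 50, max_size: int = 10_000_000) -> list:
    """Keep calls with min_size <= length <= max_size; order preserved."""
    return [c for c in calls if min_size <= c.length <= max_size]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def merge_callers(calls_a, calls_b, threshold: float = 0.8) -> list[ConsensusSV]:
    """Per-individual consensus: greedily pair calls across the two callers.

    A pair qualifies when sample, chromosome, and SV type agree and the
    reciprocal overlap is strictly greater than ``threshold``. Each call joins
    at most one consensus record; candidate pairs are taken in order of
    descending overlap, then ascending start.
    """
    calls_a = list(calls_a)
    calls_b = list(calls_b)
    by_key_b: dict[tuple, list[tuple[int, SVCall]]] = {}
    for j, b in enumerate(calls_b):
        by_key_b.setdefault((b.sample, b.chrom, b.sv_type), []).append((j, b))

    candidates = []
    for i, a in enumerate(calls_a):
        for j, b in by_key_b.get((a.sample, a.chrom, a.sv_type), []):
            ro = reciprocal_overlap(a, b)
            if ro > threshold:
                candidates.append((ro, a, b, i, j))
    candidates.sort(key=lambda t: (-t[0], min(t[1].start, t[2].start), t[3], t[4]))

    used_a: set[int] = set()
    used_b: set[int] = set()
    out: list[ConsensusSV] = []
    for ro, a, b, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append(
            ConsensusSV(
                sample=a.sample,
                chrom=a.chrom,
                start=_round_half_up((a.start + b.start) / 2),
                end=_round_half_up((a.end + b.end) / 2),
                sv_type=a.sv_type,
                callers=(a.caller, b.caller),
            )
        )
    out.sort(key=lambda c: (c.sample, c.chrom, c.start, c.end))
    return out


def multi_sample_consensus(records, threshold: float = 0.8) -> pd.DataFrame:
    """Cluster per-individual consensus records across samples.

    Single-linkage greedy clustering under the same strict reciprocal-overlap
    rule (same chromosome and type); the cluster representative takes the
    median start and end. Returns one row per cluster with member samples.
    """
    recs = sorted(records, key=lambda r: (r.chrom, r.sv_type, r.start, r.end))
    rows = []
    for (chrom, sv_type), group in groupby(recs, key=lambda r: (r.chrom, r.sv_type)):
        clusters: list[list[ConsensusSV]] = []
        for r in group:
            placed = False
            for cl in clusters:
                if any(reciprocal_overlap(r.as_call(), m.as_call()) > threshold for m in cl):
                    cl.append(r)
                    placed = True
                    break
            if not placed:
                clusters.append([r])
        for cl in clusters:
            starts = sorted(m.start for m in cl)
            ends = sorted(m.end for m in cl)
            rows.append(
                {
                    "chrom": chrom,
                    "start": _round_half_up(_median(starts)),
                    "end": _round_half_up(_median(ends)),
                    "sv_type": sv_type,
                    "n_samples": len({m.sample for m in cl}),
                    "samples": ",".join(sorted({m.sample for m in cl})),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sv_type", "n_samples", "samples"])


def _median(vals) -> float:
    n = len(vals)
    mid = n // 2
    return float(vals[mid]) if n % 2 else (vals[mid - 1] + vals[mid]) / 2


def gene_disruption(records, genes: pd.DataFrame) -> pd.DataFrame:
    """Flag consensus SVs intersecting gene intervals by >= 1 base.

    ``genes`` has columns gene, chrom, start, end in 1-based inclusive
    coordinates (see read_genes_bed). Returns per-sample per-gene hits.
    """
    rows = []
    for r in records:
        sub = genes[genes["chrom"].astype(str) == r.chrom]
        for _, g in sub.iterrows():
            if min(r.end, g["end"]) - max(r.start, g["start"]) + 1 >= 1:
                rows.append(
                    {
                        "sample": r.sample,
                        "gene": g["gene"],
                        "chrom": r.chrom,
                        "start": r.start,
                        "end": r.end,
                        "sv_type": r.sv_type,
                        "whole_gene": bool(r.start <= g["start"] and r.end >= g["end"]),
                    }
                )
    return pd.DataFrame(
        rows, columns=["sample", "gene", "chrom", "start", "end", "sv_type", "whole_gene"]
    )


# ---------------------------------------------------------------------------
# I/O


def read_sv_table(path, caller: str | None = None) -> list[SVCall]:
    """Tab-delimited SV calls with columns sample, chrom, start, end, type[, caller]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "sample": str})
    required = {"sample", "chrom", "start", "end", "type"}
    if not required <= set(df.columns):
        raise ValueError(f"SV table needs columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SVCall(
                sample=str(row.sample),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                sv_type=str(row.type),
                caller=caller or str(getattr(row, "caller", "unknown")),
            )
        )
    return out


def write_sv_table(calls, path) -> None:
    df = pd.DataFrame(
        [
            {"sample": c.sample, "chrom": c.chrom, "start": c.start, "end": c.end,
             "type": c.sv_type, "caller": c.caller}
            for c in calls
        ],
        columns=["sample", "chrom", "start", "end", "type", "caller"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_sv_vcf(path, caller: str, sample: str | None = None) -> list[SVCall]:
    """SV calls from a VCF with SVTYPE/END INFO keys; breakends are skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    out = []
    n_bnd = 0
    for v in vcf:
        sv_type = v.INFO.get("SVTYPE")
        if sv_type is None:
            continue
        if sv_type == "BND":
            n_bnd += 1
            continue
        end = v.INFO.get("END")
        end = int(end) if end is not None else v.POS + abs(int(v.INFO.get("SVLEN", 0))) - 1
        carriers = samples or ([sample] if sample else ["unknown"])
        if samples:
            carriers = [s for s, t in zip(samples, v.gt_types) if t in (1, 3)]
        for s in carriers:
            out.append(SVCall(sample=s, chrom=v.CHROM, start=v.POS, end=end,
                              sv_type=sv_type, caller=caller))
    if n_bnd:
        logger.info("excluded %d breakend (BND) records from %s", n_bnd, path)
    return out


def read_genes_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) -> DataFrame with 1-based inclusive start/end."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "gene"], dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(int)
    return df[["gene", "chrom", "start", "end"]]
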