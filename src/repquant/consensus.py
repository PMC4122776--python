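"""Per-position analysis along a repeat subfamily consensus sequence.

Covers three related views of a single subfamily (the motivating case
is the human-specific LINE-1 element L1Hs, whose genomic copies are
predominantly 5'-truncated):

* read coverage depth along the consensus from local alignments, with
  soft-clipped bases excluded;
* the cumulative distribution of genomic-instance alignment start and
  end positions on the consensus (the truncation structure);
* per-position paired log2 fold-change tracks between two libraries
  (e.g. tumor vs matched normal), each normalized by its total mapping
  reads, with a small pseudocount for zero-coverage positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import RepeatInstance

DEFAULT_PSEUDOCOUNT = 1e-6  # on per-read-normalized coverage


@dataclass
class CoverageVector:
    """Per-position depth over [0, L), plus the source library's total
    mapping reads used as the normalizer."""

    depth: np.ndarray
    total_mapping_reads: int

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if (self.depth < 0).any():
            raise ValueError("negative depth")
        if self.total_mapping_reads <= 0:
            raise ValueError("total_mapping_reads must be positive")

    @property
    def normalized(self) -> np.ndarray:
        return self.depth / self.total_mapping_reads


def _aligned_blocks(aln) -> list[tuple[int, int]]:
    """Aligned (non-soft-clipped) reference spans of one alignment.

    Accepts a pysam AlignedSegment (via get_blocks), a plain (start,
    end) pair, or an explicit list of block pairs.
    """
    if hasattr(aln, "get_blocks"):
        return list(aln.get_blocks())
    if isinstance(aln, tuple) and len(aln) == 2 and isinstance(aln[0], int):
        return [aln]
    return list(aln)


def consensus_coverage(
    alignments: Iterable,
    consensus_length: int,
    total_mapping_reads: int,
) -> CoverageVector:
    """depth(p) = number of alignments whose aligned span covers p.

    Soft-clipped bases never enter the reference span, so they are
    excluded by construction.
    """
    diff = np.zeros(consensus_length + 1, dtype=float)
    for aln in alignments:
        for start, end in _aligned_blocks(aln):
            if start < 0 or end > consensus_length:
                raise ValueError(
                    f"alignment block [{start}, {end}) outside consensus [0, {consensus_length})"
                )
            diff[start] += 1
            diff[end] -= 1
    return CoverageVector(np.cumsum(diff[:-1]), total_mapping_reads)


def coverage_from_sam(
    sam_path, consensus_length: int, total_mapping_reads: int
) -> CoverageVector:
    """Coverage from a SAM/BAM of local alignments to the consensus."""
    import pysam

    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        alns = [rec for rec in fh if not rec.is_unmapped]
        return consensus_coverage(alns, consensus_length, total_mapping_reads)


@dataclass
class InstanceSpanCDF:
    """Cumulative fraction of instances whose alignment starts at or
    before p (start_cdf) and ends at or before p (end_cdf, last aligned
    position), for each consensus position p."""

    start_cdf: np.ndarray
    end_cdf: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": np.arange(self.start_cdf.size),
             "start_cdf": self.start_cdf,
             "end_cdf": self.end_cdf}
        )


def instance_span_cdf(
    spans: Sequence[tuple[int, int]], consensus_length: int
) -> InstanceSpanCDF:
    """Build start/end CDFs from one best alignment span (start, end)
    per genomic instance; a preponderance of large start values reflects
    5' truncation."""
    if not spans:
        raise ValueError("no instance spans")
    n = len(spans)
    starts = np.zeros(consensus_length + 1)
    ends = np.zeros(consensus_length + 1)
    for s, e in spans:
        if not (0 <= s < e <= consensus_length):
            raise ValueError(f"span [{s}, {e}) outside consensus")
        starts[s] += 1
        ends[e - 1] += 1  # last aligned position
    return InstanceSpanCDF(
        np.cumsum(starts[:-1]) / n,
        np.cumsum(ends[:-1]) / n,
    )


def best_alignment_spans(sam_path) -> list[tuple[int, int]]:
    """One best span per query from a SAM of instance-to-consensus
    alignments: highest alignment score (AS tag), ties broken by
    leftmost start."""
    import pysam

    best: dict[str, tuple[float, int, int]] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            score = float(rec.get_tag("AS")) if rec.has_tag("AS") else 0.0
            span = (rec.reference_start, rec.reference_end)
            cur = best.get(rec.query_name)
            cand = (-score, span[0], span[1])
            if cur is None or cand[:2] < cur[:2]:
                best[rec.query_name] = cand
    return [(s, e) for _neg, s, e in sorted(best.values())]


def paired_log2fc_profile(
    tumor: CoverageVector,
    normal: CoverageVector,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Per position p: log2((tumor_norm(p) + c) / (normal_norm(p) + c)),
    where each track is depth / total mapping reads and c is the
    pseudocount keeping zero-coverage positions finite."""
    if tumor.depth.size != normal.depth.size:
        raise ValueError("coverage vectors are on different consensus lengths")
    return np.log2(
        (tumor.normalized + pseudocount) / (normal.normalized + pseudocount)
    )


# ---------------------------------------------------------------------------
# genic vs intergenic contribution


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _overlap_len(start: int, end: int, merged: Sequence[tuple[int, int]]) -> int:
    total = 0
    for s, e in merged:
        if s >= end:
            break
        if e > start:
            total += min(end, e) - max(start, s)
    return total


def classify_genic(
    instances: Sequence[RepeatInstance],
    gene_intervals: Sequence[tuple[str, int, int]],
    min_fraction: float = 0.99,
) -> tuple[list[RepeatInstance], list[RepeatInstance]]:
    """Partition instances into genic (>= min_fraction of their length
    inside gene bodies) and intergenic (>= min_fraction outside);
    instances satisfying neither rule are excluded from both."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in gene_intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    merged = {c: _merge_intervals(iv) for c, iv in by_chrom.items()}
    genic, intergenic = [], []
    for inst in instances:
        ov = _overlap_len(inst.start, inst.end, merged.get(inst.chrom, []))
        frac = ov / inst.length
        if frac >= min_fraction:
            genic.append(inst)
        elif 1.0 - frac >= min_fraction:
            intergenic.append(inst)
    return genic, intergenic


def genic_intergenic_summary(
    unique_alignments_by_sample: Mapping[str, Sequence[tuple[str, int, int]]],
    instances: Sequence[RepeatInstance],
    gene_intervals: Sequence[tuple[str, int, int]],
    library_sizes: Mapping[str, int],
    pairs: Sequence[tuple[str, str]],
    min_fraction: float = 0.99,
    pseudocount_cpm: float = 0.01,
) -> pd.DataFrame:
    """Per-pair (e.g. tumor vs normal) log2FC of summed unique-read
    counts over genic and intergenic instance sets, CPM-normalized by
    the supplied total mapping reads (no between-sample normalization).

    ``unique_alignments_by_sample`` maps sample -> (chrom, start, end)
    intervals of uniquely mapped reads. A read counts once per
    partition if it overlaps any instance in that partition by >=1 bp.
    Returns a DataFrame indexed by (tumor, normal) pair with columns
    ``genic_log2fc`` and ``intergenic_log2fc`` (NaN for a partition
    with no instances).
    """
    from .counting import build_instance_trees, overlapping_subfamilies

    genic, intergenic = classify_genic(instances, gene_intervals, min_fraction)
    parts = {"genic": genic, "intergenic": intergenic}
    trees = {name: build_instance_trees(p) for name, p in parts.items()}
    cpm: dict[str, dict[str, float]] = {name: {} for name in parts}
    for sample, alns in unique_alignments_by_sample.items():
        lib = library_sizes[sample]
        if lib <= 0:
            raise ValueError(f"library size for {sample!r} must be positive")
        counts = {name: 0 for name in parts}
        for chrom, start, end in alns:
            for name in parts:
                if overlapping_subfamilies(trees[name], chrom, start, end):
                    counts[name] += 1
        for name in parts:
            cpm[name][sample] = counts[name] * 1e6 / lib
    rows = []
    for tumor, normal in pairs:
        row = {}
        for name, part in parts.items():
            if not part:
                row[f"{name}_log2fc"] = np.nan
                continue
            row[f"{name}_log2fc"] = np.log2(
                (cpm[name][tumor] + pseudocount_cpm)
                / (cpm[name][normal] + pseudocount_cpm)
            )
        rows.append(row)
    return pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(pairs, names=["tumor", "normal"]))
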