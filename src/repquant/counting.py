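"""Read partitioning, subfamily assignment and the three counting strategies.

Reads are first aligned to the genome and partitioned into uniquely
mapping reads and multi-mapping reads. Uniquely mapping reads are
assigned to every repeat subfamily whose annotated instance they
overlap by at least 1 bp; multi-mapping reads are aligned to the
per-subfamily pseudogenomes and assigned to every subfamily with at
least one valid alignment. For each read r this yields a set S_r of
subfamilies with N_s(r) = |S_r|, from which three per-subfamily tallies
are computed:

* total:      #{r : s in S_r}                 (a read counts once per subfamily)
* unique:     #{r : S_r = {s}}                (ambiguous reads discarded)
* fractional: sum over {r : s in S_r} of 1/N_s(r), rounded to the
              nearest integer (ties to even); the unrounded sum is kept.

Paired-end mates are independent counting units keyed (read_id, mate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .align import KmerIndex, Placement
from .annotation import RepeatHierarchy, RepeatInstance

ReadKey = tuple[str, int]  # (read_id, mate flag: 0 single, 1/2 paired)


@dataclass(frozen=True, slots=True)
class UniqueAlignment:
    read_id: str
    mate: int
    chrom: str
    start: int
    end: int


@dataclass(frozen=True, slots=True)
class MultimapRead:
    read_id: str
    mate: int
    sequence: str


@dataclass
class AlignmentPartition:
    """Reads split into uniquely-mapping and multi-mapping sets."""

    unique: list[UniqueAlignment] = field(default_factory=list)
    multimap: list[MultimapRead] = field(default_factory=list)
    n_unmapped: int = 0
    library_size_override: int | None = None


class ReadSubfamilyMap:
    """Per (read_id, mate): the set S_r of subfamilies the read aligns to."""

    def __init__(self) -> None:
        self._sets: dict[ReadKey, frozenset[str]] = {}

    def add(self, read_id: str, mate: int, subfamilies: Iterable[str]) -> None:
        key = (read_id, mate)
        s = frozenset(subfamilies)
        if not s:
            raise ValueError("S_r must be non-empty; drop unassigned reads upstream")
        if key in self._sets:
            raise ValueError(f"read {key} assigned twice")
        self._sets[key] = s

    def update(self, other: "ReadSubfamilyMap") -> None:
        overlap = self._sets.keys() & other._sets.keys()
        if overlap:
            raise ValueError(f"reads present in both maps, e.g. {next(iter(overlap))}")
        self._sets.update(other._sets)

    def items(self) -> Iterator[tuple[ReadKey, frozenset[str]]]:
        return iter(self._sets.items())

    def __len__(self) -> int:
        return len(self._sets)

    def __getitem__(self, key: ReadKey) -> frozenset[str]:
        return self._sets[key]


# ---------------------------------------------------------------------------
# partitioning


def _mate_from_name(name: str) -> tuple[str, int]:
    if name.endswith("/1"):
        return name[:-2], 1
    if name.endswith("/2"):
        return name[:-2], 2
    return name, 0


def partition_alignments(
    unique_sam: str | Path,
    multimap_reads: str | Path | None = None,
) -> AlignmentPartition:
    """Build a partition from an aligner's outputs: a SAM/BAM of
    uniquely-placed reads and a FASTQ/FASTA of multi-mapping overflow
    reads. Unmapped SAM records are dropped (counted)."""
    import pysam
    from Bio import SeqIO

    part = AlignmentPartition()
    seen: set[ReadKey] = set()
    with pysam.AlignmentFile(str(unique_sam), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                part.n_unmapped += 1
                continue
            mate = 1 if rec.is_read1 else 2 if rec.is_read2 else 0
            part.unique.append(
                UniqueAlignment(
                    rec.query_name, mate, rec.reference_name,
                    rec.reference_start, rec.reference_end,
                )
            )
            seen.add((rec.query_name, mate))
    if multimap_reads is not None:
        fmt = "fastq" if str(multimap_reads).endswith(("fastq", "fq")) else "fasta"
        for rec in SeqIO.parse(str(multimap_reads), fmt):
            name, mate = _mate_from_name(rec.id)
            if (name, mate) in seen:
                raise ValueError(
                    f"read {name!r} present in both unique and multimap inputs"
                )
            part.multimap.append(MultimapRead(name, mate, str(rec.seq).upper()))
    return part


def partition_with_matcher(
    reads: Iterable[tuple[str, int, str]],
    genome_index: KmerIndex,
    max_mismatch: int | None = None,
) -> AlignmentPartition:
    """Partition raw reads with the internal matcher: exactly one genome
    placement -> unique; more than one -> multi-mapping; none -> unmapped."""
    part = AlignmentPartition()
    for read_id, mate, seq in reads:
        placements = genome_index.find(seq, max_mismatch)
        if len(placements) == 1:
            pl = placements[0]
            part.unique.append(
                UniqueAlignment(read_id, mate, pl.target, pl.pos, pl.pos + len(seq))
            )
        elif len(placements) > 1:
            part.multimap.append(MultimapRead(read_id, mate, seq))
        else:
            part.n_unmapped += 1
    return part


# ---------------------------------------------------------------------------
# subfamily assignment


def build_instance_trees(
    instances: Iterable[RepeatInstance],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for inst in instances:
        trees.setdefault(inst.chrom, IntervalTree()).addi(
            inst.start, inst.end, inst.subfamily
        )
    return trees


def overlapping_subfamilies(
    trees: Mapping[str, IntervalTree],
    chrom: str,
    start: int,
    end: int,
    min_overlap: int = 1,
) -> set[str]:
    tree = trees.get(chrom)
    if tree is None:
        return set()
    return {
        iv.data
        for iv in tree.overlap(start, end)
        if min(end, iv.end) - max(start, iv.begin) >= min_overlap
    }


def assign_unique_reads(
    unique_alignments: Iterable[UniqueAlignment],
    instances: Iterable[RepeatInstance] | Mapping[str, IntervalTree],
    min_overlap_fraction: float | None = None,
) -> ReadSubfamilyMap:
    """Assign uniquely-mapped reads to every subfamily whose instance
    they overlap by >=1 bp (or by >= min_overlap_fraction of the read
    length if given); reads overlapping nothing are non-repetitive and
    omitted from the map."""
    trees = (
        instances
        if isinstance(instances, Mapping)
        else build_instance_trees(instances)
    )
    rmap = ReadSubfamilyMap()
    for ua in unique_alignments:
        min_bp = (
            1
            if min_overlap_fraction is None
            else max(1, int(np.ceil(min_overlap_fraction * (ua.end - ua.start))))
        )
        subs = overlapping_subfamilies(trees, ua.chrom, ua.start, ua.end, min_bp)
        if subs:
            rmap.add(ua.read_id, ua.mate, subs)
    return rmap


def map_multireads(
    multimap: Iterable[MultimapRead],
    pseudogenome_index: KmerIndex,
    max_mismatch: int | None = None,
) -> tuple[ReadSubfamilyMap, int]:
    """Align multi-mapping reads to the pseudogenomes; S_r is the set of
    subfamilies with >=1 alignment (within-pseudogenome hits collapse).
    Returns the map and the number of dropped (nowhere-aligning) reads."""
    rmap = ReadSubfamilyMap()
    n_dropped = 0
    for mr in multimap:
        subs = pseudogenome_index.find_targets(mr.sequence, max_mismatch)
        if subs:
            rmap.add(mr.read_id, mr.mate, subs)
        else:
            n_dropped += 1
    return rmap, n_dropped


# ---------------------------------------------------------------------------
# counting


STRATEGIES = ("total", "unique", "fractional")


def count_reads(
    read_map: ReadSubfamilyMap, subfamilies: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tally one sample under all three strategies.

    Returns a DataFrame indexed by subfamily with columns ``total``,
    ``unique``, ``fractional_unrounded`` and ``fractional`` (nearest
    integer, ties to even).
    """
    total: dict[str, int] = {}
    uniq: dict[str, int] = {}
    frac: dict[str, float] = {}
    for _key, s_r in read_map.items():
        n_s = len(s_r)
        w = 1.0 / n_s
        for sub in s_r:
            total[sub] = total.get(sub, 0) + 1
            frac[sub] = frac.get(sub, 0.0) + w
            if n_s == 1:
                uniq[sub] = uniq.get(sub, 0) + 1
    if subfamilies is None:
        subfamilies = sorted(total)
    df = pd.DataFrame(
        {
            "total": [total.get(s, 0) for s in subfamilies],
            "unique": [uniq.get(s, 0) for s in subfamilies],
            "fractional_unrounded": [frac.get(s, 0.0) for s in subfamilies],
        },
        index=pd.Index(subfamilies, name="subfamily"),
    )
    df["fractional"] = np.rint(df["fractional_unrounded"]).astype(int)
    return df


@dataclass
class CountTable:
    """Subfamily x sample count matrix under one counting strategy."""

    strategy: str
    counts: pd.DataFrame  # subfamily x sample
    library_sizes: pd.Series  # per sample
    unrounded: pd.DataFrame | None = None  # fractional strategy only

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)

    def cpm(self) -> pd.DataFrame:
        return cpm(self)

    def aggregate(self, level: str, hierarchy: RepeatHierarchy) -> "CountTable":
        return aggregate(self, level, hierarchy)


def build_count_table(
    strategy: str,
    per_sample: Mapping[str, pd.DataFrame],
    library_sizes: Mapping[str, int],
) -> CountTable:
    """Assemble a CountTable from per-sample ``count_reads`` outputs."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    samples = list(per_sample)
    all_subs = sorted(set().union(*(df.index for df in per_sample.values())))
    col = strategy
    counts = pd.DataFrame(
        {s: per_sample[s][col].reindex(all_subs, fill_value=0) for s in samples}
    )
    counts.index.name = "subfamily"
    unrounded = None
    if strategy == "fractional":
        unrounded = pd.DataFrame(
            {
                s: per_sample[s]["fractional_unrounded"].reindex(all_subs, fill_value=0.0)
                for s in samples
            }
        )
        unrounded.index.name = "subfamily"
    return CountTable(
        strategy, counts, pd.Series(library_sizes, dtype=float), unrounded
    )


def aggregate(table: CountTable, level: str, hierarchy: RepeatHierarchy) -> CountTable:
    """Sum counts over subfamilies sharing a family or class."""
    if level not in ("family", "class"):
        raise ValueError("level must be 'family' or 'class'")
    key = hierarchy.family_of if level == "family" else hierarchy.class_of
    groups = [key(s) for s in table.counts.index]  # KeyError if absent
    counts = table.counts.groupby(groups).sum()
    counts.index.name = level
    unrounded = None
    if table.unrounded is not None:
        unrounded = table.unrounded.groupby(groups).sum()
        unrounded.index.name = level
    return CountTable(table.strategy, counts, table.library_sizes, unrounded)


def cpm(table: CountTable) -> pd.DataFrame:
    """Counts per million mapping reads: count * 1e6 / library size."""
    lib = table.library_sizes
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return table.counts * 1e6 / lib


# ---------------------------------------------------------------------------
# end-to-end single-sample quantification (internal matcher)


@dataclass
class QuantResult:
    counts: pd.DataFrame  # count_reads output
    library_size: int
    read_fates: dict[str, int]
    read_map: ReadSubfamilyMap


def quantify_sample(
    partition: AlignmentPartition,
    instances: Sequence[RepeatInstance] | Mapping[str, IntervalTree],
    pseudogenome_index: KmerIndex,
    subfamilies: Sequence[str] | None = None,
    max_mismatch: int | None = None,
) -> QuantResult:
    """Assign a partitioned sample and tally all three strategies.

    Library size defaults to uniquely-mapped reads plus multi-mapping
    reads that aligned to at least one pseudogenome; an explicit
    ``partition.library_size_override`` (externally computed total
    mapping reads) takes precedence.
    """
    unique_map = assign_unique_reads(partition.unique, instances)
    multi_map, n_dropped = map_multireads(
        partition.multimap, pseudogenome_index, max_mismatch
    )
    n_multi_assigned = len(multi_map)
    unique_map.update(multi_map)
    counts = count_reads(unique_map, subfamilies)
    library = (
        partition.library_size_override
        if partition.library_size_override is not None
        else len(partition.unique) + n_multi_assigned
    )
    fates = {
        "unique_mapped": len(partition.unique),
        "unique_repeat_assigned": len(unique_map) - n_multi_assigned,
        "multimap_assigned": n_multi_assigned,
        "multimap_dropped": n_dropped,
        "unmapped": partition.n_unmapped,
    }
    return QuantResult(counts, int(library), fates, unique_map)
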