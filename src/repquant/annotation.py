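"""Repeat and gene annotation I/O.

Repeat annotations follow the three-level RepeatMasker taxonomy:
subfamily (e.g. L1PA2) < family (L1) < class (LINE). All internal
coordinates are 0-based half-open; conversion to/from the 1-based
inclusive RepeatMasker convention happens only at the parse/serialize
boundary.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence


@dataclass(frozen=True, slots=True)
class RepeatInstance:
    """One annotated genomic copy of a repeat subfamily."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # "+" or "-"
    subfamily: str
    family: str
    repclass: str
    instance_id: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.subfamily}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


# Characters that cannot appear in per-subfamily output filenames.
_UNSAFE = re.compile(r"[/\\:*?\"<>|\s]")


def sanitize_name(name: str) -> str:
    """Deterministically replace filename-unsafe characters with '_'."""
    return _UNSAFE.sub("_", name)


class RepeatHierarchy:
    """Mapping subfamily -> (family, class), plus per-subfamily instance counts.

    Also records the sanitized (filename-safe) name for each subfamily,
    used to name per-subfamily pseudogenome files.
    """

    def __init__(
        self,
        mapping: Mapping[str, tuple[str, str]],
        n_instances: Mapping[str, int] | None = None,
    ) -> None:
        self._map = dict(mapping)
        self._n = Counter(n_instances or {})
        self._safe: dict[str, str] = {}
        used: set[str] = set()
        for sub in sorted(self._map):
            safe = sanitize_name(sub)
            while safe in used:  # collision after substitution
                safe += "_"
            used.add(safe)
            self._safe[sub] = safe

    @classmethod
    def from_instances(cls, instances: Iterable[RepeatInstance]) -> "RepeatHierarchy":
        mapping: dict[str, tuple[str, str]] = {}
        counts: Counter[str] = Counter()
        for inst in instances:
            pair = (inst.family, inst.repclass)
            prev = mapping.setdefault(inst.subfamily, pair)
            if prev != pair:
                raise ValueError(
                    f"subfamily {inst.subfamily!r} maps to both {prev} and {pair}"
                )
            counts[inst.subfamily] += 1
        return cls(mapping, counts)

    @property
    def subfamilies(self) -> list[str]:
        return sorted(self._map)

    def family_of(self, subfamily: str) -> str:
        return self._map[subfamily][0]

    def class_of(self, subfamily: str) -> str:
        return self._map[subfamily][1]

    def n_instances(self, subfamily: str) -> int:
        return self._n[subfamily]

    def safe_name(self, subfamily: str) -> str:
        return self._safe[subfamily]

    def __contains__(self, subfamily: str) -> bool:
        return subfamily in self._map

    def __len__(self) -> int:
        return len(self._map)


class RepeatMaskerParseError(ValueError):
    pass


def parse_repeatmasker(path: str | Path) -> tuple[list[RepeatInstance], RepeatHierarchy]:
    """Parse a RepeatMasker ``.out`` file.

    The format has 3 header lines followed by whitespace-delimited
    records. Query begin/end are 1-based inclusive; the strand column is
    "+" or "C" (complement); the class/family column is "class/family"
    or bare "class" (family then defaults to the class name).
    """
    instances: list[RepeatInstance] = []
    with open(path) as fh:
        lines = fh.readlines()
    next_id = 0
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        tokens = line.split()
        if len(tokens) < 14:
            raise RepeatMaskerParseError(
                f"line {lineno}: expected >=14 whitespace-delimited columns, "
                f"got {len(tokens)}"
            )
        try:
            begin = int(tokens[5])
            end = int(tokens[6])
        except ValueError as exc:
            raise RepeatMaskerParseError(
                f"line {lineno}: non-integer query coordinates"
            ) from exc
        if begin > end:
            raise RepeatMaskerParseError(f"line {lineno}: query begin > end")
        strand_tok = tokens[8]
        if strand_tok == "+":
            strand = "+"
        elif strand_tok in ("C", "-"):
            strand = "-"
        else:
            raise RepeatMaskerParseError(
                f"line {lineno}: unrecognized strand column {strand_tok!r}"
            )
        clsfam = tokens[10]
        repclass, _, family = clsfam.partition("/")
        family = family or repclass
        instances.append(
            RepeatInstance(
                chrom=tokens[4],
                start=begin - 1,
                end=end,
                strand=strand,
                subfamily=tokens[9],
                family=family,
                repclass=repclass,
                instance_id=next_id,
            )
        )
        next_id += 1
    return instances, RepeatHierarchy.from_instances(instances)


DEFAULT_EXCLUDED_CLASSES = frozenset({"Simple_repeat"})


def filter_repeat_classes(
    instances: Sequence[RepeatInstance],
    excluded_classes: Iterable[str] = DEFAULT_EXCLUDED_CLASSES,
) -> list[RepeatInstance]:
    """Drop instances whose class is excluded (default: simple sequence
    repeats), preserving order."""
    excluded = set(excluded_classes)
    return [inst for inst in instances if inst.repclass not in excluded]


def write_bed(instances: Iterable[RepeatInstance], path: str | Path) -> None:
    """Write instances as 6-column BED (name column = subfamily)."""
    with open(path, "w") as fh:
        for inst in instances:
            fh.write(
                f"{inst.chrom}\t{inst.start}\t{inst.end}\t{inst.subfamily}\t0\t{inst.strand}\n"
            )


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) triples from a BED file (>=3 columns)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def read_custom_annotation(
    bed_path: str | Path, class_table_path: str | Path
) -> tuple[list[RepeatInstance], RepeatHierarchy]:
    """Read a custom repeat annotation: BED6 with the subfamily in the
    name column, plus a 2-column sidecar TSV mapping subfamily to
    "class/family" (or bare class)."""
    mapping: dict[str, tuple[str, str]] = {}
    with open(class_table_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sub, clsfam = line.rstrip("\n").split("\t")[:2]
            repclass, _, family = clsfam.partition("/")
            mapping[sub] = (family or repclass, repclass)
    instances: list[RepeatInstance] = []
    with open(bed_path) as fh:
        next_id = 0
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            sub = f[3]
            if sub not in mapping:
                raise KeyError(f"subfamily {sub!r} missing from class table")
            family, repclass = mapping[sub]
            instances.append(
                RepeatInstance(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[5] if len(f) > 5 else "+",
                    subfamily=sub,
                    family=family,
                    repclass=repclass,
                    instance_id=next_id,
                )
            )
            next_id += 1
    return instances, RepeatHierarchy.from_instances(instances)
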