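"""Per-subfamily pseudogenome construction.

A pseudogenome concatenates every annotated genomic copy of one repeat
subfamily — each extracted on the genomic plus strand with a small
flank — separated by runs of spacer characters (N by default) so that
no read can align across the junction between two copies. These
sequences are the alignment target for multi-mapping reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._genome import contig_length, fetch
from .annotation import RepeatHierarchy, RepeatInstance


@dataclass(frozen=True, slots=True)
class PseudogenomeConfig:
    flank_bp: int = 15
    spacer_bp: int = 200
    spacer_char: str = "N"

    def __post_init__(self) -> None:
        if self.flank_bp < 0 or self.spacer_bp < 0:
            raise ValueError("flank_bp and spacer_bp must be >= 0")
        if len(self.spacer_char) != 1:
            raise ValueError("spacer_char must be a single character")


@dataclass
class Pseudogenome:
    subfamily: str
    sequence: str
    # (instance_id, start, end) spans of each extracted segment
    offsets: list[tuple[int, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


def extract_with_flank(genome, instance: RepeatInstance, flank_bp: int) -> str:
    """Extract the instance plus up to ``flank_bp`` of genomic flank on
    each side, clamped at contig boundaries, on the plus strand."""
    clen = contig_length(genome, instance.chrom)
    lo = max(0, instance.start - flank_bp)
    hi = min(clen, instance.end + flank_bp)
    return fetch(genome, instance.chrom, lo, hi)


def build_pseudogenome(
    instances: Sequence[RepeatInstance],
    genome,
    config: PseudogenomeConfig = PseudogenomeConfig(),
) -> Pseudogenome:
    """Concatenate all instances of one subfamily, in annotation order,
    with spacer between consecutive segments."""
    if not instances:
        raise ValueError("cannot build a pseudogenome from zero instances")
    subfamily = instances[0].subfamily
    if any(inst.subfamily != subfamily for inst in instances):
        raise ValueError("all instances must belong to the same subfamily")
    spacer = config.spacer_char * config.spacer_bp
    parts: list[str] = []
    offsets: list[tuple[int, int, int]] = []
    cursor = 0
    for i, inst in enumerate(instances):
        if i > 0:
            parts.append(spacer)
            cursor += config.spacer_bp
        seg = extract_with_flank(genome, inst, config.flank_bp)
        parts.append(seg)
        offsets.append((inst.instance_id, cursor, cursor + len(seg)))
        cursor += len(seg)
    return Pseudogenome(subfamily=subfamily, sequence="".join(parts), offsets=offsets)


def build_pseudogenome_set(
    instances: Iterable[RepeatInstance],
    genome,
    config: PseudogenomeConfig = PseudogenomeConfig(),
) -> dict[str, Pseudogenome]:
    """One in-memory pseudogenome per subfamily (annotation order within
    each subfamily), keyed by subfamily name, sorted for determinism."""
    by_sub: dict[str, list[RepeatInstance]] = {}
    for inst in instances:
        by_sub.setdefault(inst.subfamily, []).append(inst)
    return {
        sub: build_pseudogenome(by_sub[sub], genome, config) for sub in sorted(by_sub)
    }


def pseudogenome_sequences(pgs: Mapping[str, Pseudogenome]) -> dict[str, str]:
    return {sub: pg.sequence for sub, pg in pgs.items()}


def build_all_pseudogenomes(
    instances: Iterable[RepeatInstance],
    genome,
    config: PseudogenomeConfig,
    out_dir: str | Path,
    hierarchy: RepeatHierarchy | None = None,
):
    """Write one FASTA per subfamily plus a TSV manifest.

    Returns the manifest as a list of (subfamily, filename, n_instances,
    length) rows, in sorted subfamily order. Deterministic: re-running
    with identical inputs produces byte-identical files.
    """
    import pandas as pd

    instances = list(instances)
    if hierarchy is None:
        hierarchy = RepeatHierarchy.from_instances(instances)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pgs = build_pseudogenome_set(instances, genome, config)
    rows = []
    for sub, pg in pgs.items():
        safe = hierarchy.safe_name(sub)
        fname = f"{safe}.fa"
        with open(out_dir / fname, "w") as fh:
            fh.write(f">{sub}\n")
            seq = pg.sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
        rows.append((sub, fname, len(pg.offsets), len(pg)))
    manifest = pd.DataFrame(
        rows, columns=["subfamily", "file", "n_instances", "length"]
    )
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
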