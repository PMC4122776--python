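"""Synthetic toy genomes with planted repeat landscapes, and the
brute-force alignment oracle.

The generator emulates, at desk scale, the structure the counting
pipeline faces on a real genome: repeat subfamilies with many diverged
genomic copies, and homology groups of subfamilies derived from a
shared ancestral consensus (the situation that produces reads mapping
to several subfamilies at once, as with recent primate LINE-1
subfamilies). Mutations are substitutions only, which keeps the
Hamming-distance oracle exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import Placement, encode, revcomp
from .annotation import RepeatHierarchy, RepeatInstance

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SubfamilySpec:
    """One planted subfamily.

    ``homology_group``: subfamilies sharing a group name derive their
    consensus from a common ancestral sequence, each mutated at
    ``group_divergence`` (sibling consensuses are then ~2x that apart).
    ``copy_divergence`` is the per-copy substitution rate from the
    subfamily consensus.
    """

    name: str
    family: str
    repclass: str
    consensus_length: int
    n_copies: int
    copy_divergence: float = 0.02
    homology_group: str | None = None
    group_divergence: float = 0.05
    contig: str | None = None  # default: first contig

    def __post_init__(self) -> None:
        if not (0 <= self.copy_divergence < 0.5) or not (0 <= self.group_divergence < 0.5):
            raise ValueError("divergence rates must be in [0, 0.5)")


@dataclass
class FixtureConfig:
    contigs: dict[str, int] = field(default_factory=lambda: {"chrT": 30_000})
    subfamilies: list[SubfamilySpec] = field(default_factory=list)
    gene_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    gc: float = 0.5
    min_gap: int = 100
    seed: int = 0


@dataclass
class ToyGenome:
    genome: dict[str, str]
    instances: list[RepeatInstance]
    hierarchy: RepeatHierarchy
    consensus: dict[str, str]
    gene_intervals: list[tuple[str, int, int]]
    config: FixtureConfig

    def write_genome(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in self.genome:
                fh.write(f">{name}\n")
                seq = self.genome[name]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def write_consensus(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.consensus):
                fh.write(f">{name}\n{self.consensus[name]}\n")

    def write_genes_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self.gene_intervals:
                fh.write(f"{chrom}\t{s}\t{e}\tgene\t0\t+\n")

    def write_repeatmasker(self, path: str | Path) -> None:
        """Emit the planted annotation in RepeatMasker .out layout."""
        header = (
            "   SW  perc perc perc  query     position in query     matching"
            "  repeat           position in repeat\n"
            "score  div. del. ins.  sequence  begin  end    (left)  repeat"
            "           class/family     begin  end    (left)  ID\n"
            "\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for inst in self.instances:
                strand = "+" if inst.strand == "+" else "C"
                clsfam = (
                    inst.repclass
                    if inst.family == inst.repclass
                    else f"{inst.repclass}/{inst.family}"
                )
                fh.write(
                    f"  500  5.0  0.0  0.0  {inst.chrom}  {inst.start + 1}  {inst.end}"
                    f"  (0)  {strand}  {inst.subfamily}  {clsfam}  1  {inst.length}"
                    f"  (0)  {inst.instance_id + 1}\n"
                )


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    hit = rng.random(codes.size) < rate
    shift = rng.integers(1, 4, size=int(hit.sum()))
    out[hit] = (out[hit] + shift) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def make_toy_genome(config: FixtureConfig) -> ToyGenome:
    """Generate a toy genome with planted repeat copies at recorded
    coordinates. Deterministic given the config (including its seed)."""
    rng = np.random.default_rng(config.seed)
    contig_names = list(config.contigs)
    if not contig_names:
        raise ValueError("config must define at least one contig")

    # subfamily consensuses (homology groups share a mutated ancestor)
    consensus: dict[str, np.ndarray] = {}
    groups: dict[str, list[SubfamilySpec]] = {}
    for spec in config.subfamilies:
        if spec.homology_group is not None:
            groups.setdefault(spec.homology_group, []).append(spec)
    parents = {
        g: _random_seq(rng, max(s.consensus_length for s in members), config.gc)
        for g, members in sorted(groups.items())
    }
    for spec in config.subfamilies:
        if spec.homology_group is not None:
            parent = parents[spec.homology_group][: spec.consensus_length]
            consensus[spec.name] = _mutate(parent, spec.group_divergence, rng)
        else:
            consensus[spec.name] = _random_seq(rng, spec.consensus_length, config.gc)

    # draw copies and place them per contig
    copies_by_contig: dict[str, list[tuple[SubfamilySpec, np.ndarray, str]]] = {
        c: [] for c in contig_names
    }
    for spec in config.subfamilies:
        contig = spec.contig or contig_names[0]
        if contig not in config.contigs:
            raise ValueError(f"unknown contig {contig!r} for {spec.name}")
        for _ in range(spec.n_copies):
            copy = _mutate(consensus[spec.name], spec.copy_divergence, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            copies_by_contig[contig].append((spec, copy, strand))

    genome: dict[str, str] = {}
    instances: list[RepeatInstance] = []
    next_id = 0
    for contig in contig_names:
        clen = config.contigs[contig]
        copies = copies_by_contig[contig]
        order = rng.permutation(len(copies))
        copies = [copies[i] for i in order]
        total_copy = sum(c.size for _, c, _ in copies)
        slack = clen - total_copy - config.min_gap * (len(copies) + 1)
        if slack < 0:
            raise ValueError(f"copies do not fit on contig {contig!r}")
        extra = (
            rng.multinomial(slack, np.full(len(copies) + 1, 1 / (len(copies) + 1)))
            if copies
            else np.array([slack])
        )
        gaps = extra + config.min_gap
        parts: list[np.ndarray] = []
        cursor = 0
        placed: list[tuple[SubfamilySpec, int, int, str]] = []
        for i, (spec, copy, strand) in enumerate(copies):
            g = _random_seq(rng, int(gaps[i]), config.gc)
            parts.append(g)
            cursor += g.size
            inserted = copy if strand == "+" else encode(revcomp(_decode(copy)))
            parts.append(inserted)
            placed.append((spec, cursor, cursor + inserted.size, strand))
            cursor += inserted.size
        parts.append(_random_seq(rng, int(gaps[-1]) if copies else clen, config.gc))
        genome[contig] = _decode(np.concatenate(parts))
        assert len(genome[contig]) == clen
        for spec, s, e, strand in placed:  # coordinate order == annotation order
            instances.append(
                RepeatInstance(
                    chrom=contig, start=s, end=e, strand=strand,
                    subfamily=spec.name, family=spec.family,
                    repclass=spec.repclass, instance_id=next_id,
                )
            )
            next_id += 1

    hierarchy = RepeatHierarchy.from_instances(instances) if instances else RepeatHierarchy({})
    return ToyGenome(
        genome=genome,
        instances=instances,
        hierarchy=hierarchy,
        consensus={k: _decode(v) for k, v in consensus.items()},
        gene_intervals=list(config.gene_intervals),
        config=config,
    )


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_align(
    reads: Mapping[str, str] | Iterable[tuple[str, str]],
    targets: Mapping[str, str],
    max_mismatch: int = 2,
) -> dict[str, list[Placement]]:
    """Exhaustive scan: every (target, position, strand) placement of
    each read with Hamming distance <= max_mismatch. Substitutions
    only; ambiguity characters never match. Deterministic
    (target, pos, strand) ordering. Oracle for the production matcher —
    intended for test-scale inputs only."""
    read_items = list(reads.items()) if isinstance(reads, Mapping) else list(reads)
    enc_targets = {name: encode(seq) for name, seq in targets.items()}
    out: dict[str, list[Placement]] = {}
    for rid, seq in read_items:
        hits: list[Placement] = []
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            enc_r = encode(oriented)
            L = enc_r.size
            for name, enc_t in enc_targets.items():
                n = enc_t.size
                if L > n:
                    continue
                mm = np.zeros(n - L + 1, dtype=np.int32)
                for j in range(L):
                    col = enc_t[j : j + n - L + 1]
                    mm += (col != enc_r[j]) | (col > 3) | (enc_r[j] > 3)
                for p in np.flatnonzero(mm <= max_mismatch):
                    hits.append(Placement(name, int(p), strand, int(mm[p])))
        hits.sort()
        out[rid] = hits
    return out
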