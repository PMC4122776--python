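"""Uniform access to genome sequences.

Accepts either an in-memory mapping of contig name -> sequence string
or a ``pyfaidx.Fasta`` handle (random access over an indexed FASTA).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping


def open_genome(path_or_mapping) -> object:
    """Return a genome handle. Strings/paths are opened with pyfaidx."""
    if isinstance(path_or_mapping, (str, Path)):
        import pyfaidx

        return pyfaidx.Fasta(str(path_or_mapping))
    return path_or_mapping


def contig_length(genome, chrom: str) -> int:
    try:
        return len(genome[chrom])
    except KeyError as exc:
        raise KeyError(f"contig {chrom!r} not present in genome") from exc


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end] as an uppercase plus-strand string."""
    try:
        seg = genome[chrom][start:end]
    except KeyError as exc:
        raise KeyError(f"contig {chrom!r} not present in genome") from exc
    return str(seg).upper()


def contig_names(genome) -> list[str]:
    if isinstance(genome, Mapping):
        return list(genome)
    return list(genome.keys())
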