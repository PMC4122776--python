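"""HMM ChIP-seq read simulator and counting-strategy evaluation.

A two-state (low/high) Markov chain walks base-by-base along a contig;
inside user-supplied feature intervals it follows a transition matrix
that favours the high-emission state, elsewhere a background matrix
that favours the low state. Each base draws a nonnegative sampling
weight from a state-specific Normal (high mean 3.0, sd 0.1 by default),
and read start positions are drawn from the categorical distribution
proportional to those weights. Because the simulator records the true
start coordinate of every read, per-subfamily "true abundance" counts
can be computed and used as a benchmark for the counting strategies.

Replicate r re-draws the hidden path and emissions with seed base + r,
which is how technical variance between replicates is introduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._genome import contig_length, fetch
from .align import revcomp
from .annotation import RepeatInstance
from .counting import build_instance_trees, overlapping_subfamilies

# State indices
LOW, HIGH = 0, 1


def _check_stochastic(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (2, 2) or not np.allclose(mat.sum(axis=1), 1.0):
        raise ValueError(f"{name} must be a 2x2 row-stochastic matrix")
    if (mat < 0).any():
        raise ValueError(f"{name} has negative entries")
    return mat


@dataclass
class HMMConfig:
    """Two-state chain parameters.

    Rows/columns are ordered (low, high). Defaults: the background
    matrix strongly favours the low state with short, rare high-state
    excursions (background signal variability); the feature matrix
    yields predominant occupancy of the high-emission state
    (mean 3.0 +/- sd 0.1) over enriched features.
    """

    background_transition: np.ndarray = field(
        default_factory=lambda: np.array([[0.999, 0.001], [0.20, 0.80]])
    )
    feature_transition: np.ndarray = field(
        default_factory=lambda: np.array([[0.10, 0.90], [0.01, 0.99]])
    )
    emission_mean: tuple[float, float] = (1.0, 3.0)  # (low, high)
    emission_sd: tuple[float, float] = (0.1, 0.1)

    def __post_init__(self) -> None:
        self.background_transition = _check_stochastic(
            self.background_transition, "background_transition"
        )
        self.feature_transition = _check_stochastic(
            self.feature_transition, "feature_transition"
        )
        if min(self.emission_sd) < 0:
            raise ValueError("emission_sd must be >= 0")


def stationary_high_occupancy(transition: np.ndarray) -> float:
    """Stationary P(high) of a 2-state chain: a/(a+b) with
    a = P(low->high), b = P(high->low)."""
    a = transition[LOW, HIGH]
    b = transition[HIGH, LOW]
    if a + b == 0:
        raise ValueError("degenerate chain with a = b = 0")
    return a / (a + b)


@dataclass
class EmissionProfile:
    contig: str
    weights: np.ndarray  # per-bp sampling weight, >= 0
    states: np.ndarray  # hidden path, uint8
    feature_intervals: list[tuple[int, int]]


def simulate_emission_profile(
    contig_length_bp: int,
    feature_intervals: Sequence[tuple[int, int]],
    config: HMMConfig,
    seed: int,
    contig: str = "chr",
) -> EmissionProfile:
    """Walk the chain along the contig and draw per-bp weights."""
    feats = sorted((int(s), int(e)) for s, e in feature_intervals)
    in_feature = np.zeros(contig_length_bp, dtype=bool)
    for s, e in feats:
        if s < 0 or e > contig_length_bp or s >= e:
            raise ValueError(f"feature [{s}, {e}) outside contig")
        in_feature[s:e] = True
    rng = np.random.default_rng(seed)
    u = rng.random(contig_length_bp)
    # P(next = high | state) per matrix
    bg_high = config.background_transition[:, HIGH]
    ft_high = config.feature_transition[:, HIGH]
    states = np.zeros(contig_length_bp, dtype=np.uint8)
    state = LOW
    for i in range(contig_length_bp):
        p_high = ft_high[state] if in_feature[i] else bg_high[state]
        state = HIGH if u[i] < p_high else LOW
        states[i] = state
    means = np.asarray(config.emission_mean)[states]
    sds = np.asarray(config.emission_sd)[states]
    weights = np.maximum(rng.normal(means, sds), 0.0)
    return EmissionProfile(contig, weights, states, feats)


@dataclass
class SimulatedReadSet:
    """Reads drawn from an emission profile, with their true coordinates."""

    truth: pd.DataFrame  # read_id, chrom, start, strand, replicate
    sequences: list[str]
    read_length: int
    replicate: int = 0

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in zip(self.truth["read_id"], self.sequences):
                fh.write(f">{rid}\n{seq}\n")

    def write_truth_tsv(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def write_fastq(self, path: str | Path, quality_char: str = "I") -> None:
        """Constant-quality FASTQ output (base calls are error-free)."""
        with open(path, "w") as fh:
            for rid, seq in zip(self.truth["read_id"], self.sequences):
                fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")

    def write_sam(self, path: str | Path, contig_len: int) -> None:
        """Emit the true alignments as a SAM file."""
        chrom = self.truth["chrom"].iloc[0] if len(self.truth) else "chr"
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            fh.write(f"@SQ\tSN:{chrom}\tLN:{contig_len}\n")
            for (_, row), seq in zip(self.truth.iterrows(), self.sequences):
                flag = 16 if row["strand"] == "-" else 0
                out_seq = revcomp(seq) if row["strand"] == "-" else seq
                fh.write(
                    f"{row['read_id']}\t{flag}\t{row['chrom']}\t{row['start'] + 1}\t255"
                    f"\t{self.read_length}M\t*\t0\t0\t{out_seq}\t*\n"
                )

    def reads(self) -> Iterable[tuple[str, int, str]]:
        """(read_id, mate, sequence) triples for the counting pipeline."""
        for rid, seq in zip(self.truth["read_id"], self.sequences):
            yield rid, 0, seq


def sample_reads(
    profile: EmissionProfile,
    genome,
    n_reads: int,
    read_length: int,
    seed: int,
    replicate: int = 0,
) -> SimulatedReadSet:
    """Draw read start positions proportional to the emission weights
    (restricted to starts where the read fits), extract sequences from
    the genome, and assign strands uniformly at random. Base calls are
    error-free; minus-strand reads are reverse-complemented."""
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    clen = contig_length(genome, profile.contig)
    if read_length > clen:
        raise ValueError("read_length exceeds contig length")
    w = profile.weights[: clen - read_length + 1]
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero emission profile")
    rng = np.random.default_rng(seed)
    starts = rng.choice(w.size, size=n_reads, p=w / total)
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")
    contig_seq = fetch(genome, profile.contig, 0, clen)
    seqs = []
    for s, st in zip(starts, strands):
        seq = contig_seq[s : s + read_length]
        seqs.append(revcomp(seq) if st == "-" else seq)
    truth = pd.DataFrame(
        {
            "read_id": [f"rep{replicate}_read{i}" for i in range(n_reads)],
            "chrom": profile.contig,
            "start": starts.astype(int),
            "strand": strands,
            "replicate": replicate,
        }
    )
    return SimulatedReadSet(truth, seqs, read_length, replicate)


def simulate_replicates(
    genome,
    contig: str,
    feature_intervals: Sequence[tuple[int, int]],
    config: HMMConfig,
    n_reads: int,
    read_length: int,
    n_replicates: int,
    seed: int,
) -> list[SimulatedReadSet]:
    """Technical replicates: replicate r re-draws the hidden path and
    emissions with seed ``seed + r``."""
    clen = contig_length(genome, contig)
    out = []
    for r in range(n_replicates):
        profile = simulate_emission_profile(
            clen, feature_intervals, config, seed + r, contig
        )
        out.append(
            sample_reads(profile, genome, n_reads, read_length, seed + r, replicate=r)
        )
    return out


# ---------------------------------------------------------------------------
# truth benchmark and evaluation metrics


def true_abundance(
    truth: pd.DataFrame,
    read_length: int,
    instances: Sequence[RepeatInstance] | Mapping,
    subfamilies: Sequence[str] | None = None,
) -> pd.Series:
    """Benchmark counts from the simulator's true coordinates: each
    read's true interval [start, start+len) is tested for >=1 bp overlap
    with annotated instances (the same rule used for uniquely-mapped
    reads) and contributes one count to every overlapped subfamily."""
    trees = (
        instances if isinstance(instances, Mapping) else build_instance_trees(instances)
    )
    counts: dict[str, int] = {}
    for chrom, start in zip(truth["chrom"], truth["start"]):
        for sub in overlapping_subfamilies(trees, chrom, start, start + read_length):
            counts[sub] = counts.get(sub, 0) + 1
    if subfamilies is None:
        subfamilies = sorted(counts)
    return pd.Series(
        [counts.get(s, 0) for s in subfamilies],
        index=pd.Index(subfamilies, name="subfamily"),
        name="true_abundance",
    )


def average_log2cpm(
    counts: pd.DataFrame, library_sizes: pd.Series, prior_count: float = 0.5
) -> pd.Series:
    """log2 of the replicate-averaged CPM, with a +prior_count offset on
    counts before scaling to handle zeros."""
    lib = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    cpm = (counts + prior_count) * 1e6 / lib
    return np.log2(cpm.mean(axis=1))


def r_squared(true_vals, est_vals) -> float:
    """Identity-line R^2: 1 - SS_res/SS_tot of the estimate around the
    y = x line, clamped at 0."""
    x = np.asarray(true_vals, dtype=float)
    y = np.asarray(est_vals, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ss_res = np.sum((y - x) ** 2)
    ss_tot = np.sum((x - x.mean()) ** 2)
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return max(1.0 - ss_res / ss_tot, 0.0)


def r_squared_by_group(
    true_vals: pd.Series, est_vals: pd.Series, groups: pd.Series
) -> pd.Series:
    """Per-group identity-line R^2 (plus 'all'), zero-clamped."""
    est_vals = est_vals.reindex(true_vals.index)
    groups = groups.reindex(true_vals.index)
    out = {"all": r_squared(true_vals.values, est_vals.values)}
    for g, idx in true_vals.groupby(groups).groups.items():
        out[str(g)] = r_squared(true_vals[idx].values, est_vals[idx].values)
    return pd.Series(out)


def distance_matrix(vectors: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between labelled column vectors."""
    if vectors.isna().any().any():
        raise ValueError("NaN in input vectors")
    d = squareform(pdist(vectors.T.values, metric="euclidean"))
    return pd.DataFrame(d, index=vectors.columns, columns=vectors.columns)


# ---------------------------------------------------------------------------
# end-to-end strategy benchmark


@dataclass
class StrategyBenchmark:
    """Replicate-averaged log2CPM per strategy and against truth."""

    log2cpm: pd.DataFrame  # columns: unique, total, fractional, true
    distances: pd.DataFrame  # pairwise Euclidean
    r2_by_class: pd.DataFrame  # strategies x classes
    counts: dict[str, pd.DataFrame]  # strategy -> subfamily x replicate counts
    true_counts: pd.DataFrame
    library_sizes: dict[str, pd.Series]
    n_assigned: pd.Series | None = None  # repeat-assigned reads per replicate


def run_strategy_benchmark(
    genome,
    contig: str,
    instances: Sequence[RepeatInstance],
    hierarchy,
    feature_intervals: Sequence[tuple[int, int]],
    config: HMMConfig,
    n_reads: int,
    read_length: int,
    n_replicates: int,
    seed: int,
    max_mismatch: int = 2,
    pseudogenome_config=None,
) -> StrategyBenchmark:
    """Simulate replicates, quantify them with the internal matcher
    under all three strategies, and compare replicate-averaged log2CPM
    vectors with the true abundance."""
    from .align import KmerIndex
    from .counting import partition_with_matcher, quantify_sample
    from .pseudogenome import (
        PseudogenomeConfig,
        build_pseudogenome_set,
        pseudogenome_sequences,
    )

    pg_config = pseudogenome_config or PseudogenomeConfig()
    subfamilies = hierarchy.subfamilies
    trees = build_instance_trees(instances)
    genome_index = KmerIndex(
        {contig: fetch(genome, contig, 0, contig_length(genome, contig))},
        max_mismatch,
    )
    pg_index = KmerIndex(
        pseudogenome_sequences(build_pseudogenome_set(instances, genome, pg_config)),
        max_mismatch,
    )
    readsets = simulate_replicates(
        genome, contig, feature_intervals, config,
        n_reads, read_length, n_replicates, seed,
    )
    strat_cols = ("unique", "total", "fractional", "fractional_unrounded")
    est_counts: dict[str, dict[str, pd.Series]] = {s: {} for s in strat_cols}
    est_libs: dict[str, int] = {}
    n_assigned: dict[str, int] = {}
    true_cols: dict[str, pd.Series] = {}
    true_libs: dict[str, int] = {}
    for rs in readsets:
        rep = f"rep{rs.replicate}"
        part = partition_with_matcher(rs.reads(), genome_index, max_mismatch)
        res = quantify_sample(part, trees, pg_index, subfamilies, max_mismatch)
        for strat in strat_cols:
            est_counts[strat][rep] = res.counts[strat]
        est_libs[rep] = res.library_size
        n_assigned[rep] = len(res.read_map)
        true_cols[rep] = true_abundance(rs.truth, read_length, trees, subfamilies)
        true_libs[rep] = n_reads
    counts = {
        strat: pd.DataFrame(est_counts[strat]) for strat in est_counts
    }
    true_counts = pd.DataFrame(true_cols)
    est_lib_series = pd.Series(est_libs, dtype=float)
    true_lib_series = pd.Series(true_libs, dtype=float)
    log2cpm = pd.DataFrame(
        {
            strat: average_log2cpm(counts[strat], est_lib_series)
            for strat in ("unique", "total", "fractional")
        }
    )
    log2cpm["true"] = average_log2cpm(true_counts, true_lib_series)
    distances = distance_matrix(log2cpm)
    classes = pd.Series(
        {s: hierarchy.class_of(s) for s in subfamilies}, name="class"
    )
    r2 = pd.DataFrame(
        {
            strat: r_squared_by_group(log2cpm["true"], log2cpm[strat], classes)
            for strat in ("unique", "total", "fractional")
        }
    ).T
    return StrategyBenchmark(
        log2cpm=log2cpm,
        distances=distances,
        r2_by_class=r2,
        counts=counts,
        true_counts=true_counts,
        library_sizes={"estimated": est_lib_series, "true": true_lib_series},
        n_assigned=pd.Series(n_assigned),
    )
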