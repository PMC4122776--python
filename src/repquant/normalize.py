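"""Between-sample normalization of count tables.

Implements trimmed-mean-of-M-values (TMM) scaling factors with the
standard defaults (30% trim on M, 5% on A, weighted by the asymptotic
binomial variance), mirroring the canonical published procedure so that
factors agree with the reference implementation. Differential testing
itself (negative-binomial GLM, FDR) is deliberately delegated to
external packages; this module exports count tables and sample sheets
in a layout those tools consume directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import CountTable


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
    weighted: bool = True,
) -> float:
    """TMM factor of one sample against the reference sample."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[fin], a[fin], v[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().values
    rank_a = pd.Series(a).rank().values
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.nansum(m[keep] / v[keep]) / np.nansum(1.0 / v[keep])
    else:
        f = np.nanmean(m[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    library_sizes: pd.Series | Mapping[str, float] | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
    weighted: bool = True,
) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference sample (unless given) is the one whose 75th
    percentile of library-size-scaled counts is closest to the mean of
    those percentiles across samples. Zero-count features are excluded
    pairwise through the log-ratio computation.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("sample with all-zero counts")
    if library_sizes is None:
        lib = counts.sum(axis=0).astype(float)
    else:
        lib = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    x = counts.to_numpy(dtype=float)
    f75 = np.array(
        [np.quantile(x[:, j] / lib.iloc[j], 0.75) for j in range(x.shape[1])]
    )
    if reference is None:
        ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_j = counts.columns.get_loc(reference)
    factors = np.array(
        [
            _tmm_pair_factor(
                x[:, j], x[:, ref_j], lib.iloc[j], lib.iloc[ref_j],
                trim_m, trim_a, weighted,
            )
            for j in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


@dataclass
class NormalizedTable:
    """A CountTable with per-sample TMM factors; effective library size
    is library_size x factor."""

    table: CountTable
    factors: pd.Series

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.table.library_sizes * self.factors


def normalize(table: CountTable, **kwargs) -> NormalizedTable:
    return NormalizedTable(
        table, tmm_factors(table.counts, table.library_sizes, **kwargs)
    )


def normalized_log2fc(
    normalized: NormalizedTable,
    pairs: Sequence[tuple[str, str]],
    pseudocount_reads: float = 0.5,
    use_effective: bool = True,
) -> pd.DataFrame:
    """Per-feature log2FC for each (numerator, denominator) sample pair
    on the normalized scale: log2((y_t/L_t + c) / (y_n/L_n + c)).

    L is the effective (TMM-scaled) library size by default, or the raw
    library size with ``use_effective=False``. The pseudocount c
    corresponds to ``pseudocount_reads`` reads at the geometric-mean
    library size, making the offset symmetric across the pair.
    """
    lib = (
        normalized.effective_library_sizes
        if use_effective
        else normalized.table.library_sizes
    )
    counts = normalized.table.counts
    for a, b in pairs:
        for s in (a, b):
            if s not in counts.columns:
                raise KeyError(f"sample {s!r} not in table")
    c = pseudocount_reads / np.exp(np.mean(np.log(lib.astype(float))))
    out = {}
    for a, b in pairs:
        ra = counts[a] / lib[a] + c
        rb = counts[b] / lib[b] + c
        out[f"{a}_vs_{b}"] = np.log2(ra / rb)
    return pd.DataFrame(out)


def export_count_table(
    table: CountTable,
    path: str | Path,
    hierarchy=None,
    sample_sheet: pd.DataFrame | None = None,
    sample_sheet_path: str | Path | None = None,
) -> None:
    """Write a TSV of integer counts (subfamily, family, class, then one
    column per sample) plus an optional sample sheet, with byte-stable
    row/column ordering so re-export is reproducible."""
    df = table.counts.sort_index().copy()
    if hierarchy is not None:
        df.insert(0, "class", [hierarchy.class_of(s) for s in df.index])
        df.insert(0, "family", [hierarchy.family_of(s) for s in df.index])
    df.to_csv(path, sep="\t")
    if sample_sheet is not None:
        if sample_sheet_path is None:
            sample_sheet_path = Path(path).with_suffix(".samples.tsv")
        sample_sheet.to_csv(sample_sheet_path, sep="\t", index=False)
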