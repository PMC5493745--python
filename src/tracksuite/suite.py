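"""Integrative statistics over suites of tracks.

Hierarchy on top of the pairwise statistic T:

* Q — per-track combination of T values against the rest of a suite
  (mean form: Q_i = (1/(n-1)) * sum_{j != i} T(A_i, A_j));
* R — whole-suite combination of Q values (mean/mean form:
  R = (1/n) * sum_i Q_i);
* cross-suite matrices of T for every pair across two suites;
* binned occurrence / co-occurrence aggregation over genome regions;
* the higher-order coverage-depth count (bp covered by >= k tracks), which is
  not decomposable into pairwise computations and is computed by a boundary
  sweep.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .pairwise import DegenerateMarginError, get_statistic
from .tracks import (
    BinSpec,
    Track,
    contingency_in_bin,
    contingency_table,
    coverage_in_bin,
)

AGGREGATORS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": lambda v: float(np.mean(v)),
    "max": lambda v: float(np.max(v)),
    "min": lambda v: float(np.min(v)),
}


def get_aggregator(kind: str) -> Callable[[np.ndarray], float]:
    try:
        return AGGREGATORS[kind]
    except KeyError:
        raise KeyError(
            f"unknown aggregator {kind!r}; choose from {tuple(AGGREGATORS)}"
        ) from None


def _resolve_stat(stat) -> Callable:
    return get_statistic(stat) if isinstance(stat, str) else stat


def rank_descending(values: Sequence[float], labels: Sequence[str]
                    ) -> np.ndarray:
    """Rank 1 = largest value; ties get the average rank.

    NaN values (failed statistics) sink to the bottom.
    """
    v = np.asarray(values, dtype=float)
    filled = np.where(np.isnan(v), -np.inf, v)
    return rankdata(-filled, method="average")


@dataclass
class SuiteAnalysisResult:
    """Per-track values and ranks for one suite-level analysis."""

    labels: list[str]
    values: list[float]
    ranks: list[float]
    stat_name: str
    aggregator: str | None = None
    suite_value: float | None = None
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def per_track_values(self) -> dict[str, float]:
        return dict(zip(self.labels, self.values))

    @property
    def per_track_ranks(self) -> dict[str, float]:
        return dict(zip(self.labels, self.ranks))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "label": self.labels,
            "value": self.values,
            "rank": self.ranks,
        })
        # stable output: by rank, label-lexicographic within ties
        return df.sort_values(["rank", "label"], kind="stable").reset_index(drop=True)


def pairwise_matrix(tracks: Sequence[Track], stat="forbes") -> np.ndarray:
    """Symmetric n x n matrix of T over a suite; diagonal is NaN."""
    fn = _resolve_stat(stat)
    n = len(tracks)
    M = np.full((n, n), np.nan)
    for i, j in itertools.combinations(range(n), 2):
        M[i, j] = M[j, i] = float(fn(contingency_table(tracks[i], tracks[j])))
    return M


def q_statistic(i: int, tracks: Sequence[Track], stat="forbes",
                agg: str = "mean",
                _matrix: np.ndarray | None = None) -> float:
    """Q_i: aggregate of T(A_i, A_j) over all j != i."""
    if len(tracks) < 2:
        raise ValueError("Q statistic requires at least 2 tracks")
    if _matrix is not None:
        row = np.delete(_matrix[i], i)
    else:
        fn = _resolve_stat(stat)
        row = np.array([
            float(fn(contingency_table(tracks[i], tracks[j])))
            for j in range(len(tracks)) if j != i
        ])
    return get_aggregator(agg)(row)


def q_statistics(tracks: Sequence[Track], stat="forbes", agg: str = "mean"
                 ) -> SuiteAnalysisResult:
    """Q for every track of the suite, with descending ranks."""
    if len(tracks) < 2:
        raise ValueError("Q statistics require at least 2 tracks")
    M = pairwise_matrix(tracks, stat)
    values = [q_statistic(i, tracks, stat, agg, _matrix=M)
              for i in range(len(tracks))]
    labels = [t.label for t in tracks]
    return SuiteAnalysisResult(
        labels=labels, values=values,
        ranks=list(rank_descending(values, labels)),
        stat_name=stat if isinstance(stat, str) else getattr(stat, "__name__", "custom"),
        aggregator=agg,
    )


def r_statistic(tracks: Sequence[Track], stat="forbes",
                agg_inner: str = "mean", agg_outer: str = "mean") -> float:
    """R: aggregate of the Q values over the whole suite."""
    if len(tracks) < 2:
        raise ValueError("R statistic requires at least 2 tracks")
    M = pairwise_matrix(tracks, stat)
    qs = np.array([
        q_statistic(i, tracks, stat, agg_inner, _matrix=M)
        for i in range(len(tracks))
    ])
    return get_aggregator(agg_outer)(qs)


def query_vs_suite(query: Track, tracks: Sequence[Track], stat="forbes"
                   ) -> SuiteAnalysisResult:
    """T(query, A_j) for each suite track, ranked descending (rank 1 = most
    similar).  Per-track statistic failures are recorded, not raised."""
    if not tracks:
        raise ValueError("suite must contain at least 1 track")
    fn = _resolve_stat(stat)
    labels = [t.label for t in tracks]
    values: list[float] = []
    errors: dict[str, str] = {}
    for t in tracks:
        try:
            values.append(float(fn(contingency_table(query, t))))
        except DegenerateMarginError as err:
            values.append(float("nan"))
            errors[t.label] = str(err)
    return SuiteAnalysisResult(
        labels=labels, values=values,
        ranks=list(rank_descending(values, labels)),
        stat_name=stat if isinstance(stat, str) else getattr(stat, "__name__", "custom"),
        errors=errors,
    )


@dataclass
class CrossSuiteMatrix:
    rows: list[str]
    cols: list[str]
    values: np.ndarray  # n1 x n2, NaN where the statistic failed
    stat_name: str
    errors: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def row_means(self) -> np.ndarray:
        return np.nanmean(self.values, axis=1)

    @property
    def col_means(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)

    @property
    def grand_mean(self) -> float:
        return float(np.nanmean(self.values))

    def double_centered(self) -> np.ndarray:
        """value - rowmean - colmean + grandmean (sums to 0 when complete)."""
        return (self.values - self.row_means[:, None]
                - self.col_means[None, :] + self.grand_mean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.rows, columns=self.cols)

    def to_heatmap(self, path: str) -> None:
        """Optional PNG/PDF heatmap export (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, 0.5 * len(self.cols)),
                     max(3, 0.5 * len(self.rows))))
        im = ax.imshow(self.values, aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(self.cols)), self.cols, rotation=90)
        ax.set_yticks(range(len(self.rows)), self.rows)
        fig.colorbar(im, ax=ax, label=self.stat_name)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def cross_suite_matrix(tracks1: Sequence[Track], tracks2: Sequence[Track],
                       stat="forbes") -> CrossSuiteMatrix:
    """Full n1 x n2 matrix of T across two suites."""
    if not tracks1 or not tracks2:
        raise ValueError("both suites must be non-empty")
    fn = _resolve_stat(stat)
    values = np.full((len(tracks1), len(tracks2)), np.nan)
    errors: dict[tuple[str, str], str] = {}
    for i, a in enumerate(tracks1):
        for j, b in enumerate(tracks2):
            try:
                values[i, j] = float(fn(contingency_table(a, b)))
            except DegenerateMarginError as err:
                errors[(a.label, b.label)] = str(err)
    return CrossSuiteMatrix(
        rows=[t.label for t in tracks1], cols=[t.label for t in tracks2],
        values=values,
        stat_name=stat if isinstance(stat, str) else getattr(stat, "__name__", "custom"),
        errors=errors,
    )


@dataclass
class BinnedResult:
    """Per-bin aggregated values with descending ranks."""

    bin_names: list[str]
    values: list[float]  # aggregated per-bin value (fractions / statistic)
    raw_bp: list[float] | None
    ranks: list[float]
    mode: str
    missing_pairs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin": self.bin_names, "value": self.values,
                           "rank": self.ranks})
        if self.raw_bp is not None:
            df["raw_bp"] = self.raw_bp
        return df.sort_values(["rank", "bin"], kind="stable").reset_index(drop=True)


def binned_occurrence(tracks: Sequence[Track], bins: BinSpec,
                      agg: str = "mean") -> BinnedResult:
    """Per-bin aggregate of per-track coverage fractions within the bin."""
    if len(bins) == 0:
        raise ValueError("empty bin specification")
    if not tracks:
        raise ValueError("suite must be non-empty")
    agg_fn = get_aggregator(agg)
    names, values, raw = [], [], []
    for name, seg in bins:
        cov = np.array([coverage_in_bin(t, seg) for t in tracks], dtype=float)
        names.append(name)
        values.append(agg_fn(cov / seg.length))
        raw.append(float(cov.sum()))
    return BinnedResult(bin_names=names, values=values, raw_bp=raw,
                        ranks=list(rank_descending(values, names)),
                        mode="occurrence")


def binned_cooccurrence(tracks: Sequence[Track], bins: BinSpec,
                        stat="jaccard", agg: str = "mean") -> BinnedResult:
    """Per-bin aggregate of the pairwise statistic over all unordered pairs,
    with the bin itself as the universe (bin length replaces N).

    Pairs with degenerate margins inside a bin are recorded as missing and
    excluded from the aggregate; a bin where every pair is degenerate gets
    NaN and ranks last.
    """
    if len(tracks) < 2:
        raise ValueError("co-occurrence requires at least 2 tracks")
    if len(bins) == 0:
        raise ValueError("empty bin specification")
    fn = _resolve_stat(stat)
    agg_fn = get_aggregator(agg)
    names, values = [], []
    missing: dict[str, list[tuple[str, str]]] = {}
    for name, seg in bins:
        pair_vals = []
        for a, b in itertools.combinations(tracks, 2):
            try:
                ct = contingency_in_bin(a, b, seg)
                pair_vals.append(float(fn(ct)))
            except DegenerateMarginError:
                missing.setdefault(name, []).append((a.label, b.label))
        names.append(name)
        values.append(agg_fn(np.array(pair_vals)) if pair_vals else float("nan"))
    return BinnedResult(bin_names=names, values=values, raw_bp=None,
                        ranks=list(rank_descending(values, names)),
                        mode="cooccurrence", missing_pairs=missing)


def coverage_depth_count(tracks: Sequence[Track], k: int) -> int:
    """bp covered by at least ``k`` of the suite's tracks.

    Single boundary sweep per chromosome — a genuinely higher-order statistic
    (cannot be decomposed into pairwise overlaps).
    """
    n = len(tracks)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    genome = tracks[0].genome
    total = 0
    for chrom, _ in genome:
        pos_parts, delta_parts = [], []
        for t in tracks:
            s, e = t.arrays(chrom)
            if len(s):
                pos_parts.append(s)
                delta_parts.append(np.ones(len(s), dtype=np.int64))
                pos_parts.append(e)
                delta_parts.append(-np.ones(len(e), dtype=np.int64))
        if not pos_parts:
            continue
        pos = np.concatenate(pos_parts)
        delta = np.concatenate(delta_parts)
        order = np.argsort(pos, kind="stable")
        pos, delta = pos[order], delta[order]
        depth = np.cumsum(delta)
        widths = np.diff(pos)
        total += int(widths[depth[:-1] >= k].sum())
    return total


def depth_profile(tracks: Sequence[Track]) -> dict[int, int]:
    """bp covered by >= k tracks, for every k in 1..n."""
    return {k: coverage_depth_count(tracks, k)
            for k in range(1, len(tracks) + 1)}
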