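"""Monte Carlo hypothesis testing over tracks and suites.

The p-value estimator is the add-one form p = (k+1)/(m+1), where k counts
null statistics at least as extreme as the observed one: it is strictly
positive (p >= 1/(m+1)) and avoids misleading exact-zero p-values from
finite sampling.  "At least as extreme" means >= for the greater
alternative, <= for less, and |x - c| >= |obs - c| with c = null mean for
two-sided.

Every result records the multiplicity class of the analysis, derived
mechanically from the scope of the statistic and of the sampler: if either
the statistic is defined across tracks of a suite or the sampler draws
elements across tracks, the result is at the integrative level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .pairwise import get_statistic
from .samplers import (
    PER_TRACK_SPEC,
    SamplerSpec,
    sample_across_suites,
    sample_suite_per_track,
    sample_track_preserving_structure,
)
from .suite import (
    BinnedResult,
    binned_cooccurrence,
    binned_occurrence,
    cross_suite_matrix,
    r_statistic,
)
from .tracks import BinSpec, Track, contingency_table


def classify_multiplicity(statistic_scope: str, sampler_scope: str) -> str:
    """Multiplicity class from (statistic scope x sampler scope).

    statistic_scope: 'single-track' | 'single-pair' | 'across-tracks' |
    'higher-order'; sampler_scope: 'per-track' | 'across-tracks' |
    'across-suites'.
    """
    if statistic_scope == "higher-order":
        return "higher-order"
    if statistic_scope == "across-tracks" or sampler_scope in (
            "across-tracks", "across-suites"):
        return "integrative"
    if statistic_scope == "single-track":
        return "trivial"
    return "contrasting"


@dataclass
class McTestResult:
    """Observed statistic, its Monte Carlo null sample, and the p-value."""

    observed: float
    null_values: np.ndarray
    p_value: float
    alternative: str
    m: int
    sampler: SamplerSpec | str
    seed: int | None = None
    label: str | None = None
    multiplicity_class: str | None = None
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        assert 0.0 < self.p_value <= 1.0
        assert self.p_value >= 1.0 / (self.m + 1) - 1e-12


def mc_p_value(observed: float, null_values: np.ndarray,
               alternative: str = "greater") -> float:
    """Add-one Monte Carlo p-value (k+1)/(m+1)."""
    null_values = np.asarray(null_values, dtype=float)
    m = len(null_values)
    if alternative == "greater":
        k = int(np.sum(null_values >= observed))
    elif alternative == "less":
        k = int(np.sum(null_values <= observed))
    elif alternative == "two-sided":
        center = float(np.mean(null_values))
        k = int(np.sum(np.abs(null_values - center) >= abs(observed - center)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (k + 1) / (m + 1)


def monte_carlo_test(statistic: Callable, data, sampler: Callable,
                     m: int = 99, alternative: str = "greater",
                     seed: int | None = None,
                     sampler_spec: SamplerSpec | str = "custom",
                     multiplicity_class: str | None = None) -> McTestResult:
    """Generic Monte Carlo test.

    ``statistic(data) -> float``; ``sampler(data, rng) -> null data``.  A
    statistic failure on a null sample is redrawn at most once, then the
    test aborts (silent redraws would bias the null distribution).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    observed = float(statistic(data))
    root = np.random.SeedSequence(seed)
    null_values = np.empty(m, dtype=float)
    for i, child in enumerate(root.spawn(m)):
        rng = np.random.default_rng(child)
        try:
            null_values[i] = float(statistic(sampler(data, rng)))
        except Exception:
            try:
                null_values[i] = float(statistic(sampler(data, rng)))
            except Exception as err:
                raise RuntimeError(
                    f"statistic failed twice on null sample {i}: {err}"
                ) from err
    p = mc_p_value(observed, null_values, alternative)
    return McTestResult(observed=observed, null_values=null_values, p_value=p,
                        alternative=alternative, m=m, sampler=sampler_spec,
                        seed=seed, multiplicity_class=multiplicity_class)


def adjust_p_values(p: Sequence[float], method: str = "benjamini-hochberg"
                    ) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    if method not in ("benjamini-hochberg", "bh"):
        raise ValueError(f"unknown adjustment method {method!r}")
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _attach_bh(results: list[McTestResult]) -> None:
    adj = adjust_p_values([r.p_value for r in results])
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)


def per_track_query_test(query: Track, tracks: Sequence[Track],
                         stat="forbes", centered: bool = False,
                         m: int = 99, alternative: str = "greater",
                         seed: int | None = None) -> list[McTestResult]:
    """Per-suite-track test of T(query, A_i), randomizing only the query.

    With ``centered``, the statistic is T(query, A_i) minus the suite mean
    of T(query, A_j) — similarity relative to the suite average, an
    integrative statistic.  The whole suite is held fixed; the query track
    is randomized by the structure-preserving per-track sampler.
    """
    if centered and len(tracks) < 2:
        raise ValueError("centered statistic requires at least 2 suite tracks")
    fn = get_statistic(stat) if isinstance(stat, str) else stat

    def t_row(q: Track) -> np.ndarray:
        row = np.array([float(fn(contingency_table(q, t))) for t in tracks])
        return row - row.mean() if centered else row

    observed = t_row(query)
    root = np.random.SeedSequence(seed)
    null_rows = np.empty((m, len(tracks)))
    for i, child in enumerate(root.spawn(m)):
        rng = np.random.default_rng(child)
        null_rows[i] = t_row(sample_track_preserving_structure(query, rng))
    mult = classify_multiplicity(
        "across-tracks" if centered else "single-pair", "per-track")
    results = [
        McTestResult(
            observed=float(observed[j]),
            null_values=null_rows[:, j].copy(),
            p_value=mc_p_value(observed[j], null_rows[:, j], alternative),
            alternative=alternative, m=m, sampler=PER_TRACK_SPEC, seed=seed,
            label=t.label, multiplicity_class=mult,
        )
        for j, t in enumerate(tracks)
    ]
    _attach_bh(results)
    return results


def query_suite_mean_test(query: Track, tracks: Sequence[Track],
                          stat="forbes", m: int = 99,
                          alternative: str = "greater",
                          seed: int | None = None) -> McTestResult:
    """Suite-level test: does the suite as a whole coincide with the query?

    Statistic is the mean of T(query, A_j) over the suite; null randomizes
    the query track only.
    """
    fn = get_statistic(stat) if isinstance(stat, str) else stat

    def statistic(q: Track) -> float:
        return float(np.mean([
            float(fn(contingency_table(q, t))) for t in tracks
        ]))

    return monte_carlo_test(
        statistic, query,
        sampler=lambda q, rng: sample_track_preserving_structure(q, rng),
        m=m, alternative=alternative, seed=seed, sampler_spec=PER_TRACK_SPEC,
        multiplicity_class=classify_multiplicity("across-tracks", "per-track"),
    )


def suite_coherence_test(tracks: Sequence[Track], stat="forbes",
                         m: int = 99, seed: int | None = None,
                         agg_inner: str = "mean", agg_outer: str = "mean"
                         ) -> McTestResult:
    """Are the tracks of the suite, as a whole, more similar than chance?

    Statistic is R; null randomizes every track independently with the
    structure-preserving sampler; greater alternative.
    """
    if len(tracks) < 2:
        raise ValueError("suite coherence requires at least 2 tracks")
    return monte_carlo_test(
        lambda ts: r_statistic(ts, stat, agg_inner, agg_outer),
        list(tracks),
        sampler=lambda ts, rng: sample_suite_per_track(ts, rng),
        m=m, alternative="greater", seed=seed, sampler_spec=PER_TRACK_SPEC,
        multiplicity_class=classify_multiplicity("across-tracks", "per-track"),
    )


def max_q_test(tracks: Sequence[Track], stat="forbes", m: int = 99,
               seed: int | None = None) -> McTestResult:
    """Is the most representative track more similar to the rest than any
    track would be by chance?  Statistic = max_i Q_i; per-track null."""
    if len(tracks) < 2:
        raise ValueError("requires at least 2 tracks")

    def statistic(ts: Sequence[Track]) -> float:
        from .suite import q_statistics
        return float(np.nanmax(q_statistics(ts, stat).values))

    return monte_carlo_test(
        statistic, list(tracks),
        sampler=lambda ts, rng: sample_suite_per_track(ts, rng),
        m=m, alternative="greater", seed=seed, sampler_spec=PER_TRACK_SPEC,
        multiplicity_class=classify_multiplicity("across-tracks", "per-track"),
    )


@dataclass
class BinnedTestResult:
    suite_result: McTestResult  # variance-across-bins test
    per_bin: list[McTestResult]
    observed: BinnedResult


def binned_variation_test(tracks: Sequence[Track], bins: BinSpec,
                          mode: str = "occurrence", stat="jaccard",
                          agg: str = "mean", m: int = 99,
                          seed: int | None = None) -> BinnedTestResult:
    """Do per-bin values vary across bins more than expected by chance?

    Suite-level statistic is the variance across bins of the per-bin
    aggregated value; per-bin statistics are the bin values themselves
    (greater alternative).  The null randomizes each track genome-wide
    (per-track sampler), so per-bin tests are conditional on each track's
    genome-wide propensities.
    """
    if len(bins) < 2:
        raise ValueError("binned tests require at least 2 bins")

    def bin_values(ts: Sequence[Track]) -> np.ndarray:
        if mode == "occurrence":
            res = binned_occurrence(ts, bins, agg)
        elif mode == "cooccurrence":
            res = binned_cooccurrence(ts, bins, stat, agg)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return np.asarray(res.values, dtype=float)

    observed_res = (binned_occurrence(tracks, bins, agg)
                    if mode == "occurrence"
                    else binned_cooccurrence(tracks, bins, stat, agg))
    observed = np.asarray(observed_res.values, dtype=float)
    root = np.random.SeedSequence(seed)
    null_rows = np.empty((m, len(bins)))
    for i, child in enumerate(root.spawn(m)):
        rng = np.random.default_rng(child)
        null_rows[i] = bin_values(sample_suite_per_track(tracks, rng))
    mult = classify_multiplicity(
        "across-tracks" if mode == "cooccurrence" else "single-track",
        "per-track")
    # suite-level: variance of per-bin values (NaN-safe)
    obs_var = float(np.nanvar(observed))
    null_var = np.nanvar(null_rows, axis=1)
    suite_result = McTestResult(
        observed=obs_var, null_values=null_var,
        p_value=mc_p_value(obs_var, null_var, "greater"),
        alternative="greater", m=m, sampler=PER_TRACK_SPEC, seed=seed,
        label="variance-across-bins",
        multiplicity_class="integrative" if mode == "cooccurrence" else "contrasting",
    )
    per_bin = [
        McTestResult(
            observed=float(observed[j]), null_values=null_rows[:, j].copy(),
            p_value=mc_p_value(observed[j], null_rows[:, j], "greater"),
            alternative="greater", m=m, sampler=PER_TRACK_SPEC, seed=seed,
            label=name, multiplicity_class=mult,
        )
        for j, name in enumerate(bins.names)
    ]
    _attach_bh(per_bin)
    return BinnedTestResult(suite_result=suite_result, per_bin=per_bin,
                            observed=observed_res)


@dataclass
class CrossSuiteTestResult:
    suite_pair_result: McTestResult  # max |normalized cell| test
    cell_p: np.ndarray  # n1 x n2 per-cell p-values
    cell_p_adjusted: np.ndarray
    observed_values: np.ndarray
    observed_normalized: np.ndarray
    rows: list[str]
    cols: list[str]


PERMUTE_TRACKS_SPEC = SamplerSpec(
    category="across-suites", variant="permute-tracks",
    preserve=("track-multiset", "suite-sizes"),
)


def cross_suite_test(tracks1: Sequence[Track], tracks2: Sequence[Track],
                     stat="forbes", cell_normalized: bool = True,
                     m: int = 99, seed: int | None = None
                     ) -> CrossSuiteTestResult:
    """Do specific cross-suite track pairs co-occur more than expected?

    Per-cell statistic is the double-centered T value (conditioning on each
    track's marginal propensity to co-occur with the other suite) when
    ``cell_normalized``, else raw T.  The suite-pair statistic is the
    maximum absolute normalized cell value.  Null: whole tracks permuted
    between the suites.
    """
    if cell_normalized and (len(tracks1) < 2 or len(tracks2) < 2):
        raise ValueError("normalized mode requires >= 2 tracks per suite")

    def matrices(pair):
        t1, t2 = pair
        M = cross_suite_matrix(t1, t2, stat)
        return M.values, M.double_centered()

    obs_raw, obs_norm = matrices((tracks1, tracks2))
    obs_cells = obs_norm if cell_normalized else obs_raw
    root = np.random.SeedSequence(seed)
    null_cells = np.empty((m,) + obs_cells.shape)
    null_max = np.empty(m)
    for i, child in enumerate(root.spawn(m)):
        rng = np.random.default_rng(child)
        s1, s2 = sample_across_suites(tracks1, tracks2, "permute-tracks",
                                      seed=rng)
        raw, norm = matrices((s1, s2))
        null_cells[i] = norm if cell_normalized else raw
        null_max[i] = float(np.nanmax(np.abs(norm)))
    obs_max = float(np.nanmax(np.abs(obs_norm)))
    suite_pair = McTestResult(
        observed=obs_max, null_values=null_max,
        p_value=mc_p_value(obs_max, null_max, "greater"),
        alternative="greater", m=m, sampler=PERMUTE_TRACKS_SPEC, seed=seed,
        label="max-abs-normalized-cell",
        multiplicity_class=classify_multiplicity("across-tracks",
                                                 "across-suites"),
    )
    n1, n2 = obs_cells.shape
    cell_p = np.empty((n1, n2))
    for i, j in itertools.product(range(n1), range(n2)):
        cell_p[i, j] = mc_p_value(obs_cells[i, j], null_cells[:, i, j],
                                  "greater")
    cell_p_adj = adjust_p_values(cell_p.ravel()).reshape(cell_p.shape)
    return CrossSuiteTestResult(
        suite_pair_result=suite_pair, cell_p=cell_p,
        cell_p_adjusted=cell_p_adj, observed_values=obs_raw,
        observed_normalized=obs_norm,
        rows=[t.label for t in tracks1], cols=[t.label for t in tracks2],
    )
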