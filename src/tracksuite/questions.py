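"""High-level analyses over track collections.

Five canonical questions, each composing the lower-level statistics with
optional Monte Carlo tests:

* q1 — which tracks are most representative / most atypical for the suite?
* q2 — which tracks coincide most strongly with a separate query track?
* q3 — do tracks of one suite coincide strongly with tracks of another?
* q4 — in which genome regions (bins) does the suite occur most?
* q5 — in which bins does the suite co-occur most strongly?

Plus the trivial-multiplicity per-track description (values neither compared
nor integrated).  Every result carries its multiplicity class and the exact
analysis spec for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import mc as _mc
from .suite import (
    BinnedResult,
    CrossSuiteMatrix,
    SuiteAnalysisResult,
    binned_cooccurrence,
    binned_occurrence,
    cross_suite_matrix,
    q_statistics,
    query_vs_suite,
)
from .tracks import BinSpec, Track

QUESTIONS = ("q1-representative", "q2-rank-vs-query", "q3-cross-suite",
             "q4-binned-occurrence", "q5-binned-cooccurrence")


@dataclass(frozen=True)
class AnalysisSpec:
    question: str
    stat: str = "forbes"
    aggregator: str = "mean"
    m: int = 99
    seed: int | None = None
    with_tests: bool = False
    centered: bool = False

    def __post_init__(self) -> None:
        if self.question not in QUESTIONS:
            raise ValueError(
                f"unknown question {self.question!r}; choose from {QUESTIONS}"
            )

    def provenance(self) -> dict:
        return asdict(self)


@dataclass
class QuestionResult:
    spec: AnalysisSpec
    table: pd.DataFrame
    multiplicity_class: str
    descriptive: object = None
    tests: dict = field(default_factory=dict)

    def test_frame(self) -> pd.DataFrame | None:
        rows = []
        for name, res in self.tests.items():
            items = res if isinstance(res, list) else [res]
            for r in items:
                if isinstance(r, _mc.McTestResult):
                    rows.append({
                        "test": name, "label": r.label or "<suite>",
                        "observed": r.observed, "p": r.p_value,
                        "p_adjusted": r.adjusted_p, "m": r.m,
                        "sampler": (r.sampler.describe()
                                    if isinstance(r.sampler, _mc.SamplerSpec)
                                    else str(r.sampler)),
                        "multiplicity_class": r.multiplicity_class,
                    })
        return pd.DataFrame(rows) if rows else None


def run_q1_representative(tracks: Sequence[Track], spec: AnalysisSpec
                          ) -> QuestionResult:
    """Rank tracks by Q (typicality); top = most representative."""
    res: SuiteAnalysisResult = q_statistics(tracks, spec.stat, spec.aggregator)
    result = QuestionResult(
        spec=spec, table=res.to_frame(), descriptive=res,
        multiplicity_class="contrasting",
    )
    if spec.with_tests:
        result.tests["suite_coherence"] = _mc.suite_coherence_test(
            tracks, spec.stat, m=spec.m, seed=spec.seed)
        result.tests["max_q"] = _mc.max_q_test(
            tracks, spec.stat, m=spec.m, seed=spec.seed)
        result.multiplicity_class = "integrative"
    return result


def run_q2_rank_vs_query(tracks: Sequence[Track], query: Track,
                         spec: AnalysisSpec) -> QuestionResult:
    """Rank suite tracks by similarity T to a separate query track."""
    res = query_vs_suite(query, tracks, spec.stat)
    result = QuestionResult(
        spec=spec, table=res.to_frame(), descriptive=res,
        multiplicity_class="contrasting",
    )
    if spec.with_tests:
        result.tests["per_track"] = _mc.per_track_query_test(
            query, tracks, spec.stat, centered=False, m=spec.m, seed=spec.seed)
        if len(tracks) >= 2:
            result.tests["per_track_centered"] = _mc.per_track_query_test(
                query, tracks, spec.stat, centered=True, m=spec.m,
                seed=spec.seed)
        result.tests["suite_mean"] = _mc.query_suite_mean_test(
            query, tracks, spec.stat, m=spec.m, seed=spec.seed)
        result.multiplicity_class = "integrative"
    return result


def run_q3_cross_suite(tracks1: Sequence[Track], tracks2: Sequence[Track],
                       spec: AnalysisSpec) -> QuestionResult:
    """Full cross-suite T matrix, optionally with the permutation test."""
    M: CrossSuiteMatrix = cross_suite_matrix(tracks1, tracks2, spec.stat)
    result = QuestionResult(
        spec=spec, table=M.to_frame(), descriptive=M,
        multiplicity_class="integrative",
    )
    if spec.with_tests:
        result.tests["cross_suite"] = _mc.cross_suite_test(
            tracks1, tracks2, spec.stat, m=spec.m, seed=spec.seed)
    return result


def run_q4_binned_occurrence(tracks: Sequence[Track], bins: BinSpec,
                             spec: AnalysisSpec) -> QuestionResult:
    """Rank bins by aggregated per-track coverage fraction."""
    res: BinnedResult = binned_occurrence(tracks, bins, spec.aggregator)
    result = QuestionResult(
        spec=spec, table=res.to_frame(), descriptive=res,
        multiplicity_class="contrasting",
    )
    if spec.with_tests:
        result.tests["binned_variation"] = _binned_tests(
            tracks, bins, "occurrence", spec)
    return result


def run_q5_binned_cooccurrence(tracks: Sequence[Track], bins: BinSpec,
                               spec: AnalysisSpec) -> QuestionResult:
    """Rank bins by aggregated pairwise co-occurrence within the bin."""
    res = binned_cooccurrence(tracks, bins, spec.stat, spec.aggregator)
    result = QuestionResult(
        spec=spec, table=res.to_frame(), descriptive=res,
        multiplicity_class="integrative",
    )
    if spec.with_tests:
        result.tests["binned_variation"] = _binned_tests(
            tracks, bins, "cooccurrence", spec)
    return result


def _binned_tests(tracks, bins, mode, spec):
    res = _mc.binned_variation_test(
        tracks, bins, mode=mode, stat=spec.stat, agg=spec.aggregator,
        m=spec.m, seed=spec.seed)
    return [res.suite_result] + res.per_bin


def run_trivial_multiplicity(tracks: Sequence[Track]) -> pd.DataFrame:
    """Per-track descriptors only: no comparison, no integration, no tests."""
    rows = [{
        "label": t.label,
        "segment_count": t.segment_count,
        "elements_pre_merge": t.elements_pre_merge,
        "coverage_bp": t.coverage_bp,
        "coverage_fraction": t.coverage_fraction(),
        "mean_segment_length": (t.coverage_bp / t.segment_count
                                if t.segment_count else 0.0),
    } for t in tracks]
    return pd.DataFrame(rows)
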