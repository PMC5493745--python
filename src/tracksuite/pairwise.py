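"""Pairwise track co-occurrence statistics computed from a bp contingency table.

Every statistic here is a pure, symmetric function of a
:class:`~tracksuite.tracks.ContingencyTable` in which each base pair of the
genome is one binary observation per track.  Larger values always mean more
co-occurrence.

* ``jaccard`` — intersection over union; cheap, but confounded by track size
  when ranking (avoid for size-heterogeneous suites).
* ``forbes`` — observed over expected co-coverage under independence;
  equals 1 at independence.
* ``tetrachoric`` — the correlation of a latent bivariate normal assumed to
  generate both binary tracks by thresholding; estimated by maximum
  likelihood with thresholds fixed from the marginal coverage fractions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize, stats

from .tracks import ContingencyTable, Track, contingency_table

STAT_NAMES = ("jaccard", "forbes", "tetrachoric")


class DegenerateMarginError(ValueError):
    """A statistic is mathematically undefined for this table's margins."""


def jaccard(ct: ContingencyTable) -> float:
    """|A∩B| / |A∪B|; 0 (with a warning) when both tracks are empty."""
    union = ct.n_both + ct.n_a_only + ct.n_b_only
    if union == 0:
        warnings.warn("Jaccard of two empty tracks defined as 0", stacklevel=2)
        return 0.0
    return ct.n_both / union


def forbes(ct: ContingencyTable) -> float:
    """N·|A∩B| / (|A|·|B|): ratio of observed to independence-expected overlap."""
    cov_a, cov_b = ct.coverage_a, ct.coverage_b
    if cov_a == 0 or cov_b == 0:
        raise DegenerateMarginError("Forbes undefined for empty track")
    return ct.N * ct.n_both / (cov_a * cov_b)


@dataclass(frozen=True)
class TetrachoricResult:
    rho: float
    converged: bool
    method: str  # "maximum-likelihood" | "closed-form-median"

    def __float__(self) -> float:
        return self.rho


def _bvn_upper(rho: float, ta: float, tb: float) -> float:
    """P(X > ta, Y > tb) for standard bivariate normal with correlation rho."""
    phi2 = stats.multivariate_normal.cdf(
        [ta, tb], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]],
    )
    return 1.0 - stats.norm.cdf(ta) - stats.norm.cdf(tb) + phi2


def _cell_probs(rho: float, ta: float, tb: float
                ) -> tuple[float, float, float, float]:
    """(p_both, p_a_only, p_b_only, p_neither) implied by thresholds and rho."""
    phi2 = stats.multivariate_normal.cdf(
        [ta, tb], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]],
    )
    fa, fb = stats.norm.cdf(ta), stats.norm.cdf(tb)
    p_neither = phi2
    p_b_only = fa - phi2
    p_a_only = fb - phi2
    p_both = 1.0 - fa - fb + phi2
    return p_both, p_a_only, p_b_only, p_neither


def tetrachoric(ct: ContingencyTable, *, continuity_correction: bool = True,
                xatol: float = 1e-6) -> TetrachoricResult:
    """ML estimate of the latent correlation underlying a 2x2 bp table.

    Thresholds are fixed at the normal quantiles of the marginal coverage
    fractions; rho is found by bounded 1-D likelihood maximization over
    (-1+eps, 1-eps).  A zero interior cell gets a 0.5 continuity correction
    before estimation (disable with ``continuity_correction=False``), except
    in the exactly-degenerate perfect agreement/disagreement cases which
    return ±1 directly.
    """
    n = np.array(ct.as_tuple(), dtype=float)  # both, a_only, b_only, neither
    N = n.sum()
    if ct.coverage_a in (0, ct.N) or ct.coverage_b in (0, ct.N):
        raise DegenerateMarginError(
            "tetrachoric undefined for degenerate margin "
            "(track empty or covering the whole genome)"
        )
    if n[1] == 0 and n[2] == 0:
        return TetrachoricResult(1.0, True, "maximum-likelihood")
    if n[0] == 0 and n[3] == 0:
        return TetrachoricResult(-1.0, True, "maximum-likelihood")
    if continuity_correction and (n == 0).any():
        n = n + np.where(n == 0, 0.5, 0.0)
        N = n.sum()
    fa = (n[0] + n[1]) / N  # covered fraction of A
    fb = (n[0] + n[2]) / N
    ta = stats.norm.ppf(1.0 - fa)  # covered iff latent > threshold
    tb = stats.norm.ppf(1.0 - fb)

    def negloglik(rho: float) -> float:
        probs = np.clip(_cell_probs(rho, ta, tb), 1e-300, None)
        return -float(np.dot(n, np.log(probs)))

    eps = 1e-6
    res = optimize.minimize_scalar(
        negloglik, bounds=(-1.0 + eps, 1.0 - eps), method="bounded",
        options={"xatol": xatol},
    )
    rho = float(np.clip(res.x, -1.0, 1.0))
    return TetrachoricResult(rho, bool(res.success), "maximum-likelihood")


def tetrachoric_median_split(ct: ContingencyTable,
                             margin_tol: float = 0.01) -> TetrachoricResult:
    """Closed form for median-split tables: P(both) = 1/4 + arcsin(rho)/(2π)."""
    N = ct.N
    fa, fb = ct.coverage_a / N, ct.coverage_b / N
    if abs(fa - 0.5) > margin_tol or abs(fb - 0.5) > margin_tol:
        raise ValueError(
            "closed-form median-split estimator requires both margins ~0.5 "
            f"(got {fa:.3f}, {fb:.3f})"
        )
    arg = 2.0 * math.pi * (ct.n_both / N - 0.25)
    rho = math.sin(max(-math.pi / 2, min(math.pi / 2, arg)))
    return TetrachoricResult(rho, True, "closed-form-median")


_STATS: dict[str, Callable[[ContingencyTable], float]] = {
    "jaccard": jaccard,
    "forbes": forbes,
    "tetrachoric": lambda ct: tetrachoric(ct).rho,
}


def get_statistic(name: str) -> Callable[[ContingencyTable], float]:
    """Look up a pairwise statistic by name."""
    try:
        return _STATS[name]
    except KeyError:
        raise KeyError(
            f"unknown statistic {name!r}; choose from {STAT_NAMES}"
        ) from None


def pairwise_T(a: Track, b: Track, stat: str | Callable = "forbes") -> float:
    """The pairwise track statistic T: stat(contingency_table(a, b))."""
    fn = get_statistic(stat) if isinstance(stat, str) else stat
    value = fn(contingency_table(a, b))
    return float(value) if not isinstance(value, TetrachoricResult) else value.rho
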