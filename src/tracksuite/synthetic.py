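"""Synthetic track suites with known, controllable statistical structure.

The generator draws, per chromosome, a block-wise constant latent standard
normal signal z (block width configurable, default 50 bp, so thresholded
tracks have realistic multi-bp segments).  Track i gets its own field

    x_i = rho_i * z + sqrt(1 - rho_i^2) * eps_i

with eps_i an independent block field, and is covered exactly on the blocks
where x_i exceeds its empirical quantile matching the requested coverage
fraction.  This latent model is precisely the model assumed by the
tetrachoric statistic: two tracks i, j have latent correlation
rho_i * rho_j, which makes parameter recovery a well-posed test.

Planted structures (an associated pair, a co-occurrence bin, an occurrence
hotspot) are layered on top of an otherwise independent suite, and the
ground truth is returned with the tracks and embedded as GSuite metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import GenomeDefinition
from .gsuite import GSuite, GSuiteHeader, GSuiteTrackRef, write_gsuite
from .tracks import Segment, Track, merge_intervals, write_bed

LATENT_MODELS = ("independent", "shared-signal", "planted-pair", "planted-bin")


@dataclass(frozen=True)
class SyntheticSuiteSpec:
    genome: GenomeDefinition
    n_tracks: int
    coverage_fractions: tuple[float, ...]  # per-track targets in (0, 1)
    latent_model: str = "independent"
    rho: tuple[float, ...] = ()            # per-track loading on the shared signal
    planted_pair: tuple[int, int] = (0, 1)
    planted_rho: float = 0.8
    planted_bin: Segment | None = None
    planted_shift: float = 0.0             # latent mean shift inside planted bin
    block_bp: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_model not in LATENT_MODELS:
            raise ValueError(f"unknown latent model {self.latent_model!r}")
        if len(self.coverage_fractions) != self.n_tracks:
            raise ValueError("need one coverage fraction per track")
        for f in self.coverage_fractions:
            if not 0.0 < f < 1.0:
                raise ValueError(f"coverage fraction {f} outside (0, 1)")
        if self.latent_model == "shared-signal":
            if len(self.rho) != self.n_tracks:
                raise ValueError("shared-signal model needs one rho per track")
            for r in self.rho:
                if not -1.0 < r < 1.0:
                    raise ValueError(f"rho {r} outside (-1, 1)")
        if self.block_bp < 1:
            raise ValueError("block_bp must be >= 1")


@dataclass
class SuiteGroundTruth:
    rho: tuple[float, ...]
    latent_correlation: np.ndarray  # n x n matrix of pairwise latent corr
    planted_pair: tuple[int, int] | None = None
    planted_bin: Segment | None = None


def _threshold_blocks(x: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean mask covering the top `fraction` of blocks (empirical quantile)."""
    k = int(round(fraction * len(x)))
    k = max(1, min(len(x) - 1, k))
    cutoff_idx = np.argpartition(x, len(x) - k)[len(x) - k:]
    mask = np.zeros(len(x), dtype=bool)
    mask[cutoff_idx] = True
    return mask


def _blocks_to_intervals(mask: np.ndarray, block_bp: int, chrom_len: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    idx = np.flatnonzero(mask)
    if not len(idx):
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    starts = idx * block_bp
    ends = np.minimum(starts + block_bp, chrom_len)
    return merge_intervals(starts, ends)


def _track_rhos(spec: SyntheticSuiteSpec) -> tuple[float, ...]:
    if spec.latent_model == "shared-signal":
        return spec.rho
    return tuple(0.0 for _ in range(spec.n_tracks))


def generate_suite(spec: SyntheticSuiteSpec
                   ) -> tuple[list[Track], SuiteGroundTruth]:
    """Generate a suite of tracks plus its generative ground truth."""
    rng = np.random.default_rng(spec.seed)
    rhos = _track_rhos(spec)
    n = spec.n_tracks
    fields: dict[str, np.ndarray] = {}  # chrom -> (n, nblocks) latent fields
    for chrom, length in spec.genome:
        nblocks = math.ceil(length / spec.block_bp)
        z = rng.standard_normal(nblocks)
        eps = rng.standard_normal((n, nblocks))
        loadings = np.asarray(rhos)[:, None]
        x = loadings * z + np.sqrt(1.0 - loadings ** 2) * eps

        if spec.latent_model == "planted-pair":
            i, j = spec.planted_pair
            z2 = rng.standard_normal(nblocks)
            r = spec.planted_rho
            for t in (i, j):
                x[t] = r * z2 + math.sqrt(1.0 - r * r) * rng.standard_normal(nblocks)
        if spec.latent_model == "planted-bin" and spec.planted_bin is not None \
                and spec.planted_bin.chromosome == chrom:
            b0 = spec.planted_bin.start // spec.block_bp
            b1 = math.ceil(spec.planted_bin.end / spec.block_bp)
            width = b1 - b0
            z_local = rng.standard_normal(width)
            r = spec.planted_rho
            for t in range(n):
                local_eps = rng.standard_normal(width)
                x[t, b0:b1] = (r * z_local
                               + math.sqrt(1.0 - r * r) * local_eps
                               + spec.planted_shift)
        fields[chrom] = x

    tracks: list[Track] = []
    for t in range(n):
        by_chrom = {}
        for chrom, length in spec.genome:
            mask = _threshold_blocks(fields[chrom][t],
                                     spec.coverage_fractions[t])
            s, e = _blocks_to_intervals(mask, spec.block_bp, length)
            if len(s):
                by_chrom[chrom] = (s, e)
        tracks.append(Track(spec.genome, by_chrom, label=f"track{t:02d}"))

    corr = np.outer(rhos, rhos)
    np.fill_diagonal(corr, 1.0)
    truth = SuiteGroundTruth(
        rho=rhos, latent_correlation=corr,
        planted_pair=(spec.planted_pair
                      if spec.latent_model == "planted-pair" else None),
        planted_bin=(spec.planted_bin
                     if spec.latent_model == "planted-bin" else None),
    )
    return tracks, truth


def generate_query_and_suite(genome: GenomeDefinition,
                             rho: Sequence[float],
                             coverage_fractions: Sequence[float] | None = None,
                             query_fraction: float = 0.2,
                             block_bp: int = 50,
                             seed: int = 0) -> tuple[Track, list[Track],
                                                     SuiteGroundTruth]:
    """A query track plus a suite whose latent correlation *to the query* is
    exactly the given rho values.

    The query is the shared signal itself (loading 1), so
    tetrachoric(query, track_i) estimates rho[i].
    """
    n = len(rho)
    fractions = (tuple(coverage_fractions) if coverage_fractions is not None
                 else tuple(0.2 for _ in range(n)))
    spec = SyntheticSuiteSpec(
        genome=genome, n_tracks=n + 1,
        coverage_fractions=(query_fraction,) + fractions,
        latent_model="shared-signal",
        rho=(1.0 - 1e-9,) + tuple(rho),  # query loads ~1 on the shared signal
        block_bp=block_bp, seed=seed,
    )
    tracks, truth = generate_suite(spec)
    query = tracks[0].with_label("query")
    suite = [t.with_label(f"ref{i:02d}") for i, t in enumerate(tracks[1:])]
    truth = SuiteGroundTruth(
        rho=tuple(rho),
        latent_correlation=truth.latent_correlation[1:, 1:],
    )
    return query, suite, truth


def generate_toy_gsuite(directory: str | Path, spec: SyntheticSuiteSpec
                        ) -> tuple[Path, list[Track], SuiteGroundTruth]:
    """Materialize a generated suite as BED files plus a GSuite manifest.

    Ground-truth values are embedded as metadata columns (``true_rho``,
    ``coverage_fraction``), demonstrating the format's metadata capability
    while serving recovery tests.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tracks, truth = generate_suite(spec)
    refs = []
    for i, track in enumerate(tracks):
        bed = directory / f"{track.label}.bed"
        write_bed(track, bed)
        refs.append(GSuiteTrackRef(
            uri=bed.name, title=track.label,
            metadata=(
                ("true_rho", f"{truth.rho[i]:.6g}"),
                ("coverage_fraction", f"{spec.coverage_fractions[i]:.6g}"),
            ),
        ))
    suite = GSuite(
        headers=(
            GSuiteHeader("location", "local"),
            GSuiteHeader("file-format", "bed"),
            GSuiteHeader("track-type", "segments"),
            GSuiteHeader("genome", spec.genome.name),
        ),
        tracks=tuple(refs),
    )
    gsuite_path = directory / "suite.gsuite"
    write_gsuite(suite, gsuite_path)
    spec.genome.to_chrom_sizes(directory / "genome.chrom.sizes")
    return gsuite_path, tracks, truth
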