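"""Monte Carlo null-model samplers for tracks and suites.

Three categories of randomization, each preserving declared structure:

1. per-track — each track randomized separately; the per-chromosome multisets
   of segment lengths and inter-segment gaps (including the two flanks) are
   independently permuted and the track re-laid out, preserving segment
   count, length multiset, gap multiset and coverage.
2. pooled-within-suite — all segments (with their genomic positions) are
   placed in one pool and re-dealt to tracks, with or without replacement,
   with or without preserving per-track segment counts.
3. across-suites — either pool elements across both suites, or permute whole
   tracks between the suites.

Chromosomes are randomized independently; a segment never changes
chromosome.  All randomness flows from a single integer seed via
``numpy.random.SeedSequence`` spawning, so identical seeds give identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tracks import Segment, Track

def _permute_gaps_valid(gaps: np.ndarray, n_segments: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Uniform draw over distinct gap arrangements with no internal zero.

    Zero gaps can only come from the flanks of a normalized track (internal
    gaps are >= 1), and a zero permuted inward would merge two segments.
    Permuting the nonzero gaps and placing the zeros on uniformly chosen
    flank slots is exactly the distribution of a uniformly random multiset
    permutation conditioned on validity.
    """
    zeros = int(np.sum(gaps == 0))
    if n_segments == 1 or zeros == 0:
        return rng.permutation(gaps)
    mid = rng.permutation(gaps[gaps != 0])
    zero = np.zeros(1, dtype=gaps.dtype)
    if zeros == 2:
        return np.concatenate((zero, mid, zero))
    if rng.integers(2) == 0:
        return np.concatenate((zero, mid))
    return np.concatenate((mid, zero))


@dataclass(frozen=True)
class SamplerSpec:
    """Identity and declared guarantees of a sampler configuration."""

    category: str  # per-track | pooled-within-suite | across-suites
    variant: str = ""
    preserve: tuple[str, ...] = ()
    seed: int | None = None

    def describe(self) -> str:
        v = f"/{self.variant}" if self.variant else ""
        return f"{self.category}{v}"


PER_TRACK_SPEC = SamplerSpec(
    category="per-track",
    variant="permute-lengths-and-gaps",
    preserve=("segment-count", "length-multiset", "gap-multiset",
              "coverage-bp", "chromosome-assignment"),
)


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_track_preserving_structure(track: Track, seed=None) -> Track:
    """Randomize one track, preserving per-chromosome length and gap multisets.

    For each chromosome the segment lengths and the n+1 gaps (left flank,
    n-1 inter-segment gaps, right flank) are permuted independently and laid
    out alternately (gap, segment, gap, ...).  Zero flank gaps are kept on
    the flanks (an internal zero gap would merge two segments); the draw is
    uniform over all valid distinct layouts.
    """
    if track.is_empty:
        raise ValueError("cannot randomize an empty track")
    rng = _rng_from(seed)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, _ in track.genome:
        s, e = track.arrays(chrom)
        if not len(s):
            continue
        chrom_len = track.genome.length_of(chrom)
        lengths = e - s
        gaps = np.empty(len(s) + 1, dtype=np.int64)
        gaps[0] = s[0]
        gaps[1:-1] = s[1:] - e[:-1]
        gaps[-1] = chrom_len - e[-1]
        new_lengths = rng.permutation(lengths)
        new_gaps = _permute_gaps_valid(gaps, len(s), rng)
        starts = np.cumsum(new_gaps[:-1]) + np.concatenate(
            ([0], np.cumsum(new_lengths[:-1]))
        )
        by_chrom[chrom] = (starts, starts + new_lengths)
    return Track(track.genome, by_chrom, label=track.label,
                 elements_pre_merge=track.elements_pre_merge)


def sample_suite_per_track(tracks: Sequence[Track], seed=None) -> list[Track]:
    """Category 1: randomize each track independently with derived sub-seeds."""
    if isinstance(seed, np.random.Generator):
        children = seed.spawn(len(tracks))
    else:
        children = np.random.SeedSequence(seed).spawn(len(tracks))
    return [
        sample_track_preserving_structure(t, np.random.default_rng(child))
        for t, child in zip(tracks, children)
    ]


def _tracks_from_assignment(segments: list[Segment],
                            assignment: np.ndarray,
                            templates: Sequence[Track]) -> list[Track]:
    out = []
    for i, template in enumerate(templates):
        segs = [segments[j] for j in np.flatnonzero(assignment == i)]
        out.append(Track.from_segments(template.genome, segs,
                                       label=template.label))
    return out


def sample_suite_pooled(tracks: Sequence[Track], *,
                        preserve_counts: bool = True,
                        replacement: bool = False,
                        seed=None) -> list[Track]:
    """Category 2: pool all segments across the suite and re-deal them.

    Segments keep their genomic positions; only track membership is
    randomized.  ``preserve_counts`` keeps each track's pre-merge segment
    count; otherwise counts are multinomial-uniform.  Without replacement the
    pool is partitioned exactly; with replacement each track draws its
    segments independently from the pool.  Segments that collide inside one
    output track are merged at normalization (the pre-merge count is kept on
    the Track).
    """
    if len(tracks) < 2:
        raise ValueError("pooled sampling requires at least 2 tracks")
    rng = _rng_from(seed)
    pool: list[Segment] = []
    counts: list[int] = []
    for t in tracks:
        segs = list(t.segments())
        pool.extend(segs)
        counts.append(len(segs))
    n_tracks, pool_size = len(tracks), len(pool)

    if not replacement:
        if preserve_counts:
            labels = np.repeat(np.arange(n_tracks), counts)
            assignment = rng.permutation(labels)
        else:
            assignment = rng.integers(0, n_tracks, size=pool_size)
        return _tracks_from_assignment(pool, assignment, tracks)

    if preserve_counts:
        draw_counts = counts
    else:
        draw_counts = rng.multinomial(pool_size, np.full(n_tracks, 1 / n_tracks))
    out = []
    for template, c in zip(tracks, draw_counts):
        idx = rng.integers(0, pool_size, size=c)
        out.append(Track.from_segments(
            template.genome, [pool[j] for j in idx], label=template.label))
    return out


def sample_across_suites(tracks1: Sequence[Track], tracks2: Sequence[Track],
                         mode: str = "permute-tracks", *,
                         preserve_counts: bool = True,
                         replacement: bool = False,
                         seed=None) -> tuple[list[Track], list[Track]]:
    """Category 3: randomize across two suites.

    ``permute-tracks`` reassigns whole tracks to the suites uniformly at
    random, preserving suite sizes.  ``pool-elements`` pools segments across
    both suites (as :func:`sample_suite_pooled` on the concatenation) and
    re-splits into the original suite sizes.
    """
    if not tracks1 or not tracks2:
        raise ValueError("both suites must be non-empty")
    rng = _rng_from(seed)
    n1 = len(tracks1)
    if mode == "permute-tracks":
        combined = list(tracks1) + list(tracks2)
        perm = rng.permutation(len(combined))
        shuffled = [combined[i] for i in perm]
        return shuffled[:n1], shuffled[n1:]
    if mode == "pool-elements":
        combined = list(tracks1) + list(tracks2)
        sampled = sample_suite_pooled(
            combined, preserve_counts=preserve_counts,
            replacement=replacement, seed=rng)
        return sampled[:n1], sampled[n1:]
    raise ValueError(
        f"unknown mode {mode!r}; choose 'permute-tracks' or 'pool-elements'"
    )


def assert_preserved(original: Track, sampled: Track) -> None:
    """Verify the per-track sampler's declared preservation guarantees."""
    assert sampled.genome == original.genome
    for chrom, _ in original.genome:
        s0, e0 = original.arrays(chrom)
        s1, e1 = sampled.arrays(chrom)
        assert len(s0) == len(s1), f"segment count changed on {chrom}"
        if not len(s0):
            continue
        chrom_len = original.genome.length_of(chrom)
        assert sorted(e0 - s0) == sorted(e1 - s1), f"length multiset changed on {chrom}"

        def gap_multiset(s, e):
            gaps = [int(s[0])]
            gaps += [int(g) for g in (s[1:] - e[:-1])]
            gaps.append(int(chrom_len - e[-1]))
            return sorted(gaps)

        assert gap_multiset(s0, e0) == gap_multiset(s1, e1), \
            f"gap multiset changed on {chrom}"
        assert (s1[1:] > e1[:-1]).all(), f"segments touch/overlap on {chrom}"
        assert s1[0] >= 0 and e1[-1] <= chrom_len, f"out of bounds on {chrom}"
    assert sampled.coverage_bp == original.coverage_bp
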