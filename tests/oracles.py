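"""Independent brute-force oracles used across the test suite.

These deliberately materialize per-basepair boolean/depth arrays and never
share code with the package's interval arithmetic.
"""

from __future__ import annotations

import numpy as np

from tracksuite import GenomeDefinition, Track
from tracksuite.tracks import Segment


def track_masks(track: Track) -> dict[str, np.ndarray]:
    """One boolean array per chromosome, length = chromosome length."""
    masks = {}
    for chrom, length in track.genome:
        mask = np.zeros(length, dtype=bool)
        s, e = track.arrays(chrom)
        for i in range(len(s)):
            mask[s[i]:e[i]] = True
        masks[chrom] = mask
    return masks


def flat_mask(track: Track) -> np.ndarray:
    """All chromosomes concatenated in genome order."""
    return np.concatenate([track_masks(track)[c] for c, _ in track.genome])


def oracle_contingency(a: Track, b: Track) -> tuple[int, int, int, int]:
    ma, mb = flat_mask(a), flat_mask(b)
    return (
        int(np.sum(ma & mb)),
        int(np.sum(ma & ~mb)),
        int(np.sum(~ma & mb)),
        int(np.sum(~ma & ~mb)),
    )


def oracle_coverage_in_bin(track: Track, seg: Segment) -> int:
    mask = track_masks(track)[seg.chromosome]
    return int(mask[seg.start:seg.end].sum())


def oracle_depth_count(tracks: list[Track], k: int) -> int:
    depth = np.sum([flat_mask(t) for t in tracks], axis=0)
    return int(np.sum(depth >= k))


def random_track(rng: np.random.Generator, genome: GenomeDefinition,
                 max_segments: int = 8, label: str = "t",
                 allow_empty: bool = False) -> Track:
    """Random raw (possibly overlapping) segments, normalized on construction."""
    segs = []
    low = 0 if allow_empty else 1
    for chrom, length in genome:
        n = int(rng.integers(low, max_segments + 1))
        for _ in range(n):
            start = int(rng.integers(0, length))
            end = int(rng.integers(start + 1, min(length, start + max(2, length // 4)) + 1))
            segs.append((chrom, start, end))
    return Track.from_segments(genome, segs, label=label)
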