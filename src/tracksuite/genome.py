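"""Genome definitions: an ordered set of named chromosomes with lengths.

The total genome size ``N`` (sum of chromosome lengths) is the universe for
every base-pair contingency table computed by this package.  A genome is
ordinarily loaded from a two-column ``chrom.sizes`` file (tab-separated
chromosome name and length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping


class GenomeMismatchError(ValueError):
    """Raised when two operands are anchored to different genomes."""


@dataclass(frozen=True)
class GenomeDefinition:
    """Named chromosomes with lengths; the coordinate universe for all tracks.

    Parameters
    ----------
    name
        Free-text label for the genome build.
    chromosomes
        Ordered ``(chromosome_name, length_in_bp)`` pairs.  Lengths must be
        strictly positive and names unique.
    """

    name: str
    chromosomes: tuple[tuple[str, int], ...]
    _lengths: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        chroms = tuple((str(c), int(n)) for c, n in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        seen: dict[str, int] = {}
        for chrom, length in chroms:
            if length <= 0:
                raise ValueError(
                    f"chromosome {chrom!r} has non-positive length {length}"
                )
            if chrom in seen:
                raise ValueError(f"duplicate chromosome name {chrom!r}")
            seen[chrom] = length
        if not seen:
            raise ValueError("genome must contain at least one chromosome")
        object.__setattr__(self, "_lengths", seen)

    @property
    def N(self) -> int:
        """Total genome size in bp (the contingency-table universe)."""
        return sum(length for _, length in self.chromosomes)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(
                f"unknown chromosome {chrom!r} in genome {self.name!r}"
            ) from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.chromosomes)

    @classmethod
    def from_chrom_sizes(cls, path: str | Path, name: str | None = None) -> "GenomeDefinition":
        """Load a genome from a two-column ``chrom.sizes`` file."""
        path = Path(path)
        pairs: list[tuple[str, int]] = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            try:
                length = int(fields[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: length {fields[1]!r} is not an integer"
                ) from None
            pairs.append((fields[0], length))
        return cls(name=name or path.stem, chromosomes=tuple(pairs))

    def to_chrom_sizes(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{chrom}\t{length}\n" for chrom, length in self.chromosomes)
        )

    @classmethod
    def from_dict(cls, lengths: Mapping[str, int] | Iterable[tuple[str, int]],
                  name: str = "custom") -> "GenomeDefinition":
        items = lengths.items() if isinstance(lengths, Mapping) else lengths
        return cls(name=name, chromosomes=tuple(items))
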