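"""The GSuite tabular text format for collections of genomic tracks.

Dialect implemented here (the normative grammar for this package):

* Header lines start with ``##`` and have the form ``##key: value``.
  Keys are case-insensitive and unique per file; unknown keys are preserved
  verbatim on round trip.  Recognized keys: ``location`` (local | remote |
  multiple), ``file-format``, ``track-type``, ``genome``.
* An optional single column-declaration line starts with ``#`` and names
  tab-separated columns; the first column is ``uri`` and the second
  ``title``.  Any further columns are per-track metadata.
* All subsequent non-empty lines are tab-separated data rows.
* A file containing no ``#`` lines at all is the degenerate bare-URL form:
  one URI per line, no metadata — still a valid GSuite.
* Missing metadata values are written as ``.`` and parsed as absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, Sequence

from .genome import GenomeDefinition
from .tracks import BedFormatError, Track, read_bed

RECOGNIZED_HEADERS = ("location", "file-format", "track-type", "genome")
MISSING = "."


class GSuiteParseError(ValueError):
    pass


@dataclass(frozen=True)
class GSuiteHeader:
    key: str
    value: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "key", self.key.lower())


@dataclass(frozen=True)
class GSuiteTrackRef:
    """One row of a GSuite: a URI plus title and metadata values."""

    uri: str
    title: str = ""
    metadata: tuple[tuple[str, str], ...] = ()
    line_number: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.uri:
            raise ValueError("track uri must be non-empty")

    @property
    def metadata_dict(self) -> dict[str, str]:
        return dict(self.metadata)

    def get(self, column: str) -> str | None:
        """Metadata value, or None when missing ('.')."""
        value = self.metadata_dict.get(column)
        return None if value in (None, MISSING) else value

    @property
    def is_remote(self) -> bool:
        return "://" in self.uri and not self.uri.startswith("file://")

    @property
    def local_path(self) -> Path:
        if self.uri.startswith("file://"):
            return Path(self.uri[len("file://"):])
        return Path(self.uri)


@dataclass(frozen=True)
class GSuite:
    """An ordered collection of track references with headers and metadata."""

    headers: tuple[GSuiteHeader, ...] = ()
    tracks: tuple[GSuiteTrackRef, ...] = ()

    def __post_init__(self) -> None:
        keys = [h.key for h in self.headers]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate header keys")
        cols = None
        for t in self.tracks:
            tcols = tuple(k for k, _ in t.metadata)
            if cols is None:
                cols = tcols
            elif tcols != cols:
                raise ValueError(
                    "metadata columns differ across tracks "
                    f"({tcols} vs {cols})"
                )

    @property
    def n(self) -> int:
        """Number of tracks in the suite."""
        return len(self.tracks)

    @property
    def metadata_columns(self) -> tuple[str, ...]:
        if not self.tracks:
            return ()
        return tuple(k for k, _ in self.tracks[0].metadata)

    def header(self, key: str) -> str | None:
        for h in self.headers:
            if h.key == key.lower():
                return h.value
        return None

    def titles(self) -> tuple[str, ...]:
        return tuple(t.title for t in self.tracks)

    def __iter__(self) -> Iterator[GSuiteTrackRef]:
        return iter(self.tracks)

    def __len__(self) -> int:
        return self.n


def _default_title(uri: str) -> str:
    base = uri.rstrip("/").rsplit("/", 1)[-1]
    return base.rsplit(".", 1)[0] if "." in base else base


def parse_gsuite(source: str | Path, *, is_text: bool = False) -> GSuite:
    """Parse a GSuite file (or raw text with ``is_text=True``).

    A plain text file of one URI per line is a valid GSuite instance.
    """
    if is_text:
        text, origin = str(source), "<text>"
    else:
        text, origin = Path(source).read_text(), str(source)

    headers: list[GSuiteHeader] = []
    columns: list[str] | None = None
    tracks: list[GSuiteTrackRef] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if line.startswith("##"):
            if tracks or columns is not None:
                raise GSuiteParseError(
                    f"{origin}:{lineno}: header after data/column line"
                )
            body = line[2:]
            if ":" not in body:
                raise GSuiteParseError(
                    f"{origin}:{lineno}: malformed header (expected '##key: value')"
                )
            key, _, value = body.partition(":")
            key = key.strip().lower()
            if any(h.key == key for h in headers):
                raise GSuiteParseError(
                    f"{origin}:{lineno}: duplicate header key {key!r}"
                )
            headers.append(GSuiteHeader(key, value.strip()))
        elif line.startswith("#"):
            if columns is not None:
                raise GSuiteParseError(
                    f"{origin}:{lineno}: second column-declaration line"
                )
            if tracks:
                raise GSuiteParseError(
                    f"{origin}:{lineno}: column declaration after data rows"
                )
            columns = [c.strip() for c in line[1:].split("\t")]
            if len(columns) < 1 or columns[0] != "uri":
                raise GSuiteParseError(
                    f"{origin}:{lineno}: first declared column must be 'uri'"
                )
            if len(columns) > 1 and columns[1] != "title":
                raise GSuiteParseError(
                    f"{origin}:{lineno}: second declared column must be 'title'"
                )
            meta_cols = columns[2:]
            if len(set(meta_cols)) != len(meta_cols):
                raise GSuiteParseError(
                    f"{origin}:{lineno}: duplicate metadata column names"
                )
        else:
            if columns is None:
                # bare-URI row
                fields = line.split("\t")
                if len(fields) != 1:
                    raise GSuiteParseError(
                        f"{origin}:{lineno}: tab-separated row without a "
                        "column-declaration line"
                    )
                uri = fields[0].strip()
                tracks.append(GSuiteTrackRef(
                    uri=uri, title=_default_title(uri), line_number=lineno))
            else:
                fields = line.split("\t")
                if len(fields) != len(columns):
                    raise GSuiteParseError(
                        f"{origin}:{lineno}: expected {len(columns)} fields, "
                        f"got {len(fields)}"
                    )
                uri = fields[0]
                title = fields[1] if len(columns) > 1 else _default_title(uri)
                meta = tuple(zip(columns[2:], fields[2:]))
                tracks.append(GSuiteTrackRef(
                    uri=uri, title=title, metadata=meta, line_number=lineno))
    try:
        return GSuite(headers=tuple(headers), tracks=tuple(tracks))
    except ValueError as err:
        raise GSuiteParseError(f"{origin}: {err}") from None


def format_gsuite(suite: GSuite) -> str:
    """Serialize a GSuite to text; ``parse_gsuite`` of the result is identity."""
    lines: list[str] = []
    for h in suite.headers:
        lines.append(f"##{h.key}: {h.value}")
    cols = suite.metadata_columns
    bare = not suite.headers and not cols and all(
        t.title == _default_title(t.uri) for t in suite.tracks
    )
    if not bare:
        lines.append("#" + "\t".join(("uri", "title") + cols))
    for t in suite.tracks:
        for col, value in (("uri", t.uri), ("title", t.title)) + t.metadata:
            if "\t" in value or "\n" in value:
                raise ValueError(
                    f"value for {col!r} contains a tab/newline, which the "
                    "GSuite format cannot escape"
                )
        if bare:
            lines.append(t.uri)
        else:
            lines.append("\t".join((t.uri, t.title) + tuple(v for _, v in t.metadata)))
    return "\n".join(lines) + ("\n" if lines else "")


def write_gsuite(suite: GSuite, path: str | Path) -> None:
    Path(path).write_text(format_gsuite(suite))


@dataclass(frozen=True)
class ValidationProblem:
    uri: str
    message: str


def validate_gsuite(suite: GSuite, genome: GenomeDefinition | None = None,
                    check_files: bool = False,
                    base_dir: str | Path | None = None
                    ) -> list[ValidationProblem]:
    """Collect per-track problems without aborting on the first.

    With ``check_files``, local files are opened and parsed as BED against
    the genome; remote URIs are reported as unsupported.
    """
    problems: list[ValidationProblem] = []
    if suite.n == 0:
        problems.append(ValidationProblem("<suite>", "suite contains no tracks"))
    for t in suite.tracks:
        if t.is_remote:
            if check_files:
                problems.append(ValidationProblem(
                    t.uri, "remote retrieval unsupported; fetch the file "
                           "locally and update the uri"))
            continue
        if not check_files:
            continue
        path = t.local_path
        if base_dir is not None and not path.is_absolute():
            path = Path(base_dir) / path
        if not path.exists():
            problems.append(ValidationProblem(t.uri, f"missing local file {path}"))
            continue
        if genome is not None:
            try:
                read_bed(path, genome, label=t.title)
            except BedFormatError as err:
                problems.append(ValidationProblem(t.uri, f"unparseable BED: {err}"))
    return problems


def filter_gsuite(suite: GSuite,
                  predicate: Callable[[GSuiteTrackRef], bool] | None = None,
                  *, column: str | None = None, value: str | None = None,
                  complement: bool = False) -> GSuite:
    """Order-preserving subset of a suite.

    Either pass an explicit ``predicate`` or a ``column == value`` equality
    (title and uri are addressable as columns).  ``complement=True`` returns
    the non-matching tracks instead.
    """
    if predicate is None:
        if column is None:
            raise ValueError("need a predicate or a column/value pair")
        if column not in ("uri", "title") + suite.metadata_columns:
            raise KeyError(
                f"unknown column {column!r}; declared columns are "
                f"{('uri', 'title') + suite.metadata_columns}"
            )

        def predicate(t: GSuiteTrackRef, _c=column, _v=value) -> bool:
            if _c == "uri":
                return t.uri == _v
            if _c == "title":
                return t.title == _v
            return t.metadata_dict.get(_c) == _v

    keep = [t for t in suite.tracks if bool(predicate(t)) != complement]
    return replace(suite, tracks=tuple(keep))


def load_suite_tracks(suite: GSuite, genome: GenomeDefinition,
                      base_dir: str | Path | None = None) -> list[Track]:
    """Load all referenced BED files as Tracks, in suite order.

    Duplicate titles are disambiguated with an index suffix so downstream
    per-label tables stay unambiguous.
    """
    titles = list(suite.titles())
    seen: dict[str, int] = {}
    labels: list[str] = []
    for title in titles:
        if titles.count(title) > 1:
            seen[title] = seen.get(title, 0) + 1
            labels.append(f"{title}.{seen[title]}")
        else:
            labels.append(title)
    out: list[Track] = []
    for ref, label in zip(suite.tracks, labels):
        if ref.is_remote:
            raise ValueError(
                f"track {ref.title!r} has remote uri {ref.uri!r}; fetch it "
                "locally first (remote retrieval is unsupported)"
            )
        path = ref.local_path
        if base_dir is not None and not path.is_absolute():
            path = Path(base_dir) / path
        try:
            out.append(read_bed(path, genome, label=label))
        except (OSError, BedFormatError) as err:
            raise type(err)(f"track {ref.title!r}: {err}") from None
    return out


def gsuite_from_uris(uris: Sequence[str]) -> GSuite:
    return GSuite(tracks=tuple(
        GSuiteTrackRef(uri=u, title=_default_title(u)) for u in uris
    ))
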