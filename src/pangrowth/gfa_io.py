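"""Streaming GFA v1.0 / v1.1 input and output.

Parses S-, L-, P- and W-lines of a Graphical Fragment Assembly file into an
in-memory pangenome graph model. P-lines (paths) and W-lines (walks) are
reduced to the same internal representation: an ordered list of oriented
steps. Unknown record types are skipped. Segment resolution is deferred to
the end of the stream, so record order does not matter.

Path names may carry a coordinate suffix ``name:start-end`` (0-based,
half-open, BED convention) and may follow the PanSN naming scheme
``sample#haplotype#contig`` used for automatic path grouping.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional

log = logging.getLogger(__name__)

__all__ = [
    "GfaError",
    "Segment",
    "Link",
    "Step",
    "PathRecord",
    "PangenomeGraph",
    "parse_gfa",
    "parse_path_name",
    "parse_pansn",
    "write_gfa",
]


class GfaError(ValueError):
    """Raised on malformed or inconsistent GFA input."""


@dataclass(frozen=True)
class Segment:
    """A node of the graph: a named DNA segment.

    ``sequence`` is retained only when the parser is asked for it; ``length``
    is always known (from the literal sequence or from the ``LN:i`` tag).
    """

    name: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise GfaError(
                f"segment {self.name!r}: length {self.length} != "
                f"sequence length {len(self.sequence)}"
            )
        if self.length < 0:
            raise GfaError(f"segment {self.name!r}: negative length")


@dataclass(frozen=True)
class Link:
    """An L-line: an adjacency between two oriented segments."""

    from_segment: str
    from_orient: str
    to_segment: str
    to_orient: str


@dataclass(frozen=True)
class Step:
    """One oriented segment visit inside a path."""

    segment: str
    orient: str


@dataclass
class PathRecord:
    """A path (P-line) or walk (W-line) through the graph.

    ``base_name`` is ``raw_name`` with any ``:start-end`` coordinate suffix
    removed; ``coord_range`` holds that suffix as a 0-based half-open
    interval in path bp coordinates. ``walk_meta`` keeps the native W-line
    fields (sample, hap_index, seq_id, seq_start, seq_end) for round-trip
    output.
    """

    raw_name: str
    base_name: str
    coord_range: Optional[tuple[int, int]]
    steps: tuple[Step, ...]
    origin: str  # "P" or "W"
    walk_meta: Optional[tuple[str, str, str, int, int]] = None

    def __post_init__(self) -> None:
        if not self.steps:
            raise GfaError(f"path {self.raw_name!r} has no steps")
        if self.coord_range is not None:
            start, end = self.coord_range
            if not (0 <= start < end):
                raise GfaError(
                    f"path {self.raw_name!r}: invalid coordinate range "
                    f"[{start},{end})"
                )


@dataclass
class PangenomeGraph:
    """Segments, links, and paths of a pangenome (variation) graph."""

    segments: dict[str, Segment] = field(default_factory=dict)
    links: list[Link] = field(default_factory=list)
    paths: list[PathRecord] = field(default_factory=list)

    def segment_length(self, name: str) -> int:
        return self.segments[name].length

    @property
    def total_bp(self) -> int:
        return sum(s.length for s in self.segments.values())

    def path_by_name(self, raw_name: str) -> PathRecord:
        for p in self.paths:
            if p.raw_name == raw_name:
                return p
        raise KeyError(raw_name)


# coordinate suffix: "name:123-456"; a literal en-dash is tolerated
_COORD_RE = re.compile(r"^(?P<base>.+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_path_name(raw_name: str) -> tuple[str, Optional[tuple[int, int]]]:
    """Split an optional ``:start-end`` coordinate suffix off a path name.

    The range is 0-based and half-open, matching BED. Returns
    ``(base_name, None)`` when no suffix is present.

    >>> parse_path_name("chr1:10-200")
    ('chr1', (10, 200))
    >>> parse_path_name("sample#1#ctg")
    ('sample#1#ctg', None)
    """
    if not raw_name:
        raise GfaError("empty path name")
    m = _COORD_RE.match(raw_name.replace("–", "-"))
    if m is None:
        return raw_name, None
    start, end = int(m.group("start")), int(m.group("end"))
    if start >= end:
        raise GfaError(
            f"path name {raw_name!r}: coordinate suffix start >= end"
        )
    return m.group("base"), (start, end)


def parse_pansn(base_name: str) -> tuple[str, str, str]:
    """Decompose a PanSN path name ``sample#haplotype#contig``.

    Returns ``(sample, haplotype_key, contig)`` where the haplotype grouping
    key is ``sample#haplotype``. A name without two ``#`` separators falls
    back to the whole name for both grouping modes.
    """
    parts = base_name.split("#", 2)
    if len(parts) == 3:
        sample, hap, contig = parts
        return sample, f"{sample}#{hap}", contig
    return base_name, base_name, base_name


_WALK_STEP_RE = re.compile(r"([><])([^><\s]+)")


def _parse_walk_string(walk: str, lineno: int) -> tuple[Step, ...]:
    steps = tuple(
        Step(seg, "+" if sign == ">" else "-")
        for sign, seg in _WALK_STEP_RE.findall(walk)
    )
    consumed = sum(1 + len(s.segment) for s in steps)
    if consumed != len(walk):
        raise GfaError(f"line {lineno}: malformed walk string {walk!r}")
    return steps


def _parse_pline_steps(seglist: str, lineno: int) -> tuple[Step, ...]:
    steps = []
    for item in seglist.split(","):
        if len(item) < 2 or item[-1] not in "+-":
            raise GfaError(
                f"line {lineno}: malformed path step {item!r} "
                "(expected '<segment><+|->')"
            )
        steps.append(Step(item[:-1], item[-1]))
    return tuple(steps)


def _segment_from_sline(
    fields: list[str], lineno: int, need_sequence: bool
) -> Segment:
    if len(fields) < 3:
        raise GfaError(f"line {lineno}: S-line with fewer than 3 fields")
    name, seq = fields[1], fields[2]
    ln_tag: Optional[int] = None
    for tag in fields[3:]:
        if tag.startswith("LN:i:"):
            ln_tag = int(tag[5:])
    if seq == "*":
        if ln_tag is None:
            raise GfaError(
                f"line {lineno}: segment {name!r} has sequence '*' and no "
                "LN:i tag; a length is required"
            )
        return Segment(name, ln_tag)
    if ln_tag is not None and ln_tag != len(seq):
        raise GfaError(
            f"line {lineno}: segment {name!r} LN tag {ln_tag} contradicts "
            f"sequence length {len(seq)}"
        )
    return Segment(name, len(seq), seq if need_sequence else None)


def parse_gfa(
    stream: Iterable[str] | IO[str], need_sequence: bool = False
) -> PangenomeGraph:
    """Parse GFA v1.0/v1.1 text into a :class:`PangenomeGraph`.

    Parameters
    ----------
    stream:
        An iterable of lines (an open text file, a list, ...).
    need_sequence:
        When True, segment sequences are stored on the graph; otherwise only
        lengths are kept, bounding memory by graph topology rather than
        total sequence.

    P-line segment lists and W-line walk strings produce identical step
    lists. Records may arrive in any order; referential integrity (paths and
    links against segments) is checked after the full stream is consumed.
    """
    graph = PangenomeGraph()
    deferred: list[tuple[int, PathRecord]] = []
    deferred_links: list[tuple[int, Link]] = []
    skipped: dict[str, int] = {}
    seen_path_names: set[str] = set()

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line:
            continue
        kind = line[0]
        fields = line.split("\t")
        if kind == "S":
            seg = _segment_from_sline(fields, lineno, need_sequence)
            if seg.name in graph.segments:
                raise GfaError(
                    f"line {lineno}: duplicate segment name {seg.name!r}"
                )
            graph.segments[seg.name] = seg
        elif kind == "L":
            if len(fields) < 5:
                raise GfaError(f"line {lineno}: L-line with fewer than 5 fields")
            deferred_links.append(
                (lineno, Link(fields[1], fields[2], fields[3], fields[4]))
            )
        elif kind == "P":
            if len(fields) < 3:
                raise GfaError(f"line {lineno}: P-line with fewer than 3 fields")
            raw_name = fields[1]
            base, coord = parse_path_name(raw_name)
            steps = _parse_pline_steps(fields[2], lineno)
            deferred.append(
                (lineno, PathRecord(raw_name, base, coord, steps, "P"))
            )
        elif kind == "W":
            if len(fields) < 7:
                raise GfaError(f"line {lineno}: W-line with fewer than 7 fields")
            sample, hap, seq_id = fields[1], fields[2], fields[3]
            seq_start, seq_end, walk = fields[4], fields[5], fields[6]
            steps = _parse_walk_string(walk, lineno)
            if seq_start == "*" or seq_end == "*":
                raw_name = f"{sample}#{hap}#{seq_id}"
                base, coord, meta = raw_name, None, (sample, hap, seq_id, 0, 0)
            else:
                s, e = int(seq_start), int(seq_end)
                raw_name = f"{sample}#{hap}#{seq_id}:{s}-{e}"
                base, coord = f"{sample}#{hap}#{seq_id}", (s, e)
                meta = (sample, hap, seq_id, s, e)
            deferred.append(
                (lineno, PathRecord(raw_name, base, coord, steps, "W", meta))
            )
        else:
            skipped[kind] = skipped.get(kind, 0) + 1

    for kind, count in sorted(skipped.items()):
        log.info("skipped %d line(s) of unhandled type %r", count, kind)

    for lineno, link in deferred_links:
        for seg in (link.from_segment, link.to_segment):
            if seg not in graph.segments:
                raise GfaError(
                    f"line {lineno}: link references unknown segment {seg!r}"
                )
        graph.links.append(link)
    for lineno, path in deferred:
        if path.raw_name in seen_path_names:
            raise GfaError(
                f"line {lineno}: duplicate path name {path.raw_name!r}"
            )
        seen_path_names.add(path.raw_name)
        for step in path.steps:
            if step.segment not in graph.segments:
                raise GfaError(
                    f"line {lineno}: path {path.raw_name!r} references "
                    f"unknown segment {step.segment!r}"
                )
        graph.paths.append(path)
    return graph


def write_gfa(graph: PangenomeGraph, stream: IO[str]) -> None:
    """Write a graph back out as GFA v1.1 (fixture round-trip support)."""
    stream.write("H\tVN:Z:1.1\n")
    for seg in graph.segments.values():
        if seg.sequence is not None:
            stream.write(f"S\t{seg.name}\t{seg.sequence}\n")
        else:
            stream.write(f"S\t{seg.name}\t*\tLN:i:{seg.length}\n")
    for link in graph.links:
        stream.write(
            f"L\t{link.from_segment}\t{link.from_orient}"
            f"\t{link.to_segment}\t{link.to_orient}\t0M\n"
        )
    for path in graph.paths:
        if path.origin == "W" and path.walk_meta is not None:
            sample, hap, seq_id, s, e = path.walk_meta
            walk = "".join(
                (">" if st.orient == "+" else "<") + st.segment
                for st in path.steps
            )
            stream.write(f"W\t{sample}\t{hap}\t{seq_id}\t{s}\t{e}\t{walk}\n")
        else:
            seglist = ",".join(st.segment + st.orient for st in path.steps)
            stream.write(f"P\t{path.raw_name}\t{seglist}\t*\n")
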