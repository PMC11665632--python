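"""From paths to coverage: countables, grouping, subsetting, histogram.

A *countable* is the unit being counted in the pangenome graph: a node
(segment), an edge (adjacency between two oriented segments), or a base
pair. The *coverage* of a countable is the number of distinct path groups
that contain it at least once — traversal multiplicity inside a path never
matters, which keeps highly repetitive sequence from inflating growth.

The end product of this module is the coverage histogram h(i): the
(bp-weighted, for base pairs) number of countables with coverage exactly i,
for i = 0..n groups. All growth/core curves downstream are computed from
h alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .gfa_io import GfaError, PangenomeGraph, PathRecord, Step, parse_pansn

log = logging.getLogger(__name__)

__all__ = [
    "CountableKind",
    "GroupAssignment",
    "SubsetSpec",
    "ExclusionSpec",
    "CoverageTable",
    "CoverageHistogram",
    "canonical_edge",
    "itemize_path",
    "group_paths",
    "restrict_path",
    "compute_coverage",
    "build_histogram",
    "edge_universe",
    "read_bed",
    "read_path_list",
    "read_grouping_table",
    "write_coverage_table_tsv",
    "write_histogram_tsv",
    "read_histogram_tsv",
]


class CountableKind(str, Enum):
    """What to count: graph nodes, edges, or base pairs."""

    node = "node"
    edge = "edge"
    bp = "bp"


EdgeKey = tuple[str, str, str, str]
Countable = Union[str, EdgeKey]


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


def canonical_edge(step_a: Step, step_b: Step) -> EdgeKey:
    """Canonical key for the edge traversed from ``step_a`` to ``step_b``.

    A traversal and its reverse complement — (a,oa)→(b,ob) and
    (b,¬ob)→(a,¬oa) — describe the same adjacency and must be counted once;
    the lexicographically smaller oriented form is the representative.
    """
    fwd: EdgeKey = (step_a.segment, step_a.orient, step_b.segment, step_b.orient)
    rev: EdgeKey = (step_b.segment, _flip(step_b.orient),
                    step_a.segment, _flip(step_a.orient))
    return min(fwd, rev)


def itemize_path(path: PathRecord, kind: CountableKind) -> set[Countable]:
    """The set of countables a path contains (duplicates collapse).

    Node and bp mode both return distinct segment names — in bp mode the
    bases enter later through per-segment weights. Edge mode returns the
    canonical edge keys of consecutive step pairs; a single-step path has
    an empty edge set.
    """
    kind = CountableKind(kind)
    if kind in (CountableKind.node, CountableKind.bp):
        return {st.segment for st in path.steps}
    return {
        canonical_edge(a, b) for a, b in zip(path.steps, path.steps[1:])
    }


@dataclass
class GroupAssignment:
    """Mapping of every path to exactly one group, with a stable order.

    n = number of groups replaces the raw path count everywhere downstream.
    """

    mapping: dict[str, str]
    groups: list[str]

    @property
    def n(self) -> int:
        return len(self.groups)

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        labels = set(self.groups)
        if len(labels) != len(self.groups):
            raise ValueError("group labels must be distinct")
        for path, grp in self.mapping.items():
            if grp not in labels:
                raise ValueError(f"path {path!r} maps to unknown group {grp!r}")


def group_paths(
    graph: PangenomeGraph,
    mode: str = "none",
    table: Optional[Mapping[str, str]] = None,
) -> GroupAssignment:
    """Group the graph's paths by path, PanSN sample/haplotype, or a table.

    ``mode`` is one of ``none`` (each path its own group), ``sample`` /
    ``haplotype`` (keys derived from PanSN names), or ``table`` (explicit
    path → group mapping, e.g. from a two-column TSV). Group order is the
    order of first appearance in the GFA (table mode: in the table).
    """
    mapping: dict[str, str] = {}
    groups: list[str] = []

    def add(path_name: str, label: str) -> None:
        mapping[path_name] = label
        if label not in mapping_seen:
            mapping_seen.add(label)
            groups.append(label)

    mapping_seen: set[str] = set()
    if mode == "table":
        if table is None:
            raise ValueError("table mode requires a mapping")
        missing = [p.raw_name for p in graph.paths if p.raw_name not in table]
        if missing:
            raise GfaError(
                "paths missing from grouping table: " + ", ".join(missing)
            )
        # group order follows first appearance in the table
        for name, label in table.items():
            if label not in mapping_seen:
                mapping_seen.add(label)
                groups.append(label)
        for p in graph.paths:
            mapping[p.raw_name] = table[p.raw_name]
        return GroupAssignment(mapping, groups)

    for p in graph.paths:
        if mode == "none":
            add(p.raw_name, p.raw_name)
        elif mode in ("sample", "haplotype"):
            sample, hap, _ = parse_pansn(p.base_name)
            add(p.raw_name, sample if mode == "sample" else hap)
        else:
            raise ValueError(f"unknown grouping mode {mode!r}")
    return GroupAssignment(mapping, groups)


@dataclass
class SubsetSpec:
    """Which parts of the pangenome to keep (empty spec keeps everything).

    Either whole paths by base name, or BED-style intervals
    (base_name, start, end) in path bp coordinates, 0-based half-open.
    """

    names: set[str] = field(default_factory=set)
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, ivs in self.intervals.items():
            for s, e in ivs:
                if not (0 <= s < e):
                    raise ValueError(
                        f"invalid interval [{s},{e}) for path {name!r}"
                    )

    @property
    def empty(self) -> bool:
        return not self.names and not self.intervals

    def matches_name(self, base_name: str) -> bool:
        return base_name in self.names

    def intervals_for(self, base_name: str) -> list[tuple[int, int]]:
        return self.intervals.get(base_name, [])


class ExclusionSpec(SubsetSpec):
    """Same shape as :class:`SubsetSpec`; empty means exclude nothing.

    Exclusion acts at the countable level: any countable matched by the
    spec through any path is deleted from the universe and from every
    path's set, not merely from the matched path.
    """


def read_bed(path: str) -> "SubsetSpec":
    """Read a BED (3+ columns, 0-based half-open) into a spec."""
    spec = SubsetSpec()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line with fewer than 3 columns: {line!r}")
            name, start, end = fields[0], int(fields[1]), int(fields[2])
            spec.intervals.setdefault(name, []).append((start, end))
    return spec


def read_path_list(path: str) -> "SubsetSpec":
    """Read a path-name list (one per line, optional ``:start-end`` suffix)."""
    from .gfa_io import parse_path_name

    spec = SubsetSpec()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            base, coord = parse_path_name(line)
            if coord is None:
                spec.names.add(base)
            else:
                spec.intervals.setdefault(base, []).append(coord)
    return spec


def read_grouping_table(path: str) -> dict[str, str]:
    """Read a two-column TSV mapping path name → group label."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"grouping table line needs 2 columns: {line!r}")
            table[fields[0]] = fields[1]
    return table


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class RestrictedPath:
    """Countables of one path surviving a subset/exclusion projection."""

    nodes: set[str]
    edges: set[EdgeKey]
    node_bp: dict[str, int]  # retained overlap length per node, bp mode


def restrict_path(
    path: PathRecord,
    segment_lengths: Mapping[str, int],
    spec: Optional[SubsetSpec],
) -> RestrictedPath:
    """Project a subset/exclusion spec onto one path's countables.

    BED intervals are mapped onto the step list via cumulative bp
    coordinates (a path's own ``:start-end`` suffix offsets the spec's
    coordinates). A node is retained iff it overlaps a spec interval by at
    least 1 bp and contributes its overlap length as bp weight, so node
    counts stay interpretable while bp totals are exact. An edge is
    retained iff both incident (originally consecutive) steps are retained.
    Whole-path name matches and empty specs retain everything.
    """
    lengths = [segment_lengths[st.segment] for st in path.steps]
    path_len = sum(lengths)

    def full() -> RestrictedPath:
        nodes = {st.segment for st in path.steps}
        edges = {
            canonical_edge(a, b) for a, b in zip(path.steps, path.steps[1:])
        }
        node_bp = {st.segment: segment_lengths[st.segment] for st in path.steps}
        return RestrictedPath(nodes, edges, node_bp)

    if spec is None or spec.empty:
        return full()
    if spec.matches_name(path.base_name):
        return full()
    raw_ivs = spec.intervals_for(path.base_name)
    if not raw_ivs:
        return RestrictedPath(set(), set(), {})

    offset = path.coord_range[0] if path.coord_range is not None else 0
    clipped = 0
    local: list[tuple[int, int]] = []
    for gs, ge in raw_ivs:
        s, e = gs - offset, ge - offset
        if s < 0 or e > path_len:
            clipped += 1
        s, e = max(s, 0), min(e, path_len)
        if s < e:
            local.append((s, e))
    if clipped:
        log.warning(
            "%d interval(s) extend beyond path %r (length %d); clipped",
            clipped, path.raw_name, path_len,
        )
    merged = _merge_intervals(local)

    kept_idx: list[int] = []
    overlaps: list[int] = []
    cum = 0
    for idx, length in enumerate(lengths):
        lo, hi = cum, cum + length
        ov = sum(
            max(0, min(hi, e) - max(lo, s)) for s, e in merged
        )
        if ov >= 1:
            kept_idx.append(idx)
            overlaps.append(ov)
        cum += length

    nodes: set[str] = set()
    node_bp: dict[str, int] = {}
    for idx, ov in zip(kept_idx, overlaps):
        seg = path.steps[idx].segment
        nodes.add(seg)
        node_bp[seg] = max(node_bp.get(seg, 0), ov)
    kept_set = set(kept_idx)
    edges = {
        canonical_edge(path.steps[i], path.steps[i + 1])
        for i in kept_idx
        if i + 1 in kept_set
    }
    return RestrictedPath(nodes, edges, node_bp)


def edge_universe(graph: PangenomeGraph) -> set[EdgeKey]:
    """All canonical edges: L-lines united with path-traversed adjacencies.

    Paths are the primary object; adjacencies they traverse are counted
    even when the corresponding L-line is absent (a warning reports how
    many such edges were found).
    """
    from_links = {
        canonical_edge(
            Step(l.from_segment, l.from_orient), Step(l.to_segment, l.to_orient)
        )
        for l in graph.links
    }
    from_paths: set[EdgeKey] = set()
    for p in graph.paths:
        from_paths.update(
            canonical_edge(a, b) for a, b in zip(p.steps, p.steps[1:])
        )
    missing = from_paths - from_links
    if missing and graph.links:
        log.warning(
            "%d path-traversed edge(s) have no corresponding L-line; "
            "counted anyway", len(missing),
        )
    return from_links | from_paths


@dataclass
class CoverageTable:
    """Coverage (distinct-group count) and weight per covered countable.

    ``weight`` is the bp length (retained overlap, maximal over paths) for
    node-derived keys in bp mode, else 1. ``universe_weight`` is the total
    weight of the countable universe after exclusion; it feeds h(0).
    ``membership`` records, per group, the set of countables it covers.
    """

    kind: CountableKind
    coverage: dict[Countable, int]
    weight: dict[Countable, int]
    n: int
    universe_weight: int
    membership: dict[str, set[Countable]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, cov in self.coverage.items():
            if not (1 <= cov <= self.n):
                raise ValueError(f"coverage {cov} out of range for {key!r}")
        for key, w in self.weight.items():
            if w < 1:
                raise ValueError(f"non-positive weight for {key!r}")


def compute_coverage(
    graph: PangenomeGraph,
    kind: CountableKind,
    grouping: GroupAssignment,
    subset: Optional[SubsetSpec] = None,
    exclusion: Optional[ExclusionSpec] = None,
) -> CoverageTable:
    """Count, per countable, the distinct groups containing it.

    A group with several member paths through the same countable
    contributes 1. Subsetting restricts which countables each path
    contributes (and their bp weight); exclusion globally deletes matched
    countables from the universe and from every path's set.
    """
    kind = CountableKind(kind)
    seg_len = {name: s.length for name, s in graph.segments.items()}

    projections = {
        p.raw_name: restrict_path(p, seg_len, subset) for p in graph.paths
    }

    excluded: set[Countable] = set()
    if exclusion is not None and not exclusion.empty:
        for p in graph.paths:
            ex = restrict_path(p, seg_len, exclusion)
            if kind == CountableKind.edge:
                excluded.update(ex.edges)
            else:
                excluded.update(ex.nodes)

    membership: dict[str, set[Countable]] = {g: set() for g in grouping.groups}
    weight: dict[Countable, int] = {}
    for p in graph.paths:
        proj = projections[p.raw_name]
        label = grouping.mapping[p.raw_name]
        if kind == CountableKind.edge:
            keys: Iterable[Countable] = proj.edges - excluded
            membership[label].update(keys)
        else:
            keys = proj.nodes - excluded
            membership[label].update(keys)
            if kind == CountableKind.bp:
                for seg in keys:
                    w = proj.node_bp[seg]
                    weight[seg] = max(weight.get(seg, 0), w)

    coverage: dict[Countable, int] = {}
    for grp_keys in membership.values():
        for key in grp_keys:
            coverage[key] = coverage.get(key, 0) + 1
    if kind != CountableKind.bp:
        weight = {key: 1 for key in coverage}

    if kind == CountableKind.node:
        universe = len(graph.segments) - len(
            {k for k in excluded if isinstance(k, str)}
        )
    elif kind == CountableKind.bp:
        universe = graph.total_bp - sum(
            seg_len[k] for k in excluded if isinstance(k, str)
        )
    else:
        universe = len(edge_universe(graph) - excluded)

    return CoverageTable(
        kind=kind,
        coverage=coverage,
        weight=weight,
        n=grouping.n,
        universe_weight=universe,
        membership=membership,
    )


@dataclass
class CoverageHistogram:
    """h(i): total countable weight at coverage exactly i, i = 0..n."""

    kind: CountableKind
    n: int
    h: np.ndarray  # length n + 1

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if self.h.shape != (self.n + 1,):
            raise ValueError("histogram must have length n + 1")
        if (self.h < 0).any():
            raise ValueError("histogram entries must be non-negative")

    @property
    def total_covered(self) -> float:
        """Σ_{i≥1} h(i): total weight touched by at least one group."""
        return float(self.h[1:].sum())

    @property
    def total(self) -> float:
        return float(self.h.sum())


def build_histogram(
    table: CoverageTable, graph: Optional[PangenomeGraph] = None
) -> CoverageHistogram:
    """Tally the coverage table into h(i).

    h(0) is the universe weight not covered by any group; it never enters a
    curve but closes the conservation identity Σ_{i≥0} h(i) = universe
    weight (total graph sequence length in unrestricted bp mode).
    """
    h = np.zeros(table.n + 1)
    for key, cov in table.coverage.items():
        h[cov] += table.weight[key]
    covered = h[1:].sum()
    h[0] = max(table.universe_weight - covered, 0.0)
    return CoverageHistogram(kind=table.kind, n=table.n, h=h)


def _fmt_key(key: Countable) -> str:
    if isinstance(key, str):
        return key
    a, oa, b, ob = key
    return f"{a}{oa}>{b}{ob}"


def write_coverage_table_tsv(table: CoverageTable, stream: IO[str],
                             groups: Sequence[str]) -> None:
    """Full per-countable coverage table: id, weight, coverage, 0/1 per group."""
    header = ["countable", "weight", "coverage"] + list(groups)
    stream.write("\t".join(header) + "\n")
    for key in sorted(table.coverage, key=_fmt_key):
        row = [_fmt_key(key), str(table.weight[key]), str(table.coverage[key])]
        row += [
            "1" if key in table.membership.get(g, ()) else "0" for g in groups
        ]
        stream.write("\t".join(row) + "\n")


def write_histogram_tsv(hist: CoverageHistogram, stream: IO[str]) -> None:
    stream.write("coverage\th\n")
    for i, v in enumerate(hist.h):
        stream.write(f"{i}\t{v:.10g}\n")


def read_histogram_tsv(path: str, kind: CountableKind = CountableKind.node
                       ) -> CoverageHistogram:
    """Read a histogram TSV written by :func:`write_histogram_tsv`."""
    rows: list[tuple[int, float]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("coverage"):
            raise ValueError(f"{path}: not a histogram TSV")
        for line in fh:
            if not line.strip():
                continue
            i, v = line.split("\t")
            rows.append((int(i), float(v)))
    rows.sort()
    n = rows[-1][0]
    h = np.zeros(n + 1)
    for i, v in rows:
        h[i] = v
    return CoverageHistogram(kind=kind, n=n, h=h)
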