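"""Synthetic pangenome graphs with known ground truth, plus exact oracles.

The generator emits a GFA v1.1 text together with the exact per-path
countable sets for all three kinds (nodes, edges, base pairs), so every
other module can be tested without external data. Structure is statistical,
not biological: each path samples each segment independently with
probability p, optionally revisiting segments (duplication) and reversing
step orientation (inversion); segment lengths are deliberately non-uniform
so bp weighting is genuinely exercised.

The oracles implement the two defining views of pangenome growth literally,
by exhaustive enumeration — average union size over all C(n,m) subsets, and
average incremental union over all n! orders — and serve as the independent
reference the closed-form curves are checked against. They never sample.
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "generate_gfa",
    "write_ground_truth_json",
    "oracle_subset_growth",
    "oracle_permutation_growth",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic graph generator.

    p is the per-segment inclusion probability of each path; duplication
    and inversion rates control step revisits and reverse orientation.
    With ``pansn`` the paths are named sample#haplotype#contig (two
    haplotype paths per sample), enabling grouping tests.
    """

    n_paths: int = 5
    n_segments: int = 12
    length_range: tuple[int, int] = (2, 12)
    p: float = 0.6
    duplication_rate: float = 0.1
    inversion_rate: float = 0.1
    pansn: bool = False
    walks: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_paths < 1 or self.n_segments < 1:
            raise ValueError("need at least one path and one segment")
        if not (0 < self.p <= 1):
            raise ValueError("inclusion probability must be in (0, 1]")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid segment length range")


# local canonicalization keeps the ground truth independent of abacus
def _canon(a: str, oa: str, b: str, ob: str) -> tuple[str, str, str, str]:
    flip = {"+": "-", "-": "+"}
    return min((a, oa, b, ob), (b, flip[ob], a, flip[oa]))


@dataclass
class GroundTruth:
    """Exact per-path countable sets and segment lengths of a fixture."""

    seg_length: dict[str, int]
    # path raw_name -> {"node": set, "edge": set, "bp": {seg: length}}
    path_sets: dict[str, dict[str, object]] = field(default_factory=dict)

    def sets_for(self, kind: str) -> dict[str, Union[set, dict]]:
        return {name: d[kind] for name, d in self.path_sets.items()}

    def weighted_sets(self, kind: str) -> dict[str, dict[object, int]]:
        """Per-path {countable: weight} for oracle consumption."""
        out: dict[str, dict[object, int]] = {}
        for name, d in self.path_sets.items():
            if kind == "bp":
                out[name] = dict(d["bp"])  # seg -> length
            else:
                out[name] = {key: 1 for key in d[kind]}
        return out


def generate_gfa(spec: FixtureSpec) -> tuple[str, GroundTruth]:
    """Emit a synthetic GFA v1.1 text with its exact ground truth.

    Segments get random DNA sequences with lengths uniform on the spec's
    range; every consecutive oriented pair traversed by a path receives an
    L-line. Fixed seed → byte-identical output.
    """
    # independent streams: changing e.g. the duplication rate must not
    # perturb the inclusion draws of the same seed
    rng_seq = random.Random(f"{spec.seed}:seq")
    rng_incl = random.Random(f"{spec.seed}:incl")
    rng_orient = random.Random(f"{spec.seed}:orient")
    rng_dup = random.Random(f"{spec.seed}:dup")
    seg_names = [f"s{i + 1}" for i in range(spec.n_segments)]
    lo, hi = spec.length_range
    seg_length = {name: rng_seq.randint(lo, hi) for name in seg_names}
    seg_seq = {
        name: "".join(rng_seq.choice(_BASES) for _ in range(seg_length[name]))
        for name in seg_names
    }

    truth = GroundTruth(seg_length=dict(seg_length))
    path_steps: list[tuple[str, list[tuple[str, str]]]] = []
    for k in range(spec.n_paths):
        chosen = [s for s in seg_names if rng_incl.random() < spec.p]
        if not chosen:
            chosen = [rng_incl.choice(seg_names)]
        steps = [
            (s, "-" if rng_orient.random() < spec.inversion_rate else "+")
            for s in chosen
        ]
        # duplication: revisit an already-included segment at a random spot
        extra = [s for s in chosen if rng_dup.random() < spec.duplication_rate]
        for s in extra:
            orient = "-" if rng_dup.random() < spec.inversion_rate else "+"
            steps.insert(rng_dup.randint(0, len(steps)), (s, orient))
        if spec.pansn:
            name = f"S{k // 2:02d}#{k % 2 + 1}#chr1"
        else:
            name = f"path{k + 1}"
        path_steps.append((name, steps))

        nodes = {s for s, _ in steps}
        edges = {
            _canon(a, oa, b, ob)
            for (a, oa), (b, ob) in zip(steps, steps[1:])
        }
        truth.path_sets[name] = {
            "node": nodes,
            "edge": edges,
            "bp": {s: seg_length[s] for s in nodes},
        }

    lines = ["H\tVN:Z:1.1"]
    for name in seg_names:
        lines.append(f"S\t{name}\t{seg_seq[name]}")
    links_seen: set[tuple[str, str, str, str]] = set()
    for _, steps in path_steps:
        for (a, oa), (b, ob) in zip(steps, steps[1:]):
            if (a, oa, b, ob) not in links_seen:
                links_seen.add((a, oa, b, ob))
                lines.append(f"L\t{a}\t{oa}\t{b}\t{ob}\t0M")
    for name, steps in path_steps:
        if spec.walks:
            sample, hap, seq_id = (name.split("#", 2) + ["1", name])[:3] \
                if "#" in name else (name, "1", "chr1")
            length = sum(seg_length[s] for s, _ in steps)
            walk = "".join((">" if o == "+" else "<") + s for s, o in steps)
            lines.append(f"W\t{sample}\t{hap}\t{seq_id}\t0\t{length}\t{walk}")
        else:
            seglist = ",".join(s + o for s, o in steps)
            lines.append(f"P\t{name}\t{seglist}\t*")
    text = "\n".join(lines) + "\n"

    if spec.walks:
        # walk identities are synthesized as sample#hap#seq:start-end
        remapped: dict[str, dict[str, object]] = {}
        for (name, steps), old in zip(path_steps, truth.path_sets.items()):
            sample, hap, seq_id = (name.split("#", 2) + ["1", name])[:3] \
                if "#" in name else (name, "1", "chr1")
            length = sum(seg_length[s] for s, _ in steps)
            remapped[f"{sample}#{hap}#{seq_id}:0-{length}"] = old[1]
        truth.path_sets = remapped
    return text, truth


def write_ground_truth_json(truth: GroundTruth, stream: IO[str]) -> None:
    """JSON sidecar: per-path countable sets, edges as 4-tuples."""
    doc = {
        "seg_length": truth.seg_length,
        "paths": {
            name: {
                "node": sorted(d["node"]),
                "edge": sorted(list(e) for e in d["edge"]),
                "bp": dict(sorted(d["bp"].items())),
            }
            for name, d in truth.path_sets.items()
        },
    }
    json.dump(doc, stream, indent=1)


WeightedSet = Mapping[object, Union[int, float]]


def _union_at_least(sets: Sequence[WeightedSet], t: int) -> float:
    counts: dict[object, int] = {}
    weights: dict[object, float] = {}
    for s in sets:
        for key, w in s.items():
            counts[key] = counts.get(key, 0) + 1
            weights[key] = max(weights.get(key, 0.0), float(w))
    return sum(weights[k] for k, c in counts.items() if c >= t)


def oracle_subset_growth(
    path_sets: Sequence[WeightedSet], m: int, t: int
) -> float:
    """Average weighted count of countables in >= t of m chosen sets,
    over ALL C(n,m) subsets, by explicit enumeration.

    This is the defining average the closed-form curves must reproduce;
    n is capped at 12 because the enumeration is exponential.
    """
    n = len(path_sets)
    if n > 12:
        raise ValueError("enumeration oracle capped at n <= 12")
    if not (1 <= m <= n):
        raise ValueError("require 1 <= m <= n")
    total = 0.0
    count = 0
    for combo in itertools.combinations(range(n), m):
        total += _union_at_least([path_sets[i] for i in combo], t)
        count += 1
    return total / count


def oracle_permutation_growth(
    path_sets: Sequence[WeightedSet],
) -> np.ndarray:
    """Average cumulative union size at each prefix length over all n! orders.

    The order-based definition of pangenome growth, enumerated literally;
    n is capped at 7 (5040 orders).
    """
    n = len(path_sets)
    if n > 7:
        raise ValueError("permutation oracle capped at n <= 7")
    totals = np.zeros(n)
    count = 0
    for order in itertools.permutations(range(n)):
        seen: dict[object, float] = {}
        for k, idx in enumerate(order):
            for key, w in path_sets[idx].items():
                seen[key] = max(seen.get(key, 0.0), float(w))
            totals[k] += sum(seen.values())
        count += 1
    return totals / count
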