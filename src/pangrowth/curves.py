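"""Exact growth, core, and quorum-core curves from a coverage histogram.

Pangenome growth at subset size m is the average size of the union of all
C(n,m) combinations of m groups — equivalently, the average over all
inclusion orders of the cumulative union after m additions. Instead of
sampling permutations, each countable's contribution is computed in closed
form from its coverage i: a countable covered by i of the n groups is
present (with quorum threshold t) in

    Σ_{j=t}^{min(i,m)} C(i,j) · C(n−i, m−j)

of the C(n,m) subsets, which for t=1 collapses to C(n,m) − C(n−i,m). The
coverage histogram h(i) therefore suffices to evaluate every curve exactly:

    value(m) = Σ_i h(i) · P[at least t(m) of the i covering groups drawn],

with t(m) = max(c, ⌈q·m⌉) combining the coverage threshold c and the quorum
q. Growth is (c=1, q=0); the strict core is q=1; relaxed cores take
0 < q < 1. All ratios are exact integer arithmetic reduced to float at the
last step, so values are reliable far beyond the range where C(n,m)
overflows doubles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import IO, Mapping, Sequence, Union

import numpy as np

from .abacus import CoverageHistogram

__all__ = [
    "CurveSpec",
    "GrowthCurve",
    "binom",
    "tail_weight",
    "growth_curve",
    "core_curve",
    "ordered_growth",
    "write_curves_tsv",
    "read_curves_tsv",
]


def binom(a: int, b: int) -> int:
    """Exact binomial coefficient C(a, b); 0 outside 0 <= b <= a."""
    if b < 0 or b > a:
        return 0
    return math.comb(a, b)


def _as_fraction(q: Union[int, float, Fraction]) -> Fraction:
    if isinstance(q, Fraction):
        return q
    if isinstance(q, int):
        return Fraction(q)
    # decimal user inputs like 0.3 mean 3/10, not the nearest double
    return Fraction(q).limit_denominator(10**6)


@dataclass(frozen=True)
class CurveSpec:
    """A (coverage threshold c, quorum q) curve request.

    c >= 1 discards countables below an absolute coverage floor; the quorum
    q in [0,1] is the fraction of the m chosen groups that must contain a
    countable (threshold ⌈q·m⌉, an at-least constraint).
    """

    coverage: int = 1
    quorum: Union[float, Fraction] = 0

    def __post_init__(self) -> None:
        if self.coverage < 1:
            raise ValueError("coverage threshold must be >= 1")
        q = _as_fraction(self.quorum)
        if not (0 <= q <= 1):
            raise ValueError("quorum must lie in [0, 1]")

    def threshold(self, m: int) -> int:
        """t(m) = max(c, ⌈q·m⌉)."""
        q = _as_fraction(self.quorum)
        return max(self.coverage, math.ceil(q * m))

    def label(self) -> str:
        return f"c{self.coverage}_q{float(_as_fraction(self.quorum)):g}"


@dataclass
class GrowthCurve:
    """Expected (weighted) countable totals for subset sizes m = 1..n."""

    spec: CurveSpec
    n: int
    values: np.ndarray  # index 0 holds m=1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n,):
            raise ValueError("curve must have one value per m = 1..n")

    def value_at(self, m: int) -> float:
        return float(self.values[m - 1])


def _tail_count(n: int, i: int, m: int, t: int) -> int:
    """Number of m-subsets of n groups containing >= t of the i covering ones."""
    if t <= 0:
        return binom(n, m)
    if t == 1:
        return binom(n, m) - binom(n - i, m)
    return sum(binom(i, j) * binom(n - i, m - j)
               for j in range(t, min(i, m) + 1))


def tail_weight(n: int, i: int, m: int, t: int) -> float:
    """P[a uniform random m-subset of n groups contains >= t of i marked ones].

    Hypergeometric tail, computed from exact integers. For t=1 this equals
    1 − C(n−i, m)/C(n, m): the chance the subset hits at least one of the i
    groups covering a countable.
    """
    if not (0 <= i <= n):
        raise ValueError("require 0 <= i <= n")
    if not (1 <= m <= n):
        raise ValueError("require 1 <= m <= n")
    if t < 0:
        raise ValueError("require t >= 0")
    return float(Fraction(_tail_count(n, i, m, t), binom(n, m)))


def _histogram_fractions(hist: CoverageHistogram) -> list[Fraction]:
    out = []
    for v in hist.h:
        f = Fraction(v).limit_denominator(10**9) if v % 1 else Fraction(int(v))
        out.append(f)
    return out


def growth_curve(hist: CoverageHistogram, spec: CurveSpec) -> GrowthCurve:
    """Exact expected curve for one (c, q) spec.

    value(m) = Σ_{i=1}^{n} h(i) · tail_weight(n, i, m, t(m)). With the
    default spec (c=1, q=0) this is the pangenome growth curve; weighted
    (bp) histograms flow through unchanged.
    """
    n = hist.n
    if n < 1:
        raise ValueError("histogram must cover at least one group")
    hfrac = _histogram_fractions(hist)
    values = np.empty(n)
    for m in range(1, n + 1):
        t = spec.threshold(m)
        denom = binom(n, m)
        acc = Fraction(0)
        for i in range(1, n + 1):
            if hfrac[i]:
                acc += hfrac[i] * Fraction(_tail_count(n, i, m, t), denom)
        values[m - 1] = float(acc)
    return GrowthCurve(spec=spec, n=n, values=values)


def core_curve(hist: CoverageHistogram,
               q: Union[float, Fraction] = 1) -> GrowthCurve:
    """Core curve: countables present in at least ⌈q·m⌉ of the m groups.

    q=1 is the strict core — value(m) = Σ_{i>=m} h(i)·C(i,m)/C(n,m), ending
    at h(n) for m=n. q=0 is rejected: that is the growth curve, and the
    caller should ask for it explicitly.
    """
    qf = _as_fraction(q)
    if qf == 0:
        raise ValueError("q=0 degenerates to the growth curve; request that "
                         "explicitly via growth_curve")
    return growth_curve(hist, CurveSpec(coverage=1, quorum=qf))


def ordered_growth(
    group_sets: Mapping[str, Mapping[object, Union[int, float]]],
    order: Sequence[str],
) -> np.ndarray:
    """Cumulative weighted union size along one fixed group order.

    ``group_sets`` maps each group label to {countable: weight}; entry k of
    the result is the weighted size of the union of the first k+1 groups
    (a countable seen with different weights counts its maximum). No
    averaging — this is the single-order growth histogram.
    """
    if sorted(order) != sorted(group_sets):
        raise ValueError("order must be a permutation of the group labels")
    seen: dict[object, float] = {}
    out = np.empty(len(order))
    for k, label in enumerate(order):
        for key, w in group_sets[label].items():
            seen[key] = max(seen.get(key, 0.0), float(w))
        out[k] = sum(seen.values())
    return out


def write_curves_tsv(curves: Sequence[GrowthCurve], stream: IO[str]) -> None:
    """One row per m, one column per (c,q) spec."""
    if not curves:
        raise ValueError("no curves to write")
    n = curves[0].n
    if any(c.n != n for c in curves):
        raise ValueError("curves disagree on n")
    stream.write("m\t" + "\t".join(c.spec.label() for c in curves) + "\n")
    for m in range(1, n + 1):
        row = "\t".join(f"{c.value_at(m):.10g}" for c in curves)
        stream.write(f"{m}\t{row}\n")


def read_curves_tsv(path: str) -> dict[str, np.ndarray]:
    """Read a curves TSV back as {column label: values for m = 1..n}."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "m":
            raise ValueError(f"{path}: not a curves TSV")
        cols: dict[str, list[float]] = {name: [] for name in header[1:]}
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            for name, val in zip(header[1:], fields[1:]):
                cols[name].append(float(val))
    return {name: np.asarray(vals) for name, vals in cols.items()}
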