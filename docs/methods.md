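# Methods

## The model

A pangenome graph (variation graph) is a sequence graph whose nodes carry
DNA segments and whose paths spell out the constituent genomes. `pangrowth`
quantifies how much of the graph is shared or gained as genomes are added,
counting any of three *countables*: nodes, edges (adjacencies between
oriented segments, direction-insensitive), or base pairs (nodes weighted by
their length).

The **coverage** of a countable is the number of distinct path groups that
contain it at least once. Traversal multiplicity is deliberately ignored: a
path that loops through a segment five times contributes coverage 1. This
keeps highly repetitive sequence from inflating growth and core estimates.

The **pangenome growth curve** at subset size m is the expected size of the
union of m groups, averaged uniformly over all C(n, m) subsets of the n
groups (equivalently: the average cumulative union over all n! inclusion
orders). The **core curve** is the analogous expectation for countables
present in all m chosen groups, relaxed by a quorum q ∈ (0, 1] to "present
in at least ⌈q·m⌉ of the m".

## Exact computation

No sampling is involved. All curves are evaluated in closed form from the
coverage histogram h(i) — the (bp-weighted) number of countables with
coverage exactly i. A countable covered by i groups is present in at least
t of a random m-subset with probability

    P(n, i, m, t) = Σ_{j=t}^{min(i,m)} C(i,j)·C(n−i, m−j) / C(n,m),

the hypergeometric tail; for t = 1 this collapses to 1 − C(n−i,m)/C(n,m).
Every curve value is

    value(m) = Σ_{i=1}^{n} h(i) · P(n, i, m, t(m)),   t(m) = max(c, ⌈q·m⌉),

where c ≥ 1 is an absolute coverage-threshold floor and q the quorum.
Growth is (c=1, q=0); the strict core is q=1.

All binomials are exact Python integers and each ratio is reduced with
`fractions.Fraction` before a single final conversion to float, so results
hold to well below 1e-9 relative error at any n where C(n,m) would long
have overflowed doubles. The generic double sum costs O(n²) per curve point
(O(n³) per curve); the t=1 shortcut is O(n) per point. This is more than
fast enough for realistic group counts (n is the number of samples or
haplotypes, typically tens to hundreds).

Quorum rounding uses the ceiling: q=0.5 at m=3 demands presence in 2 of
the 3 chosen groups. The coverage threshold c combines with the quorum as
t(m) = max(c, ⌈q·m⌉) — a single monotone rule honouring both constraints.
q is interpreted as a decimal (0.3 means 3/10 exactly, via a bounded
rational conversion), so thresholds never wobble on floating-point
representation.

h(0) — the universe weight never touched by any group — is carried for
conservation checks and reporting only; no curve consumes it.

## Counting semantics

* **Edges** are canonicalized under reverse complement: the traversals
  (a,oa)→(b,ob) and (b,¬ob)→(a,¬oa) are the same adjacency; the
  lexicographically smaller oriented form is the key. Orientation otherwise
  matters: (s1+→s2+) and (s1+→s2−) are distinct edges.
* **Edge universe**: adjacencies traversed by paths are counted even when
  the GFA lacks the matching L-line (a warning reports the count); the
  universe is the union of L-line edges and path-traversed edges.
* **Grouping**: paths can be grouped per path (default), by PanSN sample or
  haplotype (`sample#haplotype#contig` names; malformed names fall back to
  themselves), or by an explicit table. The group count n replaces the path
  count everywhere.
* **Subsetting** projects BED intervals (0-based, half-open) onto each
  path's cumulative bp coordinates; a path's own `name:start-end` suffix
  offsets the spec coordinates. A node overlapping the spec by ≥ 1 bp is
  retained for node counting but contributes only its overlap length in bp
  mode; an edge survives iff both its (originally consecutive) endpoints
  are retained. Intervals reaching beyond the path are clipped with a
  warning.
* **Exclusion** is global: a countable matched by the exclusion spec (via
  any path) is deleted from the universe and from every path's set. In bp
  mode an excluded node leaves entirely.
* When different paths retain different partial overlaps of the same node,
  the histogram uses the **maximum** retained overlap as that node's
  weight: a base pair is one countable, and max-overlap approximates
  per-base resolution without per-base bookkeeping. An exact per-base mode
  (splitting nodes at interval breakpoints) would be a natural extension;
  it is not implemented.

## Extrapolation

Three estimators are offered side by side, without model selection:

* **Power law (Heaps)** on the growth increments Δ(m) = value(m) −
  value(m−1): Δ(m) = κ·m^(−α), fitted by ordinary linear regression of
  log Δ on log m (convex, deterministic; a nonlinear fit of the same model
  would weight points differently). α ≤ 1 is reported as an *open*
  pangenome, α > 1 as *closed*. Non-positive increments cannot enter the
  log fit and are dropped with a warning. The extrapolant continues the
  observed curve: F(M) = value(n) + Σ_{m=n+1}^{M} κ·m^(−α), hence is exact
  at m = n by construction.
* **Exponential decay** on the strict core curve: F(m) = κ_c·e^(−m/τ_c) +
  Ω via nonlinear least squares, with Ω the asymptotic core size.
  Initialization Ω₀ = min, κ₀ = max − min, τ₀ = n/4 and bounds κ, Ω ≥ 0,
  τ > 0 give robust convergence on monotone decreasing data.
* **Chao2**, nonparametric, from incidence counts: with S_obs = Σ_{i≥1}
  h(i), q1 = h(1), q2 = h(2), the classic estimate is S_obs + q1²/(2·q2),
  falling back to the bias-corrected S_obs + q1(q1−1)/2 when q2 = 0; the
  bias-corrected variant S_obs + ((n−1)/n)·q1(q1−1)/(2(q2+1)) is reported
  alongside. The estimate never drops below S_obs.

The power-law and exponential parameterizations follow standard pangenome
practice; the method names alone do not pin down a formula, so the precise
forms above are this package's documented choice.

## Synthetic data

The fixture generator emits GFA v1.1 graphs together with exact per-path
countable sets (the ground truth). Each of the n paths includes each
segment independently with probability p (default 0.6); segment lengths
are uniform on 2–12 bp with genuine random DNA sequences so bp weighting is
exercised with non-uniform weights; duplication (default 0.1) re-inserts
visited segments to exercise multiplicity insensitivity; inversion
(default 0.1) flips step orientation to exercise edge canonicalization.
Independent RNG streams drive inclusion, orientation, and duplication, so
changing one rate leaves the other draws untouched. Test fixtures use
3–8 paths and ~12 segments: large enough that all coverage classes occur,
small enough that the brute-force oracles (all C(n,m) subsets; all n!
orders for n ≤ 6) run in milliseconds, and validation sweeps use 100
seeded replicates.

What the generator does not emulate: biological variation structure (SNP
and SV spectra, linkage, shared haplotype blocks), bubble topology of real
graph builders, or chromosome-scale path lengths. Passing tests therefore
demonstrate the *exactness of the combinatorics and bookkeeping* on
arbitrary path-set structure — which is the method's claim — not
robustness to any particular biological signal, of which the method has
none to exploit: the computation depends on the input only through h(i).

The oracles are exhaustive enumeration, never sampling: the product's
claim is exactness, so its reference must be exact too.

## Numerical and design choices

* Exact integer combinatorics throughout; float conversion last.
* Curve values are expectations and are reported unrounded.
* The coordinate suffix `name:start-end` and all BED input are 0-based
  half-open — one convention across every coordinate input.
* Degenerate inputs: an empty histogram yields an all-zero curve; q=0
  passed to the core-curve routine is rejected (it *is* the growth curve —
  the caller must say so); a constant core curve fits κ_c ≈ 0 with Ω at
  the constant; fewer than two positive increments abort the power-law fit.
* P-line overlap CIGARs are ignored (coverage counting does not consume
  them); GFA v2 records, containments, and jumps are out of scope.
* Runs are single-threaded and deterministic; a `--threads` flag is
  accepted for interface compatibility and does not affect results.

## Limitations

* The max-overlap bp rule under subsetting is an approximation when
  overlapping BED features retain different fractions of one node across
  paths (see above).
* Extrapolations are educated estimates: Heaps and exponential-decay fits
  assume the parametric form continues beyond n, and Chao2 assumes
  exchangeable incidence sampling. They agree with each other only insofar
  as the data do.
* The HTML report is static (embedded PNG plots and TSV tables), not
  interactive.
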