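"""Inversion polarity, reversal histories, branch assignment and rates.

Polarity of each rearrangement is read from marker order around the
breakpoints against an outgroup; multi-inversion regions are resolved by
sorting signed permutations by reversals (exact Hannenhalli-Pevzner distance
on the breakpoint graph, with hurdle and fortress corrections); inversions
are placed on the species tree under a single-origin (Dollo-like)
assumption; and per-lineage fixation rates are compared with an exact
conditional Poisson test (binomial conditioning on the total count).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass

from scipy.stats import binom

from .synteny import SignedPermutation
from .tree import SpeciesTree

# ---------------------------------------------------------------------------
# polarity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolarityCall:
    """Which of two taxa carries the ancestral arrangement at one breakpoint.

    ``status`` is "resolved", "no_inversion" (both match the outgroup) or
    "undetermined" (neither matches, or too few shared markers)."""

    ancestral_taxon: str | None
    derived_taxon: str | None
    status: str
    evidence: dict[str, tuple[str, ...]]


def _matches(order: tuple[str, ...], reference: tuple[str, ...]) -> bool:
    # a full reversal is the same local arrangement read from the other strand
    return order == reference or order == reference[::-1]


def infer_polarity(
    order_taxon_a,
    order_taxon_b,
    order_outgroup,
    taxon_a: str = "taxon_a",
    taxon_b: str = "taxon_b",
    min_shared: int = 4,
) -> PolarityCall:
    """The taxon whose breakpoint-flanking marker order equals the outgroup's
    is ancestral; the other is derived. Orders are marker-id sequences
    spanning one breakpoint; a window whose order (or content — the derived
    junction juxtaposes different genes) differs from the outgroup's is the
    derived arrangement. Never guesses: a taxon sharing fewer than
    ``min_shared`` markers with the outgroup window, or neither taxon
    matching the outgroup, yields an undetermined call."""
    a, b, out = tuple(order_taxon_a), tuple(order_taxon_b), tuple(order_outgroup)
    evidence = {taxon_a: a, taxon_b: b, "outgroup": out}
    overlap_a = len(set(a) & set(out))
    overlap_b = len(set(b) & set(out))
    if min(overlap_a, overlap_b) < min_shared // 2 or max(overlap_a, overlap_b) < min_shared:
        return PolarityCall(None, None, "undetermined", evidence)
    match_a, match_b = _matches(a, out), _matches(b, out)
    if match_a and match_b:
        return PolarityCall(None, None, "no_inversion", evidence)
    if match_a:
        return PolarityCall(taxon_a, taxon_b, "resolved", evidence)
    if match_b:
        return PolarityCall(taxon_b, taxon_a, "resolved", evidence)
    return PolarityCall(None, None, "undetermined", evidence)


# ---------------------------------------------------------------------------
# sorting signed permutations by reversals (Hannenhalli-Pevzner)
# ---------------------------------------------------------------------------


def _breakpoint_graph(elements: tuple[int, ...]):
    """Unsigned point representation framed by 0 and 2n+1, its cycles, and
    the gray edges (as position pairs) grouped by cycle."""
    n = len(elements)
    points = [0]
    for x in elements:
        points.extend((2 * x - 1, 2 * x) if x > 0 else (-2 * x, -2 * x - 1))
    points.append(2 * n + 1)
    pos = {v: i for i, v in enumerate(points)}

    # each position has one black neighbour (pairing of consecutive points)
    # and one gray neighbour (pairing of consecutive values)
    black = list(range(2 * n + 2))
    for i in range(0, 2 * n + 2, 2):
        black[i], black[i + 1] = i + 1, i
    gray = list(range(2 * n + 2))
    for k in range(n + 1):
        i, j = pos[2 * k], pos[2 * k + 1]
        gray[i], gray[j] = j, i

    cycles: list[list[tuple[int, int]]] = []  # gray edges per cycle
    visited = [False] * (2 * n + 2)
    for start in range(2 * n + 2):
        if visited[start]:
            continue
        edges = []
        i = start
        while not visited[i]:
            visited[i] = True
            j = black[i]
            visited[j] = True
            k = gray[j]
            edges.append((min(j, k), max(j, k)))
            i = k
        cycles.append(edges)
    return cycles


def _interleave(e1: tuple[int, int], e2: tuple[int, int]) -> bool:
    a, b = e1
    c, d = e2
    return (a < c < b < d) or (c < a < d < b)


def _components(cycles):
    """Connected components of nontrivial cycles under gray-edge
    interleaving. Returns (positions, oriented) per component; a gray edge is
    oriented iff its endpoint positions share parity."""
    nontrivial = [cyc for cyc in cycles if len(cyc) > 1]
    k = len(nontrivial)
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            if find(i) == find(j):
                continue
            if any(_interleave(e1, e2) for e1 in nontrivial[i] for e2 in nontrivial[j]):
                parent[find(j)] = find(i)
    comps: dict[int, list[int]] = {}
    for i in range(k):
        comps.setdefault(find(i), []).append(i)
    out = []
    for members in comps.values():
        edges = [e for m in members for e in nontrivial[m]]
        positions = sorted({p for e in edges for p in e})
        oriented = any((i + j) % 2 == 0 for i, j in edges)
        out.append((positions, oriented))
    return out


def _hurdles(unoriented: list[list[int]]) -> list[int]:
    """Indices of hurdles among unoriented components (given as sorted
    position lists). On the circle closed between the two frame points, a
    component is a hurdle iff it does not separate two other unoriented
    components, i.e. all others fall in a single arc between its points."""
    hurdles = []
    for i, pts in enumerate(unoriented):
        arcs = set()
        for j, other in enumerate(unoriented):
            if i == j:
                continue
            arcs.add(bisect_right(pts, other[0]) % len(pts))
        if len(arcs) <= 1:
            hurdles.append(i)
    return hurdles


def _hurdles_and_fortress(components) -> tuple[int, int]:
    unoriented = [pts for pts, oriented in components if not oriented]
    hurdle_idx = _hurdles(unoriented)
    h = len(hurdle_idx)
    if h == 0 or h % 2 == 0 or h < 3:
        return h, 0
    # fortress: an odd number of hurdles, every one of them a superhurdle
    # (its removal turns some protected non-hurdle into a hurdle)
    for i in hurdle_idx:
        rest = [pts for j, pts in enumerate(unoriented) if j != i]
        before = {tuple(unoriented[j]) for j in hurdle_idx if j != i}
        after = {tuple(rest[j]) for j in _hurdles(rest)}
        if not (after - before):
            return h, 0  # hurdle i is simple: removing it protects nothing new
    return h, 1


def reversal_distance(perm: SignedPermutation) -> int:
    """Minimum number of reversals transforming ``perm`` into the positive
    identity: d = (n+1) - c + h + f on the breakpoint graph, where c counts
    cycles, h hurdles and f the fortress correction."""
    n = perm.n
    if n == 0:
        return 0
    cycles = _breakpoint_graph(perm.elements)
    h, f = _hurdles_and_fortress(_components(cycles))
    return (n + 1) - len(cycles) + h + f


def apply_reversal(elements: tuple[int, ...], i: int, j: int) -> tuple[int, ...]:
    """Reverse (and negate) the slice of elements with indices i..j inclusive."""
    if not 0 <= i <= j < len(elements):
        raise ValueError(f"reversal ({i}, {j}) out of range")
    mid = tuple(-x for x in reversed(elements[i : j + 1]))
    return elements[:i] + mid + elements[j + 1 :]


@dataclass(frozen=True)
class ReversalScenario:
    permutation: SignedPermutation
    reversals: tuple[tuple[int, int], ...]
    distance: int


def sort_by_reversals(perm: SignedPermutation) -> ReversalScenario:
    """One optimal reversal scenario, deterministic: at every step the
    lexicographically smallest (start, end) reversal that decreases the exact
    distance is taken, so the returned sequence is the lexicographically
    smallest optimal one."""
    elements = perm.elements
    d = reversal_distance(perm)
    steps: list[tuple[int, int]] = []
    current = elements
    remaining = d
    while remaining > 0:
        for i in range(len(current)):
            found = False
            for j in range(i, len(current)):
                nxt = apply_reversal(current, i, j)
                if reversal_distance(SignedPermutation(perm.chrom, nxt)) == remaining - 1:
                    steps.append((i, j))
                    current = nxt
                    remaining -= 1
                    found = True
                    break
            if found:
                break
        else:  # pragma: no cover - HP guarantees a decreasing reversal exists
            raise RuntimeError("no distance-decreasing reversal found")
    return ReversalScenario(perm, tuple(steps), d)


# ---------------------------------------------------------------------------
# branch assignment
# ---------------------------------------------------------------------------

TIP_STATES = ("fixed", "polymorphic", "absent", "extinct_ancestral")


@dataclass(frozen=True)
class BranchAssignment:
    inversion_id: str
    branch: str
    tip_states: dict[str, str]


def assign_to_branches(
    tip_states: dict[str, dict[str, str]], tree: SpeciesTree
) -> list[BranchAssignment]:
    """Place each inversion on the earliest branch consistent with every tip
    carrying its derived state, under a single-origin assumption.

    ``tip_states`` maps inversion id -> {tip -> state}; states are "fixed",
    "polymorphic", "absent" or "extinct_ancestral" (the derived arrangement
    arose on the tip's lineage but was later replaced by nested inversions).
    A tip-state pattern impossible under a single origin raises, naming the
    conflicting taxa.
    """
    out = []
    for inv_id, states in tip_states.items():
        for tip, st in states.items():
            if st not in TIP_STATES:
                raise ValueError(f"inversion {inv_id}: bad state {st!r} for {tip}")
        present = {t for t, s in states.items() if s != "absent"}
        if not present:
            raise ValueError(f"inversion {inv_id}: derived state present in no taxon")
        branch = tree.mrca(present)
        below = tree.tips_below(branch)
        missing = sorted(below - present)
        if branch == tree.root or missing:
            raise ValueError(
                f"inversion {inv_id}: a single origin consistent with presence in "
                f"{sorted(present)} conflicts with absence in {missing or sorted(set(tree.tips) - present)}"
            )
        full = {t: states.get(t, "absent") for t in tree.tips}
        out.append(BranchAssignment(inv_id, branch, full))
    return out


# ---------------------------------------------------------------------------
# fixation rates
# ---------------------------------------------------------------------------


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention for rates)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def fixation_rate(k: int, t: float) -> float:
    """Fixed-inversion rate k/t in inversions/Myr (raw; display at 2
    significant figures via ``round_sig``)."""
    if t <= 0:
        raise ValueError("exposure t must be positive")
    if k < 0:
        raise ValueError("count k must be non-negative")
    return k / t


@dataclass(frozen=True)
class RateComparison:
    k1: int
    k2: int
    t1: float
    t2: float
    rate1: float
    rate2: float
    ratio: float | None
    p_one_sided: float
    p_two_sided: float
    method: str = "exact conditional binomial (Poisson rates)"


def rate_ratio_test(k1: int, t1: float, k2: int, t2: float) -> RateComparison:
    """Exact comparison of two Poisson rates: conditional on n = k1 + k2,
    k1 ~ Binomial(n, t1/(t1+t2)) under equal rates. One-sided tail in the
    direction of the observed imbalance; two-sided by tail doubling, capped
    at 1. n = 0 gives p = 1."""
    if k1 < 0 or k2 < 0:
        raise ValueError("counts must be non-negative")
    if t1 <= 0 or t2 <= 0:
        raise ValueError("exposures must be positive")
    rate1, rate2 = k1 / t1, k2 / t2
    ratio = rate1 / rate2 if rate2 > 0 else None
    n = k1 + k2
    if n == 0:
        return RateComparison(k1, k2, t1, t2, rate1, rate2, ratio, 1.0, 1.0)
    p0 = t1 / (t1 + t2)
    upper = float(binom.sf(k1 - 1, n, p0))  # P(X >= k1)
    lower = float(binom.cdf(k1, n, p0))  # P(X <= k1)
    one = upper if k1 >= n * p0 else lower
    two = min(1.0, 2.0 * min(upper, lower))
    return RateComparison(k1, k2, t1, t2, rate1, rate2, ratio, one, two)
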