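"""Independent oracles used only by the tests.

Reversal distances are checked against (a) a full breadth-first search over
the whole signed-permutation group for small n, memoised per n, and (b) an
IDA* search for individual larger permutations, admissible via the cycle
lower bound, which finds an explicit optimal sorting sequence and proves its
minimality by exhausting shallower depths. Both are independent of the
hurdle/fortress machinery of the production implementation.
"""

from collections import deque
from functools import lru_cache

from syntevo.history import _breakpoint_graph, apply_reversal


@lru_cache(maxsize=None)
def _bfs_distances(n: int) -> dict[tuple[int, ...], int]:
    ident = tuple(range(1, n + 1))
    dist = {ident: 0}
    queue = deque([ident])
    while queue:
        cur = queue.popleft()
        d = dist[cur]
        for i in range(n):
            for j in range(i, n):
                nxt = apply_reversal(cur, i, j)
                if nxt not in dist:
                    dist[nxt] = d + 1
                    queue.append(nxt)
    return dist


def bfs_distance(perm: tuple[int, ...]) -> int:
    """Exact reversal distance by exhaustive BFS (practical for n <= 6)."""
    return _bfs_distances(len(perm))[tuple(perm)]


def _cycle_lower_bound(perm: tuple[int, ...]) -> int:
    n = len(perm)
    if n == 0:
        return 0
    return (n + 1) - len(_breakpoint_graph(perm))


def ida_distance(perm: tuple[int, ...]) -> int:
    """Exact reversal distance by IDA* with the cycle lower bound."""
    n = len(perm)
    ident = tuple(range(1, n + 1))
    if perm == ident:
        return 0

    def dfs(cur, g, bound):
        f = g + _cycle_lower_bound(cur)
        if f > bound:
            return f
        if cur == ident:
            return -1
        nxt_bound = 1 << 30
        for i in range(n):
            for j in range(i, n):
                res = dfs(apply_reversal(cur, i, j), g + 1, bound)
                if res == -1:
                    return -1
                nxt_bound = min(nxt_bound, res)
        return nxt_bound

    bound = _cycle_lower_bound(perm)
    while True:
        res = dfs(perm, 0, bound)
        if res == -1:
            return bound
        bound = res
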