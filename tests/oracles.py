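"""Independent oracles used by the test suite.

These deliberately avoid the package's dynamic-programming and counting
code paths: local alignment scores come from exhaustive enumeration of all
alignments of all substring pairs, and reachability comes from a plain
breadth-first search.
"""

from __future__ import annotations

from planaflex.align import ScoringScheme


def enumerate_global_score(a: str, b: str, scheme: ScoringScheme) -> int:
    """Best global alignment score of two peptides by pure enumeration.

    Recurses over every monotone alignment (no memoisation), charging
    gap_open + gap_extend for a gap's first residue and gap_extend for each
    extension.
    """
    go, ge = scheme.gap_open, scheme.gap_extend

    def rec(i: int, j: int, last: str) -> int:
        if i == len(a) and j == len(b):
            return 0
        best = None
        if i < len(a) and j < len(b):
            best = scheme.score(a[i], b[j]) + rec(i + 1, j + 1, "M")
        if i < len(a):
            cost = ge if last == "U" else go + ge
            val = -cost + rec(i + 1, j, "U")
            best = val if best is None else max(best, val)
        if j < len(b):
            cost = ge if last == "L" else go + ge
            val = -cost + rec(i, j + 1, "L")
            best = val if best is None else max(best, val)
        return best

    return rec(0, 0, "M")


def enumerate_local_score(a: str, b: str, scheme: ScoringScheme) -> int:
    """Best local alignment score: max over all substring pairs, floored at 0."""
    best = 0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(best, enumerate_global_score(
                        a[i0:i1], b[j0:j1], scheme))
    return best


def bfs_reachable(edges: list[tuple[str, str]], root: str) -> set[str]:
    """All nodes reachable from root (root included), plain BFS."""
    adj: dict[str, list[str]] = {}
    for parent, child in edges:
        adj.setdefault(parent, []).append(child)
    seen = {root}
    frontier = [root]
    while frontier:
        node = frontier.pop()
        for nxt in adj.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return seen
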