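"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's alignment engine: global alignment
scores are found by exhaustive enumeration of all gapped alignments, local
scores by maximizing the global score over all substring pairs, and graph
components by a plain depth-first search.
"""

from __future__ import annotations

import math


def brute_global_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> float:
    """Best score over every possible gapped alignment (exponential scan).

    Gap of length g costs gap_open + gap_extend*(g-1); end gaps penalized.
    """
    best = -math.inf

    def rec(i: int, j: int, last: str, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "D", score + matrix[a[i], b[j]])
        if i < len(a):
            cost = gap_extend if last == "A" else gap_open
            rec(i + 1, j, "A", score - cost)
        if j < len(b):
            cost = gap_extend if last == "B" else gap_open
            rec(i, j + 1, "B", score - cost)

    rec(0, 0, "", 0.0)
    return best


def brute_local_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> float:
    """Smith-Waterman optimum as the max over all substring pairs."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = brute_global_score(
                        a[i1:i2], b[j1:j2], matrix, gap_open, gap_extend
                    )
                    best = max(best, s)
    return best


def dfs_components(nodes, edges) -> list[frozenset]:
    """Connected components by explicit depth-first search."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        stack = [start]
        comp = set()
        while stack:
            n = stack.pop()
            if n in comp:
                continue
            comp.add(n)
            stack.extend(adj[n] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def best_trim(aligned_a: str, aligned_b: str, min_length: int):
    """Exhaustive scan over all (left, right) end trims.

    Maximizes identities minus gap columns with >= min_length residues in
    each de-gapped segment; ties prefer wider, then left-most windows.
    Returns (left, right) half-open column window or None.
    """
    L = len(aligned_a)
    best = None
    window = None
    for left in range(L):
        for right in range(left + 1, L + 1):
            sa = aligned_a[left:right]
            sb = aligned_b[left:right]
            ra = sum(1 for c in sa if c not in "-.")
            rb = sum(1 for c in sb if c not in "-.")
            if ra < min_length or rb < min_length:
                continue
            ident = sum(
                1 for x, y in zip(sa, sb) if x == y and x not in "-."
            )
            gaps = sum(1 for x, y in zip(sa, sb) if x in "-." or y in "-.")
            cand = (ident - gaps, right - left, -left)
            if best is None or cand > best:
                best = cand
                window = (left, right)
    return window
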