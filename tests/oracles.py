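"""Independent oracles used by the test-suite.

These deliberately re-derive results by exhaustive or closed-form means
and share no code with the package implementation: nested-structure
enumeration by backtracking for folding, memoised top-down recursion for
the gapped alignments, a literal transcription of the degradome category
table, and the rank-formula Spearman coefficient.
"""

from __future__ import annotations

from functools import lru_cache

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


def max_pairs_enumeration(seq: str, min_loop: int = 3) -> int:
    """Maximum nested pairing by explicit backtracking over pair sets."""
    s = seq.upper().replace("U", "T")
    n = len(s)

    def best(positions: tuple[int, ...]) -> int:
        if len(positions) < 2:
            return 0
        first, rest = positions[0], positions[1:]
        score = best(rest)                      # first stays unpaired
        for idx, j in enumerate(rest):
            if j - first <= min_loop:
                continue
            if (s[first], s[j]) in _PAIRS:
                inside = tuple(p for p in rest[:idx] if first < p < j)
                outside = tuple(p for p in rest[idx + 1:])
                score = max(score, 1 + best(inside) + best(outside))
        return score

    return best(tuple(range(n)))


def affine_align_score(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Optimal global affine-gap score by memoised top-down recursion."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        out = float("-inf")
        if i < len(a) and j < len(b):
            out = max(out, float(sub[a[i], b[j]]) + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if state == "X" else gap_open
            out = max(out, -cost + rec(i + 1, j, "X"))
        if j < len(b):
            cost = gap_extend if state == "Y" else gap_open
            out = max(out, -cost + rec(i, j + 1, "Y"))
        return out

    score = rec(0, 0, "M")
    rec.cache_clear()
    return score


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def site_penalty_recursion(mirna: str, window: str) -> float:
    """Optimal duplex penalty by memoised recursion (miRNA vs reversed window)."""
    m = mirna.upper().replace("U", "T")
    t = window.upper().replace("U", "T")[::-1]

    def weight(pos: int) -> float:
        return 2.0 if 2 <= pos <= 13 else 1.0

    def pair_cost(x: str, y: str) -> float:
        if _COMP.get(x) == y:
            return 0.0
        if (x, y) in (("G", "T"), ("T", "G")):
            return 0.5
        return 1.0

    n = len(m)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == n and j == len(t):
            return 0.0
        out = float("inf")
        if i < n and j < len(t):
            out = min(out, pair_cost(m[i], t[j]) * weight(i + 1) + rec(i + 1, j + 1))
        if i < n:
            out = min(out, 2.0 * weight(i + 1) + rec(i + 1, j))
        if j < len(t):
            out = min(out, 2.0 * weight(min(i + 1, n)) + rec(i, j + 1))
        return out

    penalty = rec(0, 0)
    rec.cache_clear()
    return penalty


def degradome_category(counts: dict[int, int], pos: int) -> int | None:
    """Literal transcription of the category definition table."""
    r = counts.get(pos, 0)
    if r == 0:
        return None
    if r == 1:
        return 4
    values = sorted(counts.values())
    if r == values[-1]:
        return 0 if values.count(values[-1]) == 1 else 1
    k = len(values)
    median = values[k // 2] if k % 2 else (values[k // 2 - 1] + values[k // 2]) / 2
    return 2 if r > median else 3


def spearman_rank_formula(x, y) -> float:
    """Spearman rho via average ranks and the Pearson-on-ranks formula."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den
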