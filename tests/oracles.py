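"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: a plain-Python
Needleman–Wunsch with exhaustive co-optimal backtracking, an exhaustive
tandem-duplication/random-loss move generator, and a from-scratch
adjacency enumerator for breakpoint counting.
"""

from __future__ import annotations

from itertools import product


# ---------------------------------------------------------------------------
# global alignment
# ---------------------------------------------------------------------------

def nw_matrix(q: str, r: str, match=1, mismatch=-1, gap=-2):
    n, m = len(q), len(r)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        dp[i][0] = i * gap
    for j in range(1, m + 1):
        dp[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if q[i - 1] == r[j - 1] and q[i - 1] != "N" else mismatch
            dp[i][j] = max(
                dp[i - 1][j - 1] + sub, dp[i - 1][j] + gap, dp[i][j - 1] + gap
            )
    return dp


def nw_optimal_score(q, r, match=1, mismatch=-1, gap=-2) -> int:
    return nw_matrix(q, r, match, mismatch, gap)[len(q)][len(r)]


def _identity_of(aq: str, ar: str) -> float:
    """Identity over columns between first and last aligned pair."""
    paired = [i for i in range(len(aq)) if aq[i] != "-" and ar[i] != "-"]
    if not paired:
        return 0.0
    lo, hi = paired[0], paired[-1]
    cols = hi - lo + 1
    same = sum(
        1 for i in range(lo, hi + 1)
        if aq[i] == ar[i] and aq[i] not in ("-", "N")
    )
    return same / cols


def nw_count_optimal(q, r, match=1, mismatch=-1, gap=-2) -> int:
    """Number of co-optimal global alignments (may be astronomically large)."""
    dp = nw_matrix(q, r, match, mismatch, gap)
    n, m = len(q), len(r)
    count = [[0] * (m + 1) for _ in range(n + 1)]
    count[0][0] = 1
    for i in range(n + 1):
        for j in range(m + 1):
            if i == j == 0:
                continue
            c = 0
            if i > 0 and j > 0:
                sub = match if q[i - 1] == r[j - 1] and q[i - 1] != "N" else mismatch
                if dp[i][j] == dp[i - 1][j - 1] + sub:
                    c += count[i - 1][j - 1]
            if i > 0 and dp[i][j] == dp[i - 1][j] + gap:
                c += count[i - 1][j]
            if j > 0 and dp[i][j] == dp[i][j - 1] + gap:
                c += count[i][j - 1]
            count[i][j] = c
    return count[n][m]


def nw_optimal_identity_range(q, r, match=1, mismatch=-1, gap=-2, cap=20000):
    """(score, min identity, max identity) over all co-optimal alignments.

    Enumerates every optimal alignment by backtracking; raises if the
    number of co-optimal alignments exceeds ``cap``.
    """
    dp = nw_matrix(q, r, match, mismatch, gap)
    idents: list[float] = []
    stack = [(len(q), len(r), "", "")]
    while stack:
        i, j, aq, ar = stack.pop()
        if i == 0 and j == 0:
            idents.append(_identity_of(aq[::-1], ar[::-1]))
            if len(idents) > cap:
                raise RuntimeError("too many co-optimal alignments")
            continue
        if i > 0 and j > 0:
            sub = match if q[i - 1] == r[j - 1] and q[i - 1] != "N" else mismatch
            if dp[i][j] == dp[i - 1][j - 1] + sub:
                stack.append((i - 1, j - 1, aq + q[i - 1], ar + r[j - 1]))
        if i > 0 and dp[i][j] == dp[i - 1][j] + gap:
            stack.append((i - 1, j, aq + q[i - 1], ar + "-"))
        if j > 0 and dp[i][j] == dp[i][j - 1] + gap:
            stack.append((i, j - 1, aq + "-", ar + r[j - 1]))
    return dp[len(q)][len(r)], min(idents), max(idents)


# ---------------------------------------------------------------------------
# TDRL move generation
# ---------------------------------------------------------------------------

def circular_canon(pairs) -> tuple:
    """Canonical rotation of a circular signed sequence (unique gene names)."""
    pairs = list(pairs)
    if not pairs:
        return ()
    k = min(range(len(pairs)), key=lambda i: pairs[i][0])
    return tuple(pairs[k:] + pairs[:k])


def all_single_tdrl_results(pairs) -> set[tuple]:
    """Every circular arrangement reachable from ``pairs`` by one TDRL:
    duplicate a contiguous circular block, keep an arbitrary subset from the
    first copy and the complement from the second."""
    pairs = list(pairs)
    n = len(pairs)
    out: set[tuple] = set()
    for s in range(n):
        for k in range(1, n + 1):
            block = [pairs[(s + i) % n] for i in range(k)]
            rest = [pairs[(s + k + i) % n] for i in range(n - k)]
            for mask in range(1 << k):
                kept1 = [block[i] for i in range(k) if (mask >> i) & 1]
                kept2 = [block[i] for i in range(k) if not (mask >> i) & 1]
                out.add(circular_canon(kept1 + kept2 + rest))
    return out


def all_signed_perms(names):
    """Every signed linear order of ``names`` (as circular representatives)."""
    from itertools import permutations

    for perm in permutations(names):
        for signs in product((1, -1), repeat=len(names)):
            yield tuple(zip(perm, signs))


# ---------------------------------------------------------------------------
# breakpoints
# ---------------------------------------------------------------------------

def breakpoints_by_enumeration(a_pairs, b_pairs) -> int:
    def adjacencies(pairs):
        pairs = list(pairs)
        n = len(pairs)
        adj = set()
        for i in range(n):
            (x, sx), (y, sy) = pairs[i], pairs[(i + 1) % n]
            adj.add(min((x, sx, y, sy), (y, -sy, x, -sx)))
        return adj

    return len(adjacencies(a_pairs) - adjacencies(b_pairs))
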