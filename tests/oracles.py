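"""Independent reference implementations used only to check the package.

These are deliberately written from first principles (plain-Python dynamic
programs and exhaustive path enumeration) and share no code with the
implementation under test.
"""

from __future__ import annotations

from functools import lru_cache

NEG = float("-inf")


def sw_local_score(q: str, s: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Smith-Waterman local score, affine gaps costing open + L * extend."""
    m, n = len(q), len(s)
    go = gap_open + gap_extend
    ge = gap_extend
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (consume s)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in subject (consume q)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - ge)
            diag = H[i - 1][j - 1] + matrix[q[i - 1], s[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def nw_global_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Needleman-Wunsch global score with the same affine-gap convention."""
    m, n = len(a), len(b)
    go = gap_open + gap_extend
    ge = gap_extend
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0.0
    for j in range(1, n + 1):
        E[0][j] = -go - ge * (j - 1)
        H[0][j] = E[0][j]
    for i in range(1, m + 1):
        F[i][0] = -go - ge * (i - 1)
        H[i][0] = F[i][0]
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - ge)
            H[i][j] = max(H[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]], E[i][j], F[i][j])
    return int(H[m][n])


def enumerate_global_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Global score by exhaustive enumeration of all gapped alignment paths.

    Exponential; only for very short strings.  Validates the DP oracles.
    """
    go = gap_open + gap_extend
    ge = gap_extend

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(matrix[a[i], b[j]] + rec(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b
            cost = ge if last == "A" else go
            options.append(-cost + rec(i + 1, j, "A"))
        if j < len(b):  # gap in a
            cost = ge if last == "B" else go
            options.append(-cost + rec(i, j + 1, "B"))
        return max(options)

    result = rec(0, 0, "M")
    rec.cache_clear()
    return int(result)


def enumerate_local_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Local score as the max global score over all substring pairs (and 0)."""
    best = 0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    sc = enumerate_global_score(a[i1:i2], b[j1:j2], matrix, gap_open, gap_extend)
                    best = max(best, sc)
    return best


def msa3_optimal_sp(a: str, b: str, c: str, matrix, gap_res: int) -> int:
    """Optimal sum-of-pairs score of a 3-sequence alignment.

    Exhaustive 3D dynamic program; gap-gap column pairs are free, gap-residue
    pairs cost ``gap_res``, residue pairs score per the matrix.  Linear gap
    model, matching the package's sum-of-pairs convention.
    """
    la, lb, lc = len(a), len(b), len(c)

    def colscore(x, y, z):
        total = 0
        for p, q in ((x, y), (x, z), (y, z)):
            if p is None and q is None:
                continue
            if p is None or q is None:
                total += gap_res
            else:
                total += int(matrix[p, q])
        return total

    H = [[[NEG] * (lc + 1) for _ in range(lb + 1)] for _ in range(la + 1)]
    H[0][0][0] = 0.0
    for i in range(la + 1):
        for j in range(lb + 1):
            for k in range(lc + 1):
                cur = H[i][j][k]
                if cur == NEG:
                    continue
                for di in (0, 1):
                    for dj in (0, 1):
                        for dk in (0, 1):
                            if di + dj + dk == 0:
                                continue
                            ni, nj, nk = i + di, j + dj, k + dk
                            if ni > la or nj > lb or nk > lc:
                                continue
                            col = colscore(
                                a[i] if di else None,
                                b[j] if dj else None,
                                c[k] if dk else None,
                            )
                            val = cur + col
                            if val > H[ni][nj][nk]:
                                H[ni][nj][nk] = val
    return int(H[la][lb][lc])
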