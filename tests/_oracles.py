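"""Independent brute-force implementations used as test oracles.

These deliberately share nothing with the package implementation except the
canonical tie-break rules that define the alignment (documented in
rumenamp._align): per-cell pointer priority diagonal > up > left, endpoint
scan corner -> last row (descending j) -> last column (descending i), with
replacement only on strictly greater scores.
"""

from __future__ import annotations


def nw_distance_oracle(a: str, b: str) -> float:
    """Plain-Python DP mirror of the end-gap-free alignment distance."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    P = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        row, prev = H[i], H[i - 1]
        for j in range(1, m + 1):
            s = 1 if a[i - 1] == b[j - 1] else -1
            best, ptr = prev[j - 1] + s, 0
            if prev[j] - 2 > best:
                best, ptr = prev[j] - 2, 1
            if row[j - 1] - 2 > best:
                best, ptr = row[j - 1] - 2, 2
            row[j] = best
            P[i][j] = ptr
    bi, bj, best = n, m, H[n][m]
    for j in range(m - 1, -1, -1):
        if H[n][j] > best:
            best, bi, bj = H[n][j], n, j
    for i in range(n - 1, -1, -1):
        if H[i][m] > best:
            best, bi, bj = H[i][m], i, m
    i, j = bi, bj
    mismatches = gaps = columns = 0
    while i > 0 and j > 0:
        ptr = P[i][j]
        columns += 1
        if ptr == 0:
            mismatches += a[i - 1] != b[j - 1]
            i, j = i - 1, j - 1
        elif ptr == 1:
            gaps += 1
            i -= 1
        else:
            gaps += 1
            j -= 1
    if columns == 0:
        return 1.0
    return (mismatches + gaps) / columns


def single_linkage_otus(seqs: list[str], cutoff: float, dist) -> list[set[int]]:
    """Exhaustive single-linkage partition at ``cutoff`` (union-find)."""
    parent = list(range(len(seqs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if dist(seqs[i], seqs[j]) <= cutoff:
                parent[find(i)] = find(j)
    clusters: dict[int, set[int]] = {}
    for i in range(len(seqs)):
        clusters.setdefault(find(i), set()).add(i)
    return list(clusters.values())


def bray_curtis_oracle(x: list[float], y: list[float]) -> float:
    """Textbook per-pair Bray-Curtis loop."""
    shared = sum(min(xi, yi) for xi, yi in zip(x, y))
    total = sum(x) + sum(y)
    return 1.0 - 2.0 * shared / total if total > 0 else 0.0
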