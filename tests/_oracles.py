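"""Independent oracles used by the test suite and nothing else."""

import numpy as np


def brute_force_contiguity(lengths):
    """Independent oracle: largest / N50 / L50 from first principles.

    N50 is the largest length x present in the multiset whose
    at-least-x records cover >= half the total; L50 is the smallest j
    such that the j largest records cover >= half the total, found by
    trying every j.
    """
    total = sum(lengths)
    n50 = max(
        x for x in set(lengths) if sum(l for l in lengths if l >= x) >= total / 2
    )
    ordered = sorted(lengths, reverse=True)
    l50 = next(
        j
        for j in range(1, len(lengths) + 1)
        if sum(ordered[:j]) >= total / 2
    )
    return max(lengths), n50, l50


def dp_kmeans_1d(values, k):
    """Exact 1-D k-clustering by dynamic programming (O(k n^2)).

    Minimizes within-cluster sum of squares over contiguous segments of
    the sorted values (optimal 1-D clusters are contiguous). Returns
    (labels in input order, optimal SSE).
    """
    arr = np.asarray(values, dtype=float)
    order = np.argsort(arr, kind="stable")
    x = arr[order]
    n = len(x)
    pre = np.concatenate([[0.0], np.cumsum(x)])
    pre2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i, j):  # cost of x[i:j]
        s = pre[j] - pre[i]
        s2 = pre2[j] - pre2[i]
        return s2 - s * s / (j - i)

    INF = float("inf")
    dp = [[INF] * (n + 1) for _ in range(k + 1)]
    cut = [[0] * (n + 1) for _ in range(k + 1)]
    dp[0][0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            for i in range(c - 1, j):
                cand = dp[c - 1][i] + seg_cost(i, j)
                if cand < dp[c][j] - 1e-12:
                    dp[c][j] = cand
                    cut[c][j] = i
    labels_sorted = [0] * n
    j = n
    for c in range(k, 0, -1):
        i = cut[c][j]
        for t in range(i, j):
            labels_sorted[t] = c - 1
        j = i
    labels = [0] * n
    for pos, orig in enumerate(order):
        labels[orig] = labels_sorted[pos]
    return labels, dp[k][n]
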