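"""Independent brute-force oracles, written from the definitional sums.

Deliberately scalar Python loops over float values — no shared code with
the package's vectorized implementations.
"""

import math


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    dx = sum((x[i] - mx) ** 2 for i in range(n))
    dy = sum((y[i] - my) ** 2 for i in range(n))
    return num / math.sqrt(dx * dy)


def weighted_pearson(x, y, w):
    sw = sum(w)
    wn = [wi / sw for wi in w]
    mx = sum(wn[i] * x[i] for i in range(len(x)))
    my = sum(wn[i] * y[i] for i in range(len(y)))
    cov = sum(wn[i] * (x[i] - mx) * (y[i] - my) for i in range(len(x)))
    vx = sum(wn[i] * (x[i] - mx) ** 2 for i in range(len(x)))
    vy = sum(wn[i] * (y[i] - my) ** 2 for i in range(len(y)))
    return cov / math.sqrt(vx * vy)


def row_ec(row_a, row_b, ref_positions):
    """Correlation of two reference rows over explicit positions."""
    xa = [row_a[j] for j in ref_positions]
    xb = [row_b[j] for j in ref_positions]
    return pearson(xa, xb)


def pcm(matrix):
    """All-pairs correlation matrix from a list-of-rows matrix."""
    k = len(matrix)
    out = [[1.0] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            r = pearson(matrix[i], matrix[j])
            out[i][j] = out[j][i] = r
    return out


def euclidean(row_a, row_b, positions):
    return math.sqrt(sum((row_a[j] - row_b[j]) ** 2 for j in positions))


def quantile(samples, x):
    """Linear-interpolation empirical quantile (sort-and-index)."""
    s = sorted(samples)
    pos = x * (len(s) - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    if lo == hi:
        return s[lo]
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def mean_sd(values):
    """Two-pass mean and sample standard deviation."""
    n = len(values)
    m = sum(values) / n
    var = sum((v - m) ** 2 for v in values) / (n - 1)
    return m, math.sqrt(var)


def ranks_average_ties(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def spearman(x, y):
    return pearson(ranks_average_ties(list(x)), ranks_average_ties(list(y)))


def ccn_nodes(pcm_a, pcm_b, thr_a, thr_b):
    """Exhaustive all-pairs conserved-edge scan; returns (nodes, n_edges)."""
    k = len(pcm_a)
    nodes = set()
    n_edges = 0
    for i in range(k):
        for j in range(i + 1, k):
            if pcm_a[i][j] > thr_a and pcm_b[i][j] > thr_b:
                n_edges += 1
                nodes.add(i)
                nodes.add(j)
    return nodes, n_edges


def auc(scores, labels):
    """Exhaustive pairwise concordance; ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
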