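"""Independent brute-force reference implementations for small graphs.

Pure-Python, written directly from the metric definitions (exhaustive
Floyd-Warshall over all intermediates, explicit triangle enumeration,
explicit neighbor-subgraph efficiency).  Deliberately naive: these never
share code with the package implementations they check.
"""

import math


def floyd_warshall(lengths):
    """All-pairs shortest paths on an explicit step-length matrix.

    lengths[i][j] is the length of the direct step i->j, or inf.
    """
    n = len(lengths)
    d = [row[:] for row in lengths]
    for i in range(n):
        d[i][i] = 0.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def length_matrix(w, weighted):
    n = len(w)
    inf = math.inf
    return [
        [
            (1.0 / w[i][j] if weighted else 1.0) if w[i][j] > 0 else inf
            for j in range(n)
        ]
        for i in range(n)
    ]


def global_efficiency(w, weighted):
    n = len(w)
    if n < 2:
        return 0.0
    d = floyd_warshall(length_matrix(w, weighted))
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i][j]):
                total += 1.0 / d[i][j]
    return total / (n * (n - 1))


def local_efficiency(w, weighted):
    n = len(w)
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if w[i][j] > 0]
        if len(nbrs) < 2:
            continue
        sub = [[w[a][b] for b in nbrs] for a in nbrs]
        total += global_efficiency(sub, weighted)
    return total / n if n else 0.0


def average_degree(w):
    n = len(w)
    if n == 0:
        return 0.0
    return sum(sum(1 for j in range(n) if w[i][j] > 0) for i in range(n)) / n


def average_strength(w):
    n = len(w)
    if n == 0:
        return 0.0
    return sum(sum(w[i][j] for j in range(n)) for i in range(n)) / n


def average_clustering(w, weighted):
    """Triangle enumeration; weighted form is the geometric-mean intensity."""
    n = len(w)
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if w[i][j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        tri = 0.0
        for a in nbrs:
            for b in nbrs:
                if a != b and w[a][b] > 0:
                    if weighted:
                        tri += (w[i][a] * w[a][b] * w[b][i]) ** (1.0 / 3.0)
                    else:
                        tri += 1.0
        total += tri / (k * (k - 1))
    return total / n


def pairwise_tally(streamline_pairs):
    """Brute-force accumulation oracle for connectome construction.

    streamline_pairs: iterable of ((region_i, region_j), fa).  Returns
    ({frozenset: count}, {frozenset: mean fa}).
    """
    counts, sums = {}, {}
    for pair, fa in streamline_pairs:
        key = frozenset(pair)
        counts[key] = counts.get(key, 0) + 1
        sums[key] = sums.get(key, 0.0) + fa
    means = {k: sums[k] / counts[k] for k in counts}
    return counts, means
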