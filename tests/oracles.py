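"""Independent brute-force reference implementations used only by tests.

Everything here is written from the definitions, with plain Python loops and
sort-and-slice logic, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def tmm_oracle(counts, lib, trim_m=0.30, trim_a=0.05, min_genes=10):
    """Trimmed mean of M-values, loop-based.

    counts: genes x samples array; lib: library sizes.  Returns factors with
    geometric mean one.
    """
    counts = np.asarray(counts, dtype=float)
    lib = np.asarray(lib, dtype=float)
    n_samples = counts.shape[1]
    # reference by upper quartile of nonzero CPM closest to the mean
    uqs = []
    for j in range(n_samples):
        nz = [counts[g, j] / lib[j] * 1e6 for g in range(counts.shape[0]) if counts[g, j] > 0]
        uqs.append(np.percentile(nz, 75))
    mean_uq = sum(uqs) / len(uqs)
    ref = min(range(n_samples), key=lambda j: (abs(uqs[j] - mean_uq), j))

    raw = [1.0] * n_samples
    for j in range(n_samples):
        if j == ref:
            continue
        entries = []
        for g in range(counts.shape[0]):
            ks, kr = counts[g, j], counts[g, ref]
            if ks > 0 and kr > 0:
                ps, pr = ks / lib[j], kr / lib[ref]
                m = math.log2(ps / pr)
                a = 0.5 * math.log2(ps * pr)
                var = (lib[j] - ks) / (lib[j] * ks) + (lib[ref] - kr) / (lib[ref] * kr)
                entries.append((g, m, a, var))
        n = len(entries)
        if n == 0:
            continue
        km = int(math.floor(n * trim_m))
        ka = int(math.floor(n * trim_a))
        by_m = sorted(entries, key=lambda e: (e[1], e[0]))
        keep_m = {e[0] for e in by_m[km : n - km]}
        by_a = sorted(entries, key=lambda e: (e[2], e[0]))
        keep_a = {e[0] for e in by_a[ka : n - ka]}
        kept = [e for e in entries if e[0] in keep_m and e[0] in keep_a]
        if len(kept) < min_genes:
            continue
        num = sum(e[1] / e[3] for e in kept)
        den = sum(1.0 / e[3] for e in kept)
        raw[j] = 2.0 ** (num / den)
    gm = math.exp(sum(math.log(f) for f in raw) / n_samples)
    return [f / gm for f in raw]


def bh_oracle(pvalues):
    """Step-up BH from the definition: q_(i) = min_{j>=i} m p_(j) / j."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: (p[i], i))
    q = [0.0] * m
    for rank_pos, i in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        q[i] = min(1.0, min(candidates))
    return q


def pearson_oracle(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def _avg_ranks(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    return pearson_oracle(_avg_ranks(list(x)), _avg_ranks(list(y)))


def kendall_taub_oracle(x, y):
    """Tau-b from pair counting with tie corrections."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    denom = math.sqrt(
        (concordant + discordant + ties_x) * (concordant + discordant + ties_y)
    )
    return (concordant - discordant) / denom


def upgma_oracle(points, labels):
    """Naive O(n^3) average-linkage agglomeration on Euclidean distances.

    Returns the merge sequence [(members_a, members_b, height), ...] with
    member sets as frozensets of labels.
    """
    points = [np.asarray(p, dtype=float) for p in points]
    clusters = {i: frozenset([labels[i]]) for i in range(len(points))}
    dist = {}
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            dist[(i, j)] = float(np.linalg.norm(points[i] - points[j]))
    sizes = {i: 1 for i in clusters}
    merges = []
    next_id = len(points)
    active = set(clusters)
    while len(active) > 1:
        best = min(
            ((min(i, j), max(i, j)) for i in active for j in active if i < j),
            key=lambda ij: (dist[ij], ij),
        )
        i, j = best
        h = dist[(i, j)]
        merges.append((clusters[i], clusters[j], h))
        merged = clusters[i] | clusters[j]
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            d_new = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[(min(next_id, k), max(next_id, k))] = d_new
        clusters[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    return merges


def hypergeom_upper_tail(N, K, n, k):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for kk in range(k, min(n, K) + 1):
        total += (
            math.comb(K, kk) * math.comb(N - K, n - kk) / math.comb(N, n)
        )
    return total
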