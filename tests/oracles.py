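"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (O(n^2) loops, exhaustive
enumeration, hand-written closed forms) and shares no code with the
package under test.
"""

from __future__ import annotations

import itertools
import math


def gini_bruteforce(values) -> float:
    """Pairwise mean-absolute-difference definition, O(n^2)."""
    x = list(values)
    n = len(x)
    mu = sum(x) / n
    total = sum(abs(a - b) for a in x for b in x)
    return total / (2 * n * n * mu)


def density_bruteforce(edges, nodes) -> float:
    n = len(nodes)
    if n < 2:
        return 0.0
    return len(set(edges)) / (n * (n - 1))


def reciprocity_bruteforce(edges) -> float | None:
    es = set(edges)
    if not es:
        return None
    return sum(1 for (a, b) in es if (b, a) in es) / len(es)


def giant_fraction_unionfind(edges, nodes) -> float | None:
    """Largest weak component share via a hand-rolled union-find."""
    nodes = list(nodes)
    if not nodes:
        return None
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for a, b in edges:
        union(a, b)
    sizes: dict = {}
    for v in nodes:
        r = find(v)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values()) / len(nodes)


def modularity_undirected(weighted_edges, partition) -> float:
    """Newman modularity of an undirected weighted graph.

    ``weighted_edges``: {(u, v): w} with u != v, each unordered pair once.
    ``partition``: node -> community id.
    """
    two_m = 2 * sum(weighted_edges.values())
    if two_m == 0:
        return 0.0
    degree: dict = {}
    for (u, v), w in weighted_edges.items():
        degree[u] = degree.get(u, 0) + w
        degree[v] = degree.get(v, 0) + w
    q = 0.0
    for (u, v), w in weighted_edges.items():
        if partition[u] == partition[v]:
            q += 2 * w / two_m
    comm_deg: dict = {}
    for node, d in degree.items():
        c = partition[node]
        comm_deg[c] = comm_deg.get(c, 0) + d
    for d in comm_deg.values():
        q -= (d / two_m) ** 2
    return q


def set_partitions(items):
    """All set partitions (restricted-growth-string enumeration)."""
    items = list(items)
    n = len(items)
    if n == 0:
        yield []
        return

    def rec(i, groups):
        if i == n:
            yield [list(g) for g in groups]
            return
        for g in groups:
            g.append(items[i])
            yield from rec(i + 1, groups)
            g.pop()
        groups.append([items[i]])
        yield from rec(i + 1, groups)
        groups.pop()

    yield from rec(0, [])


def max_modularity_exhaustive(weighted_edges, nodes) -> float:
    """Exhaustive-search optimum modularity (feasible for <= 8 nodes)."""
    best = -math.inf
    for parts in set_partitions(nodes):
        partition = {}
        for cid, group in enumerate(parts):
            for v in group:
                partition[v] = cid
        best = max(best, modularity_undirected(weighted_edges, partition))
    return best


def ols_normal_equations(x, y):
    """Simple-regression closed form: slope, intercept, SE, t-p, R^2."""
    from scipy.stats import t as tdist

    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    rss = sum((yi - intercept - slope * xi) ** 2 for xi, yi in zip(x, y))
    sst = sum((yi - my) ** 2 for yi in y)
    r2 = 1.0 - rss / sst if sst > 0 else 0.0
    se = math.sqrt(rss / (n - 2) / sxx) if n > 2 else float("nan")
    if se > 0:
        tval = slope / se
        p = 2 * tdist.sf(abs(tval), n - 2)
    else:
        p = float("nan")
    return {"slope": slope, "intercept": intercept, "se": se, "p": p,
            "r2": r2, "rss": rss}


def poly_rss(x, y, degree) -> float:
    """Least-squares RSS by solving the normal equations with Gaussian
    elimination — no numpy."""
    n = len(x)
    k = degree + 1
    ata = [[sum(xi ** (i + j) for xi in x) for j in range(k)]
           for i in range(k)]
    atb = [sum((xi ** i) * yi for xi, yi in zip(x, y)) for i in range(k)]
    # Gaussian elimination with partial pivoting
    for col in range(k):
        piv = max(range(col, k), key=lambda r: abs(ata[r][col]))
        ata[col], ata[piv] = ata[piv], ata[col]
        atb[col], atb[piv] = atb[piv], atb[col]
        for r in range(col + 1, k):
            f = ata[r][col] / ata[col][col]
            for c in range(col, k):
                ata[r][c] -= f * ata[col][c]
            atb[r] -= f * atb[col]
    coef = [0.0] * k
    for r in range(k - 1, -1, -1):
        s = atb[r] - sum(ata[r][c] * coef[c] for c in range(r + 1, k))
        coef[r] = s / ata[r][r]
    return sum((yi - sum(c * xi ** i for i, c in enumerate(coef))) ** 2
               for xi, yi in zip(x, y))


def welch_manual(a, b):
    """Textbook Welch statistic, Satterthwaite df, two-sided p."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def pearson_manual(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def anova_two_way_ss(grid):
    """Sums of squares of an additive two-way design (rows x cols).

    ``grid``: list of lists, one observation per cell.
    """
    a = len(grid)
    b = len(grid[0])
    flat = [v for row in grid for v in row]
    grand = sum(flat) / (a * b)
    row_means = [sum(row) / b for row in grid]
    col_means = [sum(grid[i][j] for i in range(a)) / a for j in range(b)]
    ss_rows = b * sum((m - grand) ** 2 for m in row_means)
    ss_cols = a * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((v - grand) ** 2 for v in flat)
    ss_resid = ss_total - ss_rows - ss_cols
    return {"rows": ss_rows, "cols": ss_cols, "resid": ss_resid,
            "total": ss_total}
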