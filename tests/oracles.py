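"""Independent brute-force oracles used only by the test suite."""

import itertools
import math

import numpy as np


def topk_edges_bruteforce(rho, names, k):
    """Full-sort reference for top-k edge retention (positive rho only)."""
    edges = set()
    n = len(names)
    for i in range(n):
        partners = [
            (names[j], rho[i, j]) for j in range(n) if j != i and rho[i, j] > 0
        ]
        partners.sort(key=lambda t: (-t[1], t[0]))
        for name, _ in partners[:k]:
            edges.add(frozenset((names[i], name)))
    return edges


def modularity_reference(graph, assignment):
    """Newman–Girvan Q computed straight from the adjacency matrix."""
    nodes = list(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        a[idx[u], idx[v]] = w
        a[idx[v], idx[u]] = w
    two_w = a.sum()
    s = a.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if assignment[nodes[i]] == assignment[nodes[j]]:
                q += a[i, j] - s[i] * s[j] / two_w
    return q / two_w


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1 :]
        yield [[first]] + partition


def best_modularity_exhaustive(graph):
    """Global optimum Q over all partitions of the node set (n <= 8)."""
    nodes = list(graph.nodes)
    best = -math.inf
    for partition in set_partitions(nodes):
        assignment = {}
        for label, block in enumerate(partition):
            for node in block:
                assignment[node] = label
        best = max(best, modularity_reference(graph, assignment))
    return best


def hypergeom_tail_exact(k, n, K, N):
    """P(X >= k) by direct summation of binomial coefficients."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(n, K) + 1)
    ) / total


def ari_from_contingency(labels_a, labels_b):
    """Adjusted Rand index straight from the contingency-table formula."""
    cats_a = sorted(set(labels_a))
    cats_b = sorted(set(labels_b))
    table = np.zeros((len(cats_a), len(cats_b)), dtype=int)
    for la, lb in zip(labels_a, labels_b):
        table[cats_a.index(la), cats_b.index(lb)] += 1
    n = table.sum()
    sum_ij = sum(math.comb(int(x), 2) for x in table.ravel())
    sum_a = sum(math.comb(int(x), 2) for x in table.sum(axis=1))
    sum_b = sum(math.comb(int(x), 2) for x in table.sum(axis=0))
    expected = sum_a * sum_b / math.comb(int(n), 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def welch_reference(x, y):
    """Welch t and p from the textbook formula + t CDF via scipy only for
    the incomplete-beta special function (not the t-test routine)."""
    from scipy.special import betainc

    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    # two-sided p from the regularized incomplete beta: P(|T|>t)
    p = betainc(df / 2, 0.5, df / (df + t * t))
    return t, df, p


def venn_bruteforce(a, b, c):
    counts = dict.fromkeys(["A", "B", "C", "AB", "AC", "BC", "ABC"], 0)
    for item in a | b | c:
        key = "".join(
            letter for letter, s in zip("ABC", (a, b, c)) if item in s
        )
        counts[key] += 1
    return counts


def random_sparse_graph(rng, n):
    """Connected-ish random weighted graph on n nodes for enumeration tests."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.45:
            g.add_edge(i, j, weight=float(rng.uniform(0.1, 1.0)))
    if g.number_of_edges() == 0:
        g.add_edge(0, 1, weight=1.0)
    return g
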