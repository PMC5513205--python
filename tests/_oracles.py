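"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive: path intersection for LCA, the
textbook step-up definition for BH, full sign-pattern enumeration for the
signed-rank test.  None of it shares code with the implementation under
test.
"""

from __future__ import annotations

import itertools

import numpy as np

from metaratio.taxonomy import RANK_ORDER, TaxonomyTree, build_taxonomy


def brute_force_lca(tree: TaxonomyTree, taxa) -> str:
    """Deepest node on the common prefix of all root-to-taxon paths."""
    taxa = list(taxa)
    if not taxa:
        return "unassigned"
    paths = [tree.lineage(t) for t in taxa]
    common = None
    for path in paths:
        s = set(path)
        common = s if common is None else common & s
    # the common ancestors always form a root chain; deepest = longest lineage
    return max(common, key=lambda n: len(tree.lineage(n)))


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Textbook step-up: adj_(i) = min_{j >= i} m * p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        adj_sorted[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def random_taxonomy(rng: np.random.Generator, max_nodes: int = 200):
    """Random ranked tree honoring the strict rank-deepening invariant.

    Returns (tree, node ids).  Node 0 is the root; every other node attaches
    to any earlier node whose rank leaves room below it.
    """
    n = int(rng.integers(2, max_nodes + 1))
    max_rank = len(RANK_ORDER) - 1
    ranks = [0]
    parents = [0]
    for i in range(1, n):
        while True:
            p = int(rng.integers(0, i))
            if ranks[p] < max_rank:
                break
        ranks.append(int(rng.integers(ranks[p] + 1, max_rank + 1)))
        parents.append(p)
    ids = [f"n{i:03d}" for i in range(n)]
    edges = [
        (ids[i], ids[parents[i]], RANK_ORDER[ranks[i]], ids[i])
        for i in range(1, n)
    ]
    if len(edges) == 0:  # n == 1 cannot happen (n >= 2), but keep safe
        edges = [(ids[0], ids[0], "root", ids[0])]
    return build_taxonomy(edges), ids


def exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Two-tailed exact signed-rank p by enumerating all sign patterns.

    Assumes nonzero differences with distinct magnitudes (no ties).
    """
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_low = np.mean(ws <= w_obs)
    p_high = np.mean(ws >= w_obs)
    return float(min(1.0, 2 * min(p_low, p_high)))
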