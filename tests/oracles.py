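"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: betweenness by explicit
shortest-path enumeration, BH by the classical step-up rejection rule,
the hypergeometric tail by exact combinatorial sums, and ROC AUC by the
pairwise Mann-Whitney comparison.
"""

from collections import deque
from fractions import Fraction
from math import comb

import numpy as np


def betweenness_by_enumeration(nodes, edges):
    """Unordered-pair betweenness via per-pair shortest-path counting."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def bfs(src):
        dist = {src: 0}
        sigma = {src: 1}
        order = []
        q = deque([src])
        while q:
            u = q.popleft()
            order.append(u)
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0
                    q.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        return dist, sigma

    info = {n: bfs(n) for n in nodes}
    bet = {n: 0.0 for n in nodes}
    nodes = list(nodes)
    for i, s in enumerate(nodes):
        dist_s, sigma_s = info[s]
        for t in nodes[i + 1:]:
            if t not in dist_s:
                continue
            d_st = dist_s[t]
            sigma_st = sigma_s[t]
            dist_t, sigma_t = info[t]
            for v in nodes:
                if v in (s, t) or v not in dist_s or v not in dist_t:
                    continue
                if dist_s[v] + dist_t[v] == d_st:
                    bet[v] += sigma_s[v] * sigma_t[v] / sigma_st
    return bet


def bh_rejections_stepup(p, threshold):
    """Classical BH step-up rejection set at FDR level ``threshold``.

    The condition ``p_(k) <= (k/m) t`` is applied in its rescaled form
    ``p_(k) m / k <= t`` so that knife-edge thresholds (e.g. t equal to an
    adjusted p-value) compare identically under floating point.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] * m / rank <= threshold:
            k_star = rank
    return set(order[:k_star].tolist())


def hypergeom_upper_tail(k, K, n, N):
    """Exact P(X >= k) by summing the tail of the pmf with Fractions."""
    total = Fraction(0)
    denom = comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return float(total)


def roc_auc_pairwise(probs, labels):
    """Mann-Whitney AUC: mean over (pos, neg) pairs with tie half-credit."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))


def exclusive_intersections_bruteforce(named_sets):
    """Exclusive UpSet counts by scanning every gene of the union."""
    union = set().union(*named_sets.values())
    out = {}
    for g in union:
        sig = frozenset(name for name, s in named_sets.items() if g in s)
        out[sig] = out.get(sig, 0) + 1
    return out
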