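"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, O(n^3) loops,
per-pair BFS path counting) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np

BASES = "ACGT"


# ---------------------------------------------------------------------------
# scanner oracles
# ---------------------------------------------------------------------------


def enumerate_word_sf(iweights: np.ndarray, background, w: int):
    """Exact survival function by enumerating all 4^w words.

    Word probability: context marginal for the first m letters, chained
    transitions afterwards. Returns (scores, probs) arrays over words.
    """
    m = background.order
    n_ctx = 4**m
    words = np.arange(4**w)
    digits = [(words // 4 ** (w - 1 - i)) % 4 for i in range(w)]
    scores = sum(iweights[i][digits[i]] for i in range(w))
    if m == 0:
        probs = np.ones(len(words))
        for i in range(w):
            probs = probs * background.transition[0][digits[i]]
    else:
        ctx = np.zeros(len(words), dtype=int)
        for i in range(min(m, w)):
            ctx = ctx * 4 + digits[i]
        if w <= m:
            # marginal over the remaining context letters
            probs = np.zeros(len(words))
            full = background.context_probs
            for c in range(n_ctx):
                prefix = c // 4 ** (m - w)
                probs[prefix] += full[c]
        else:
            probs = background.context_probs[ctx].copy()
            for i in range(m, w):
                probs = probs * background.transition[ctx, digits[i]]
                ctx = (ctx * 4 + digits[i]) % n_ctx
    return scores, probs


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def brute_scan(seq: str, weights: np.ndarray, iweights: np.ndarray, dist, p_threshold: float):
    """Window-by-window rescoring with direct p-value lookup.

    Returns a set of (start 1-based, strand, word, pvalue) tuples, both
    strands, N windows skipped.
    """
    w = iweights.shape[0]
    seq = seq.upper()
    hits = set()
    for j in range(len(seq) - w + 1):
        window = seq[j : j + w]
        if "N" in window or any(c not in BASES for c in window):
            continue
        for strand in "+-":
            word = window if strand == "+" else revcomp(window)
            iscore = sum(iweights[i][BASES.index(word[i])] for i in range(w))
            p = float(dist.pvalue_int(iscore))
            if p <= p_threshold:
                hits.add((j + 1, strand, word, p))
    return hits


def count_kmers(seq: str, k: int) -> dict[str, int]:
    """Hash-count of k-mers without N."""
    out: dict[str, int] = {}
    for j in range(len(seq) - k + 1):
        word = seq[j : j + k]
        if all(c in BASES for c in word):
            out[word] = out.get(word, 0) + 1
    return out


# ---------------------------------------------------------------------------
# graph oracles
# ---------------------------------------------------------------------------


def _bfs_paths(adj: dict, source):
    """Shortest-path distance and path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj.get(u, ()):  # successors
            if v == u:
                continue
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def brute_betweenness(nodes, edges) -> dict:
    """Directed betweenness via all-sources BFS path counting.

    B(n) = sum over ordered pairs (s, t), s != t != n, with sigma_st > 0 of
    sigma_s(n) * sigma_n(t) / sigma_st when dist_s(n) + dist_n(t) == dist_st.
    """
    adj: dict = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
    dist = {}
    sigma = {}
    for n in nodes:
        dist[n], sigma[n] = _bfs_paths(adj, n)
    B = {n: 0.0 for n in nodes}
    for s in nodes:
        for t in nodes:
            if s == t or t not in dist[s]:
                continue
            dst = dist[s][t]
            for n in nodes:
                if n in (s, t):
                    continue
                if n in dist[s] and t in dist[n] and dist[s][n] + dist[n][t] == dst:
                    B[n] += sigma[s][n] * sigma[n][t] / sigma[s][t]
    return B


def brute_ffls(nodes, edges):
    """All FFL triples by the O(n^3) loop."""
    eset = set(edges)
    triples = []
    for x in nodes:
        for y in nodes:
            if y == x or (x, y) not in eset:
                continue
            for z in nodes:
                if z in (x, y):
                    continue
                if (x, z) in eset and (y, z) in eset:
                    triples.append((x, y, z))
    return triples


def greedy_step_argmax(targets: dict, covered: set):
    """Best next candidate by recomputation: max gain, then max outdegree,
    then lexicographic id. Returns (node, gain)."""
    best = None
    for c, ts in targets.items():
        gain = len(ts - covered)
        key = (-gain, -len(ts), c)
        if best is None or key < best[0]:
            best = (key, c, gain)
    return best[1], best[2]


def brute_rbh(forward, reverse, max_evalue, min_identity, min_coverage):
    """Mutual-best pairs by exhaustive comparison of surviving hits."""

    def surviving(hits):
        return [
            h
            for h in hits
            if h.evalue <= max_evalue
            and h.percent_identity >= min_identity
            and h.percent_coverage >= min_coverage
        ]

    def best_per_query(hits):
        out = {}
        for h in hits:
            out.setdefault(h.query_id, []).append(h)
        result = {}
        for q, hs in out.items():
            hs.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
            result[q] = hs[0].subject_id
        return result

    fwd = best_per_query(surviving(forward))
    rev = best_per_query(surviving(reverse))
    return sorted((q, s) for q, s in fwd.items() if rev.get(s) == q)
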