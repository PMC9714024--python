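"""Numba kernels for the hierarchical navigable small world (HNSW) graph.

Construction follows the original HNSW contract: node levels are drawn
geometrically with normalization 1/ln(M); insertion descends greedily from
the top layer, then at each layer at or below the node's level runs a
best-first search with an ef_construction-sized candidate list and connects
to up to M neighbors chosen by the select-neighbors heuristic (a candidate
is kept only if it is closer to the new node than to every already-selected
neighbor).  Layer 0 allows up to 2M links per node; over-full neighbor lists
are re-pruned with the same heuristic.

Distances: metric code 0 = cosine (vectors pre-normalized, dist = 1 - dot),
metric code 1 = squared Euclidean.  All heap orderings are lexicographic on
(distance, node index) so builds and searches are bit-deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

COSINE = 0
EUCLIDEAN = 1


@njit(cache=True)
def _dist(data, metric, q, j):
    s = 0.0
    if metric == COSINE:
        for t in range(data.shape[1]):
            s += np.float64(q[t]) * np.float64(data[j, t])
        return 1.0 - s
    else:
        for t in range(data.shape[1]):
            diff = np.float64(q[t]) - np.float64(data[j, t])
            s += diff * diff
        return s


@njit(cache=True)
def _heap_push(hd, hi, size, d, i):
    """Min-heap push keyed lexicographically on (distance, index)."""
    pos = size
    hd[pos] = d
    hi[pos] = i
    while pos > 0:
        parent = (pos - 1) >> 1
        if hd[parent] > hd[pos] or (hd[parent] == hd[pos] and hi[parent] > hi[pos]):
            hd[parent], hd[pos] = hd[pos], hd[parent]
            hi[parent], hi[pos] = hi[pos], hi[parent]
            pos = parent
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(hd, hi, size):
    d0 = hd[0]
    i0 = hi[0]
    size -= 1
    hd[0] = hd[size]
    hi[0] = hi[size]
    pos = 0
    while True:
        left = 2 * pos + 1
        right = left + 1
        best = pos
        if left < size and (
            hd[left] < hd[best] or (hd[left] == hd[best] and hi[left] < hi[best])
        ):
            best = left
        if right < size and (
            hd[right] < hd[best] or (hd[right] == hd[best] and hi[right] < hi[best])
        ):
            best = right
        if best == pos:
            break
        hd[best], hd[pos] = hd[pos], hd[best]
        hi[best], hi[pos] = hi[pos], hi[best]
        pos = best
    return d0, i0, size


@njit(cache=True)
def _grow(arr, size):
    out = np.empty(arr.shape[0] * 2, dtype=arr.dtype)
    out[:size] = arr[:size]
    return out


@njit(cache=True)
def _search_layer(data, metric, q, ep, layer, ef, nbr0, cnt0, nbru, cntu, visited, epoch):
    """Best-first search on one layer starting from entry point ``ep``.

    Returns (dists, ids, n) for up to ``ef`` nearest nodes (heap order, not
    sorted).  ``visited`` is an epoch-tagged scratch array.
    """
    cap = 4 * ef + 8
    cd = np.empty(cap, np.float64)  # candidate min-heap
    ci = np.empty(cap, np.int64)
    rd = np.empty(ef + 1, np.float64)  # result max-heap, stored negated
    ri = np.empty(ef + 1, np.int64)
    csize = 0
    rsize = 0

    visited[ep] = epoch
    d = _dist(data, metric, q, ep)
    csize = _heap_push(cd, ci, csize, d, ep)
    rsize = _heap_push(rd, ri, rsize, -d, -ep)

    while csize > 0:
        dc, c, csize = _heap_pop(cd, ci, csize)
        worst_d = -rd[0]
        worst_i = -ri[0]
        if rsize >= ef and (dc > worst_d or (dc == worst_d and c > worst_i)):
            break
        if layer == 0:
            deg = cnt0[c]
        else:
            deg = cntu[layer - 1, c]
        for idx in range(deg):
            if layer == 0:
                e = nbr0[c, idx]
            else:
                e = nbru[layer - 1, c, idx]
            if visited[e] == epoch:
                continue
            visited[e] = epoch
            de = _dist(data, metric, q, e)
            worst_d = -rd[0]
            worst_i = -ri[0]
            if rsize < ef or de < worst_d or (de == worst_d and e < worst_i):
                if csize >= cd.shape[0]:
                    cd = _grow(cd, csize)
                    ci = _grow(ci, csize)
                csize = _heap_push(cd, ci, csize, de, e)
                rsize = _heap_push(rd, ri, rsize, -de, -e)
                if rsize > ef:
                    _, _, rsize = _heap_pop(rd, ri, rsize)
    out_d = np.empty(rsize, np.float64)
    out_i = np.empty(rsize, np.int64)
    for t in range(rsize):
        out_d[t] = -rd[t]
        out_i[t] = -ri[t]
    return out_d, out_i, rsize


@njit(cache=True)
def _sort_by_dist_then_id(dists, ids):
    """Indices sorting candidates ascending by (distance, node index)."""
    order1 = np.argsort(ids, kind="quicksort")  # ids unique
    order2 = np.argsort(dists[order1], kind="mergesort")  # stable: keeps id order
    return order1[order2]


@njit(cache=True)
def _select_heuristic(data, metric, dists, ids, n, m):
    """Select up to m neighbors: keep a candidate only if it is closer to the
    query than to every already-selected neighbor."""
    order = _sort_by_dist_then_id(dists[:n], ids[:n])
    sel = np.empty(m, np.int64)
    nsel = 0
    for oi in range(n):
        if nsel >= m:
            break
        c = ids[order[oi]]
        dcq = dists[order[oi]]
        ok = True
        for si in range(nsel):
            if _dist(data, metric, data[c], sel[si]) < dcq:
                ok = False
                break
        if ok:
            sel[nsel] = c
            nsel += 1
    return sel, nsel


@njit(cache=True)
def _greedy_descend(data, metric, q, ep, layer, nbr0, cnt0, nbru, cntu):
    """Move to the strictly closest neighbor until a local minimum.

    The current node's full neighbor row is scanned before moving so the row
    and its degree always belong to the same node.
    """
    d_ep = _dist(data, metric, q, ep)
    improved = True
    while improved:
        improved = False
        if layer == 0:
            deg = cnt0[ep]
        else:
            deg = cntu[layer - 1, ep]
        best = ep
        best_d = d_ep
        for idx in range(deg):
            if layer == 0:
                e = nbr0[ep, idx]
            else:
                e = nbru[layer - 1, ep, idx]
            de = _dist(data, metric, q, e)
            if de < best_d or (de == best_d and e < best):
                best_d = de
                best = e
        if best != ep:
            ep = best
            d_ep = best_d
            improved = True
    return ep


@njit(cache=True)
def _shrink(data, metric, node, extra, layer, m_max, nbr0, cnt0, nbru, cntu):
    """Re-prune ``node``'s neighbor list (plus one extra link) down to m_max."""
    if layer == 0:
        deg = cnt0[node]
    else:
        deg = cntu[layer - 1, node]
    cand_i = np.empty(deg + 1, np.int64)
    cand_d = np.empty(deg + 1, np.float64)
    for idx in range(deg):
        if layer == 0:
            e = nbr0[node, idx]
        else:
            e = nbru[layer - 1, node, idx]
        cand_i[idx] = e
        cand_d[idx] = _dist(data, metric, data[node], e)
    cand_i[deg] = extra
    cand_d[deg] = _dist(data, metric, data[node], extra)
    sel, nsel = _select_heuristic(data, metric, cand_d, cand_i, deg + 1, m_max)
    for si in range(nsel):
        if layer == 0:
            nbr0[node, si] = sel[si]
        else:
            nbru[layer - 1, node, si] = sel[si]
    if layer == 0:
        cnt0[node] = nsel
    else:
        cntu[layer - 1, node] = nsel


@njit(cache=True)
def build_graph(data, metric, levels, m, ef_construction):
    """Insert all nodes (in row order) and return the layered adjacency."""
    n = data.shape[0]
    maxlev = 0
    for i in range(n):
        if levels[i] > maxlev:
            maxlev = levels[i]
    nbr0 = np.full((n, 2 * m), -1, np.int32)
    cnt0 = np.zeros(n, np.int32)
    ulev = maxlev if maxlev > 0 else 1
    nbru = np.full((ulev, n, m), -1, np.int32)
    cntu = np.zeros((ulev, n), np.int32)
    visited = np.full(n, -1, np.int64)
    epoch = 0
    entry = 0
    top = levels[0]
    for i in range(1, n):
        lvl = levels[i]
        q = data[i]
        ep = entry
        for lc in range(top, lvl, -1):
            ep = _greedy_descend(data, metric, q, ep, lc, nbr0, cnt0, nbru, cntu)
        start = top if top < lvl else lvl
        for lc in range(start, -1, -1):
            epoch += 1
            rdists, rids, rn = _search_layer(
                data, metric, q, ep, lc, ef_construction, nbr0, cnt0, nbru, cntu,
                visited, epoch,
            )
            sel, nsel = _select_heuristic(data, metric, rdists, rids, rn, m)
            m_max = 2 * m if lc == 0 else m
            for si in range(nsel):
                s = sel[si]
                # forward link i -> s (nsel <= m <= m_max, never overflows)
                if lc == 0:
                    nbr0[i, cnt0[i]] = s
                    cnt0[i] += 1
                else:
                    nbru[lc - 1, i, cntu[lc - 1, i]] = s
                    cntu[lc - 1, i] += 1
                # reverse link s -> i, pruning if over-full
                if lc == 0:
                    deg = cnt0[s]
                else:
                    deg = cntu[lc - 1, s]
                if deg < m_max:
                    if lc == 0:
                        nbr0[s, deg] = i
                        cnt0[s] = deg + 1
                    else:
                        nbru[lc - 1, s, deg] = i
                        cntu[lc - 1, s] = deg + 1
                else:
                    _shrink(data, metric, s, i, lc, m_max, nbr0, cnt0, nbru, cntu)
            # nearest found node seeds the next layer down
            best = rids[0]
            bestd = rdists[0]
            for t in range(1, rn):
                if rdists[t] < bestd or (rdists[t] == bestd and rids[t] < best):
                    bestd = rdists[t]
                    best = rids[t]
            ep = best
        if lvl > top:
            top = lvl
            entry = i
    return nbr0, cnt0, nbru, cntu, entry, top


@njit(cache=True)
def search_graph(data, metric, q, k, ef, nbr0, cnt0, nbru, cntu, entry, top):
    """Top-k node indices and distances, ascending (distance, index)."""
    ep = entry
    for lc in range(top, 0, -1):
        ep = _greedy_descend(data, metric, q, ep, lc, nbr0, cnt0, nbru, cntu)
    visited = np.full(data.shape[0], -1, np.int64)
    eff = ef if ef > k else k
    rdists, rids, rn = _search_layer(
        data, metric, q, ep, 0, eff, nbr0, cnt0, nbru, cntu, visited, 0
    )
    order = _sort_by_dist_then_id(rdists[:rn], rids[:rn])
    nk = k if k < rn else rn
    out_d = np.empty(nk, np.float64)
    out_i = np.empty(nk, np.int64)
    for t in range(nk):
        out_d[t] = rdists[order[t]]
        out_i[t] = rids[order[t]]
    return out_d, out_i
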