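"""Quadric edge-collapse mesh simplification.

Classic quadric-error-metric decimation for closed manifold triangle meshes:
per-vertex quadrics accumulated from area-weighted face planes, a lazy
priority queue of candidate collapses, a link-condition check that preserves
manifoldness (hence watertightness of a closed input), and a normal-flip
guard that rejects collapses inverting adjacent triangles.

Only free functions and numpy arrays — the public mesh type lives in
``mesh_prep``.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np

_COND_EPS = 1e-9


def _vertex_quadrics(pos: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = pos[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1)
    ok = norm > 0
    unit = np.zeros_like(n)
    unit[ok] = n[ok] / norm[ok, None]
    d = -np.einsum("ij,ij->i", unit, tri[:, 0])
    plane = np.concatenate([unit, d[:, None]], axis=1)  # (m, 4)
    # area-weighted fundamental quadrics
    kf = plane[:, :, None] * plane[:, None, :] * (0.5 * norm)[:, None, None]
    q = np.zeros((len(pos), 4, 4))
    for c in range(3):
        np.add.at(q, faces[:, c], kf)
    return q


def _batch_costs(q: np.ndarray, pu: np.ndarray, pv: np.ndarray):
    """Optimal collapse positions and costs for a batch of edge quadrics.

    ``q``: (k, 4, 4) summed endpoint quadrics; ``pu``/``pv``: (k, 3) endpoint
    positions.  Solves the normal equations where well conditioned, otherwise
    falls back to the best of {midpoint, u, v}.
    """
    k = len(q)
    a = q[:, :3, :3]
    b = -q[:, :3, 3]
    best = 0.5 * (pu + pv)
    scale = np.abs(a).sum(axis=(1, 2)) + 1e-300
    det = np.linalg.det(a)
    solvable = np.abs(det) > _COND_EPS * scale**3 / 27.0
    pos = best.copy()
    if np.any(solvable):
        pos[solvable] = np.linalg.solve(a[solvable], b[solvable][..., None])[..., 0]
    # guard: a wildly extrapolated solution means near-singular A; clamp it
    span = np.linalg.norm(pv - pu, axis=1) + 1e-12
    far = np.linalg.norm(pos - best, axis=1) > 10.0 * span
    pos[far] = best[far]

    def _eval(p):
        ph = np.concatenate([p, np.ones((k, 1))], axis=1)
        return np.einsum("ki,kij,kj->k", ph, q, ph)

    candidates = np.stack([pos, best, pu, pv])  # (4, k, 3)
    costs = np.stack([_eval(c) for c in candidates])  # (4, k)
    choice = np.argmin(costs, axis=0)
    idx = np.arange(k)
    return candidates[choice, idx], costs[choice, idx]


def quadric_decimate(
    vertices: np.ndarray, faces: np.ndarray, target_faces: int
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse edges of a closed manifold mesh until ``target_faces`` remain.

    Returns compacted (vertices, faces).  May stop early (above target) if no
    further collapse passes the manifoldness/flip guards; the caller decides
    whether that is an error.
    """
    pos = np.array(vertices, dtype=np.float64)
    f = np.array(faces, dtype=np.int64)
    nv = len(pos)
    quad = _vertex_quadrics(pos, f)

    vfaces: list[set[int]] = [set() for _ in range(nv)]
    vneigh: list[set[int]] = [set() for _ in range(nv)]
    for fid, (a, b, c) in enumerate(f):
        vfaces[a].add(fid)
        vfaces[b].add(fid)
        vfaces[c].add(fid)
        vneigh[a].update((b, c))
        vneigh[b].update((a, c))
        vneigh[c].update((a, b))

    alive_v = np.ones(nv, dtype=bool)
    alive_f = np.ones(len(f), dtype=bool)
    n_alive = len(f)
    version = np.zeros(nv, dtype=np.int64)
    counter = itertools.count()

    edges = np.unique(np.sort(np.concatenate(
        [f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1), axis=0)
    opt, cost = _batch_costs(quad[edges[:, 0]] + quad[edges[:, 1]],
                             pos[edges[:, 0]], pos[edges[:, 1]])
    heap = [
        (cost[i], next(counter), int(edges[i, 0]), int(edges[i, 1]), 0, 0, opt[i])
        for i in range(len(edges))
    ]
    heapq.heapify(heap)

    def push_edges(u: int) -> None:
        nbrs = [w for w in vneigh[u] if alive_v[w]]
        if not nbrs:
            return
        nb = np.asarray(nbrs)
        p, c = _batch_costs(quad[u] + quad[nb], np.broadcast_to(pos[u], (len(nb), 3)),
                            pos[nb])
        for i, w in enumerate(nbrs):
            heapq.heappush(heap, (c[i], next(counter), u, int(w),
                                  int(version[u]), int(version[w]), p[i]))

    while n_alive > target_faces and heap:
        c, _, u, v, su, sv, p = heapq.heappop(heap)
        if (not alive_v[u] or not alive_v[v] or version[u] != su
                or version[v] != sv or v not in vneigh[u]):
            continue
        shared = vfaces[u] & vfaces[v]
        if len(shared) != 2:
            continue
        apex = set()
        for fid in shared:
            apex.update(int(x) for x in f[fid] if x != u and x != v)
        if (vneigh[u] & vneigh[v]) != apex:
            continue  # link condition: collapse would pinch the surface

        # normal-flip guard on every surviving face around u and v
        ring = list((vfaces[u] | vfaces[v]) - shared)
        rf = f[ring]
        old_tri = pos[rf]
        new_tri = old_tri.copy()
        mask = (rf == u) | (rf == v)
        new_tri[mask] = p
        old_n = np.cross(old_tri[:, 1] - old_tri[:, 0], old_tri[:, 2] - old_tri[:, 0])
        new_n = np.cross(new_tri[:, 1] - new_tri[:, 0], new_tri[:, 2] - new_tri[:, 0])
        dots = np.einsum("ij,ij->i", old_n, new_n)
        if np.any(dots <= 0):
            continue

        # commit
        pos[u] = p
        quad[u] = quad[u] + quad[v]
        alive_v[v] = False
        for fid in shared:
            alive_f[fid] = False
            for x in f[fid]:
                vfaces[x].discard(fid)
        n_alive -= len(shared)
        for fid in list(vfaces[v]):
            row = f[fid]
            row[row == v] = u
            vfaces[u].add(fid)
        vfaces[v].clear()
        for w in vneigh[v]:
            if w == u:
                continue
            vneigh[w].discard(v)
            vneigh[w].add(u)
            vneigh[u].add(w)
        vneigh[u].discard(v)
        for w in vneigh[u]:
            vneigh[w].discard(v)
        vneigh[v].clear()
        version[u] += 1
        version[v] += 1
        push_edges(u)

    out_f = f[alive_f]
    used = np.unique(out_f)
    remap = np.full(nv, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return pos[used], remap[out_f]
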