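"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately written as naive enumeration (python
loops, BFS flood fill, O(n^2) pair counting) so it shares no code path
with the package implementations it checks.
"""

from __future__ import annotations

import numpy as np


def brute_glcm(levels: np.ndarray, mask: np.ndarray, g: int, direction) -> np.ndarray:
    """Symmetric co-occurrence counts by explicit voxel-pair enumeration."""
    mat = np.zeros((g, g))
    nx, ny, nz = levels.shape
    dx, dy, dz = direction
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                qx, qy, qz = x + dx, y + dy, z + dz
                if not (0 <= qx < nx and 0 <= qy < ny and 0 <= qz < nz):
                    continue
                if not mask[qx, qy, qz]:
                    continue
                a = levels[x, y, z] - 1
                b = levels[qx, qy, qz] - 1
                mat[a, b] += 1
                mat[b, a] += 1
    return mat


def brute_glrlm(levels: np.ndarray, mask: np.ndarray, g: int, direction) -> np.ndarray:
    """Run-length counts by walking every maximal run voxel by voxel."""
    nx, ny, nz = levels.shape
    dx, dy, dz = direction

    def inside(x, y, z):
        return 0 <= x < nx and 0 <= y < ny and 0 <= z < nz

    runs = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                lv = levels[x, y, z]
                px, py, pz = x - dx, y - dy, z - dz
                # only start a run at its first voxel
                if inside(px, py, pz) and mask[px, py, pz] and levels[px, py, pz] == lv:
                    continue
                length = 1
                qx, qy, qz = x + dx, y + dy, z + dz
                while inside(qx, qy, qz) and mask[qx, qy, qz] and levels[qx, qy, qz] == lv:
                    length += 1
                    qx, qy, qz = qx + dx, qy + dy, qz + dz
                runs.append((lv, length))
    rmax = max((r for _v, r in runs), default=1)
    mat = np.zeros((g, rmax))
    for lv, length in runs:
        mat[lv - 1, length - 1] += 1
    return mat


def brute_glszm_zones(levels: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """(level, size) of every 26-connected constant-level zone, via BFS."""
    nx, ny, nz = levels.shape
    seen = np.zeros_like(mask, dtype=bool)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    zones = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                lv = levels[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in offsets:
                        qx, qy, qz = cx + dx, cy + dy, cz + dz
                        if not (0 <= qx < nx and 0 <= qy < ny and 0 <= qz < nz):
                            continue
                        if seen[qx, qy, qz] or not mask[qx, qy, qz]:
                            continue
                        if levels[qx, qy, qz] != lv:
                            continue
                        seen[qx, qy, qz] = True
                        stack.append((qx, qy, qz))
                zones.append((int(lv), size))
    return zones


def brute_ngtdm(levels: np.ndarray, mask: np.ndarray, g: int):
    """(n_g, s_g) by explicit 26-neighbourhood loops."""
    nx, ny, nz = levels.shape
    n_g = np.zeros(g)
    s_g = np.zeros(g)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                neigh = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if (dx, dy, dz) == (0, 0, 0):
                                continue
                            qx, qy, qz = x + dx, y + dy, z + dz
                            if 0 <= qx < nx and 0 <= qy < ny and 0 <= qz < nz:
                                if mask[qx, qy, qz]:
                                    neigh.append(levels[qx, qy, qz])
                if not neigh:
                    continue
                lv = levels[x, y, z]
                n_g[lv - 1] += 1
                s_g[lv - 1] += abs(lv - sum(neigh) / len(neigh))
    return n_g, s_g


def brute_auroc(scores, labels) -> float:
    """O(n^2) positive/negative pair counting, ties worth 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_relieff(x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Literal ReliefF transcription: per-instance k nearest hits/misses
    under Manhattan distance on range-scaled features."""
    n, p = x.shape
    span = x.max(axis=0) - x.min(axis=0)
    span[span == 0] = 1.0
    xs = x / span
    counts = {c: int((y == c).sum()) for c in np.unique(y)}
    priors = {c: counts[c] / n for c in counts}
    w = np.zeros(p)
    for i in range(n):
        dists = [
            (sum(abs(xs[i, f] - xs[j, f]) for f in range(p)), j)
            for j in range(n)
            if j != i
        ]
        hits = sorted((d, j) for d, j in dists if y[j] == y[i])[:k]
        misses = sorted((d, j) for d, j in dists if y[j] != y[i])[:k]
        miss_cls = 1 - y[i]
        miss_w = priors[miss_cls] / (1.0 - priors[y[i]])
        for f in range(p):
            hit_term = sum(abs(xs[i, f] - xs[j, f]) for _d, j in hits) / len(hits)
            miss_term = sum(abs(xs[i, f] - xs[j, f]) for _d, j in misses) / len(misses)
            w[f] += (miss_w * miss_term - hit_term) / n
    return w


def brute_quantize(values: np.ndarray, g: int) -> np.ndarray:
    """Sort-and-partition oracle: level of each value by its sorted rank."""
    order = np.argsort(values, kind="stable")
    n = len(values)
    boundaries = [int(np.ceil(k * n / g)) for k in range(1, g + 1)]
    levels = np.empty(n, dtype=int)
    for pos, idx in enumerate(order):
        rank = pos + 1  # 1-based rank after stable sort
        levels[idx] = next(k for k, b in enumerate(boundaries, start=1) if rank <= b)
    # equal values all map to the lowest level among their ranks' levels
    # (ties crossing a boundary go to the lower level)
    vals_to_level: dict[float, int] = {}
    for pos, idx in enumerate(order):
        v = values[idx]
        if v in vals_to_level:
            vals_to_level[v] = min(vals_to_level[v], levels[idx])
        else:
            vals_to_level[v] = levels[idx]
    for idx in range(n):
        levels[idx] = vals_to_level[values[idx]]
    return levels
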