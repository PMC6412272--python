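"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the mathematical definitions with plain
loops / exhaustive search, deliberately ignoring the vectorized paths in
the package.
"""

from __future__ import annotations

import math

import numpy as np


def otsu_exhaustive(gray: np.ndarray) -> int:
    """Lowest threshold maximizing between-class variance, by trying all 256."""
    values = gray.ravel().astype(np.float64)
    n = values.size
    best_t, best_var = 0, -1.0
    for t in range(256):
        c0 = values[values <= t]
        c1 = values[values > t]
        if c0.size == 0 or c1.size == 0:
            continue
        w0, w1 = c0.size / n, c1.size / n
        var = w0 * w1 * (c0.mean() - c1.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def glcm_pairs(q: np.ndarray, offset: tuple[int, int], levels: int,
               symmetric: bool = True, normalize: bool = True) -> np.ndarray:
    """Co-occurrence matrix by explicit double loop over pixel positions."""
    H, W = q.shape
    dr, dc = offset
    m = np.zeros((levels, levels), dtype=np.float64)
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                m[q[r, c], q[r2, c2]] += 1
                if symmetric:
                    m[q[r2, c2], q[r, c]] += 1
    if normalize and m.sum() > 0:
        m = m / m.sum()
    return m


def haralick_direct(p: np.ndarray, log_base: float = 2.0):
    """Contrast, entropy, correlation by direct elementwise summation."""
    L = p.shape[0]
    contrast = 0.0
    entropy = 0.0
    for a in range(L):
        for b in range(L):
            contrast += (a - b) ** 2 * p[a, b]
            if p[a, b] > 0:
                entropy -= p[a, b] * math.log(p[a, b], log_base)
    pr = p.sum(axis=1)
    pc = p.sum(axis=0)
    mu_r = sum(a * pr[a] for a in range(L))
    mu_c = sum(b * pc[b] for b in range(L))
    var_r = sum((a - mu_r) ** 2 * pr[a] for a in range(L))
    var_c = sum((b - mu_c) ** 2 * pc[b] for b in range(L))
    if var_r <= 0 or var_c <= 0:
        corr = 0.0
    else:
        corr = sum(
            (a - mu_r) * (b - mu_c) * p[a, b] for a in range(L) for b in range(L)
        ) / math.sqrt(var_r * var_c)
    return contrast, entropy, corr


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """Connected components by iterative flood fill in raster-scan order.

    Returns (label array, list of areas); labels are assigned in the order
    each component's first pixel is met scanning row-major.
    """
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    H, W = mask.shape
    labels = np.zeros((H, W), dtype=np.int32)
    areas = []
    next_label = 0
    for r0 in range(H):
        for c0 in range(W):
            if mask[r0, c0] and labels[r0, c0] == 0:
                next_label += 1
                stack = [(r0, c0)]
                labels[r0, c0] = next_label
                area = 0
                while stack:
                    r, c = stack.pop()
                    area += 1
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = next_label
                            stack.append((rr, cc))
                areas.append(area)
    return labels, areas


def erode_bf(mask: np.ndarray, offsets: list[tuple[int, int]]) -> np.ndarray:
    """Erosion by explicit offset check; out-of-image counts as foreground."""
    H, W = mask.shape
    out = np.zeros_like(mask)
    for r in range(H):
        for c in range(W):
            ok = True
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and not mask[rr, cc]:
                    ok = False
                    break
            out[r, c] = ok
    return out


def dilate_bf(mask: np.ndarray, offsets: list[tuple[int, int]]) -> np.ndarray:
    """Dilation by explicit offset check; out-of-image counts as background."""
    H, W = mask.shape
    out = np.zeros_like(mask)
    for r in range(H):
        for c in range(W):
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and mask[rr, cc]:
                    out[r, c] = True
                    break
    return out


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    """All integer offsets with Euclidean norm <= radius."""
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]


def open_bf(mask: np.ndarray, radius: int) -> np.ndarray:
    offs = disk_offsets(radius)
    return dilate_bf(erode_bf(mask, offs), offs)
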