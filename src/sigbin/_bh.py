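"""Numba kernels for the Barnes-Hut gradient: quadtree build and traversal.

The quadtree is stored in flat arrays. Each node is a square cell; leaves
hold one distinct point position with a multiplicity (exact duplicates and
points closer than the maximum depth resolves are aggregated), so
degenerate inputs cannot recurse unboundedly. A cell of side w at distance
r from the target point is summarized by its center of mass when
w / r < theta; theta = 0 therefore descends to the leaves and reproduces
the exact repulsive sum.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MAX_DEPTH = 60


@njit(cache=True)
def _build_tree(Y):
    n = Y.shape[0]
    cap = 16 * n + 2048
    child = np.full((cap, 4), -1, dtype=np.int64)
    center = np.zeros((cap, 2), dtype=np.float64)
    half = np.zeros(cap, dtype=np.float64)
    cum_mass = np.zeros(cap, dtype=np.float64)
    com_sum = np.zeros((cap, 2), dtype=np.float64)
    is_leaf = np.ones(cap, dtype=np.bool_)
    leaf_pt = np.zeros((cap, 2), dtype=np.float64)
    leaf_mult = np.zeros(cap, dtype=np.int64)

    xmin = Y[:, 0].min()
    xmax = Y[:, 0].max()
    ymin = Y[:, 1].min()
    ymax = Y[:, 1].max()
    cx = 0.5 * (xmin + xmax)
    cy = 0.5 * (ymin + ymax)
    h = 0.5 * max(xmax - xmin, ymax - ymin)
    h = h * (1.0 + 1e-9) + 1e-12
    center[0, 0] = cx
    center[0, 1] = cy
    half[0] = h
    n_nodes = 1

    for i in range(n):
        x = Y[i, 0]
        y = Y[i, 1]
        node = 0
        depth = 0
        while True:
            cum_mass[node] += 1.0
            com_sum[node, 0] += x
            com_sum[node, 1] += y
            if is_leaf[node]:
                if leaf_mult[node] == 0:
                    leaf_pt[node, 0] = x
                    leaf_pt[node, 1] = y
                    leaf_mult[node] = 1
                    break
                if (leaf_pt[node, 0] == x and leaf_pt[node, 1] == y) or depth >= _MAX_DEPTH:
                    leaf_mult[node] += 1
                    break
                # split: push the stored point into its child quadrant
                px = leaf_pt[node, 0]
                py = leaf_pt[node, 1]
                pm = leaf_mult[node]
                is_leaf[node] = False
                leaf_mult[node] = 0
                q = (1 if px >= center[node, 0] else 0) + (2 if py >= center[node, 1] else 0)
                c = n_nodes
                n_nodes += 1
                hh = 0.5 * half[node]
                center[c, 0] = center[node, 0] + (hh if (q & 1) else -hh)
                center[c, 1] = center[node, 1] + (hh if (q & 2) else -hh)
                half[c] = hh
                child[node, q] = c
                leaf_pt[c, 0] = px
                leaf_pt[c, 1] = py
                leaf_mult[c] = pm
                cum_mass[c] = pm
                com_sum[c, 0] = px * pm
                com_sum[c, 1] = py * pm
                # fall through: descend with the new point
            q = (1 if x >= center[node, 0] else 0) + (2 if y >= center[node, 1] else 0)
            c = child[node, q]
            if c == -1:
                c = n_nodes
                n_nodes += 1
                hh = 0.5 * half[node]
                center[c, 0] = center[node, 0] + (hh if (q & 1) else -hh)
                center[c, 1] = center[node, 1] + (hh if (q & 2) else -hh)
                half[c] = hh
                child[node, q] = c
            node = c
            depth += 1

    return child, half, cum_mass, com_sum, is_leaf, n_nodes


@njit(cache=True)
def _repulsion(Y, theta):
    """Per-point unnormalized repulsive force and partition-sum contribution.

    Returns (F, Z_i) where F_i = sum_cells m * q^2 * (y_i - com) with
    q = 1 / (1 + d^2), and Z_i = sum_cells m * q INCLUDING the point's own
    self term (q = 1), which the caller subtracts.
    """
    n = Y.shape[0]
    child, half, cum_mass, com_sum, is_leaf, _ = _build_tree(Y)
    F = np.zeros((n, 2), dtype=np.float64)
    Zi = np.zeros(n, dtype=np.float64)
    stack = np.empty(4096, dtype=np.int64)
    for i in range(n):
        x = Y[i, 0]
        y = Y[i, 1]
        top = 0
        stack[top] = 0
        top += 1
        fx = 0.0
        fy = 0.0
        z = 0.0
        while top > 0:
            top -= 1
            node = stack[top]
            m = cum_mass[node]
            if m == 0.0:
                continue
            comx = com_sum[node, 0] / m
            comy = com_sum[node, 1] / m
            dx = x - comx
            dy = y - comy
            d2 = dx * dx + dy * dy
            w = 2.0 * half[node]
            if is_leaf[node] or w * w < theta * theta * d2:
                q = 1.0 / (1.0 + d2)
                z += m * q
                mq2 = m * q * q
                fx += mq2 * dx
                fy += mq2 * dy
            else:
                for k in range(4):
                    c = child[node, k]
                    if c != -1:
                        stack[top] = c
                        top += 1
        F[i, 0] = fx
        F[i, 1] = fy
        Zi[i] = z
    return F, Zi


@njit(cache=True)
def _attraction(Y, indptr, indices, data):
    """Sparse attractive force: F_i = sum_j p_ij * q_ij * (y_i - y_j)."""
    n = Y.shape[0]
    F = np.zeros((n, 2), dtype=np.float64)
    for i in range(n):
        fx = 0.0
        fy = 0.0
        for idx in range(indptr[i], indptr[i + 1]):
            j = indices[idx]
            p = data[idx]
            dx = Y[i, 0] - Y[j, 0]
            dy = Y[i, 1] - Y[j, 1]
            q = 1.0 / (1.0 + dx * dx + dy * dy)
            fx += p * q * dx
            fy += p * q * dy
        F[i, 0] = fx
        F[i, 1] = fy
    return F
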