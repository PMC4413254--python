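"""Regularized least-squares gridding of scattered data.

Bilinear interpolation ties each data point to its four surrounding grid
nodes; a second-difference penalty in both directions regularizes nodes
away from data.  This is the classic smoothed scattered-data gridder: the
solution minimizes ||A z - v||^2 + lambda^2 ||L z||^2.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

__all__ = ["gridfit"]


def gridfit(
    x: np.ndarray,
    y: np.ndarray,
    v: np.ndarray,
    xnodes: np.ndarray,
    ynodes: np.ndarray,
    smoothness: float = 1.0,
) -> np.ndarray:
    """Fit a smooth surface z(xnodes, ynodes) to scattered values v(x, y).

    Returns an array of shape (len(ynodes), len(xnodes)).  Data outside the
    node lattice raise; callers clip or extend the lattice.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    v = np.asarray(v, float).ravel()
    xn = np.asarray(xnodes, float)
    yn = np.asarray(ynodes, float)
    nx, ny = len(xn), len(yn)
    if nx < 2 or ny < 2:
        raise ValueError("need at least a 2x2 node lattice")
    if np.any(x < xn[0]) or np.any(x > xn[-1]) or np.any(y < yn[0]) or np.any(y > yn[-1]):
        raise ValueError("data outside the node lattice")

    def node_index(vals, nodes):
        idx = np.searchsorted(nodes, vals, side="right") - 1
        return np.clip(idx, 0, len(nodes) - 2)

    ix = node_index(x, xn)
    iy = node_index(y, yn)
    tx = (x - xn[ix]) / (xn[ix + 1] - xn[ix])
    ty = (y - yn[iy]) / (yn[iy + 1] - yn[iy])

    def node(i, j):  # column index of node (ix=i, iy=j)
        return i * ny + j

    nd = len(x)
    rows = np.repeat(np.arange(nd), 4)
    cols = np.concatenate(
        [node(ix, iy), node(ix + 1, iy), node(ix, iy + 1), node(ix + 1, iy + 1)]
    ).reshape(4, nd).T.ravel()
    weights = np.stack(
        [(1 - tx) * (1 - ty), tx * (1 - ty), (1 - tx) * ty, tx * ty]
    ).T.ravel()
    A = sp.csr_matrix((weights, (rows, cols)), shape=(nd, nx * ny))

    # thin-plate style curvature penalty: second differences along x and y
    # plus the cross (twist) term, so no surface mode is left unpenalized
    blocks = []
    gi, gj = np.meshgrid(np.arange(1, nx - 1), np.arange(ny), indexing="ij")
    cx = (gi * ny + gj).ravel()
    blocks.append((cx, np.full(cx.size, ny), (1.0, -2.0, 1.0)))
    gi, gj = np.meshgrid(np.arange(nx), np.arange(1, ny - 1), indexing="ij")
    cy = (gi * ny + gj).ravel()
    blocks.append((cy, np.ones(cy.size, dtype=int), (1.0, -2.0, 1.0)))
    rows_l, cols_l, vals_l = [], [], []
    r = 0
    for centres, off, stencil in blocks:
        rows_l.append(np.repeat(np.arange(r, r + centres.size), 3))
        cols_l.append(np.stack([centres - off, centres, centres + off]).T.ravel())
        vals_l.append(np.tile(stencil, centres.size))
        r += centres.size
    # twist: sqrt(2) * cross second difference over each cell
    gi, gj = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    c00 = (gi * ny + gj).ravel()
    rows_l.append(np.repeat(np.arange(r, r + c00.size), 4))
    cols_l.append(np.stack([c00, c00 + ny, c00 + 1, c00 + ny + 1]).T.ravel())
    vals_l.append(np.tile([np.sqrt(2), -np.sqrt(2), -np.sqrt(2), np.sqrt(2)], c00.size))
    r += c00.size
    L = sp.csr_matrix(
        (np.concatenate(vals_l), (np.concatenate(rows_l), np.concatenate(cols_l))),
        shape=(r, nx * ny),
    )

    # scale the penalty relative to the data term (dimensionless smoothness)
    a_norm = sp.linalg.norm(A, 1)
    l_norm = max(sp.linalg.norm(L, 1), 1e-12)
    lam = smoothness * a_norm / l_norm

    lhs = (A.T @ A + (lam**2) * (L.T @ L)).tocsc()
    rhs = A.T @ v
    z = spsolve(lhs, rhs)
    return z.reshape(nx, ny).T
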