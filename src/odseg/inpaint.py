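"""Vessel removal by harmonic (Laplace) inpainting.

Pixels under the vessel mask are treated as missing and reconstructed so
that each filled pixel equals the average of its four axial neighbors —
the discrete Laplace equation with Dirichlet data on the known pixels.
Out-of-bounds neighbors at the image border are reflected.  The default
solver assembles one sparse linear system (exact and fast at working-crop
sizes); a Jacobi fixed-point iteration is available as an independent
route to the same solution.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .errors import InputError


def _neighbor_indices(h: int, w: int):
    """Row/col indices of the 4 axial neighbors with border reflection
    (an out-of-bounds neighbor maps back to the pixel itself)."""
    rr, cc = np.mgrid[0:h, 0:w]
    nbrs = []
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        nr = np.clip(rr + dr, 0, h - 1)
        nc = np.clip(cc + dc, 0, w - 1)
        nbrs.append((nr, nc))
    return nbrs


def laplace_inpaint(channel: np.ndarray, missing: np.ndarray, method: str = "direct",
                    tol: float = 1e-9, max_iter: int = 100_000) -> np.ndarray:
    """Fill ``missing`` pixels of ``channel`` harmonically.

    Known pixels are returned unchanged; each filled pixel satisfies
    ``E0 = (En + Es + Ee + Ew) / 4`` (with reflected neighbors at borders).

    Parameters
    ----------
    method:
        ``"direct"`` — sparse Dirichlet solve (exact);
        ``"jacobi"`` — iterated neighbor averaging to fixed point.
    """
    channel = np.asarray(channel, dtype=float)
    missing = np.asarray(missing, dtype=bool)
    if channel.shape != missing.shape:
        raise InputError("channel and mask shapes do not match")
    if missing.all():
        raise InputError("cannot inpaint: no known pixels")
    if not missing.any():
        return channel.copy()
    if method == "jacobi":
        return _jacobi(channel, missing, tol, max_iter)
    if method != "direct":
        raise InputError(f"unknown method {method!r}")

    h, w = channel.shape
    unknown_id = -np.ones((h, w), dtype=np.int64)
    miss_r, miss_c = np.nonzero(missing)
    n = miss_r.size
    unknown_id[miss_r, miss_c] = np.arange(n)

    rows, cols, vals = [np.arange(n)], [np.arange(n)], [np.full(n, 4.0)]
    rhs = np.zeros(n)
    for nr, nc in _neighbor_indices(h, w):
        nbr_r, nbr_c = nr[miss_r, miss_c], nc[miss_r, miss_c]
        nbr_missing = missing[nbr_r, nbr_c]
        # known neighbor -> RHS; missing neighbor -> off-diagonal coefficient
        rhs += np.where(nbr_missing, 0.0, channel[nbr_r, nbr_c])
        sel = np.nonzero(nbr_missing)[0]
        rows.append(sel)
        cols.append(unknown_id[nbr_r[sel], nbr_c[sel]])
        vals.append(np.full(sel.size, -1.0))
    a = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    out = channel.copy()
    out[miss_r, miss_c] = spsolve(a, rhs)
    return out


def _jacobi(channel: np.ndarray, missing: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    out = channel.copy()
    # initialize unknowns at the mean of known pixels for faster convergence
    out[missing] = channel[~missing].mean()
    for _ in range(max_iter):
        p = np.pad(out, 1, mode="edge")
        avg = (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]) / 4.0
        delta = np.abs(avg[missing] - out[missing]).max()
        out[missing] = avg[missing]
        if delta < tol:
            break
    return out


def inpaint_channels(
    v: np.ndarray, s: np.ndarray, vessel_mask: np.ndarray, method: str = "direct"
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the same harmonic fill to the V and S channels."""
    if v.shape != s.shape or v.shape != vessel_mask.shape:
        raise InputError("channel and mask shapes do not match")
    return (
        laplace_inpaint(v, vessel_mask, method=method),
        laplace_inpaint(s, vessel_mask, method=method),
    )
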