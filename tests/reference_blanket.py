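"""Literal per-voxel reference implementation of the blanket recursion.

Evaluates the blanket definitions voxel by voxel with explicit loops over the
4D grid, independent of the vectorized scipy-based path in
``fractalperf.fractal``.  Slow; intended for arrays no larger than ~6^4.
"""

import math

import numpy as np


def _clip_slices(idx, shape, radius=1):
    return tuple(
        slice(max(i - radius, 0), min(i + radius + 1, n))
        for i, n in zip(idx, shape)
    )


def ref_blanket_step_chebyshev(u, b):
    """One blanket iteration; neighborhood = Chebyshev ball of radius 1.

    Replicate padding at the grid boundary is equivalent to clipping the
    neighborhood to the grid, which is what this does.
    """
    u_new = np.empty_like(u)
    b_new = np.empty_like(b)
    shape = u.shape
    for idx in np.ndindex(shape):
        sl = _clip_slices(idx, shape)
        u_new[idx] = max(u[idx] + 1.0, u[sl].max())
        b_new[idx] = min(b[idx] - 1.0, b[sl].min())
    return u_new, b_new


def ref_blanket_step_axial(u, b):
    """One blanket iteration; neighborhood = center plus the 8 face neighbors."""
    u_new = np.empty_like(u)
    b_new = np.empty_like(b)
    shape = u.shape
    for idx in np.ndindex(shape):
        vals = [u[idx]]
        lows = [b[idx]]
        for ax in range(4):
            for d in (-1, 1):
                j = list(idx)
                j[ax] = min(max(j[ax] + d, 0), shape[ax] - 1)
                vals.append(u[tuple(j)])
                lows.append(b[tuple(j)])
        u_new[idx] = max(u[idx] + 1.0, max(vals))
        b_new[idx] = min(b[idx] - 1.0, min(lows))
    return u_new, b_new


def ref_hypervolume(u, b, eps):
    return float(np.sum(u - b)) / (2.0 * eps)


def ref_fd_global(volume, eps_max=4, neighborhood="chebyshev"):
    """FD = 4 - least-squares slope of log V(eps) on log eps, eps = 1..eps_max."""
    step = {
        "chebyshev": ref_blanket_step_chebyshev,
        "axial": ref_blanket_step_axial,
    }[neighborhood]
    u = np.array(volume, dtype=float)
    b = u.copy()
    log_v = []
    for eps in range(1, eps_max + 1):
        u, b = step(u, b)
        log_v.append(math.log(ref_hypervolume(u, b, eps)))
    log_eps = np.log(np.arange(1, eps_max + 1, dtype=float))
    xc = log_eps - log_eps.mean()
    yc = np.array(log_v) - np.mean(log_v)
    slope = float((xc * yc).sum() / (xc * xc).sum())
    return 4.0 - slope


def ref_fd_map(volume, eps_max=4, kernel=3):
    """Local FD map via per-voxel kernel sums of (u - b); literal loops."""
    u = np.array(volume, dtype=float)
    b = u.copy()
    shape = u.shape
    radius = kernel // 2
    log_v = np.empty((eps_max,) + shape)
    for eps in range(1, eps_max + 1):
        u, b = ref_blanket_step_chebyshev(u, b)
        sep = u - b
        for idx in np.ndindex(shape):
            # replicate padding: boundary voxels repeat, i.e. clipped indices
            total = 0.0
            for off in np.ndindex((kernel,) * 4):
                j = tuple(
                    min(max(i + o - radius, 0), n - 1)
                    for i, o, n in zip(idx, off, shape)
                )
                total += sep[j]
            log_v[(eps - 1,) + idx] = math.log(total / (2.0 * eps))
    log_eps = np.log(np.arange(1, eps_max + 1, dtype=float))
    xc = log_eps - log_eps.mean()
    yc = log_v - log_v.mean(axis=0, keepdims=True)
    slope = np.tensordot(xc, yc, axes=(0, 0)) / (xc * xc).sum()
    return 4.0 - slope
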