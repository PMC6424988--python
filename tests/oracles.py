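"""Independent brute-force oracles used by the tests.

Everything here is written as plainly as possible (dense matrices, explicit
loops, ray marching) and never calls the production projector/recon code.
"""

from __future__ import annotations

import math

import numpy as np


def dense_view_matrix(shape2d: tuple[int, int], spacing_mm: float,
                      angle_deg: float,
                      mu2d: np.ndarray | None = None) -> np.ndarray:
    """Explicit (n_bins x n_pixels) single-view projection matrix.

    Loop-built bilinear gather rotation (columns normalized to conserve
    each in-frame pixel), optional attenuation by the exclusive tail sum of
    the rotated mu map toward the detector at +y, then summation over
    depth.  Mirrors the production discretization by independent
    construction.
    """
    nx, ny = shape2d
    npix = nx * ny
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0

    G_interp = np.zeros((npix, npix))
    for ti in range(nx):
        for tj in range(ny):
            tx, ty = ti - cx, tj - cy
            sx = c * tx - s * ty + cx
            sy = s * tx + c * ty + cy
            i0, j0 = math.floor(sx), math.floor(sy)
            fx, fy = sx - i0, sy - j0
            for di, dj, w in ((0, 0, (1 - fx) * (1 - fy)),
                              (1, 0, fx * (1 - fy)),
                              (0, 1, (1 - fx) * fy),
                              (1, 1, fx * fy)):
                ii, jj = i0 + di, j0 + dj
                if 0 <= ii < nx and 0 <= jj < ny and w > 0:
                    G_interp[ti * ny + tj, ii * ny + jj] += w
    # counts use the emission-conserving (column-normalized) operator;
    # the mu field is rotated with plain interpolation
    G = G_interp.copy()
    colsum = G.sum(axis=0)
    keep = colsum > 1e-12
    G[:, keep] /= colsum[keep]

    if mu2d is None:
        t = np.ones((nx, ny))
    else:
        mu_rot = (G_interp @ mu2d.ravel()).reshape(nx, ny)
        dl_cm = spacing_mm / 10.0
        t = np.ones((nx, ny))
        for i in range(nx):
            for j in range(ny):
                tail = mu_rot[i, j + 1:].sum()
                t[i, j] = math.exp(-dl_cm * tail)

    P = np.zeros((nx, npix))
    for b in range(nx):
        for j in range(ny):
            P[b] += t[b, j] * G[b * ny + j]
    return P


def ray_march_path_length(mask2d: np.ndarray, i: int, j: int,
                          angle_deg: float, spacing_mm: float,
                          step_frac: float = 0.05) -> float:
    """Path length (cm) through a mask from pixel (i,j) along one direction.

    Marches from the pixel centre toward the detector direction of the
    given view angle in small steps, bilinearly sampling the mask.
    """
    nx, ny = mask2d.shape
    th = math.radians(angle_deg)
    # detector direction: +y axis of the frame rotated by angle
    dx, dy = math.sin(th), math.cos(th)
    step = step_frac
    total = 0.0
    t = 0.0
    max_t = 2.0 * (nx + ny)
    while t < max_t:
        x = i + dx * t
        y = j + dy * t
        i0, j0 = math.floor(x), math.floor(y)
        fx, fy = x - i0, y - j0
        val = 0.0
        for di, dj, w in ((0, 0, (1 - fx) * (1 - fy)), (1, 0, fx * (1 - fy)),
                          (0, 1, (1 - fx) * fy), (1, 1, fx * fy)):
            ii, jj = i0 + di, j0 + dj
            if 0 <= ii < nx and 0 <= jj < ny:
                val += w * mask2d[ii, jj]
        total += val * step
        t += step
    return total * spacing_mm / 10.0


def flood_fill_26(above: np.ndarray, seed: tuple[int, int, int]) -> np.ndarray:
    """Exhaustive 26-connected flood fill from a seed within a boolean mask."""
    out = np.zeros_like(above, dtype=bool)
    if not above[seed]:
        return out
    stack = [seed]
    out[seed] = True
    nx, ny, nz = above.shape
    while stack:
        i, j, k = stack.pop()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if di == dj == dk == 0:
                        continue
                    ii, jj, kk = i + di, j + dj, k + dk
                    if (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz
                            and above[ii, jj, kk] and not out[ii, jj, kk]):
                        out[ii, jj, kk] = True
                        stack.append((ii, jj, kk))
    return out


def pearson_textbook(x: np.ndarray, y: np.ndarray) -> float:
    """Direct product-moment formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = math.sqrt(n * (x * x).sum() - x.sum() ** 2) * \
        math.sqrt(n * (y * y).sum() - y.sum() ** 2)
    return num / den
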