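"""Numba kernels: ray tracing, forward projection and row-action sweeps.

Everything here is an internal hot path.  The public per-ray operations in
:mod:`polyct.projector` and :mod:`polyct.recon` are plain NumPy and define
the semantics; the kernels replicate them for whole sinograms, and a test
pins the two routes against each other on a small problem.

Conventions (shared with the Python layer):
  * square n x n pixel grid, pixel size h mm, centred on the rotation
    center; pixel (ix, iy) covers [x0+ix*h, x0+(ix+1)h) x [x0+iy*h, ...),
    with x0 = -n*h/2 and flat index j = iy*n + ix (C order of image[iy, ix]);
  * view angle 0 puts the source on the +x axis, rotation counter-clockwise;
  * detector cell centres are the ray endpoints;
  * lengths are mm, attenuation cm^-1: optical depth uses a 0.1 mm->cm factor.
"""

import math

import numpy as np
from numba import njit

MM_TO_CM = 0.1


@njit(cache=True)
def ray_endpoints(beta, sod, sdd, n_cells, cell_size, c):
    """Source point and detector-cell-centre endpoint of ray (view beta, cell c)."""
    cb = math.cos(beta)
    sb = math.sin(beta)
    sx = sod * cb
    sy = sod * sb
    u = (c + 0.5 - 0.5 * n_cells) * cell_size
    ex = sx - sdd * cb - u * sb
    ey = sy - sdd * sb + u * cb
    return sx, sy, ex, ey


@njit(cache=True)
def trace(sx, sy, ex, ey, x0, h, n, idx, lens):
    """Exact ray-pixel intersection lengths (Amanatides-Woo traversal).

    Fills ``idx``/``lens`` (buffers of size >= 2n+4) with the flat pixel
    indices crossed by the segment (sx,sy)->(ex,ey) and the intersection
    lengths in the same units as the coordinates.  Returns the entry count;
    0 if the segment misses the grid.
    """
    dx = ex - sx
    dy = ey - sy
    length = math.sqrt(dx * dx + dy * dy)
    if length == 0.0:
        return 0
    side = n * h
    tmin = 0.0
    tmax = 1.0
    if dx != 0.0:
        t1 = (x0 - sx) / dx
        t2 = (x0 + side - sx) / dx
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    elif sx < x0 or sx >= x0 + side:
        return 0
    if dy != 0.0:
        t1 = (x0 - sy) / dy
        t2 = (x0 + side - sy) / dy
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    elif sy < x0 or sy >= x0 + side:
        return 0
    if tmin >= tmax:
        return 0
    px = sx + tmin * dx
    py = sy + tmin * dy
    ix = int((px - x0) / h)
    iy = int((py - x0) / h)
    if ix < 0:
        ix = 0
    elif ix > n - 1:
        ix = n - 1
    if iy < 0:
        iy = 0
    elif iy > n - 1:
        iy = n - 1
    if dx > 0.0:
        step_x = 1
        t_max_x = (x0 + (ix + 1) * h - sx) / dx
        t_delta_x = h / dx
    elif dx < 0.0:
        step_x = -1
        t_max_x = (x0 + ix * h - sx) / dx
        t_delta_x = -h / dx
    else:
        step_x = 0
        t_max_x = math.inf
        t_delta_x = math.inf
    if dy > 0.0:
        step_y = 1
        t_max_y = (x0 + (iy + 1) * h - sy) / dy
        t_delta_y = h / dy
    elif dy < 0.0:
        step_y = -1
        t_max_y = (x0 + iy * h - sy) / dy
        t_delta_y = -h / dy
    else:
        step_y = 0
        t_max_y = math.inf
        t_delta_y = math.inf
    t = tmin
    m = 0
    while t < tmax - 1e-12:
        if t_max_x < t_max_y:
            tn = t_max_x
        else:
            tn = t_max_y
        if tn > tmax:
            tn = tmax
        seg = (tn - t) * length
        if seg > 0.0:
            idx[m] = iy * n + ix
            lens[m] = seg
            m += 1
        if t_max_x < t_max_y:
            ix += step_x
            t_max_x += t_delta_x
        else:
            iy += step_y
            t_max_y += t_delta_y
        t = tn
        if ix < 0 or ix >= n or iy < 0 or iy >= n:
            break
    return m


@njit(cache=True, inline="always")
def _label_of(mu_j, thresholds):
    lab = 0
    while lab < thresholds.size and mu_j > thresholds[lab]:
        lab += 1
    return lab


@njit(cache=True)
def _poly_p_and_weights(t_k, mu_hat, sd, weights_out):
    """p = -log sum_n sd_n exp(-sum_k mu_hat[k,n] t_k), with per-material
    transmission-weighted spectral averages of mu_hat written to weights_out.
    Max-shifted for overflow safety.  Returns p."""
    n_mat, n_e = mu_hat.shape
    s_min = math.inf
    for nn in range(n_e):
        s = 0.0
        for k in range(n_mat):
            s += mu_hat[k, nn] * t_k[k]
        if s < s_min:
            s_min = s
    den = 0.0
    for k in range(n_mat):
        weights_out[k] = 0.0
    for nn in range(n_e):
        s = 0.0
        for k in range(n_mat):
            s += mu_hat[k, nn] * t_k[k]
        e = sd[nn] * math.exp(-(s - s_min))
        den += e
        for k in range(n_mat):
            weights_out[k] += e * mu_hat[k, nn]
    for k in range(n_mat):
        weights_out[k] /= den
    return s_min - math.log(den)


@njit(cache=True)
def poly_sinogram(mu, labels, mu_hat, sd, angles, sod, sdd, n_cells, cell_size,
                  n_px, h):
    """Polychromatic fan-beam sinogram of a labelled mu(E0) image."""
    n_views = angles.size
    n_mat = mu_hat.shape[0]
    out = np.zeros((n_views, n_cells))
    x0 = -0.5 * n_px * h
    idx = np.empty(2 * n_px + 4, np.int64)
    lens = np.empty(2 * n_px + 4, np.float64)
    t_k = np.empty(n_mat)
    w = np.empty(n_mat)
    for v in range(n_views):
        beta = angles[v]
        for c in range(n_cells):
            sx, sy, ex, ey = ray_endpoints(beta, sod, sdd, n_cells, cell_size, c)
            m = trace(sx, sy, ex, ey, x0, h, n_px, idx, lens)
            for k in range(n_mat):
                t_k[k] = 0.0
            for e in range(m):
                j = idx[e]
                t_k[labels[j]] += lens[e] * mu[j]
            for k in range(n_mat):
                t_k[k] *= MM_TO_CM
            out[v, c] = _poly_p_and_weights(t_k, mu_hat, sd, w)
    return out


@njit(cache=True)
def mono_sinogram(mu, angles, sod, sdd, n_cells, cell_size, n_px, h):
    """Monochromatic (linear) fan-beam sinogram: optical depth per ray."""
    n_views = angles.size
    out = np.zeros((n_views, n_cells))
    x0 = -0.5 * n_px * h
    idx = np.empty(2 * n_px + 4, np.int64)
    lens = np.empty(2 * n_px + 4, np.float64)
    for v in range(n_views):
        beta = angles[v]
        for c in range(n_cells):
            sx, sy, ex, ey = ray_endpoints(beta, sod, sdd, n_cells, cell_size, c)
            m = trace(sx, sy, ex, ey, x0, h, n_px, idx, lens)
            acc = 0.0
            for e in range(m):
                acc += lens[e] * mu[idx[e]]
            out[v, c] = acc * MM_TO_CM
    return out


@njit(cache=True)
def eart_sweep(mu, sino, thresholds, mu_hat, sd, angles, view_order, sod, sdd,
               n_cells, cell_size, n_px, h, relax):
    """One full E-ART sweep over all rays, updating ``mu`` in place.

    Per ray: labels from the current image by thresholding, exact
    polychromatic forward projection, linearised gradient row (the
    characteristic function treated as locally constant), Kaczmarz-style
    correction, nonnegativity clamp.
    """
    n_mat = mu_hat.shape[0]
    x0 = -0.5 * n_px * h
    idx = np.empty(2 * n_px + 4, np.int64)
    lens = np.empty(2 * n_px + 4, np.float64)
    labs = np.empty(2 * n_px + 4, np.int64)
    t_k = np.empty(n_mat)
    w = np.empty(n_mat)
    for vo in range(view_order.size):
        v = view_order[vo]
        beta = angles[v]
        for c in range(n_cells):
            sx, sy, ex, ey = ray_endpoints(beta, sod, sdd, n_cells, cell_size, c)
            m = trace(sx, sy, ex, ey, x0, h, n_px, idx, lens)
            if m == 0:
                continue
            for k in range(n_mat):
                t_k[k] = 0.0
            for e in range(m):
                j = idx[e]
                lab = _label_of(mu[j], thresholds)
                labs[e] = lab
                t_k[lab] += lens[e] * mu[j]
            for k in range(n_mat):
                t_k[k] *= MM_TO_CM
            p_est = _poly_p_and_weights(t_k, mu_hat, sd, w)
            norm2 = 0.0
            for e in range(m):
                a = MM_TO_CM * lens[e] * w[labs[e]]
                norm2 += a * a
            if norm2 <= 0.0:
                continue
            corr = relax * (sino[v, c] - p_est) / norm2
            for e in range(m):
                j = idx[e]
                a = MM_TO_CM * lens[e] * w[labs[e]]
                mu[j] += corr * a
                if mu[j] < 0.0:
                    mu[j] = 0.0
    return mu


@njit(cache=True)
def sart_sweep(mu, sino, angles, sod, sdd, n_cells, cell_size, n_px, h, relax):
    """One SART sweep (view-by-view simultaneous update) on the linear model."""
    x0 = -0.5 * n_px * h
    idx = np.empty(2 * n_px + 4, np.int64)
    lens = np.empty(2 * n_px + 4, np.float64)
    corr = np.empty(n_px * n_px)
    wsum = np.empty(n_px * n_px)
    for v in range(angles.size):
        beta = angles[v]
        for j in range(n_px * n_px):
            corr[j] = 0.0
            wsum[j] = 0.0
        for c in range(n_cells):
            sx, sy, ex, ey = ray_endpoints(beta, sod, sdd, n_cells, cell_size, c)
            m = trace(sx, sy, ex, ey, x0, h, n_px, idx, lens)
            if m == 0:
                continue
            row_sum = 0.0
            p_est = 0.0
            for e in range(m):
                r = MM_TO_CM * lens[e]
                row_sum += r
                p_est += r * mu[idx[e]]
            if row_sum <= 0.0:
                continue
            resid = (sino[v, c] - p_est) / row_sum
            for e in range(m):
                r = MM_TO_CM * lens[e]
                corr[idx[e]] += r * resid
                wsum[idx[e]] += r
        for j in range(n_px * n_px):
            if wsum[j] > 0.0:
                mu[j] += relax * corr[j] / wsum[j]
                if mu[j] < 0.0:
                    mu[j] = 0.0
    return mu
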