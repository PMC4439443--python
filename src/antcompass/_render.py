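"""Numba ray-casting kernel behind the eye model.

One or more rays per retina pixel, nearest-hit sampling.  Triangles are
grouped by tussock; each group carries a bounding sphere so rays skip clumps
they cannot intersect.  Rays that miss every blade hit the infinite ground
plane (z = 0) when pointing downward, otherwise the sky.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True, fastmath=True)
def render_rays(origin, dirs, v0, e1, e2, intensity,
                group_start, centers, radii, ground_i, sky_i):
    """Intensity seen along each unit ray from ``origin``.

    dirs: (N, 3); returns (N,) intensities.
    """
    n = dirs.shape[0]
    out = np.empty(n)
    ox, oy, oz = origin[0], origin[1], origin[2]
    n_groups = group_start.shape[0] - 1
    # per-call constants of the ray-vs-bounding-sphere test
    ocx = np.empty(n_groups)
    ocy = np.empty(n_groups)
    ocz = np.empty(n_groups)
    c2 = np.empty(n_groups)
    for g in range(n_groups):
        ocx[g] = ox - centers[g, 0]
        ocy[g] = oy - centers[g, 1]
        ocz[g] = oz - centers[g, 2]
        c2[g] = (ocx[g] * ocx[g] + ocy[g] * ocy[g] + ocz[g] * ocz[g]
                 - radii[g] * radii[g])
    for p in range(n):
        dx, dy, dz = dirs[p, 0], dirs[p, 1], dirs[p, 2]
        if dz < 0.0:
            best_t = -oz / dz          # ground-plane hit
            best_i = ground_i
        else:
            best_t = np.inf
            best_i = sky_i
        for g in range(n_groups):
            b = dx * ocx[g] + dy * ocy[g] + dz * ocz[g]
            disc = b * b - c2[g]
            if disc < 0.0:
                continue
            sq = np.sqrt(disc)
            if -b - sq > best_t or -b + sq < 0.0:
                continue
            for t_i in range(group_start[g], group_start[g + 1]):
                # Moller-Trumbore
                e1x, e1y, e1z = e1[t_i, 0], e1[t_i, 1], e1[t_i, 2]
                e2x, e2y, e2z = e2[t_i, 0], e2[t_i, 1], e2[t_i, 2]
                px = dy * e2z - dz * e2y
                py = dz * e2x - dx * e2z
                pz = dx * e2y - dy * e2x
                det = e1x * px + e1y * py + e1z * pz
                if -_EPS < det < _EPS:
                    continue
                inv = 1.0 / det
                tx = ox - v0[t_i, 0]
                ty = oy - v0[t_i, 1]
                tz = oz - v0[t_i, 2]
                u = (tx * px + ty * py + tz * pz) * inv
                if u < 0.0 or u > 1.0:
                    continue
                qx = ty * e1z - tz * e1y
                qy = tz * e1x - tx * e1z
                qz = tx * e1y - ty * e1x
                v = (dx * qx + dy * qy + dz * qz) * inv
                if v < 0.0 or u + v > 1.0:
                    continue
                t = (e2x * qx + e2y * qy + e2z * qz) * inv
                if _EPS < t < best_t:
                    best_t = t
                    best_i = intensity[t_i]
        out[p] = best_i
    return out
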