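"""Independent oracles used by the tests.

These deliberately avoid the package's fast paths: a plain-numpy ray-triangle
renderer looping over every triangle (no bounding-sphere culling, no numba),
a direct-summation image difference, and shapely for point-to-polyline
distance.
"""

from __future__ import annotations

import numpy as np


def brute_force_ray(origin, direction, triangles, intensities,
                    ground_i, sky_i) -> float:
    """Nearest-hit intensity along one ray, checking every triangle."""
    o = np.asarray(origin, float)
    d = np.asarray(direction, float)
    if d[2] < 0.0:
        best_t, best_i = -o[2] / d[2], ground_i
    else:
        best_t, best_i = np.inf, sky_i
    for tri, inten in zip(triangles, intensities):
        v0, v1, v2 = tri
        e1, e2 = v1 - v0, v2 - v0
        p = np.cross(d, e2)
        det = float(e1 @ p)
        if abs(det) <= 1e-12:
            continue
        inv = 1.0 / det
        tvec = o - v0
        u = float(tvec @ p) * inv
        if u < 0.0 or u > 1.0:
            continue
        q = np.cross(tvec, e1)
        v = float(d @ q) * inv
        if v < 0.0 or u + v > 1.0:
            continue
        t = float(e2 @ q) * inv
        if 1e-12 < t < best_t:
            best_t, best_i = t, inten
    return best_i


def brute_force_pixel(world, pose, spec, row, col) -> float:
    """Pixel intensity via the brute-force ray oracle (mean over sub-rays)."""
    from antcompass.eye import _head_ray_dirs, _rotation
    s2 = spec.supersampling ** 2
    dirs = _head_ray_dirs(spec) @ _rotation(pose).T
    start = (row * spec.n_cols + col) * s2
    vals = [brute_force_ray(pose.position, dirs[start + j],
                            world.triangles, world.intensities,
                            world.ground_intensity, world.sky_intensity)
            for j in range(s2)]
    return float(np.mean(vals))


def direct_image_difference(a: np.ndarray, b: np.ndarray) -> float:
    """Sum of squared differences via an explicit python loop."""
    total = 0.0
    for x, y in zip(np.asarray(a, float).ravel(), np.asarray(b, float).ravel()):
        total += (x - y) ** 2
    return total


def shapely_distance_to_route(point, route) -> float:
    from shapely.geometry import LineString, Point
    return float(LineString(route.points).distance(Point(point)))
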