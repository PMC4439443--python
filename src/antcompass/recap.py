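"""Closed-loop route recapitulation driven by the visual compass.

The simulated ant starts at the route origin facing the route tangent.  At
every step it adopts a head pitch drawn from the test distribution, scans yaw
over +/-90 deg around its current heading (2 deg steps), finds the globally
best match between the scanned views and the full memory bank, turns to that
heading and advances 1 cm.  The run halts as `completed` on arriving within a
small radius of the route end, as `deviated` if it strays more than 1 m from
the route polyline, or as `overshot` once the travelled path exceeds the route
length by 0.1 m -- which also bounds the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eye import render_scan, wrap_deg
from .memory import MemoryBank, pairwise_sq_diffs
from .world import PitchDistribution, Route, World, sample_pitch_trace

__all__ = ["RecapResult", "recapitulate_route", "distance_to_route"]

STEP_M = 0.01


@dataclass
class RecapResult:
    """Outcome of one closed-loop run."""

    path: np.ndarray                       # (S+1, 2), consecutive points 1 cm apart
    outcome: str                           # completed | deviated | overshot
    headings_deg: np.ndarray = field(default=None)
    matched_indices: np.ndarray = field(default=None)
    pitches_deg: np.ndarray = field(default=None)
    final_distance_to_end_m: float = float("nan")

    @property
    def n_steps(self) -> int:
        return len(self.path) - 1


def distance_to_route(point, route: Route) -> float:
    """Minimum Euclidean distance (m) from a point to the route polyline."""
    p = np.asarray(point, dtype=np.float64)
    a = route.points[:-1]
    b = route.points[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.einsum("ij,ij->i", p[None, :] - a, ab) / np.where(denom == 0, 1.0, denom)
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.sqrt(((proj - p) ** 2).sum(axis=1)).min())


def recapitulate_route(world: World, bank: MemoryBank, route: Route,
                       test_pitch_dist: PitchDistribution, seed: int = 0,
                       scan_half_deg: float = 90.0, step_deg: float = 2.0,
                       arrival_radius_m: float = 0.05,
                       overshoot_m: float = 0.1,
                       deviation_limit_m: float = 1.0) -> RecapResult:
    """Attempt to retrace ``route`` using the full memory bank as compass."""
    max_steps = int(round((route.length_m + overshoot_m) / STEP_M))
    pitches = sample_pitch_trace(test_pitch_dist, max_steps, seed).angles_deg
    offsets = np.arange(-scan_half_deg, scan_half_deg + 1e-9, step_deg)
    end = route.points[-1]

    pos = route.points[0].copy()
    heading = float(route.headings_deg[0])
    path = [pos.copy()]
    headings, matched = [], []
    outcome = "overshot"
    for k in range(max_steps):
        yaws = heading + offsets
        scan = render_scan(world, pos[0], pos[1], float(pitches[k]), yaws,
                           bank.spec, z=bank.eye_height_m)
        diffs = pairwise_sq_diffs(scan, bank.images)
        row, col = np.unravel_index(np.argmin(diffs), diffs.shape)
        heading = wrap_deg(float(yaws[row]))
        rad = np.radians(heading)
        pos = pos + STEP_M * np.array([np.cos(rad), np.sin(rad)])
        path.append(pos.copy())
        headings.append(heading)
        matched.append(int(col) + 1)
        if np.hypot(*(pos - end)) <= arrival_radius_m:
            outcome = "completed"
            break
        if distance_to_route(pos, route) > deviation_limit_m:
            outcome = "deviated"
            break
    n = len(path) - 1
    return RecapResult(
        path=np.array(path), outcome=outcome,
        headings_deg=np.array(headings),
        matched_indices=np.array(matched, dtype=np.int64),
        pitches_deg=pitches[:n].copy(),
        final_distance_to_end_m=float(np.hypot(*(path[-1] - end))))
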