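"""Visual compass: rotational image difference functions and their quality.

A stored (reference) view I^r can be used as a compass: rotate the current
viewpoint in yaw, compute the pixel-wise sum of squared intensity differences
sum_i (I_i - I_i^r)^2 at each rotation, and head in the direction of the
minimum of the resulting rotational image difference function (rIDF).  Two
metrics quantify how head pitch degrades this: the absolute heading error of
the rIDF minimum, and a detectability index (median rIDF / minimum rIDF --
near 1 means the scan carries little directional information).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eye import PanoramicImage, Pose, RetinaSpec, render_scan, wrap_deg
from .world import World

__all__ = ["RIDF", "HeadingResult", "image_difference", "compute_ridf",
           "ridf_minimum", "heading_error", "detectability"]

#: Yaw step (deg) used for rotational scans throughout the analyses.
DEFAULT_RIDF_STEP_DEG = 2.0


@dataclass
class RIDF:
    """Image differences over a full 360 deg yaw scan against one reference.

    ``offsets_deg`` are rotations relative to the reference heading, strictly
    increasing and spanning 360 deg at a uniform step.
    """

    offsets_deg: np.ndarray
    values: np.ndarray
    reference_pose: Pose
    test_pose: Pose

    def __post_init__(self) -> None:
        self.offsets_deg = np.asarray(self.offsets_deg, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.offsets_deg.shape != self.values.shape or self.offsets_deg.ndim != 1:
            raise ValueError("offsets and values must be equal-length 1-D arrays")


@dataclass
class HeadingResult:
    """Heading recovered by a compass scan, with match diagnostics."""

    heading_deg: float
    ridf_min: float
    detectability: float
    matched_index: int | None = None
    matched_pitch_deg: float | None = None


def image_difference(current: PanoramicImage, reference: PanoramicImage) -> float:
    """Pixel-wise sum of squared intensity differences between two views."""
    if current.values.shape != reference.values.shape:
        raise ValueError("image shapes differ")
    d = current.values - reference.values
    return float(np.sum(d * d))


def compute_ridf(world: World, location, pitch_deg: float,
                 reference: PanoramicImage,
                 step_deg: float = DEFAULT_RIDF_STEP_DEG) -> RIDF:
    """Scan yaw through 360 deg at ``location`` and difference each rendered
    view against the reference.

    Offsets are taken relative to the reference heading; each test view is
    re-rendered at the given pitch (pitch breaks column-shift equivalence, so
    no shift shortcut is used).
    """
    if abs(360.0 / step_deg - round(360.0 / step_deg)) > 1e-9:
        raise ValueError("step must divide 360")
    x, y = float(location[0]), float(location[1])
    offsets = np.arange(-180.0, 180.0, step_deg)
    yaws = reference.pose.yaw_deg + offsets
    scan = render_scan(world, x, y, pitch_deg, yaws, reference.spec,
                       z=reference.pose.z)
    d = scan - reference.flat()[None, :]
    values = np.einsum("ij,ij->i", d, d)
    test_pose = Pose(x, y, reference.pose.z, yaw_deg=reference.pose.yaw_deg,
                     pitch_deg=pitch_deg)
    return RIDF(offsets, values, reference.pose, test_pose)


def ridf_minimum(ridf: RIDF) -> tuple[float, float]:
    """Global minimum of the rIDF as (offset_deg, value).

    Ties are broken towards the smallest absolute offset, then negative
    before positive.
    """
    if len(ridf.values) == 0:
        raise ValueError("empty rIDF")
    vmin = ridf.values.min()
    tied = np.flatnonzero(ridf.values == vmin)
    offs = ridf.offsets_deg[tied]
    order = np.lexsort((offs > 0, np.abs(offs)))
    best = tied[order[0]]
    return float(ridf.offsets_deg[best]), float(vmin)


def heading_error(selected_deg: float, true_heading_deg: float) -> float:
    """Circular absolute difference between two headings, in [0, 180]."""
    return abs(wrap_deg(selected_deg - true_heading_deg))


def detectability(ridf: RIDF) -> float:
    """Median rIDF divided by minimum rIDF (>= 1; +inf on a perfect match)."""
    if len(ridf.values) == 0:
        raise ValueError("empty rIDF")
    vmin = float(ridf.values.min())
    if vmin == 0.0:
        return float("inf")
    return float(np.median(ridf.values)) / vmin
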