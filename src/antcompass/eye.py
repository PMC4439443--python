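"""Ant-eye model: a low-resolution spherical retina rendered from a pose.

The retina is a window in a uniformly curved (spherical) visual field: 296 deg
horizontally and 76 deg vertically at 4 deg per pixel, giving 74 columns x
19 rows, with a 64 deg blindspot centred directly behind.  At
zero pitch the central row looks at the horizon.  Pitching the head rotates
the whole window on the sphere, so the rendered horizon shifts and curves
non-uniformly across the image -- the distortion at the heart of the analysis.

Conventions: yaw 0 = +x axis, counter-clockwise positive; pitch positive =
head up; azimuth positive to the ant's left.  Image row 0 is the top of the
visual field, column 0 the leftmost azimuth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ._render import render_rays
from .world import World

__all__ = ["Pose", "RetinaSpec", "PanoramicImage", "pixel_directions",
           "render_view", "render_scan", "DEFAULT_EYE_HEIGHT_M"]

#: Eye height above the ground plane (m); configurable per pose.
DEFAULT_EYE_HEIGHT_M = 0.005


def wrap_deg(angle: float) -> float:
    """Wrap an angle to (-180, 180]."""
    a = (-angle + 180.0) % 360.0
    return 180.0 - a


@dataclass(frozen=True)
class Pose:
    x: float
    y: float
    z: float = DEFAULT_EYE_HEIGHT_M
    yaw_deg: float = 0.0
    pitch_deg: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "yaw_deg", wrap_deg(self.yaw_deg))
        if abs(self.pitch_deg) > 90.0:
            raise ValueError("|pitch| must be <= 90 deg")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class RetinaSpec:
    """Angular layout of the retina grid (uniform spacing on the sphere).

    ``supersampling`` is the renderer's anti-aliasing factor: each pixel's
    intensity is the mean over an s x s grid of sub-rays spanning the pixel's
    angular footprint (1 = a single ray through the pixel centre).
    """

    hfov_deg: float = 296.0
    vfov_deg: float = 76.0
    resolution_deg: float = 4.0
    supersampling: int = 2

    def __post_init__(self) -> None:
        for fov, limit in ((self.hfov_deg, 360.0), (self.vfov_deg, 180.0)):
            if not 0 < fov <= limit:
                raise ValueError("field of view out of range")
            if abs(fov / self.resolution_deg
                   - round(fov / self.resolution_deg)) > 1e-9:
                raise ValueError("fov must be a multiple of the resolution")
        if self.supersampling < 1:
            raise ValueError("supersampling must be >= 1")

    @property
    def n_cols(self) -> int:
        return int(round(self.hfov_deg / self.resolution_deg))

    @property
    def n_rows(self) -> int:
        return int(round(self.vfov_deg / self.resolution_deg))

    @property
    def azimuths_deg(self) -> np.ndarray:
        """Column-centre azimuths, left (+) to right (-); blindspot behind."""
        half = (self.hfov_deg - self.resolution_deg) / 2.0
        return half - self.resolution_deg * np.arange(self.n_cols)

    @property
    def elevations_deg(self) -> np.ndarray:
        """Row-centre elevations, top (+) to bottom (-)."""
        half = (self.vfov_deg - self.resolution_deg) / 2.0
        return half - self.resolution_deg * np.arange(self.n_rows)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols


def _rotation(pose: Pose) -> np.ndarray:
    """World-from-head rotation: pitch about the transverse (y) axis, then
    yaw about the world vertical."""
    p = np.radians(pose.pitch_deg)
    y = np.radians(pose.yaw_deg)
    # pitch up: forward (1,0,0) -> (cos p, 0, sin p)
    r_pitch = np.array([[np.cos(p), 0.0, -np.sin(p)],
                        [0.0, 1.0, 0.0],
                        [np.sin(p), 0.0, np.cos(p)]])
    r_yaw = np.array([[np.cos(y), -np.sin(y), 0.0],
                      [np.sin(y), np.cos(y), 0.0],
                      [0.0, 0.0, 1.0]])
    return r_yaw @ r_pitch


def _sphere_dirs(az_deg: np.ndarray, el_deg: np.ndarray) -> np.ndarray:
    az = np.radians(az_deg)
    el = np.radians(el_deg)
    return np.stack([np.cos(el) * np.cos(az),
                     np.cos(el) * np.sin(az),
                     np.sin(el) * np.ones_like(az)], axis=-1)


def pixel_directions(spec: RetinaSpec, pose: Pose) -> np.ndarray:
    """World-frame unit view direction of every pixel centre, (rows, cols, 3).

    Head-frame directions are rotated first by pitch about the head's
    transverse (y) axis, then the whole head by yaw about the world vertical.
    """
    az = spec.azimuths_deg[None, :] + 0.0 * spec.elevations_deg[:, None]
    el = spec.elevations_deg[:, None] + 0.0 * spec.azimuths_deg[None, :]
    return _sphere_dirs(az, el) @ _rotation(pose).T


@lru_cache(maxsize=8)
def _head_ray_dirs(spec: RetinaSpec) -> np.ndarray:
    """Head-frame sub-ray directions, (n_pixels * s^2, 3), pixel-major.

    Sub-rays sit on an s x s grid inside each pixel's angular footprint
    (s = 1 reduces to the pixel centre).
    """
    s = spec.supersampling
    sub = ((np.arange(s) + 0.5) / s - 0.5) * spec.resolution_deg
    az = (spec.azimuths_deg[None, :, None, None]
          + sub[None, None, None, :])
    el = (spec.elevations_deg[:, None, None, None]
          + sub[None, None, :, None])
    az, el = np.broadcast_arrays(az, el)
    d = _sphere_dirs(az, el).reshape(-1, 3)
    d.setflags(write=False)
    return d


def _render_flat(world: World, x: float, y: float, z: float,
                 yaw_deg: float, pitch_deg: float,
                 spec: RetinaSpec) -> np.ndarray:
    """Render one view as a flat (n_pixels,) array of pixel-mean intensities."""
    pose = Pose(x, y, z, yaw_deg=yaw_deg, pitch_deg=pitch_deg)
    dirs = _head_ray_dirs(spec) @ _rotation(pose).T
    v0, e1, e2, inten, starts, centers, radii = world.accel()
    vals = render_rays(np.array([x, y, z]), np.ascontiguousarray(dirs),
                       v0, e1, e2, inten, starts, centers, radii,
                       world.ground_intensity, world.sky_intensity)
    s2 = spec.supersampling ** 2
    if s2 > 1:
        vals = vals.reshape(-1, s2).mean(axis=1)
    return vals


@dataclass
class PanoramicImage:
    """A rendered retinotopic view tagged with the pose that produced it."""

    values: np.ndarray
    pose: Pose
    spec: RetinaSpec = field(default_factory=RetinaSpec)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError("image shape does not match the retina spec")

    def flat(self) -> np.ndarray:
        return self.values.ravel()

    def save_npy(self, path) -> None:
        np.save(path, self.values)

    def to_png(self, path, lo: float = 0.0, hi: float = 1.0) -> None:
        import imageio.v3 as iio
        scaled = np.clip((self.values - lo) / (hi - lo), 0.0, 1.0)
        iio.imwrite(path, (scaled * 255).round().astype(np.uint8))


def render_view(world: World, pose: Pose,
                spec: RetinaSpec = RetinaSpec()) -> PanoramicImage:
    """Render the retinotopic view of ``world`` from ``pose``.

    Each pixel averages an s x s grid of sub-rays over its angular footprint
    (s = ``spec.supersampling``); a sub-ray carries the intensity of the
    nearest blade triangle it hits, else the ground for downward rays
    (infinite ground plane), else the sky.  The pose must lie inside the
    world extent.
    """
    if not world.contains(pose.x, pose.y):
        raise ValueError("pose lies outside the world extent")
    vals = _render_flat(world, pose.x, pose.y, pose.z,
                        pose.yaw_deg, pose.pitch_deg, spec)
    return PanoramicImage(vals.reshape(spec.n_rows, spec.n_cols), pose, spec)


def render_scan(world: World, x: float, y: float, pitch_deg: float,
                yaws_deg: np.ndarray, spec: RetinaSpec = RetinaSpec(),
                z: float = DEFAULT_EYE_HEIGHT_M) -> np.ndarray:
    """Render one view per yaw sample at a fixed position and pitch.

    Returns a (len(yaws), n_pixels) matrix of flattened images -- the raw
    material of a rotational scan.
    """
    if not world.contains(x, y):
        raise ValueError("position lies outside the world extent")
    out = np.empty((len(yaws_deg), spec.n_pixels))
    for k, yaw in enumerate(yaws_deg):
        out[k] = _render_flat(world, x, y, z, float(yaw), pitch_deg, spec)
    return out
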