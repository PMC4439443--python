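"""Head- and body-pitch angles from manually labelled video-frame landmarks.

Frames are labelled with three points in image coordinates (y increasing
downward): the centre of the mandible, the dorsal head-neck joint, and the
ventral alitrunk-petiole joint.  The head angle is the direction of the
neck-to-mandible segment relative to the image horizontal, the body angle
that of the petiole-to-neck segment, with the convention that 90 deg points
straight down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FrameLandmarks", "segment_angle", "angles_from_landmarks",
           "summarize_pitch"]

LANDMARK_COLUMNS = ["frame", "x_mandible", "y_mandible", "x_neck", "y_neck",
                    "x_petiole", "y_petiole"]


@dataclass(frozen=True)
class FrameLandmarks:
    """Labelled landmark coordinates (px) for one video frame."""

    frame: int
    mandible: tuple[float, float]
    neck: tuple[float, float]
    petiole: tuple[float, float]


def segment_angle(anterior, posterior, y_down: bool = True) -> float:
    """Angle (deg) of the posterior-to-anterior vector vs the image horizontal.

    With image-style coordinates (``y_down=True``), a downward-pointing vector
    reads +90 deg and an upward one -90 deg.  Set ``y_down=False`` for
    mathematical (y-up) coordinates; this simply negates the angle.
    """
    ax, ay = float(anterior[0]), float(anterior[1])
    px, py = float(posterior[0]), float(posterior[1])
    dx, dy = ax - px, ay - py
    if dx == 0.0 and dy == 0.0:
        raise ValueError("segment endpoints coincide")
    if not y_down:
        dy = -dy
    return float(np.degrees(np.arctan2(dy, dx)))


def angles_from_landmarks(landmarks: pd.DataFrame,
                          y_down: bool = True) -> pd.DataFrame:
    """Per-frame head and body angles from a landmark table.

    Expects columns ``frame, x_mandible, y_mandible, x_neck, y_neck,
    x_petiole, y_petiole``.  Head angle uses (mandible, neck); body angle uses
    (neck, alitrunk-petiole joint).
    """
    missing = [c for c in LANDMARK_COLUMNS if c not in landmarks.columns]
    if missing:
        raise ValueError(f"landmark table missing columns: {missing}")
    rows = []
    for rec in landmarks.itertuples(index=False):
        rows.append({
            "frame": rec.frame,
            "head_deg": segment_angle((rec.x_mandible, rec.y_mandible),
                                      (rec.x_neck, rec.y_neck), y_down),
            "body_deg": segment_angle((rec.x_neck, rec.y_neck),
                                      (rec.x_petiole, rec.y_petiole), y_down),
        })
    return pd.DataFrame(rows)


def summarize_pitch(trace, bin_width_deg: float = 2.0) -> dict:
    """Order statistics and a histogram of a pitch-angle sequence."""
    a = np.asarray(trace, dtype=np.float64).ravel()
    if a.size == 0:
        raise ValueError("empty pitch trace")
    q1, med, q3 = np.percentile(a, [25, 50, 75])
    lo = np.floor(a.min() / bin_width_deg) * bin_width_deg
    hi = np.ceil(a.max() / bin_width_deg) * bin_width_deg
    edges = np.arange(lo, hi + bin_width_deg, bin_width_deg)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width_deg])
    counts, edges = np.histogram(a, bins=edges)
    return {
        "n": int(a.size),
        "median_deg": float(med),
        "iqr_deg": float(q3 - q1),
        "min_deg": float(a.min()),
        "max_deg": float(a.max()),
        "range_deg": float(a.max() - a.min()),
        "hist_counts": counts.tolist(),
        "hist_edges_deg": edges.tolist(),
    }
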