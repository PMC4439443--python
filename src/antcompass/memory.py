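"""Route memory banks and the five memory/retrieval strategies.

During learning, a view is stored every 1 cm along the route, facing the route
tangent, at the head pitch given by the learning pitch trace (an 8.12 m route
yields exactly 812 memories).  At test time a heading is recovered by scanning
yaw and matching against stored views under one of five strategies:

  closest  -- the single memory 1 cm further along the route;
  local    -- best-matching memory within +/-15 cm (current position excluded);
  full     -- best-matching memory over the whole route (current excluded);
  limited  -- as full, but memories stored at |pitch| > 10 deg are discarded,
              and if the current view exceeds that pitch the previously
              computed heading is kept instead of computing a new one;
  averaged -- as full, over a bank whose k-th image is the pixel-wise mean of
              stored images k-4 .. k (window shrinking at the route start).

"Best match" means the smallest global rIDF minimum across candidate
memories; ties go to the spatially nearer memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .compass import HeadingResult
from .eye import PanoramicImage, Pose, RetinaSpec, render_scan
from .world import PitchTrace, Route, World

__all__ = ["MemoryEntry", "MemoryBank", "StrategySpec", "build_memory_bank",
           "build_averaged_bank", "recover_heading", "pairwise_sq_diffs",
           "candidate_indices", "best_match", "STRATEGIES"]

STRATEGIES = ("closest", "local", "full", "limited", "averaged")


@dataclass
class MemoryEntry:
    """One stored route view (1-based index; arc length in cm)."""

    index: int
    s_cm: float
    pose: Pose
    image: PanoramicImage


@dataclass
class MemoryBank:
    """Ordered route memories at exactly 1 cm arc-length spacing.

    Images are held flattened as an (M, n_pixels) matrix for fast pairwise
    differencing; ``entry(i)`` rebuilds the i-th (1-based) MemoryEntry view.
    """

    images: np.ndarray                      # (M, n_pixels)
    s_cm: np.ndarray                        # (M,)
    x_m: np.ndarray
    y_m: np.ndarray
    yaw_deg: np.ndarray
    pitch_deg: np.ndarray
    spec: RetinaSpec = field(default_factory=RetinaSpec)
    pitch_kind: str = "zero"
    eye_height_m: float = 0.005

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 2 or self.images.shape[1] != self.spec.n_pixels:
            raise ValueError("images must be (M, n_pixels) for the retina spec")
        if np.any(np.abs(np.diff(self.s_cm) - 1.0) > 1e-9):
            raise ValueError("memory entries must be 1 cm apart and ordered")

    def __len__(self) -> int:
        return len(self.images)

    def entry(self, index: int) -> MemoryEntry:
        i = index - 1
        if not 0 <= i < len(self):
            raise IndexError(f"memory index {index} out of range 1..{len(self)}")
        pose = Pose(self.x_m[i], self.y_m[i], self.eye_height_m,
                    yaw_deg=self.yaw_deg[i], pitch_deg=self.pitch_deg[i])
        img = PanoramicImage(
            self.images[i].reshape(self.spec.n_rows, self.spec.n_cols),
            pose, self.spec)
        return MemoryEntry(index, float(self.s_cm[i]), pose, img)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        """Persist as a directory of per-entry NPY images plus a CSV manifest."""
        import pandas as pd
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        idx = np.arange(1, len(self) + 1)
        pd.DataFrame({
            "index": idx, "s_cm": self.s_cm, "x_m": self.x_m, "y_m": self.y_m,
            "yaw_deg": self.yaw_deg, "pitch_deg": self.pitch_deg,
        }).to_csv(d / "manifest.csv", index=False)
        for i in idx:
            np.save(d / f"{i:04d}.npy",
                    self.images[i - 1].reshape(self.spec.n_rows, self.spec.n_cols))

    @classmethod
    def load(cls, directory, spec: RetinaSpec = RetinaSpec(),
             pitch_kind: str = "unknown") -> "MemoryBank":
        import pandas as pd
        d = Path(directory)
        man = pd.read_csv(d / "manifest.csv")
        images = np.stack([np.load(d / f"{i:04d}.npy").ravel()
                           for i in man["index"]])
        return cls(images, man["s_cm"].to_numpy(float),
                   man["x_m"].to_numpy(float), man["y_m"].to_numpy(float),
                   man["yaw_deg"].to_numpy(float),
                   man["pitch_deg"].to_numpy(float), spec, pitch_kind)


@dataclass(frozen=True)
class StrategySpec:
    """Which retrieval strategy to use, and its tunable windows."""

    strategy: str = "full"
    local_window_cm: float = 15.0
    pitch_limit_deg: float = 10.0
    averaging_window: int = 5
    scan_step_deg: float = 2.0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if min(self.local_window_cm, self.pitch_limit_deg,
               self.averaging_window, self.scan_step_deg) <= 0:
            raise ValueError("strategy parameters must be positive")


def build_memory_bank(world: World, route: Route, pitch_trace: PitchTrace,
                      spec: RetinaSpec = RetinaSpec(),
                      eye_height_m: float = 0.005) -> MemoryBank:
    """Render and store one view per 1 cm route position.

    Each entry faces the route tangent at its position and is pitched by the
    corresponding trace value; the trace must have one angle per storage
    position.
    """
    idxs = route.storage_indices(0.01)
    if len(pitch_trace) != len(idxs):
        raise ValueError(
            f"pitch trace length {len(pitch_trace)} != {len(idxs)} storage positions")
    images = np.empty((len(idxs), spec.n_pixels))
    for k, i in enumerate(idxs):
        x, y = route.points[i]
        yaw = route.headings_deg[i]
        images[k] = render_scan(world, x, y, float(pitch_trace.angles_deg[k]),
                                np.array([yaw]), spec, z=eye_height_m)[0]
    return MemoryBank(
        images=images,
        s_cm=np.round(idxs * route.spacing_m * 100.0, 9),
        x_m=route.points[idxs, 0], y_m=route.points[idxs, 1],
        yaw_deg=route.headings_deg[idxs],
        pitch_deg=pitch_trace.angles_deg.copy(),
        spec=spec, pitch_kind=pitch_trace.kind, eye_height_m=eye_height_m)


def build_averaged_bank(bank: MemoryBank, window: int = 5) -> MemoryBank:
    """Replace each stored image by the running mean of the last ``window``
    images (the window shrinks near the route start, so entry 1 is unchanged)."""
    if len(bank) == 0:
        raise ValueError("empty memory bank")
    out = np.empty_like(bank.images)
    for k in range(len(bank)):
        out[k] = bank.images[max(0, k - window + 1):k + 1].mean(axis=0)
    return replace(bank, images=out)


def pairwise_sq_diffs(scan: np.ndarray, images: np.ndarray) -> np.ndarray:
    """Sum-of-squared-differences matrix between scan views and stored images.

    scan (Y, P) x images (M, P) -> (Y, M), computed via the Gram expansion
    ||a - b||^2 = ||a||^2 + ||b||^2 - 2 a.b (clipped at zero).
    """
    s2 = np.einsum("ij,ij->i", scan, scan)
    m2 = np.einsum("ij,ij->i", images, images)
    d = s2[:, None] + m2[None, :] - 2.0 * (scan @ images.T)
    return np.clip(d, 0.0, None, out=d)


def candidate_indices(bank: MemoryBank, test_index: int,
                      spec: StrategySpec) -> np.ndarray:
    """1-based indices of the memories a strategy may match against.

    The memory co-located with the test point (``test_index``) is always
    excluded; the ``limited`` strategy additionally drops memories stored at
    |pitch| beyond its gate.  ``averaged`` searches the same set as ``full``
    (over the averaged images).
    """
    M = len(bank)
    if spec.strategy == "closest":
        if test_index + 1 > M:
            raise IndexError("no memory 1 cm further along the route")
        return np.array([test_index + 1])
    idx = np.arange(1, M + 1)
    if spec.strategy == "local":
        mask = (np.abs(bank.s_cm - float(test_index)) <= spec.local_window_cm)
        mask &= idx != test_index
    elif spec.strategy in ("full", "averaged"):
        mask = idx != test_index
    elif spec.strategy == "limited":
        mask = (np.abs(bank.pitch_deg) <= spec.pitch_limit_deg) & (idx != test_index)
        if not mask.any():
            raise ValueError("limited strategy: no memories survive the pitch gate")
    cand = idx[mask]
    if len(cand) == 0:
        raise ValueError("no candidate memories for this strategy")
    return cand


def best_match(diffs: np.ndarray, cand: np.ndarray, s_cand: np.ndarray,
               s_test: float) -> tuple[int, int]:
    """(scan row, candidate column) of the best rIDF minimum; ties to the
    spatially nearer memory, then scan order."""
    vmin = diffs.min()
    rows, cols = np.nonzero(diffs == vmin)
    if len(rows) > 1:
        order = np.lexsort((rows, np.abs(s_cand[cols] - s_test)))
        rows, cols = rows[order], cols[order]
    return int(rows[0]), int(cols[0])


def recover_heading(bank: MemoryBank, world: World, test_location,
                    test_pitch_deg: float, test_index: int,
                    spec: StrategySpec = StrategySpec(),
                    previous_heading_deg: float | None = None) -> HeadingResult:
    """Recover a world-frame heading at a test location using one strategy.

    ``test_index`` is the 1-based index of the memory co-located with the test
    point (0 if the test point precedes the first memory); that memory is
    excluded from search.  For the ``limited`` strategy a ``previous_heading``
    must be supplied (the route-start tangent at the first test point): it is
    returned unchanged whenever the current pitch exceeds the gate.
    """
    M = len(bank)
    if not 0 <= test_index <= M:
        raise IndexError("test_index out of range")
    s_test = float(test_index)  # cm; entries sit at s = 1..M cm

    if spec.strategy == "limited" and abs(test_pitch_deg) > spec.pitch_limit_deg:
        if previous_heading_deg is None:
            raise ValueError("limited strategy requires a previous heading")
        return HeadingResult(float(previous_heading_deg), float("nan"),
                             float("nan"), None, None)

    images = bank.images
    if spec.strategy == "averaged":
        images = build_averaged_bank(bank, spec.averaging_window).images
    cand = candidate_indices(bank, test_index, spec)

    x, y = float(test_location[0]), float(test_location[1])
    yaws = np.arange(0.0, 360.0, spec.scan_step_deg)
    scan = render_scan(world, x, y, test_pitch_deg, yaws, bank.spec,
                       z=bank.eye_height_m)
    diffs = pairwise_sq_diffs(scan, images[cand - 1])
    row, col = best_match(diffs, cand, bank.s_cm[cand - 1], s_test)
    ridf = diffs[:, col]
    vmin = float(ridf.min())
    detect = float("inf") if vmin == 0.0 else float(np.median(ridf)) / vmin
    m = int(cand[col])
    return HeadingResult(float(yaws[row]), float(diffs[row, col]), detect,
                         m, float(bank.pitch_deg[m - 1]))
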