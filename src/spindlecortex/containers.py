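"""Interchange containers: space-time kymographs and position tracks.

These are the formats that connect simulation, synthetic data generation
and quantification: a kymograph is the cortical intensity sampled along a
1D path over time together with the DNA track; a trajectory is a set of
time-stamped positions (1D or 2D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trajectory:
    """Time-stamped positions in μm: shape (n,) for 1D or (n, 2) for 2D."""

    t: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.t.ndim != 1 or len(self.t) != len(self.positions):
            raise ValueError("times and positions must have matching lengths")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def is_1d(self) -> bool:
        return self.positions.ndim == 1

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class Kymograph:
    """Space-time intensity matrix with the DNA track.

    ``intensity`` has shape (n_space, n_time); ``x`` are the spatial
    coordinates (μm) and ``t`` the frame times (min). ``dna_center`` gives
    the DNA centre per frame and ``dna_half_extent`` its half-width
    (scalar or per frame). ``normalization`` records the state:
    "raw", "global-mean" or "per-frame-mean".
    """

    x: np.ndarray
    t: np.ndarray
    intensity: np.ndarray
    dna_center: np.ndarray | None = None
    dna_half_extent: float | np.ndarray | None = None
    normalization: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.x), len(self.t)):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match "
                f"{len(self.x)} coordinates x {len(self.t)} frames"
            )
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.dna_center is not None:
            self.dna_center = np.asarray(self.dna_center, dtype=float)
            if self.dna_center.shape != self.t.shape:
                raise ValueError("DNA track must have one position per frame")

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def frame(self, j: int) -> np.ndarray:
        return self.intensity[:, j]

    def dna_track(self) -> Trajectory:
        if self.dna_center is None:
            raise ValueError("kymograph carries no DNA track")
        return Trajectory(self.t, self.dna_center)
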