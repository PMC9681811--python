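"""Core geometric containers: rectangular analysis windows and planar point patterns.

Coordinates and distances are in micrometres throughout.  Intensities are
stored internally in points/um^2; the user-facing unit is bundles/mm^2
(factor 1e6), matching how quantitative histology papers mix um spacings
with mm^-2 densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: conversion factor between points/um^2 and points/mm^2
UM2_PER_MM2 = 1e6


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular analysis window (um)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate window: need x_max > x_min and y_max > y_min, "
                f"got ({self.x_min}, {self.x_max}, {self.y_min}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        """Window area in um^2."""
        return self.width * self.height

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the (closed) window."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return (
            (xy[:, 0] >= self.x_min)
            & (xy[:, 0] <= self.x_max)
            & (xy[:, 1] >= self.y_min)
            & (xy[:, 1] <= self.y_max)
        )

    def boundary_distance(self, xy: np.ndarray) -> np.ndarray:
        """Distance from each point to the nearest window edge (um)."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return np.minimum.reduce(
            [
                xy[:, 0] - self.x_min,
                self.x_max - xy[:, 0],
                xy[:, 1] - self.y_min,
                self.y_max - xy[:, 1],
            ]
        )

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min,
            "x_max": self.x_max,
            "y_min": self.y_min,
            "y_max": self.y_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Window":
        return cls(
            x_min=float(d["x_min"]),
            x_max=float(d["x_max"]),
            y_min=float(d["y_min"]),
            y_max=float(d["y_max"]),
        )


@dataclass
class PointPattern:
    """A set of bundle-centre coordinates with its analysis window.

    The homogeneous intensity convention is always ``n / window area``;
    no fitted or adaptive intensity enters the regularity statistics.
    """

    points: np.ndarray
    window: Window
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if pts.size and not np.all(self.window.contains(pts)):
            n_out = int((~self.window.contains(pts)).sum())
            raise ValueError(f"{n_out} point(s) fall outside the declared window")

    @property
    def n(self) -> int:
        return int(self.points.shape[0])

    @property
    def intensity(self) -> float:
        """lambda = n / area, in points/um^2."""
        return self.n / self.window.area

    @property
    def intensity_per_mm2(self) -> float:
        """lambda in bundles/mm^2 (user-facing)."""
        return self.intensity * UM2_PER_MM2

    def nn_distances(self) -> np.ndarray:
        """Per-point nearest-neighbour distances (um)."""
        from scipy.spatial import cKDTree

        if self.n < 2:
            raise ValueError("nearest-neighbour distances need at least 2 points")
        d, _ = cKDTree(self.points).query(self.points, k=2)
        return d[:, 1]
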