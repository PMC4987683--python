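"""Filtering and geometry of segmented GFP point clouds.

Raw 3D segmentation emits one point per GFP-expressing cell cluster plus
clutter from the plate and the agar bed. Two spatial filters clean a frame:
a close-neighbor density filter (drop points with too few neighbors within
a Euclidean radius) and an axis-aligned bounding-box filter. The number of
points that survive filtering is the count reported throughout the
analysis. EB radius is estimated from the minimal enclosing (circumscribed)
circle of the 2D projection, and volume occupancy as count / radius³.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely import MultiPoint, minimum_bounding_radius

__all__ = [
    "PointCloudFrame",
    "FilterParams",
    "neighbor_filter",
    "bbox_filter",
    "count_points",
    "estimate_radius",
    "volume_occupancy",
]


@dataclass
class PointCloudFrame:
    """3D GFP point positions and intensities at one time point for one EB.

    ``points`` is an (n, 3) array of x, y, z in µm; ``intensities`` an (n,)
    array of non-negative arbitrary units.
    """

    time: float  # hours
    points: np.ndarray
    intensities: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.intensities is None:
            self.intensities = np.ones(len(self.points))
        self.intensities = np.asarray(self.intensities, dtype=float).reshape(-1)
        if len(self.intensities) != len(self.points):
            raise ValueError("points and intensities must have equal length")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.points)

    def take(self, mask: np.ndarray) -> "PointCloudFrame":
        return PointCloudFrame(self.time, self.points[mask], self.intensities[mask])


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the spatial clean-up filters.

    min_neighbors: minimum other points required within neighbor_radius.
    neighbor_radius: Euclidean search radius, µm.
    bounding_box: ((xmin, xmax), (ymin, ymax), (zmin, zmax)) in µm, optional.
    """

    min_neighbors: int = 5
    neighbor_radius: float = 40.0
    bounding_box: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.min_neighbors < 0:
            raise ValueError("min_neighbors must be >= 0")
        if self.neighbor_radius <= 0:
            raise ValueError("neighbor_radius must be positive")


def neighbor_filter(frame: PointCloudFrame, p: FilterParams) -> PointCloudFrame:
    """Close-neighbor density filter.

    Retains exactly the points with >= ``p.min_neighbors`` *other* points
    within ``p.neighbor_radius`` (Euclidean, the point itself excluded),
    judged in a single pass against the original cloud — the filter is not
    iterated to a fixpoint, so re-applying it to its own output can remove
    further points.
    """
    if len(frame) == 0 or p.min_neighbors == 0:
        return frame.take(np.ones(len(frame), dtype=bool))
    tree = cKDTree(frame.points)
    # query_ball_point counts the point itself, hence the +1
    counts = np.array([len(ix) for ix in tree.query_ball_point(frame.points, p.neighbor_radius)])
    return frame.take(counts - 1 >= p.min_neighbors)


def bbox_filter(
    frame: PointCloudFrame, box: tuple[tuple[float, float], ...]
) -> PointCloudFrame:
    """Axis-aligned bounding-box filter (closed box: faces are retained).

    Focuses on the area of interest and removes plate/agar clutter.
    """
    box = tuple(tuple(map(float, b)) for b in box)
    if len(box) != 3 or any(b[0] >= b[1] for b in box):
        raise ValueError("box must have positive extent on each of 3 axes")
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    mask = np.all((frame.points >= lo) & (frame.points <= hi), axis=1)
    return frame.take(mask)


def count_points(frame: PointCloudFrame) -> int:
    """Number of GFP points after filtering — the quantity tracked over time."""
    return len(frame)


def estimate_radius(points_2d: np.ndarray) -> float:
    """EB radius (µm) from the minimal enclosing circle of a 2D projection.

    Mirrors the circumscribed-circle radius measurement made on a
    phase-contrast image prior to reporter onset. A single point has
    radius 0.
    """
    pts = np.asarray(points_2d, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    if len(pts) == 1:
        return 0.0
    return float(minimum_bounding_radius(MultiPoint(pts)))


def volume_occupancy(count: float, radius: float) -> float:
    """GFP volume occupancy: segmentation point count / radius³ (µm⁻³).

    A proxy for the fraction of the EB volume expressing the reporter;
    doubling the radius at fixed count divides the ratio by 8.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    return count / radius**3
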