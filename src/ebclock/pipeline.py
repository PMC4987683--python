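"""End-to-end plumbing: clouds → counts → fits → clocks.

Thin composition of the module stages, used by examples and batch runs.
"""

from __future__ import annotations

import logging

import numpy as np

from .kinetics import DevClock, EBTimeSeries, NoSignalError, fit_impulse
from .pointcloud import FilterParams, PointCloudFrame, bbox_filter, count_points, neighbor_filter

__all__ = ["counts_from_clouds", "clocks_from_series"]

logger = logging.getLogger(__name__)


def counts_from_clouds(
    frames: list[PointCloudFrame],
    eb_id: str,
    filter_params: FilterParams | None = None,
    box: tuple[tuple[float, float], ...] | None = None,
) -> EBTimeSeries:
    """Filtered GFP point count per frame: bounding box, then density filter."""
    fp = filter_params or FilterParams()
    counts, times = [], []
    for f in frames:
        g = bbox_filter(f, box) if box is not None else f
        g = neighbor_filter(g, fp)
        times.append(f.time)
        counts.append(count_points(g))
    return EBTimeSeries(eb_id=eb_id, times=np.array(times), counts=np.array(counts, dtype=float))


def clocks_from_series(
    series: list[EBTimeSeries], threshold: float = 300.0
) -> list[DevClock]:
    """Fit every series and detect events; no-signal EBs are skipped (logged)."""
    clocks = []
    for s in series:
        try:
            clocks.append(fit_impulse(s, threshold=threshold))
        except NoSignalError:
            logger.info("EB %s below threshold: skipped", s.eb_id)
    return clocks
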