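"""Particle detection and frame-to-frame linking.

A functional stand-in for the bright-field tracking used to record XY
trajectories: threshold + connected components with intensity-weighted
centroids (scikit-image), then greedy nearest-neighbour linking with a
hard displacement gate and no gap closing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .imaging import FrameStack
from .params import Trajectory

__all__ = ["Detection", "detect", "link"]


@dataclass
class Detection:
    """One detected spot: frame index, centroid in um, summed intensity."""

    frame: int
    centroid: tuple[float, float]   # (x, y) um
    integrated_intensity: float


def detect(frame: FrameStack | np.ndarray, threshold: float,
           min_area: int = 1, pixel_size: float | None = None,
           frame_index: int = 0) -> list[Detection]:
    """Detect particles in a single plane.

    Connected components of pixels above ``threshold`` with area of at
    least ``min_area`` px; the centroid is intensity-weighted and
    converted to um. An empty list is a valid result.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(frame, FrameStack):
        img = frame.pixels[0]
        px = frame.pixel_size
    else:
        img = np.asarray(frame, dtype=float)
        px = pixel_size if pixel_size is not None else 1.0
    labels = measure.label(img > threshold)
    out: list[Detection] = []
    # centroid weights use threshold-subtracted intensity: weighting the
    # raw counts over a hard mask biases the centroid toward the mask's
    # pixel grid, subtracting the cut level removes most of that bias
    excess = np.clip(img - threshold, 0.0, None)
    for region, raw in zip(measure.regionprops(labels, intensity_image=excess),
                           measure.regionprops(labels, intensity_image=img)):
        if region.area < min_area:
            continue
        cy, cx = region.centroid_weighted
        out.append(Detection(frame=frame_index, centroid=(cx * px, cy * px),
                             integrated_intensity=float(raw.image_intensity.sum())))
    return out


def link(detections_per_frame: list[list[Detection]], max_disp: float,
         frame_interval: float = 0.2) -> list[Trajectory]:
    """Link detections across consecutive frames into trajectories.

    Greedy nearest-neighbour per frame pair: candidate links sorted by
    displacement (ties by lowest track id), accepted unless either end is
    taken or the displacement exceeds ``max_disp`` (um). Unmatched
    detections start new tracks; a track that finds no match terminates
    (no gap closing). Tracks shorter than 2 frames are dropped.
    """
    next_id = 0
    active: dict[int, tuple[int, tuple[float, float]]] = {}  # id -> (frame, xy)
    points: dict[int, list[tuple[int, float, float]]] = {}

    for f, dets in enumerate(detections_per_frame):
        prev = list(active.items())
        assigned_dets: set[int] = set()
        assigned_tracks: set[int] = set()
        if prev and dets:
            cands = []
            for tid, (pf, pxy) in prev:
                if pf != f - 1:
                    continue
                for j, det in enumerate(dets):
                    disp = float(np.hypot(det.centroid[0] - pxy[0],
                                          det.centroid[1] - pxy[1]))
                    if disp <= max_disp:
                        cands.append((disp, tid, j))
            for disp, tid, j in sorted(cands):
                if tid in assigned_tracks or j in assigned_dets:
                    continue
                assigned_tracks.add(tid)
                assigned_dets.add(j)
                det = dets[j]
                points[tid].append((f, *det.centroid))
                active[tid] = (f, det.centroid)
        # terminate unmatched tracks
        for tid in [t for t, (pf, _) in active.items()
                    if pf == f - 1 and t not in assigned_tracks]:
            del active[tid]
        # start new tracks from unmatched detections
        for j, det in enumerate(dets):
            if j in assigned_dets:
                continue
            points[next_id] = [(f, *det.centroid)]
            active[next_id] = (f, det.centroid)
            next_id += 1

    trajs = []
    for tid in sorted(points):
        pts = points[tid]
        if len(pts) < 2:
            continue
        frames = np.array([p[0] for p in pts], dtype=float)
        xy = np.array([[p[1], p[2]] for p in pts])
        trajs.append(Trajectory(particle_id=tid, times=frames * frame_interval,
                                xy=xy))
    return trajs
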