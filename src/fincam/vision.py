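"""Moving-object detection and tracking in chamber video.

Detection follows a gradient-contour chain: per-pixel temporal-median
background subtraction, gradient magnitude of the difference image
(3x3 central differences), hysteresis thresholding of the gradient,
morphological closing, hole filling, then connected-component analysis
with area gating.  Tracking links per-frame detections into one track
per passing fish with a constant-velocity nearest-neighbour data
association, distance gating, and a bounded frame-gap tolerance.

Each completed track is one counted fish passage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours, regionprops
from skimage.morphology import closing as _closing, disk


@dataclass(frozen=True)
class DetectionParams:
    """Tuning knobs of the detection chain.

    gradient_threshold is the high hysteresis threshold on the gradient
    magnitude of the background-subtracted image, in gray levels per
    pixel; the low threshold is half of it.  Components with area
    outside [min_area_px, max_area_px] are discarded (max_area_px None
    means one quarter of the frame).
    """

    gradient_threshold: float = 12.0
    min_area_px: int = 150
    max_area_px: int | None = None
    #: Gaussian pre-smoothing of the difference image (px); suppresses
    #: sensor-noise percolation through the low hysteresis threshold
    smooth_sigma: float = 1.0
    #: erosion applied after hole filling, compensating the outward half
    #: of the smoothed edge-gradient band so areas match the silhouette
    edge_erode_px: int = 2


@dataclass(frozen=True)
class TrackingParams:
    """Gating distance (px), tolerated missed frames, minimum length.

    The default gate corresponds to the fastest plausible transit:
    a fish crossing the full frame width in about half a second at
    60 fps moves ~ width/30 px per frame; 60 px covers that at native
    scale with margin at the scaled-down test geometry.
    """

    gating_px: float = 60.0
    max_gap_frames: int = 2
    min_track_length: int = 3


@dataclass
class Detection:
    frame_index: int
    contour: np.ndarray            # (N, 2) closed polygon, (row, col)
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1) half-open
    centroid: tuple[float, float]
    area_px: int
    mean_intensity: float
    mask: np.ndarray | None = None   # component mask cropped to bbox

    def to_json_dict(self) -> dict:
        return {
            "frame_index": self.frame_index,
            "bbox": list(self.bbox),
            "centroid": list(self.centroid),
            "area_px": int(self.area_px),
            "mean_intensity": float(self.mean_intensity),
            "contour": np.asarray(self.contour).tolist(),
        }


@dataclass
class Track:
    track_id: int
    detections: list[Detection] = field(default_factory=list)

    @property
    def first_frame(self) -> int:
        return self.detections[0].frame_index

    @property
    def last_frame(self) -> int:
        return self.detections[-1].frame_index

    def best_detection(self) -> Detection:
        """Largest-area detection: the least-clipped view of the fish."""
        return max(self.detections, key=lambda d: d.area_px)


def estimate_background(frames: np.ndarray, window: int = 31) -> np.ndarray:
    """Per-pixel temporal median over (up to) ``window`` frames.

    The median is robust to any object occupying a pixel in a minority
    of frames, so static pixels are reproduced exactly in noise-free
    input.  ``window`` must be odd and >= 3; if fewer frames than
    ``window`` are available all frames are used (with a warning).
    """
    frames = np.asarray(frames)
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if len(frames) < window:
        warnings.warn(
            f"only {len(frames)} frames for background window {window}; using all",
            stacklevel=2,
        )
        window = len(frames)
    # evenly spread sample of `window` frames across the sequence
    idx = np.linspace(0, len(frames) - 1, window).round().astype(int)
    return np.median(frames[idx].astype(float), axis=0)


def _component_to_detection(frame: np.ndarray, comp_mask: np.ndarray,
                            frame_index: int) -> Detection:
    prop = regionprops(comp_mask.astype(np.uint8), intensity_image=frame)[0]
    r0, c0, r1, c1 = prop.bbox
    # pad by 1 px so the iso-contour of the mask closes around the object
    padded = np.pad(comp_mask[r0:r1, c0:c1], 1).astype(float)
    contours = find_contours(padded, 0.5)
    contour = max(contours, key=len) + [r0 - 1, c0 - 1]
    return Detection(
        frame_index=frame_index,
        contour=contour,
        bbox=(r0, c0, r1, c1),
        centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
        area_px=int(prop.area),
        mean_intensity=float(prop.intensity_mean),
        mask=comp_mask[r0:r1, c0:c1].copy(),
    )


def detect_objects(frame: np.ndarray, background: np.ndarray,
                   params: DetectionParams = DetectionParams(),
                   frame_index: int = 0) -> list[Detection]:
    """Segment moving objects in one frame against a background model.

    Returns detections sorted by (centroid row, centroid col).
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {background.shape}"
        )
    diff = frame - background
    if params.smooth_sigma > 0:
        diff = ndimage.gaussian_filter(diff, params.smooth_sigma)
    gr, gc = np.gradient(diff)
    grad = np.hypot(gr, gc)

    high = params.gradient_threshold
    low = high / 2.0
    # hysteresis: keep low-threshold pixels connected to a high-threshold pixel
    low_mask = grad >= low
    lbl, _ = ndimage.label(low_mask, structure=np.ones((3, 3), dtype=int))
    keep = np.unique(lbl[grad >= high])
    edges = np.isin(lbl, keep[keep > 0])

    filled = ndimage.binary_fill_holes(_closing(edges, disk(2)))
    if params.edge_erode_px > 0:
        filled = ndimage.binary_erosion(filled, disk(params.edge_erode_px))

    max_area = params.max_area_px
    if max_area is None:
        max_area = frame.size // 4

    comp_lbl, n = ndimage.label(filled, structure=np.ones((3, 3), dtype=int))
    detections = []
    for i in range(1, n + 1):
        comp = comp_lbl == i
        area = int(comp.sum())
        if area < params.min_area_px or area > max_area:
            continue
        detections.append(_component_to_detection(frame, comp, frame_index))
    detections.sort(key=lambda d: d.centroid)
    return detections


def detect_sequence(frames: np.ndarray,
                    params: DetectionParams = DetectionParams(),
                    background: np.ndarray | None = None,
                    background_window: int = 31) -> list[list[Detection]]:
    """Run detection over every frame of a sequence."""
    frames = np.asarray(frames)
    if background is None:
        w = min(background_window, len(frames))
        if w % 2 == 0:
            w -= 1
        background = estimate_background(frames, max(w, 3))
    return [detect_objects(f, background, params, frame_index=i)
            for i, f in enumerate(frames)]


class _ActiveTrack:
    __slots__ = ("track", "velocity", "misses")

    def __init__(self, track: Track):
        self.track = track
        self.velocity = np.zeros(2)
        self.misses = 0

    def predict(self) -> np.ndarray:
        last = np.asarray(self.track.detections[-1].centroid)
        return last + self.velocity * (self.misses + 1)

    def update(self, det: Detection) -> None:
        prev = self.track.detections[-1]
        dt = det.frame_index - prev.frame_index
        self.velocity = (np.asarray(det.centroid) - np.asarray(prev.centroid)) / dt
        self.track.detections.append(det)
        self.misses = 0


def link_tracks(per_frame: list[list[Detection]],
                params: TrackingParams = TrackingParams()) -> list[Track]:
    """Associate per-frame detections into tracks.

    Greedy nearest-neighbour on the constant-velocity prediction, gated
    at ``gating_px``; ties broken by smallest predicted distance, then
    lowest track_id.  Tracks missing for more than ``max_gap_frames``
    are closed; tracks shorter than ``min_track_length`` are dropped.
    """
    active: list[_ActiveTrack] = []
    finished: list[Track] = []
    next_id = 0
    for dets in per_frame:
        # candidate (distance, track order, det order) associations
        pairs = []
        for ti, at in enumerate(active):
            pred = at.predict()
            for di, det in enumerate(dets):
                d = float(np.hypot(*(pred - np.asarray(det.centroid))))
                if d <= params.gating_px:
                    pairs.append((d, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for d, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            active[ti].update(dets[di])
            used_t.add(ti)
            used_d.add(di)
        # age out unmatched existing tracks, then open new ones
        still = []
        for ti, at in enumerate(active):
            if ti not in used_t:
                at.misses += 1
                if at.misses > params.max_gap_frames:
                    finished.append(at.track)
                    continue
            still.append(at)
        active = still
        for di, det in enumerate(dets):
            if di not in used_d:
                t = Track(track_id=next_id, detections=[det])
                next_id += 1
                active.append(_ActiveTrack(t))
    finished.extend(at.track for at in active)
    finished = [t for t in finished if len(t.detections) >= params.min_track_length]
    finished.sort(key=lambda t: t.track_id)
    for new_id, t in enumerate(finished):
        t.track_id = new_id
    return finished


def count_passages(tracks: list[Track]) -> int:
    """Number of counted fish: one completed track per passage."""
    return len(tracks)


# -- serialization ----------------------------------------------------------

SCHEMA_VERSION = 1


def write_tracks(path: str | Path, tracks: list[Track]) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "tracks": [
            {
                "track_id": t.track_id,
                "first_frame": t.first_frame,
                "last_frame": t.last_frame,
                "detections": [d.to_json_dict() for d in t.detections],
            }
            for t in tracks
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_tracks(path: str | Path) -> list[Track]:
    payload = json.loads(Path(path).read_text())
    tracks = []
    for t in payload["tracks"]:
        dets = [
            Detection(
                frame_index=d["frame_index"],
                contour=np.asarray(d["contour"]),
                bbox=tuple(d["bbox"]),
                centroid=tuple(d["centroid"]),
                area_px=d["area_px"],
                mean_intensity=d["mean_intensity"],
            )
            for d in t["detections"]
        ]
        tracks.append(Track(track_id=t["track_id"], detections=dets))
    return tracks
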