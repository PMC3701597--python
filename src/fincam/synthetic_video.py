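"""Ground-truthed synthetic underwater video of fish silhouettes.

This module emulates the imaging conditions of an open-codend viewing
chamber: a fixed grayscale camera watches a backlit chamber while fish
transit the field of view roughly along the tow axis.  Fish are rendered
as filled silhouettes (tapered elliptical body plus species-specific
fins), because in the real instrument the even backlighting reduces each
animal to a high-contrast silhouette in which fin detail — dorsal,
adipose, anal, caudal, or a trailing dorsal-fin thread — is the main
species cue.

Turbidity is modelled as a multiplicative loss of foreground/background
contrast, ``exp(-TURBIDITY_ATTENUATION * NTU)``, plus additive Gaussian
sensor noise whose standard deviation grows linearly in NTU.  The single
attenuation constant is calibrated so that detection recall on the
default species collapses below 50% near 80 NTU, the regime where the
real system degrades, while scenes at 30 NTU or below remain easy.

Coordinates are (row, col), 0-based, origin at the top-left; angles are
measured counter-clockwise from the column (+x) axis, in degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import polygon as _draw_polygon
from skimage.morphology import closing as _closing, disk

# -- imaging-chain constants ------------------------------------------------

#: native sensor geometry (rows, cols) and frame rate of the instrument
NATIVE_FRAME_SHAPE = (1200, 1600)
NATIVE_FRAME_RATE_HZ = 60.0

#: scaled-down default used throughout the test suite for speed
DEFAULT_TEST_FRAME_SHAPE = (300, 400)

#: contrast attenuation per NTU: contrast scales as exp(-c * NTU)
TURBIDITY_ATTENUATION = 0.04
#: additive Gaussian noise SD grows by this many gray levels per NTU
TURBIDITY_NOISE_SLOPE = 0.15

FIN_KINDS = ("dorsal", "adipose", "anal", "caudal", "thread")


@dataclass(frozen=True)
class SpeciesShapeSpec:
    """Parametric silhouette of one species.

    The body is a tapered ellipse of length ``body_length_px`` and depth
    ``body_length_px / body_aspect``; fins are attached at anchor
    positions along the body axis (0 = snout, 1 = tail) with an extent
    expressed as a fraction of the body depth.
    """

    name: str
    body_length_px: float
    body_aspect: float
    fin_profile: tuple[tuple[float, float, str], ...] = ()
    intensity: float = 200.0

    def __post_init__(self) -> None:
        if self.body_length_px <= 0:
            raise ValueError(f"body_length_px must be > 0, got {self.body_length_px}")
        if self.body_aspect <= 1:
            raise ValueError(f"body_aspect must be > 1, got {self.body_aspect}")
        anchors = [a for a, _, _ in self.fin_profile]
        if any(b <= a for a, b in zip(anchors, anchors[1:])):
            raise ValueError("fin anchors must be strictly increasing")
        for anchor, extent, kind in self.fin_profile:
            if not 0.0 <= anchor <= 1.0:
                raise ValueError(f"fin anchor {anchor} outside [0, 1]")
            if not 0.0 <= extent <= 0.5:
                raise ValueError(f"fin extent {extent} outside [0, 0.5]")
            if kind not in FIN_KINDS:
                raise ValueError(f"unknown fin kind {kind!r}")


def default_species() -> dict[str, SpeciesShapeSpec]:
    """Default species library: three look-alike estuarine pelagics.

    A slender smelt-like fish with an adipose fin, a deeper-bodied shad
    with the trailing dorsal-fin thread over the caudal peduncle, and a
    larger plain-finned shad.  Sizes are in chamber pixels at the test
    frame scale and were chosen for silhouette separability.
    """
    return {
        "delta_smelt": SpeciesShapeSpec(
            name="delta_smelt",
            body_length_px=60.0,
            body_aspect=4.6,
            fin_profile=(
                (0.42, 0.45, "dorsal"),
                (0.62, 0.38, "anal"),
                (0.78, 0.22, "adipose"),
                (0.97, 0.50, "caudal"),
            ),
        ),
        "threadfin_shad": SpeciesShapeSpec(
            name="threadfin_shad",
            body_length_px=55.0,
            body_aspect=2.7,
            fin_profile=(
                (0.45, 0.40, "dorsal"),
                (0.55, 0.20, "thread"),
                (0.70, 0.35, "anal"),
                (0.97, 0.45, "caudal"),
            ),
        ),
        "american_shad": SpeciesShapeSpec(
            name="american_shad",
            body_length_px=75.0,
            body_aspect=3.3,
            fin_profile=(
                (0.40, 0.35, "dorsal"),
                (0.72, 0.30, "anal"),
                (0.97, 0.48, "caudal"),
            ),
        ),
    }


@dataclass(frozen=True)
class FishEntry:
    """One fish in a scene: spec, entry frame, and straight-line motion."""

    spec: SpeciesShapeSpec
    entry_frame: int
    entry_point: tuple[float, float]      # (row, col) at entry_frame
    velocity: tuple[float, float]         # (d_row, d_col) px / frame
    orientation_deg: float = 0.0
    scale: float = 1.0


@dataclass(frozen=True)
class SceneSpec:
    frame_shape: tuple[int, int] = DEFAULT_TEST_FRAME_SHAPE
    frame_rate_hz: float = NATIVE_FRAME_RATE_HZ
    duration_s: float = 1.0
    fish: tuple[FishEntry, ...] = ()
    turbidity_ntu: float = 10.0
    noise_sd: float = 2.0
    background_level: float = 40.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


@dataclass
class TrackTruth:
    """Ground truth for one fish: where its mask actually landed."""

    fish_index: int
    species: str
    frames: list[int] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class GroundTruth:
    tracks: list[TrackTruth]
    species_totals: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "tracks": [
                    {
                        "fish_index": t.fish_index,
                        "species": t.species,
                        "frames": t.frames,
                        "centroids": t.centroids,
                    }
                    for t in self.tracks
                ],
                "species_totals": self.species_totals,
            },
            indent=2,
        )


# -- silhouette rendering ---------------------------------------------------

_N_BODY_SAMPLES = 64


def _body_outline(spec: SpeciesShapeSpec, scale: float) -> np.ndarray:
    """Closed polygon (x, y) of the finned silhouette, head at x=0, y up > 0.

    y here is mathematical (up positive); conversion to row/col happens in
    :func:`species_silhouette`.
    """
    length = spec.body_length_px * scale
    half_depth = length / spec.body_aspect / 2.0

    # tapered body: elliptical depth profile sharpened toward snout and tail
    s = np.linspace(0.0, 1.0, _N_BODY_SAMPLES)
    profile = half_depth * np.sqrt(np.clip(1.0 - (2 * s - 1) ** 2, 0.0, 1.0)) ** 0.85
    top = np.column_stack([s * length, profile])
    bottom = np.column_stack([s[::-1] * length, -profile[::-1]])
    body = np.vstack([top, bottom])

    fins: list[np.ndarray] = []
    for anchor, extent, kind in spec.fin_profile:
        x0 = anchor * length
        # body half-depth at the anchor
        d = half_depth * np.sqrt(max(1.0 - (2 * anchor - 1) ** 2, 0.0)) ** 0.85
        h = extent * 2 * half_depth
        fin_len = 0.12 * length
        if kind == "dorsal":
            fins.append(np.array([
                [x0 - fin_len / 2, d * 0.5], [x0 + fin_len / 2, d * 0.5],
                [x0 + fin_len * 0.3, d + h], [x0 - fin_len * 0.1, d + h * 0.8],
            ]))
        elif kind == "anal":
            fins.append(np.array([
                [x0 - fin_len / 2, -d * 0.5], [x0 + fin_len / 2, -d * 0.5],
                [x0 + fin_len * 0.2, -d - h],
            ]))
        elif kind == "adipose":
            fins.append(np.array([
                [x0 - fin_len / 3, d * 0.5], [x0 + fin_len / 3, d * 0.5],
                [x0, d + h],
            ]))
        elif kind == "caudal":
            # forked tail extending beyond the body
            tail_len = 0.18 * length
            fins.append(np.array([
                [x0 - fin_len / 2, 0.6 * d], [x0 + tail_len, h],
                [x0 + tail_len * 0.55, 0.0], [x0 + tail_len, -h],
                [x0 - fin_len / 2, -0.6 * d],
            ]))
        elif kind == "thread":
            # trailing filament from the rear of the dorsal fin back over
            # the caudal peduncle
            thread_len = 0.30 * length
            fins.append(np.array([
                [x0, d * 0.4], [x0 + thread_len, d + h * 2.2],
                [x0 + thread_len * 0.95, d + h * 2.2 - 1.5 * scale],
                [x0 + 0.02 * length, d * 0.2],
            ]))
    return body, fins


def species_silhouette(
    spec: SpeciesShapeSpec, orientation_deg: float = 0.0, scale: float = 1.0
) -> np.ndarray:
    """Rasterize one species silhouette as a binary mask.

    The mask is a single 8-connected component: the finned body polygon
    is rasterized and morphologically closed to bridge rasterization
    gaps at thin fin attachments.

    Parameters
    ----------
    spec : SpeciesShapeSpec
    orientation_deg : body-axis angle, CCW from the column axis.
    scale : linear scale factor, must be > 0.
    """
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    body, fins = _body_outline(spec, scale)

    theta = np.deg2rad(orientation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])

    polys = [body @ rot.T] + [f @ rot.T for f in fins]
    allpts = np.vstack(polys)
    # (x, y up) -> (row, col) with a margin; flip y
    xmin, ymin = allpts.min(axis=0)
    xmax, ymax = allpts.max(axis=0)
    margin = 3
    n_rows = int(np.ceil(ymax - ymin)) + 2 * margin
    n_cols = int(np.ceil(xmax - xmin)) + 2 * margin
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    for poly in polys:
        cols = poly[:, 0] - xmin + margin
        rows = (ymax - poly[:, 1]) + margin
        rr, cc = _draw_polygon(rows, cols, shape=mask.shape)
        mask[rr, cc] = True
    mask = _closing(mask, disk(2))
    if mask.sum() == 0:
        raise ValueError("degenerate spec: silhouette rasterized to zero area")
    return mask


# -- scene rendering --------------------------------------------------------

def effective_noise_sd(noise_sd: float, turbidity_ntu: float) -> float:
    return noise_sd + TURBIDITY_NOISE_SLOPE * turbidity_ntu


def contrast_factor(turbidity_ntu: float) -> float:
    return float(np.exp(-TURBIDITY_ATTENUATION * turbidity_ntu))


def render_scene(scene: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene to frames plus exact ground truth.

    Returns
    -------
    frames : uint8 array (n_frames, rows, cols)
    truth : GroundTruth with one track per fish, listing the frames in
        which the fish mask intersects the frame and the realized mask
        centroid in each.
    """
    rng = np.random.default_rng(scene.seed)
    n_frames = scene.n_frames
    shape = tuple(scene.frame_shape)
    atten = contrast_factor(scene.turbidity_ntu)
    sd = effective_noise_sd(scene.noise_sd, scene.turbidity_ntu)

    base = np.full(shape, float(scene.background_level))
    frames = np.empty((n_frames,) + shape, dtype=np.uint8)
    tracks = [
        TrackTruth(fish_index=i, species=entry.spec.name)
        for i, entry in enumerate(scene.fish)
    ]
    # one rasterization per fish (constant orientation/scale along the path)
    masks = [
        species_silhouette(e.spec, e.orientation_deg, e.scale) for e in scene.fish
    ]
    mask_offsets = []
    for m in masks:
        r, c = np.nonzero(m)
        mask_offsets.append((r - r.mean(), c - c.mean()))

    for f in range(n_frames):
        img = base.copy()
        for i, entry in enumerate(scene.fish):
            dt = f - entry.entry_frame
            if dt < 0:
                continue
            cr = entry.entry_point[0] + entry.velocity[0] * dt
            cc = entry.entry_point[1] + entry.velocity[1] * dt
            rr = np.round(mask_offsets[i][0] + cr).astype(int)
            ccx = np.round(mask_offsets[i][1] + cc).astype(int)
            keep = (rr >= 0) & (rr < shape[0]) & (ccx >= 0) & (ccx < shape[1])
            if not keep.any():
                continue
            rr, ccx = rr[keep], ccx[keep]
            fg = scene.background_level + (entry.spec.intensity - scene.background_level) * atten
            img[rr, ccx] = fg
            tracks[i].frames.append(f)
            tracks[i].centroids.append((float(rr.mean()), float(ccx.mean())))
        if sd > 0:
            img = img + rng.normal(0.0, sd, size=shape)
        frames[f] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    totals: dict[str, int] = {}
    for entry in scene.fish:
        totals[entry.spec.name] = totals.get(entry.spec.name, 0) + 1
    return frames, GroundTruth(tracks=tracks, species_totals=totals)


# -- disk format ------------------------------------------------------------

def write_scene(out_dir: str | Path, frames: np.ndarray, truth: GroundTruth,
                scene: SceneSpec) -> None:
    """Write frames as zero-padded PNGs plus JSON sidecar and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(len(frames))))
    for i, frame in enumerate(frames):
        iio.imwrite(out / f"frame_{i:0{width}d}.png", frame)
    sidecar = {
        "frame_rate_hz": scene.frame_rate_hz,
        "frame_shape": list(scene.frame_shape),
        "n_frames": int(len(frames)),
        "seed": scene.seed,
        "turbidity_ntu": scene.turbidity_ntu,
    }
    (out / "scene.json").write_text(json.dumps(sidecar, indent=2))
    (out / "ground_truth.json").write_text(truth.to_json())


def read_scene(in_dir: str | Path) -> tuple[np.ndarray, dict]:
    """Read a frame directory written by :func:`write_scene`."""
    src = Path(in_dir)
    sidecar = json.loads((src / "scene.json").read_text())
    paths = sorted(src.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {src}")
    frames = np.stack([iio.imread(p) for p in paths])
    return frames, sidecar
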