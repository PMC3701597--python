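"""Silhouette shape descriptors for species identification.

The feature vector per detected object comprises: object size (pixel
area), the seven Hu invariant moments (log-magnitude transformed with
sign preserved), the aspect ratio of the inertia-equivalent ellipse,
the defect from a pure ellipse, the RMS deviation from each normalized
species template image, and a radial local pattern — the centroid-to-
boundary radius profile sampled at B angles from the major axis and
normalized by the mean radius, which is a standard rotation- and
scale-normalized outline signature.

All descriptors are translation-invariant by construction; Hu moments,
aspect ratio, ellipse defect and the radial pattern are additionally
rotation- and scale-invariant up to rasterization error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.measure import moments_central, moments_hu, moments_normalized
from skimage.transform import rotate as _rotate_image, resize as _resize

#: floor inside the log transform of Hu magnitudes
HU_LOG_EPS = 1e-30
#: normalized template frame (rows, cols); major axis horizontal
TEMPLATE_SHAPE = (64, 128)
#: number of radial-pattern samples
DEFAULT_RADIAL_BINS = 32


@dataclass
class SpeciesTemplate:
    """A normalized reference silhouette image for one species.

    ``image`` has shape :data:`TEMPLATE_SHAPE`, major axis horizontal,
    head to the left, and is intensity-normalized to zero mean and unit
    variance over the template frame.
    """

    species: str
    image: np.ndarray

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.shape != TEMPLATE_SHAPE:
            raise ValueError(
                f"template shape {self.image.shape} != {TEMPLATE_SHAPE}"
            )


@dataclass
class FeatureVector:
    area_px: float
    hu: np.ndarray                  # 7 values
    aspect_ratio: float
    ellipse_defect: float
    template_rms: dict[str, float]
    radial_pattern: np.ndarray      # B values

    def to_array(self, template_order: list[str] | None = None) -> np.ndarray:
        if template_order is None:
            template_order = sorted(self.template_rms)
        return np.concatenate([
            [self.area_px], self.hu, [self.aspect_ratio, self.ellipse_defect],
            [self.template_rms[s] for s in template_order],
            self.radial_pattern,
        ])

    @staticmethod
    def column_names(template_order: list[str],
                     n_radial: int = DEFAULT_RADIAL_BINS) -> list[str]:
        return (
            ["area_px"] + [f"hu{i + 1}" for i in range(7)]
            + ["aspect_ratio", "ellipse_defect"]
            + [f"rms_{s}" for s in template_order]
            + [f"radial_{i:02d}" for i in range(n_radial)]
        )


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    return mask


def _second_moments(mask: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """Centroid and second central moments (per-area) of a binary mask."""
    r, c = np.nonzero(mask)
    n = r.size
    rbar, cbar = r.mean(), c.mean()
    mrr = ((r - rbar) ** 2).mean()
    mcc = ((c - cbar) ** 2).mean()
    mrc = ((r - rbar) * (c - cbar)).mean()
    return np.array([rbar, cbar]), mrr, mcc, mrc


def _axes_and_orientation(mask: np.ndarray):
    """Eigen-structure of the second-moment tensor.

    Returns (centroid, semi-major SD, semi-minor SD, orientation) where
    orientation is the CCW angle of the major axis from the column axis
    in radians.
    """
    cen, mrr, mcc, mrc = _second_moments(mask)
    cov = np.array([[mcc, -mrc], [-mrc, mrr]])  # in (x=col, y=-row) frame
    evals, evecs = np.linalg.eigh(cov)
    # eigh sorts ascending: [minor, major]
    lam_minor, lam_major = evals
    vx, vy = evecs[:, 1]
    theta = np.arctan2(vy, vx)
    return cen, np.sqrt(max(lam_major, 1e-12)), np.sqrt(max(lam_minor, 1e-12)), theta


def hu_moments(mask: np.ndarray) -> np.ndarray:
    """Seven Hu invariants of a binary mask, sign-preserving log scale.

    Each invariant h is reported as sign(h) * log10(|h| + eps) to tame
    the dynamic range across orders while keeping the sign, which
    carries chirality information in the seventh invariant.

    Accepts a binary mask or a non-negative weighted (e.g. anti-aliased)
    mask; the weights enter the moments directly.
    """
    return np.sign(h := raw_hu_moments(mask)) * np.log10(np.abs(h) + HU_LOG_EPS)


def raw_hu_moments(mask: np.ndarray) -> np.ndarray:
    """Untransformed Hu invariants (useful for analytic checks)."""
    arr = np.asarray(mask, dtype=float)
    if arr.sum() <= 0:
        raise ValueError("empty mask")
    return moments_hu(moments_normalized(moments_central(arr)))


def aspect_ratio(mask: np.ndarray) -> float:
    """Major/minor axis ratio of the inertia-equivalent ellipse, >= 1."""
    mask = _check_mask(mask)
    r, c = np.nonzero(mask)
    if np.ptp(r) < 1 or np.ptp(c) < 1:
        raise ValueError("degenerate mask: need >= 2 px extent in both axes")
    _, sd_major, sd_minor, _ = _axes_and_orientation(mask)
    if sd_minor <= 1e-6:
        raise ValueError("degenerate mask: zero minor axis")
    return float(sd_major / sd_minor)


def _ellipse_mask(shape: tuple[int, int], centroid: np.ndarray, a: float,
                  b: float, theta: float) -> np.ndarray:
    """Pixel-center rasterization of an ellipse (semi-axes a >= b)."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    x = cc - centroid[1]
    y = -(rr - centroid[0])       # mathematical y up
    u = x * np.cos(theta) + y * np.sin(theta)
    v = -x * np.sin(theta) + y * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def fitted_ellipse_mask(mask: np.ndarray) -> np.ndarray:
    """Moment-fitted ellipse: same centroid, orientation, axis ratio, area."""
    mask = _check_mask(mask)
    cen, sd_major, sd_minor, theta = _axes_and_orientation(mask)
    a0, b0 = 2.0 * sd_major, 2.0 * sd_minor
    area = mask.sum()
    s = np.sqrt(area / (np.pi * a0 * b0))
    return _ellipse_mask(mask.shape, cen, a0 * s, b0 * s, theta)


def ellipse_defect(mask: np.ndarray) -> float:
    """Symmetric-difference area with the fitted ellipse, per mask area.

    0 for a perfect (rasterized) ellipse; in [0, 2] since the fitted
    ellipse has the same area as the mask.
    """
    mask = _check_mask(mask)
    ell = fitted_ellipse_mask(mask)
    return float(np.logical_xor(mask, ell).sum() / mask.sum())


# -- template normalization -------------------------------------------------

def normalize_object(image: np.ndarray, mask: np.ndarray,
                     shape: tuple[int, int] = TEMPLATE_SHAPE,
                     orient: bool = True) -> np.ndarray:
    """Bring an object to the canonical template frame.

    Rotates the major axis horizontal, flips so the heavier (head) end —
    by the sign of the third moment along the major axis — lies to the
    left, crops to the mask bounding box with a small margin, resamples
    to ``shape`` and normalizes to zero mean, unit variance over the
    frame.  Raises on zero-variance (degenerate) input.
    """
    mask = _check_mask(mask)
    image = np.asarray(image, dtype=float)
    obj = np.where(mask, image, 0.0)

    # crop to the mask bbox first so the result depends only on the
    # object content, never on its position in the frame
    r, c = np.nonzero(mask)
    sl = (slice(r.min(), r.max() + 1), slice(c.min(), c.max() + 1))
    obj_c = np.pad(obj[sl], 2)
    mask_c = np.pad(mask[sl], 2)

    if orient:
        _, _, _, theta = _axes_and_orientation(mask_c)
        deg = np.rad2deg(theta)
        obj_c = _rotate_image(obj_c, -deg, resize=True, order=1,
                              preserve_range=True)
        mask_r = _rotate_image(mask_c.astype(float), -deg, resize=True,
                               order=0, preserve_range=True) > 0.5
        r, c = np.nonzero(mask_r)
        if r.size == 0:
            raise ValueError("mask vanished during normalization")
        sl = (slice(r.min(), r.max() + 1), slice(c.min(), c.max() + 1))
        obj_c, mask_c = obj_c[sl], mask_r[sl]

    # head-left: put the long/heavy end (negative column skewness) left;
    # the residual near-zero-skew ambiguity is resolved against the
    # template by the flip search in template_rms
    cc = np.nonzero(mask_c)[1].astype(float)
    skew = ((cc - cc.mean()) ** 3).mean()
    if skew < 0:
        obj_c = obj_c[:, ::-1]

    out = _resize(obj_c, shape, order=1, preserve_range=True, anti_aliasing=True)
    sd = out.std()
    if sd < 1e-9:
        raise ValueError("degenerate normalization: zero variance")
    return (out - out.mean()) / sd


def normalized_rms(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square difference of two normalized template frames."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def template_rms(image: np.ndarray, mask: np.ndarray,
                 template: SpeciesTemplate) -> float:
    """RMS deviation of an object from a normalized species template.

    The object is normalized exactly as templates are; the residual
    mirror ambiguities (left/right from near-zero skew, up/down from
    the 180-degree major-axis ambiguity) are resolved by taking the
    reflection with the smallest RMS.
    """
    norm = normalize_object(image, mask)
    return min(
        normalized_rms(norm, template.image),
        normalized_rms(norm[:, ::-1], template.image),
        normalized_rms(norm[::-1, :], template.image),
        normalized_rms(norm[::-1, ::-1], template.image),
    )


def make_template(species: str, image: np.ndarray,
                  mask: np.ndarray) -> SpeciesTemplate:
    """Build a SpeciesTemplate from a reference object image + mask."""
    return SpeciesTemplate(species=species, image=normalize_object(image, mask))


# -- radial pattern ---------------------------------------------------------

def radial_pattern(mask: np.ndarray, n_bins: int = DEFAULT_RADIAL_BINS) -> np.ndarray:
    """Centroid-to-boundary radius profile, sampled at ``n_bins`` angles.

    Angles start at the major-axis orientation and advance CCW; radii
    are found by ray-marching from the centroid and are divided by the
    mean radius, giving scale invariance and rotation invariance up to
    the major-axis alignment (and its 180-degree ambiguity).
    """
    if n_bins < 8:
        raise ValueError(f"n_bins must be >= 8, got {n_bins}")
    mask = _check_mask(mask)
    cen, _, _, theta = _axes_and_orientation(mask)
    r_max = float(np.hypot(*mask.shape)) + 2.0
    step = 0.25
    n_steps = int(r_max / step)
    t = (np.arange(n_steps) + 1) * step
    radii = np.empty(n_bins)
    maskf = mask.astype(float)
    for k in range(n_bins):
        ang = theta + 2 * np.pi * k / n_bins
        # mathematical angle: +x = +col, +y = -row
        rr = cen[0] - t * np.sin(ang)
        cc = cen[1] + t * np.cos(ang)
        # bilinear sampling keeps the boundary estimate sub-pixel accurate
        vals = ndimage.map_coordinates(maskf, np.vstack([rr, cc]), order=1,
                                       mode="constant", cval=0.0)
        hit = vals >= 0.5
        radii[k] = t[np.nonzero(hit)[0][-1]] if hit.any() else 0.0
    mean_r = radii.mean()
    if mean_r <= 0:
        raise ValueError("degenerate mask: zero mean radius")
    return radii / mean_r


# -- assembly ---------------------------------------------------------------

def feature_vector(image: np.ndarray, mask: np.ndarray,
                   templates: list[SpeciesTemplate],
                   n_radial: int = DEFAULT_RADIAL_BINS) -> FeatureVector:
    """Assemble the full shape descriptor for one object."""
    if not templates:
        raise ValueError("at least one species template is required")
    mask = _check_mask(mask)
    return FeatureVector(
        area_px=float(mask.sum()),
        hu=hu_moments(mask),
        aspect_ratio=aspect_ratio(mask),
        ellipse_defect=ellipse_defect(mask),
        template_rms={t.species: template_rms(image, mask, t) for t in templates},
        radial_pattern=radial_pattern(mask, n_radial),
    )


# -- template persistence ---------------------------------------------------

def write_templates(out_dir: str | Path, templates: list[SpeciesTemplate]) -> None:
    """Store templates as 16-bit PNGs plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for t in templates:
        lo, hi = t.image.min(), t.image.max()
        scaled = np.round((t.image - lo) / (hi - lo) * 65535).astype(np.uint16)
        fname = f"template_{t.species}.png"
        iio.imwrite(out / fname, scaled)
        manifest.append({"species": t.species, "file": fname,
                         "min": float(lo), "max": float(hi)})
    (out / "templates.json").write_text(json.dumps(manifest, indent=2))


def read_templates(in_dir: str | Path) -> list[SpeciesTemplate]:
    src = Path(in_dir)
    manifest = json.loads((src / "templates.json").read_text())
    out = []
    for item in manifest:
        scaled = iio.imread(src / item["file"]).astype(float) / 65535.0
        image = scaled * (item["max"] - item["min"]) + item["min"]
        out.append(SpeciesTemplate(species=item["species"], image=image))
    return out
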