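"""Synthetic angiogram phantoms with exact ground truth.

The generator emulates what makes angiography frames hard to binarize
globally: dark curvilinear vessels of slowly varying width on a brighter
background, a smooth low-order illumination gradient, additive sensor
noise, and disconnected dark distractors (catheter/guidewire-like thin
curves and blobs standing in for assistive devices).  It does not attempt
physically realistic X-ray projection, contrast-agent dynamics, or
temporal cine sequences — results on phantoms demonstrate algorithmic
behaviour (noise ordering, tracing, pruning, diameter recovery), not
clinical performance.

Vessels are rendered by stamping disks of radius width/2 (strict interior)
along a smooth centreline, so the perpendicular chord width of the truth
mask matches the requested width profile within one pixel and ground truth
is exact (no anti-aliasing).  All randomness flows from the spec's seed;
outputs are integer rasters, hence bit-identical across runs and platforms.

The module also provides simple deterministic geometric masks (bars, jagged
bars, U-shapes) used to probe cover selection and diameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .diameter import DiameterProfile

__all__ = [
    "VesselSpec",
    "PhantomSpec",
    "PhantomTruth",
    "SegmentationScores",
    "generate_phantom",
    "evaluate_segmentation",
    "evaluate_diameter_recovery",
    "bar_mask",
    "diagonal_bar_mask",
    "jagged_bar_mask",
    "u_mask",
    "render_mask",
]


@dataclass(frozen=True)
class VesselSpec:
    """One vessel: a bounded-curvature random-walk centreline with a smooth
    width profile and an optional stenosis (fractional width reduction)."""

    start: tuple[float, float]
    heading: float = 0.0  # radians; 0 points straight down (+row)
    length: int = 600  # centreline steps (1 px each)
    base_width: float = 11.0
    width_wobble: float = 2.0
    wobble_period: float = 150.0
    stenosis: tuple[float, float] | None = None  # (location fraction, severity)
    stenosis_sigma: float = 20.0  # arc-length scale of the narrowing, px
    curvature_sd: float = 0.03  # heading increment sd per step, radians


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one phantom frame.

    With ``vessels=None``, ``n_vessels`` random vessels are drawn from the
    seed: starting near the top border, heading downward with bounded
    curvature.  Distractors are rendered dark but never enter the truth
    mask, and are kept disconnected from the vessels.
    """

    image_size: int = 512
    n_vessels: int = 1
    vessels: tuple[VesselSpec, ...] | None = None
    vessel_intensity: float = 70.0
    background_intensity: float = 190.0
    illumination_amplitude: float = 30.0
    noise_sd: float = 8.0
    n_blob_distractors: int = 3
    blob_radius_range: tuple[float, float] = (3.0, 10.0)
    n_wire_distractors: int = 1
    seed: int = 0


class PhantomTruth(NamedTuple):
    """Exact ground truth: vessel mask, per-vessel centrelines and widths."""

    mask: np.ndarray
    centerlines: tuple[np.ndarray, ...]  # each (N, 2) float (row, col)
    widths: tuple[np.ndarray, ...]  # each (N,) float, px


class SegmentationScores(NamedTuple):
    precision: float
    recall: float
    false_positives: int


def _vessel_path(vs: VesselSpec, shape: tuple[int, int], rng: np.random.Generator):
    """Centreline points and width profile; stops at the frame border."""
    pts = []
    r, c = vs.start
    theta = vs.heading
    for _ in range(vs.length):
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            break
        pts.append((r, c))
        r += math.cos(theta)
        c += math.sin(theta)
        if vs.curvature_sd > 0:
            theta += rng.normal(0.0, vs.curvature_sd)
    pts = np.asarray(pts, dtype=float)
    s = np.arange(len(pts), dtype=float)
    widths = vs.base_width + vs.width_wobble * np.sin(
        2.0 * math.pi * s / vs.wobble_period
    )
    if vs.stenosis is not None:
        loc_frac, severity = vs.stenosis
        s0 = loc_frac * (len(pts) - 1)
        widths = widths * (
            1.0 - severity * np.exp(-((s - s0) ** 2) / (2.0 * vs.stenosis_sigma**2))
        )
    if len(widths) and widths.min() < 3.0:
        raise ValueError(
            f"width profile drops to {widths.min():.2f} px; minimum is 3 px"
        )
    return pts, widths


def _stamp_centerline(
    mask: np.ndarray, points: np.ndarray, widths: np.ndarray
) -> None:
    """Stamp disks of radius width/2 (strict) along a centreline, in place."""
    h, w = mask.shape
    for (r, c), width in zip(points, widths):
        half = width / 2.0
        r0, r1 = max(0, math.ceil(r - half)), min(h - 1, math.floor(r + half))
        c0, c1 = max(0, math.ceil(c - half)), min(w - 1, math.floor(c + half))
        if r1 < r0 or c1 < c0:
            continue
        rr = np.arange(r0, r1 + 1, dtype=float)[:, None] - r
        cc = np.arange(c0, c1 + 1, dtype=float)[None, :] - c
        mask[r0 : r1 + 1, c0 : c1 + 1] |= rr * rr + cc * cc < half * half


def _random_vessel_paths(spec: PhantomSpec, rng: np.random.Generator):
    """Paths of ``n_vessels`` random vessels, each spanning a good part of
    the frame (short walks that wander out of the image early are redrawn,
    mirroring how a main coronary branch crosses most of an angiograph)."""
    size = spec.image_size
    out = []
    for _ in range(spec.n_vessels):
        for _attempt in range(50):
            vs = VesselSpec(
                start=(2.0, float(rng.uniform(0.2, 0.8) * size)),
                heading=float(rng.normal(0.0, 0.25)),
                length=int(1.5 * size),
                base_width=float(rng.uniform(9.0, 15.0)),
                width_wobble=2.0,
                curvature_sd=0.03,
            )
            pts, widths = _vessel_path(vs, (size, size), rng)
            if len(pts) >= 0.7 * size:
                out.append((pts, widths))
                break
    return out


def _illumination(size: int, amplitude: float, rng: np.random.Generator):
    """Smooth low-order polynomial shading field in [-amplitude, amplitude]."""
    y, x = np.mgrid[0:size, 0:size].astype(float)
    y = 2.0 * y / (size - 1) - 1.0
    x = 2.0 * x / (size - 1) - 1.0
    coef = rng.uniform(-1.0, 1.0, size=5)
    f = coef[0] * x + coef[1] * y + coef[2] * x * y + coef[3] * x * x + coef[4] * y * y
    peak = np.abs(f).max()
    return amplitude * f / peak if peak > 0 else f


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render a phantom frame and its exact ground truth.

    Deterministic given ``spec.seed``.  Raises ``ValueError`` if any vessel's
    width profile drops below 3 px.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    if spec.vessels is not None:
        paths = []
        for vs in spec.vessels:
            pts, widths = _vessel_path(vs, (size, size), rng)
            if len(pts):
                paths.append((pts, widths))
    else:
        paths = _random_vessel_paths(spec, rng)

    mask = np.zeros((size, size), dtype=bool)
    centerlines, width_profiles = [], []
    for pts, widths in paths:
        _stamp_centerline(mask, pts, widths)
        centerlines.append(pts)
        width_profiles.append(widths)

    field_img = spec.background_intensity + _illumination(
        size, spec.illumination_amplitude, rng
    )
    field_img[mask] = spec.vessel_intensity

    # distance to the nearest vessel pixel, for keeping distractors detached
    clearance = (
        ndi.distance_transform_edt(~mask) if mask.any()
        else np.full((size, size), np.inf)
    )

    for _ in range(spec.n_blob_distractors):
        radius = rng.uniform(*spec.blob_radius_range)
        for _attempt in range(100):
            r = rng.uniform(radius + 2, size - radius - 2)
            c = rng.uniform(radius + 2, size - radius - 2)
            if clearance[int(r), int(c)] > radius + 4:
                blob = np.zeros_like(mask)
                _stamp_centerline(blob, np.array([[r, c]]), np.array([2 * radius]))
                blob &= clearance > 2
                field_img[blob] = spec.vessel_intensity + rng.uniform(-10, 10)
                break

    for _ in range(spec.n_wire_distractors):
        r = rng.uniform(0.1, 0.9) * size
        c = rng.uniform(0.1, 0.9) * size
        theta = rng.uniform(0, 2 * math.pi)
        wire_pts = []
        for _step in range(int(0.25 * size)):
            if not (0 <= r < size and 0 <= c < size):
                break
            if clearance[int(r), int(c)] > 4:
                wire_pts.append((r, c))
            r += math.cos(theta)
            c += math.sin(theta)
            theta += rng.normal(0.0, 0.05)
        if wire_pts:
            wire = np.zeros_like(mask)
            _stamp_centerline(
                wire, np.asarray(wire_pts), np.full(len(wire_pts), 2.5)
            )
            wire &= clearance > 2
            field_img[wire] = spec.vessel_intensity + 15.0

    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, field_img.shape)
        np.clip(noise, -3 * spec.noise_sd, 3 * spec.noise_sd, out=noise)
        field_img = field_img + noise

    img = np.clip(np.rint(field_img), 0, 255).astype(np.uint8)
    truth = PhantomTruth(
        mask=mask,
        centerlines=tuple(centerlines),
        widths=tuple(width_profiles),
    )
    return img, truth


# ---------------------------------------------------------------------------
# recovery metrics


def evaluate_segmentation(pred: np.ndarray, truth: PhantomTruth) -> SegmentationScores:
    """Pixel-set precision/recall of a predicted mask against ground truth.

    Conventions for empty sets: precision is 1 when nothing was predicted
    (no false positives); recall is 1 when there is nothing to find.
    """
    pred = np.asarray(pred, dtype=bool)
    if pred.shape != truth.mask.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.mask.shape}"
        )
    tp = int((pred & truth.mask).sum())
    fp = int((pred & ~truth.mask).sum())
    fn = int((~pred & truth.mask).sum())
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return SegmentationScores(precision=precision, recall=recall, false_positives=fp)


def evaluate_diameter_recovery(
    profile: DiameterProfile, truth: PhantomTruth
) -> tuple[float, float]:
    """(bias, rmse) of profile diameters against the nearest true widths.

    Each profile sample's midpoint is matched to the nearest ground-truth
    centreline point; the error is estimate minus true width there.
    """
    if len(profile) == 0:
        raise ValueError("empty diameter profile")
    if not truth.centerlines:
        raise ValueError("phantom truth has no centreline")
    all_pts = np.vstack(truth.centerlines)
    all_widths = np.concatenate(truth.widths)
    tree = cKDTree(all_pts)
    _, idx = tree.query(np.asarray(profile.positions))
    err = np.asarray(profile.diameters) - all_widths[idx]
    return float(err.mean()), float(np.sqrt((err**2).mean()))


# ---------------------------------------------------------------------------
# deterministic geometric masks for probing cover behaviour


def bar_mask(
    shape: tuple[int, int],
    width: int,
    orientation: str = "vertical",
    length: int | None = None,
    offset: tuple[int, int] = (2, 2),
) -> np.ndarray:
    """An exact axis-aligned rectangle of vessel pixels.

    ``vertical`` bars are *width* columns wide; ``horizontal`` bars are
    *width* rows tall.
    """
    mask = np.zeros(shape, dtype=bool)
    r0, c0 = offset
    if orientation == "vertical":
        length = length if length is not None else shape[0] - 2 * r0
        mask[r0 : r0 + length, c0 : c0 + width] = True
    elif orientation == "horizontal":
        length = length if length is not None else shape[1] - 2 * c0
        mask[r0 : r0 + width, c0 : c0 + length] = True
    else:
        raise ValueError("orientation must be 'vertical' or 'horizontal'")
    return mask


def diagonal_bar_mask(
    shape: tuple[int, int], width: float, margin: int = 4
) -> np.ndarray:
    """A 45-degree bar of perpendicular width *width* along the anti-diagonal
    (running down-left), rendered by centreline stamping so the width is
    Euclidean.  Its perpendicular chord direction (down-right) belongs to
    the five-direction cover set."""
    mask = np.zeros(shape, dtype=bool)
    # centreline along r + c = k, run past the borders so the bar is clipped
    # by the frame (a vessel crossing the field of view) rather than capped
    # by rounded tips, and crossing top and left borders away from a frame
    # corner so no chord is truncated by the frame
    k = int(0.8 * min(shape))
    t = np.arange(-int(width), k + int(width), dtype=float)
    pts = np.stack([t, k - t], axis=1)
    _stamp_centerline(mask, pts, np.full(len(t), float(width)))
    return mask


def jagged_bar_mask(
    shape: tuple[int, int],
    width: int = 9,
    edge_amplitude: int = 1,
    seed: int = 0,
    offset: tuple[int, int] = (4, 10),
    length: int | None = None,
    correlation: float = 1.5,
) -> np.ndarray:
    """A vertical bar with +/- ``edge_amplitude`` jitter on both flanks,
    emulating the jagged outline produced by binarization.

    The jitter is spatially correlated (Gaussian-smoothed noise, scale
    ``correlation`` rows) because binarization jitter rides on a smooth
    underlying vessel edge; per-row independent noise would model a rougher
    boundary than thresholding ever produces.
    """
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    r0, c0 = offset
    length = length if length is not None else shape[0] - 2 * r0
    amp = edge_amplitude
    left = np.rint(
        ndi.gaussian_filter1d(rng.normal(0.0, 1.8 * amp, length), correlation)
    ).astype(int).clip(-amp, amp)
    right = np.rint(
        ndi.gaussian_filter1d(rng.normal(0.0, 1.8 * amp, length), correlation)
    ).astype(int).clip(-amp, amp)
    for k in range(length):
        mask[r0 + k, c0 + left[k] : c0 + width + right[k]] = True
    return mask


def u_mask(shape: tuple[int, int], width: float = 9.0, margin: int = 8) -> np.ndarray:
    """A U-shaped vessel: two vertical arms entering at the top frame border,
    joined by a curved bottom — the geometry where a downward/rightward-only
    cover set fails at the bend.  The arms reach the border (as vessels enter
    a real frame) rather than ending in rounded caps."""
    h, w = shape
    radius = (w - 2 * margin - width) / 2.0
    cx = w / 2.0
    bottom = h - margin - width / 2.0 - radius
    pts = []
    # left arm down from the top border
    for r in np.arange(0.0, bottom, 1.0):
        pts.append((r, cx - radius))
    # semicircular bottom, left to right
    for ang in np.linspace(math.pi, 0.0, int(math.pi * radius)):
        pts.append((bottom + radius * math.sin(ang), cx - radius * math.cos(ang)))
    # right arm up to the top border
    for r in np.arange(bottom, -1.0, -1.0):
        pts.append((r, cx + radius))
    mask = np.zeros(shape, dtype=bool)
    pts = np.asarray(pts)
    _stamp_centerline(mask, pts, np.full(len(pts), float(width)))
    return mask


def render_mask(
    mask: np.ndarray,
    vessel_intensity: float = 60.0,
    background_intensity: float = 200.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Turn a binary mask into a flat two-tone grayscale frame (optionally
    with clipped additive noise)."""
    img = np.full(mask.shape, background_intensity, dtype=float)
    img[mask] = vessel_intensity
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, img.shape)
        np.clip(noise, -3 * noise_sd, 3 * noise_sd, out=noise)
        img += noise
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
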