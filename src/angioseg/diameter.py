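"""Vessel diameter profile and colour-coded visualisation.

The main cover tree's longest path orders the covers from one end of the
vessel to the other; each cover's Euclidean chord length is the local
diameter estimate in pixels (no physical calibration — angiography frames
carry none here), and the cover midpoint serves as the centreline position.
A localized narrowing (stenosis) appears as a dip in the profile.

For visualisation each cover's pixels are painted with the colour of its
diameter's quantile bin over a fixed palette (dark blue = narrowest bin,
red = widest); pixels under no cover show the grayscale frame.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cover import CoverTree

__all__ = ["DiameterProfile", "extract_profile", "colorize", "write_profile_csv",
           "PALETTE"]

#: fixed blue-to-red palette (RGB); bin 0 = narrowest diameters
PALETTE = (
    (13, 8, 135),
    (84, 2, 163),
    (139, 10, 165),
    (185, 50, 137),
    (219, 92, 104),
    (244, 136, 73),
    (254, 188, 43),
    (240, 249, 33),
)


@dataclass(frozen=True)
class DiameterProfile:
    """Ordered diameter samples along the main vessel path."""

    positions: tuple[tuple[float, float], ...]  # cover midpoints (row, col)
    diameters: tuple[float, ...]  # cover lengths, pixels
    directions: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.diameters)

    @property
    def minimum(self) -> float:
        return min(self.diameters)

    @property
    def median(self) -> float:
        return float(np.median(self.diameters))


def extract_profile(main: CoverTree) -> DiameterProfile:
    """One sample per cover on the main tree's longest path, in path order."""
    if main.size == 0:
        raise ValueError("empty cover tree: no vessel to profile")
    path = main.longest_path()
    covers = [main.nodes[idx] for idx in path]
    return DiameterProfile(
        positions=tuple(cv.midpoint for cv in covers),
        diameters=tuple(cv.length for cv in covers),
        directions=tuple(cv.direction for cv in covers),
    )


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(values, np.linspace(0.0, 1.0, n_bins + 1))
    inner = edges[1:-1]
    return np.searchsorted(inner, values, side="right")


def colorize(img: np.ndarray, main: CoverTree, n_bins: int = 5) -> np.ndarray:
    """RGB overlay: covers painted by diameter quantile bin over the frame.

    All covers of *main* are painted (not only the longest path), so the
    whole traced vessel is visible, as in per-segment diameter maps.
    A constant-width vessel lands in a single bin and hence a single colour.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    img = np.asarray(img)
    out = np.repeat(img[..., None], 3, axis=2).astype(np.uint8)
    if main.size == 0:
        return out
    lengths = np.array([cv.length for cv in main.nodes])
    bins = _quantile_bins(lengths, n_bins)
    palette = [PALETTE[int(round(k * (len(PALETTE) - 1) / max(1, n_bins - 1)))]
               for k in range(n_bins)]
    for cover, b in zip(main.nodes, bins):
        color = palette[min(int(b), n_bins - 1)]
        for r, c in cover.pixels():
            out[r, c] = color
    return out


def write_profile_csv(profile: DiameterProfile, path: str | Path) -> None:
    """Write the profile (index, row, col, direction, diameter_px)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "row", "col", "direction", "diameter_px"])
        for k, ((r, c), d, direc) in enumerate(
            zip(profile.positions, profile.diameters, profile.directions)
        ):
            writer.writerow([k, f"{r:.1f}", f"{c:.1f}", direc, f"{d:.4f}"])
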