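"""Tile classification: assigning vascular / nonvascular labels.

The classifier stage is pluggable so that any per-tile model (e.g. a trained
CNN) can be slotted in.  Three kinds ship with the package:

* ``heuristic`` (default) — a deterministic contrast test built on the same
  exact two-cluster thresholding the segmentation stage uses.  A tile is
  vascular iff (a) its two-cluster split is non-degenerate, (b) the cluster
  centres are separated by at least ``min_contrast`` gray levels, and (c)
  the dark-cluster fraction lies within ``[min_fraction, max_fraction]`` —
  excluding tiles that are nearly empty of dark pixels and tiles that are
  nearly all dark (shadow, image border).
* ``oracle`` — labels from a ground-truth mask (phantom work): a tile is
  vascular iff its true vessel-pixel fraction is at least ``min_fraction``.
* ``external`` — labels loaded from a CSV file (columns i, j, label with
  1-based tile indices), the adapter for user-supplied models.

Downstream, the regional expansion stage tolerates misses: a vascular tile
mislabelled nonvascular is still recovered as long as a neighbouring tile is
labelled, because each labelled tile expands into its 3 x 3 block.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .rpe import DegenerateValuesError, cluster_sizes, kmeans2_threshold
from .tiling import TileGrid, TileLabel

__all__ = [
    "HeuristicParams",
    "TileClassifier",
    "classify_tiles",
    "heuristic_score",
    "read_label_csv",
    "write_label_csv",
]


@dataclass(frozen=True)
class HeuristicParams:
    """Tunables of the reference heuristic (gray levels / fractions)."""

    min_contrast: float = 40.0
    min_fraction: float = 0.05
    max_fraction: float = 0.80


@dataclass
class TileClassifier:
    """A pluggable per-tile labeller.

    ``kind`` is one of ``heuristic``, ``oracle``, ``external``.  ``params``
    holds kind-specific settings: :class:`HeuristicParams` for the
    heuristic; ``truth_mask`` (bool array) and optional ``min_fraction`` for
    the oracle; ``labels`` (array) or ``path`` (CSV) for external labels.
    """

    kind: str = "heuristic"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("heuristic", "oracle", "external"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


def heuristic_score(tile_pixels, params: HeuristicParams | None = None):
    """Label one tile's intensity multiset; returns (label, diagnostics).

    Degenerate tiles (constant intensity) are nonvascular, not errors.
    """
    params = params or HeuristicParams()
    diag = {"separation": 0.0, "dark_fraction": 0.0, "degenerate": False}
    try:
        thr = kmeans2_threshold(tile_pixels)
    except DegenerateValuesError:
        diag["degenerate"] = True
        return TileLabel.NONVASCULAR, diag
    n_dark, n_bright = cluster_sizes(tile_pixels, thr)
    diag["separation"] = thr.center_bright - thr.center_dark
    diag["dark_fraction"] = n_dark / (n_dark + n_bright)
    vascular = (
        diag["separation"] >= params.min_contrast
        and params.min_fraction <= diag["dark_fraction"] <= params.max_fraction
    )
    return (TileLabel.VASCULAR if vascular else TileLabel.NONVASCULAR), diag


def classify_tiles(grid: TileGrid, clf: TileClassifier | None = None) -> TileGrid:
    """Assign a VASCULAR/NONVASCULAR label to every tile of *grid*.

    Deterministic given the grid and classifier parameters; no tile is left
    UNKNOWN.  Modifies ``grid.labels`` in place and returns the grid.
    """
    clf = clf or TileClassifier()
    if clf.kind == "heuristic":
        params = clf.params.get("heuristic", None)
        if params is None:
            params = HeuristicParams(
                **{k: v for k, v in clf.params.items() if k in HeuristicParams.__annotations__}
            )
        for i in range(grid.n_rows):
            for j in range(grid.n_cols):
                grid.labels[i, j], _ = heuristic_score(grid.tile(i, j), params)
    elif clf.kind == "oracle":
        truth = clf.params.get("truth_mask")
        if truth is None:
            raise ValueError("oracle classifier requires params['truth_mask']")
        truth = np.asarray(truth, dtype=bool)
        if truth.shape != grid.image.shape:
            raise ValueError("truth mask shape does not match the image")
        min_fraction = clf.params.get("min_fraction", 0.05)
        area = grid.tile_size ** 2
        for i in range(grid.n_rows):
            for j in range(grid.n_cols):
                rs, cs = grid.tile_slices(i, j)
                frac = truth[rs, cs].sum() / area
                grid.labels[i, j] = (
                    TileLabel.VASCULAR if frac >= min_fraction else TileLabel.NONVASCULAR
                )
    else:  # external
        labels = clf.params.get("labels")
        if labels is None:
            path = clf.params.get("path")
            if path is None:
                raise ValueError(
                    "external classifier requires params['labels'] or params['path']"
                )
            labels = read_label_csv(path, (grid.n_rows, grid.n_cols))
        labels = np.asarray(labels, dtype=np.int8)
        if labels.shape != grid.labels.shape:
            raise ValueError("label grid shape does not match the tile grid")
        if not np.isin(labels, (TileLabel.VASCULAR, TileLabel.NONVASCULAR)).all():
            raise ValueError("external labels must be VASCULAR or NONVASCULAR")
        grid.labels[:] = labels
    return grid


def read_label_csv(path: str | Path, shape: tuple[int, int]) -> np.ndarray:
    """Load a per-tile label CSV (columns i, j, label; 1-based indices)."""
    labels = np.full(shape, TileLabel.UNKNOWN, dtype=np.int8)
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            i, j = int(row["i"]) - 1, int(row["j"]) - 1
            labels[i, j] = int(row["label"])
    if (labels == TileLabel.UNKNOWN).any():
        raise ValueError(f"label file {path} does not cover every tile")
    return labels


def write_label_csv(labels: np.ndarray, path: str | Path) -> None:
    """Write a per-tile label CSV with 1-based tile indices."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["i", "j", "label"])
        for i in range(labels.shape[0]):
            for j in range(labels.shape[1]):
                writer.writerow([i + 1, j + 1, int(labels[i, j])])
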