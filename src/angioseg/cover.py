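"""Optimal cover tree (OCT): chord-based vessel tracing, noise pruning and
the raw material for diameter estimation.

A *cover* is a maximal run of vessel (black) pixels cast from a boundary
pixel of a black region along one of five fixed directions — vertically
down (S), vertically up (N), horizontal (E), 45 degrees down-right (SE) and
45 degrees up-right (NE).  Its Euclidean length (span for axial rays, span
times sqrt(2) for diagonal rays) estimates the local vessel diameter when
the chord crosses the vessel roughly perpendicular to its course.

Binarized vessel edges are jagged, so the raw shortest chord at each edge
pixel flips direction erratically.  Two selection rules stabilise it:

* Rule 1 — the orientation of consecutive covers may differ by at most
  ``max_angle_step`` (default 45 degrees).
* Rule 2 — the length of consecutive covers must agree within a tolerance
  (vessel width varies slowly along a path).

When no candidate, or more than one, satisfies both rules, the candidate
with the previous cover's exact direction is preferred if present;
otherwise the shortest candidate overall is taken (ties broken by a fixed
direction priority).

Covers selected while walking one black region's boundary are chained into
a spanning tree; trees whose covers touch (8-adjacency) are merged; the
tree with the longest node path is the main vessel, and black regions not
under it are pruned as noise — including, by design, genuinely disconnected
secondary vessels.
"""

from __future__ import annotations

import json
import logging
import math
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

__all__ = [
    "Cover",
    "CoverTree",
    "CoverRuleConfig",
    "DIRECTIONS",
    "scan_boundary_pixels",
    "cast_covers",
    "select_cover",
    "build_cover_forest",
    "merge_adjacent_trees",
    "select_main_tree",
    "prune_mask",
    "forest_to_json",
    "forest_from_json",
]

_SQRT2 = math.sqrt(2.0)

#: direction name -> (drow, dcol) unit step
DIRECTIONS: dict[str, tuple[int, int]] = {
    "S": (1, 0),
    "N": (-1, 0),
    "E": (0, 1),
    "SE": (1, 1),
    "NE": (-1, 1),
}

#: per-pixel Euclidean step length along each ray
_STEP_LEN = {d: (_SQRT2 if d in ("SE", "NE") else 1.0) for d in DIRECTIONS}

#: undirected chord orientation in degrees (a cover is a chord; its
#: orientation, not its casting sense, is what Rule 1 constrains)
_ORIENT = {"E": 0.0, "SE": 45.0, "S": 90.0, "N": 90.0, "NE": 135.0}

#: fixed tie-break priority for equal-length candidates
_PRIORITY = {"E": 0, "S": 1, "N": 2, "SE": 3, "NE": 4}

FIVE_DIRECTIONS = ("S", "N", "E", "SE", "NE")
THREE_DIRECTIONS = ("S", "E", "SE")

#: 8-connectivity structuring element used for region labelling
_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Cover:
    """A directed chord across a black region.

    ``clipped`` marks a chord stopped by the image border rather than by
    the region's edge; such a run does not join two edge pixels of the
    region, so selection prefers region-terminated chords when any exist.
    """

    anchor: tuple[int, int]
    direction: str
    span: int
    length: float
    end: tuple[int, int]
    clipped: bool = False

    def pixels(self) -> list[tuple[int, int]]:
        """The span pixels along the ray, anchor first."""
        dr, dc = DIRECTIONS[self.direction]
        r, c = self.anchor
        return [(r + k * dr, c + k * dc) for k in range(self.span)]

    @property
    def midpoint(self) -> tuple[float, float]:
        return (
            (self.anchor[0] + self.end[0]) / 2.0,
            (self.anchor[1] + self.end[1]) / 2.0,
        )


@dataclass(frozen=True)
class CoverTree:
    """A spanning tree of adjacent covers tracing one connected region.

    ``edges`` are index pairs into ``nodes``.  ``path_length`` is the number
    of nodes on the longest simple path (the tree diameter in nodes).
    """

    nodes: tuple[Cover, ...]
    edges: tuple[tuple[int, int], ...]
    n_fallbacks: int = 0

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def path_length(self) -> int:
        return len(self.longest_path())

    def longest_path(self) -> list[int]:
        """Node indices along the longest simple path, oriented so the first
        node's anchor precedes the last node's anchor in scan order."""
        if not self.nodes:
            return []
        adj = self._adjacency()
        far, _ = self._bfs_farthest(0, adj)
        far2, parent = self._bfs_farthest(far, adj)
        path = [far2]
        while parent[path[-1]] != -1:
            path.append(parent[path[-1]])
        if self.nodes[path[0]].anchor > self.nodes[path[-1]].anchor:
            path.reverse()
        return path

    def _adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.nodes]
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def _bfs_farthest(self, start: int, adj: list[list[int]]):
        parent = [-2] * len(self.nodes)
        parent[start] = -1
        queue = deque([start])
        order = []
        while queue:
            u = queue.popleft()
            order.append(u)
            for v in sorted(adj[u]):
                if parent[v] == -2:
                    parent[v] = u
                    queue.append(v)
        return order[-1], parent

    def earliest_anchor(self) -> tuple[int, int]:
        return min(cv.anchor for cv in self.nodes)


@dataclass(frozen=True)
class CoverRuleConfig:
    """Cover casting and selection settings.

    ``length_tolerance`` for Rule 2 defaults to the hybrid bound
    ``max(length_tolerance_abs, length_tolerance_rel * previous.length)``;
    with ``tolerance_mode="window"`` it is ``max(abs, 2 * sd)`` of the last
    ``window`` selected lengths instead.
    """

    directions: tuple[str, ...] = FIVE_DIRECTIONS
    max_angle_step: float = 45.0
    length_tolerance_rel: float = 0.25
    length_tolerance_abs: float = 2.0
    rules_enabled: bool = True
    tolerance_mode: str = "hybrid"  # "hybrid" | "window"
    window: int = 5
    keep_top_n: int = 1

    def __post_init__(self) -> None:
        if not self.directions:
            raise ValueError("at least one cover direction is required")
        unknown = set(self.directions) - set(DIRECTIONS)
        if unknown:
            raise ValueError(f"unknown cover directions: {sorted(unknown)}")
        if not (0.0 < self.max_angle_step <= 90.0):
            raise ValueError("max_angle_step must lie in (0, 90]")
        if self.tolerance_mode not in ("hybrid", "window"):
            raise ValueError("tolerance_mode must be 'hybrid' or 'window'")


def orientation_difference(d1: str, d2: str) -> float:
    """Minimum circular distance between two chord orientations, mod 180."""
    a = abs(_ORIENT[d1] - _ORIENT[d2]) % 180.0
    return min(a, 180.0 - a)


def scan_boundary_pixels(mask: np.ndarray) -> list[tuple[int, int]]:
    """Vessel pixels whose 4-neighbourhood is not entirely vessel, row-major.

    Image-border neighbours count as not-black, so pixels on the frame edge
    are boundary pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    interior = np.zeros_like(mask)
    interior[1:-1, 1:-1] = (
        mask[:-2, 1:-1] & mask[2:, 1:-1] & mask[1:-1, :-2] & mask[1:-1, 2:]
    )
    boundary = mask & ~interior
    return [(int(r), int(c)) for r, c in np.argwhere(boundary)]


def cast_covers(
    mask: np.ndarray, anchor: tuple[int, int], cfg: CoverRuleConfig | None = None
) -> list[Cover]:
    """Candidate covers from *anchor* along each configured direction.

    A direction yields a candidate when its first step stays on vessel; the
    span is then maximal along the ray.  If no direction's first step stays
    on vessel (an isolated pixel, or a pixel whose only black neighbours lie
    against the ray directions), every configured direction yields a span-1
    candidate so the pixel is still representable as a degenerate chord.
    """
    cfg = cfg or CoverRuleConfig()
    mask = np.asarray(mask, dtype=bool)
    r0, c0 = anchor
    h, w = mask.shape
    if not (0 <= r0 < h and 0 <= c0 < w) or not mask[r0, c0]:
        raise ValueError(f"anchor {anchor} is not a vessel pixel")

    out: list[Cover] = []
    for d in cfg.directions:
        dr, dc = DIRECTIONS[d]
        r, c = r0 + dr, c0 + dc
        if not (0 <= r < h and 0 <= c < w and mask[r, c]):
            continue
        span = 2
        while True:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < h and 0 <= nc < w):
                clipped = True
                break
            if mask[nr, nc]:
                r, c, span = nr, nc, span + 1
            else:
                clipped = False
                break
        out.append(
            Cover(anchor=anchor, direction=d, span=span,
                  length=span * _STEP_LEN[d], end=(r, c), clipped=clipped)
        )
    if not out:
        out = [
            Cover(anchor=anchor, direction=d, span=1, length=_STEP_LEN[d],
                  end=anchor)
            for d in cfg.directions
        ]
    return out


def _shortest(candidates: Sequence[Cover]) -> Cover:
    return min(candidates, key=lambda cv: (cv.length, _PRIORITY[cv.direction]))


def _rule2_tolerance(
    previous: Cover, cfg: CoverRuleConfig, history: Sequence[float] | None
) -> float:
    if cfg.tolerance_mode == "window" and history:
        recent = np.asarray(history[-cfg.window :], dtype=float)
        return max(cfg.length_tolerance_abs, 2.0 * float(recent.std()))
    return max(cfg.length_tolerance_abs, cfg.length_tolerance_rel * previous.length)


def select_cover(
    candidates: Sequence[Cover],
    previous: Cover | None,
    cfg: CoverRuleConfig | None = None,
    history: Sequence[float] | None = None,
) -> Cover:
    """Choose the optimal cover among *candidates* (see module docstring)."""
    cover, _ = _select_cover(candidates, previous, cfg or CoverRuleConfig(), history)
    return cover


def _select_cover(
    candidates: Sequence[Cover],
    previous: Cover | None,
    cfg: CoverRuleConfig,
    history: Sequence[float] | None = None,
) -> tuple[Cover, bool]:
    """Returns (cover, fallback_used)."""
    if not candidates:
        raise ValueError("empty candidate list")
    # chords stopped by the image border do not join two region-edge pixels;
    # let them compete only when nothing region-terminated exists
    unclipped = [cv for cv in candidates if not cv.clipped]
    if unclipped:
        candidates = unclipped
    if previous is None or not cfg.rules_enabled:
        return _shortest(candidates), False

    tol = _rule2_tolerance(previous, cfg, history)
    admissible = [
        cv
        for cv in candidates
        if orientation_difference(cv.direction, previous.direction)
        <= cfg.max_angle_step
        and abs(cv.length - previous.length) <= tol
    ]
    if len(admissible) == 1:
        return admissible[0], False
    # zero or several admissible: prefer the previous direction, else shortest.
    # A fallback event is any selection that itself violates the rules.
    same = [cv for cv in candidates if cv.direction == previous.direction]
    chosen = same[0] if same else _shortest(candidates)
    return chosen, chosen not in admissible


def build_cover_forest(
    mask: np.ndarray, cfg: CoverRuleConfig | None = None
) -> list[CoverTree]:
    """Cover every black region of *mask* and return one spanning tree each.

    Regions are processed in the scan order (top-down, left-right) of their
    first boundary pixel.  Within a region, boundary pixels are visited in
    scan order; pixels already lying under a selected cover are skipped, and
    each selected cover is chained to the previously selected one.
    Deterministic for a given mask and configuration.
    """
    cfg = cfg or CoverRuleConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    region_labels, n_regions = ndi.label(mask, structure=_CONN8)
    boundary = scan_boundary_pixels(mask)
    covered = np.zeros_like(mask)

    # group boundary pixels by region, preserving scan order
    per_region: dict[int, list[tuple[int, int]]] = {}
    region_order: list[int] = []
    for rc in boundary:
        lab = int(region_labels[rc])
        if lab not in per_region:
            per_region[lab] = []
            region_order.append(lab)
        per_region[lab].append(rc)

    # most recent selected cover under each pixel (region-local node index);
    # regions are 8-connected components, so ids never bleed across regions
    sel_id = np.full(mask.shape, -1, dtype=np.int64)
    h, w = mask.shape

    forest: list[CoverTree] = []
    for lab in region_order:
        nodes: list[Cover] = []
        edges: list[tuple[int, int]] = []
        lengths: list[float] = []
        n_fallbacks = 0
        for rc in per_region[lab]:
            if covered[rc]:
                continue
            # the rules compare against the previous ADJACENT cover: the
            # most recently selected cover touching this anchor, if any
            r0, c0 = rc
            window = sel_id[
                max(0, r0 - 1) : min(h, r0 + 2), max(0, c0 - 1) : min(w, c0 + 2)
            ]
            prev_idx = int(window.max())
            previous = nodes[prev_idx] if prev_idx >= 0 else None
            candidates = cast_covers(mask, rc, cfg)
            cover, fb = _select_cover(
                candidates, previous, cfg, lengths if previous is not None else None
            )
            n_fallbacks += fb
            nodes.append(cover)
            if len(nodes) >= 2:
                edges.append(
                    (prev_idx if prev_idx >= 0 else len(nodes) - 2, len(nodes) - 1)
                )
            for px in cover.pixels():
                covered[px] = True
                sel_id[px] = len(nodes) - 1
            lengths.append(cover.length)
        if n_fallbacks:
            logger.debug(
                "region %d: %d rule fallback events over %d covers",
                lab, n_fallbacks, len(nodes),
            )
        forest.append(
            CoverTree(nodes=tuple(nodes), edges=tuple(edges), n_fallbacks=n_fallbacks)
        )
    assert len(forest) == n_regions  # every black region holds >= 1 cover
    return forest


def merge_adjacent_trees(forest: Sequence[CoverTree]) -> list[CoverTree]:
    """Unite trees whose covers contain 8-adjacent pixels (transitively).

    Idempotent: merged trees' regions are pixel-disjoint and non-adjacent,
    so a second application changes nothing.
    """
    if len(forest) <= 1:
        return list(forest)

    owner: dict[tuple[int, int], tuple[int, int]] = {}
    for t_idx, tree in enumerate(forest):
        for n_idx, cover in enumerate(tree.nodes):
            for px in cover.pixels():
                owner[px] = (t_idx, n_idx)

    parent = list(range(len(forest)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # cross-tree cover adjacencies; one connecting edge per union event
    connectors: list[tuple[int, int, int, int]] = []  # t1, n1, t2, n2
    for (r, c), (t1, n1) in owner.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                hit = owner.get((r + dr, c + dc))
                if hit is None or hit[0] == t1:
                    continue
                t2, n2 = hit
                a, b = find(t1), find(t2)
                if a != b:
                    parent[max(a, b)] = min(a, b)
                    connectors.append((t1, n1, t2, n2))

    groups: dict[int, list[int]] = {}
    for t_idx in range(len(forest)):
        groups.setdefault(find(t_idx), []).append(t_idx)

    merged: list[CoverTree] = []
    for root in sorted(groups):
        members = sorted(groups[root])
        offset: dict[int, int] = {}
        nodes: list[Cover] = []
        edges: list[tuple[int, int]] = []
        fallbacks = 0
        for t_idx in members:
            offset[t_idx] = len(nodes)
            tree = forest[t_idx]
            nodes.extend(tree.nodes)
            edges.extend(
                (a + offset[t_idx], b + offset[t_idx]) for a, b in tree.edges
            )
            fallbacks += tree.n_fallbacks
        for t1, n1, t2, n2 in connectors:
            if find(t1) == root:
                edges.append((offset[t1] + n1, offset[t2] + n2))
        merged.append(
            CoverTree(nodes=tuple(nodes), edges=tuple(edges), n_fallbacks=fallbacks)
        )
    return merged


def select_main_tree(forest: Sequence[CoverTree]) -> CoverTree:
    """The tree with the longest node path; ties by size, then earliest anchor."""
    if not forest:
        raise ValueError("empty forest: no vessel to select")
    return max(
        forest,
        key=lambda t: (t.path_length, t.size, tuple(-x for x in t.earliest_anchor())),
    )


def select_top_trees(forest: Sequence[CoverTree], n: int = 1) -> list[CoverTree]:
    """The *n* best trees by the main-tree ordering (escape hatch for runs
    that want to keep more than the single main vessel)."""
    ranked = sorted(
        forest,
        key=lambda t: (t.path_length, t.size, tuple(-x for x in t.earliest_anchor())),
        reverse=True,
    )
    return ranked[: max(1, n)]


def prune_mask(
    mask: np.ndarray, main: CoverTree | Iterable[CoverTree]
) -> np.ndarray:
    """Remove black regions not covered by the retained tree(s).

    Connected components (8-connectivity) of *mask* containing at least one
    pixel of a retained cover stay; everything else becomes background.
    """
    mask = np.asarray(mask, dtype=bool)
    trees = [main] if isinstance(main, CoverTree) else list(main)
    region_labels, _ = ndi.label(mask, structure=_CONN8)
    keep: set[int] = set()
    for tree in trees:
        for cover in tree.nodes:
            for px in cover.pixels():
                lab = int(region_labels[px])
                if lab:
                    keep.add(lab)
    if not keep:
        return np.zeros_like(mask)
    return np.isin(region_labels, sorted(keep))


def forest_to_json(forest: Sequence[CoverTree], path: str | Path | None = None):
    """Serialize a forest as a JSON array of trees (node dicts + edge pairs)."""
    payload = [
        {
            "nodes": [
                {
                    "anchor": list(cv.anchor),
                    "direction": cv.direction,
                    "span": cv.span,
                    "length": cv.length,
                    "end": list(cv.end),
                }
                for cv in tree.nodes
            ],
            "edges": [list(e) for e in tree.edges],
            "n_fallbacks": tree.n_fallbacks,
        }
        for tree in forest
    ]
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=1))
    return payload


def forest_from_json(source: str | Path | list) -> list[CoverTree]:
    """Inverse of :func:`forest_to_json` (accepts a path or parsed payload)."""
    if isinstance(source, (str, Path)):
        source = json.loads(Path(source).read_text())
    forest = []
    for item in source:
        nodes = tuple(
            Cover(
                anchor=tuple(nd["anchor"]),
                direction=nd["direction"],
                span=int(nd["span"]),
                length=float(nd["length"]),
                end=tuple(nd["end"]),
            )
            for nd in item["nodes"]
        )
        edges = tuple((int(a), int(b)) for a, b in item["edges"])
        forest.append(
            CoverTree(nodes=nodes, edges=edges, n_fallbacks=int(item.get("n_fallbacks", 0)))
        )
    return forest
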