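"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from angioseg.phantom import PhantomSpec, generate_phantom


def kmeans2_sse_oracle(values):
    """Brute-force exact 1-D two-means: try every cut position in sorted
    order, computing each side's SSE by naive slicing with exact integer
    arithmetic (works on integer-valued multisets).

    Returns ``(best_sse_num, best_sse_den)`` — the optimal within-cluster
    sum of squares as an exact fraction — plus the cut value.
    """
    v = np.sort(np.asarray(values).ravel().astype(np.int64))
    uniq = np.unique(v)
    assert uniq.size >= 2
    best = None
    for cut in uniq[:-1]:
        left = v[v <= cut]
        right = v[v > cut]
        num, den = _sse_frac(left), _sse_frac(right)
        sse_num = num[0] * den[1] + den[0] * num[1]
        sse_den = num[1] * den[1]
        if best is None or sse_num * best[1] < best[0] * sse_den:
            best = (sse_num, sse_den, int(cut))
    return best


def _sse_frac(x):
    """Sum of squared deviations of integer array *x* as (numerator, denominator)."""
    n = int(x.size)
    if n == 0:
        return (0, 1)
    s = int(x.sum())
    q = int((x.astype(object) ** 2).sum())
    return (q * n - s * s, n)


def partition_sse_frac(values, delta):
    """Exact SSE of splitting integer *values* at threshold *delta*."""
    v = np.asarray(values).ravel().astype(np.int64)
    left, right = v[v < delta], v[v >= delta]
    num_l, den_l = _sse_frac(left)
    num_r, den_r = _sse_frac(right)
    return (num_l * den_r + den_l * num_r, den_l * den_r)


def ray_walk_oracle(mask, cover):
    """Independently re-walk a cover's ray: all span pixels must be vessel
    and the next pixel along the ray must be background or off-image."""
    from angioseg.cover import DIRECTIONS

    dr, dc = DIRECTIONS[cover.direction]
    r, c = cover.anchor
    h, w = mask.shape
    for k in range(cover.span):
        rr, cc = r + k * dr, c + k * dc
        if not (0 <= rr < h and 0 <= cc < w and mask[rr, cc]):
            return False
    nr, nc = r + cover.span * dr, c + cover.span * dc
    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc]:
        return False
    # span-1 fallback covers are allowed to have vessel neighbours off-ray
    return cover.span >= 1


@pytest.fixture(scope="session")
def default_phantom():
    """One representative 512x512 phantom with truth, reused read-only."""
    img, truth = generate_phantom(PhantomSpec(seed=11))
    img.setflags(write=False)
    truth.mask.setflags(write=False)
    return img, truth
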