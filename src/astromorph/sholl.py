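"""Skeletonization and concentric-ring Sholl intersection profiling.

Ring dialect
------------
Rings are rasterized as the *supercover* of the ideal circle: a pixel
belongs to the ring of radius ``r`` iff the circle passes through its unit
square, i.e. ``nearest(square, center) <= r <= farthest(square, center)``.
The supercover of a circle is a 4-connected closed digital curve, so an
8-connected skeleton path crossing from inside the ring to outside must
share at least one pixel with it — no pinhole crossings, unlike midpoint /
Bresenham circles.  The radius-1 ring is the 8-neighborhood of the center.

Two counting modes are provided: ``"pixel"`` counts skeleton pixels lying
on the ring (the default, matching totals reported as pixel-level
crossings summed across radii), ``"run"`` counts 8-connected components of
the skeleton-ring intersection (the classical crossing count).
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .types import CalibratedImage, ShollProfile, Skeleton

_STRUCT8 = np.ones((3, 3), dtype=bool)
_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


def classify_skeleton(
    skel_mask: np.ndarray, soma_mask: Optional[np.ndarray] = None
) -> Skeleton:
    """Classify skeleton pixels into endpoints, branch points and soma
    attachments.  Endpoints have at most one skeleton 8-neighbor (isolated
    pixels count as endpoints); branch points have three or more.  Primary
    attachments are skeleton pixels 8-adjacent to the soma; one 8-connected
    attachment cluster is one primary process."""
    skel_mask = np.asarray(skel_mask, dtype=bool)
    if not skel_mask.any():
        empty = np.empty((0, 2), dtype=int)
        return Skeleton(skel_mask, empty, empty, empty, 0)
    nb = ndimage.convolve(skel_mask.astype(np.uint8), _NEIGHBOR_KERNEL,
                          mode="constant")
    endpoints = np.argwhere(skel_mask & (nb <= 1))
    branch_points = np.argwhere(skel_mask & (nb >= 3))
    if soma_mask is not None and soma_mask.any():
        near_soma = ndimage.binary_dilation(soma_mask, structure=_STRUCT8)
        attach_mask = skel_mask & near_soma & ~soma_mask
        _, n_prim = ndimage.label(attach_mask, structure=_STRUCT8)
        attachments = np.argwhere(attach_mask)
    else:
        attachments = np.empty((0, 2), dtype=int)
        n_prim = 0
    return Skeleton(skel_mask, endpoints, branch_points, attachments, int(n_prim))


def skeletonize_processes(
    process_mask: np.ndarray, soma_mask: Optional[np.ndarray] = None
) -> Skeleton:
    """Thin the process mask to 1-px curves (topology-preserving) and
    classify the result against the soma mask.  An empty mask yields an
    empty skeleton."""
    process_mask = np.asarray(process_mask, dtype=bool)
    skel = skeletonize(process_mask) if process_mask.any() else process_mask.copy()
    return classify_skeleton(skel, soma_mask)


def rasterize_ring(
    center: Tuple[int, int], radius: float, shape: Tuple[int, int]
) -> np.ndarray:
    """Supercover ring of ``radius`` around ``center``, clipped to ``shape``.

    Returns a boolean mask; see the module docstring for the dialect.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    r0, c0 = center
    lo_r = max(0, int(math.floor(r0 - radius - 1)))
    hi_r = min(shape[0], int(math.ceil(r0 + radius + 2)))
    lo_c = max(0, int(math.floor(c0 - radius - 1)))
    hi_c = min(shape[1], int(math.ceil(c0 + radius + 2)))
    mask = np.zeros(shape, dtype=bool)
    if lo_r >= hi_r or lo_c >= hi_c:
        return mask
    yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    dy = np.abs(yy - r0).astype(float)
    dx = np.abs(xx - c0).astype(float)
    nearest = np.hypot(np.maximum(dy - 0.5, 0.0), np.maximum(dx - 0.5, 0.0))
    farthest = np.hypot(dy + 0.5, dx + 0.5)
    mask[lo_r:hi_r, lo_c:hi_c] = (nearest <= radius) & (radius <= farthest)
    return mask


def _max_ring_radius(center: Tuple[int, int], shape: Tuple[int, int]) -> float:
    """Distance from center to the farthest grid corner (rings beyond this
    cannot touch the grid)."""
    corners = [(0, 0), (0, shape[1] - 1), (shape[0] - 1, 0),
               (shape[0] - 1, shape[1] - 1)]
    return max(math.hypot(center[0] - y, center[1] - x) for y, x in corners)


def sholl_profile(
    skeleton: Skeleton,
    center: Tuple[int, int],
    interval: int = 10,
    mode: str = "pixel",
) -> ShollProfile:
    """Count skeleton-ring intersections on rings at every multiple of
    ``interval`` up to the largest ring touching the grid.

    ``pixel`` mode counts intersecting pixels; ``run`` mode counts
    8-connected components of the intersection.  Each ring is computed
    independently (no state is carried between radii).
    """
    if interval < 1:
        raise ValueError("interval must be >= 1")
    if mode not in ("pixel", "run"):
        raise ValueError(f"unknown mode {mode!r}")
    shape = skeleton.mask.shape
    r_max = _max_ring_radius(center, shape)
    radii = np.arange(interval, int(math.floor(r_max)) + 1, interval, dtype=int)
    counts = np.zeros(len(radii), dtype=int)
    for i, r in enumerate(radii):
        inter = skeleton.mask & rasterize_ring(center, int(r), shape)
        if mode == "pixel":
            counts[i] = int(inter.sum())
        else:
            _, n = ndimage.label(inter, structure=_STRUCT8)
            counts[i] = n
    return ShollProfile(center=tuple(center), interval=int(interval),
                        radii=radii, counts=counts, mode=mode)


def last_intersection_radius_um(profile: ShollProfile, microns_per_px: float) -> float:
    """Radius of the most distal intersecting ring, in microns."""
    if microns_per_px <= 0:
        raise ValueError("microns_per_px must be > 0")
    return profile.last_intersection_radius * microns_per_px


def save_profile_csv(profile: ShollProfile, microns_per_px: float, path) -> None:
    """Serialize a profile as CSV (radius_px, radius_um, count) with a JSON
    header comment recording center, interval and mode."""
    import json

    header = json.dumps({
        "center_row_col": list(profile.center),
        "interval_px": profile.interval,
        "mode": profile.mode,
        "microns_per_px": microns_per_px,
        "coordinates": "(row, col), 0-based, origin top-left",
    }, sort_keys=True)
    lines = [f"# {header}", "radius_px,radius_um,count"]
    for r, c in zip(profile.radii, profile.counts):
        lines.append(f"{int(r)},{r * microns_per_px:.6g},{int(c)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def save_overlay(
    image: CalibratedImage, profile: ShollProfile, path
) -> None:  # pragma: no cover - plotting convenience
    """Write a PNG of the image with the Sholl rings overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(image.pixels, cmap="gray", interpolation="nearest")
    for r in profile.radii:
        ax.add_patch(plt.Circle((profile.center[1], profile.center[0]), r,
                                fill=False, color="tab:orange", lw=0.6))
    ax.plot(profile.center[1], profile.center[0], "r+", ms=8)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
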