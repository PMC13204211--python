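"""The six morphometric descriptors of a single astrocyte.

Two distance origins are deliberately distinct: maximum process length is
measured from the soma *outline* to the most distal process on the last
intersecting ring, while the territory radius is the last intersection
radius measured from the soma *center*.  No interpolation is performed
beyond the last ring, so lengths are quantized to the ring interval.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import ZeroPrimariesError
from .sholl import last_intersection_radius_um, rasterize_ring
from .types import MetricVector, SegmentationResult, ShollProfile, Skeleton

logger = logging.getLogger(__name__)

_SMALL_SOMA_PX = 4


def soma_size(soma_mask: np.ndarray, microns_per_px: float) -> float:
    """Soma area in um^2 (foreground pixel count times the squared
    calibration)."""
    if microns_per_px <= 0:
        raise ValueError("microns_per_px must be > 0")
    n = int(np.count_nonzero(soma_mask))
    if n == 0:
        raise ValueError("empty soma mask")
    if n <= _SMALL_SOMA_PX:
        logger.warning("soma mask has only %d px; area estimate is unreliable", n)
    return n * microns_per_px**2


def max_process_length(
    skeleton: Skeleton,
    soma_mask: np.ndarray,
    profile: ShollProfile,
    microns_per_px: float,
) -> float:
    """Straight-line distance (um) from the soma outline to the most distal
    process on the last intersecting ring.

    Among skeleton pixels lying on that ring, the one maximizing the
    Euclidean distance to the nearest soma pixel defines the length.
    Returns 0 (with a warning) for an empty skeleton or an all-zero
    profile."""
    last_r = profile.last_intersection_radius
    if skeleton.is_empty or last_r == 0:
        logger.warning("empty skeleton or no ring intersections; length = 0")
        return 0.0
    ring = rasterize_ring(profile.center, last_r, skeleton.mask.shape)
    candidates = skeleton.mask & ring
    if not candidates.any():  # possible only if profile was not built from this skeleton
        raise ValueError("profile does not match skeleton: last ring has no pixels")
    dist_to_soma = ndimage.distance_transform_edt(~np.asarray(soma_mask, dtype=bool))
    return float(dist_to_soma[candidates].max()) * microns_per_px


def total_intersections(profile: ShollProfile) -> int:
    """Sum of per-ring intersection counts across all radii."""
    return int(profile.counts.sum())


def terminal_primary_ratio(skeleton: Skeleton) -> float:
    """Terminal branch endings divided by soma-originating primaries.

    Terminals are skeleton endpoints that are neither soma attachments nor
    on the image border (border endpoints are truncated processes and are
    excluded, with a log record).  A cell with zero primaries cannot be
    interpreted and raises :class:`ZeroPrimariesError`.
    """
    if skeleton.n_primaries == 0:
        raise ZeroPrimariesError("no soma-originating primary process")
    h, w = skeleton.mask.shape
    attach = {tuple(p) for p in skeleton.primary_attachments}
    n_terminal = 0
    n_border = 0
    for y, x in skeleton.endpoints:
        if (y, x) in attach:
            continue
        if y == 0 or x == 0 or y == h - 1 or x == w - 1:
            n_border += 1
            continue
        n_terminal += 1
    if n_border:
        logger.info("excluded %d border-truncated endpoint(s)", n_border)
    return n_terminal / skeleton.n_primaries


def territory_size(last_radius_um: float) -> float:
    """Circular territory area (um^2) enclosed by the last intersection
    radius: pi * r^2."""
    if last_radius_um < 0:
        raise ValueError("radius must be >= 0")
    return math.pi * last_radius_um**2


def compute_metric_vector(
    seg: SegmentationResult,
    skeleton: Skeleton,
    profile: ShollProfile,
    microns_per_px: float,
    cell_id: str = "",
    group: str = "",
    compartment: str = "",
) -> MetricVector:
    """Assemble all six descriptors for one cell.

    ``length_soma_ratio`` is computed from the two component metrics, never
    independently.  Component errors (empty soma, zero primaries) propagate.
    """
    soma = soma_size(seg.soma_mask, microns_per_px)
    max_len = max_process_length(skeleton, seg.soma_mask, profile, microns_per_px)
    tpr = terminal_primary_ratio(skeleton)
    last_um = last_intersection_radius_um(profile, microns_per_px)
    return MetricVector(
        max_process_length=max_len,
        total_intersections=float(total_intersections(profile)),
        terminal_primary_ratio=tpr,
        soma_size=soma,
        length_soma_ratio=max_len / soma,
        territory_size=territory_size(last_um),
        cell_id=cell_id,
        group=group,
        compartment=compartment,
    )
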