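"""Synthetic single-cell and multi-cell phantom generation.

Phantoms are drawn directly as rasters: a filled-disc soma at the canvas
center with ``n_primaries`` arms starting on the soma outline at equally
spaced angles (plus optional angular jitter).  All ground-truth fields are
computed from the same raster, so parameter-recovery tests are exact.

Intensity model: foreground 200, background 30 on the 0-255 scale, with
optional Gaussian noise; binary output is also supported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .errors import CanvasOverflowError, PlacementError
from .reference import GLOBAL_MEDIANS, PROFILE_MEDIANS, TABLE_PATTERNS
from .types import CalibratedImage, METRIC_NAMES, MetricVector

#: Default calibration (um/px).  The source protocol does not state one, so
#: this is a documented, configurable default.
DEFAULT_MICRONS_PER_PX = 0.25

_FG, _BG = 200.0, 30.0


@dataclass
class PhantomSpec:
    """Parameters of a star-shaped single-astrocyte phantom.

    ``branch_depth`` counts symmetric bifurcation levels beyond the primary
    segment (0 = unbranched straight arms).  ``jitter`` is the standard
    deviation (degrees) of angular perturbation applied to each primary arm.
    """

    soma_radius: float = 10.0
    n_primaries: int = 4
    arm_length: float = 60.0
    branch_depth: int = 0
    branch_angle: float = 50.0
    jitter: float = 0.0
    microns_per_px: float = DEFAULT_MICRONS_PER_PX
    seed: int = 0
    arm_thickness: int = 1
    child_fraction: float = 0.6
    intensity_noise: float = 0.0
    binary: bool = False
    canvas: Optional[int] = None  # side length; auto-sized when None

    def __post_init__(self) -> None:
        if self.soma_radius < 1:
            raise ValueError("soma_radius must be >= 1")
        if self.n_primaries < 0:
            raise ValueError("n_primaries must be >= 0")
        if self.arm_length < 0:
            raise ValueError("arm_length must be >= 0")
        if self.microns_per_px <= 0:
            raise ValueError("microns_per_px must be > 0")
        if self.branch_depth < 0:
            raise ValueError("branch_depth must be >= 0")
        if self.arm_thickness < 1 or self.arm_thickness > 3:
            raise ValueError("arm_thickness must be in 1..3")

    @property
    def reach(self) -> float:
        """Analytic upper bound on the arm tip distance from the center (px)."""
        total = self.arm_length * sum(
            self.child_fraction**d for d in range(self.branch_depth + 1)
        )
        return self.soma_radius + (total if self.n_primaries else 0.0)


@dataclass
class PhantomTruth:
    """Exact-by-construction ground truth for one phantom or field.

    ``soma_mask`` and ``cell_mask`` are the raster masks the truths were
    derived from; downstream tests compare against them directly.
    """

    soma_area: int
    primary_count: int
    terminal_count: int
    max_reach: float
    planted_cell_count: Optional[int] = None
    soma_mask: Optional[np.ndarray] = None
    cell_mask: Optional[np.ndarray] = None
    center: Optional[Tuple[int, int]] = None


def _draw_arm(
    mask: np.ndarray,
    start: Tuple[float, float],
    angle: float,
    length: float,
    depth: int,
    branch_angle: float,
    child_fraction: float,
) -> None:
    """Recursively draw a straight segment and its bifurcating children."""
    ey = start[0] + length * math.sin(angle)
    ex = start[1] + length * math.cos(angle)
    rr, cc = draw_line(
        int(round(start[0])), int(round(start[1])), int(round(ey)), int(round(ex))
    )
    mask[rr, cc] = True
    if depth > 0:
        half = math.radians(branch_angle) / 2.0
        for s in (-1.0, 1.0):
            _draw_arm(
                mask,
                (ey, ex),
                angle + s * half,
                length * child_fraction,
                depth - 1,
                branch_angle,
                child_fraction,
            )


def _render(soma: np.ndarray, arms: np.ndarray, spec_noise: float, binary: bool,
            rng: np.random.Generator) -> np.ndarray:
    cell = soma | arms
    if binary:
        return cell
    img = np.full(cell.shape, _BG, dtype=float)
    img[cell] = _FG
    if spec_noise > 0:
        img = img + rng.normal(0.0, spec_noise, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _masks_from_spec(spec: PhantomSpec, rng: np.random.Generator,
                     side: int) -> Tuple[np.ndarray, np.ndarray, Tuple[int, int]]:
    center = (side // 2, side // 2)
    soma = np.zeros((side, side), dtype=bool)
    rr, cc = draw_disk(center, spec.soma_radius + 0.5, shape=soma.shape)
    soma[rr, cc] = True
    arms = np.zeros_like(soma)
    for i in range(spec.n_primaries):
        angle = 2.0 * math.pi * i / spec.n_primaries
        if spec.jitter > 0:
            angle += math.radians(rng.normal(0.0, spec.jitter))
        sy = center[0] + spec.soma_radius * math.sin(angle)
        sx = center[1] + spec.soma_radius * math.cos(angle)
        _draw_arm(arms, (sy, sx), angle, spec.arm_length, spec.branch_depth,
                  spec.branch_angle, spec.child_fraction)
    if spec.arm_thickness > 1:
        arms = ndimage.binary_dilation(
            arms, np.ones((spec.arm_thickness, spec.arm_thickness), dtype=bool)
        )
    return soma, arms, center


def make_star_astrocyte(spec: PhantomSpec) -> Tuple[CalibratedImage, PhantomTruth]:
    """Draw a star phantom and its exact raster-derived ground truth.

    Raises :class:`CanvasOverflowError` if an explicit ``canvas`` cannot
    contain the soma plus total arm reach; nothing is ever silently clipped.
    """
    margin = 5 + spec.arm_thickness
    needed = 2 * int(math.ceil(spec.reach)) + 2 * margin + 1
    side = spec.canvas if spec.canvas is not None else needed
    if side < needed:
        raise CanvasOverflowError(
            f"canvas side {side} px cannot contain reach {spec.reach:.1f} px "
            f"(needs >= {needed})"
        )
    rng = np.random.default_rng(spec.seed)
    soma, arms, center = _masks_from_spec(spec, rng, side)
    cell = soma | arms
    img = _render(soma, arms, spec.intensity_noise, spec.binary, rng)

    ys, xs = np.nonzero(cell)
    max_reach = float(np.hypot(ys - center[0], xs - center[1]).max()) if ys.size else 0.0
    truth = PhantomTruth(
        soma_area=int(soma.sum()),
        primary_count=spec.n_primaries if arms.any() else 0,
        terminal_count=(spec.n_primaries * 2**spec.branch_depth) if arms.any() else 0,
        max_reach=max_reach,
        soma_mask=soma,
        cell_mask=cell,
        center=center,
    )
    image = CalibratedImage(pixels=img, microns_per_px=spec.microns_per_px)
    return image, truth


def make_field_image(
    n_cells: int,
    min_separation: float,
    field_area_mm2: float = 0.159,
    seed: int = 0,
    microns_per_px: float = DEFAULT_MICRONS_PER_PX,
    cell_spec: Optional[PhantomSpec] = None,
    n_specks: int = 0,
    speck_size: int = 1,
    intensity_noise: float = 0.0,
    binary: bool = False,
    max_tries_per_cell: int = 500,
) -> Tuple[CalibratedImage, PhantomTruth]:
    """Place ``n_cells`` small phantoms on a square field without overlap.

    The field side is derived from ``field_area_mm2`` and the calibration.
    Cell centers are drawn uniformly, rejecting draws closer than
    ``min_separation`` (px) to an accepted center or too close to the
    border.  ``n_specks`` sub-cellular debris objects (``speck_size`` px
    squares) can be added away from the cells to exercise size filtering.

    Raises :class:`PlacementError` when placement is infeasible after
    bounded retries.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    side = int(round(math.sqrt(field_area_mm2 * 1e6) / microns_per_px))
    if side < 4:
        raise ValueError("field too small for the given calibration")
    rng = np.random.default_rng(seed)
    spec = cell_spec or PhantomSpec(
        soma_radius=5, n_primaries=4, arm_length=12, microns_per_px=microns_per_px
    )
    reach = spec.reach + spec.arm_thickness
    margin = int(math.ceil(reach)) + 2
    if n_cells and side - 2 * margin <= 0:
        raise PlacementError("field smaller than a single cell footprint")

    soma_union = np.zeros((side, side), dtype=bool)
    arm_union = np.zeros_like(soma_union)
    centers: List[Tuple[int, int]] = []
    for i in range(n_cells):
        placed = False
        for _ in range(max_tries_per_cell):
            cy = int(rng.integers(margin, side - margin))
            cx = int(rng.integers(margin, side - margin))
            if any(math.hypot(cy - y, cx - x) < min_separation for y, x in centers):
                continue
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {i + 1}/{n_cells} after "
                f"{max_tries_per_cell} tries (min_separation={min_separation})"
            )
        sub = PhantomSpec(**{**asdict(spec), "seed": int(rng.integers(2**31))})
        local_side = 2 * margin + 1
        soma, arms, lc = _masks_from_spec(sub, rng, local_side)
        oy, ox = cy - lc[0], cx - lc[1]
        soma_union[oy:oy + local_side, ox:ox + local_side] |= soma
        arm_union[oy:oy + local_side, ox:ox + local_side] |= arms
        centers.append((cy, cx))

    cell_union = soma_union | arm_union
    if n_specks:
        keepout = ndimage.binary_dilation(cell_union, iterations=3) if n_cells else cell_union
        placed_specks = 0
        for _ in range(max_tries_per_cell * max(1, n_specks)):
            if placed_specks >= n_specks:
                break
            sy = int(rng.integers(1, side - 1 - speck_size))
            sx = int(rng.integers(1, side - 1 - speck_size))
            patch = np.s_[sy:sy + speck_size, sx:sx + speck_size]
            if keepout[patch].any():
                continue
            arm_union[patch] = True
            placed_specks += 1
        if placed_specks < n_specks:
            raise PlacementError("could not place all requested specks")
        cell_union = soma_union | arm_union

    img = _render(soma_union, arm_union, intensity_noise, binary, rng)
    truth = PhantomTruth(
        soma_area=int(soma_union.sum()),
        primary_count=0,
        terminal_count=0,
        max_reach=0.0,
        planted_cell_count=n_cells,
        soma_mask=soma_union,
        cell_mask=cell_union,
    )
    image = CalibratedImage(pixels=img, microns_per_px=microns_per_px)
    return image, truth


# -- metric-vector cohorts --------------------------------------------------

#: Side-of-median fill-in centers for metrics without a published
#: per-profile median (terminal-to-primary ratio).  Chosen on the correct
#: side of the reference global median per the signature table; flagged as
#: fill-ins, not published point values.
_TPR_FILL = {1: 1.5, 2: 1.5, 3: 1.5, 4: 2.5, 5: 1.5, 6: 2.5}


def profile_center(profile: int) -> Dict[str, float]:
    """Generation center for one profile: published medians plus fill-ins.

    ``length_soma_ratio`` is always derived as
    ``max_process_length / soma_size`` so that generated vectors satisfy the
    MetricVector consistency invariant (the published per-profile ratio
    medians are medians of ratios, not ratios of medians).
    """
    center = dict(PROFILE_MEDIANS[profile])
    center["terminal_primary_ratio"] = _TPR_FILL[profile]
    center["length_soma_ratio"] = (
        center["max_process_length"] / center["soma_size"]
    )
    return center


def make_metric_cohort(
    profile_mix: Dict[int, int],
    seed: int = 0,
    noise: float = 0.0,
) -> List[MetricVector]:
    """Draw a cohort of metric vectors with known generating profiles.

    Each sampled metric is a log-normal perturbation of the profile center
    (``value = center * exp(noise * z)``); draws landing on the wrong side
    of the reference global median are reflected back
    (``value -> median^2 / value``) so the generating signature is
    preserved.  ``length_soma_ratio`` is derived from the sampled length
    and soma metrics.  The generating profile is recorded in ``cell_id``
    as ``P<profile>_<index>``.
    """
    if not all(p in PROFILE_MEDIANS for p in profile_mix):
        raise ValueError("profile_mix keys must be in 1..6")
    rng = np.random.default_rng(seed)
    out: List[MetricVector] = []
    sampled = [m for m in METRIC_NAMES if m != "length_soma_ratio"]
    for profile in sorted(profile_mix):
        center = profile_center(profile)
        pattern = dict(zip(METRIC_NAMES, TABLE_PATTERNS[profile]))
        for i in range(profile_mix[profile]):
            values = {}
            for m in sampled:
                v = center[m] * math.exp(noise * rng.standard_normal()) if noise else center[m]
                med = GLOBAL_MEDIANS[m]
                wrong = (v > med) != (pattern[m] == "above")
                if noise and wrong and v > 0:
                    v = med * med / v
                values[m] = v
            values["length_soma_ratio"] = (
                values["max_process_length"] / values["soma_size"]
            )
            out.append(
                MetricVector(cell_id=f"P{profile}_{i:03d}", **values)
            )
    return out


# -- serialization ----------------------------------------------------------

def save_phantom(
    image: CalibratedImage, truth: PhantomTruth, spec, path: Path
) -> Tuple[Path, Path]:
    """Write a phantom as single-channel 8-bit TIFF plus a JSON truth sidecar."""
    import tifffile

    path = Path(path)
    px = image.pixels
    if px.dtype == bool:
        px = px.astype(np.uint8) * 255
    tifffile.imwrite(path, px)
    record = {
        "microns_per_px": image.microns_per_px,
        "truth": {
            "soma_area": truth.soma_area,
            "primary_count": truth.primary_count,
            "terminal_count": truth.terminal_count,
            "max_reach": truth.max_reach,
            "planted_cell_count": truth.planted_cell_count,
            "center": list(truth.center) if truth.center else None,
        },
        "spec": asdict(spec) if spec is not None else None,
    }
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path, sidecar
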