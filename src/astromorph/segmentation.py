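"""Cell, soma and process segmentation, gap closing, and field counting.

Connectivity is 8-connected throughout, matching the skeleton stage.
Coordinates are (row, col), 0-based, origin top-left.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize
from skimage.segmentation import find_boundaries, watershed

from .errors import NoSignalError, SomaSeparationError
from .types import CalibratedImage, FieldCountRecord, SegmentationResult

_STRUCT8 = np.ones((3, 3), dtype=bool)


def _threshold(pixels: np.ndarray, threshold_mode: Union[str, float]) -> np.ndarray:
    """Binarize an intensity grid. ``threshold_mode`` is ``"otsu"`` or a
    fixed cutoff on the image's own intensity scale (foreground is strictly
    above the cutoff)."""
    if pixels.dtype == bool:
        return pixels.copy()
    px = np.asarray(pixels, dtype=float)
    if threshold_mode == "otsu":
        if np.ptp(px) == 0:
            raise NoSignalError("image is constant; Otsu threshold undefined")
        t = threshold_otsu(px)
    else:
        t = float(threshold_mode)
    return px > t


def _split_touching(fg: np.ndarray) -> np.ndarray:
    """Watershed-based separation of touching objects: seeds at distance
    maxima, boundary pixels between basins removed from the foreground."""
    dist = ndimage.distance_transform_edt(fg)
    # seeds: regional maxima of the smoothed distance map
    smoothed = ndimage.gaussian_filter(dist, sigma=1.0)
    maxima = (smoothed == ndimage.maximum_filter(smoothed, size=7)) & fg
    markers, n = ndimage.label(maxima, structure=_STRUCT8)
    if n <= 1:
        return fg
    labels = watershed(-dist, markers, mask=fg)
    cuts = find_boundaries(labels, mode="outer") & fg
    out = fg & ~cuts
    return out if out.any() else fg


def threshold_foreground(
    image: CalibratedImage, threshold_mode: Union[str, float] = "otsu"
) -> np.ndarray:
    """Binarize the whole image (all components kept).

    Raises :class:`NoSignalError` on an empty or constant result."""
    fg = _threshold(image.pixels, threshold_mode)
    if not fg.any():
        raise NoSignalError("thresholding produced an empty foreground")
    return fg


def segment_cell(
    image: CalibratedImage,
    threshold_mode: Union[str, float] = "otsu",
    use_watershed: bool = False,
) -> np.ndarray:
    """Return the binary mask of the cell at (or nearest to) the image center.

    Foreground = pixels above the threshold; with ``use_watershed`` touching
    objects are split first.  Only the 8-connected component containing the
    image center — or, if the center is background, the component nearest to
    it — is kept.

    Raises :class:`NoSignalError` when thresholding yields no foreground.
    """
    fg = _threshold(image.pixels, threshold_mode)
    if not fg.any():
        raise NoSignalError("thresholding produced an empty foreground")
    if use_watershed:
        fg = _split_touching(fg)
    labels, n = ndimage.label(fg, structure=_STRUCT8)
    center = (fg.shape[0] // 2, fg.shape[1] // 2)
    lab = labels[center]
    if lab == 0:
        ys, xs = np.nonzero(fg)
        nearest = np.argmin(np.hypot(ys - center[0], xs - center[1]))
        lab = labels[ys[nearest], xs[nearest]]
    return labels == lab


def _endpoint_directions(
    skel: np.ndarray, labels: np.ndarray, window: int = 5
) -> List[Tuple[Tuple[int, int], int, Optional[np.ndarray]]]:
    """Skeleton endpoints with their component label and outward unit
    direction (endpoint minus centroid of nearby same-component skeleton
    pixels); direction is None for isolated pixels."""
    nb = ndimage.convolve(skel.astype(np.uint8), _STRUCT8.astype(np.uint8),
                          mode="constant") - skel.astype(np.uint8)
    out = []
    for y, x in zip(*np.nonzero(skel & (nb <= 1))):
        lab = labels[y, x]
        y0, y1 = max(0, y - window), min(skel.shape[0], y + window + 1)
        x0, x1 = max(0, x - window), min(skel.shape[1], x + window + 1)
        local = skel[y0:y1, x0:x1] & (labels[y0:y1, x0:x1] == lab)
        ys, xs = np.nonzero(local)
        if len(ys) < 2:
            out.append(((y, x), lab, None))
            continue
        vec = np.array([y - (y0 + ys.mean()), x - (x0 + xs.mean())])
        norm = np.hypot(*vec)
        out.append(((y, x), lab, vec / norm if norm > 0 else None))
    return out


def close_gaps(
    process_mask: np.ndarray,
    max_gap: float,
    max_angle_deg: float = 60.0,
) -> np.ndarray:
    """Bridge near-collinear component endpoints within ``max_gap`` pixels.

    Endpoints of different 8-connected components whose separation is at
    most ``max_gap`` and whose local orientations are compatible with the
    bridge direction (within ``max_angle_deg``) are joined by a 1-px
    segment.  Nothing else is added; ``max_gap = 0`` is the identity.
    The output never has fewer foreground pixels or more components than
    the input.
    """
    out = process_mask.copy()
    if max_gap <= 0 or not process_mask.any():
        return out
    labels, n = ndimage.label(process_mask, structure=_STRUCT8)
    if n <= 1:
        return out
    skel = skeletonize(process_mask)
    endpoints = _endpoint_directions(skel, labels)
    cos_tol = math.cos(math.radians(max_angle_deg))

    candidates = []
    for i in range(len(endpoints)):
        (ay, ax), alab, adir = endpoints[i]
        for j in range(i + 1, len(endpoints)):
            (by, bx), blab, bdir = endpoints[j]
            if alab == blab:
                continue
            d = math.hypot(by - ay, bx - ax)
            if d > max_gap or d == 0:
                continue
            bridge = np.array([by - ay, bx - ax]) / d
            if adir is not None and float(adir @ bridge) < cos_tol:
                continue
            if bdir is not None and float(bdir @ -bridge) < cos_tol:
                continue
            candidates.append((d, (ay, ax), (by, bx), alab, blab))

    parent = list(range(n + 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for d, a, b, alab, blab in sorted(candidates, key=lambda c: c[0]):
        ra, rb = find(alab), find(blab)
        if ra == rb:
            continue
        parent[ra] = rb
        rr, cc = draw_line(a[0], a[1], b[0], b[1])
        out[rr, cc] = True
    return out


def separate_soma(
    cell_mask: np.ndarray,
    soma_center_hint: Optional[Tuple[int, int]] = None,
    min_soma_area_px: int = 9,
) -> SegmentationResult:
    """Split a cell mask into a soma core and the remaining processes.

    The soma is the connected component, covering the hint pixel, of the
    morphological opening of the mask with the largest disc radius that
    leaves the hint covered.  Without a hint the center of the maximal
    inscribed disc is used.  Opening is computed exactly via the Euclidean
    distance transform (erosion = distance > r, dilation by disc of the
    surviving core).  If every radius fails, the maximal inscribed disc at
    the hint is the fallback; a soma smaller than ``min_soma_area_px``
    raises :class:`SomaSeparationError`.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise SomaSeparationError("empty cell mask")
    edt = ndimage.distance_transform_edt(cell_mask)
    if soma_center_hint is None:
        hint = np.unravel_index(int(np.argmax(edt)), edt.shape)
    else:
        hint = tuple(int(v) for v in soma_center_hint)
        if not cell_mask[hint]:
            raise ValueError("soma_center_hint lies outside the cell mask")

    soma = None
    for r in range(int(math.floor(edt[hint])), 0, -1):
        core = edt > r  # exact Euclidean-disc erosion
        if not core[hint]:
            continue
        core_labels, _ = ndimage.label(core, structure=_STRUCT8)
        core_comp = core_labels == core_labels[hint]
        dist_to_core = ndimage.distance_transform_edt(~core_comp)
        # Dilate by the full inscribed radius (plus 7% slack) rather than the
        # floored erosion radius: raster opening otherwise leaves a thin rim
        # of the soma boundary in the process mask, which corrupts
        # skeletonization; the relative slack additionally absorbs the blocky
        # boundary of nearest-neighbor-upsampled ROIs, keeping soma area
        # scale-invariant within ~2%.
        candidate = (dist_to_core <= 1.07 * float(edt[hint])) & cell_mask
        labels, _ = ndimage.label(candidate, structure=_STRUCT8)
        soma = labels == labels[hint]
        break
    if soma is None:
        # fallback: maximal inscribed disc at the hint
        yy, xx = np.mgrid[: cell_mask.shape[0], : cell_mask.shape[1]]
        soma = (np.hypot(yy - hint[0], xx - hint[1]) <= max(edt[hint], 1.0)) & cell_mask
    if soma.sum() < min_soma_area_px:
        raise SomaSeparationError(
            f"soma core has {int(soma.sum())} px (< {min_soma_area_px}); "
            "degenerate hint or mask"
        )
    cy, cx = ndimage.center_of_mass(soma)
    center = (int(round(cy)), int(round(cx)))
    if not soma[center]:
        ys, xs = np.nonzero(soma)
        k = int(np.argmin(np.hypot(ys - cy, xs - cx)))
        center = (int(ys[k]), int(xs[k]))
    return SegmentationResult(
        cell_mask=cell_mask,
        soma_mask=soma,
        process_mask=cell_mask & ~soma,
        soma_center=center,
    )


def count_cells_in_field(
    image: CalibratedImage,
    min_object_area_um2: float,
    threshold_mode: Union[str, float] = "otsu",
) -> int:
    """Count 8-connected foreground objects at least ``min_object_area_um2``
    in area after thresholding.  A constant (signal-free) image counts 0."""
    try:
        fg = _threshold(image.pixels, threshold_mode)
    except NoSignalError:
        return 0
    if not fg.any():
        return 0
    labels, n = ndimage.label(fg, structure=_STRUCT8)
    areas_px = np.bincount(labels.ravel())[1:]
    min_px = min_object_area_um2 / image.microns_per_px**2
    return int(np.sum(areas_px >= min_px))


def summarize_case(
    field_counts: Sequence[int],
    case_id: str = "",
    group: str = "",
    compartment: str = "",
) -> FieldCountRecord:
    """Aggregate per-field counts into a per-case record (sum retained
    alongside the per-field distribution)."""
    if len(field_counts) == 0:
        raise ValueError("field_counts must be nonempty")
    return FieldCountRecord(
        case_id=case_id,
        group=group,
        compartment=compartment,
        field_counts=list(field_counts),
    )
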