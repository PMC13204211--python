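"""Core domain types shared by all pipeline stages.

Coordinate convention: (row, col), 0-based, origin at the top-left corner of
the image.  All physical quantities carry their unit in the field name or
docstring; conversion from pixels uses ``microns_per_px``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

#: Canonical metric ordering used for patterns, CSV columns and reports.
METRIC_NAMES: Tuple[str, ...] = (
    "max_process_length",
    "total_intersections",
    "terminal_primary_ratio",
    "soma_size",
    "length_soma_ratio",
    "territory_size",
)

#: Units of the six descriptors, for report headers.
METRIC_UNITS = {
    "max_process_length": "um",
    "total_intersections": "count",
    "terminal_primary_ratio": "dimensionless",
    "soma_size": "um2",
    "length_soma_ratio": "um-1",
    "territory_size": "um2",
}


@dataclass
class CalibratedImage:
    """A 2D raster with physical calibration and acquisition metadata.

    ``pixels`` is either an 8-bit intensity grid (0-255) or a boolean mask.
    """

    pixels: np.ndarray
    microns_per_px: float
    case_id: str = ""
    group: str = ""
    compartment: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if not self.microns_per_px > 0:
            raise ValueError("microns_per_px must be > 0")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class SegmentationResult:
    """Cell/soma/process masks for one cell.

    Invariants: ``soma_mask | process_mask == cell_mask``,
    ``soma_mask & process_mask`` is empty, ``soma_center`` lies inside
    ``soma_mask`` and the soma is a single 8-connected component.
    """

    cell_mask: np.ndarray
    soma_mask: np.ndarray
    process_mask: np.ndarray
    soma_center: Tuple[int, int]

    def __post_init__(self) -> None:
        if self.cell_mask.shape != self.soma_mask.shape != self.process_mask.shape:
            raise ValueError("mask shapes differ")
        if not self.soma_mask[self.soma_center]:
            raise ValueError("soma_center must lie inside soma_mask")


@dataclass
class FieldCountRecord:
    """Per-field cell counts for one case/compartment plus their sum."""

    case_id: str
    compartment: str
    field_counts: Sequence[int]
    group: str = ""

    def __post_init__(self) -> None:
        counts = [int(c) for c in self.field_counts]
        if any(c < 0 for c in counts):
            raise ValueError("field counts must be non-negative")
        self.field_counts = counts

    @property
    def cumulative(self) -> int:
        return int(sum(self.field_counts))


@dataclass
class Skeleton:
    """1-px-wide skeleton with pixel classification.

    ``endpoints`` are skeleton pixels with at most one skeleton 8-neighbor,
    ``branch_points`` have three or more, ``primary_attachments`` are
    skeleton pixels 8-adjacent to the soma mask.  ``n_primaries`` counts
    8-connected clusters of attachment pixels (one cluster = one primary
    process).
    """

    mask: np.ndarray
    endpoints: np.ndarray  # (N, 2) int
    branch_points: np.ndarray
    primary_attachments: np.ndarray
    n_primaries: int

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class ShollProfile:
    """Per-ring intersection counts on concentric rings around a center.

    ``radii`` are strictly increasing multiples of ``interval`` (pixels);
    ``counts`` holds one intersection count per radius.  ``mode`` is
    ``"pixel"`` (count of skeleton pixels on the ring) or ``"run"``
    (count of 8-connected components of the skeleton-ring intersection).
    """

    center: Tuple[int, int]
    interval: int
    radii: np.ndarray
    counts: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.radii) != len(self.counts):
            raise ValueError("radii and counts must have equal length")
        if self.mode not in ("pixel", "run"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def last_intersection_radius(self) -> int:
        """Largest radius (px) with a nonzero count; 0 if all counts are 0."""
        nz = self.radii[self.counts > 0]
        return int(nz.max()) if nz.size else 0


@dataclass
class MetricVector:
    """The six morphometric descriptors of one astrocyte.

    Units: ``max_process_length`` um; ``total_intersections`` count;
    ``terminal_primary_ratio`` dimensionless; ``soma_size`` um^2;
    ``length_soma_ratio`` um^-1; ``territory_size`` um^2.
    """

    max_process_length: float
    total_intersections: float
    terminal_primary_ratio: float
    soma_size: float
    length_soma_ratio: float
    territory_size: float
    cell_id: str = ""
    compartment: str = ""
    group: str = ""

    def as_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in METRIC_NAMES}


@dataclass
class GlobalMedians:
    """Pooled per-metric medians (and IQRs) over a cohort."""

    medians: dict
    iqrs: dict = field(default_factory=dict)

    def __getitem__(self, metric: str) -> float:
        return self.medians[metric]


@dataclass
class ProfileAssignment:
    """Above/below pattern for one cell and the matched profile row."""

    pattern: Tuple[str, ...]
    profile_id: Union[int, str]  # 1..6 or "unclassified"
    disambiguator_used: bool = False
    cell_id: str = ""


@dataclass
class GroupComparison:
    """Omnibus + targeted pairwise comparison results for one variable."""

    groups: Sequence[str]
    H: float
    p: float
    posthoc: list  # of dicts: pair, p_raw, q, reject
    reference: Optional[str] = None
    reference_tie: bool = False
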