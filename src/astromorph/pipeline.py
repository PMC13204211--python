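"""End-to-end orchestration: manifest-driven batch processing of single-cell
ROIs and multi-cell fields, cohort assembly, profiling, and statistics.

The manifest is a CSV with columns ``path, case_id, group, compartment`` and
optionally ``kind`` (``cell`` default, or ``field``), ``roi_center_row`` /
``roi_center_col`` (triggering ROI extraction), and ``cell_id``.

Per-cell analysis failures (no signal, zero primaries, degenerate soma) are
logged and excluded — never silently dropped: the number of manifest cell
rows always equals metric rows plus logged exclusions.  The run aborts only
on I/O errors.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .errors import AstromorphError
from .morphometrics import compute_metric_vector
from .profiling import assign_profiles, global_medians
from .segmentation import (
    close_gaps,
    count_cells_in_field,
    segment_cell,
    separate_soma,
    summarize_case,
)
from .sholl import skeletonize_processes, sholl_profile
from .stats import bky_fdr, kruskal_wallis, targeted_posthoc
from .types import CalibratedImage, METRIC_NAMES, METRIC_UNITS, MetricVector

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """All tunable parameters of a run; every value is recorded in the log."""

    manifest: Union[str, Path] = ""
    out_dir: Union[str, Path] = "."
    microns_per_px: float = 0.25
    interval: int = 10
    mode: str = "pixel"
    threshold: Union[str, float] = "otsu"
    use_watershed: bool = False
    max_gap: float = 0.0
    fields_per_case: int = 10
    field_area_mm2: float = 0.159
    min_object_area_um2: float = 5.0
    alpha: float = 0.05
    seed: int = 0
    roi_side: int = 300
    scale_factor: int = 4

    def __post_init__(self) -> None:
        if self.mode not in ("pixel", "run"):
            raise ValueError("mode must be 'pixel' or 'run'")
        for name in ("microns_per_px", "interval", "fields_per_case",
                     "field_area_mm2", "min_object_area_um2", "alpha",
                     "roi_side", "scale_factor"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


def extract_roi(
    image: CalibratedImage,
    center: Tuple[int, int],
    side: int = 300,
    scale_factor: int = 4,
) -> CalibratedImage:
    """Crop a ``side``-square ROI around ``center`` and upsample it by
    nearest-neighbor ``scale_factor``; the calibration is divided by the
    factor so physical measurements are unchanged.  An out-of-bounds ROI is
    an error."""
    if scale_factor < 1 or int(scale_factor) != scale_factor:
        raise ValueError("scale_factor must be a positive integer")
    scale_factor = int(scale_factor)
    r0 = center[0] - side // 2
    c0 = center[1] - side // 2
    if r0 < 0 or c0 < 0 or r0 + side > image.shape[0] or c0 + side > image.shape[1]:
        raise ValueError(
            f"ROI {side}x{side} at {center} exceeds image bounds {image.shape}"
        )
    crop = image.pixels[r0:r0 + side, c0:c0 + side]
    if scale_factor > 1:
        crop = np.repeat(np.repeat(crop, scale_factor, axis=0), scale_factor, axis=1)
    return CalibratedImage(
        pixels=crop,
        microns_per_px=image.microns_per_px / scale_factor,
        case_id=image.case_id,
        group=image.group,
        compartment=image.compartment,
    )


def process_cell_image(
    image: CalibratedImage, config: PipelineConfig, cell_id: str = ""
):
    """Run one cell through segmentation, gap closing, skeletonization,
    Sholl profiling and metric extraction.

    Gap closing runs on the full thresholded foreground *before* the
    center-component selection, so that process fragments severed by
    sectioning are reconnected to the cell instead of being discarded
    as separate components."""
    if config.max_gap > 0:
        from .segmentation import threshold_foreground

        fg = threshold_foreground(image, config.threshold)
        fg = close_gaps(fg, config.max_gap)
        image = CalibratedImage(fg, image.microns_per_px, image.case_id,
                                image.group, image.compartment)
        cell = segment_cell(image, threshold_mode=0.5,
                            use_watershed=config.use_watershed)
    else:
        cell = segment_cell(image, threshold_mode=config.threshold,
                            use_watershed=config.use_watershed)
    seg = separate_soma(cell)
    skel = skeletonize_processes(seg.process_mask, seg.soma_mask)
    profile = sholl_profile(skel, seg.soma_center, interval=config.interval,
                            mode=config.mode)
    vector = compute_metric_vector(
        seg, skel, profile, image.microns_per_px,
        cell_id=cell_id, group=image.group, compartment=image.compartment,
    )
    return vector, seg, skel, profile


def _load_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) to a single channel
        arr = arr[..., :3].mean(axis=2).astype(arr.dtype)
    return arr


def _metrics_frame(vectors: List[MetricVector], config: PipelineConfig,
                   case_ids: List[str]) -> pd.DataFrame:
    rows = []
    for vec, case in zip(vectors, case_ids):
        row = {"cell_id": vec.cell_id, "case_id": case, "group": vec.group,
               "compartment": vec.compartment}
        for m in METRIC_NAMES:
            row[f"{m}_{METRIC_UNITS[m]}"] = getattr(vec, m)
        row.update(mode=config.mode, interval_px=config.interval,
                   microns_per_px=config.microns_per_px)
        rows.append(row)
    return pd.DataFrame(rows)


def _comparison_record(comp) -> dict:
    return {
        "groups": list(comp.groups),
        "H": comp.H,
        "p": comp.p,
        "reference": comp.reference,
        "reference_tie": comp.reference_tie,
        "posthoc": [
            {"pair": [str(a) for a in entry["pair"]], "p_raw": entry["p_raw"],
             "q": entry["q"], "reject": entry["reject"]}
            for entry in comp.posthoc
        ],
    }


def run_pipeline(config: PipelineConfig) -> Dict[str, Path]:
    """Execute the full pipeline for a manifest; returns output paths.

    Outputs (CSV/JSON, deterministic for identical config + inputs):
    ``metrics.csv``, ``profiles.csv``, ``medians.json``, ``density.csv``,
    ``stats.json``, ``exclusions.csv``, ``run_log.txt``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(config.manifest, dtype={"case_id": str})
    if "kind" not in manifest.columns:
        manifest["kind"] = "cell"
    manifest["kind"] = manifest["kind"].fillna("cell")

    vectors: List[MetricVector] = []
    case_ids: List[str] = []
    exclusions: List[dict] = []
    field_rows: List[dict] = []

    for idx, row in manifest.iterrows():
        path = Path(row["path"])
        if not path.is_absolute():
            path = Path(config.manifest).parent / path
        pixels = _load_image(path)  # I/O errors abort the run
        cal = float(row["microns_per_px"]) if "microns_per_px" in row and pd.notna(
            row.get("microns_per_px")) else config.microns_per_px
        image = CalibratedImage(
            pixels=pixels, microns_per_px=cal,
            case_id=str(row.get("case_id", "")),
            group=str(row.get("group", "")),
            compartment=str(row.get("compartment", "")),
        )
        if row["kind"] == "field":
            n = count_cells_in_field(image, config.min_object_area_um2,
                                     threshold_mode=config.threshold)
            field_rows.append({"case_id": image.case_id, "group": image.group,
                               "compartment": image.compartment, "count": n})
            continue
        cell_id = str(row["cell_id"]) if "cell_id" in row and pd.notna(
            row.get("cell_id")) else f"cell_{idx:04d}"
        if {"roi_center_row", "roi_center_col"} <= set(manifest.columns) and \
                pd.notna(row.get("roi_center_row")):
            image = extract_roi(
                image, (int(row["roi_center_row"]), int(row["roi_center_col"])),
                side=config.roi_side, scale_factor=config.scale_factor,
            )
        try:
            vector, *_ = process_cell_image(image, config, cell_id=cell_id)
        except AstromorphError as exc:
            logger.warning("excluding cell %s: %s", cell_id, exc)
            exclusions.append({"cell_id": cell_id,
                               "reason": f"{type(exc).__name__}: {exc}"})
            continue
        vectors.append(vector)
        case_ids.append(image.case_id)

    outputs: Dict[str, Path] = {}

    metrics_df = _metrics_frame(vectors, config, case_ids)
    outputs["metrics"] = out_dir / "metrics.csv"
    metrics_df.to_csv(outputs["metrics"], index=False, float_format=_FLOAT_FMT)

    excl_df = pd.DataFrame(exclusions, columns=["cell_id", "reason"])
    outputs["exclusions"] = out_dir / "exclusions.csv"
    excl_df.to_csv(outputs["exclusions"], index=False)

    stats_report: Dict[str, dict] = {
        "alpha": config.alpha,
        "percentile_rule": "linear interpolation",
        "counting_mode": config.mode,
    }

    if vectors:
        medians = global_medians(vectors)
        outputs["medians"] = out_dir / "medians.json"
        outputs["medians"].write_text(json.dumps(
            {"medians": medians.medians, "iqrs": medians.iqrs},
            indent=2, sort_keys=True))
        assignments = assign_profiles(vectors, medians)
        prof_rows = []
        for vec, asg in zip(vectors, assignments):
            row = {"cell_id": vec.cell_id}
            row.update({f"{m}_{METRIC_UNITS[m]}": getattr(vec, m)
                        for m in METRIC_NAMES})
            row.update({f"{m}_side": s for m, s in zip(METRIC_NAMES, asg.pattern)})
            row["profile_id"] = asg.profile_id
            row["disambiguator_used"] = asg.disambiguator_used
            prof_rows.append(row)
        outputs["profiles"] = out_dir / "profiles.csv"
        pd.DataFrame(prof_rows).to_csv(outputs["profiles"], index=False,
                                       float_format=_FLOAT_FMT)
        by_profile: Dict[object, Dict[str, list]] = {}
        for vec, asg in zip(vectors, assignments):
            if asg.profile_id == "unclassified":
                continue
            bucket = by_profile.setdefault(asg.profile_id, {m: [] for m in METRIC_NAMES})
            for m in METRIC_NAMES:
                bucket[m].append(getattr(vec, m))
        n_classified = sum(len(b["soma_size"]) for b in by_profile.values())
        if len(by_profile) >= 2 and n_classified >= 3:
            stats_report["metrics"] = {}
            for m in METRIC_NAMES:
                comp = targeted_posthoc(
                    m, {p: by_profile[p][m] for p in by_profile}, alpha=config.alpha)
                stats_report["metrics"][m] = _comparison_record(comp)

    if field_rows:
        density_records = []
        seen = {}
        for fr in field_rows:  # manifest order defines field order per case
            key = (fr["case_id"], fr["compartment"])
            seen.setdefault(key, {"group": fr["group"], "counts": []})
            seen[key]["counts"].append(fr["count"])
        for (case_id, compartment), entry in seen.items():
            rec = summarize_case(entry["counts"], case_id=case_id,
                                 group=entry["group"], compartment=compartment)
            row = {"case_id": case_id, "group": entry["group"],
                   "compartment": compartment}
            for i in range(config.fields_per_case):
                row[f"field_{i + 1}"] = (rec.field_counts[i]
                                         if i < len(rec.field_counts) else "")
            row["cumulative"] = rec.cumulative
            density_records.append(row)
        outputs["density"] = out_dir / "density.csv"
        pd.DataFrame(density_records).to_csv(outputs["density"], index=False)

        stats_report["density"] = {}
        density_df = pd.DataFrame(density_records)
        for compartment, sub in density_df.groupby("compartment", sort=True):
            groups = {g: gsub["cumulative"].to_numpy(dtype=float)
                      for g, gsub in sub.groupby("group", sort=True)}
            if len(groups) < 2 or sum(len(v) for v in groups.values()) < 3:
                continue
            labels = sorted(groups)
            h, p = kruskal_wallis([groups[g] for g in labels])
            pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
            from .stats import _pairwise_p  # shared pairwise statistic

            raw = [_pairwise_p(groups[a], groups[b]) for a, b in pairs]
            reject, adjusted = bky_fdr(raw, alpha=config.alpha)
            stats_report["density"][compartment] = {
                "groups": labels, "H": h, "p": p,
                "posthoc": [
                    {"pair": list(pair), "p_raw": raw[i], "q": float(adjusted[i]),
                     "reject": bool(reject[i])}
                    for i, pair in enumerate(pairs)
                ],
            }

    outputs["stats"] = out_dir / "stats.json"
    outputs["stats"].write_text(json.dumps(stats_report, indent=2, sort_keys=True))

    outputs["run_log"] = out_dir / "run_log.txt"
    log_lines = [f"astromorph {__version__}",
                 "coordinates: (row, col), 0-based, origin top-left"]
    for f in dataclasses.fields(config):
        log_lines.append(f"{f.name} = {getattr(config, f.name)}")
    log_lines.append(f"cells_in = {int((manifest['kind'] == 'cell').sum())}")
    log_lines.append(f"metric_rows = {len(vectors)}")
    log_lines.append(f"exclusions = {len(exclusions)}")
    outputs["run_log"].write_text("\n".join(log_lines) + "\n")
    return outputs
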