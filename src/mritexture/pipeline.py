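"""End-to-end study orchestration.

For every case (one annotated slice pair) and every field strength:
quantize the slice, then extract the four Haralick features per ROI with

* Method 1 — one masked GLCM per direction over the ROI, features averaged
  over directions; and
* Method 2 — sliding-window texture maps averaged over the ROI pixels.

ROIs are annotated in the high-field frame and propagated to the low-field
frame through the case's rigid transform.  A study concatenates the
per-case feature records and compares cancerous against non-suspicious
ROIs per (feature, field, method) stratum with Welch's t-test, Cohen's d
and the required per-group sample size.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as mio
from .geometry import ImageGeometry, RigidTransform, RoiSpec, propagate_roi
from .glcm import (
    DEFAULT_DIRECTIONS,
    FEATURE_NAMES,
    EmptyGlcmError,
    FeatureRecord,
    features_over_directions,
)
from .maps import summarize_map_over_roi, texture_map
from .phantom import generate_phantom_pair, make_study_configs
from .preprocess import quantize
from .stats import build_comparison_table

__all__ = [
    "PipelineConfig",
    "CaseEntry",
    "StudyManifest",
    "StudyResult",
    "analyze_case",
    "run_case",
    "run_study",
    "simulate_study",
    "write_simulated_study",
    "records_to_frame",
]

log = logging.getLogger("mritexture")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the analysis, with the study-condition defaults."""

    n_levels: int = 64
    range_mode: str = "percentile"  # robust default; "global_minmax" available
    percentile_range: Tuple[float, float] = (1.0, 99.0)
    glcm_distance: int = 1
    combine: str = "mean_features"  # or "mean_glcm"
    window_size: int = 9
    map_roi_only: bool = True  # restrict Method 2 maps to ROI pixels
    alpha: float = 0.05
    power_target: float = 0.80
    correction: Optional[str] = None  # None | "bonferroni" | "holm"
    test: str = "welch"  # or "paired"

    @property
    def directions(self) -> Tuple[Tuple[int, int], ...]:
        d = self.glcm_distance
        return tuple((dr * d, dc * d) for dr, dc in DEFAULT_DIRECTIONS)

    @property
    def quant_range_mode(self):
        if self.range_mode == "percentile":
            return ("percentile", *self.percentile_range)
        return self.range_mode

    def to_dict(self) -> dict:
        d = asdict(self)
        d["percentile_range"] = list(self.percentile_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "percentile_range" in d:
            d["percentile_range"] = tuple(d["percentile_range"])
        return cls(**d)


@dataclass(frozen=True)
class CaseEntry:
    case_id: str
    highfield_path: str
    lowfield_path: str
    transform_path: str
    roi_path: str


@dataclass(frozen=True)
class StudyManifest:
    cases: Tuple[CaseEntry, ...]
    config_path: Optional[str] = None

    @classmethod
    def from_json(cls, path) -> "StudyManifest":
        obj = json.loads(Path(path).read_text())
        base = Path(path).parent
        cases = tuple(
            CaseEntry(
                c["case_id"],
                str(base / c["highfield"]),
                str(base / c["lowfield"]),
                str(base / c["transform"]),
                str(base / c["rois"]),
            )
            for c in obj["cases"]
        )
        cfg = obj.get("config")
        return cls(cases, str(base / cfg) if cfg else None)

    def validate(self) -> None:
        """Fail fast: every referenced file must exist and parse before any
        computation starts."""
        if not self.cases:
            raise ValueError("manifest lists no cases")
        for c in self.cases:
            for p in (c.highfield_path, c.lowfield_path):
                mio.load_image(p)
            mio.load_transform(c.transform_path)
            if not mio.load_rois(c.roi_path):
                raise ValueError(f"case {c.case_id}: empty ROI file")


def _roi_pairs(rois: Sequence[RoiSpec]) -> List[Tuple[RoiSpec, RoiSpec]]:
    by_id = {}
    for r in rois:
        by_id.setdefault(r.lesion_id, {})[r.label] = r
    pairs = []
    for lesion_id, d in sorted(by_id.items()):
        if set(d) != {"cancerous", "non_suspicious"}:
            raise ValueError(f"lesion {lesion_id}: missing matched ROI")
        pairs.append((d["cancerous"], d["non_suspicious"]))
    return pairs


def _extract_field_records(
    image: np.ndarray,
    rois: Sequence[RoiSpec],
    field_name: str,
    config: PipelineConfig,
    case_id: str,
    valid: Optional[np.ndarray] = None,
) -> List[FeatureRecord]:
    q = quantize(image, config.n_levels, config.quant_range_mode)
    records: List[FeatureRecord] = []
    masks = {}
    for roi in rois:
        m = roi.rasterize(q.shape)
        if valid is not None:
            m = m & valid
        masks[(roi.lesion_id, roi.label)] = m

    union = np.zeros(q.shape, dtype=bool)
    for m in masks.values():
        union |= m
    maps = texture_map(
        q,
        window_size=config.window_size,
        directions=config.directions,
        combine=config.combine,
        pixels=union if config.map_roi_only else None,
    )

    for roi in rois:
        m = masks[(roi.lesion_id, roi.label)]
        try:
            feats, ndir = features_over_directions(
                q, mask=m, directions=config.directions, combine=config.combine
            )
        except EmptyGlcmError:
            warnings.warn(
                f"case {case_id} {field_name}: ROI {roi.lesion_id}/{roi.label} "
                "too small for any GLCM pair; skipped"
            )
            log.warning("skipping degenerate ROI %s/%s", roi.lesion_id, roi.label)
            continue
        records.append(
            FeatureRecord(*feats, "method1", field_name, roi.label,
                          roi.lesion_id, case_id, ndir)
        )
        vals = {}
        try:
            for name in FEATURE_NAMES:
                vals[name] = summarize_map_over_roi(maps[name], m).mean
        except ValueError:
            warnings.warn(
                f"case {case_id} {field_name}: ROI {roi.lesion_id}/{roi.label} "
                "has no valid map pixel; Method 2 skipped"
            )
            continue
        records.append(
            FeatureRecord(vals["energy"], vals["contrast"], vals["homogeneity"],
                          vals["correlation"], "method2", field_name, roi.label,
                          roi.lesion_id, case_id, len(config.directions))
        )
    return records


def analyze_case(
    highfield: np.ndarray,
    lowfield: np.ndarray,
    transform: RigidTransform,
    rois: Sequence[RoiSpec],
    geometry_high: ImageGeometry,
    geometry_low: ImageGeometry,
    config: PipelineConfig = PipelineConfig(),
    case_id: str = "case",
    lowfield_validity: Optional[np.ndarray] = None,
    fields: Sequence[str] = ("highfield", "lowfield"),
) -> List[FeatureRecord]:
    """Extract Method 1 and Method 2 feature records for one slice pair.

    ``rois`` are in the high-field frame; they are propagated to the
    low-field frame through ``transform`` before low-field extraction.
    """
    _roi_pairs(rois)  # validates matched-pair structure
    records: List[FeatureRecord] = []
    if "highfield" in fields:
        records += _extract_field_records(highfield, rois, "highfield", config, case_id)
    if "lowfield" in fields:
        low_rois = [propagate_roi(r, transform, geometry_high, geometry_low) for r in rois]
        records += _extract_field_records(
            lowfield, low_rois, "lowfield", config, case_id, valid=lowfield_validity
        )
    return records


def run_case(entry: CaseEntry, config: PipelineConfig = PipelineConfig()) -> List[FeatureRecord]:
    """File-based case runner: load images, transform and ROIs, then analyze."""
    high, geom_high = mio.load_image(entry.highfield_path)
    low, geom_low = mio.load_image(entry.lowfield_path)
    T = mio.load_transform(entry.transform_path)
    rois = mio.load_rois(entry.roi_path)
    return analyze_case(
        high, low, T, rois, geom_high, geom_low, config, case_id=entry.case_id
    )


def records_to_frame(records: Iterable[FeatureRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass(frozen=True)
class StudyResult:
    records: pd.DataFrame
    comparison: pd.DataFrame
    power_table: pd.DataFrame


def _power_table(comparison: pd.DataFrame) -> pd.DataFrame:
    """Low-field effect sizes and required sample sizes per feature/method
    (the reporting shape of the original power analysis)."""
    sub = comparison[comparison.field_strength == "lowfield"]
    return sub[["feature", "method", "d", "required_n"]].reset_index(drop=True)


def run_study(
    manifest: StudyManifest,
    config: PipelineConfig = PipelineConfig(),
    out_dir: Optional[str] = None,
) -> StudyResult:
    """Run every case, build the comparison and power tables, optionally
    write CSV/JSON reports and texture maps."""
    manifest.validate()
    if len(manifest.cases) < 2:
        raise ValueError("a study needs at least 2 cases")
    all_records: List[FeatureRecord] = []
    skipped = 0
    for entry in manifest.cases:
        try:
            recs = run_case(entry, config)
        except (ValueError, EmptyGlcmError) as exc:
            warnings.warn(f"case {entry.case_id} skipped: {exc}")
            skipped += 1
            continue
        log.info("case %s: %d records", entry.case_id, len(recs))
        all_records.extend(recs)
    if not all_records:
        raise RuntimeError("all cases were skipped; no records to analyze")

    result = summarize_records(all_records, config)
    if out_dir is not None:
        _write_reports(result, config, Path(out_dir))
    return result


def summarize_records(
    records: Sequence[FeatureRecord], config: PipelineConfig = PipelineConfig()
) -> StudyResult:
    comparison = build_comparison_table(
        records, alpha=config.alpha, power_target=config.power_target,
        correction=config.correction,
    )
    return StudyResult(records_to_frame(records), comparison, _power_table(comparison))


def _write_reports(result: StudyResult, config: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(out / "feature_records.csv", index=False)
    result.comparison.to_csv(out / "comparison_table.csv", index=False)
    result.power_table.to_csv(out / "power_table.csv", index=False)
    (out / "comparison_table.json").write_text(
        result.comparison.to_json(orient="records", indent=2)
    )
    mio.save_yaml(out / "config_used.yaml", config.to_dict())


def simulate_study(
    n_pairs: int = 28,
    seed: int = 0,
    null: bool = False,
    config: PipelineConfig = PipelineConfig(),
    fields: Sequence[str] = ("highfield", "lowfield"),
    **phantom_overrides,
) -> StudyResult:
    """Generate and analyze an in-memory synthetic study.

    One phantom slice pair per case; ``null=True`` makes lesion texture
    identical to background (type-I-error conditions).  Method 2 maps are
    restricted to ROI pixels.
    """
    records: List[FeatureRecord] = []
    for k, pconf in enumerate(make_study_configs(n_pairs, seed, null, **phantom_overrides)):
        pair = generate_phantom_pair(pconf)
        records.extend(
            analyze_case(
                pair.highfield, pair.lowfield, pair.true_transform, list(pair.rois),
                pair.geometry_high, pair.geometry_low, config,
                case_id=f"case{k:03d}", lowfield_validity=pair.lowfield_validity,
                fields=fields,
            )
        )
    return summarize_records(records, config)


def write_simulated_study(
    out_dir,
    n_pairs: int = 28,
    seed: int = 0,
    null: bool = False,
    **phantom_overrides,
) -> StudyManifest:
    """Write a synthetic study to disk (NIfTI slices, ROI/transform JSON,
    manifest) in the layout `run` expects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, pconf in enumerate(make_study_configs(n_pairs, seed, null, **phantom_overrides)):
        pair = generate_phantom_pair(pconf)
        cid = f"case{k:03d}"
        case_dir = out / cid
        case_dir.mkdir(exist_ok=True)
        mio.save_image(case_dir / "highfield.nii", pair.highfield, pair.geometry_high)
        mio.save_image(case_dir / "lowfield.nii", pair.lowfield, pair.geometry_low)
        mio.save_transform(case_dir / "transform.json", pair.true_transform)
        mio.save_rois(case_dir / "rois.json", pair.rois, case=cid)
        entries.append(
            {
                "case_id": cid,
                "highfield": f"{cid}/highfield.nii",
                "lowfield": f"{cid}/lowfield.nii",
                "transform": f"{cid}/transform.json",
                "rois": f"{cid}/rois.json",
            }
        )
    (out / "manifest.json").write_text(json.dumps({"cases": entries}, indent=2))
    return StudyManifest.from_json(out / "manifest.json")
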