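"""End-to-end orchestration: simulate → quantify → featurize → compare.

``run_pipeline`` drives the full analysis on a simulated cohort and
writes the study-style reports: a per-case metrics table, a per-case
feature table, a paired-comparison table per feature, a size-stratified
summary with db/wb fold changes, and 50-bin tumor intensity histograms.
Every output file is recorded in a manifest together with the
configuration and master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import quant, radiomics, stats
from .phantom import (
    AcquisitionConfig,
    CohortCase,
    LesionSpec,
    PatientAttributes,
    default_acquisition_configs,
    generate_cohort,
)
from .volume import UptakeVolume, VoiMask

__all__ = [
    "RunConfig",
    "ConfigError",
    "run_pipeline",
    "quantify_case",
    "featurize_case",
    "intensity_histogram",
    "save_cohort",
    "load_cohort",
]

logger = logging.getLogger("petpair")

#: World-space (mm) center of the pseudo-contralateral background VOI —
#: normal parenchyma distant from the (centered) lesion.
CONTRALATERAL_POINT_MM = (20.0, 60.0, 20.0)
from .phantom import LIVER_CENTER_MM  # noqa: E402  (shared geometry constant)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the study's stated values."""

    n_cases: int = 10
    seed: int = 0
    db_acquisition: AcquisitionConfig = field(
        default_factory=lambda: default_acquisition_configs()["db"]
    )
    wb_acquisition: AcquisitionConfig = field(
        default_factory=lambda: default_acquisition_configs()["wb"]
    )
    threshold_db: float = 3.0
    threshold_wb: float = 2.5
    resample_mm: float = 2.0
    bin_width: float = 0.5
    peak_kernel_cm: float = 1.2
    mtv_fraction: float = 0.40
    d_mri_cutoff_cm: float = 2.5
    histogram_bins: int = 50
    out_dir: str = "petpair-run"

    def __post_init__(self) -> None:
        for name in ("n_cases", "threshold_db", "threshold_wb", "resample_mm",
                     "bin_width", "peak_kernel_cm", "mtv_fraction",
                     "d_mri_cutoff_cm", "histogram_bins"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("db_acquisition", "wb_acquisition"):
            if key in d and isinstance(d[key], dict):
                d[key] = AcquisitionConfig(**d[key])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Per-case analysis
# ---------------------------------------------------------------------------

def _seed_index(suv: UptakeVolume, case: CohortCase) -> tuple[int, int, int]:
    """Hottest voxel near the lesion center — the operator's click."""
    center = suv.index_of(case.lesion.center_mm)
    half = [
        max(1, int(round(case.lesion.radius_mm / 2.0 / s))) for s in suv.spacing
    ]
    sl = tuple(
        slice(max(0, c - h), min(n, c + h + 1))
        for c, h, n in zip(center, half, suv.shape)
    )
    block = np.asarray(suv.data[sl])
    local = np.unravel_index(int(np.argmax(block)), block.shape)
    return tuple(s.start + l for s, l in zip(sl, local))


def _tumor_and_suv(case: CohortCase, modality: str, config: RunConfig):
    image = case.image(modality)
    attrs = case.attrs(modality)
    suv = quant.compute_suv(image, attrs)
    sul = quant.suv_to_sul(suv, attrs)
    threshold = config.threshold_db if modality == "db" else config.threshold_wb
    tumor = quant.segment_tumor(
        suv, modality, seed_point=_seed_index(suv, case), threshold=threshold
    )
    return suv, sul, tumor


def quantify_case(case: CohortCase, modality: str, config: RunConfig | None = None) -> dict:
    """Uptake-metric row (PERCIST panel) for one case and modality."""
    config = config or RunConfig()
    suv, sul, tumor = _tumor_and_suv(case, modality, config)
    backgrounds = {
        "contralateral": quant.background_voi(
            sul, "background-contralateral", sul.index_of(CONTRALATERAL_POINT_MM),
            diameter_cm=config.peak_kernel_cm,
        )
    }
    if modality == "wb":
        backgrounds["liver"] = quant.background_voi(
            sul, "background-liver", sul.index_of(LIVER_CENTER_MM),
            diameter_cm=config.peak_kernel_cm, shape="sphere",
        )
    metrics = quant.uptake_metrics(
        sul, suv, tumor, backgrounds, d_mri_cm=case.d_mri_cm,
        mtv_fraction=config.mtv_fraction,
        peak_kernel_diameter_cm=config.peak_kernel_cm,
    )
    row = {"case_id": case.case_id}
    row.update(metrics.to_row())
    return row


def featurize_case(case: CohortCase, modality: str, config: RunConfig | None = None) -> dict:
    """Radiomic feature row (20 features on the SUV image) for one case."""
    config = config or RunConfig()
    suv, _, tumor = _tumor_and_suv(case, modality, config)
    features = radiomics.extract_features(
        suv, tumor, target_spacing_mm=config.resample_mm, bin_width=config.bin_width
    )
    row = {"case_id": case.case_id, "modality": modality,
           "d_MRI_cm": case.d_mri_cm}
    provenance = features.pop("provenance")
    row.update(features)
    row["provenance"] = json.dumps(provenance)
    return row


def intensity_histogram(
    image: UptakeVolume, mask: VoiMask, n_bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram of in-mask values (QC view of tumor signal).

    Bins span the in-mask min..max; a constant region has its range
    widened by machine epsilon so the single occupied bin is valid.
    Counts always sum to the mask voxel count.
    """
    vals = mask.values_in(image)
    if vals.size == 0:
        raise ValueError("mask is empty")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        # Widen a degenerate range just enough for n_bins representable bins.
        eps = max(abs(hi), 1.0) * 1e-9 * n_bins
        lo, hi = lo - eps, hi + eps
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    return edges, counts


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def save_cohort(cases: list[CohortCase], out_dir: str | Path) -> list[Path]:
    """Write cohort volumes (NIfTI) and JSON sidecars; returns the files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest_rows = []
    for case in cases:
        for modality in ("db", "wb"):
            p = out_dir / f"{case.case_id}_{modality}.nii.gz"
            case.image(modality).save(p)
            written.append(p)
        sidecar = out_dir / f"{case.case_id}.json"
        sidecar.write_text(json.dumps({
            "case_id": case.case_id,
            "lesion": dataclasses.asdict(case.lesion),
            "d_mri_cm": case.d_mri_cm,
            "true_lesion_volume_ml": case.true_lesion_volume_ml,
            "parenchyma_suv": case.parenchyma_suv,
            "liver_suv": case.liver_suv,
            "attrs_db": dataclasses.asdict(case.attrs_db),
            "attrs_wb": dataclasses.asdict(case.attrs_wb),
        }, indent=2))
        written.append(sidecar)
        manifest_rows.append({"case_id": case.case_id, "d_mri_cm": case.d_mri_cm,
                              "true_lesion_volume_ml": case.true_lesion_volume_ml})
    manifest = out_dir / "cohort.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    written.append(manifest)
    return written


def load_cohort(in_dir: str | Path) -> list[CohortCase]:
    """Reload a cohort written by :func:`save_cohort`."""
    in_dir = Path(in_dir)
    cases = []
    for sidecar in sorted(in_dir.glob("case-*.json")):
        meta = json.loads(sidecar.read_text())
        lesion = LesionSpec(**{**meta["lesion"],
                               "center_mm": tuple(meta["lesion"]["center_mm"])})
        cases.append(CohortCase(
            case_id=meta["case_id"],
            lesion=lesion,
            d_mri_cm=meta["d_mri_cm"],
            true_lesion_volume_ml=meta["true_lesion_volume_ml"],
            parenchyma_suv=meta["parenchyma_suv"],
            liver_suv=meta["liver_suv"],
            attrs_db=PatientAttributes(**meta["attrs_db"]),
            attrs_wb=PatientAttributes(**meta["attrs_wb"]),
            db=UptakeVolume.load(in_dir / f"{meta['case_id']}_db.nii.gz",
                                 unit="Bq/mL", modality="db"),
            wb=UptakeVolume.load(in_dir / f"{meta['case_id']}_wb.nii.gz",
                                 unit="Bq/mL", modality="wb"),
        ))
    if not cases:
        raise FileNotFoundError(f"no cohort sidecars found under {in_dir}")
    return cases


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _write_histograms(case: CohortCase, modality: str, config: RunConfig,
                      out_dir: Path) -> Path:
    suv, sul, tumor = _tumor_and_suv(case, modality, config)
    edges, counts = intensity_histogram(sul, tumor, n_bins=config.histogram_bins)
    df = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                       "count": counts})
    p = out_dir / f"{case.case_id}_{modality}_sul_histogram.csv"
    df.to_csv(p, index=False)
    return p


def run_pipeline(config: RunConfig, cases: list[CohortCase] | None = None) -> dict:
    """Run the full simulate → quantify → featurize → compare pipeline.

    Returns the run manifest (also written to ``manifest.txt`` in the
    output directory).  A pre-generated cohort may be passed to skip the
    simulation stage; otherwise one is generated from ``config``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    files.append(config.to_yaml(out_dir / "config.yaml"))

    logger.info("stage simulate: %d cases, seed %d", config.n_cases, config.seed)
    if cases is None:
        cases = generate_cohort(
            config.n_cases, seed=config.seed,
            db_config=config.db_acquisition, wb_config=config.wb_acquisition,
        )
    vol_dir = out_dir / "volumes"
    files.extend(save_cohort(cases, vol_dir))

    metric_rows, feature_rows = [], []
    hist_dir = out_dir / "histograms"
    hist_dir.mkdir(exist_ok=True)
    for case in cases:
        for modality in ("db", "wb"):
            try:
                logger.info("stage quantify: %s %s", case.case_id, modality)
                metric_rows.append(quantify_case(case, modality, config))
                logger.info("stage featurize: %s %s", case.case_id, modality)
                feature_rows.append(featurize_case(case, modality, config))
                files.append(_write_histograms(case, modality, config, hist_dir))
            except Exception as exc:
                raise RuntimeError(
                    f"stage failed for {case.case_id} ({modality}): {exc}"
                ) from exc

    metrics = pd.DataFrame(metric_rows)
    for col in ("TBR_liver", "TBR_contralateral"):
        metrics[col] = metrics[col].astype(float)  # None -> NaN
    features = pd.DataFrame(feature_rows)
    metrics_path = out_dir / "metrics.csv"
    features_path = out_dir / "features.csv"
    metrics.to_csv(metrics_path, index=False)
    features.to_csv(features_path, index=False)
    files.extend([metrics_path, features_path])

    logger.info("stage compare")
    metric_cols = ["SUL_max", "SUL_mean", "SUL_peak", "MTV_mL", "TLG",
                   "TBR_liver", "TBR_contralateral"]
    cmp_metrics = stats.compare_modalities(
        metrics[metrics.modality == "db"], metrics[metrics.modality == "wb"],
        [c for c in metric_cols if c != "TBR_liver"],
    )
    cmp_features = stats.compare_modalities(
        features[features.modality == "db"], features[features.modality == "wb"],
        list(radiomics.FEATURE_NAMES),
    )
    strat = stats.stratified_summary(
        metrics[["case_id", "modality", "d_MRI_cm"] + metric_cols],
        cutoff_cm=config.d_mri_cutoff_cm,
    )
    cmp_metrics_path = out_dir / "comparison_metrics.csv"
    cmp_features_path = out_dir / "comparison_features.csv"
    strat_path = out_dir / "stratified_metrics.csv"
    cmp_metrics.to_csv(cmp_metrics_path, index=False)
    cmp_features.to_csv(cmp_features_path, index=False)
    strat.to_csv(strat_path, index=False)
    files.extend([cmp_metrics_path, cmp_features_path, strat_path])

    folds = {
        f"{row.metric}|{row.stratum}": row.fold_change
        for row in strat.itertuples()
        if np.isfinite(row.fold_change)
    }
    folds_path = out_dir / "fold_changes.json"
    folds_path.write_text(json.dumps(folds, indent=2))
    files.append(folds_path)

    manifest = {
        "seed": config.seed,
        "n_cases": len(cases),
        "config": config.to_dict(),
        "files": sorted(str(p.relative_to(out_dir)) for p in files),
    }
    manifest_path = out_dir / "manifest.txt"
    lines = [f"seed: {config.seed}", f"n_cases: {len(cases)}", "files:"]
    lines += [f"  {f}" for f in manifest["files"]]
    manifest_path.write_text("\n".join(lines) + "\n")
    manifest["files"].append("manifest.txt")
    return manifest
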