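"""Cohort file I/O: NIfTI images, CSV manifests/tables, JSON metrics, YAML config.

On-disk cohort layout (all standard formats, no bespoke binary)::

    cohort/
      manifest.csv        one row per lesion: patient_id, lesion_id, label,
                          risk flags, relative file paths
      meta.json           acquisition times (s) and pixel spacing (mm)
      P000_dce.nii.gz     4D DCE series (H, W, 1, T)
      P000_t2.nii.gz      T2-weighted image
      P000_parenchyma.nii.gz / P000_aorta.nii.gz   uint8 ROI masks
      P000_L0_mask.nii.gz                          uint8 lesion masks

Pixel indices are 0-based, masks live on the image grid and the time axis
is seconds from the first acquisition.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .classify import FoldResult, ModelConfig
from .core import CLASS_ORDER, CohortLoadError, DceSeries, Lesion, PatientRecord
from .evaluate import ClassMetrics, ConfusionMatrix
from .features import ExtractionConfig
from .phantom import PhantomConfig

RISK_COLUMNS = ("steatosis", "cirrhosis", "primary_tumor")


def _affine(spacing: tuple[float, float]) -> np.ndarray:
    return np.diag([spacing[1], spacing[0], 1.0, 1.0])


def _save_nifti(path: Path, array: np.ndarray, spacing: tuple[float, float]) -> None:
    nib.save(nib.Nifti1Image(array, _affine(spacing)), str(path))


def write_cohort(records: list[PatientRecord], out_dir: str | Path) -> Path:
    """Write a cohort to ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    first = records[0]
    meta = {
        "times_s": first.dce.times_s.tolist(),
        "pixel_spacing_mm": list(first.dce.pixel_spacing_mm),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))

    rows = []
    for record in records:
        spacing = record.dce.pixel_spacing_mm
        dce_name = f"{record.patient_id}_dce.nii.gz"
        t2_name = f"{record.patient_id}_t2.nii.gz"
        par_name = f"{record.patient_id}_parenchyma.nii.gz"
        aorta_name = f"{record.patient_id}_aorta.nii.gz"
        # NIfTI stores (x, y, z, t): transpose (T, H, W) -> (W, H, 1, T)
        dce_4d = record.dce.data.transpose(2, 1, 0)[:, :, None, :]
        _save_nifti(out / dce_name, dce_4d, spacing)
        _save_nifti(out / t2_name, record.t2.T, spacing)
        _save_nifti(out / par_name, record.parenchyma_mask.T.astype(np.uint8), spacing)
        _save_nifti(out / aorta_name, record.aorta_mask.T.astype(np.uint8), spacing)
        for lesion in record.lesions:
            mask_name = f"{lesion.lesion_id}_mask.nii.gz"
            _save_nifti(out / mask_name, lesion.mask.T.astype(np.uint8), spacing)
            rows.append(
                {
                    "patient_id": record.patient_id,
                    "lesion_id": lesion.lesion_id,
                    "label": lesion.label,
                    **{k: record.risk_factors.get(k, 0) for k in RISK_COLUMNS},
                    "dce_path": dce_name,
                    "t2_path": t2_name,
                    "lesion_mask_path": mask_name,
                    "parenchyma_mask_path": par_name,
                    "aorta_mask_path": aorta_name,
                }
            )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def _load_nifti(path: Path, row: str) -> np.ndarray:
    if not path.exists():
        raise CohortLoadError(f"file {path.name} referenced by lesion {row} is missing")
    return np.asarray(nib.load(str(path)).dataobj)


def read_cohort(manifest_path: str | Path) -> list[PatientRecord]:
    """Load a cohort written by :func:`write_cohort`, validating every record."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise CohortLoadError(f"manifest {manifest_path} not found")
    base = manifest_path.parent
    meta = json.loads((base / "meta.json").read_text())
    times = np.asarray(meta["times_s"], dtype=float)
    spacing = tuple(meta["pixel_spacing_mm"])

    table = pd.read_csv(manifest_path)
    records = []
    for patient_id, group in table.groupby("patient_id", sort=True):
        first = group.iloc[0]
        dce_4d = _load_nifti(base / first["dce_path"], first["lesion_id"])
        if dce_4d.ndim != 4:
            raise CohortLoadError(f"{first['dce_path']}: expected a 4D DCE series")
        data = dce_4d[:, :, 0, :].transpose(2, 1, 0)  # back to (T, H, W)
        if data.shape[0] != times.size:
            raise CohortLoadError(
                f"{first['dce_path']}: {data.shape[0]} frames but {times.size} time stamps"
            )
        t2 = _load_nifti(base / first["t2_path"], first["lesion_id"]).T
        parenchyma = _load_nifti(base / first["parenchyma_mask_path"], first["lesion_id"]).T
        aorta = _load_nifti(base / first["aorta_mask_path"], first["lesion_id"]).T
        lesions = []
        for _, row in group.iterrows():
            mask = _load_nifti(base / row["lesion_mask_path"], row["lesion_id"]).T
            if mask.shape != data.shape[1:]:
                raise CohortLoadError(
                    f"lesion {row['lesion_id']}: mask shape {mask.shape} "
                    f"does not match grid {data.shape[1:]}"
                )
            if row["label"] not in CLASS_ORDER:
                raise CohortLoadError(f"lesion {row['lesion_id']}: unknown label {row['label']!r}")
            lesions.append(
                Lesion(mask=mask.astype(bool), label=row["label"], lesion_id=str(row["lesion_id"]))
            )
        try:
            records.append(
                PatientRecord(
                    patient_id=str(patient_id),
                    dce=DceSeries(data, times, spacing),
                    t2=t2,
                    lesions=lesions,
                    parenchyma_mask=parenchyma.astype(bool),
                    aorta_mask=aorta.astype(bool),
                    risk_factors={k: int(first[k]) for k in RISK_COLUMNS},
                )
            )
        except ValueError as exc:
            raise CohortLoadError(f"patient {patient_id}: {exc}") from exc
    return records


def write_ttp_map(path: str | Path, ttp: np.ndarray, spacing: tuple[float, float]) -> None:
    """Export a TTP feature map as a NIfTI image."""
    _save_nifti(Path(path), np.asarray(ttp).T, spacing)


# --- tables and reports ----------------------------------------------------

def write_fold_results(folds: list[FoldResult], path: str | Path) -> None:
    rows = []
    for f in folds:
        row = {
            "lesion_id": f.lesion_id,
            "patient_id": f.patient_id,
            "true": f.true_label,
            "predicted": f.predicted_label,
        }
        row.update({f"p_{c}": f.probabilities[i] for i, c in enumerate(CLASS_ORDER)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fold_results(path: str | Path) -> list[FoldResult]:
    table = pd.read_csv(path)
    return [
        FoldResult(
            lesion_id=str(row["lesion_id"]),
            patient_id=str(row["patient_id"]),
            true_label=str(row["true"]),
            predicted_label=str(row["predicted"]),
            probabilities=np.array([row[f"p_{c}"] for c in CLASS_ORDER]),
        )
        for _, row in table.iterrows()
    ]


def write_confusion_csv(cm: ConfusionMatrix, path: str | Path) -> None:
    pd.DataFrame(cm.counts, index=list(cm.class_order), columns=list(cm.class_order)).to_csv(path)


def read_confusion_csv(path: str | Path) -> ConfusionMatrix:
    """Read a confusion matrix CSV (rows true, columns predicted, labelled)."""
    table = pd.read_csv(path, index_col=0)
    order = tuple(str(c) for c in table.columns)
    return ConfusionMatrix(table.to_numpy(dtype=int), class_order=order)


def metrics_report(
    metrics: ClassMetrics, benign_malignant: ClassMetrics | None = None, decimals: int = 2
) -> dict:
    """JSON-ready metrics report with the 2-decimal report rounding applied."""
    report = {"five_class": metrics.rounded(decimals).as_dict()}
    report["five_class_raw"] = metrics.as_dict()
    if benign_malignant is not None:
        report["benign_malignant"] = benign_malignant.rounded(decimals).as_dict()
        report["benign_malignant_raw"] = benign_malignant.as_dict()
    return report


def write_metrics_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))


# --- configuration ---------------------------------------------------------

def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration into the package's config dataclasses.

    Recognized top-level keys: ``phantom``, ``extraction``, ``model``; each
    maps to keyword arguments of the matching config dataclass. Unknown
    keys raise, so typos fail loudly.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"phantom", "extraction", "model"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    out = {}
    if "phantom" in raw:
        section = dict(raw["phantom"])
        for key in ("times_s", "lesions_per_patient"):
            if key in section:
                section[key] = tuple(section[key])
        out["phantom"] = PhantomConfig(**section)
    if "extraction" in raw:
        out["extraction"] = ExtractionConfig(**raw["extraction"])
    if "model" in raw:
        out["model"] = ModelConfig(**raw["model"])
    return out
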