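"""Standard-format I/O: NIfTI-1 volumes, TSV tables, JSON sidecars.

Cohort directory layout (BIDS-inspired, flat):

    cohort/
      atlas/atlas.nii.gz, atlas/regions.tsv
      masks/{brain,wm,csf}.nii.gz
      clinical.tsv
      ground_truth.json
      sub-<id>/bold.nii.gz, pw.nii.gz, pd.nii.gz, true_alff.nii.gz,
               motion.tsv, acq.json
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cbf import AcqParams, PerfusionPair
from .types import BoldSeries, MotionParams, Parcellation, TissueMasks

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def affine_for(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size_mm
    return aff


def save_volume(path: Path, data: np.ndarray, voxel_size_mm: float,
                dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine_for(voxel_size_mm))
    nib.save(img, str(path))


def load_volume(path: Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    vox = float(img.header.get_zooms()[0])
    return np.asarray(img.get_fdata()), vox


def save_motion(path: Path, motion: MotionParams) -> None:
    pd.DataFrame(motion.values, columns=MOTION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def load_motion(path: Path) -> MotionParams:
    """Read a 6-column motion TSV, with or without a header row."""
    first = Path(path).read_text().splitlines()[0].split("\t")
    has_header = not all(_is_float(tok) for tok in first)
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    if df.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got {df.shape[1]}")
    return MotionParams(values=df.to_numpy(float))


def _is_float(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def save_parcellation(atlas_dir: Path, parc: Parcellation,
                      voxel_size_mm: float) -> None:
    atlas_dir.mkdir(parents=True, exist_ok=True)
    save_volume(atlas_dir / "atlas.nii.gz", parc.labels, voxel_size_mm,
                dtype=np.int16)
    parc.regions.to_csv(atlas_dir / "regions.tsv", sep="\t", index=False)


def load_parcellation(atlas_dir: Path) -> tuple[Parcellation, float]:
    labels, vox = load_volume(atlas_dir / "atlas.nii.gz")
    regions = pd.read_csv(atlas_dir / "regions.tsv", sep="\t")
    return Parcellation(labels=np.round(labels).astype(np.int32),
                        regions=regions), vox


def save_masks(mask_dir: Path, masks: TissueMasks, voxel_size_mm: float) -> None:
    mask_dir.mkdir(parents=True, exist_ok=True)
    for name, vol in (("brain", masks.brain), ("wm", masks.wm), ("csf", masks.csf)):
        save_volume(mask_dir / f"{name}.nii.gz", vol.astype(np.uint8),
                    voxel_size_mm, dtype=np.uint8)


def load_masks(mask_dir: Path) -> TissueMasks:
    vols = {name: load_volume(mask_dir / f"{name}.nii.gz")[0] > 0.5
            for name in ("brain", "wm", "csf")}
    return TissueMasks(**vols)


def save_bold(path: Path, series: BoldSeries, voxel_size_mm: float) -> None:
    save_volume(path, series.values, voxel_size_mm)


def load_bold(path: Path, tr_s: float, brain_mask: np.ndarray) -> BoldSeries:
    data, _ = load_volume(path)
    return BoldSeries(values=data, tr_s=tr_s, brain_mask=brain_mask)


def save_acq(path: Path, acq: AcqParams) -> None:
    path.write_text(json.dumps({
        "pld_s": acq.pld_s, "tau_s": acq.tau_s, "t1_blood_s": acq.t1_blood_s,
        "alpha": acq.alpha, "lambda_ml_g": acq.lambda_ml_g}, indent=1))


def load_acq(path: Path) -> AcqParams:
    d = json.loads(path.read_text())
    if "pld_s" not in d:
        raise ValueError(f"{path}: acquisition sidecar lacks mandatory pld_s")
    return AcqParams(**d)


def load_perfusion(subject_dir: Path) -> PerfusionPair:
    pw, _ = load_volume(subject_dir / "pw.nii.gz")
    pdv, _ = load_volume(subject_dir / "pd.nii.gz")
    return PerfusionPair(pw=pw, pd=pdv)


def save_matrix_tsv(path: Path, data: pd.DataFrame, sidecar: dict | None = None
                    ) -> None:
    data.to_csv(path, sep="\t", index_label="subject", float_format="%.8f")
    if sidecar is not None:
        Path(str(path).replace(".tsv", ".json")).write_text(
            json.dumps(sidecar, indent=1, default=str))


def load_matrix_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject")
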