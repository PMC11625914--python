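"""Pipeline orchestration: simulate -> features -> cbf -> nvc -> stats.

Each stage reads from / writes to a cohort directory (see :mod:`nvcoupling.io`
for the layout), records what it did in ``<out>/manifest.json`` (input/config
hashes, warnings) and is skipped on re-run when nothing changed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .cbf import AcqParams, compute_cbf, smooth_cbf
from .features import (bandpass, compute_alff, compute_dc, compute_reho,
                       nuisance_regress, smooth_gaussian, zscore_map)
from .nvc import build_matrices
from .stats import (cluster_progression, correlate_with_scores,
                    group_effect_scan, roc_auc)
from .synthetic import CohortSpec, generate_cohort
from .types import NETWORK_NAMES, FeatureMap

logger = logging.getLogger(__name__)

STAGES = ("simulate", "features", "cbf", "nvc", "stats")
ECAS_SCORE_COLUMNS = ["ecas_language", "ecas_fluency", "ecas_executive",
                      "ecas_memory", "ecas_visuospatial", "ecas_total",
                      "ecas_als_specific", "ecas_non_als_specific"]


class MissingInputError(FileNotFoundError):
    """A stage input is absent; message names the subject and file."""


@dataclass
class PipelineConfig:
    """Resolved pipeline parameters; written next to the outputs of each run."""

    cohort_root: str = "cohort"
    output_root: str = "derivatives"
    # preprocessing
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    fwhm_mm: float = 6.0
    nuisance: bool = True
    # features
    reho_neighborhood: int = 27
    dc_threshold: float = 0.25
    # CBF calibration constants (PLD is per-subject metadata)
    tau_s: float = 1.8
    t1_blood_s: float = 1.65
    alpha: float = 0.85
    lambda_ml_g: float = 0.9
    # NVC
    min_voxels: int = 10
    metrics: tuple = ("ALFF", "ReHo", "DC")
    # stats
    fdr_q: float = 0.05
    k_clusters: int = 3
    n_boot: int = 2000
    seed: int = 0
    # simulation (only used by the simulate stage)
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["metrics"] = list(d["metrics"])
        return d


def _hash_config(cfg_part: dict, *file_paths: Path) -> str:
    h = hashlib.sha256(json.dumps(cfg_part, sort_keys=True, default=str).encode())
    for p in sorted(map(str, file_paths)):
        h.update(p.encode())
        h.update(hashlib.sha256(Path(p).read_bytes()).digest())
    return h.hexdigest()


class Manifest:
    def __init__(self, out_root: Path):
        self.path = out_root / "manifest.json"
        self.data = json.loads(self.path.read_text()) if self.path.exists() else {}

    def unchanged(self, stage: str, digest: str) -> bool:
        return self.data.get(stage, {}).get("hash") == digest

    def record(self, stage: str, digest: str, outputs: list[str],
               warnings: list[str] | None = None) -> None:
        self.data[stage] = {"hash": digest, "outputs": outputs,
                            "warnings": warnings or []}
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=1))


def _subject_dirs(root: Path) -> list[Path]:
    return sorted(p for p in root.iterdir() if p.is_dir() and p.name.startswith("sub-"))


def _require(path: Path, subject: str) -> Path:
    if not path.exists():
        raise MissingInputError(f"subject {subject}: missing input {path}")
    return path


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def run_simulate(config: PipelineConfig) -> Path:
    """Generate the synthetic cohort and write it under ``cohort_root``."""
    root = Path(config.cohort_root)
    spec = CohortSpec(**{**config.simulate, "seed": config.seed})
    cohort = generate_cohort(spec, with_images=True)
    root.mkdir(parents=True, exist_ok=True)
    nio.save_parcellation(root / "atlas", cohort.parcellation, spec.voxel_size_mm)
    nio.save_masks(root / "masks", cohort.masks, spec.voxel_size_mm)
    cohort.clinical.to_csv(root / "clinical.tsv", sep="\t")
    (root / "ground_truth.json").write_text(
        json.dumps(cohort.truth.scalars(), indent=1))
    (root / "cohort_spec.json").write_text(json.dumps(
        {**dataclasses.asdict(spec),
         "planted_rho": spec.planted_rho}, indent=1, default=str))
    for sid, imgs in cohort.subjects.items():
        sdir = root / sid
        sdir.mkdir(exist_ok=True)
        nio.save_bold(sdir / "bold.nii.gz", imgs.bold, spec.voxel_size_mm)
        nio.save_volume(sdir / "pw.nii.gz", imgs.perfusion.pw, spec.voxel_size_mm)
        nio.save_volume(sdir / "pd.nii.gz", imgs.perfusion.pd, spec.voxel_size_mm)
        nio.save_volume(sdir / "true_alff.nii.gz",
                        cohort.truth.alff_patterns[sid], spec.voxel_size_mm)
        nio.save_motion(sdir / "motion.tsv", imgs.motion)
        nio.save_acq(sdir / "acq.json", imgs.acq)
    return root


def validate_cohort(root: str | Path) -> list[str]:
    """Report missing/malformed files, grid mismatches and clinical
    inconsistencies (subscore sums != totals). Empty list = pristine."""
    root = Path(root)
    findings: list[str] = []
    atlas_dir, mask_dir = root / "atlas", root / "masks"
    grid = None
    for f in ("atlas/atlas.nii.gz", "atlas/regions.tsv", "clinical.tsv",
              "masks/brain.nii.gz", "masks/wm.nii.gz", "masks/csf.nii.gz"):
        if not (root / f).exists():
            findings.append(f"missing {f}")
    if not findings:
        parc, _ = nio.load_parcellation(atlas_dir)
        grid = parc.labels.shape
    for sdir in _subject_dirs(root):
        sid = sdir.name
        for f in ("bold.nii.gz", "pw.nii.gz", "pd.nii.gz", "motion.tsv", "acq.json"):
            if not (sdir / f).exists():
                findings.append(f"{sid}: missing {f}")
        if (sdir / "bold.nii.gz").exists():
            data, _ = nio.load_volume(sdir / "bold.nii.gz")
            if grid is not None and data.shape[:3] != grid:
                findings.append(f"{sid}: BOLD grid {data.shape[:3]} != atlas grid {grid}")
            if (sdir / "motion.tsv").exists():
                motion = nio.load_motion(sdir / "motion.tsv")
                if motion.n_timepoints != data.shape[3]:
                    findings.append(
                        f"{sid}: motion rows ({motion.n_timepoints}) != "
                        f"BOLD timepoints ({data.shape[3]})")
    clin_path = root / "clinical.tsv"
    if clin_path.exists():
        clin = pd.read_csv(clin_path, sep="\t", index_col="subject")
        subs = ["bulbar", "upper_limbs", "lower_limbs", "respiratory"]
        for when in ("baseline", "12m"):
            cols = [f"alsfrs_{when}_{s}" for s in subs]
            tot = f"alsfrs_{when}_total"
            if all(c in clin for c in cols) and tot in clin:
                have = clin.dropna(subset=cols + [tot])
                bad = have[have[cols].sum(axis=1) != have[tot]]
                for sid in bad.index:
                    findings.append(f"clinical row {sid}: {when} subscores do not "
                                    f"sum to total")
    return findings


def _load_common(config: PipelineConfig):
    root = Path(config.cohort_root)
    parc, vox = nio.load_parcellation(root / "atlas")
    masks = nio.load_masks(root / "masks")
    spec = json.loads((root / "cohort_spec.json").read_text()) \
        if (root / "cohort_spec.json").exists() else {}
    tr_s = float(spec.get("tr_s", 1.5))
    return root, parc, masks, vox, tr_s


def run_features(config: PipelineConfig) -> list[str]:
    """Compute z-scored ALFF/ReHo/DC maps for every subject.

    Band-pass -> smooth -> nuisance regression -> ReHo/DC; ALFF is computed
    from the smoothed, nuisance-regressed but unfiltered series.
    """
    root, parc, masks, vox, tr_s = _load_common(config)
    out_root = Path(config.output_root)
    manifest = Manifest(out_root)
    written = []
    cfg_part = {k: getattr(config, k) for k in (
        "band_low_hz", "band_high_hz", "fwhm_mm", "nuisance",
        "reho_neighborhood", "dc_threshold", "metrics")}
    for sdir in _subject_dirs(root):
        sid = sdir.name
        bold_path = _require(sdir / "bold.nii.gz", sid)
        motion_path = _require(sdir / "motion.tsv", sid)
        digest = _hash_config(cfg_part, bold_path, motion_path)
        stage_key = f"features/{sid}"
        odir = out_root / sid
        if manifest.unchanged(stage_key, digest) and \
                all((odir / f"{m.lower()}_z.nii.gz").exists() for m in config.metrics):
            continue
        bold = nio.load_bold(bold_path, tr_s, masks.brain)
        motion = nio.load_motion(motion_path)
        smoothed = bold.copy_with(smooth_gaussian(bold.values, config.fwhm_mm, vox))
        if config.nuisance:
            clean_unfiltered = nuisance_regress(smoothed, motion, masks)
        else:
            clean_unfiltered = smoothed
        bp = bandpass(smoothed, config.band_low_hz, config.band_high_hz)
        clean_bp = nuisance_regress(bp, motion, masks) if config.nuisance else bp
        odir.mkdir(parents=True, exist_ok=True)
        produced = []
        sidecar = dict(cfg_part)
        for metric in config.metrics:
            if metric == "ALFF":
                fmap = compute_alff(clean_unfiltered,
                                    (config.band_low_hz, config.band_high_hz))
            elif metric == "ReHo":
                fmap = compute_reho(clean_bp, config.reho_neighborhood)
            elif metric == "DC":
                fmap = compute_dc(clean_bp, config.dc_threshold)
            else:
                raise ValueError(f"unknown metric {metric}")
            zmap = zscore_map(fmap, masks.brain)
            path = odir / f"{metric.lower()}_z.nii.gz"
            nio.save_volume(path, zmap.values, vox)
            produced.append(str(path))
        (odir / "features.json").write_text(json.dumps(sidecar, indent=1))
        manifest.record(stage_key, digest, produced)
        written.extend(produced)
    return written


def run_cbf(config: PipelineConfig) -> list[str]:
    """Quantify, smooth and z-score each subject's CBF map."""
    root, parc, masks, vox, _ = _load_common(config)
    out_root = Path(config.output_root)
    manifest = Manifest(out_root)
    written = []
    cfg_part = {k: getattr(config, k) for k in
                ("tau_s", "t1_blood_s", "alpha", "lambda_ml_g", "fwhm_mm")}
    for sdir in _subject_dirs(root):
        sid = sdir.name
        pw = _require(sdir / "pw.nii.gz", sid)
        pdp = _require(sdir / "pd.nii.gz", sid)
        acq_path = _require(sdir / "acq.json", sid)
        digest = _hash_config(cfg_part, pw, pdp, acq_path)
        stage_key = f"cbf/{sid}"
        odir = out_root / sid
        if manifest.unchanged(stage_key, digest) and (odir / "cbf_z.nii.gz").exists():
            continue
        pair = nio.load_perfusion(sdir)
        acq = nio.load_acq(acq_path)
        acq = AcqParams(pld_s=acq.pld_s, tau_s=config.tau_s,
                        t1_blood_s=config.t1_blood_s, alpha=config.alpha,
                        lambda_ml_g=config.lambda_ml_g)
        cbf = compute_cbf(pair, acq, masks.brain)
        cbf = smooth_cbf(cbf, config.fwhm_mm, vox)
        zmap = zscore_map(cbf, masks.brain)
        odir.mkdir(parents=True, exist_ok=True)
        path = odir / "cbf_z.nii.gz"
        nio.save_volume(path, zmap.values, vox)
        (odir / "cbf.json").write_text(json.dumps(
            {**cfg_part, "pld_s": acq.pld_s}, indent=1))
        manifest.record(stage_key, digest, [str(path)])
        written.append(str(path))
    return written


def run_nvc(config: PipelineConfig) -> dict:
    """Assemble Fisher-z NVC matrices (metric x granularity) and write TSVs."""
    root, parc, masks, vox, _ = _load_common(config)
    out_root = Path(config.output_root)
    clinical = pd.read_csv(root / "clinical.tsv", sep="\t", index_col="subject")
    subject_maps = {}
    for sdir in _subject_dirs(root):
        sid = sdir.name
        odir = out_root / sid
        maps = {}
        cbf_path = _require(odir / "cbf_z.nii.gz", sid)
        maps["CBF"] = FeatureMap("CBF", nio.load_volume(cbf_path)[0], masks.brain,
                                 zscored=True)
        for metric in config.metrics:
            p = _require(odir / f"{metric.lower()}_z.nii.gz", sid)
            maps[metric] = FeatureMap(metric, nio.load_volume(p)[0], masks.brain,
                                      zscored=True)
        subject_maps[sid] = maps
    order = [s for s in clinical.index if s in subject_maps]
    extra = sorted(set(subject_maps) - set(order))
    matrices = build_matrices(subject_maps, parc, config.min_voxels,
                              tuple(config.metrics), order + extra)
    nvc_dir = out_root / "nvc"
    nvc_dir.mkdir(parents=True, exist_ok=True)
    for (metric, gran), m in matrices.items():
        sidecar = {"metric_pair": f"{metric}-CBF", "granularity": gran,
                   "min_voxels": config.min_voxels,
                   "missing": {f"{k[0]}/{k[1]}": v for k, v in m.missing.items()}}
        nio.save_matrix_tsv(nvc_dir / f"nvc_{metric.lower()}_{gran}.tsv",
                            m.data, sidecar)
        if m.counts is not None:
            m.counts.to_csv(nvc_dir / f"nvc_{metric.lower()}_{gran}_counts.tsv",
                            sep="\t", index_label="subject")
    return matrices


def run_stats(config: PipelineConfig) -> dict:
    """Progression clustering, group-effect scans, ECAS correlations, ROC."""
    root = Path(config.cohort_root)
    out_root = Path(config.output_root)
    nvc_dir = out_root / "nvc"
    clinical = pd.read_csv(root / "clinical.tsv", sep="\t", index_col="subject")
    results: dict = {"config": config.to_dict()}

    patients = clinical[clinical["group"] == "ALS"]
    assign = cluster_progression(patients["delta_alsfrs"].to_numpy(),
                                 k=config.k_clusters, seed=config.seed)
    clinical = clinical.copy()
    clinical.loc[patients.index, "progression_kmeans"] = assign.labels
    results["progression"] = {
        "centroids": assign.centroids.tolist(),
        "sizes": assign.sizes.tolist(),
        "monthly_rates": assign.monthly_rates.tolist(),
    }

    from .types import NvcMatrix
    scans = {}
    for metric in config.metrics:
        for gran in ("network", "region"):
            path = nvc_dir / f"nvc_{metric.lower()}_{gran}.tsv"
            if not path.exists():
                raise MissingInputError(f"stats: missing NVC matrix {path}")
            data = nio.load_matrix_tsv(path)
            matrix = NvcMatrix(metric=metric, granularity=gran, data=data)
            res = group_effect_scan(matrix, clinical, "group", config.fdr_q)
            scans[f"{metric}_{gran}"] = res
            results[f"scan_{metric}_{gran}"] = {
                "significant": res.significant_units,
                "table": json.loads(res.table.to_json(orient="index")),
                "model": res.model,
            }

    alff_net = nio.load_matrix_tsv(nvc_dir / "nvc_alff_network.tsv")
    dmn = alff_net.loc[patients.index, "DMN"]
    ecas_cols = [c for c in ECAS_SCORE_COLUMNS if c in clinical.columns]
    corr = correlate_with_scores(dmn, patients[ecas_cols], config.fdr_q)
    results["ecas_correlations"] = json.loads(corr.drop(columns="reason")
                                              .to_json(orient="index"))

    vfp_sp = clinical.loc[patients.index]
    sel = vfp_sp["progression_kmeans"].isin(["VFP", "SP"])
    roc_subjects = vfp_sp.index[sel]
    roc = roc_auc(alff_net.loc[roc_subjects, "DMN"].to_numpy(),
                  vfp_sp.loc[roc_subjects, "progression_kmeans"].to_numpy(),
                  positive="SP", n_boot=config.n_boot, seed=config.seed)
    results["roc_vfp_vs_sp_dmn_alff"] = {
        "auc": roc.auc, "ci": list(roc.ci), "positive": str(roc.positive_label),
        "n": int(sel.sum()),
    }

    stats_dir = out_root / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    (stats_dir / "stats.json").write_text(json.dumps(results, indent=1))
    _write_report(stats_dir / "report.md", results, scans)
    return results


def _write_report(path: Path, results: dict, scans: dict) -> None:
    lines = ["# NVC cohort statistics", ""]
    prog = results["progression"]
    lines += ["## Progression stratification (k-means on ΔALSFRS-R)", ""]
    for name, c, n, r in zip(("VFP", "FP", "SP"), prog["centroids"],
                             prog["sizes"], prog["monthly_rates"]):
        lines.append(f"- {name}: centroid {c:.2f}, n={n}, {r:.2f} points/month")
    lines += ["", "## Group-effect scans (FDR within each matrix)", ""]
    for key, res in scans.items():
        sig = ", ".join(res.significant_units) or "none"
        lines.append(f"- {key}: significant units: {sig}")
    roc = results["roc_vfp_vs_sp_dmn_alff"]
    lines += ["", "## ROC: DMN NVC(ALFF-CBF), VFP vs SP", "",
              f"- AUC {100 * roc['auc']:.1f}% "
              f"(CI {100 * roc['ci'][0]:.1f}%-{100 * roc['ci'][1]:.1f}%)"]
    path.write_text("\n".join(lines) + "\n")


def run_stage(stage: str, config: PipelineConfig):
    """Dispatch one pipeline stage (see STAGES); 'all' runs them in order."""
    Path(config.output_root).mkdir(parents=True, exist_ok=True)
    (Path(config.output_root) / "config.json").write_text(
        json.dumps(config.to_dict(), indent=1))
    if stage == "simulate":
        return run_simulate(config)
    if stage == "features":
        return run_features(config)
    if stage == "cbf":
        return run_cbf(config)
    if stage == "nvc":
        return run_nvc(config)
    if stage == "stats":
        return run_stats(config)
    if stage == "all":
        out = None
        for s in STAGES:
            out = run_stage(s, config)
        return out
    raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES + ('all',)}")
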