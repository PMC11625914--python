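"""Reproducibility studies: parameter recovery, scan power and calibration,
printed-table reconstruction.

These functions re-run the package's own machinery on generated data and
return scalar summaries; they back both the acceptance script and the
statistical acceptance tests.  Problem sizes default to desk scale (7-region
atlas on a 16x16x12 grid, 80 timepoints) so a full study completes in minutes
on one CPU; all randomness flows from an explicit seed.
"""
from __future__ import annotations

import numpy as np

from . import reference as ref
from .cbf import compute_cbf
from .features import compute_alff, nuisance_regress, zscore_map
from .nvc import fisher_z, networkwise_nvc
from .stats import (anova_from_summary, chi_square_counts, cluster_progression,
                    group_effect_scan, monthly_rate, optimal_1d_partition,
                    pooled_mean)
from .synthetic import (CohortSpec, generate_atlas, generate_clinical,
                        generate_ground_truth, generate_subject_images,
                        make_tissue_masks, simulate_nvc_cohort)
from .types import NETWORK_NAMES


def _desk_spec(seed: int, **overrides) -> CohortSpec:
    kw = dict(grid=(16, 16, 12), n_timepoints=80, n_regions=7, seed=seed)
    kw.update(overrides)
    return CohortSpec(**kw)


def _sub_seed(seed: int, offset: int) -> int:
    return int((seed * 1000003 + offset) % (2 ** 31 - 1))


# --------------------------------------------------------------------------
# printed-table reconstruction (deterministic)
# --------------------------------------------------------------------------

def table_reconstruction() -> dict:
    """Pooled 12-month means and one-way ANOVA F values recomputed from the
    reference cohort's per-subgroup (n, mean, SD) cells, plus the age ANOVA
    and the sex chi-squared of the patient/control comparison."""
    out: dict = {}
    for row, cells in ref.ALSFRS_12M_SUBGROUPS.items():
        out[f"pooled_mean_{row}"] = pooled_mean(cells)
        f, *_ = anova_from_summary(cells)
        out[f"anova_f_{row}"] = f
    f_age, *_ = anova_from_summary(ref.AGE_GROUPS)
    out["anova_f_age"] = f_age
    out["chi2_sex"], _ = chi_square_counts(ref.SEX_TABLE)
    out["fp_monthly_rate"] = monthly_rate(ref.FP_DELTA_MEAN)
    return out


# --------------------------------------------------------------------------
# planted-coupling recovery (image path)
# --------------------------------------------------------------------------

def estimate_subject_network_z(spec: CohortSpec, sid: str, truth, parc,
                               masks) -> np.ndarray:
    """Generate one subject and estimate the 7 network Fisher-z couplings
    through the analysis path (nuisance regression -> ALFF -> CBF -> NVC;
    no spatial smoothing, since the planted pattern lives at voxel scale)."""
    imgs = generate_subject_images(spec, sid, truth, parc, masks)
    clean = nuisance_regress(imgs.bold, imgs.motion, imgs.masks)
    alff_z = zscore_map(compute_alff(clean), masks.brain)
    cbf_z = zscore_map(compute_cbf(imgs.perfusion, imgs.acq, masks.brain),
                       masks.brain)
    r = networkwise_nvc(cbf_z, alff_z, parc)["r"].to_numpy()
    return fisher_z(r)


def recovery_study(seed: int, n_cohorts: int = 20,
                   subjects_per_cohort: int = 2) -> dict:
    """Mean absolute error between planted and estimated Fisher-z coupling
    across seeded cohorts, at default generator noise."""
    errors = []
    for c in range(n_cohorts):
        # default-size grid: every network holds >= 500 voxels
        spec = CohortSpec(seed=_sub_seed(seed, c),
                          n_patients=subjects_per_cohort, n_controls=0)
        parc = generate_atlas(spec)
        masks = make_tissue_masks(spec)
        truth = generate_ground_truth(spec)
        for sid in spec.subject_ids:
            est = estimate_subject_network_z(spec, sid, truth, parc, masks)
            errors.append(np.abs(est - truth.coupling_z.loc[sid].to_numpy()))
    return {
        "mae_fisher_z": float(np.mean(errors)),
        "n_estimates": int(np.size(errors)),
    }


# --------------------------------------------------------------------------
# group-effect scan: power and calibration (subject-level coupling model)
# --------------------------------------------------------------------------

def power_study(seed: int, n_cohorts: int = 50) -> dict:
    """Detection rate of a DMN-only group reduction of one pooled SD
    (the generator default: Fisher-z shift = coupling_sd) at FDR 5%,
    48 patients vs 32 controls."""
    dmn_hits = 0
    other_hits = np.zeros(6)
    others = [n for n in NETWORK_NAMES if n != "DMN"]
    for c in range(n_cohorts):
        spec = CohortSpec(seed=_sub_seed(seed, 10_000 + c))
        matrix, clinical = simulate_nvc_cohort(spec)
        res = group_effect_scan(matrix, clinical)
        flags = res.table["significant"]
        dmn_hits += bool(flags["DMN"])
        other_hits += flags[others].to_numpy(bool)
    return {
        "dmn_detection_rate": dmn_hits / n_cohorts,
        "max_off_target_rate": float(other_hits.max() / n_cohorts),
        "n_cohorts": n_cohorts,
    }


def _null_spec(seed: int) -> CohortSpec:
    rho = {net: {"ALS": 0.35, "HC": 0.35} for net in NETWORK_NAMES}
    return CohortSpec(planted_rho=rho, seed=seed)


def type1_study(seed: int, n_cohorts: int = 100) -> dict:
    """Empirical type-I error of the per-column group test under the null
    generator (no group effect in any network), at nominal alpha = 0.05."""
    n_tests, n_hits = 0, 0
    for c in range(n_cohorts):
        matrix, clinical = simulate_nvc_cohort(_null_spec(_sub_seed(seed, 20_000 + c)))
        res = group_effect_scan(matrix, clinical)
        p = res.table["p"].to_numpy()
        n_tests += p.size
        n_hits += int((p < 0.05).sum())
    return {"type1_error_rate": n_hits / n_tests, "n_tests": n_tests}


def fdr_study(seed: int, n_cohorts: int = 200) -> dict:
    """Empirical false discovery rate of the BH-corrected 7-network scan
    under the null generator (every rejection is false, so per-cohort
    V / max(R, 1) is 1 exactly when anything is rejected)."""
    fdp = []
    for c in range(n_cohorts):
        matrix, clinical = simulate_nvc_cohort(_null_spec(_sub_seed(seed, 30_000 + c)))
        res = group_effect_scan(matrix, clinical)
        r = int(res.table["significant"].sum())
        fdp.append(r / max(r, 1))
    return {"empirical_fdr": float(np.mean(fdp)), "n_cohorts": n_cohorts}


# --------------------------------------------------------------------------
# progression stratification
# --------------------------------------------------------------------------

def stratification_study(seed: int) -> dict:
    """Error count of k-means stratification on generated ΔALSFRS-R data with
    the default planted centroids (-41, -14, -4) and SD 1.5, plus agreement
    with the exhaustive contiguous-partition optimum."""
    spec = _desk_spec(seed, n_patients=48, n_controls=0)
    truth = generate_ground_truth(spec)
    clinical = generate_clinical(spec, truth)
    pats = clinical[clinical["group"] == "ALS"]
    delta = pats["delta_alsfrs"].to_numpy(float)
    assign = cluster_progression(delta, seed=seed)
    errors = int((assign.labels != truth.cluster_labels.loc[pats.index]).sum())
    oracle_labels, _ = optimal_1d_partition(delta, k=3)
    import pandas as pd
    ours = pd.factorize(assign.labels)[0]
    same_partition = len(set(zip(ours.tolist(), oracle_labels.tolist()))) == 3
    return {
        "misassignments": errors,
        "matches_optimal_partition": bool(same_partition),
        "fp_centroid": float(assign.centroids[1]),
        "fp_monthly_rate": float(assign.monthly_rates[1]),
        "n_patients": len(delta),
    }
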