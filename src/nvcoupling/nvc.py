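"""Neurovascular coupling: spatial CBF-feature correlation per region/network.

The NVC statistic is the Pearson correlation, across all voxels of an atlas
region or of a whole network (voxels pooled over the network's regions, never
an average of per-region R values), between a CBF map and a neural-activity
surrogate map (ALFF, ReHo or DC).  R values are Fisher z-transformed and
assembled into subjects x units matrices for group statistics.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import NETWORK_NAMES, FeatureMap, NvcMatrix, Parcellation

logger = logging.getLogger(__name__)

#: correlations are clipped to +/- (1 - CLIP) before atanh so that degenerate
#: synthetic inputs (exact +/-1) keep a finite z
_CLIP = 1e-7


def fisher_z(r):
    """Fisher z transform, z = atanh(r), with |r| clipped at 1 - 1e-7."""
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r) | np.isnan(r)):
        raise ValueError("non-finite correlation value")
    out = np.arctanh(np.clip(r, -1 + _CLIP, 1 - _CLIP))
    out = np.where(np.isnan(r), np.nan, out)
    return float(out) if out.ndim == 0 else out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def _unit_nvc(cbf: FeatureMap, feat: FeatureMap, unit_mask: np.ndarray,
              min_voxels: int) -> tuple[float, int, str | None]:
    sel = unit_mask & np.isfinite(cbf.values) & np.isfinite(feat.values)
    n = int(sel.sum())
    if n < min_voxels:
        return np.nan, n, f"only {n} usable voxels (< {min_voxels})"
    r = _pearson(cbf.values[sel], feat.values[sel])
    if np.isnan(r):
        return np.nan, n, "zero variance within unit"
    return r, n, None


def regionwise_nvc(cbf: FeatureMap, feat: FeatureMap, parc: Parcellation,
                   min_voxels: int = 10) -> pd.DataFrame:
    """Pearson R between CBF and feature map over each region's voxels.

    Returns a DataFrame indexed by region id with columns r, n_voxels, reason
    (NaN r and a reason string for regions below ``min_voxels`` or with zero
    variance). Voxels with NaN in either map are dropped pairwise.
    """
    _check_grids(cbf, feat, parc)
    rows = []
    for rid in parc.region_ids:
        r, n, reason = _unit_nvc(cbf, feat, parc.labels == rid, min_voxels)
        if reason:
            logger.warning("region %d: %s", rid, reason)
        rows.append((rid, r, n, reason))
    return pd.DataFrame(rows, columns=["id", "r", "n_voxels", "reason"]).set_index("id")


def networkwise_nvc(cbf: FeatureMap, feat: FeatureMap, parc: Parcellation,
                    min_voxels: int = 10) -> pd.DataFrame:
    """Pearson R over the pooled voxels of each of the 7 networks (atlas order)."""
    _check_grids(cbf, feat, parc)
    rows = []
    for net in NETWORK_NAMES:
        r, n, reason = _unit_nvc(cbf, feat, parc.network_mask(net), min_voxels)
        if reason:
            logger.warning("network %s: %s", net, reason)
        rows.append((net, r, n, reason))
    return pd.DataFrame(rows, columns=["network", "r", "n_voxels", "reason"]
                        ).set_index("network")


def _check_grids(cbf: FeatureMap, feat: FeatureMap, parc: Parcellation) -> None:
    if not (cbf.values.shape == feat.values.shape == parc.labels.shape):
        raise ValueError("CBF map, feature map and parcellation grids differ")


def build_matrices(subject_maps: dict[str, dict[str, FeatureMap]],
                   parc: Parcellation, min_voxels: int = 10,
                   metrics: tuple[str, ...] = ("ALFF", "ReHo", "DC"),
                   subject_order: list[str] | None = None,
                   ) -> dict[tuple[str, str], NvcMatrix]:
    """Assemble Fisher-z NVC matrices for every metric x granularity.

    ``subject_maps`` maps subject id -> {"CBF": map, "ALFF": map, ...}; every
    map must be z-scored on the shared grid.  Returns a dict keyed by
    (metric, granularity) with granularity in {"network", "region"}.  Subject
    order follows ``subject_order`` when given (e.g. the clinical table).
    """
    subjects = list(subject_order) if subject_order is not None else sorted(subject_maps)
    missing_subj = [s for s in subjects if s not in subject_maps]
    if missing_subj:
        raise ValueError(f"no maps for subjects: {missing_subj}")
    for s in subjects:
        lacking = [m for m in ("CBF", *metrics) if m not in subject_maps[s]]
        if lacking:
            raise ValueError(f"subject {s} lacks maps: {lacking}")
    region_cols = [str(i) for i in parc.region_ids]
    out: dict[tuple[str, str], NvcMatrix] = {}
    for metric in metrics:
        net_z, net_n, reg_z, reg_n, miss = [], [], [], [], {}
        for s in subjects:
            cbf, feat = subject_maps[s]["CBF"], subject_maps[s][metric]
            nets = networkwise_nvc(cbf, feat, parc, min_voxels)
            regs = regionwise_nvc(cbf, feat, parc, min_voxels)
            net_z.append(fisher_z(nets["r"].to_numpy()))
            net_n.append(nets["n_voxels"].to_numpy())
            reg_z.append(fisher_z(regs["r"].to_numpy()))
            reg_n.append(regs["n_voxels"].to_numpy())
            for unit, reason in nets.loc[nets["reason"].notna(), "reason"].items():
                miss[(s, unit)] = reason
            for unit, reason in regs.loc[regs["reason"].notna(), "reason"].items():
                miss[(s, str(unit))] = reason
        out[(metric, "network")] = NvcMatrix(
            metric=metric, granularity="network",
            data=pd.DataFrame(net_z, index=subjects, columns=list(NETWORK_NAMES)),
            counts=pd.DataFrame(net_n, index=subjects, columns=list(NETWORK_NAMES)),
            missing={k: v for k, v in miss.items() if k[1] in NETWORK_NAMES})
        out[(metric, "region")] = NvcMatrix(
            metric=metric, granularity="region",
            data=pd.DataFrame(reg_z, index=subjects, columns=region_cols),
            counts=pd.DataFrame(reg_n, index=subjects, columns=region_cols),
            missing={k: v for k, v in miss.items() if k[1] not in NETWORK_NAMES})
    return out
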