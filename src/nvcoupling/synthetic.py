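"""Self-contained synthetic resting-state cohort with known ground truth.

The generator emulates the data model of a PCASL + resting-state fMRI study
of ALS patients and healthy controls, already co-registered on one grid:

* an atlas of contiguous regions partitioning a rounded-box "brain" mask,
  assigned to the 7 canonical networks;
* per subject, a BOLD series built from region-specific band-limited
  (0.01-0.1 Hz) signals times a per-voxel spatial loading, plus a linear
  motion confound and white noise (WM/CSF voxels carry no neural signal);
* a perfusion-weighted / proton-density pair whose implied CBF map has, within
  each network, an *exact* planted spatial correlation rho with the subject's
  true ALFF pattern (closed-form mixing with an orthogonalized random field);
* a clinical table with three planted progression clusters on
  12-month ALSFRS-R change and ECAS subscores correlated with the subject's
  true DMN coupling.

Every quantity used for generation is recorded in :class:`GroundTruth`, so
downstream stages can be tested by parameter recovery.
"""
from __future__ import annotations

import zlib
from collections import deque
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .cbf import AcqParams, PerfusionPair
from .features import bandpass, compute_alff
from .types import (NETWORK_NAMES, BoldSeries, MotionParams, NvcMatrix,
                    Parcellation, TissueMasks)

#: per-voxel signal loading is uniform on [0.5, 1.5] times this scale,
#: against unit-variance band-limited region signals and ``noise_sd`` noise
SIGNAL_SCALE = 3.0

#: physical CBF map = CBF_BASELINE + CBF_SPREAD * planted spatial pattern
CBF_BASELINE, CBF_SPREAD = 50.0, 12.0

#: post-labelling delays (s) and sampling weights emulating a multi-protocol
#: cohort (one PLD per subject)
PLD_CHOICES = (2.525, 2.025, 1.525)
PLD_WEIGHTS = (30, 40, 3)

#: ECAS subscore (mean, sd, max) used for patient score generation
ECAS_SPECS = {
    "ecas_language": (19.67, 6.12, 28),
    "ecas_fluency": (13.61, 7.55, 24),
    "ecas_executive": (24.74, 11.14, 48),
    "ecas_memory": (12.57, 5.38, 24),
    "ecas_visuospatial": (10.43, 1.79, 12),
}

#: baseline ALSFRS-R subscore (mean, sd) on the 0-12 scale
_ALSFRS_BASELINE = {
    "bulbar": (10.71, 1.78),
    "upper_limbs": (9.50, 2.63),
    "lower_limbs": (9.25, 2.49),
    "respiratory": (11.69, 0.77),
}


def _default_rho() -> dict:
    """Planted within-network CBF-ALFF correlation per network and group.

    Healthy-control coupling 0.35 in every network; patients identical except
    a DMN reduction of one between-subject SD on the Fisher-z scale
    (atanh(0.35) - 0.15 -> r = 0.212), the qualitative group effect the
    statistics layer is designed to detect.
    """
    rho = {net: {"ALS": 0.35, "HC": 0.35} for net in NETWORK_NAMES}
    rho["DMN"] = {"ALS": float(np.tanh(np.arctanh(0.35) - 0.15)), "HC": 0.35}
    return rho


@dataclass
class CohortSpec:
    """Study conditions for the synthetic cohort (group sizes, grid, planted
    effects).  Defaults mirror the emulated study: 48 patients / 32 controls,
    progression clusters of 8/13/27 with centroids (-41, -14, -4)."""

    n_patients: int = 48
    n_controls: int = 32
    grid: tuple[int, int, int] = (24, 24, 18)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 120
    tr_s: float = 1.5
    n_regions: int = 100
    planted_rho: dict = dc_field(default_factory=_default_rho)
    noise_sd: float = 1.0
    motion_amplitude: float = 0.5
    progression_centroids: tuple[float, float, float] = (-41.0, -14.0, -4.0)
    progression_sd: float = 1.5
    ecas_coupling_r: float = 0.4
    coupling_sd: float = 0.15  # between-subject SD of true Fisher-z coupling
    progression_sizes: tuple[int, int, int] | None = None  # VFP, FP, SP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 7:
            raise ValueError("need at least one region per network (n_regions >= 7)")
        if self.tr_s <= 0 or self.voxel_size_mm <= 0:
            raise ValueError("tr_s and voxel_size_mm must be positive")
        if self.noise_sd < 0 or self.progression_sd <= 0:
            raise ValueError("noise_sd must be >= 0 and progression_sd > 0")
        for net, by_group in self.planted_rho.items():
            for g, r in by_group.items():
                if not abs(r) < 1:
                    raise ValueError(f"planted rho for {net}/{g} must satisfy |rho| < 1")
        if not abs(self.ecas_coupling_r) < 1:
            raise ValueError("ecas_coupling_r must satisfy |r| < 1")
        c = self.progression_centroids
        if not (c[0] < c[1] < c[2]):
            raise ValueError("progression centroids must be strictly increasing "
                             "(VFP most negative)")

    @property
    def subject_ids(self) -> list[str]:
        pats = [f"sub-P{i:03d}" for i in range(1, self.n_patients + 1)]
        ctls = [f"sub-C{i:03d}" for i in range(1, self.n_controls + 1)]
        return pats + ctls

    def group_of(self, subject_id: str) -> str:
        return "ALS" if subject_id.startswith("sub-P") else "HC"


@dataclass
class GroundTruth:
    """Planted values exactly as used for generation (seed-reproducible)."""

    spec: CohortSpec
    coupling_z: pd.DataFrame     # subjects x networks, true Fisher-z coupling
    cluster_labels: pd.Series    # per patient: VFP/FP/SP
    ecas_coupling_r: float
    pld_s: pd.Series             # per subject
    alff_patterns: dict = dc_field(default_factory=dict)  # subject -> 3D volume
    cbf_patterns: dict = dc_field(default_factory=dict)   # subject -> 3D volume

    @property
    def coupling_r(self) -> pd.DataFrame:
        return np.tanh(self.coupling_z)

    def scalars(self) -> dict:
        """JSON-serializable sidecar of all planted scalars."""
        return {
            "seed": self.spec.seed,
            "planted_rho": self.spec.planted_rho,
            "coupling_z": {s: dict(zip(self.coupling_z.columns, row))
                           for s, row in zip(self.coupling_z.index,
                                             self.coupling_z.to_numpy().tolist())},
            "cluster_labels": self.cluster_labels.to_dict(),
            "ecas_coupling_r": self.ecas_coupling_r,
            "pld_s": self.pld_s.to_dict(),
        }


def _subject_rng(spec: CohortSpec, subject_id: str, stream: str) -> np.random.Generator:
    """Per-subject substream: global seed fanned out by stable CRC hashing."""
    tag = zlib.crc32(f"{stream}/{subject_id}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, tag]))


# --------------------------------------------------------------------------
# atlas and tissue masks
# --------------------------------------------------------------------------

def _superellipsoid(grid: tuple[int, int, int], scale: float = 1.0,
                    margin: float = 0.5) -> np.ndarray:
    """Rounded-box mask |x/a|^4 + |y/b|^4 + |z/c|^4 <= 1 (a box-filling brain
    stand-in: an ellipsoid cannot host 100 regions of >= 50 voxels on the
    default grid)."""
    axes = [(n - 1) / 2.0 for n in grid]
    semi = [max(a - margin, 1.0) * scale for a in axes]
    coords = np.meshgrid(*[np.arange(n) for n in grid], indexing="ij")
    r = sum(((c - a) / s) ** 4 for c, a, s in zip(coords, axes, semi))
    return r <= 1.0


def make_tissue_masks(spec: CohortSpec) -> TissueMasks:
    """Deterministic brain / WM / CSF masks shared by all subjects.

    WM is a central core, CSF a thin shell just inside the brain boundary;
    both are subsets of the brain mask and carry no neural signal in the
    generator.
    """
    brain = _superellipsoid(spec.grid)
    wm = _superellipsoid(spec.grid, scale=0.40)
    csf = brain & ~_superellipsoid(spec.grid, scale=0.95)
    return TissueMasks(brain=brain, wm=wm & ~csf, csf=csf)


def generate_atlas(spec: CohortSpec) -> Parcellation:
    """Partition the brain mask into ``n_regions`` contiguous regions of
    near-equal size by competitive region growing from farthest-point seeds,
    and assign regions to the 7 networks in contiguous id blocks."""
    brain = _superellipsoid(spec.grid)
    n_vox = int(brain.sum())
    if n_vox // spec.n_regions < 50:
        raise ValueError(
            f"grid too small: {n_vox} brain voxels cannot host {spec.n_regions} "
            "regions of >= 50 voxels")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 1]))
    coords = np.argwhere(brain)
    # farthest-point seeding for well-spread, deterministic seeds
    seeds = [rng.integers(len(coords))]
    d = np.linalg.norm(coords - coords[seeds[0]], axis=1)
    for _ in range(spec.n_regions - 1):
        nxt = int(np.argmax(d))
        seeds.append(nxt)
        d = np.minimum(d, np.linalg.norm(coords - coords[nxt], axis=1))
    labels = np.zeros(spec.grid, dtype=np.int32)
    queues = []
    for rid, si in enumerate(seeds, start=1):
        labels[tuple(coords[si])] = rid
        queues.append(deque([tuple(coords[si])]))
    sizes = np.ones(spec.n_regions, dtype=int)
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    active = set(range(spec.n_regions))
    while active:
        # grow the currently smallest region for near-equal sizes
        rid_idx = min(active, key=lambda i: (sizes[i], i))
        q = queues[rid_idx]
        grew = False
        while q and not grew:
            x, y, z = q.popleft()
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (0 <= nx < spec.grid[0] and 0 <= ny < spec.grid[1]
                        and 0 <= nz < spec.grid[2] and brain[nx, ny, nz]
                        and labels[nx, ny, nz] == 0):
                    labels[nx, ny, nz] = rid_idx + 1
                    sizes[rid_idx] += 1
                    q.append((x, y, z))  # revisit: may have more free neighbors
                    q.append((nx, ny, nz))
                    grew = True
                    break
        if not grew:
            active.discard(rid_idx)
    if (labels[brain] == 0).any():
        raise RuntimeError("region growing left unassigned brain voxels")
    labels = _balance_regions(labels, sizes, offsets, min_size=50)
    sizes = np.bincount(labels.ravel(), minlength=spec.n_regions + 1)[1:]
    if sizes.min() < 50:
        raise ValueError(f"smallest region has {sizes.min()} voxels (< 50); "
                         "increase grid or reduce n_regions")
    sizes = np.bincount(labels.ravel(), minlength=spec.n_regions + 1)[1:]
    # contiguous id blocks per network, DMN last
    base, extra = divmod(spec.n_regions, 7)
    block_sizes = [base + (1 if i < extra else 0) for i in range(7)]
    nets, names = [], []
    rid = 1
    for net, bs in zip(NETWORK_NAMES, block_sizes):
        for j in range(bs):
            nets.append(net)
            names.append(f"{net.replace(' ', '_')}_{j + 1}")
            rid += 1
    regions = pd.DataFrame({
        "id": np.arange(1, spec.n_regions + 1),
        "name": names,
        "network": nets,
    })
    return Parcellation(labels=labels, regions=regions)


def _balance_regions(labels: np.ndarray, sizes: np.ndarray, offsets,
                     min_size: int = 50, max_steals: int = 5000) -> np.ndarray:
    """Deterministically transfer boundary voxels from large regions into
    undersized neighbors until every region reaches ``min_size`` (regions can
    get pinched against the mask boundary during competitive growth).
    Transfers keep both donor and acceptor contiguous."""
    labels = labels.copy()
    sizes = sizes.copy()
    for _ in range(max_steals):
        rid_small = int(np.argmin(sizes)) + 1
        if sizes[rid_small - 1] >= min_size:
            return labels
        coords = np.argwhere(labels == rid_small)
        candidates = []  # (donor size, donor id, voxel)
        for x, y, z in coords:
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if not (0 <= nx < labels.shape[0] and 0 <= ny < labels.shape[1]
                        and 0 <= nz < labels.shape[2]):
                    continue
                donor = labels[nx, ny, nz]
                if donor > 0 and donor != rid_small:
                    candidates.append((-sizes[donor - 1], donor, (nx, ny, nz)))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        moved = False
        for _, donor, vox in candidates:
            labels[vox] = rid_small
            donor_mask = labels == donor
            n_comp = ndimage.label(donor_mask)[1]
            if n_comp == 1 and sizes[donor - 1] - 1 > min_size:
                sizes[donor - 1] -= 1
                sizes[rid_small - 1] += 1
                moved = True
                break
            labels[vox] = donor  # undo: donor would disconnect or shrink too far
        if not moved:
            raise RuntimeError(f"cannot rebalance region {rid_small} to {min_size} voxels")
    raise RuntimeError("region balancing did not converge")


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

def _cluster_sizes(spec: CohortSpec) -> tuple[int, int, int]:
    if spec.progression_sizes is not None:
        if sum(spec.progression_sizes) != spec.n_patients:
            raise ValueError("progression_sizes must sum to n_patients")
        return tuple(spec.progression_sizes)
    # largest-remainder scaling of the 8/13/27 split
    props = np.array([8, 13, 27], dtype=float) / 48.0
    raw = props * spec.n_patients
    sizes = np.floor(raw).astype(int)
    rem = spec.n_patients - sizes.sum()
    for i in np.argsort(-(raw - sizes))[:rem]:
        sizes[i] += 1
    return tuple(int(s) for s in sizes)


def generate_ground_truth(spec: CohortSpec) -> GroundTruth:
    """Draw the planted per-subject coupling, cluster labels and PLDs."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 2]))
    subjects = spec.subject_ids
    z = np.empty((len(subjects), len(NETWORK_NAMES)))
    for i, sid in enumerate(subjects):
        g = spec.group_of(sid)
        for j, net in enumerate(NETWORK_NAMES):
            z[i, j] = np.arctanh(spec.planted_rho[net][g]) + \
                spec.coupling_sd * rng.standard_normal()
    coupling_z = pd.DataFrame(z, index=subjects, columns=list(NETWORK_NAMES))
    if not (np.abs(np.tanh(coupling_z.to_numpy())) < 1).all():
        raise ValueError("planted coupling left the open interval (-1, 1)")
    sizes = _cluster_sizes(spec)
    labels = np.repeat(["VFP", "FP", "SP"], sizes)
    rng.shuffle(labels)
    patients = [s for s in subjects if spec.group_of(s) == "ALS"]
    pld = rng.choice(PLD_CHOICES, size=len(subjects),
                     p=np.array(PLD_WEIGHTS) / sum(PLD_WEIGHTS))
    return GroundTruth(
        spec=spec,
        coupling_z=coupling_z,
        cluster_labels=pd.Series(labels, index=patients, name="progression"),
        ecas_coupling_r=spec.ecas_coupling_r,
        pld_s=pd.Series(pld, index=subjects, name="pld_s"),
    )


# --------------------------------------------------------------------------
# subject images
# --------------------------------------------------------------------------

@dataclass
class SubjectImages:
    bold: BoldSeries
    perfusion: PerfusionPair
    motion: MotionParams
    masks: TissueMasks
    acq: AcqParams


def _bandlimited_signal(rng: np.random.Generator, t: int, tr_s: float,
                        brain_mask_dummy: np.ndarray | None = None) -> np.ndarray:
    """Unit-variance band-limited (0.01-0.1 Hz) time course."""
    white = rng.standard_normal(t)
    series = BoldSeries(values=white.reshape(1, 1, 1, t), tr_s=tr_s,
                        brain_mask=np.ones((1, 1, 1), dtype=bool))
    sig = bandpass(series).values.ravel()
    sd = sig.std()
    return sig / sd if sd > 0 else sig


def generate_motion(spec: CohortSpec, rng: np.random.Generator) -> MotionParams:
    """Six smoothed random walks scaled to ``motion_amplitude`` (mm / deg)."""
    t = spec.n_timepoints
    walks = np.cumsum(rng.standard_normal((t, 6)), axis=0)
    walks = ndimage.gaussian_filter1d(walks, sigma=5.0, axis=0)
    walks -= walks.mean(axis=0)
    sd = walks.std(axis=0)
    sd[sd == 0] = 1.0
    return MotionParams(values=walks / sd * spec.motion_amplitude)


def generate_subject_images(spec: CohortSpec, subject_id: str,
                            truth: GroundTruth, parc: Parcellation,
                            masks: TissueMasks | None = None) -> SubjectImages:
    """Generate one subject's BOLD series, perfusion pair and motion table.

    The BOLD model is ``loading * region_signal + motion @ weights + noise``
    with zero loading in WM/CSF; the perfusion-weighted volume is constructed
    so that ``compute_cbf`` returns a map whose within-network correlation
    with the subject's true ALFF pattern equals the planted rho exactly.
    """
    if masks is None:
        masks = make_tissue_masks(spec)
    rng = _subject_rng(spec, subject_id, "images")
    t, grid = spec.n_timepoints, spec.grid
    brain = masks.brain
    nosignal = masks.wm | masks.csf

    signal = np.zeros((*grid, t))
    loading = np.zeros(grid)
    for rid in parc.region_ids:
        sel = parc.labels == rid
        s_r = _bandlimited_signal(rng, t, spec.tr_s)
        a = rng.uniform(0.5, 1.5, size=int(sel.sum())) * SIGNAL_SCALE
        loading[sel] = a
        signal[sel] = a[:, None] * s_r[None, :]
    loading[nosignal] = 0.0
    signal[nosignal] = 0.0

    truth_series = BoldSeries(values=signal, tr_s=spec.tr_s, brain_mask=brain)
    alff_pattern = compute_alff(truth_series).values
    alff_pattern[~brain] = 0.0

    motion = generate_motion(spec, rng)
    bold = signal.copy()
    if spec.motion_amplitude > 0:
        w = rng.normal(0.0, 0.3, size=(*grid, 6))
        w[~brain] = 0.0
        bold += np.einsum("xyzk,tk->xyzt", w, motion.values)
    if spec.noise_sd > 0:
        bold[brain] += rng.normal(0.0, spec.noise_sd, size=(int(brain.sum()), t))

    cbf_pattern = _planted_cbf_pattern(spec, subject_id, truth, parc, alff_pattern, rng)
    acq = AcqParams(pld_s=float(truth.pld_s[subject_id]))
    cbf_vals = np.zeros(grid)
    cbf_vals[brain] = CBF_BASELINE + CBF_SPREAD * cbf_pattern[brain]
    pd_vol = np.full(grid, 1000.0)
    pw_vol = cbf_vals * pd_vol / acq.scale

    truth.alff_patterns[subject_id] = alff_pattern
    truth.cbf_patterns[subject_id] = cbf_vals

    return SubjectImages(
        bold=BoldSeries(values=bold, tr_s=spec.tr_s, brain_mask=brain),
        perfusion=PerfusionPair(pw=pw_vol, pd=pd_vol),
        motion=motion,
        masks=masks,
        acq=acq,
    )


def _planted_cbf_pattern(spec: CohortSpec, subject_id: str, truth: GroundTruth,
                         parc: Parcellation, alff_pattern: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Exact linear mixing: per network, pattern = rho*A_z + sqrt(1-rho^2)*E_z
    with E orthogonalized against the z-scored true ALFF pattern A_z."""
    pattern = np.zeros(spec.grid)
    for net in NETWORK_NAMES:
        rho = float(np.tanh(truth.coupling_z.loc[subject_id, net]))
        if not abs(rho) < 1:
            raise ValueError(f"|rho| >= 1 for {subject_id}/{net}")
        sel = parc.network_mask(net)
        a = alff_pattern[sel]
        if a.std() == 0:
            raise ValueError(f"degenerate ALFF pattern in network {net}")
        a_z = (a - a.mean()) / a.std()
        e = rng.standard_normal(a.size)
        e = e - e.mean()
        e = e - (e @ a_z) / (a_z @ a_z) * a_z
        e_z = e / e.std()
        pattern[sel] = rho * a_z + np.sqrt(1.0 - rho ** 2) * e_z
    return pattern


# --------------------------------------------------------------------------
# clinical table
# --------------------------------------------------------------------------

def _distribute_total(total: int, weights: np.ndarray, cap: int = 12) -> np.ndarray:
    """Split ``total`` into len(weights) integer parts in [0, cap],
    proportional to ``weights`` (largest-remainder rounding)."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() == 0:
        weights = np.ones_like(weights)
    raw = weights / weights.sum() * total
    parts = np.floor(raw).astype(int)
    rem = total - parts.sum()
    for i in np.argsort(-(raw - parts)):
        if rem == 0:
            break
        if parts[i] < cap:
            parts[i] += 1
            rem -= 1
    # cap overflow (possible when total is large and weights uneven)
    while parts.max() > cap:
        hi = int(np.argmax(parts))
        lo = int(np.argmin(parts))
        parts[hi] -= 1
        parts[lo] += 1
    while rem > 0:
        lo = int(np.argmin(parts))
        parts[lo] += 1
        rem -= 1
    return parts


def generate_clinical(spec: CohortSpec, truth: GroundTruth) -> pd.DataFrame:
    """Per-subject clinical table (demographics, ALSFRS-R, ECAS, progression).

    Patients draw ΔALSFRS-R from their planted cluster's normal
    (centroid, progression_sd); 12-month subscores are re-distributed so they
    sum to the (range-clipped) total; ECAS subscores correlate
    ``ecas_coupling_r`` with the subject's true DMN coupling; control rows
    carry demographics only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 3]))
    centroids = {"VFP": spec.progression_centroids[0],
                 "FP": spec.progression_centroids[1],
                 "SP": spec.progression_centroids[2]}
    subscore_names = list(_ALSFRS_BASELINE)
    patients = [s for s in spec.subject_ids if spec.group_of(s) == "ALS"]

    # standardized true DMN coupling across patients drives the ECAS scores
    z_dmn = truth.coupling_z.loc[patients, "DMN"].to_numpy()
    z_std = (z_dmn - z_dmn.mean()) / z_dmn.std() if z_dmn.std() > 0 else np.zeros_like(z_dmn)

    rows = []
    for i, sid in enumerate(spec.subject_ids):
        group = spec.group_of(sid)
        row = {"subject": sid, "group": group}
        if group == "ALS":
            row["age"] = float(np.clip(rng.normal(60.64, 9.62), 40, 90))
            row["sex"] = "M" if rng.random() < 30 / 48 else "F"
        else:
            row["age"] = float(np.clip(rng.normal(55.06, 16.0), 40, 90))
            row["sex"] = "M" if rng.random() < 14 / 32 else "F"
        row["education_years"] = float(np.clip(rng.normal(10.58, 4.11), 3, 20))
        if group == "HC":
            row.update({k: np.nan for k in (
                [f"alsfrs_baseline_{s}" for s in subscore_names]
                + ["alsfrs_baseline_total"]
                + [f"alsfrs_12m_{s}" for s in subscore_names]
                + ["alsfrs_12m_total", "delta_alsfrs"]
                + list(ECAS_SPECS)
                + ["ecas_total", "ecas_als_specific", "ecas_non_als_specific"])})
            row["progression"] = "NA"
            rows.append(row)
            continue
        base = {}
        for name, (m, sd) in _ALSFRS_BASELINE.items():
            base[name] = int(np.clip(np.round(rng.normal(m, sd)), 0, 12))
        base_total = sum(base.values())
        label = truth.cluster_labels[sid]
        delta_raw = rng.normal(centroids[label], spec.progression_sd)
        t12_total = int(np.clip(np.round(base_total + delta_raw), 0, 48))
        t12 = _distribute_total(t12_total, np.array(list(base.values())))
        for name, v in base.items():
            row[f"alsfrs_baseline_{name}"] = v
        row["alsfrs_baseline_total"] = base_total
        for name, v in zip(subscore_names, t12):
            row[f"alsfrs_12m_{name}"] = int(v)
        row["alsfrs_12m_total"] = t12_total
        row["delta_alsfrs"] = t12_total - base_total
        r = spec.ecas_coupling_r
        pi = patients.index(sid)
        for name, (m, sd, mx) in ECAS_SPECS.items():
            noise = rng.standard_normal()
            score = m + sd * (r * z_std[pi] + np.sqrt(1 - r ** 2) * noise)
            row[name] = int(np.clip(np.round(score), 0, mx))
        row["ecas_total"] = sum(row[n] for n in ECAS_SPECS)
        row["ecas_als_specific"] = (row["ecas_language"] + row["ecas_fluency"]
                                    + row["ecas_executive"])
        row["ecas_non_als_specific"] = row["ecas_memory"] + row["ecas_visuospatial"]
        row["progression"] = label
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")


# --------------------------------------------------------------------------
# whole-cohort convenience and matrix-level simulation
# --------------------------------------------------------------------------

@dataclass
class Cohort:
    spec: CohortSpec
    parcellation: Parcellation
    masks: TissueMasks
    truth: GroundTruth
    clinical: pd.DataFrame
    subjects: dict  # subject id -> SubjectImages (possibly lazily filled)


def generate_cohort(spec: CohortSpec, with_images: bool = True,
                    subject_subset: list[str] | None = None) -> Cohort:
    """Generate atlas, ground truth, clinical table and (optionally) images."""
    parc = generate_atlas(spec)
    masks = make_tissue_masks(spec)
    truth = generate_ground_truth(spec)
    clinical = generate_clinical(spec, truth)
    subjects = {}
    if with_images:
        todo = subject_subset if subject_subset is not None else spec.subject_ids
        for sid in todo:
            subjects[sid] = generate_subject_images(spec, sid, truth, parc, masks)
    return Cohort(spec=spec, parcellation=parc, masks=masks, truth=truth,
                  clinical=clinical, subjects=subjects)


def simulate_nvc_cohort(spec: CohortSpec, est_noise_sd: float = 0.0,
                        seed: int | None = None
                        ) -> tuple[NvcMatrix, pd.DataFrame]:
    """Subject-level NVC matrix drawn directly from the coupling model.

    Samples each subject's Fisher-z coupling from the generator's truth model
    (group mean atanh(rho) + coupling_sd jitter, plus optional measurement
    noise) together with demographics, without synthesizing images.  Used for
    the statistical calibration and power studies of the group-effect scan,
    where hundreds of cohorts are needed.
    """
    local = spec if seed is None else CohortSpec(**{**spec.__dict__, "seed": seed})
    truth = generate_ground_truth(local)
    clinical = generate_clinical(local, truth)
    rng = np.random.default_rng(np.random.SeedSequence([local.seed & 0x7FFFFFFF, 4]))
    z = truth.coupling_z.to_numpy().copy()
    if est_noise_sd > 0:
        z = z + rng.normal(0.0, est_noise_sd, size=z.shape)
    data = pd.DataFrame(z, index=truth.coupling_z.index,
                        columns=truth.coupling_z.columns)
    matrix = NvcMatrix(metric="ALFF", granularity="network", data=data,
                       counts=None, missing={})
    return matrix, clinical
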