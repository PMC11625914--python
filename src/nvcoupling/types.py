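"""Core in-memory containers shared across the pipeline.

Volumes are plain numpy arrays in voxel space (x, y, z[, t]); all subjects of a
cohort share one grid ("already co-registered"), with the affine carried only
at the NIfTI I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical 7 resting-state network names, in fixed atlas order.
NETWORK_NAMES: tuple[str, ...] = (
    "visual",
    "sensori-motor",
    "dorsal attention",
    "salience ventral attention",
    "limbic",
    "control",
    "DMN",
)

FEATURE_METRICS = ("ALFF", "ReHo", "DC")


class DegeneracyError(ValueError):
    """Raised when an input is degenerate (zero variance, rank deficiency...)."""


@dataclass
class BoldSeries:
    """4D BOLD time series with grid geometry.

    values : float array (x, y, z, t)
    tr_s   : repetition time in seconds
    brain_mask : boolean volume on the same grid
    """

    values: np.ndarray
    tr_s: float
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.values.ndim != 4:
            raise ValueError(f"BOLD values must be 4D, got shape {self.values.shape}")
        if self.brain_mask.shape != self.values.shape[:3]:
            raise ValueError("brain_mask grid does not match BOLD grid")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not np.all(np.isfinite(self.values[self.brain_mask])):
            raise ValueError("non-finite BOLD values inside brain mask")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[3]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_s

    def copy_with(self, values: np.ndarray) -> "BoldSeries":
        return BoldSeries(values=values, tr_s=self.tr_s, brain_mask=self.brain_mask)


@dataclass
class MotionParams:
    """Six rigid-body motion parameter time series (3 translations mm, 3 rotations deg)."""

    values: np.ndarray  # (t, 6)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError(f"motion parameters must be (t, 6), got {self.values.shape}")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


@dataclass
class TissueMasks:
    """Brain / white-matter / CSF masks on the BOLD grid (WM, CSF ⊆ brain)."""

    brain: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        self.brain = np.asarray(self.brain, dtype=bool)
        self.wm = np.asarray(self.wm, dtype=bool)
        self.csf = np.asarray(self.csf, dtype=bool)
        if not (self.brain.shape == self.wm.shape == self.csf.shape):
            raise ValueError("tissue masks must share one grid")
        for name, m in (("wm", self.wm), ("csf", self.csf)):
            if not m.any():
                raise ValueError(f"{name} mask is empty")
            if np.any(m & ~self.brain):
                raise ValueError(f"{name} mask is not a subset of the brain mask")


@dataclass
class FeatureMap:
    """One scalar per voxel (ALFF/ReHo/DC or CBF); NaN outside the mask once z-scored."""

    metric: str
    values: np.ndarray
    mask: np.ndarray
    zscored: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("feature map and mask shapes differ")

    def masked(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class Parcellation:
    """Integer label volume (0 = background) with a region table (id, name, network)."""

    labels: np.ndarray
    regions: pd.DataFrame  # columns: id, name, network

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("parcellation labels must be integer")
        present = set(np.unique(self.labels)) - {0}
        known = set(self.regions["id"].tolist())
        if not present <= known:
            raise ValueError(f"labels missing from region table: {sorted(present - known)}")
        bad = set(self.regions["network"]) - set(NETWORK_NAMES)
        if bad:
            raise ValueError(f"unknown network names: {sorted(bad)}")

    @property
    def region_ids(self) -> np.ndarray:
        return self.regions["id"].to_numpy()

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def network_mask(self, network: str) -> np.ndarray:
        ids = self.regions.loc[self.regions["network"] == network, "id"].to_numpy()
        return np.isin(self.labels, ids)


@dataclass
class NvcMatrix:
    """Subjects × units matrix of Fisher-z NVC values for one metric pair.

    units are either the 7 networks or the atlas regions; ``counts`` holds the
    per-cell voxel count used in the correlation, and missing cells (regions
    too small or degenerate) are NaN with a reason in ``missing``.
    """

    metric: str  # feature metric correlated against CBF: ALFF | ReHo | DC
    granularity: str  # "network" | "region"
    data: pd.DataFrame  # index: subject id, columns: unit names
    counts: pd.DataFrame = None
    missing: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape
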