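"""Single-PLD PCASL cerebral blood flow quantification.

Implements the standard single-compartment calibration

    CBF = 6000 * lambda * (PW/PD) * exp(PLD/T1b)
          -----------------------------------------   [mL/100 g/min]
          2 * alpha * T1b * (1 - exp(-tau/T1b))

with PW the perfusion-weighted difference volume, PD the proton-density
volume, PLD the post-labelling delay, tau the label duration, T1b the
longitudinal relaxation time of arterial blood, alpha the labelling
efficiency and lambda the blood-brain partition coefficient.  Vendor scaling
factors (NEX, background suppression) are omitted: NVC is a spatial
correlation and therefore invariant to any positive global scale.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import smooth_gaussian
from .types import FeatureMap

logger = logging.getLogger(__name__)


@dataclass
class AcqParams:
    """PCASL acquisition/calibration parameters (seconds unless noted).

    Defaults follow the consensus single-PLD recommendations; the PLD is
    per-subject metadata.
    """

    pld_s: float
    tau_s: float = 1.8
    t1_blood_s: float = 1.65
    alpha: float = 0.85
    lambda_ml_g: float = 0.9

    def __post_init__(self) -> None:
        for name in ("pld_s", "tau_s", "t1_blood_s", "alpha", "lambda_ml_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha > 1:
            raise ValueError("labelling efficiency alpha must be <= 1")

    @property
    def scale(self) -> float:
        """CBF per unit PW/PD ratio."""
        t1b = self.t1_blood_s
        num = 6000.0 * self.lambda_ml_g * np.exp(self.pld_s / t1b)
        den = 2.0 * self.alpha * t1b * (1.0 - np.exp(-self.tau_s / t1b))
        return float(num / den)


@dataclass
class PerfusionPair:
    """Perfusion-weighted difference and proton-density volumes (shared grid)."""

    pw: np.ndarray
    pd: np.ndarray

    def __post_init__(self) -> None:
        self.pw = np.asarray(self.pw, dtype=float)
        self.pd = np.asarray(self.pd, dtype=float)
        if self.pw.shape != self.pd.shape:
            raise ValueError("pw and pd volumes must share one grid")


def compute_cbf(pair: PerfusionPair, params: AcqParams,
                mask: np.ndarray) -> FeatureMap:
    """Quantify CBF (mL/100 g/min) voxel-wise inside ``mask``.

    Voxels with non-positive proton density are excluded (value 0) and
    counted in a warning; non-finite inputs inside the mask are an error.
    """
    mask = np.asarray(mask, dtype=bool)
    if not (np.all(np.isfinite(pair.pw[mask])) and np.all(np.isfinite(pair.pd[mask]))):
        raise ValueError("non-finite perfusion inputs inside mask")
    bad = mask & (pair.pd <= 0)
    if bad.any():
        logger.warning("compute_cbf: %d voxels with pd <= 0 excluded", int(bad.sum()))
    ok = mask & ~bad
    vals = np.zeros(pair.pw.shape, dtype=float)
    vals[ok] = params.scale * pair.pw[ok] / pair.pd[ok]
    return FeatureMap(metric="CBF", values=vals, mask=mask)


def smooth_cbf(cbf: FeatureMap, fwhm_mm: float = 6.0,
               voxel_size_mm: float = 3.0) -> FeatureMap:
    """Smooth a CBF map with a Gaussian kernel (delegates to smooth_gaussian)."""
    return smooth_gaussian(cbf, fwhm_mm, voxel_size_mm)
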