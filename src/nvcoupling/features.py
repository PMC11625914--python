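"""Voxel-wise resting-state feature maps: ALFF, ReHo, degree centrality.

The default preprocessing order mirrors the standard resting-state toolchain:
band-pass (0.01-0.1 Hz) -> spatial smoothing -> nuisance regression (Friston-24
motion expansion + WM/CSF mean signals) -> feature maps -> z-transform within
the brain mask.  ALFF is computed on the nuisance-regressed but *unfiltered*
series (band-passing first would make the in-band amplitude filter-dependent);
ReHo and DC use the band-passed series.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage, stats

from .types import BoldSeries, DegeneracyError, FeatureMap, MotionParams, TissueMasks

logger = logging.getLogger(__name__)

DEFAULT_BAND = (0.01, 0.1)

#: FWHM -> Gaussian sigma conversion factor, 2*sqrt(2*ln 2)
_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


# --------------------------------------------------------------------------
# temporal filtering
# --------------------------------------------------------------------------

def bandpass(series: BoldSeries, low_hz: float = DEFAULT_BAND[0],
             high_hz: float = DEFAULT_BAND[1]) -> BoldSeries:
    """Band-pass filter every voxel series in the frequency domain.

    Ideal (brick-wall) FFT filter with a half-amplitude cosine taper of one
    frequency bin at each band edge; the DC component is always removed, so
    the output is zero-mean per voxel.
    """
    nyq = series.nyquist_hz
    if not (0.0 <= low_hz < high_hz):
        raise ValueError(f"need 0 <= low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz >= Nyquist {nyq:.4g} Hz")
    x = series.values
    t = x.shape[-1]
    freqs = np.fft.rfftfreq(t, d=series.tr_s)
    w = np.zeros_like(freqs)
    inband = (freqs >= low_hz) & (freqs <= high_hz)
    w[inband] = 1.0
    # cosine taper of one bin just outside each edge
    df = freqs[1] - freqs[0]
    edge = ((freqs >= low_hz - df) & (freqs < low_hz)) | (
        (freqs > high_hz) & (freqs <= high_hz + df))
    w[edge] = 0.5
    w[0] = 0.0  # never pass DC
    spec = np.fft.rfft(x, axis=-1)
    out = np.fft.irfft(spec * w, n=t, axis=-1)
    return series.copy_with(out)


# --------------------------------------------------------------------------
# nuisance regression
# --------------------------------------------------------------------------

def friston24(motion: MotionParams) -> np.ndarray:
    """Friston 24-parameter expansion: 6 params, their backward first
    differences (first row zero) and the squares of those 12. Shape (t, 24)."""
    m = motion.values
    d = np.vstack([np.zeros((1, 6)), np.diff(m, axis=0)])
    block = np.hstack([m, d])
    return np.hstack([block, block ** 2])


def nuisance_design(motion: MotionParams, series: BoldSeries,
                    masks: TissueMasks) -> tuple[np.ndarray, list[str]]:
    """Intercept + 24 motion predictors + WM and CSF mean time courses."""
    t = series.n_timepoints
    if motion.n_timepoints != t:
        raise ValueError(
            f"motion rows ({motion.n_timepoints}) != BOLD timepoints ({t})")
    names = ["intercept"]
    cols = [np.ones(t)]
    base = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    names += base + [f"d_{n}" for n in base]
    names += [f"{n}_sq" for n in base] + [f"d_{n}_sq" for n in base]
    cols.append(friston24(motion))
    flat = series.values.reshape(-1, t)
    cols.append(flat[masks.wm.ravel()].mean(axis=0)[:, None])
    cols.append(flat[masks.csf.ravel()].mean(axis=0)[:, None])
    names += ["wm_mean", "csf_mean"]
    X = np.column_stack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in cols])
    return X, names


def nuisance_regress(series: BoldSeries, motion: MotionParams,
                     masks: TissueMasks) -> BoldSeries:
    """Regress the 27-column nuisance model out of every voxel series.

    Residuals are orthogonal to every retained regressor. Columns that are
    identically zero carry no signal and are dropped with a warning; genuinely
    collinear (non-zero) columns raise :class:`DegeneracyError` naming them.
    """
    X, names = nuisance_design(motion, series, masks)
    keep = ~np.all(X == 0.0, axis=0)
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.warning("dropping all-zero nuisance columns: %s", dropped)
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy QR-style elimination
        bad, kept_idx = [], []
        for j in range(X.shape[1]):
            trial = X[:, kept_idx + [j]]
            if np.linalg.matrix_rank(trial) == len(kept_idx) + 1:
                kept_idx.append(j)
            else:
                bad.append(names[j])
        raise DegeneracyError(f"nuisance design is rank deficient; collinear columns: {bad}")
    t = series.n_timepoints
    Y = series.values.reshape(-1, t).T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.T.reshape(series.values.shape)
    return series.copy_with(out)


# --------------------------------------------------------------------------
# spatial smoothing
# --------------------------------------------------------------------------

def smooth_gaussian(volume: np.ndarray | FeatureMap, fwhm_mm: float,
                    voxel_size_mm: float) -> np.ndarray | FeatureMap:
    """Gaussian smoothing, sigma = FWHM / (2*sqrt(2 ln 2)) converted to voxels.

    Plain zero-padded convolution with a unit-mass kernel: the total sum over
    the volume is preserved whenever the support lies a few sigma inside the
    grid. Accepts a raw 3D array or a FeatureMap; 4D arrays are smoothed
    volume-by-volume along the last axis.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if isinstance(volume, FeatureMap):
        sm = smooth_gaussian(volume.values, fwhm_mm, voxel_size_mm)
        return FeatureMap(metric=volume.metric, values=sm, mask=volume.mask,
                          zscored=False)
    vol = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = fwhm_mm / _FWHM_TO_SIGMA / voxel_size_mm
    if vol.ndim == 4:
        sigma = (sigma_vox, sigma_vox, sigma_vox, 0.0)
    else:
        sigma = sigma_vox
    return ndimage.gaussian_filter(vol, sigma=sigma, mode="constant", cval=0.0,
                                   truncate=6.0)


# --------------------------------------------------------------------------
# feature maps
# --------------------------------------------------------------------------

def compute_alff(series: BoldSeries, band: tuple[float, float] = DEFAULT_BAND) -> FeatureMap:
    """Amplitude of low-frequency fluctuations.

    Per voxel, the mean single-sided amplitude spectrum over the FFT bins whose
    frequency falls inside ``band`` (inclusive); non-negative by construction.
    """
    low, high = band
    t = series.n_timepoints
    freqs = np.fft.rfftfreq(t, d=series.tr_s)
    inband = (freqs >= low) & (freqs <= high)
    if not inband.any():
        raise ValueError(f"band {band} contains no resolvable FFT frequency "
                         f"(resolution {freqs[1]:.4g} Hz)")
    x = series.values
    amp = np.abs(np.fft.rfft(x, axis=-1)) * (2.0 / t)
    vals = amp[..., inband].mean(axis=-1)
    return FeatureMap(metric="ALFF", values=vals, mask=series.brain_mask)


_NEIGHBORHOOD_FOOTPRINTS = {
    7: ndimage.generate_binary_structure(3, 1),   # faces
    19: ndimage.generate_binary_structure(3, 2),  # faces + edges
    27: ndimage.generate_binary_structure(3, 3),  # full cube
}


def kendall_w(block: np.ndarray) -> float:
    """Kendall's coefficient of concordance W for an (n_series, K) block.

    Ranks are taken within each series over time; W = 12 * SS(rank sums) /
    (n^2 (K^3 - K)). No tie correction (real-valued data).
    """
    n, k = block.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, block)
    r_t = ranks.sum(axis=0)
    s = np.sum((r_t - r_t.mean()) ** 2)
    return float(12.0 * s / (n ** 2 * (k ** 3 - k)))


def compute_reho(series: BoldSeries, neighborhood: int = 27) -> FeatureMap:
    """Regional homogeneity: Kendall's W of each voxel with its neighborhood.

    Vectorized over the volume: per-voxel temporal ranks are summed over the
    (masked) neighborhood with a box correlation, and W follows from the
    variance of the rank sums. Voxels outside the brain mask get 0.
    """
    if neighborhood not in _NEIGHBORHOOD_FOOTPRINTS:
        raise ValueError(f"neighborhood must be one of {sorted(_NEIGHBORHOOD_FOOTPRINTS)}")
    k = series.n_timepoints
    if k < 3:
        raise ValueError("need at least 3 timepoints for ReHo")
    foot = _NEIGHBORHOOD_FOOTPRINTS[neighborhood].astype(float)
    mask = series.brain_mask
    x = series.values
    # temporal ranks per voxel (ties measure-zero on real data)
    order = np.argsort(x, axis=-1)
    ranks = np.empty_like(x)
    np.put_along_axis(ranks, order, np.arange(1, k + 1, dtype=float), axis=-1)
    ranks[~mask] = 0.0
    # neighborhood rank sums per timepoint, and neighbor counts
    n_in = ndimage.correlate(mask.astype(float), foot, mode="constant", cval=0.0)
    ssum = np.empty_like(ranks)
    for ti in range(k):
        ssum[..., ti] = ndimage.correlate(ranks[..., ti], foot, mode="constant",
                                          cval=0.0)
    s = np.sum((ssum - ssum.mean(axis=-1, keepdims=True)) ** 2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 12.0 * s / (np.round(n_in) ** 2 * (k ** 3 - k))
    w[~mask] = 0.0
    return FeatureMap(metric="ReHo", values=w, mask=mask)


def compute_dc(series: BoldSeries, r_threshold: float = 0.25,
               chunk: int = 2048) -> FeatureMap:
    """Binarized degree centrality: per voxel, the number of other brain-mask
    voxels whose Pearson correlation with it exceeds ``r_threshold``.

    Zero-variance voxels are excluded from the graph (degree 0, correlations
    with them treated as 0) and counted in the log.
    """
    mask = series.brain_mask
    flat = series.values[mask]  # (V, t)
    v, t = flat.shape
    if v < 2:
        raise ValueError("need at least 2 brain-mask voxels")
    centered = flat - flat.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("compute_dc: %d zero-variance voxels excluded", degenerate.sum())
    z = np.zeros_like(centered)
    ok = ~degenerate
    z[ok] = centered[ok] / (sd[ok, None] * np.sqrt(t))
    degree = np.zeros(v, dtype=float)
    for start in range(0, v, chunk):
        sl = slice(start, min(start + chunk, v))
        corr = z[sl] @ z.T  # (chunk, V)
        hits = (corr > r_threshold).sum(axis=1)
        # remove self-correlation (1 > threshold for non-degenerate voxels)
        idx = np.arange(sl.start, sl.stop)
        hits = hits - (corr[np.arange(sl.stop - sl.start), idx] > r_threshold)
        degree[sl] = hits
    degree[degenerate] = 0.0
    vals = np.zeros(mask.shape, dtype=float)
    vals[mask] = degree
    return FeatureMap(metric="DC", values=vals, mask=mask)


def zscore_map(fmap: FeatureMap, mask: np.ndarray | None = None) -> FeatureMap:
    """Z-transform within the (common brain) mask; NaN outside.

    Idempotent and invariant under per-voxel affine rescaling of the input.
    """
    mask = fmap.mask if mask is None else np.asarray(mask, dtype=bool)
    vals = fmap.values[mask]
    sd = vals.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegeneracyError(f"zero/non-finite SD within mask for {fmap.metric} map")
    out = np.full(fmap.values.shape, np.nan)
    out[mask] = (vals - vals.mean()) / sd
    return FeatureMap(metric=fmap.metric, values=out, mask=mask, zscored=True)
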