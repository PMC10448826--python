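"""Temporal and spatial preprocessing of BOLD series.

Post-registration steps only: initial-volume discarding, zero-phase FFT
band-pass filtering, 3D Gaussian smoothing, tissue-mean nuisance regression,
and a GLM-Fourier high-pass for task runs.  The resting-state order contract
is discard -> band-pass -> smooth -> nuisance regression and is enforced by
:func:`run_rest_preproc`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BoldSeries, LabelVolume

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass
class PreprocConfig:
    """Resting-state preprocessing parameters.

    band: (f_lo, f_hi) in Hz, default (0.009, 0.08) — the slow fluctuation
    band of resting-state BOLD; fwhm: spatial Gaussian kernel in mm,
    default 4; n_discard: initial volumes dropped against MR saturation,
    default 2; nuisance classes regressed out, default WM and CSF.
    """

    n_discard: int = 2
    band: tuple[float, float] = (0.009, 0.08)
    fwhm: float = 4.0
    nuisance_classes: tuple[str, ...] = ("WM", "CSF")

    def __post_init__(self) -> None:
        f_lo, f_hi = self.band
        if not 0 <= f_lo < f_hi:
            raise ValueError("band must satisfy 0 <= f_lo < f_hi")
        if self.fwhm < 0 or self.n_discard < 0:
            raise ValueError("fwhm and n_discard must be >= 0")


def effective_timepoints(n_volumes: int, tr: float, band: tuple[float, float]) -> int:
    """Effective number of independent samples after band-pass filtering.

    A band-limited series of duration T carries about 2 * bandwidth * T
    independent real degrees of freedom; correlation p-values computed on
    band-passed data should use this instead of the raw volume count, which
    would be badly anticonservative.
    """
    f_lo, f_hi = band
    t_total = n_volumes * tr
    return max(8, int(round(2.0 * (f_hi - f_lo) * t_total)))


def discard_initial(series: BoldSeries, n: int) -> BoldSeries:
    """Drop the first ``n`` volumes (MR saturation); geometry and TR unchanged."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= series.n_volumes:
        raise ValueError(f"cannot discard {n} of {series.n_volumes} volumes")
    if n == 0:
        return series
    return series.replace(series.data[..., n:])


def _band_gain(freqs: np.ndarray, f_lo: float, f_hi: float, transition_frac: float) -> np.ndarray:
    """Band-pass transfer function: flat pass band with raised-cosine edges.

    The cosine roll-offs live entirely outside [f_lo, f_hi] over a width of
    ``transition_frac`` times the edge frequency, so in-band gain is exactly
    1 and one octave outside the gain is 0 (well under the 0.1 contract).
    DC is always removed.
    """
    gain = np.zeros_like(freqs)
    lo0 = f_lo * (1.0 - transition_frac)
    hi1 = f_hi * (1.0 + transition_frac)
    inband = (freqs >= f_lo) & (freqs <= f_hi)
    gain[inband] = 1.0
    if f_lo > 0:
        ramp = (freqs > lo0) & (freqs < f_lo)
        gain[ramp] = 0.5 * (1.0 - np.cos(np.pi * (freqs[ramp] - lo0) / (f_lo - lo0)))
    else:
        gain[(freqs > 0) & (freqs < f_hi)] = 1.0
    ramp = (freqs > f_hi) & (freqs < hi1)
    gain[ramp] = 0.5 * (1.0 + np.cos(np.pi * (freqs[ramp] - f_hi) / (hi1 - f_hi)))
    gain[freqs == 0] = 0.0  # DC removal
    return gain


def temporal_bandpass(
    series: BoldSeries,
    f_lo: float = 0.009,
    f_hi: float = 0.08,
    transition_frac: float = 0.05,
) -> BoldSeries:
    """Zero-phase per-voxel band-pass via the FFT; removes the mean (DC)."""
    nyquist = 0.5 / series.tr
    if not 0 <= f_lo < f_hi:
        raise ValueError("band must satisfy 0 <= f_lo < f_hi")
    if f_hi >= nyquist:
        raise ValueError(f"f_hi={f_hi} exceeds Nyquist {nyquist} for TR={series.tr}")
    t = series.n_volumes
    flat = series.data.reshape(-1, t)
    freqs = np.fft.rfftfreq(t, d=series.tr)
    gain = _band_gain(freqs, f_lo, f_hi, transition_frac)
    out = np.fft.irfft(np.fft.rfft(flat, axis=1) * gain, n=t, axis=1)
    return series.replace(out.reshape(series.shape).astype(series.data.dtype, copy=False))


def gaussian_smooth(series: BoldSeries, fwhm_mm: float = 4.0) -> BoldSeries:
    """Volume-wise 3D Gaussian smoothing; sigma_vox = fwhm/(2.3548*voxel_size)."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return series
    sigmas = [fwhm_mm / (FWHM_TO_SIGMA * v) for v in series.voxel_size]
    out = ndimage.gaussian_filter(series.data, sigma=sigmas + [0.0], mode="nearest")
    return series.replace(out)


def nuisance_regress(
    series: BoldSeries,
    labels: LabelVolume,
    classes: tuple[str, ...] = ("WM", "CSF"),
) -> BoldSeries:
    """Regress tissue-class mean time courses out of every voxel.

    Per voxel an OLS on [intercept, class-mean courses]; residuals are
    returned.  Rank deficiency (collinear tissue courses) falls back to the
    pseudo-inverse solution with a logged warning.
    """
    regressors = [np.ones(series.n_volumes)]
    for cls in classes:
        mask = labels.tissue_mask(cls)
        if not mask.any():
            raise ValueError(f"tissue class {cls!r} has no voxels")
        regressors.append(series.data[mask].mean(axis=0))
    X = np.column_stack(regressors)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning("nuisance regressors rank-deficient (rank %d < %d)", rank, X.shape[1])
    flat = series.data.reshape(-1, series.n_volumes).T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    return series.replace(resid.T.reshape(series.shape))


def glm_fourier_highpass(series: BoldSeries, n_cycles: int = 2) -> BoldSeries:
    """Temporal drift removal for task runs: regress out slow Fourier terms.

    Removes the intercept and the ``n_cycles`` lowest-frequency sine/cosine
    pairs of the run (periods T, T/2, ... with T the run duration) as
    confounds, our fixed definition of a 'GLM-Fourier filter with 2 cycles'.
    """
    t = series.n_volumes
    idx = np.arange(t)
    cols = [np.ones(t)]
    for k in range(1, n_cycles + 1):
        cols.append(np.sin(2 * np.pi * k * idx / t))
        cols.append(np.cos(2 * np.pi * k * idx / t))
    X = np.column_stack(cols)
    flat = series.data.reshape(-1, t).T
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    return series.replace(resid.T.reshape(series.shape))


def run_rest_preproc(
    series: BoldSeries,
    labels: LabelVolume,
    config: PreprocConfig = PreprocConfig(),
) -> BoldSeries:
    """Full resting-state chain in the fixed order: discard, band-pass, smooth, nuisance."""
    out = discard_initial(series, config.n_discard)
    f_lo, f_hi = config.band
    out = temporal_bandpass(out, f_lo, f_hi)
    out = gaussian_smooth(out, config.fwhm)
    out = nuisance_regress(out, labels, config.nuisance_classes)
    return out


def run_task_preproc(
    series: BoldSeries,
    fwhm: float = 4.0,
    n_discard: int = 0,
    n_cycles: int = 2,
) -> BoldSeries:
    """Task-run chain: discard, Gaussian smooth, GLM-Fourier drift removal."""
    out = discard_initial(series, n_discard)
    out = gaussian_smooth(out, fwhm)
    return glm_fourier_highpass(out, n_cycles)
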