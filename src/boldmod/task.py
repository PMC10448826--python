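"""Task GLM, activation tables, BOLD response profiles, and temporal CNR.

The motor paradigm is a boxcar (14 s blocks repeated 7 times with 14 s
baselines at TR = 2 s, i.e. 105 volumes) convolved with a canonical
double-gamma haemodynamic response function.  Voxelwise activation is a
two-column GLM [intercept, predictor] with BY-FDR selection; region-level
reporting covers activation probability, activated volume, the trial-averaged
percent-signal-change profile with its shape parameters (PH, PT, PW, PS),
and the temporal contrast-to-noise ratio tCNR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import gamma as gamma_dist
from scipy.stats import t as t_dist

from .stats import FdrConfig, fdr_select
from .volume import BoldSeries, LabelVolume

logger = logging.getLogger(__name__)


@dataclass
class DesignParadigm:
    """Block design: initial rest, then n_cycles x (on + off), all in seconds."""

    initial_rest: float = 14.0
    n_cycles: int = 7
    on_duration: float = 14.0
    off_duration: float = 14.0
    tr: float = 2.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        for dur in (self.initial_rest, self.on_duration, self.off_duration):
            if abs(dur / self.tr - round(dur / self.tr)) > 1e-9:
                logger.warning("duration %.3f s is not a multiple of TR=%.3f s", dur, self.tr)

    @property
    def n_samples(self) -> int:
        total = self.initial_rest + self.n_cycles * (self.on_duration + self.off_duration)
        return int(round(total / self.tr))

    def boxcar(self) -> np.ndarray:
        """0/1 stimulation function sampled at TR."""
        box = np.zeros(self.n_samples)
        on_s = int(round(self.on_duration / self.tr))
        off_s = int(round(self.off_duration / self.tr))
        start = int(round(self.initial_rest / self.tr))
        for c in range(self.n_cycles):
            a = start + c * (on_s + off_s)
            box[a : a + on_s] = 1.0
        return box

    def onsets(self) -> np.ndarray:
        """Stimulus onset sample indices."""
        on_s = int(round(self.on_duration / self.tr))
        off_s = int(round(self.off_duration / self.tr))
        start = int(round(self.initial_rest / self.tr))
        return start + np.arange(self.n_cycles) * (on_s + off_s)


@dataclass
class SPMap:
    """Voxelwise GLM result: t map, betas, df, and the FDR significance mask."""

    t: np.ndarray
    beta: np.ndarray
    df: int
    sig_mask: np.ndarray
    fdr_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("df must be positive")


@dataclass
class ResponseProfile:
    """Trial-averaged percent-signal-change profile and its shape parameters."""

    time: np.ndarray  # seconds relative to stimulus onset
    delta_r: np.ndarray  # percent signal change
    n_pre: int
    on_samples: int
    tr: float
    PH: float | None = None
    PT: float | None = None
    PW: float | None = None
    PS: float | None = None
    defined: bool = True


def double_gamma_hrf(t: np.ndarray, peak: float = 5.0, undershoot: float = 15.0, ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma HRF: peak at ~5 s, undershoot at ~15 s, 6:1 ratio."""
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, peak + 1.0) - gamma_dist.pdf(t, undershoot + 1.0) / ratio
    h[t < 0] = 0.0
    return h


def hrf_regressor(design: DesignParadigm, oversample: int = 16) -> np.ndarray:
    """HRF-convolved boxcar predictor, sampled at TR, unit peak.

    The boxcar is built on an oversampled grid (default 16x) before
    convolution so the predictor is insensitive to the TR discretisation,
    then decimated back to TR samples.  An all-off design returns zeros.
    """
    dt = design.tr / oversample
    n_fine = design.n_samples * oversample
    box_fine = np.repeat(design.boxcar(), oversample)
    t_fine = np.arange(0, 32.0, dt)  # 32 s HRF support
    hrf = double_gamma_hrf(t_fine)
    pred = np.convolve(box_fine, hrf)[:n_fine] * dt
    pred = pred[::oversample]
    peak = np.abs(pred).max()
    if peak > 0:
        pred = pred / peak
    return pred


def glm_tmap(series: BoldSeries, predictor: np.ndarray, fdr: FdrConfig = FdrConfig(q=0.05, method="BY")) -> SPMap:
    """Voxelwise OLS on [intercept, predictor]; t = beta/SE, df = t-2; BY-FDR mask.

    Zero-variance voxels get t = 0 and are never selected.
    """
    predictor = np.asarray(predictor, dtype=float)
    t_len = series.n_volumes
    if predictor.size != t_len:
        raise ValueError("predictor length must equal the number of volumes")
    X = np.column_stack([np.ones(t_len), predictor])
    flat = series.data.reshape(-1, t_len).T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    df = t_len - 2
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat = np.where(se > 0, beta[1] / se, 0.0)
    p = 2.0 * t_dist.sf(np.abs(t_stat), df)
    p[se == 0] = 1.0
    mask_flat, thr = fdr_select(p, fdr)
    grid = series.grid
    return SPMap(
        t=t_stat.reshape(grid),
        beta=beta[1].reshape(grid),
        df=df,
        sig_mask=mask_flat.reshape(grid),
        fdr_threshold=thr,
    )


def activation_tables(
    spmaps: list[SPMap],
    labels: LabelVolume,
    volume_threshold_mm3: float = 15.0,
    control_regions: list[int] | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Per-region activation probability and volume across subjects.

    AP = fraction of subjects with >= 1 significant voxel in the region;
    activated volume = mean significant-voxel count x voxel volume (mm^3).
    A region is flagged ``included`` when its volume exceeds the threshold
    (default 15 mm^3) and AP is 100%.  If ``control_regions`` is given,
    1 - mean AP over that set is returned as a specificity estimate.
    """
    if not spmaps:
        raise ValueError("at least one subject SPM required")
    for sp in spmaps:
        if sp.sig_mask.shape != labels.grid:
            raise ValueError("SPM grid does not match the label volume")
    voxel_vol = float(np.prod(labels.voxel_size))
    rows = []
    for lab in labels.table["label"]:
        region = labels.labels == lab
        counts = [int((sp.sig_mask & region).sum()) for sp in spmaps]
        ap = float(np.mean([c > 0 for c in counts]))
        vol = float(np.mean(counts) * voxel_vol)
        rows.append(
            {
                "label": int(lab),
                "AP": ap,
                "activated_volume_mm3": vol,
                "included": bool(vol > volume_threshold_mm3 and ap == 1.0),
            }
        )
    table = pd.DataFrame(rows)
    specificity = None
    if control_regions is not None:
        sel = table["label"].isin(control_regions)
        specificity = float(1.0 - table.loc[sel, "AP"].mean())
    return table, specificity


def trial_average(
    series: BoldSeries,
    mask: np.ndarray,
    design: DesignParadigm,
    n_baseline: int = 5,
) -> ResponseProfile:
    """Trial-averaged percent-signal-change profile over the masked voxels.

    Each stimulation cycle contributes a window of ``n_baseline`` pre-onset
    samples, the ON block, and ``n_baseline`` post samples; windows that do
    not fit inside the run are dropped (logged).  The baseline reference R
    is the mean of the three inner points of the pre-stimulus baseline
    (points 2-4 of 5) and Delta R/R% = 100 * (x - R) / R.
    """
    course = series.data[np.asarray(mask, dtype=bool)].mean(axis=0)
    on_s = int(round(design.on_duration / design.tr))
    win_len = n_baseline + on_s + n_baseline
    windows = []
    for onset in design.onsets():
        a = onset - n_baseline
        b = onset + on_s + n_baseline
        if a < 0 or b > course.size:
            logger.info("trial_average: cycle at sample %d out of range; dropped", onset)
            continue
        windows.append(course[a:b])
    if not windows:
        raise ValueError("no stimulation window fits inside the run")
    avg = np.mean(windows, axis=0)
    baseline = avg[1 : n_baseline - 1].mean()  # inner points 2..4 of 5
    if baseline == 0:
        raise ValueError("zero baseline reference")
    delta_r = 100.0 * (avg - baseline) / baseline
    time = (np.arange(win_len) - n_baseline) * design.tr
    return ResponseProfile(
        time=time, delta_r=delta_r, n_pre=n_baseline, on_samples=on_s, tr=design.tr
    )


def _interp_crossing(t0, y0, t1, y1, level):
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def response_params(profile: ResponseProfile) -> ResponseProfile:
    """Fill PH, PT, PW, PS from the averaged profile.

    PH: peak percent signal change within the ON + post window.
    PT: time (s) from stimulus onset to that peak.
    PW: full width (s) at half of PH, half-max crossings linearly
    interpolated between samples.
    PS: rise fraction, (time from the rising half-max crossing to the
    peak) / PW; 0.5 means a symmetric response.

    A profile with PH <= 0 is flagged undefined.
    """
    y = profile.delta_r
    t = profile.time
    search = t >= 0
    idx_peak = np.argmax(np.where(search, y, -np.inf))
    ph = float(y[idx_peak])
    if ph <= 0:
        profile.defined = False
        logger.info("response_params: non-positive peak; parameters undefined")
        return profile
    pt = float(t[idx_peak])
    half = ph / 2.0
    # rising crossing: last upward crossing before the peak
    t_rise = t[0]
    for i in range(idx_peak, 0, -1):
        if y[i - 1] < half <= y[i]:
            t_rise = _interp_crossing(t[i - 1], y[i - 1], t[i], y[i], half)
            break
    # falling crossing: first downward crossing after the peak
    t_fall = t[-1]
    for i in range(idx_peak, y.size - 1):
        if y[i] >= half > y[i + 1]:
            t_fall = _interp_crossing(t[i], y[i], t[i + 1], y[i + 1], half)
            break
    pw = float(t_fall - t_rise)
    if pw <= 0:
        profile.defined = False
        return profile
    ps = float((pt - t_rise) / pw)
    profile.PH, profile.PT, profile.PW, profile.PS = ph, pt, pw, ps
    profile.defined = True
    return profile


def tcnr(voxel_course: np.ndarray, design: DesignParadigm) -> float:
    """Temporal contrast-to-noise ratio of one voxel time course.

    tCNR = (mean ON - mean OFF) / sigma_t-noise, where sigma_t-noise is the
    SD of the residual after Savitzky-Golay smoothing (order 2, window 5,
    polynomial edge fitting).  ON/OFF follow the raw boxcar, not the
    convolved predictor.  A (near-)noiseless course is flagged by returning
    inf; callers exclude such voxels from region means.
    """
    x = np.asarray(voxel_course, dtype=float)
    if x.size < 5:
        raise ValueError("tCNR needs at least 5 time points")
    box = design.boxcar()[: x.size]
    on = box > 0
    delta = x[on].mean() - x[~on].mean()
    smooth = savgol_filter(x, window_length=5, polyorder=2, mode="interp")
    sigma = float((x - smooth).std(ddof=1))
    if sigma < 1e-12:
        logger.info("tcnr: sigma_t-noise ~ 0; flagged infinite")
        return float("inf")
    return float(delta / sigma)


def region_tcnr(series: BoldSeries, sig_mask: np.ndarray, design: DesignParadigm) -> float:
    """Mean tCNR over activated voxels, excluding flagged (infinite) voxels."""
    voxels = series.data[np.asarray(sig_mask, dtype=bool)]
    if voxels.size == 0:
        return float("nan")
    vals = np.array([tcnr(v, design) for v in voxels])
    finite = np.isfinite(vals)
    if not finite.any():
        return float("inf")
    return float(vals[finite].mean())


def laterality_ratio(profile_contra: ResponseProfile, profile_ipsi: ResponseProfile) -> float:
    """Contralateral / ipsilateral peak-amplitude ratio; undefined if PH_ipsi <= 0."""
    if not (profile_contra.defined and profile_ipsi.defined):
        raise ValueError("both profiles must have defined parameters")
    if profile_ipsi.PH is None or profile_contra.PH is None or profile_ipsi.PH <= 0:
        raise ValueError("ipsilateral peak must be positive")
    return float(profile_contra.PH / profile_ipsi.PH)
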