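"""Image-quality fingerprints for BOLD series.

Four spatial metrics on the temporal mean image (SNR, CNR, FBER, EFC), four
temporal metrics (tSNR, zDVARS, MDI, Gcorr), an automatic background mask,
ratio fingerprints for head-to-head comparison of two acquisitions, and a
z-scored PCA reporting utility.

Conventions fixed here (the source definitions leave them open):

* spatial metrics use the temporal mean volume, not the first volume;
* DVARS is the spatial standard deviation of the temporal difference image;
  its standardisation divides by the expected DVARS predicted from robust
  voxel standard deviations (IQR/1.349) and lag-1 autocorrelations,
  Var[diff] = 2*sigma^2*(1-rho1) per voxel;
* Gcorr is computed through the norm identity: with z-scored voxel courses,
  the mean pairwise correlation including self-pairs equals the squared
  norm of the mean course; self-pairs are then removed exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .volume import BoldSeries, LabelVolume

logger = logging.getLogger(__name__)

#: fingerprint directionality: how each metric is better
HIGHER_BETTER = ("SNR", "CNR", "FBER", "tSNR")
LOWER_BETTER = ("EFC", "zDVARS", "MDI")
ZERO_BETTER = ("Gcorr",)


@dataclass
class QCReport:
    """The eight quality metrics plus the masks they were computed on."""

    SNR: float
    CNR: float
    FBER: float
    EFC: float
    tSNR: float
    zDVARS: float
    MDI: float
    Gcorr: float
    tsnr_map: np.ndarray | None = None
    masks: dict = field(default_factory=dict)

    def metrics(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in HIGHER_BETTER + LOWER_BETTER + ZERO_BETTER}


def background_mask(mean_volume: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Automatic background: largest dark 6-connected component outside the brain.

    Candidate voxels lie outside the brain mask and below the 5% intensity
    quantile *within* the brain; taking the largest 6-connected component of
    the candidates reliably drops bright skull/muscle voxels.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    if brain_mask.all():
        raise ValueError("no voxels outside the brain mask")
    threshold = np.quantile(mean_volume[brain_mask], 0.05)
    candidates = (~brain_mask) & (mean_volume < threshold)
    if not candidates.any():
        raise ValueError("no background candidates below the 5% brain quantile")
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    lab, n_lab = ndimage.label(candidates, structure=struct)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == int(np.argmax(sizes))


def _efc(volume: np.ndarray) -> float:
    """Entropy focus criterion, normalised to [0, 1] (0 = maximally focused)."""
    x = np.abs(np.asarray(volume, dtype=float).ravel())
    norm = np.sqrt(np.sum(x**2))
    if norm == 0:
        return 0.0
    y = x / norm
    nz = y > 0
    entropy = -np.sum(y[nz] * np.log(y[nz]))
    n = x.size
    max_entropy = np.sqrt(n) * np.log(np.sqrt(n))  # equal-energy uniform image
    return float(entropy / max_entropy)


def spatial_quality(
    series: BoldSeries,
    labels: LabelVolume,
    background: np.ndarray,
) -> dict[str, float]:
    """SNR, CNR, FBER, EFC on the temporal mean volume."""
    mean_vol = series.mean_volume()
    gm = labels.tissue_mask("GM")
    wm = labels.tissue_mask("WM")
    brain = labels.brain_mask()
    if not (gm.any() and wm.any() and np.asarray(background, bool).any()):
        raise ValueError("GM, WM and background masks must be nonempty")
    bg_sd = float(mean_vol[background].std(ddof=1))
    if bg_sd == 0:
        raise ValueError("zero background standard deviation (noiseless input)")
    snr = float(mean_vol[gm].mean() / bg_sd)
    cnr = float((mean_vol[gm].mean() - mean_vol[wm].mean()) / bg_sd)
    fber = float(mean_vol[brain].var(ddof=1) / mean_vol[background].var(ddof=1))
    return {"SNR": snr, "CNR": cnr, "FBER": fber, "EFC": _efc(mean_vol)}


def temporal_quality(series: BoldSeries, brain_mask: np.ndarray) -> dict:
    """tSNR (map and mean), zDVARS, MDI and Gcorr within the brain mask.

    Voxels with zero temporal SD have undefined tSNR; they are excluded from
    the mean and their count logged.
    """
    if series.n_volumes < 3:
        raise ValueError("temporal metrics need at least 3 volumes")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    data = series.data[brain_mask].astype(float)  # (voxels, t)
    mu = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1)
    ok = sd > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("tSNR undefined for %d zero-variance voxel(s); excluded", n_bad)
    tsnr_vox = np.zeros_like(mu)
    tsnr_vox[ok] = mu[ok] / sd[ok]
    tsnr_map = np.zeros(series.grid)
    tsnr_map[brain_mask] = tsnr_vox
    tsnr_mean = float(tsnr_vox[ok].mean()) if ok.any() else 0.0

    # DVARS: spatial SD of each temporal difference image, standardised by
    # the value expected from per-voxel robust SDs and lag-1 autocorrelation.
    diff = np.diff(data, axis=1)
    dvars = diff.std(axis=0, ddof=1)
    iqr = np.subtract(*np.percentile(data, [75, 25], axis=1))
    sigma_rob = iqr / 1.349
    centered = data - mu[:, None]
    denom = (centered[:, :-1] ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho1 = np.where(denom > 0, (centered[:, 1:] * centered[:, :-1]).sum(axis=1) / denom, 0.0)
    rho1 = np.clip(rho1, -1.0, 1.0)
    expected = np.sqrt(np.mean(2.0 * sigma_rob**2 * (1.0 - rho1)))
    zdvars = float(np.mean(dvars / expected)) if expected > 0 else 0.0

    # MDI: mean (1 - Spearman rho) between each volume and the voxelwise median
    median_vol = np.median(data, axis=1)
    ranks_med = rankdata(median_vol)
    ranks_t = np.apply_along_axis(rankdata, 0, data)
    rm = ranks_med - ranks_med.mean()
    rt = ranks_t - ranks_t.mean(axis=0)
    num = rm @ rt
    den = np.sqrt((rm**2).sum() * (rt**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    mdi = float(np.mean(1.0 - rho))

    # Gcorr via the norm identity (exact, O(voxels * t))
    z = centered[ok] / sd[ok, None]
    n_vox = z.shape[0]
    if n_vox < 2:
        gcorr = 0.0
    else:
        mean_course = z.mean(axis=0)
        g_incl = float((mean_course @ mean_course) / (series.n_volumes - 1))
        gcorr = (n_vox * g_incl - 1.0) / (n_vox - 1.0)
    return {
        "tSNR": tsnr_mean,
        "tsnr_map": tsnr_map,
        "zDVARS": zdvars,
        "MDI": mdi,
        "Gcorr": float(gcorr),
    }


def gcorr_bruteforce(series: BoldSeries, brain_mask: np.ndarray) -> float:
    """O(voxels^2) reference Gcorr: average of all distinct pairwise correlations."""
    data = series.data[np.asarray(brain_mask, bool)].astype(float)
    sd = data.std(axis=1, ddof=1)
    data = data[sd > 0]
    c = np.corrcoef(data)
    n = c.shape[0]
    return float((c.sum() - n) / (n * (n - 1)))


def qc_report(series: BoldSeries, labels: LabelVolume) -> QCReport:
    """Compute all eight metrics with the automatic background mask."""
    brain = labels.brain_mask()
    bg = background_mask(series.mean_volume(), brain)
    spat = spatial_quality(series, labels, bg)
    temp = temporal_quality(series, brain)
    return QCReport(
        SNR=spat["SNR"],
        CNR=spat["CNR"],
        FBER=spat["FBER"],
        EFC=spat["EFC"],
        tSNR=temp["tSNR"],
        zDVARS=temp["zDVARS"],
        MDI=temp["MDI"],
        Gcorr=temp["Gcorr"],
        tsnr_map=temp["tsnr_map"],
        masks={"brain": brain, "background": bg},
    )


def fingerprint(report_a: QCReport, report_b: QCReport) -> dict[str, tuple[float, float]]:
    """Normalised metric profile pair: the better acquisition scores 1.0.

    The worse one scores proportionally toward 1.0 respecting each metric's
    directionality (ratio worse/better for higher-is-better metrics, inverse
    ratio for lower-is-better; Gcorr compares absolute values).  Metrics with
    a zero denominator are flagged by exclusion from the output.
    """
    out: dict[str, tuple[float, float]] = {}
    ma, mb = report_a.metrics(), report_b.metrics()
    for name in ma:
        a, b = ma[name], mb[name]
        if name in ZERO_BETTER:
            a, b = abs(a), abs(b)
        if name in HIGHER_BETTER:
            better_is_a = a >= b
        else:  # lower (or closer to zero) is better
            better_is_a = a <= b
        if a == b:
            out[name] = (1.0, 1.0)
            continue
        hi, lo = max(a, b), min(a, b)
        if hi == 0:
            logger.warning("fingerprint: zero denominator for %s; excluded", name)
            continue
        score = lo / hi
        out[name] = (1.0, score) if better_is_a else (score, 1.0)
    return out


def fingerprint_pca(metric_table, n_components: int = 2):
    """z-scored PCA of per-subject metric fingerprints (reporting utility).

    ``metric_table`` is a pandas DataFrame (subjects x metrics).  Returns
    (scores, loadings, explained_variance_ratio).
    """
    from sklearn.decomposition import PCA

    X = np.asarray(metric_table, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Xz)
    return scores, pca.components_, pca.explained_variance_ratio_
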