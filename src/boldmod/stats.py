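"""Shared statistical machinery.

Fisher transform, critical correlation thresholds, BH/BY false-discovery-rate
step-up selection, threshold-free cluster enhancement (TFCE), and a generic
permutation-null engine.  These primitives are written here (not imported
from a stats library) because their exact conventions — the BY harmonic-sum
correction, the TFCE integration and re-normalisation, the
percentile-summary permutation null — are the load-bearing parts of the
downstream inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sps

logger = logging.getLogger(__name__)

_R_CLIP = 1.0 - 1e-7


@dataclass
class FdrConfig:
    """FDR step-up configuration: target rate q and method ('BH' or 'BY')."""

    q: float = 0.05
    method: str = "BY"

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if self.method not in ("BH", "BY"):
            raise ValueError("method must be 'BH' or 'BY'")


@dataclass
class TfceParams:
    """TFCE parameters: height exponent H, extent exponent E, step dh, connectivity.

    Defaults H=2, E=0.05 follow the cluster-enhancement settings used for
    voxelwise paired t-maps; dh=None means max(|stat|)/100; connectivity 6
    is the conservative 3D face neighbourhood.
    """

    H: float = 2.0
    E: float = 0.05
    dh: float | None = None
    connectivity: int = 6

    def __post_init__(self) -> None:
        if self.H < 0 or self.E < 0:
            raise ValueError("H and E must be >= 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class PermScheme:
    """Permutation scheme: kind, count, seed, and the null summary statistic.

    kind ∈ {'group_exchange', 'sign_flip', 'pair_exchange'}; summary is
    'max' or a quantile in (0, 1) of the voxelwise statistics (e.g. 0.999
    for an outlier-robust null).
    """

    kind: str = "sign_flip"
    n_perm: int = 1000
    seed: int = 0
    summary: float | str = "max"

    def __post_init__(self) -> None:
        if self.kind not in ("group_exchange", "sign_flip", "pair_exchange"):
            raise ValueError(f"unknown permutation kind {self.kind!r}")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


# ---------------------------------------------------------------------------
# Fisher transform and correlation significance
# ---------------------------------------------------------------------------


def fisher_z(r):
    """atanh variance-stabilising transform; |r|=1 is clipped to 1-1e-7."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must satisfy |r| <= 1")
    clipped = np.clip(r, -_R_CLIP, _R_CLIP)
    n_clip = int(np.sum(np.abs(r) >= _R_CLIP))
    if n_clip:
        logger.debug("fisher_z clipped %d value(s) at |r|=1", n_clip)
    out = np.arctanh(clipped)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    return float(out) if out.ndim == 0 else out


def critical_correlation_z(alpha: float, df: int) -> float:
    """Two-tailed critical correlation at level alpha, on the Fisher-z scale.

    r_c = t_c / sqrt(t_c^2 + df) with t_c the two-tailed t quantile; for
    alpha=0.05, df=744 this evaluates to z = 0.072, the threshold used for
    interhemispheric time-course correlations.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if df < 3:
        raise ValueError("df must be >= 3")
    t_c = sps.t.ppf(1 - alpha / 2, df)
    r_c = t_c / np.sqrt(t_c**2 + df)
    return float(fisher_z(r_c))


def correlation_pvalues(r: np.ndarray, n: int, n_nuisance: int = 0) -> np.ndarray:
    """Two-tailed p-values for Pearson correlations via the t transform.

    df = n - 2 - n_nuisance; the nuisance count accounts for regressors
    removed from the time courses before correlation and is configurable
    because the effective df of filtered fMRI data is convention-dependent.
    """
    df = n - 2 - n_nuisance
    if df < 1:
        raise ValueError("not enough time points for the requested df")
    r = np.clip(np.asarray(r, dtype=float), -_R_CLIP, _R_CLIP)
    t = r * np.sqrt(df / (1.0 - r**2))
    return 2.0 * sps.t.sf(np.abs(t), df)


# ---------------------------------------------------------------------------
# FDR step-up selection
# ---------------------------------------------------------------------------


def fdr_select(pvals, cfg: FdrConfig = FdrConfig()) -> tuple[np.ndarray, float]:
    """BH/BY step-up selection.

    Returns ``(mask, threshold)`` where ``threshold`` is the largest p-value
    passing the step-up rule (0.0 if none pass) and the mask selects all
    p <= threshold, so tied p-values share their fate.  BY divides q by the
    harmonic sum c(m) = sum_{i=1..m} 1/i to allow arbitrary dependence.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    q = cfg.q
    if cfg.method == "BY":
        q = q / np.sum(1.0 / np.arange(1, m + 1))
    p_sorted = np.sort(p.ravel())
    crit = q * np.arange(1, m + 1) / m
    passing = np.nonzero(p_sorted <= crit)[0]
    if passing.size == 0:
        return np.zeros(p.shape, dtype=bool), 0.0
    threshold = float(p_sorted[passing[-1]])
    return p <= threshold, threshold


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

_STRUCTS = {6: 1, 18: 2, 26: 3}


def _tfce_one_sided(pos: np.ndarray, params: TfceParams, dh: float) -> np.ndarray:
    """Enhance the non-negative map `pos` (already masked)."""
    out = np.zeros_like(pos, dtype=float)
    hmax = float(pos.max(initial=0.0))
    if hmax <= 0:
        return out
    struct = ndimage.generate_binary_structure(3, _STRUCTS[params.connectivity])
    n_steps = int(np.floor(hmax / dh + 1e-12))
    for k in range(1, n_steps + 1):
        h = k * dh
        supra = pos >= h
        if not supra.any():
            break
        lab, n_lab = ndimage.label(supra, structure=struct)
        sizes = np.bincount(lab.ravel())
        contrib = (sizes[lab] ** params.E) * (h**params.H) * dh
        out[supra] += contrib[supra]
    return out


def tfce(
    stat_map: np.ndarray,
    params: TfceParams = TfceParams(),
    mask: np.ndarray | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3D statistic map.

    Integrates extent(h)^E * h^H over suprathreshold levels h in steps of
    ``dh`` (right-endpoint sum), positive and negative lobes separately.
    With ``normalize=True`` the enhanced map is rescaled so its maximum
    magnitude equals the original map's maximum |stat|, putting the output
    back on the t-value scale.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if stat_map.ndim != 3:
        raise ValueError("TFCE expects a 3D map")
    if not np.all(np.isfinite(stat_map)):
        raise ValueError("statistic map must be finite")
    work = stat_map.copy()
    if mask is not None:
        work = np.where(mask, work, 0.0)
    amax = float(np.abs(work).max(initial=0.0))
    if amax == 0:
        return np.zeros_like(work)
    dh = params.dh if params.dh is not None else amax / 100.0
    enhanced = _tfce_one_sided(np.clip(work, 0, None), params, dh)
    enhanced -= _tfce_one_sided(np.clip(-work, 0, None), params, dh)
    if normalize:
        emax = float(np.abs(enhanced).max(initial=0.0))
        if emax > 0:
            enhanced *= amax / emax
    return enhanced


# ---------------------------------------------------------------------------
# Permutation null engine
# ---------------------------------------------------------------------------


def _summarize(values: np.ndarray, summary) -> float:
    values = np.asarray(values, dtype=float).ravel()
    if isinstance(summary, str):
        if summary != "max":
            raise ValueError("summary must be 'max' or a quantile in (0,1)")
        return float(values.max(initial=0.0))
    return float(np.quantile(values, float(summary)))


def permutation_null(stat_fn, n_units: int, scheme: PermScheme):
    """Generic permutation null distribution with a configurable summary.

    ``stat_fn(perm)`` must return the voxelwise/edgewise statistics for one
    permutation, where ``perm`` is a sign vector (sign_flip) or an index
    permutation (group_exchange / pair_exchange) over ``n_units`` units.
    The identity permutation is always included in the null (standard bias
    correction).  Returns ``(null_summaries, threshold)`` with the threshold
    at the 95% quantile of the summaries.
    """
    rng = np.random.default_rng(scheme.seed)
    summaries = np.empty(scheme.n_perm)
    for i in range(scheme.n_perm):
        if i == 0:  # identity permutation always in the null
            perm = np.ones(n_units, dtype=int) if scheme.kind == "sign_flip" else np.arange(n_units)
        elif scheme.kind == "sign_flip":
            perm = rng.choice([-1, 1], size=n_units)
        else:
            perm = rng.permutation(n_units)
        summaries[i] = _summarize(stat_fn(perm), scheme.summary)
    threshold = float(np.quantile(summaries, 0.95))
    return summaries, threshold
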