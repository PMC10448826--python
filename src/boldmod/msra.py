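"""Multi-seed-region analysis (MSRA).

For every grey-matter region a spherical seed (~7.5 mm diameter) is placed
at its centre of mass; the seed's mean time course is correlated with every
brain voxel and the map is BY-FDR thresholded.  Connectivity from seed
region i to target region j is the mean Pearson r of j's significant target
voxels, Fisher-z transformed — target voxels are data-driven, so the matrix
is asymmetric by construction.  The seed correlation maps (SCMs) are
retained for the downstream modulation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import FdrConfig, correlation_pvalues, fdr_select, fisher_z
from .volume import BoldSeries, LabelVolume, center_of_mass

logger = logging.getLogger(__name__)

TARGET_DIAMETER_MM = 7.5


def kernel_for_voxel_size(voxel_size_mm: float, target_diameter_mm: float = TARGET_DIAMETER_MM) -> int:
    """Odd voxel count whose physical extent is closest to the target diameter.

    1.5 mm voxels -> kernel 5 (7.5 mm); 2.0 mm voxels -> kernel 3 (6 mm).
    """
    best, best_err = 1, float("inf")
    for k in range(1, 16, 2):
        err = abs(k * voxel_size_mm - target_diameter_mm)
        if err < best_err:
            best, best_err = k, err
    return best


@dataclass
class SeedSpec:
    region: int
    kernel: int
    center: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel must be odd and >= 1")


@dataclass
class SeedCorrMap:
    """Voxelwise correlation with one seed's mean course, plus significance."""

    r: np.ndarray
    sig_mask: np.ndarray
    seed: SeedSpec
    tags: dict = field(default_factory=dict)

    def z(self, thresholded: bool = True) -> np.ndarray:
        """Fisher-z map; with ``thresholded`` non-significant voxels are zeroed."""
        z = fisher_z(self.r)
        if thresholded:
            z = np.where(self.sig_mask, z, 0.0)
        return z

    def sign_lobe(self, sign: str, thresholded: bool = True) -> np.ndarray:
        """Positive or negative correlation lobe of the z map, other sign zeroed."""
        z = self.z(thresholded)
        if sign == "positive":
            return np.clip(z, 0.0, None)
        if sign == "negative":
            return np.clip(z, None, 0.0)
        raise ValueError("sign must be 'positive' or 'negative'")


@dataclass
class ConnectivityMatrix:
    """Asymmetric region x region Fisher-z matrix (row = seed, column = target)."""

    z: np.ndarray
    counts: np.ndarray
    region_labels: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.region_labels, columns=self.region_labels)

    def symmetrized(self) -> np.ndarray:
        """Arithmetic mean of the two directed cells (used by all graph ops)."""
        return 0.5 * (self.z + self.z.T)

    def offdiag(self) -> np.ndarray:
        """Flattened off-diagonal cells (both directions) in a fixed order."""
        n = self.z.shape[0]
        mask = ~np.eye(n, dtype=bool)
        return self.z[mask]


def place_seed(
    labels: LabelVolume,
    region: int,
    kernel: int | None = None,
    brain_mask: np.ndarray | None = None,
) -> tuple[SeedSpec, np.ndarray]:
    """Spherical seed at the region's centre of mass.

    The sphere holds voxels within Euclidean radius (kernel * voxel_size)/2
    (mm) of the centre, intersected with the brain mask.  ``kernel=None``
    picks the odd count closest to 7.5 mm for the label volume's voxel size.
    """
    vs = labels.voxel_size
    if kernel is None:
        kernel = kernel_for_voxel_size(float(vs[0]))
    spec = SeedSpec(region=region, kernel=kernel, center=center_of_mass(labels, region))
    radius = kernel * float(vs[0]) / 2.0
    grid = np.indices(labels.grid)
    center = np.asarray(spec.center)
    d2 = sum(((grid[a] - center[a]) * vs[a]) ** 2 for a in range(3))
    sphere = d2 <= radius**2 + 1e-9
    brain = labels.brain_mask() if brain_mask is None else np.asarray(brain_mask, bool)
    sphere &= brain
    if not sphere.any():
        raise ValueError(f"seed sphere for region {region} is empty within the brain")
    return spec, sphere


def seed_correlation_map(
    series: BoldSeries,
    seed_mask: np.ndarray,
    seed_spec: SeedSpec | None = None,
    brain_mask: np.ndarray | None = None,
    fdr: FdrConfig = FdrConfig(q=0.05, method="BY"),
    n_nuisance: int = 0,
    n_timepoints: int | None = None,
    tags: dict | None = None,
) -> SeedCorrMap:
    """Correlate the seed's mean course with every brain voxel; BY-FDR mask.

    ``n_timepoints`` overrides the sample count used for the correlation
    p-values (e.g. the effective dof of band-passed data); default is the
    number of volumes.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    seed_course = series.data[seed_mask].mean(axis=0).astype(float)
    sd = seed_course.std()
    if sd == 0:
        raise ValueError("seed time course has zero variance")
    t = n_timepoints if n_timepoints is not None else series.n_volumes
    brain = np.ones(series.grid, dtype=bool) if brain_mask is None else np.asarray(brain_mask, bool)
    flat = series.data[brain].astype(float)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.sqrt((flat**2).sum(axis=1))
    sc = seed_course - seed_course.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r_vals = np.where(norms > 0, flat @ sc / (norms * np.sqrt((sc**2).sum())), 0.0)
    r_vals = np.clip(r_vals, -1.0, 1.0)
    p = correlation_pvalues(r_vals, n=t, n_nuisance=n_nuisance)
    p[norms == 0] = 1.0
    mask_flat, _ = fdr_select(p, fdr)
    r_map = np.zeros(series.grid)
    sig = np.zeros(series.grid, dtype=bool)
    r_map[brain] = r_vals
    sig[brain] = mask_flat
    if seed_spec is None:
        seed_spec = SeedSpec(region=-1, kernel=1, center=(0, 0, 0))
    return SeedCorrMap(r=r_map, sig_mask=sig, seed=seed_spec, tags=dict(tags or {}))


def msra_matrix(
    series: BoldSeries,
    labels: LabelVolume,
    kernel: int | None = None,
    fdr: FdrConfig = FdrConfig(q=0.05, method="BY"),
    n_nuisance: int = 0,
    n_timepoints: int | None = None,
    keep_maps: bool = True,
) -> tuple[ConnectivityMatrix, dict[int, SeedCorrMap]]:
    """Full MSRA: one SCM per grey-matter seed region, averaged into the matrix.

    Nodes are GM regions only.  Cell (seed, target) is the Fisher-z of the
    mean r over the target region's FDR-significant voxels; cells with no
    significant target voxel are 0 with count 0 (kept explicit, not
    missing).  The diagonal is set to 0 and excluded from statistics.
    """
    if series.grid != labels.grid:
        raise ValueError("series and label grids differ")
    gm_labels = labels.gm_labels()
    n = len(gm_labels)
    brain = labels.brain_mask()
    region_masks = {lab: labels.labels == lab for lab in gm_labels}
    z = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    maps: dict[int, SeedCorrMap] = {}
    for i, seed_lab in enumerate(gm_labels):
        spec, sphere = place_seed(labels, seed_lab, kernel=kernel, brain_mask=brain)
        scm = seed_correlation_map(
            series, sphere, spec, brain_mask=brain, fdr=fdr, n_nuisance=n_nuisance,
            n_timepoints=n_timepoints, tags=dict(series.tags, seed_region=seed_lab),
        )
        for j, tgt_lab in enumerate(gm_labels):
            if tgt_lab == seed_lab:
                continue
            sel = scm.sig_mask & region_masks[tgt_lab]
            c = int(sel.sum())
            counts[i, j] = c
            if c:
                z[i, j] = fisher_z(float(scm.r[sel].mean()))
        if keep_maps:
            maps[seed_lab] = scm
    return ConnectivityMatrix(z=z, counts=counts, region_labels=list(gm_labels)), maps


def write_matrix(matrix: ConnectivityMatrix, z_path, counts_path=None) -> None:
    matrix.to_frame().to_csv(z_path, sep="\t")
    if counts_path is not None:
        pd.DataFrame(
            matrix.counts, index=matrix.region_labels, columns=matrix.region_labels
        ).to_csv(counts_path, sep="\t")
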