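"""Volume containers, NIfTI-1 I/O, and label-geometry utilities.

Every stage of the pipeline exchanges data through the three containers
defined here: :class:`BoldSeries` (a 4D voxel time series with its voxel
geometry and TR), :class:`LabelVolume` (an integer parcellation plus a region
table with hemisphere, homotopic partner and tissue class), and
:class:`ProbAtlas` (per-region probability volumes).  Conventions are fixed
once: 0-based voxel indices, time axis last, identity affine for synthetic
data (real-data affines are carried through untouched).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

REGION_TABLE_COLUMNS = [
    "label",
    "name",
    "hemisphere",
    "homotopic_partner",
    "tissue_class",
]


@dataclass
class BoldSeries:
    """4D BOLD intensities indexed (x, y, z, t) with voxel size (mm) and TR (s)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    tr: float = 2.0
    tags: dict = field(default_factory=dict)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # promote a single volume to t=1
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 3D or 4D, got ndim={self.data.ndim}")
        if self.n_volumes < 1:
            raise ValueError("series must contain at least one volume")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series contains non-finite intensities")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def mean_volume(self) -> np.ndarray:
        """Temporal mean image, the substrate of the spatial quality metrics."""
        return self.data.mean(axis=3)

    def replace(self, data: np.ndarray, **tags) -> "BoldSeries":
        new_tags = dict(self.tags)
        new_tags.update(tags)
        return dataclasses.replace(self, data=data, tags=new_tags)


@dataclass
class LabelVolume:
    """Integer parcellation (0 = background) plus its region table.

    The region table has columns ``label, name, hemisphere, homotopic_partner,
    tissue_class`` with hemisphere in {L, R, M}, tissue class in
    {GM, WM, CSF}, and ``homotopic_partner`` 0 for unpaired regions.
    """

    labels: np.ndarray
    table: pd.DataFrame
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")
        missing = set(np.unique(self.labels)) - {0} - set(self.table["label"])
        if missing:
            raise ValueError(f"labels missing from region table: {sorted(missing)}")
        part = dict(zip(self.table["label"], self.table["homotopic_partner"]))
        for lab, par in part.items():
            if par and part.get(par, 0) != lab:
                raise ValueError(f"homotopic pairing not symmetric for label {lab}")

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.labels.shape

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def tissue_mask(self, *classes: str) -> np.ndarray:
        labs = self.table.loc[self.table["tissue_class"].isin(classes), "label"]
        return np.isin(self.labels, np.asarray(labs))

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def gm_labels(self) -> list[int]:
        return list(self.table.loc[self.table["tissue_class"] == "GM", "label"])

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """Unordered (left, right) label pairs, each pair listed once."""
        pairs = []
        for _, row in self.table.iterrows():
            p = row["homotopic_partner"]
            if p and row["label"] < p:
                pairs.append((int(row["label"]), int(p)))
        return pairs


@dataclass
class ProbAtlas:
    """Per-region probability volumes, shape (x, y, z, n_regions), values in [0, 1]."""

    probs: np.ndarray
    table: pd.DataFrame
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs)
        if self.probs.ndim != 4:
            raise ValueError("probability atlas must be 4D (x, y, z, region)")
        if self.probs.shape[3] != len(self.table):
            raise ValueError("one probability volume per table row required")
        if self.probs.min() < 0 or self.probs.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# NIfTI-1 I/O
# ---------------------------------------------------------------------------


def write_series(series: BoldSeries, path) -> None:
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.float32), series.affine)
    img.header.set_zooms(tuple(series.voxel_size) + ((series.tr,) if series.n_volumes > 1 else ()))
    nib.save(img, str(path))


def read_series(path, tr: float | None = None, tags: dict | None = None) -> BoldSeries:
    """Read a 3D or 4D NIfTI-1 file; a 3D image is promoted to t = 1."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise ValueError(f"not a readable NIfTI file: {path}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise ValueError(f"expected a 3D or 4D image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()
    if tr is None:
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return BoldSeries(
        data=data,
        voxel_size=tuple(float(z) for z in zooms[:3]),
        tr=tr,
        tags=tags or {},
        affine=np.asarray(img.affine),
    )


def write_labels(labels: LabelVolume, nifti_path, table_path) -> None:
    aff = np.diag(list(labels.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), aff), str(nifti_path))
    labels.table[REGION_TABLE_COLUMNS].to_csv(table_path, sep="\t", index=False)


def read_labels(nifti_path, table_path) -> LabelVolume:
    img = nib.load(str(nifti_path))
    table = pd.read_csv(table_path, sep="\t")
    return LabelVolume(
        labels=np.asanyarray(img.dataobj).astype(int),
        table=table,
        voxel_size=tuple(float(z) for z in img.header.get_zooms()[:3]),
    )


# ---------------------------------------------------------------------------
# Label handling and geometry
# ---------------------------------------------------------------------------


def max_probability_map(atlas: ProbAtlas, median_kernel: int = 3) -> LabelVolume:
    """Median-filter each region probability volume, then assign argmax labels.

    Voxels whose filtered probabilities are all zero become background.  The
    default cubic kernel of 3 voxels matches standard atlas practice; a
    kernel of 1 is the identity filter.  Boundary handling is reflect
    padding.  Ties in the argmax go to the lowest region index
    (deterministic).
    """
    if median_kernel < 1 or median_kernel % 2 == 0:
        raise ValueError("median kernel must be odd and >= 1")
    if median_kernel == 1:
        filtered = atlas.probs
    else:
        filtered = np.stack(
            [
                ndimage.median_filter(atlas.probs[..., k], size=median_kernel, mode="reflect")
                for k in range(atlas.probs.shape[3])
            ],
            axis=-1,
        )
    best = np.argmax(filtered, axis=3)
    labels = np.asarray(atlas.table["label"])[best]
    labels[filtered.max(axis=3) <= 0] = 0
    return LabelVolume(labels=labels, table=atlas.table, voxel_size=atlas.voxel_size)


def center_of_mass(labels: LabelVolume, region: int) -> tuple[int, int, int]:
    """Unweighted geometric centroid of a region, snapped into the region.

    The centroid is rounded half-down to the nearest voxel; if that voxel is
    not a member of the region (e.g. a C-shaped region whose centroid falls
    in its cavity) the nearest member voxel is returned, Euclidean ties
    broken toward the lowest linear index.
    """
    coords = np.argwhere(labels.labels == region)
    if coords.size == 0:
        raise ValueError(f"region {region} has no voxels")
    centroid = coords.mean(axis=0)
    rounded = np.ceil(centroid - 0.5).astype(int)  # round half down
    if (labels.labels[tuple(rounded)] == region):
        return tuple(int(v) for v in rounded)
    d2 = ((coords - centroid) ** 2).sum(axis=1)
    # lexsort on (linear index, distance): stable lowest-linear-index tie-break
    lin = np.ravel_multi_index(coords.T, labels.grid)
    best = np.lexsort((lin, np.round(d2, 12)))[0]
    return tuple(int(v) for v in coords[best])


def region_centroids_mm(labels: LabelVolume) -> dict[int, np.ndarray]:
    """Region centroids in millimetres (voxel index x voxel size), GM and beyond."""
    out = {}
    vs = np.asarray(labels.voxel_size)
    for lab in labels.table["label"]:
        coords = np.argwhere(labels.labels == lab)
        if coords.size:
            out[int(lab)] = coords.mean(axis=0) * vs
    return out
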