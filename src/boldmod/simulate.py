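"""Synthetic two-group, two-session BOLD studies with known ground truth.

The generator emulates the study design every downstream stage expects: a
small bilateral parcellation (mirrored left/right grey-matter blocks plus a
white-matter compartment and a ventricle), region mean time series drawn
from a multivariate normal with a planted community + homotopic correlation
structure, HRF-convolved boxcar task responses in designated motor regions,
independent thermal voxel noise, and a slow sinusoidal drift.  Two groups
(ft / rest) are scanned in two resting-state sessions (rs1, rs2) with the
task (or rest) in between; a connectivity modulation on chosen edges is
planted in the ft-group's rs2 covariance only, so its ground truth is
directly interpretable as a Delta r.

Default parameters are the study conditions: TR 2 s, 300 resting volumes
(10 min) and 105 task volumes per session, 9 subjects per group, 1.5 mm
isotropic voxels, 8 bilateral region pairs, and a planted Delta r of 0.3 on
five seed-target edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import DesignParadigm, hrf_regressor
from .volume import BoldSeries, LabelVolume, ProbAtlas

TISSUE_MEANS = {"GM": 1000.0, "WM": 800.0, "CSF": 500.0}


def nearest_psd(matrix: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Nearest positive-semi-definite repair by eigenvalue clipping.

    Hand-specified correlation targets are often slightly indefinite; the
    repair clips eigenvalues at ``eig_floor`` and restores a unit diagonal.
    """
    m = 0.5 * (np.asarray(matrix, float) + np.asarray(matrix, float).T)
    w, v = np.linalg.eigh(m)
    w = np.clip(w, eig_floor, None)
    fixed = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator (defaults = the design)."""

    dims: tuple[int, int, int] = (16, 27, 15)
    voxel_size_mm: float = 1.5
    n_region_pairs: int = 8
    block: int = 5  # GM region cube side: holds the 7.5 mm seed sphere (5 voxels at 1.5 mm)
    tissue_means: dict = field(default_factory=lambda: dict(TISSUE_MEANS))
    background_mean: float = 0.0
    signal_sd: float = 10.0  # intensity units per unit region course
    noise_sd: float = 10.0  # thermal voxel noise
    background_noise_sd: float = 2.0
    drift_amplitude: float = 10.0
    drift_period_s: float = 120.0
    tr: float = 2.0
    n_volumes: int = 300
    n_volumes_task: int = 105
    n_subjects: int = 9  # per group
    task_regions: tuple[int, ...] = ()  # filled from the atlas if empty
    task_amplitude_pct: float = 2.0
    r_homotopic: float = 0.6
    r_community: float = 0.3
    r_background: float = 0.05
    n_communities: int = 2
    subject_jitter_sd: float = 0.03
    planted_edges: tuple[tuple[int, int, float], ...] = ()
    base_covariance: np.ndarray | None = None
    include_task_sessions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        self.task_regions = tuple(self.task_regions)
        self.planted_edges = tuple(tuple(e) for e in self.planted_edges)
        if min(self.dims) < 8:
            raise ValueError("grid dims must be >= 8 per axis")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for r in (self.r_homotopic, self.r_community, self.r_background):
            if abs(r) >= 1:
                raise ValueError("correlation targets must satisfy |r| < 1")

    @property
    def n_gm(self) -> int:
        return 2 * self.n_region_pairs


def default_planted_edges(config: SimConfig, delta: float = 0.3, n_edges: int = 5) -> tuple:
    """The study's planted modulation: one seed region, ``n_edges`` targets.

    The seed is the right member of the first bilateral pair (the analogue
    of the right motor cortex); targets are other members of the seed's own
    community — the modulation strengthens edges within the task-positive
    network, mirroring the post-task phenomenon the pipeline is built to
    detect.  Returns ((seed, target, delta), ...).
    """
    P = config.n_region_pairs
    seed = P + 1  # right member of pair 0 (labels L:1..P, R:P+1..2P)
    per = int(np.ceil(P / config.n_communities))
    # community of pair 0: left members 2..per, right members P+2..P+per
    candidates = [k for k in range(2, per + 1)] + [P + k for k in range(2, per + 1)]
    if len(candidates) < n_edges:
        raise ValueError("not enough same-community regions for the requested planted edges")
    targets = candidates[:n_edges]
    return tuple((seed, t, delta) for t in targets)


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------


def make_phantom_atlas(config: SimConfig, blur_sigma: float = 0.0) -> tuple[ProbAtlas, LabelVolume]:
    """Build the bilateral block phantom parcellation.

    GM labels 1..P on the left (x < midline), P+1..2P mirrored on the right,
    label 2P+1 = white matter (the remaining interior), 2P+2 = ventricle
    (central block), 0 = background shell.  The probabilistic version is
    one-hot, optionally Gaussian-blurred at the edges.
    """
    nx, ny, nz = config.dims
    P = config.n_region_pairs
    b = config.block
    margin = 2
    # left blocks occupy x in [margin, margin+b); mirrored right; WM needs 2 central columns
    if nx < 2 * (margin + b) + 2:
        raise ValueError(f"x-dim {nx} too small for bilateral blocks of side {b}")
    stride = b + 1
    slots = []
    for z0 in range(margin, nz - margin - b + 1, stride):
        for y0 in range(margin, ny - margin - b + 1, stride):
            slots.append((y0, z0))
    if len(slots) < P:
        raise ValueError(
            f"grid {config.dims} hosts only {len(slots)} region slots; {P} pairs requested"
        )
    labels = np.zeros(config.dims, dtype=int)
    x_left = slice(margin, margin + b)
    for k in range(P):
        y0, z0 = slots[k]
        labels[x_left, y0 : y0 + b, z0 : z0 + b] = k + 1
    mirrored = labels[::-1, :, :].copy()  # mirror left blocks across the midline
    labels[mirrored > 0] = mirrored[mirrored > 0] + P
    wm_label, csf_label = 2 * P + 1, 2 * P + 2
    interior = np.zeros(config.dims, dtype=bool)
    interior[margin : nx - margin, margin : ny - margin, margin : nz - margin] = True
    cx, cy, cz = nx // 2, ny // 2, nz // 2
    vent = np.zeros(config.dims, dtype=bool)
    vent[cx - 1 : cx + 1, cy - 1 : cy + 1, cz - 1 : cz + 1] = True
    vent &= interior & (labels == 0)
    labels[vent] = csf_label
    labels[interior & (labels == 0)] = wm_label

    rows = []
    for k in range(1, P + 1):
        rows.append((k, f"region_{k:02d}_L", "L", k + P, "GM"))
        rows.append((k + P, f"region_{k:02d}_R", "R", k, "GM"))
    rows.append((wm_label, "white_matter", "M", 0, "WM"))
    rows.append((csf_label, "ventricle", "M", 0, "CSF"))
    table = pd.DataFrame(
        rows, columns=["label", "name", "hemisphere", "homotopic_partner", "tissue_class"]
    ).sort_values("label", ignore_index=True)
    vs = (config.voxel_size_mm,) * 3
    label_vol = LabelVolume(labels=labels, table=table, voxel_size=vs)

    probs = np.zeros(config.dims + (len(table),), dtype=np.float32)
    for i, lab in enumerate(table["label"]):
        probs[..., i] = (labels == lab).astype(np.float32)
    if blur_sigma > 0:
        from scipy import ndimage

        for i in range(probs.shape[-1]):
            probs[..., i] = ndimage.gaussian_filter(probs[..., i], blur_sigma)
        probs = np.clip(probs, 0.0, 1.0)
    return ProbAtlas(probs=probs, table=table, voxel_size=vs), label_vol


# ---------------------------------------------------------------------------
# Covariance targets
# ---------------------------------------------------------------------------


def base_covariance(config: SimConfig) -> np.ndarray:
    """Community + homotopic correlation target over all labelled regions.

    GM pairs are split into ``n_communities`` contiguous groups; both
    members of a pair share a community.  Correlations: homotopic partners
    ``r_homotopic``, same community ``r_community``, otherwise
    ``r_background``.  WM and ventricle courses are uncorrelated with GM.
    The result is PSD-repaired.
    """
    if config.base_covariance is not None:
        c = np.asarray(config.base_covariance, float)
        return nearest_psd(c)
    P = config.n_region_pairs
    n = config.n_gm + 2  # + WM + CSF
    community = np.empty(config.n_gm, dtype=int)
    per = int(np.ceil(P / config.n_communities))
    for k in range(P):
        community[k] = community[k + P] = k // per
    c = np.full((n, n), 0.0)
    gm = slice(0, config.n_gm)
    c[gm, gm] = config.r_background
    for i in range(config.n_gm):
        for j in range(config.n_gm):
            if i == j:
                continue
            if community[i] == community[j]:
                c[i, j] = config.r_community
    for k in range(P):
        c[k, k + P] = c[k + P, k] = config.r_homotopic
    np.fill_diagonal(c, 1.0)
    return nearest_psd(c)


def planted_covariance(config: SimConfig, cov: np.ndarray) -> np.ndarray:
    """Apply the planted Delta r of the ft-group rs2 session to a covariance."""
    c = cov.copy()
    n_gm = config.n_gm
    for seed, target, delta in config.planted_edges:
        if not (1 <= seed <= n_gm and 1 <= target <= n_gm):
            raise ValueError(f"planted edge ({seed},{target}) references a non-GM region")
        i, j = seed - 1, target - 1
        c[i, j] += delta
        c[j, i] += delta
    return nearest_psd(c)


# ---------------------------------------------------------------------------
# Sessions and studies
# ---------------------------------------------------------------------------


def _region_index_map(config: SimConfig, labels: LabelVolume) -> dict[int, int]:
    """Label -> row index of the covariance matrix (GM 1..2P, then WM, CSF)."""
    return {int(lab): i for i, lab in enumerate(sorted(labels.table["label"]))}


def simulate_session(
    labels: LabelVolume,
    config: SimConfig,
    mode: str = "rest",
    covariance: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    tags: dict | None = None,
) -> BoldSeries:
    """Simulate one session on the phantom atlas.

    Region mean courses are multivariate normal draws with the target
    correlation structure, broadcast to member voxels; each voxel adds
    independent thermal noise, a sinusoidal scanner drift, and its tissue
    baseline.  ``mode='task'`` adds the HRF-convolved boxcar response
    (``task_amplitude_pct`` of the GM baseline) in the task regions and uses
    the task-run length.
    """
    if mode not in ("rest", "task"):
        raise ValueError("mode must be 'rest' or 'task'")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    cov = covariance if covariance is not None else base_covariance(config)
    w = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if w.min() < -1e-6:
        raise ValueError("covariance not PSD after repair tolerance")
    n_vol = config.n_volumes if mode == "rest" else config.n_volumes_task
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
    courses = (chol @ rng.standard_normal((cov.shape[0], n_vol)))  # (regions, t)

    task_pred = None
    task_regions = config.task_regions
    if mode == "task":
        if not task_regions:
            raise ValueError("task mode requires task regions")
        design = DesignParadigm(tr=config.tr)
        task_pred = hrf_regressor(design)[:n_vol]

    idx = _region_index_map(config, labels)
    data = np.empty(config.dims + (n_vol,), dtype=np.float32)
    bg_noise = rng.standard_normal(data.shape).astype(np.float32)
    data[:] = config.background_mean + config.background_noise_sd * bg_noise
    t_axis = np.arange(n_vol) * config.tr
    drift = config.drift_amplitude * np.sin(
        2 * np.pi * t_axis / config.drift_period_s + rng.uniform(0, 2 * np.pi)
    )
    tissue_of = dict(zip(labels.table["label"], labels.table["tissue_class"]))
    for lab, row in idx.items():
        mask = labels.labels == lab
        n_vox = int(mask.sum())
        if n_vox == 0:
            continue
        course = config.signal_sd * courses[row]
        base = config.tissue_means[tissue_of[lab]]
        if task_pred is not None and lab in task_regions:
            course = course + (config.task_amplitude_pct / 100.0) * base * task_pred
        vox = base + course + drift + config.noise_sd * rng.standard_normal((n_vox, n_vol))
        data[mask] = vox.astype(np.float32)
    return BoldSeries(
        data=data,
        voxel_size=(config.voxel_size_mm,) * 3,
        tr=config.tr,
        tags=dict(tags or {}, mode=mode),
    )


@dataclass
class Subject:
    subject_id: str
    group: str  # 'ft' | 'rest'
    sessions: dict  # name -> BoldSeries


@dataclass
class StudySet:
    """A full synthetic study: subjects, the shared atlas, and ground truth."""

    subjects: list
    atlas: ProbAtlas
    labels: LabelVolume
    config: SimConfig
    ground_truth: dict


def simulate_study(config: SimConfig) -> StudySet:
    """Generate the two-group, two-session study; deterministic given the seed.

    Every subject gets an independent covariance jitter (symmetric
    off-diagonal perturbation, PSD-repaired, recorded in the ground truth);
    ft-group subjects get the planted Delta r added to their rs2 covariance
    and a task session in between.
    """
    if config.n_subjects < 2:
        raise ValueError("need at least 2 subjects per group")
    atlas, labels = make_phantom_atlas(config)
    cfg = config
    if not cfg.task_regions:
        # bilateral pair 0 is the designated motor region pair
        cfg = dataclasses_replace(cfg, task_regions=(1, cfg.n_region_pairs + 1))
    base = base_covariance(cfg)
    root = np.random.SeedSequence(cfg.seed)
    subjects = []
    truth_cov: dict[str, dict[str, np.ndarray]] = {}
    for group in ("ft", "rest"):
        for s in range(cfg.n_subjects):
            sid = f"{group}{s:02d}"
            child = np.random.default_rng(root.spawn(1)[0])
            jitter = cfg.subject_jitter_sd * child.standard_normal(base.shape)
            jitter = 0.5 * (jitter + jitter.T)
            np.fill_diagonal(jitter, 0.0)
            cov_subj = nearest_psd(base + jitter)
            cov_rs2 = planted_covariance(cfg, cov_subj) if group == "ft" else cov_subj
            sessions = {
                "rs1": simulate_session(labels, cfg, "rest", cov_subj, child,
                                        tags={"subject": sid, "group": group, "session": "rs1"}),
            }
            if group == "ft" and cfg.include_task_sessions:
                sessions["task"] = simulate_session(labels, cfg, "task", cov_subj, child,
                                                    tags={"subject": sid, "group": group, "session": "task"})
            sessions["rs2"] = simulate_session(labels, cfg, "rest", cov_rs2, child,
                                               tags={"subject": sid, "group": group, "session": "rs2"})
            subjects.append(Subject(subject_id=sid, group=group, sessions=sessions))
            truth_cov[sid] = {"rs1": cov_subj, "rs2": cov_rs2}
    ground_truth = {
        "base_covariance": base,
        "subject_covariances": truth_cov,
        "planted_edges": list(cfg.planted_edges),
        "task_regions": list(cfg.task_regions),
        "homotopic_pairs": labels.homotopic_pairs(),
    }
    return StudySet(subjects=subjects, atlas=atlas, labels=labels, config=cfg, ground_truth=ground_truth)


def dataclasses_replace(cfg: SimConfig, **kw) -> SimConfig:
    import dataclasses

    return dataclasses.replace(cfg, **kw)
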