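"""Detection of post-task resting-state connectivity modulation.

The end-to-end procedure: NBS on the second resting-state session (ft vs
rest group) finds a significant component; its dominant (highest-degree)
regions become seeds; per seed, voxelwise paired t-tests of the rs2-vs-rs1
seed-correlation maps (positive and negative correlation lobes separately,
per group) are TFCE-enhanced and thresholded against a sign-flip
permutation null (summary: 99.9th voxel percentile, rejection at its 95%
quantile); the two group masks are OR-combined; per-subject region mean
Delta z (rs2 - rs1) inside the mask is contrasted between groups with a
homoscedastic t-test and BH-FDR.  The result is the list of regions whose
connectivity to a task-related seed was modulated by the intervening task.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import msra as msra_mod
from . import preprocess
from .graphs import NbsResult, nbs
from .stats import FdrConfig, TfceParams, fdr_select, tfce
from .volume import LabelVolume

logger = logging.getLogger(__name__)

SIGNS = ("positive", "negative")


@dataclass
class ModulationConfig:
    """Knobs of the modulation pipeline (defaults follow the reference procedure)."""

    nbs_alpha: float = 0.05
    nbs_n_perm: int = 10_000
    tfce: TfceParams = field(default_factory=TfceParams)
    tfce_n_perm: int = 1000
    tfce_null_quantile: float = 0.999
    rejection_quantile: float = 0.95
    coverage_fraction: float = 0.01  # min mask coverage of a region
    fdr_q: float = 0.05
    max_seeds: int | None = None  # None: all regions tying at maximal degree
    seed: int = 0


@dataclass
class ModulationResult:
    seeds: list
    nbs_result: NbsResult | None
    masks: dict  # (seed, sign) -> {'ft', 'rest', 'combined'}
    delta_z: dict  # (seed, sign) -> DataFrame subjects x regions
    region_tests: pd.DataFrame | None
    audit: dict = field(default_factory=dict)

    @property
    def significant_regions(self) -> list:
        if self.region_tests is None or self.region_tests.empty:
            return []
        sel = self.region_tests[self.region_tests["significant"]]
        return sorted(set(zip(sel["seed"], sel["sign"], sel["region"])))

    def modulated_region_labels(self) -> set:
        return {r for (_, _, r) in self.significant_regions}


def select_dominant_nodes(nbs_result: NbsResult, region_labels: list[int], k: int | None = None,
                          level: float = 0.05) -> list[int]:
    """Regions with the most modulated connections in the significant components.

    Degree is counted over all components with p_FWE below ``level``; all
    regions tying at maximal degree are returned (or the top-k if ``k``).
    """
    comps = nbs_result.significant_components(level)
    if not comps:
        logger.warning("select_dominant_nodes: no significant component")
        return []
    degree: dict[int, int] = {}
    for comp in comps:
        for i, j in comp:
            degree[i] = degree.get(i, 0) + 1
            degree[j] = degree.get(j, 0) + 1
    if k is None:
        dmax = max(degree.values())
        nodes = sorted(n for n, d in degree.items() if d == dmax)
    else:
        nodes = [n for n, _ in sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))[:k]]
    return [region_labels[n] for n in nodes]


def scm_paired_t(z_rs1: np.ndarray, z_rs2: np.ndarray, signs: np.ndarray | None = None) -> np.ndarray:
    """Voxelwise paired t of rs2 - rs1 Fisher-z maps, df = n_subjects - 1.

    ``z_rs1``/``z_rs2`` are (n_subjects, x, y, z) stacks; ``signs`` applies
    per-subject sign flips for permutation testing.
    """
    diff = z_rs2 - z_rs1
    if signs is not None:
        diff = diff * signs[:, None, None, None]
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def tfce_significant_mask(
    z_rs1: np.ndarray,
    z_rs2: np.ndarray,
    brain_mask: np.ndarray,
    params: TfceParams = TfceParams(),
    n_perm: int = 1000,
    null_quantile: float = 0.999,
    rejection_quantile: float = 0.95,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """TFCE-corrected significance mask of a paired rs2-vs-rs1 contrast.

    The observed |t| map is TFCE-enhanced; per sign-flip permutation the
    99.9th percentile (outlier-robust alternative to the maximum) of the
    enhanced voxel values within the brain is recorded, and the 95% quantile
    of those summaries is the rejection threshold.  Null and threshold live
    on the raw enhanced scale, as in standard TFCE permutation testing; the
    enhanced map rescaled back to the t range is returned in the info dict
    for reporting.  Degenerate all-zero maps give an empty mask.
    """
    n = z_rs1.shape[0]
    rng = np.random.default_rng(seed)
    t_obs = scm_paired_t(z_rs1, z_rs2)
    enh_obs = tfce(np.abs(t_obs), params, mask=brain_mask, normalize=False)
    emax = enh_obs.max(initial=0.0)
    if emax == 0:
        return np.zeros_like(brain_mask, dtype=bool), {"threshold": np.inf, "null": np.array([])}
    null = np.empty(n_perm)
    for i in range(n_perm):
        signs = np.ones(n) if i == 0 else rng.choice([-1.0, 1.0], size=n)
        t_perm = scm_paired_t(z_rs1, z_rs2, signs)
        enh = tfce(np.abs(t_perm), params, mask=brain_mask, normalize=False)
        null[i] = np.quantile(enh[brain_mask], null_quantile)
    threshold = float(np.quantile(null, rejection_quantile))
    mask = (enh_obs > threshold) & brain_mask
    tmax = float(np.abs(t_obs).max(initial=0.0))
    info = {
        "threshold": threshold,
        "null": null,
        "normalized_map": enh_obs * (tmax / emax),
        "threshold_t_scale": threshold * tmax / emax,
    }
    return mask, info


def combine_masks(mask_ft: np.ndarray, mask_rest: np.ndarray) -> np.ndarray:
    """Voxelwise OR of the two group masks."""
    if mask_ft.shape != mask_rest.shape:
        raise ValueError("masks must share a grid")
    return np.asarray(mask_ft, bool) | np.asarray(mask_rest, bool)


def region_delta_z(
    z_rs1: np.ndarray,
    z_rs2: np.ndarray,
    mask: np.ndarray,
    labels: LabelVolume,
    coverage_fraction: float = 0.01,
    gm_only: bool = True,
) -> pd.DataFrame:
    """Per-subject, per-region mean Delta z (rs2 - rs1) inside the mask.

    Regions whose mask coverage does not exceed ``coverage_fraction`` of
    their voxels are excluded.  Returns a subjects x regions DataFrame.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    diff = z_rs2 - z_rs1  # (subjects, x, y, z)
    region_list = labels.gm_labels() if gm_only else list(labels.table["label"])
    cols = {}
    for lab in region_list:
        region = labels.labels == lab
        sel = region & mask
        if sel.sum() <= coverage_fraction * region.sum():
            continue
        cols[lab] = diff[:, sel].mean(axis=1)
    return pd.DataFrame(cols)


def _region_contrast_frame(delta_ft: pd.DataFrame, delta_rest: pd.DataFrame) -> pd.DataFrame:
    """Homoscedastic per-region t/p of Delta z between groups (no correction)."""
    common = [c for c in delta_ft.columns if c in delta_rest.columns]
    rows = []
    for lab in common:
        a, b = delta_ft[lab].to_numpy(), delta_rest[lab].to_numpy()
        if min(a.size, b.size) < 2:
            continue
        pooled_sd = np.sqrt(
            ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
        )
        if pooled_sd == 0:
            logger.info("group_modulation_test: zero pooled variance for region %s", lab)
            rows.append({"region": lab, "t": 0.0, "p": 1.0, "direction": "none"})
            continue
        t = (a.mean() - b.mean()) / (pooled_sd * np.sqrt(1 / a.size + 1 / b.size))
        p = 2 * sps.t.sf(abs(t), a.size + b.size - 2)
        rows.append(
            {"region": lab, "t": float(t), "p": float(p),
             "direction": "ft>rest" if t > 0 else "ft<rest"}
        )
    return pd.DataFrame(rows)


def group_modulation_test(
    delta_ft: pd.DataFrame,
    delta_rest: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Homoscedastic t-test of region Delta z between groups, BH-FDR corrected.

    Only regions present in both groups' tables are tested; the returned
    frame has t, p, the BH flag, and the signed direction (ft > rest or
    ft < rest).  FDR is applied across all rows passed in one call.
    """
    frame = _region_contrast_frame(delta_ft, delta_rest)
    if frame.empty:
        frame["significant"] = pd.Series(dtype=bool)
        return frame
    mask, _ = fdr_select(frame["p"].to_numpy(), FdrConfig(q=q, method="BH"))
    frame["significant"] = mask
    return frame


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_modulation_pipeline(
    study,
    config: ModulationConfig = ModulationConfig(),
    preproc_config: preprocess.PreprocConfig | None = None,
    msra_kernel: int | None = None,
) -> ModulationResult:
    """Run the full modulation analysis on a synthetic study.

    Stages: resting-state preprocessing -> MSRA per subject/session -> NBS on
    rs2 (ft vs rest) -> dominant-node seed selection -> per-seed/sign/group
    TFCE-corrected paired contrasts -> OR mask -> region Delta z -> group
    test with BH-FDR.  All thresholds, seeds and intermediate summaries are
    kept in the audit trail.
    """
    labels = study.labels
    pcfg = preproc_config or preprocess.PreprocConfig()
    audit: dict = {"stages": [], "seed": config.seed}

    # --- preprocessing + MSRA on rs2 (the data-driven first stage) --------
    matrices_rs2: dict[str, np.ndarray] = {}
    scms: dict[tuple[str, str], dict[int, msra_mod.SeedCorrMap]] = {}
    groups: dict[str, str] = {}
    n_nuis = len(pcfg.nuisance_classes)
    region_labels = labels.gm_labels()
    n_eff = None
    for subj in study.subjects:
        groups[subj.subject_id] = subj.group
        try:
            clean = preprocess.run_rest_preproc(subj.sessions["rs2"], labels, pcfg)
            n_eff = preprocess.effective_timepoints(clean.n_volumes, clean.tr, pcfg.band)
            mat, maps = msra_mod.msra_matrix(
                clean, labels, kernel=msra_kernel, n_nuisance=n_nuis, n_timepoints=n_eff
            )
        except Exception as exc:
            raise RuntimeError(f"[msra] failed for {subj.subject_id}/rs2") from exc
        matrices_rs2[subj.subject_id] = mat.z
        scms[(subj.subject_id, "rs2")] = maps
    audit["stages"].append("preproc+msra_rs2")

    # --- NBS on rs2, ft vs rest -------------------------------------------
    ft_ids = sorted(s for s, g in groups.items() if g == "ft")
    rest_ids = sorted(s for s, g in groups.items() if g == "rest")
    nbs_res = nbs(
        np.stack([matrices_rs2[s] for s in ft_ids]),
        np.stack([matrices_rs2[s] for s in rest_ids]),
        alpha=config.nbs_alpha,
        n_perm=config.nbs_n_perm,
        design="unpaired",
        seed=config.seed,
    )
    audit["stages"].append("nbs_rs2")
    audit["nbs_p_fwe"] = list(nbs_res.p_fwe)
    seeds = select_dominant_nodes(nbs_res, region_labels, k=config.max_seeds)
    audit["dominant_seeds"] = seeds
    if not seeds:
        return ModulationResult(
            seeds=[], nbs_result=nbs_res, masks={}, delta_z={}, region_tests=None, audit=audit
        )

    # --- rs1 SCMs, only for the selected seed regions ---------------------
    brain_for_seeds = labels.brain_mask()
    for subj in study.subjects:
        try:
            clean = preprocess.run_rest_preproc(subj.sessions["rs1"], labels, pcfg)
        except Exception as exc:
            raise RuntimeError(f"[preproc] failed for {subj.subject_id}/rs1") from exc
        maps = {}
        for seed_lab in seeds:
            spec, sphere = msra_mod.place_seed(
                labels, seed_lab, kernel=msra_kernel, brain_mask=brain_for_seeds
            )
            maps[seed_lab] = msra_mod.seed_correlation_map(
                clean, sphere, spec, brain_mask=brain_for_seeds,
                n_nuisance=n_nuis, n_timepoints=n_eff,
                tags={"subject": subj.subject_id, "session": "rs1", "seed_region": seed_lab},
            )
        scms[(subj.subject_id, "rs1")] = maps
    audit["stages"].append("rs1_scms")

    # --- per-seed TFCE contrasts, OR masks, region Delta z ----------------
    brain = labels.brain_mask()
    masks: dict = {}
    delta_z: dict = {}
    tests = []
    for seed_lab in seeds:
        for sign in SIGNS:
            stacks: dict[str, dict[str, np.ndarray]] = {}
            for grp, ids in (("ft", ft_ids), ("rest", rest_ids)):
                # unthresholded z maps: the FDR mask defines matrix target
                # voxels, not the paired-contrast input
                stacks[grp] = {
                    sess: np.stack(
                        [scms[(sid, sess)][seed_lab].sign_lobe(sign, thresholded=False)
                         for sid in ids]
                    )
                    for sess in ("rs1", "rs2")
                }
            grp_masks = {}
            for grp in ("ft", "rest"):
                m, info = tfce_significant_mask(
                    stacks[grp]["rs1"],
                    stacks[grp]["rs2"],
                    brain,
                    params=config.tfce,
                    n_perm=config.tfce_n_perm,
                    null_quantile=config.tfce_null_quantile,
                    rejection_quantile=config.rejection_quantile,
                    seed=config.seed + 101 * int(seed_lab) + 13 * SIGNS.index(sign)
                    + (0 if grp == "ft" else 7),
                )
                grp_masks[grp] = m
                audit[f"tfce_threshold/{seed_lab}/{sign}/{grp}"] = info["threshold"]
            combined = combine_masks(grp_masks["ft"], grp_masks["rest"])
            masks[(seed_lab, sign)] = {**grp_masks, "combined": combined}
            if not combined.any():
                continue
            dz = {}
            for grp in ("ft", "rest"):
                dz[grp] = region_delta_z(
                    stacks[grp]["rs1"],
                    stacks[grp]["rs2"],
                    combined,
                    labels,
                    coverage_fraction=config.coverage_fraction,
                )
            delta_z[(seed_lab, sign)] = dz
            frame = _region_contrast_frame(dz["ft"], dz["rest"])
            if frame.empty:
                continue
            frame["seed"] = seed_lab
            frame["sign"] = sign
            tests.append(frame)  # BH-FDR applied jointly across seeds x signs x regions below
    audit["stages"].append("tfce+delta_z")

    if tests:
        all_tests = pd.concat(tests, ignore_index=True)
        mask, _ = fdr_select(all_tests["p"].to_numpy(), FdrConfig(q=config.fdr_q, method="BH"))
        all_tests["significant"] = mask
    else:
        all_tests = None
    audit["stages"].append("group_test")
    return ModulationResult(
        seeds=seeds,
        nbs_result=nbs_res,
        masks=masks,
        delta_z=delta_z,
        region_tests=all_tests,
        audit=audit,
    )
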