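"""Self-validation experiments: calibration and recovery studies.

Each function runs one scripted experiment on synthetic data with known
ground truth and returns the measured quantity — empirical family-wise error
of the network-based statistic under the null, ground-truth recovery of the
MSRA matrix, end-to-end planted-modulation recovery, agreement of the FDR
and community-detection implementations with brute-force oracles, and the
analytic TFCE checks.  The test suite asserts on these numbers; the
acceptance script reports them.
"""

from __future__ import annotations

import numpy as np

from . import preprocess
from .graphs import detect_communities, modularity_bruteforce, nbs
from .modulation import ModulationConfig, run_modulation_pipeline
from .msra import msra_matrix
from .simulate import (
    SimConfig,
    base_covariance,
    dataclasses_replace,
    default_planted_edges,
    make_phantom_atlas,
    simulate_session,
    simulate_study,
)
from .stats import FdrConfig, TfceParams, fdr_select, fisher_z, tfce


def fdr_oracle_agreement(n_lists: int = 100, max_m: int = 1000, seed: int = 0) -> float:
    """Fraction of random p-lists where step-up selection equals brute force."""
    rng = np.random.default_rng(seed)
    agree = 0
    for i in range(n_lists):
        m = int(rng.integers(1, max_m + 1))
        p = rng.uniform(size=m) ** float(rng.uniform(0.5, 3.0))
        method = "BY" if i % 2 else "BH"
        mask, _ = fdr_select(p, FdrConfig(q=0.05, method=method))
        c = np.sum(1.0 / np.arange(1, m + 1)) if method == "BY" else 1.0
        best = 0.0
        for thr in np.unique(p):
            if thr <= 0.05 * np.sum(p <= thr) / (m * c):
                best = max(best, thr)
        agree += np.array_equal(mask, p <= best)
    return agree / n_lists


def tfce_checks(height: float = 3.0) -> dict:
    """Analytic single-voxel integral and dh-refinement stability of TFCE."""
    stat = np.zeros((7, 7, 7))
    stat[3, 3, 3] = height
    enhanced = tfce(stat, TfceParams(H=2.0, E=0.05, dh=height / 100), normalize=False)
    single_voxel_rel_err = abs(enhanced[3, 3, 3] - height**3 / 3) / (height**3 / 3)

    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(1)
    smooth = gaussian_filter(rng.normal(size=(10, 10, 10)), 1.5)
    smooth *= 4.0 / np.abs(smooth).max()
    amax = np.abs(smooth).max()
    coarse = tfce(smooth, TfceParams(dh=amax / 100), normalize=False)
    fine = tfce(smooth, TfceParams(dh=amax / 1000), normalize=False)
    refinement_rel_change = float(np.abs(coarse - fine).max() / np.abs(fine).max())
    return {
        "single_voxel_rel_err": float(single_voxel_rel_err),
        "refinement_rel_change": refinement_rel_change,
    }


def nbs_fwe_calibration(
    n_studies: int = 200,
    n_nodes: int = 20,
    n_subjects: int = 9,
    n_perm: int = 200,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> float:
    """Empirical FWE of NBS under the full null (identically distributed groups)."""
    rng = np.random.default_rng(seed)
    false_positives = 0
    for _ in range(n_studies):
        base = rng.normal(size=(n_nodes, n_nodes))
        base = 0.5 * (base + base.T)
        np.fill_diagonal(base, 0.0)
        a = base + rng.normal(0, noise_sd, size=(n_subjects, n_nodes, n_nodes))
        b = base + rng.normal(0, noise_sd, size=(n_subjects, n_nodes, n_nodes))
        res = nbs(a, b, alpha=0.05, n_perm=n_perm, seed=int(rng.integers(2**31)))
        false_positives += any(p < 0.05 for p in res.p_fwe)
    return false_positives / n_studies


def community_oracle_agreement(n_graphs: int = 100, seed: int = 0) -> float:
    """Fraction of small random graphs where Louvain attains the exhaustive optimum."""
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < n_graphs:
        n = int(rng.integers(5, 9))
        edges = [
            (a, b, float(rng.uniform(0.1, 1.0)))
            for a in range(n)
            for b in range(a + 1, n)
            if rng.uniform() < 0.5
        ]
        if not edges:
            continue
        _, q = detect_communities(edges, n_nodes=n, seed=int(rng.integers(2**31)))
        _, q_best = modularity_bruteforce(edges, n)
        hits += q >= q_best - 1e-9
        done += 1
    return hits / n_graphs


def msra_recovery_correlation(seed: int = 0, config: SimConfig | None = None) -> float:
    """Correlation between the estimated Fisher-z matrix and ground truth.

    One 300-volume session at the study conditions; preprocessing restricted
    to discard + smoothing + nuisance regression, since the generator's
    covariance targets are defined for the unfiltered region courses (the
    band-pass only reduces the effective temporal dof of the estimator).
    """
    cfg = config or dataclasses_replace(SimConfig(), seed=seed)
    _, labels = make_phantom_atlas(cfg)
    cov = base_covariance(cfg)
    ses = simulate_session(labels, cfg, "rest", cov, np.random.default_rng(seed))
    ses = preprocess.discard_initial(ses, 2)
    ses = preprocess.gaussian_smooth(ses, 4.0)
    ses = preprocess.nuisance_regress(ses, labels)
    mat, _ = msra_matrix(ses, labels, n_nuisance=2, keep_maps=False)
    n = len(mat.region_labels)
    off = ~np.eye(n, dtype=bool)
    truth = fisher_z(cov[:n, :n])[off]
    return float(np.corrcoef(mat.z[off], truth)[0, 1])


def _study_config(seed: int, planted: bool) -> SimConfig:
    cfg = SimConfig(seed=seed)
    if planted:
        cfg = dataclasses_replace(cfg, planted_edges=default_planted_edges(cfg))
    return cfg


def _pipeline_config(seed: int, nbs_n_perm: int = 500, tfce_n_perm: int = 200) -> ModulationConfig:
    return ModulationConfig(seed=seed, nbs_n_perm=nbs_n_perm, tfce_n_perm=tfce_n_perm)


def planted_recovery(seed: int = 0) -> dict:
    """Run the full pipeline on one planted study and score it against truth."""
    cfg = _study_config(seed, planted=True)
    study = simulate_study(cfg)
    result = run_modulation_pipeline(study, _pipeline_config(seed))
    planted_seed = cfg.planted_edges[0][0]
    targets = {t for _, t, _ in cfg.planted_edges}
    flagged = result.modulated_region_labels()
    return {
        "seed_dominant": planted_seed in result.seeds,
        "recall": len(targets & flagged) / len(targets),
        "n_flagged": len(flagged),
        "dominant_seeds": result.seeds,
    }


def null_empty_rate(n_reps: int = 50, seed: int = 0, nbs_n_perm: int = 200) -> float:
    """Fraction of no-effect studies on which the pipeline reports nothing."""
    rng = np.random.default_rng(seed)
    empty = 0
    for _ in range(n_reps):
        s = int(rng.integers(2**31))
        cfg = dataclasses_replace(_study_config(s, planted=False), include_task_sessions=False)
        study = simulate_study(cfg)
        result = run_modulation_pipeline(
            study, _pipeline_config(s, nbs_n_perm=nbs_n_perm, tfce_n_perm=150)
        )
        empty += len(result.modulated_region_labels()) == 0
    return empty / n_reps
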