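"""Graph-level analysis of MSRA connectivity matrices.

Homotopic-rank quality control, default-mode specificity ratios, density
thresholding, Louvain community detection, the network-based statistic (NBS)
with its paired-control variant (pNBS), and between/within-subject matrix
similarity.  All operations symmetrize directed MSRA matrices by averaging
the two directed cells first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats as sps
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as cc

from .stats import fisher_z

logger = logging.getLogger(__name__)


def symmetrize(matrix: np.ndarray) -> np.ndarray:
    return 0.5 * (np.asarray(matrix, float) + np.asarray(matrix, float).T)


# ---------------------------------------------------------------------------
# Resting-state graph quality
# ---------------------------------------------------------------------------


@dataclass
class HomotopicQC:
    ranks: dict  # region label -> normalized rank of the homotopic connection
    distances_mm: dict  # region label -> centroid distance to its partner
    slope_per_mm: float
    rank_at_mean_distance: float


def homotopic_rank_qc(matrix: np.ndarray, region_labels: list[int], table, centroids_mm: dict) -> HomotopicQC:
    """Normalized rank of each region's homotopic connection, with a distance fit.

    For every bilateral region the strength z(region -> partner) is ranked
    among all that region's connections; rank 1.0 means the homotopic edge
    is the strongest.  An OLS line of rank on centroid distance summarises
    distance dependence: its slope (per mm) and its fitted rank at the mean
    distance are the two QC numbers.
    """
    z = symmetrize(matrix)
    lab_to_idx = {lab: i for i, lab in enumerate(region_labels)}
    partner = dict(zip(table["label"], table["homotopic_partner"]))
    ranks, dists = {}, {}
    for lab in region_labels:
        par = partner.get(lab, 0)
        if not par or par not in lab_to_idx:
            continue
        i, j = lab_to_idx[lab], lab_to_idx[par]
        row = np.delete(z[i], i)
        hom = z[i, j]
        m = row.size
        if m < 2:
            continue
        rank = (np.sum(row < hom) + 0.5 * (np.sum(row == hom) - 1)) / (m - 1)
        ranks[lab] = float(rank)
        dists[lab] = float(np.linalg.norm(centroids_mm[lab] - centroids_mm[par]))
    if not ranks:
        raise ValueError("no bilateral regions with homotopic partners found")
    x = np.array([dists[k] for k in ranks])
    y = np.array([ranks[k] for k in ranks])
    if np.ptp(x) > 0:
        slope, intercept = np.polyfit(x, y, 1)
    else:
        slope, intercept = 0.0, float(y.mean())
    return HomotopicQC(
        ranks=ranks,
        distances_mm=dists,
        slope_per_mm=float(slope),
        rank_at_mean_distance=float(slope * x.mean() + intercept),
    )


def dmn_specificity(
    matrix: np.ndarray,
    region_labels: list[int],
    cga: tuple[int, int],
    cgm: tuple[int, int],
    mfg: tuple[int, int],
) -> float:
    """Within-network / out-of-network connectivity ratio of the DMN axis.

    mean z(anterior cingulate <-> middle cingulum) over the four hemispheric
    combinations (LL, RR, LR, RL) divided by the same mean toward the middle
    frontal gyrus.  Higher means more network-specific connectivity.
    """
    z = symmetrize(matrix)
    idx = {lab: i for i, lab in enumerate(region_labels)}

    def mean_pairs(fam_a, fam_b):
        vals = [z[idx[a], idx[b]] for a in fam_a for b in fam_b]
        return float(np.mean(vals))

    num = mean_pairs(cga, cgm)
    den = mean_pairs(cga, mfg)
    if den == 0:
        raise ZeroDivisionError("zero denominator in specificity ratio")
    return num / den


# ---------------------------------------------------------------------------
# Thresholding and communities
# ---------------------------------------------------------------------------


def density_threshold(matrix: np.ndarray, density: float = 0.07) -> list[tuple[int, int, float]]:
    """Strongest connections at a fixed density (default 7%).

    Keeps the top floor(density * m) of the m off-diagonal edge weights of
    the symmetrized matrix; ties at the cut are all included (the realised
    density is logged).  Returns (i, j, weight) with i < j as node indices.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    z = symmetrize(matrix)
    n = z.shape[0]
    iu = np.triu_indices(n, k=1)
    w = z[iu]
    m = w.size
    k = int(np.floor(density * m))
    if np.all(w == 0):
        logger.warning("density_threshold: all-zero matrix, empty edge set")
        return []
    if k == 0:
        return []
    order = np.argsort(w)[::-1]
    cut = w[order[k - 1]]
    keep = w >= cut
    if keep.sum() > k:
        logger.info("density_threshold: ties at the cut, realised density %.4f", keep.sum() / m)
    return [(int(iu[0][e]), int(iu[1][e]), float(w[e])) for e in np.nonzero(keep)[0]]


def detect_communities(
    edges: list[tuple[int, int, float]],
    n_nodes: int | None = None,
    seed: int = 0,
    n_restarts: int = 8,
) -> tuple[list[set], float]:
    """Louvain (multilevel modularity) communities of a weighted edge set.

    The greedy optimisation depends on the node-visit order, so it is run
    ``n_restarts`` times with different shufflings and the partition with
    the highest modularity Q is kept.  Deterministic given ``seed``.
    Returns (partition as list of node sets, Q).
    """
    if not edges:
        raise ValueError("empty graph")
    g = nx.Graph()
    if n_nodes is not None:
        g.add_nodes_from(range(n_nodes))
    g.add_weighted_edges_from(edges)
    best_q, best_parts = -np.inf, None
    for k in range(max(1, n_restarts)):
        parts = nx.community.louvain_communities(g, weight="weight", seed=seed + k)
        q = nx.community.modularity(g, parts, weight="weight")
        if q > best_q:
            best_q, best_parts = q, parts
    return [set(p) for p in best_parts], float(best_q)


def modularity_bruteforce(edges: list[tuple[int, int, float]], n_nodes: int) -> tuple[list[set], float]:
    """Exhaustive best-modularity partition (oracle; n_nodes <= 10)."""
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    g.add_weighted_edges_from(edges)

    def set_partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in set_partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]
            yield [[first]] + part

    best_q, best_p = -np.inf, None
    for part in set_partitions(list(range(n_nodes))):
        q = nx.community.modularity(g, [set(p) for p in part], weight="weight")
        if q > best_q:
            best_q, best_p = q, part
    return [set(p) for p in best_p], float(best_q)


# ---------------------------------------------------------------------------
# Network-based statistic
# ---------------------------------------------------------------------------


@dataclass
class NbsResult:
    """Suprathreshold components with family-wise-error p-values."""

    alpha: float
    components: list  # list of edge lists [(i, j), ...]
    p_fwe: list
    null_max_sizes: np.ndarray
    n_perm: int
    seed: int
    edge_t: np.ndarray | None = None
    edge_p: np.ndarray | None = None

    def significant_components(self, level: float = 0.05) -> list:
        return [c for c, p in zip(self.components, self.p_fwe) if p < level]


def _edge_vector(matrices: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Stack symmetrized matrices to (n_subjects, n_edges) upper-triangle vectors."""
    matrices = np.asarray(matrices, dtype=float)
    n = matrices.shape[1]
    iu = np.triu_indices(n, k=1)
    sym = 0.5 * (matrices + matrices.transpose(0, 2, 1))
    return sym[:, iu[0], iu[1]], iu


def _unpaired_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Homoscedastic two-sample t per column."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, (a.mean(axis=0) - b.mean(axis=0)) / denom, 0.0)
    return t


def _paired_t(d: np.ndarray) -> np.ndarray:
    """One-sample t on differences, per column."""
    n = d.shape[0]
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, d.mean(axis=0) / (sd / np.sqrt(n)), 0.0)
    return t


def _components_from_edges(supra: np.ndarray, iu: tuple, n_nodes: int) -> list[list[tuple[int, int]]]:
    """Connected components (by shared nodes) of the suprathreshold edge set."""
    idx = np.nonzero(supra)[0]
    if idx.size == 0:
        return []
    rows, cols = iu[0][idx], iu[1][idx]
    adj = coo_matrix((np.ones(idx.size), (rows, cols)), shape=(n_nodes, n_nodes))
    n_comp, node_lab = cc(adj, directed=False)
    comps: dict[int, list] = {}
    for e in range(idx.size):
        comps.setdefault(node_lab[rows[e]], []).append((int(rows[e]), int(cols[e])))
    return list(comps.values())


def _max_component_size(supra: np.ndarray, iu: tuple, n_nodes: int) -> int:
    comps = _components_from_edges(supra, iu, n_nodes)
    return max((len(c) for c in comps), default=0)


def nbs(
    matrices_a: np.ndarray,
    matrices_b: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 1000,
    design: str = "unpaired",
    seed: int = 0,
) -> NbsResult:
    """Network-based statistic on two sets of connectivity matrices.

    Edge-wise t-tests (homoscedastic two-sample, or paired on a-b) keep
    edges with p < alpha; connected components of those edges are scored by
    edge count and compared against a permutation null of the maximum
    component size (group-label exchange, or sign flips for the paired
    design).  The identity permutation is included in the null, so the
    smallest attainable p_FWE is 1/(n_perm).
    """
    ea, iu = _edge_vector(matrices_a)
    eb, _ = _edge_vector(matrices_b)
    n_nodes = np.asarray(matrices_a).shape[1]
    rng = np.random.default_rng(seed)
    if design == "paired":
        if ea.shape != eb.shape:
            raise ValueError("paired design needs equal-size groups")
        diff = ea - eb
        n = diff.shape[0]
        if n < 2:
            raise ValueError("need >= 2 subjects per group")
        df = n - 1

        def t_for(perm_signs):
            return _paired_t(diff * perm_signs[:, None])

        def draw():
            return rng.choice([-1, 1], size=n)

        ident = np.ones(ea.shape[0])
    elif design == "unpaired":
        na, nb = ea.shape[0], eb.shape[0]
        if min(na, nb) < 2:
            raise ValueError("need >= 2 subjects per group")
        pooled = np.vstack([ea, eb])
        df = na + nb - 2

        def t_for(order):
            return _unpaired_t(pooled[order[:na]], pooled[order[na:]])

        def draw():
            return rng.permutation(na + nb)

        ident = np.arange(na + nb)
    else:
        raise ValueError("design must be 'paired' or 'unpaired'")

    t_crit = sps.t.ppf(1 - alpha / 2, df)
    t_obs = t_for(ident)
    p_obs = 2 * sps.t.sf(np.abs(t_obs), df)
    supra_obs = np.abs(t_obs) > t_crit
    components = _components_from_edges(supra_obs, iu, n_nodes)
    components.sort(key=len, reverse=True)

    null_sizes = np.empty(n_perm, dtype=int)
    null_sizes[0] = _max_component_size(supra_obs, iu, n_nodes)  # identity included
    for i in range(1, n_perm):
        t_perm = t_for(draw())
        null_sizes[i] = _max_component_size(np.abs(t_perm) > t_crit, iu, n_nodes)
    p_fwe = [float(np.mean(null_sizes >= len(c))) for c in components]
    return NbsResult(
        alpha=alpha,
        components=components,
        p_fwe=p_fwe,
        null_max_sizes=null_sizes,
        n_perm=n_perm,
        seed=seed,
        edge_t=t_obs,
        edge_p=p_obs,
    )


def pnbs(
    exp_pairs: tuple[np.ndarray, np.ndarray],
    control_pairs: tuple[np.ndarray, np.ndarray],
    n_perm: int = 1000,
    control_quantile: float = 0.01,
    seed: int = 0,
) -> NbsResult:
    """Paired-control NBS.

    The edge threshold alpha is derived from the control cohort: the
    quantile of its paired-t p-values that leaves ``control_quantile`` of
    edges below it (so almost no control edge is suprathreshold).  That
    alpha is applied to the experimental cohort's paired t-map; surviving
    components with edge count <= the largest control component are
    eliminated; FWE comes from permuting subject-pairs between cohorts
    (recomputing alpha each time).
    """
    ea1, iu = _edge_vector(exp_pairs[0])
    ea2, _ = _edge_vector(exp_pairs[1])
    cb1, _ = _edge_vector(control_pairs[0])
    cb2, _ = _edge_vector(control_pairs[1])
    n_nodes = np.asarray(exp_pairs[0]).shape[1]
    d_exp = ea1 - ea2
    d_ctl = cb1 - cb2
    if d_ctl.shape[0] < 2 or d_exp.shape[0] < 2:
        raise ValueError("need >= 2 pairs in each cohort")
    rng = np.random.default_rng(seed)
    all_d = np.vstack([d_exp, d_ctl])
    n_exp = d_exp.shape[0]
    n_all = all_d.shape[0]

    def paired_p(d):
        t = _paired_t(d)
        return t, 2 * sps.t.sf(np.abs(t), d.shape[0] - 1)

    def analyze(order):
        de, dc = all_d[order[:n_exp]], all_d[order[n_exp:]]
        t_c, p_c = paired_p(dc)
        alpha = float(np.quantile(p_c, control_quantile))
        ctl_supra = p_c <= alpha
        ctl_max = _max_component_size(ctl_supra, iu, n_nodes)
        t_e, p_e = paired_p(de)
        comps = _components_from_edges(p_e <= alpha, iu, n_nodes)
        surviving = [c for c in comps if len(c) > ctl_max]
        return alpha, surviving, ctl_max

    ident = np.arange(n_all)
    alpha_obs, surviving_obs, ctl_max_obs = analyze(ident)
    surviving_obs.sort(key=len, reverse=True)
    null_sizes = np.empty(n_perm, dtype=int)
    null_sizes[0] = max((len(c) for c in surviving_obs), default=0)
    for i in range(1, n_perm):
        _, surv, _ = analyze(rng.permutation(n_all))
        null_sizes[i] = max((len(c) for c in surv), default=0)
    p_fwe = [float(np.mean(null_sizes >= len(c))) for c in surviving_obs]
    t_e, p_e = paired_p(d_exp)
    return NbsResult(
        alpha=alpha_obs,
        components=surviving_obs,
        p_fwe=p_fwe,
        null_max_sizes=null_sizes,
        n_perm=n_perm,
        seed=seed,
        edge_t=t_e,
        edge_p=p_e,
    )


# ---------------------------------------------------------------------------
# Matrix similarity
# ---------------------------------------------------------------------------


def matrix_similarity(matrices: list[np.ndarray]) -> np.ndarray:
    """Pairwise spatial correlation of matrices over off-diagonal cells, Fisher z.

    Returns the full n x n Fisher-z similarity matrix (diagonal at the
    clipped maximum).  Constant matrices make a pair undefined; those cells
    are NaN and a warning is logged.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices")
    n_nodes = matrices[0].shape[0]
    mask = ~np.eye(n_nodes, dtype=bool)
    vecs = np.stack([np.asarray(m, float)[mask] for m in matrices])
    sds = vecs.std(axis=1)
    if np.any(sds == 0):
        logger.warning("matrix_similarity: %d constant matrix(es); pairs undefined", int((sds == 0).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(vecs)
    return _safe_fisher(r)


def _safe_fisher(r: np.ndarray) -> np.ndarray:
    out = np.full_like(r, np.nan, dtype=float)
    ok = np.isfinite(r)
    out[ok] = fisher_z(r[ok])
    return out


def within_subject_similarity(rs1_matrices: dict, rs2_matrices: dict) -> dict:
    """Per-subject rs1 <-> rs2 matrix correlation (Fisher z), reproducibility."""
    out = {}
    for sid, m1 in rs1_matrices.items():
        m2 = rs2_matrices[sid]
        mask = ~np.eye(m1.shape[0], dtype=bool)
        v1, v2 = np.asarray(m1, float)[mask], np.asarray(m2, float)[mask]
        if v1.std() == 0 or v2.std() == 0:
            out[sid] = float("nan")
            continue
        out[sid] = float(fisher_z(np.corrcoef(v1, v2)[0, 1]))
    return out
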