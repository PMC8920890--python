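"""Cell-state association: cell-cycle trajectory, phase-specific expression,
apoptosis clustering and guilt-by-association refinement.

Cells are placed on a one-dimensional principal curve through PCA space of
the most variable cell-cycle genes; canonical markers (Gas1 for G0, Ccnd1
for G1, Ccne2 for G1/S, Ccnb1 for G2/M) segment the curve into phases.
Phase-specific genes come from a one-way ANOVA across phases; an analogous
route clusters G1 cells on apoptosis-related genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, rankdata, spearmanr
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "log_normalize",
    "select_variable_genes",
    "fit_trajectory",
    "assign_phase",
    "anova_phase_de",
    "apoptosis_cluster",
    "guilt_by_association",
    "pam_kmedoids",
    "PHASE_CYCLE",
]

PHASE_CYCLE = ["G0", "G1", "G1/S", "G2/M"]


def log_normalize(counts: pd.DataFrame, scale: float = 10_000) -> pd.DataFrame:
    """Depth-normalize and log-transform: ln(1 + count / cell_total * scale).

    Raises on zero-total cells — those should have been removed by QC.
    """
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = list(counts.columns[totals <= 0][:5])
        raise ValueError(f"zero-total cell(s): {bad}")
    return np.log1p(counts.astype(float).div(totals, axis=1) * scale)


def select_variable_genes(normalized: pd.DataFrame, universe=None,
                          n_top: int = 50, *, counts: pd.DataFrame | None = None,
                          lowess_frac: float = 0.3) -> list:
    """Rank genes by standardized variance against a smoothed mean-variance trend.

    A local regression of log10 variance on log10 mean gives each gene an
    expected standard deviation; values standardized against it are clipped
    at sqrt(n_cells) and the variance of the clipped z-scores ranks the
    genes. Works on raw counts if given (the usual convention), else on the
    normalized matrix.
    """
    mat = counts if counts is not None else normalized
    if universe is not None:
        universe = [g for g in universe if g in mat.index]
        mat = mat.loc[universe]
    x = mat.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    ok = (mean > 0) & (var > 0)
    if ok.sum() == 0:
        return []
    lm, lv = np.log10(mean[ok]), np.log10(var[ok])
    fit = lowess(lv, lm, frac=lowess_frac, return_sorted=False)
    sd_exp = np.sqrt(10.0 ** fit)
    n = x.shape[1]
    clip = np.sqrt(n)
    z = (x[ok] - mean[ok][:, None]) / sd_exp[:, None]
    np.clip(z, -clip, clip, out=z)
    std_var = z.var(axis=1, ddof=1)
    idx = mat.index[ok]
    order = pd.DataFrame({"v": std_var, "g": idx}).sort_values(
        ["v", "g"], ascending=[False, True], kind="mergesort"
    )
    if n_top > len(order):
        warnings.warn(f"universe smaller than n_top; returning all {len(order)}",
                      stacklevel=2)
    return list(order["g"].iloc[:n_top])


# ---------------------------------------------------------------------------
# principal curve
# ---------------------------------------------------------------------------

def _project_to_polyline(points: np.ndarray, curve: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto a polyline; return arc-length coordinates and distances."""
    seg_vec = np.diff(curve, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    seg_len = np.where(seg_len == 0, 1e-12, seg_len)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    lam = np.empty(len(points))
    dist = np.empty(len(points))
    for i, p in enumerate(points):
        diff = p[None, :] - curve[:-1]
        t = np.clip(np.einsum("ij,ij->i", diff, seg_vec) / seg_len**2, 0.0, 1.0)
        proj = curve[:-1] + t[:, None] * seg_vec
        d = np.linalg.norm(points[i][None, :] - proj, axis=1)
        j = int(np.argmin(d))
        lam[i] = cum[j] + t[j] * seg_len[j]
        dist[i] = d[j]
    return lam, dist


def _smooth_curve(x: np.ndarray, lam: np.ndarray, frac: float) -> np.ndarray | None:
    order = np.argsort(lam, kind="mergesort")
    lam_o = lam[order]
    curve = np.column_stack([
        lowess(x[order, d], lam_o, frac=frac, return_sorted=False)
        for d in range(x.shape[1])
    ])
    if not np.all(np.isfinite(curve)):
        return None
    return curve


def _principal_curve(x: np.ndarray, *, max_iter: int = 30, tol: float = 1e-4,
                     lowess_frac: float = 0.3) -> np.ndarray:
    """Hastie-Stuetzle principal curve: iterate projection and per-dimension
    smoothing of the coordinates against arc length.

    Two initializations are tried — the first principal component (linear
    structure) and the angular position in the PC1-PC2 plane (closed
    cell-cycle-like structure) — and the one with the smaller projection
    error after one smoothing pass is iterated to convergence.
    """
    pc = PCA(n_components=min(2, x.shape[1])).fit_transform(x)
    inits = [pc[:, 0]]
    if pc.shape[1] > 1:
        inits.append(np.arctan2(pc[:, 1], pc[:, 0]))
    best_lam, best_total = None, np.inf
    for lam0 in inits:
        curve = _smooth_curve(x, lam0, lowess_frac)
        if curve is None:
            continue
        lam1, dist = _project_to_polyline(x, curve)
        total = float(np.sum(dist**2))
        if total < best_total:
            best_lam, best_total = lam1, total
    if best_lam is None:
        # degenerate geometry (too few distinct positions to smooth):
        # the PC1 coordinate, shifted to a non-negative arc length, is exact
        lam = pc[:, 0] - pc[:, 0].min()
        return lam
    lam, prev = best_lam, best_total
    for _ in range(max_iter):
        curve = _smooth_curve(x, lam, lowess_frac)
        if curve is None:
            break
        lam_new, dist = _project_to_polyline(x, curve)
        total = float(np.sum(dist**2))
        if not np.isfinite(total):
            raise RuntimeError("principal curve failed to converge")
        lam = lam_new
        if abs(prev - total) < tol * max(total, 1e-12):
            break
        prev = total
    return lam


def fit_trajectory(normalized: pd.DataFrame, variable_genes, n_pcs: int = 3) -> pd.Series:
    """Arc-length coordinate of each cell on the principal curve through the
    top principal components of the variable genes."""
    genes = [g for g in variable_genes if g in normalized.index]
    if len(genes) < 3:
        raise ValueError("need at least 3 variable genes")
    mat = normalized.loc[genes].to_numpy(dtype=float).T  # cells x genes
    if mat.shape[0] < 10:
        raise ValueError("need at least 10 cells")
    mat = mat - mat.mean(axis=0)
    pcs = PCA(n_components=min(n_pcs, mat.shape[1])).fit_transform(mat)
    lam = _principal_curve(pcs)
    return pd.Series(lam, index=normalized.columns, name="lambda")


def assign_phase(coordinates: pd.Series, marker_expression: pd.DataFrame,
                 markers: dict | None = None, window: int = 15) -> pd.DataFrame:
    """Label cells with cell-cycle phases by dominant smoothed marker.

    Cells are ordered by curve coordinate, each marker set's mean expression
    smoothed with a centered rolling mean of ``window`` cells, and every cell
    labeled by the phase whose smoothed marker dominates at its position
    (ties toward the earlier phase in cycle order G0 -> G1 -> G1/S -> G2/M).
    """
    markers = markers or {p: [p] for p in PHASE_CYCLE}
    if window > len(coordinates):
        raise ValueError("window larger than cell count")
    order = coordinates.sort_values(kind="mergesort").index
    smoothed = {}
    for phase in PHASE_CYCLE:
        genes = [g for g in markers.get(phase, []) if g in marker_expression.index]
        if not genes:
            raise ValueError(f"marker gene(s) for phase {phase!r} absent")
        sig = marker_expression.loc[genes, order].mean(axis=0)
        smoothed[phase] = sig.rolling(window, center=True, min_periods=1).mean()
    sm = pd.DataFrame(smoothed)
    if float(sm.max().max() - sm.min().min()) < 1e-12:
        warnings.warn("constant markers: single-phase labeling (degenerate boundaries)",
                      stacklevel=2)
    # idxmax takes the first column on ties; column order is cycle order
    labels = sm.idxmax(axis=1)
    out = pd.DataFrame({
        "coordinate": coordinates[order],
        "phase": labels,
    })
    return out.reindex(coordinates.index)


def anova_phase_de(normalized: pd.DataFrame, phases: pd.Series, *,
                   alpha: float = 0.01) -> pd.DataFrame:
    """One-way ANOVA of expression across phases, BH-adjusted.

    Fold induction is the mean in the gene's top phase over the mean across
    all other phases. Genes with zero variance everywhere are flagged with
    undefined p.
    """
    phases = phases.loc[normalized.columns]
    groups = [normalized.loc[:, phases == p] for p in pd.unique(phases)]
    groups = [g for g in groups if g.shape[1] >= 3]
    if len(groups) < 2:
        raise ValueError("need >= 2 phases with >= 3 cells each")
    arrays = [g.to_numpy(dtype=float) for g in groups]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = f_oneway(*arrays, axis=1)
    means = np.column_stack([a.mean(axis=1) for a in arrays])
    top = np.argmax(means, axis=1)
    other = np.array([
        np.delete(means[i], top[i]).mean() for i in range(len(means))
    ])
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = means[np.arange(len(means)), top] / np.where(other > 0, other, np.nan)
    undefined = ~np.isfinite(p)
    padj = np.full_like(p, np.nan)
    ok = ~undefined
    if ok.any():
        padj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame({
        "F": f, "p": p, "p_adj": padj, "fold_induction": fold,
        "top_phase": [pd.unique(phases)[i] for i in top],
        "significant": (padj < alpha) & ok,
        "undefined": undefined,
    }, index=normalized.index)


# ---------------------------------------------------------------------------
# apoptosis route
# ---------------------------------------------------------------------------

def pam_kmedoids(x: np.ndarray, k: int, *, max_iter: int = 100) -> np.ndarray:
    """Partitioning Around Medoids (BUILD + SWAP), deterministic.

    Small-n implementation on the full Euclidean distance matrix.
    """
    n = len(x)
    if k < 1 or k > n:
        raise ValueError("k must be in [1, n]")
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        best_gain, best_j = -np.inf, None
        dmin = d[:, medoids].min(axis=1)
        for j in range(n):
            if j in medoids:
                continue
            gain = np.sum(np.maximum(dmin - d[:, j], 0.0))
            if gain > best_gain:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    # SWAP
    for _ in range(max_iter):
        assign = np.argmin(d[:, medoids], axis=1)
        cost = d[np.arange(n), np.array(medoids)[assign]].sum()
        improved = False
        for mi in range(k):
            for j in range(n):
                if j in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = j
                tcost = d[:, trial].min(axis=1).sum()
                if tcost < cost - 1e-12:
                    medoids, cost, improved = trial, tcost, True
        if not improved:
            break
    return np.argmin(d[:, medoids], axis=1)


def apoptosis_cluster(normalized: pd.DataFrame, apoptosis_genes, *,
                      n_top: int = 75, k: int = 3, n_pcs: int = 3,
                      means: pd.Series | None = None) -> pd.Series:
    """Cluster (G1) cells on their most variable apoptosis-related genes.

    The CV²-mean relationship over all genes is fitted with a gamma GLM of
    CV² on reciprocal mean; genes are ranked by observed/fitted CV² and the
    top ``n_top`` apoptosis-list members enter PCA, followed by k-medoids on
    the leading PC coordinates.
    """
    import statsmodels.api as sm

    if normalized.shape[1] < k:
        raise ValueError("fewer distinct cells than clusters")
    x = normalized.to_numpy(dtype=float)
    mu = x.mean(axis=1)
    ok = mu > 0
    cv2_obs = np.full(len(mu), np.nan)
    cv2_obs[ok] = x[ok].var(axis=1, ddof=1) / mu[ok] ** 2
    fit_ok = ok & np.isfinite(cv2_obs) & (cv2_obs > 0)
    design = sm.add_constant(1.0 / mu[fit_ok])
    glm = sm.GLM(cv2_obs[fit_ok], design,
                 family=sm.families.Gamma(link=sm.families.links.Identity()))
    res = glm.fit()
    fitted = np.full(len(mu), np.nan)
    fitted[fit_ok] = res.predict(design)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = cv2_obs / fitted
    ratio_s = pd.Series(ratio, index=normalized.index)
    apop = [g for g in apoptosis_genes if g in normalized.index]
    ranked = ratio_s[apop].dropna().sort_values(ascending=False, kind="mergesort")
    top = list(ranked.index[:n_top])
    mat = normalized.loc[top].to_numpy(dtype=float).T
    mat = mat - mat.mean(axis=0)
    pcs = PCA(n_components=min(n_pcs, mat.shape[1], mat.shape[0])).fit_transform(mat)
    labels = pam_kmedoids(pcs, k)
    return pd.Series(labels, index=normalized.columns, name="cluster")


def guilt_by_association(normalized: pd.DataFrame, target: str,
                         de_results: pd.DataFrame, *, threshold: float = 0.1,
                         min_shared: int = 10, min_target_cells: int = 20) -> pd.DataFrame:
    """Refine knockdown-responsive candidates by correlation with the target.

    For each gene, the Spearman correlation with the target is computed over
    cells where at least one of the two genes is expressed (double-zero
    cells excluded per pair). Genes pass when |rho| >= ``threshold`` and the
    correlation sign is consistent with their knockdown response
    (``de_results`` column ``direction`` in {'down', 'up'}): positively
    correlated genes should go down when the target is knocked down, and
    vice versa.
    """
    tvals = normalized.loc[target].to_numpy(dtype=float)
    if np.sum(tvals > 0) < min_target_cells:
        raise ValueError(f"target expressed in fewer than {min_target_cells} cells")
    rows = []
    for gene in de_results.index:
        if gene not in normalized.index or gene == target:
            continue
        g = normalized.loc[gene].to_numpy(dtype=float)
        keep = (tvals > 0) | (g > 0)
        if keep.sum() < min_shared:
            continue
        rho = spearmanr(tvals[keep], g[keep]).statistic
        direction = de_results.at[gene, "direction"]
        consistent = (rho >= threshold and direction == "down") or (
            rho <= -threshold and direction == "up"
        )
        rows.append((gene, float(rho), direction, bool(consistent)))
    out = pd.DataFrame(rows, columns=["gene_id", "spearman_rho", "direction", "retained"])
    return out.set_index("gene_id")
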