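"""The malignant-continuum analysis: per-sample differential expression of a
target epithelial subtype against a pooled normal reference, PCA of the
resulting log2 fold-change profiles, principal-curve ordering of samples,
and Spearman gene trends along the continuum.

The chain is:

1. :func:`hurdle_de` — for one sample's target-subtype cells vs the pooled
   reference, a two-part hurdle test per gene: a test on detection rates
   plus a test on log-expression among expressing cells, combined by
   Fisher's method.  By default both parts adjust for each cell's overall
   detection rate (CDR, the fraction of genes a cell expresses): depth
   differences between cell groups shift detection and magnitude for all
   genes at once, and leaving the covariate out makes the null
   anti-conservative whenever groups are depth-imbalanced.
   ``depth_adjust=False`` gives the plain two-proportion z-test + Welch
   t-test.  The effect size is
   ``log2((mean(expm1(target)) + 1) / (mean(expm1(ref)) + 1))``.
2. :func:`profile_all_samples` — one hurdle run per sample, BH-adjusted
   within each sample.
3. :func:`select_continuum_genes` — genes significant (p_adj < alpha) in at
   least ``min_samples`` samples.
4. :func:`continuum_pca` — unscaled, column-centered PCA of the
   samples x selected-genes log2FC matrix (untested entries imputed as 0).
5. :func:`fit_principal_curve` — Hastie–Stuetzle principal curve in the
   PC1–PC2 plane; each sample's arc-length position, rescaled to [0, 1] and
   oriented from normal to tumor, is its place on the malignant continuum.
6. :func:`gene_trends` — per-gene Spearman correlation of log2FC against
   PC2 (or arc-length position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

_TINY_P = 1e-300


# ---------------------------------------------------------------------------
# hurdle differential expression
# ---------------------------------------------------------------------------

def _group_moments(values: np.ndarray, expressed: np.ndarray):
    """Mean and unbiased variance of each gene's values over expressing
    cells only; NaN where fewer than two cells express the gene."""
    k = expressed.sum(axis=0).astype(float)
    s1 = (values * expressed).sum(axis=0)
    s2 = (values**2 * expressed).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(k > 0, s1 / np.maximum(k, 1), np.nan)
        var = np.where(
            k > 1, (s2 - k * mean**2) / np.maximum(k - 1, 1), np.nan
        )
    var = np.maximum(var, 0.0)
    return k, mean, var


def _detection_p_plain(expr_t, expr_r, n_t, n_r, pct_t, pct_r):
    """Two-proportion z-test on detection rates (pooled variance)."""
    k_t = expr_t.sum(axis=0)
    k_r = expr_r.sum(axis=0)
    p_pool = (k_t + k_r) / (n_t + n_r)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(p_pool * (1 - p_pool) * (1 / n_t + 1 / n_r))
        z = (pct_t - pct_r) / se
    ok = (p_pool > 0) & (p_pool < 1)
    return np.where(ok, 2 * stats.norm.sf(np.abs(np.where(ok, z, 0.0))), np.nan)


def _continuous_p_plain(target, reference, expr_t, expr_r):
    """Welch t-test on log-expression among expressing cells."""
    kk_t, m_t, v_t = _group_moments(target, expr_t)
    kk_r, m_r, v_r = _group_moments(reference, expr_r)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom2 = v_t / kk_t + v_r / kk_r
        t_stat = (m_t - m_r) / np.sqrt(denom2)
        df = denom2**2 / (
            (v_t / kk_t) ** 2 / np.maximum(kk_t - 1, 1)
            + (v_r / kk_r) ** 2 / np.maximum(kk_r - 1, 1)
        )
    ok = (kk_t > 1) & (kk_r > 1) & (denom2 > 0)
    return np.where(
        ok,
        2 * stats.t.sf(np.abs(np.where(ok, t_stat, 0.0)), np.where(ok, df, 1.0)),
        np.nan,
    )


def _detection_p_adjusted(y: np.ndarray, group: np.ndarray, c: np.ndarray):
    """p-value of the group effect in y ~ 1 + c + group per gene (OLS),
    with y the detection indicator and c the centered CDR covariate.

    The group regressor is residualized on [1, c] once (shared across
    genes); each gene then needs only inner products.
    """
    n = len(group)
    c2 = float((c**2).sum())
    if c2 <= 0:
        nan = np.full(y.shape[1], np.nan)
        return nan, nan.copy()
    g_res = group - group.mean() - (float((c * group).sum()) / c2) * c
    g2 = float((g_res**2).sum())
    y_mean = y.mean(axis=0)
    b_c = (c @ y) / c2
    y_res = y - y_mean[None, :] - c[:, None] * b_c[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        b = (g_res @ y_res) / g2
        rss = (y_res**2).sum(axis=0) - b**2 * g2
        df = n - 3
        sigma2 = rss / df
        t_stat = b / np.sqrt(sigma2 / g2)
    ok = (df >= 1) & (sigma2 > 0) & (g2 > 0)
    p = np.where(
        ok, 2 * stats.t.sf(np.abs(np.where(ok, t_stat, 0.0)), df), np.nan
    )
    return p, np.where(ok, t_stat, np.nan)


def _blom_scores(values: np.ndarray, expr: np.ndarray) -> np.ndarray:
    """Van der Waerden/Blom normal scores of each gene's values among its
    expressing cells: Phi^-1((rank - 0.375) / (k + 0.25)).

    Rank-based scores keep the continuous hurdle part's extreme tail
    honest where raw log-expression is too skewed for a t reference (few
    expressing cells); non-expressing cells get score 0 and are masked out
    downstream.
    """
    filled = np.where(expr, values, -np.inf)
    ranks = stats.rankdata(filled, axis=0, method="average")
    k = expr.sum(axis=0)
    n_zero = expr.shape[0] - k
    r_expr = ranks - n_zero[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        q = (r_expr - 0.375) / (k[None, :] + 0.25)
    scores = np.where(expr, stats.norm.ppf(np.clip(q, 1e-10, 1 - 1e-10)), 0.0)
    return scores


def _continuous_p_adjusted(
    values: np.ndarray, expr: np.ndarray, group: np.ndarray, c: np.ndarray
):
    """p-value of the group effect in score ~ 1 + c + group per gene (OLS),
    restricted to each gene's expressing cells (masked normal equations),
    where score is the Blom normal score of the value within the gene's
    expressing cells."""
    values = _blom_scores(values, expr)
    m = expr.astype(float)
    k = m.sum(axis=0)
    k_t = (m * group[:, None]).sum(axis=0)
    k_r = k - k_t
    sc = c @ m
    scc = (c**2) @ m
    sg = group @ m
    scg = (c * group) @ m
    sy = (values * m).sum(axis=0)
    syc = (c[:, None] * values * m).sum(axis=0)
    syg = (group[:, None] * values * m).sum(axis=0)
    syy = (values**2 * m).sum(axis=0)

    G = values.shape[1]
    xtx = np.empty((G, 3, 3))
    xtx[:, 0, 0] = k
    xtx[:, 0, 1] = xtx[:, 1, 0] = sc
    xtx[:, 0, 2] = xtx[:, 2, 0] = sg
    xtx[:, 1, 1] = scc
    xtx[:, 1, 2] = xtx[:, 2, 1] = scg
    xtx[:, 2, 2] = sg  # group is 0/1 so sum g^2 = sum g
    xty = np.stack([sy, syc, syg], axis=1)

    det = np.linalg.det(xtx)
    scale = np.maximum(k, 1.0) ** 3
    solvable = (k_t > 1) & (k_r > 1) & (k >= 4) & (np.abs(det) > 1e-10 * scale)
    p = np.full(G, np.nan)
    stat = np.full(G, np.nan)
    idx = np.flatnonzero(solvable)
    if len(idx) == 0:
        return p, solvable, stat
    inv = np.linalg.inv(xtx[idx])
    beta = np.einsum("gij,gj->gi", inv, xty[idx])
    rss = syy[idx] - np.einsum("gi,gi->g", beta, xty[idx])
    df = k[idx] - 3
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = rss / df
        se = np.sqrt(sigma2 * inv[:, 2, 2])
        t_stat = beta[:, 2] / se
    ok = (sigma2 > 0) & (se > 0)
    p[idx[ok]] = 2 * stats.t.sf(np.abs(t_stat[ok]), df[ok])
    stat[idx[ok]] = t_stat[ok]
    return p, solvable, stat


def _brown_scale(p_det, p_t, stat_det, stat_cont):
    """Dependence correction for Fisher's combination (Brown's method via
    the Kost–McDermott covariance approximation).

    The two hurdle parts are computed from the same cells, so their
    statistics are positively dependent within a gene; plain Fisher then
    overstates joint significance in the far tail.  The cross-part
    correlation is estimated once per run as the Spearman correlation of
    the signed part statistics across genes (rank-based, so signal genes
    and heavy tails cannot dominate it), mapped to a Pearson scale.
    Returns (scale f, effective df) of the scaled-chi-square null for
    w_det + w_cont.
    """
    both = ~np.isnan(stat_det) & ~np.isnan(stat_cont)
    if both.sum() < 30:
        return 1.0, 4.0
    rho_s, _ = stats.spearmanr(stat_det[both], stat_cont[both])
    if np.isnan(rho_s):
        return 1.0, 4.0
    r = 2 * np.sin(np.pi * rho_s / 6)  # rank-to-Pearson under normality
    r = float(np.clip(r, 0.0, 0.98))
    if r == 0.0:
        return 1.0, 4.0
    cov = r * (3.263 + 0.710 * r + 0.027 * r**3)
    var = 8.0 + 2.0 * cov
    mean = 4.0
    f = var / (2.0 * mean)
    df_eff = 2.0 * mean**2 / var
    return f, df_eff


def hurdle_de(
    target: np.ndarray,
    reference: np.ndarray,
    min_cells: int = 10,
    min_pct: float = 0.05,
    depth_adjust: bool = True,
) -> pd.DataFrame | None:
    """Two-part hurdle DE of target cells vs reference cells, per gene.

    Returns a frame with columns log2fc, p_value, pct_expr_target,
    pct_expr_ref, tested — or None when either group has fewer than
    ``min_cells`` cells (the caller flags the sample unprofiled).  Genes
    expressed in less than ``min_pct`` of cells in *both* groups are kept
    in the frame but marked untested (p = NaN).

    With ``depth_adjust`` (default), both parts are OLS tests of the group
    coefficient with the centered per-cell CDR (fraction of genes
    detected) as covariate; genes where the masked regression is singular
    fall back to the plain part.  Without it, the parts are a
    two-proportion z-test and a Welch t-test.
    """
    n_t, n_r = target.shape[0], reference.shape[0]
    if n_t < min_cells or n_r < min_cells:
        return None
    expr_t = target > 0
    expr_r = reference > 0
    pct_t = expr_t.mean(axis=0)
    pct_r = expr_r.mean(axis=0)
    tested = (pct_t >= min_pct) | (pct_r >= min_pct)

    mean_t = np.expm1(target).mean(axis=0)
    mean_r = np.expm1(reference).mean(axis=0)
    log2fc = np.log2((mean_t + 1.0) / (mean_r + 1.0))

    brown_f, brown_df = 1.0, 4.0
    if depth_adjust:
        values = np.concatenate([target, reference], axis=0)
        expr = np.concatenate([expr_t, expr_r], axis=0)
        group = np.concatenate(
            [np.ones(n_t), np.zeros(n_r)]
        )
        cdr = expr.mean(axis=1)
        c = cdr - cdr.mean()
        p_det, stat_det = _detection_p_adjusted(expr.astype(float), group, c)
        p_cont, solvable, stat_cont = _continuous_p_adjusted(values, expr, group, c)
        # degenerate-regression genes keep the unadjusted continuous part
        fallback = ~solvable
        if fallback.any():
            p_plain = _continuous_p_plain(target, reference, expr_t, expr_r)
            p_cont = np.where(fallback, p_plain, p_cont)
        p_t = p_cont
        brown_f, brown_df = _brown_scale(p_det, p_t, stat_det, stat_cont)
    else:
        p_det = _detection_p_plain(expr_t, expr_r, n_t, n_r, pct_t, pct_r)
        p_t = _continuous_p_plain(target, reference, expr_t, expr_r)

    # Fisher combination: chi2 with 2 df per defined part; with depth
    # adjustment the two-part null is Brown's scaled chi-square instead,
    # absorbing the within-gene dependence of the parts
    parts = np.stack([p_det, p_t])
    defined = ~np.isnan(parts)
    n_parts = defined.sum(axis=0)
    logs = np.where(defined, -2 * np.log(np.clip(parts, _TINY_P, 1.0)), 0.0)
    chi2_stat = logs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p_one = stats.chi2.sf(chi2_stat, 2.0)
        p_two = stats.chi2.sf(chi2_stat / brown_f, brown_df)
    p_comb = np.where(n_parts == 2, p_two, np.where(n_parts == 1, p_one, 1.0))
    p_value = np.where(tested, p_comb, np.nan)

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p_value,
            "pct_expr_target": pct_t,
            "pct_expr_ref": pct_r,
            "tested": tested,
        }
    )


def profile_all_samples(
    norm: NormalizedMatrix,
    target_subtype: str = "SLC1",
    reference_stage: str = "normal",
    include_reference_samples: bool = True,
    min_cells: int = 10,
    min_pct: float = 0.05,
    depth_adjust: bool = True,
) -> pd.DataFrame:
    """Per-sample log2FC profile of the target subtype vs pooled reference.

    The reference is every target-subtype cell from reference-stage
    samples, pooled.  Each sample's target-subtype cells are tested against
    it with :func:`hurdle_de`; BH adjustment is applied within each sample
    across its tested genes.  Samples below ``min_cells`` target cells are
    flagged unprofiled (logged) and omitted.  Reference-stage samples are
    profiled too by default so they can anchor the normal end of the
    continuum.
    """
    cells = norm.cells
    ref_mask = (
        (cells["stage"] == reference_stage) & (cells["cell_type"] == target_subtype)
    ).to_numpy()
    if ref_mask.sum() == 0:
        raise ValueError(
            f"no {target_subtype!r} cells in stage {reference_stage!r} to use "
            "as reference"
        )
    reference = norm.values[ref_mask]
    gene_ids = norm.genes["gene_id"].to_numpy()

    frames = []
    for sid in pd.unique(cells["sample_id"]):
        smask = (cells["sample_id"] == sid).to_numpy()
        stage = cells.loc[smask, "stage"].iloc[0]
        if stage == reference_stage and not include_reference_samples:
            continue
        tmask = smask & (cells["cell_type"] == target_subtype).to_numpy()
        res = hurdle_de(
            norm.values[tmask],
            reference,
            min_cells=min_cells,
            min_pct=min_pct,
            depth_adjust=depth_adjust,
        )
        if res is None:
            logger.info(
                "sample %s unprofiled: %d target cells < min_cells=%d",
                sid,
                int(tmask.sum()),
                min_cells,
            )
            continue
        res.insert(0, "gene", gene_ids)
        res.insert(0, "sample_id", sid)
        res["n_target_cells"] = int(tmask.sum())
        res["n_ref_cells"] = int(ref_mask.sum())
        p = res["p_value"].to_numpy()
        adj = np.full(len(p), np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        res["p_adj"] = adj
        frames.append(res)
    if not frames:
        raise ValueError("no sample could be profiled")
    return pd.concat(frames, ignore_index=True)


def select_continuum_genes(
    profile: pd.DataFrame, alpha: float = 0.05, min_samples: int = 2
) -> list[str]:
    """Genes with p_adj < alpha in at least ``min_samples`` samples."""
    if profile.empty:
        raise ValueError("empty profile")
    sig = profile[profile["p_adj"] < alpha]
    counts = sig.groupby("gene")["sample_id"].nunique()
    selected = sorted(counts.index[counts >= min_samples])
    if not selected:
        raise ValueError(
            "no gene passes the selection rule; consider a larger alpha or "
            "smaller min_samples"
        )
    return selected


# ---------------------------------------------------------------------------
# PCA of log2FC profiles
# ---------------------------------------------------------------------------

def log2fc_matrix(
    profile: pd.DataFrame, genes: list[str]
) -> tuple[pd.DataFrame, int]:
    """Samples x genes log2FC matrix; untested entries imputed as 0."""
    wide = profile.pivot(index="sample_id", columns="gene", values="log2fc")
    wide = wide.reindex(columns=genes)
    n_imputed = int(wide.isna().sum().sum())
    if n_imputed:
        logger.info("imputing %d missing log2FC entries as 0", n_imputed)
    return wide.fillna(0.0), n_imputed


def continuum_pca(
    profile: pd.DataFrame, genes: list[str]
) -> tuple[pd.DataFrame, tuple[float, float], int]:
    """Column-centered, unscaled PCA of the log2FC matrix.

    Returns (pc_coords with columns PC1/PC2 indexed by sample, explained
    variance ratios, number of imputed entries).  Each component's sign is
    fixed so that its largest-magnitude gene loading is positive.  Raises
    if fewer than 3 samples, fewer than 2 genes, or every sample profile is
    identical (rank 0).  Exactly collinear samples are valid: PC2 then
    carries zero variance.
    """
    wide, n_imputed = log2fc_matrix(profile, genes)
    if wide.shape[0] < 3:
        raise ValueError(f"need >= 3 samples, have {wide.shape[0]}")
    if wide.shape[1] < 2:
        raise ValueError(f"need >= 2 selected genes, have {wide.shape[1]}")
    x = wide.to_numpy(float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[0] <= 1e-12:
        raise ValueError("all sample profiles identical; PCA undefined (rank 0)")
    coords = u[:, :2] * s[:2]
    coords[:, s[:2] <= 1e-12 * s[0]] = 0.0
    loadings = vt[:2]
    for j in range(2):
        top = np.argmax(np.abs(loadings[j]))
        if loadings[j, top] < 0:
            loadings[j] = -loadings[j]
            coords[:, j] = -coords[:, j]
    total_var = (s**2).sum()
    evr = (float(s[0] ** 2 / total_var), float(s[1] ** 2 / total_var))
    pc = pd.DataFrame(coords, index=wide.index, columns=["PC1", "PC2"])
    return pc, evr, n_imputed


# ---------------------------------------------------------------------------
# principal curve
# ---------------------------------------------------------------------------

@dataclass
class ContinuumResult:
    selected_genes: list[str]
    pc_coords: pd.DataFrame
    explained_variance: tuple[float, float]
    curve: np.ndarray  # ordered polyline, m x 2
    position: dict[str, float]
    orientation_anchor: str
    converged: bool = True
    n_imputed: int = 0


def _project_to_polyline(points: np.ndarray, poly: np.ndarray):
    """Orthogonal projection of each point onto a polyline.

    Returns (projected points, arc-length parameter of each projection).
    """
    seg_vec = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    keep = seg_len > 0
    if not keep.all():
        # collapse zero-length segments
        poly = np.concatenate([poly[:1], poly[1:][keep]], axis=0)
        seg_vec = np.diff(poly, axis=0)
        seg_len = np.linalg.norm(seg_vec, axis=1)
    if len(poly) < 2:
        # degenerate curve: a single point
        proj = np.repeat(poly[:1], len(points), axis=0)
        return proj, np.zeros(len(points))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_d2 = np.full(len(points), np.inf)
    best_proj = np.zeros_like(points)
    best_arc = np.zeros(len(points))
    for i in range(len(seg_vec)):
        a, v, L = poly[i], seg_vec[i], seg_len[i]
        t = np.clip(((points - a) @ v) / (L * L), 0.0, 1.0)
        proj = a + t[:, None] * v
        d2 = ((points - proj) ** 2).sum(axis=1)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        best_proj[better] = proj[better]
        best_arc[better] = cum[i] + t[better] * L
    return best_proj, best_arc


def _smooth_coordinate(lam: np.ndarray, y: np.ndarray, frac: float) -> np.ndarray:
    """Lowess (locally linear) smoother of y against lam, evaluated at lam.

    Local linear fits reproduce exactly affine data exactly, so a straight
    configuration of samples degenerates to its own line.
    """
    fitted = lowess(y, lam, frac=frac, it=0, return_sorted=False)
    return np.asarray(fitted, float)


def fit_principal_curve(
    pc_coords: pd.DataFrame,
    stages: pd.Series | dict,
    tol: float = 1e-4,
    max_iter: int = 30,
    frac: float = 0.7,
    reference_stage: str = "normal",
) -> tuple[np.ndarray, dict[str, float], bool, str]:
    """Hastie–Stuetzle principal curve in the PC1–PC2 plane.

    Initializes positions on PC1, then alternates (a) smoothing each
    coordinate against the current positions (lowess, span ``frac``) and
    (b) projecting samples back onto the resulting polyline, until the
    mean squared orthogonal projection distance stabilises (relative
    change < ``tol``) or ``max_iter`` is reached (non-convergence is
    flagged, the last iterate returned).

    Positions are arc lengths along the curve rescaled to [0, 1] and
    oriented so reference-stage (normal) samples sit at the low end and
    the most progressed stage present at the high end.
    """
    from .io import STAGES

    if isinstance(stages, dict):
        stages = pd.Series(stages)
    x = pc_coords[["PC1", "PC2"]].to_numpy(float)
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 samples, have {n}")
    scale = max(np.ptp(x[:, 0]), np.ptp(x[:, 1]), 1e-12)

    lam = x[:, 0].copy()
    d2_hist: list[float] = []
    converged = False
    curve = None
    arc = lam
    for _ in range(max_iter):
        order = np.argsort(lam, kind="mergesort")
        fitted = np.column_stack(
            [_smooth_coordinate(lam, x[:, j], frac) for j in range(2)]
        )
        curve = fitted[order]
        proj, arc = _project_to_polyline(x, curve)
        d2 = (((x - proj) / scale) ** 2).sum(axis=1).mean()
        lam = arc
        # converged when the fit error stabilises; comparing against the
        # recent history also catches the short periodic orbits a discrete
        # smoother can settle into
        if any(
            abs(prev - d2) <= tol * max(prev, 1e-12) for prev in d2_hist[-6:]
        ):
            converged = True
            break
        d2_hist.append(d2)
    if not converged:
        logger.warning("principal curve did not converge in %d iterations", max_iter)

    pos = arc.copy()
    span = pos.max() - pos.min()
    if span <= 0:
        pos = np.zeros(n)
    else:
        pos = (pos - pos.min()) / span

    sample_ids = list(pc_coords.index)
    stage_of = {s: stages[s] for s in sample_ids}
    present = [st for st in STAGES if st in set(stage_of.values())]
    anchor_hi = present[-1] if present else None
    ref_pos = [p for s, p in zip(sample_ids, pos) if stage_of[s] == reference_stage]
    hi_pos = [p for s, p in zip(sample_ids, pos) if stage_of[s] == anchor_hi]
    if ref_pos and hi_pos and anchor_hi != reference_stage:
        if np.mean(ref_pos) > np.mean(hi_pos):
            pos = 1.0 - pos
            curve = curve[::-1].copy()
    position = {s: float(p) for s, p in zip(sample_ids, pos)}
    return curve, position, converged, anchor_hi or reference_stage


def order_samples(
    profile: pd.DataFrame,
    stages: pd.Series | dict,
    alpha: float = 0.05,
    min_samples: int = 2,
    tol: float = 1e-4,
    max_iter: int = 30,
    frac: float = 0.7,
    reference_stage: str = "normal",
) -> ContinuumResult:
    """Full continuum ordering: gene selection -> PCA -> principal curve."""
    genes = select_continuum_genes(profile, alpha=alpha, min_samples=min_samples)
    pc, evr, n_imputed = continuum_pca(profile, genes)
    curve, position, converged, anchor = fit_principal_curve(
        pc,
        stages,
        tol=tol,
        max_iter=max_iter,
        frac=frac,
        reference_stage=reference_stage,
    )
    return ContinuumResult(
        selected_genes=genes,
        pc_coords=pc,
        explained_variance=evr,
        curve=curve,
        position=position,
        orientation_anchor=anchor,
        converged=converged,
        n_imputed=n_imputed,
    )


# ---------------------------------------------------------------------------
# gene trends
# ---------------------------------------------------------------------------

def gene_trends(
    profile: pd.DataFrame,
    axis_values: pd.Series | dict,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of each gene's per-sample log2FC against an
    axis (PC2 coordinates by default upstream, or arc-length positions).

    Genes with a constant log2FC vector get rho = NaN and a flag; BH is
    applied across the testable genes.
    """
    if isinstance(axis_values, dict):
        axis_values = pd.Series(axis_values)
    wide = profile.pivot(index="sample_id", columns="gene", values="log2fc")
    wide = wide.loc[wide.index.intersection(axis_values.index)]
    if len(wide) < 4:
        raise ValueError(f"need >= 4 profiled samples, have {len(wide)}")
    if genes is not None:
        wide = wide.reindex(columns=genes)
    axis = axis_values.loc[wide.index].to_numpy(float)

    rows = []
    for gene in wide.columns:
        y = wide[gene].to_numpy(float)
        ok = ~np.isnan(y)
        if ok.sum() < 4 or np.unique(y[ok]).size < 2 or np.unique(axis[ok]).size < 2:
            rows.append({"gene": gene, "spearman_rho": np.nan, "p_value": np.nan, "constant": True})
            continue
        rho, p = stats.spearmanr(axis[ok], y[ok])
        rows.append(
            {"gene": gene, "spearman_rho": float(rho), "p_value": float(p), "constant": False}
        )
    out = pd.DataFrame(rows)
    adj = np.full(len(out), np.nan)
    ok = out["p_value"].notna().to_numpy()
    if ok.any():
        adj[ok] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    out["p_adj"] = adj
    return out


# ---------------------------------------------------------------------------
# one-vs-rest markers
# ---------------------------------------------------------------------------

def one_vs_rest_markers(
    norm: NormalizedMatrix,
    label_column: str = "cell_type",
    top_n: int = 5,
    alpha: float = 0.05,
    min_cells: int = 10,
    min_pct: float = 0.05,
    depth_adjust: bool = True,
) -> pd.DataFrame:
    """Per cell type, hurdle DE of that type vs all others; genes with
    p_adj < alpha ranked by log2fc, top_n reported per type."""
    labels = norm.cells[label_column]
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    gene_ids = norm.genes["gene_id"].to_numpy()
    frames = []
    for ct in types:
        mask = (labels == ct).to_numpy()
        res = hurdle_de(
            norm.values[mask],
            norm.values[~mask],
            min_cells=min_cells,
            min_pct=min_pct,
            depth_adjust=depth_adjust,
        )
        if res is None:
            logger.warning("cell type %s below min_cells; skipped", ct)
            continue
        p = res["p_value"].to_numpy()
        adj = np.full(len(p), np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        res["p_adj"] = adj
        res.insert(0, "gene", gene_ids)
        res.insert(0, "cell_type", ct)
        sig = res[(res["p_adj"] < alpha)].sort_values("log2fc", ascending=False)
        frames.append(sig.head(top_n))
    if not frames:
        return pd.DataFrame(
            columns=["cell_type", "gene", "log2fc", "p_value", "p_adj"]
        )
    return pd.concat(frames, ignore_index=True)
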