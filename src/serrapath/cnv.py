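"""Reference-anchored copy-number inference from expression.

Large chromosomal gains and losses leave a coherent shift in the expression
of neighbouring genes.  The procedure here is a deliberately transparent
windowed-mean realization of that idea: center each gene's log-normalized
expression on the mean of a reference cell population (normal epithelial
cells from normal samples), clip extreme values, then smooth along genomic
position within each chromosome.  From the smoothed profile it derives

* a per-cell CNV score — the mean squared smoothed deviation, a
  nonnegative burden measure that is 0 only for a perfectly neutral cell;
* per-sample chromosome-arm event percentages — the fraction of an arm's
  genes whose sample-mean smoothed signal exceeds a gain (or falls below a
  loss) threshold;
* a Kruskal–Wallis comparison of CNV scores across stages or cell types.

No HMM segmentation or subclustering is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class CNVProfile:
    """Smoothed reference-centered expression, genes in genomic order."""

    smoothed: np.ndarray  # cells x genes
    cells: pd.DataFrame
    genes: pd.DataFrame  # reordered genomically; unplaced genes dropped
    window: int
    cap: float
    reference_cells: list[str]


def _chromosome_sort_key(chrom: pd.Series) -> pd.Series:
    def key(c):
        try:
            return (0, int(c))
        except (TypeError, ValueError):
            return (1, str(c))

    return chrom.map(key)


def genomic_order(genes: pd.DataFrame) -> np.ndarray:
    """Indices sorting genes by (chromosome, start); unplaced genes excluded."""
    placed = genes["arm"].ne("NA") & genes["chromosome"].notna()
    n_dropped = int((~placed).sum())
    if n_dropped:
        logger.warning("dropping %d unplaced genes from CNV analysis", n_dropped)
    sub = genes.loc[placed].copy()
    sub["_ck"] = _chromosome_sort_key(sub["chromosome"])
    order = sub.sort_values(["_ck", "start"], kind="mergesort").index.to_numpy()
    return order


def relative_expression(
    norm: NormalizedMatrix, reference_cells: np.ndarray | list, cap: float = 3.0
) -> np.ndarray:
    """Per gene, subtract the reference-cell mean; clip to +/- cap.

    ``reference_cells`` is a boolean mask over rows of ``norm`` or a list of
    barcodes.  Raises on an empty reference.
    """
    if isinstance(reference_cells, (list, tuple, pd.Series)):
        ref_mask = norm.cells["barcode"].isin(list(reference_cells)).to_numpy()
    else:
        ref_mask = np.asarray(reference_cells, dtype=bool)
    if ref_mask.sum() == 0:
        raise ValueError("empty reference cell set")
    ref_mean = norm.values[ref_mask].mean(axis=0)
    centered = norm.values - ref_mean[None, :]
    np.clip(centered, -cap, cap, out=centered)
    return centered


def _smooth_block(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1, shrinking symmetrically at the
    block edges so the window never crosses the block boundary."""
    if window == 1:
        return block.copy()
    n = block.shape[1]
    half = (window - 1) // 2
    cs = np.zeros((block.shape[0], n + 1))
    np.cumsum(block, axis=1, out=cs[:, 1:])
    out = np.empty_like(block)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[:, i] = (cs[:, i + k + 1] - cs[:, i - k]) / (2 * k + 1)
    return out


def smooth_by_position(
    centered: np.ndarray,
    cells: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 101,
    cap: float = 3.0,
    reference_cells: list[str] | None = None,
) -> CNVProfile:
    """Moving-average smoothing along genomic position, per chromosome.

    ``window`` must be odd and >= 1 (1 is the identity); smoothing never
    crosses a chromosome boundary and shrinks symmetrically at its edges.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    order = genomic_order(genes)
    g = genes.loc[order].reset_index(drop=True)
    x = centered[:, order]
    smoothed = np.empty_like(x)
    start = 0
    ck = _chromosome_sort_key(g["chromosome"])
    boundaries = np.flatnonzero(ck.values[1:] != ck.values[:-1]) + 1
    for stop in [*boundaries, len(g)]:
        smoothed[:, start:stop] = _smooth_block(x[:, start:stop], window)
        start = stop
    return CNVProfile(
        smoothed=smoothed,
        cells=cells.reset_index(drop=True),
        genes=g,
        window=window,
        cap=cap,
        reference_cells=list(reference_cells or []),
    )


def cnv_score(profile: CNVProfile) -> pd.DataFrame:
    """Per-cell mean squared smoothed deviation from neutrality."""
    scores = (profile.smoothed**2).mean(axis=1)
    out = profile.cells[["barcode", "sample_id", "stage", "cell_type"]].copy()
    out = out.rename(columns={"barcode": "cell_id"})
    out["cnv_score"] = scores
    return out


def arm_events(
    profile: CNVProfile,
    gain_thr: float = 0.1,
    loss_thr: float = 0.1,
) -> pd.DataFrame:
    """Per-sample arm gain/loss percentages.

    For each (sample, arm): average the smoothed profile over the sample's
    non-reference cells (all its cells when the whole sample is reference,
    as for normal anchors), then report the percentage of the arm's genes
    whose mean exceeds ``gain_thr`` (gain) or falls below ``-loss_thr``
    (loss).  Arms with zero genes are omitted with a warning.
    """
    ref = set(profile.reference_cells)
    rows = []
    arms = profile.genes["arm"].to_numpy()
    arm_names = list(dict.fromkeys(arms))  # genomic order
    for sid, grp in profile.cells.groupby("sample_id", sort=True):
        non_ref = ~grp["barcode"].isin(ref)
        idx = grp.index[non_ref] if non_ref.any() else grp.index
        sample_mean = profile.smoothed[idx].mean(axis=0)
        for arm in arm_names:
            gmask = arms == arm
            if not gmask.any():
                logger.warning("arm %s has no genes; omitted", arm)
                continue
            vals = sample_mean[gmask]
            rows.append(
                {
                    "sample_id": sid,
                    "arm": arm,
                    "pct_gain": 100.0 * float((vals > gain_thr).mean()),
                    "pct_loss": 100.0 * float((vals < -loss_thr).mean()),
                }
            )
    return pd.DataFrame(rows)


def score_group_test(
    scores: pd.DataFrame, grouping: str = "stage"
) -> tuple[float, float]:
    """Kruskal–Wallis H test of CNV scores across groups (tie-corrected)."""
    groups = [g["cnv_score"].to_numpy() for _, g in scores.groupby(grouping)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError(f"need >= 2 non-empty groups under {grouping!r}")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1 or all(
        np.array_equal(g, groups[0]) for g in groups[1:]
    ):
        return 0.0, 1.0  # identical samples: H = 0 by definition
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
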