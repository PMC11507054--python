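"""Control-matched gene-set module scoring and cell-cycle phase calls.

A module score for a gene set is the mean log-normalized expression of the
set's genes minus the mean of expression-matched control genes: genes are
binned by their average expression across cells, and each set gene draws
controls from its own bin.  Subtracting bin-matched controls removes the
baseline-expression confound, so a score near 0 means "no coherent
elevation of this program".

Cell-cycle phase is assigned from S-phase and G2M-phase module scores:
G1 when both are <= 0, otherwise the phase with the larger score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)


def module_score(
    norm: NormalizedMatrix,
    gene_set: list[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
    program: str = "program",
) -> pd.DataFrame:
    """Score every cell for one gene set against bin-matched controls.

    Genes are ranked by mean expression over cells and cut into ``n_bins``
    equal-size bins.  For each set gene, ``n_ctrl`` control genes are drawn
    from its bin excluding set genes — without replacement while the bin
    lasts, topping up with replacement if the bin is exhausted.  The score
    is mean(set expression) - mean(control expression) per cell; control
    draws are deterministic for a fixed seed.

    Set genes absent from the matrix are dropped with a warning; if none
    remain this raises ``ValueError``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    names = norm.genes["gene_name"].to_numpy()
    name_to_idx: dict[str, int] = {}
    for i, n in enumerate(names):
        name_to_idx.setdefault(n, i)
    set_idx = [name_to_idx[g] for g in gene_set if g in name_to_idx]
    missing = [g for g in gene_set if g not in name_to_idx]
    if missing:
        logger.warning(
            "module_score(%s): %d set genes absent from matrix", program, len(missing)
        )
    if not set_idx:
        raise ValueError(f"no gene of set {program!r} present in the matrix")
    set_idx = np.array(sorted(set(set_idx)))

    avg = norm.values.mean(axis=0)
    # rank-based equal-size bins; ties broken by gene order for determinism
    order = np.argsort(avg, kind="mergesort")
    bins = np.empty(len(avg), dtype=int)
    bins[order] = np.arange(len(avg)) * n_bins // len(avg)

    rng = np.random.default_rng(seed)
    in_set = np.zeros(len(avg), dtype=bool)
    in_set[set_idx] = True
    ctrl_idx_parts = []
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set)
        if len(pool) == 0:
            logger.warning(
                "module_score(%s): bin of gene %s has no control genes",
                program,
                names[gi],
            )
            continue
        if len(pool) >= n_ctrl:
            draw = rng.choice(pool, size=n_ctrl, replace=False)
        else:
            extra = rng.choice(pool, size=n_ctrl - len(pool), replace=True)
            draw = np.concatenate([pool, extra])
        ctrl_idx_parts.append(draw)
    if not ctrl_idx_parts:
        raise ValueError(f"no control genes available for set {program!r}")
    ctrl_idx = np.concatenate(ctrl_idx_parts)

    score = norm.values[:, set_idx].mean(axis=1) - norm.values[:, ctrl_idx].mean(axis=1)
    return pd.DataFrame(
        {
            "cell_id": norm.cells["barcode"].to_numpy(),
            "program": program,
            "score": score,
        }
    )


def score_programs(
    norm: NormalizedMatrix,
    sets: dict[str, list[str]],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score several programs; each gets an independent control draw derived
    from the same master seed."""
    ss = np.random.SeedSequence(seed)
    frames = []
    for child, (name, genes) in zip(ss.spawn(len(sets)), sets.items()):
        sub_seed = int(child.generate_state(1)[0] % 2**31)
        frames.append(
            module_score(norm, genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=sub_seed, program=name)
        )
    return pd.concat(frames, ignore_index=True)


def assign_phase(scores: pd.DataFrame, s_program: str = "S", g2m_program: str = "G2M") -> pd.DataFrame:
    """Cell-cycle phase from S and G2M module scores.

    G1 iff both scores <= 0; otherwise the argmax score's phase (ties go
    to S, which can only occur at exactly equal positive scores).
    """
    wide = scores.pivot(index="cell_id", columns="program", values="score")
    for prog in (s_program, g2m_program):
        if prog not in wide.columns or wide[prog].isna().any():
            raise ValueError(f"missing {prog} score for some cells")
    s = wide[s_program].to_numpy()
    g2m = wide[g2m_program].to_numpy()
    phase = np.where((s <= 0) & (g2m <= 0), "G1", np.where(s >= g2m, "S", "G2M"))
    return pd.DataFrame(
        {
            "cell_id": wide.index.to_numpy(),
            "s_score": s,
            "g2m_score": g2m,
            "phase": phase,
        }
    )


def score_by_group(
    scores: pd.DataFrame, groups: pd.Series | dict
) -> tuple[pd.DataFrame, float]:
    """Per-group median/IQR of one program's scores + Kruskal–Wallis p.

    ``groups`` maps cell_id to a group label (e.g. trajectory state or
    stage).  Returns (summary table, p value).
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    df = scores.copy()
    df["group"] = df["cell_id"].map(groups)
    if df["group"].isna().any():
        raise ValueError("some cells have no group label")
    labels = sorted(df["group"].unique())
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    samples = []
    for lab in labels:
        vals = df.loc[df["group"] == lab, "score"].to_numpy()
        samples.append(vals)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {"group": lab, "n": len(vals), "median": med, "q1": q1, "q3": q3}
        )
    pooled = np.concatenate(samples)
    if np.unique(pooled).size == 1 or all(
        np.array_equal(s, samples[0]) for s in samples[1:]
    ):
        p = 1.0
    else:
        _, p = stats.kruskal(*samples)
    return pd.DataFrame(rows), float(p)
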