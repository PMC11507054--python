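"""Stage-wise cell-type composition tables and pairwise rank-sum tests.

Per-sample cell-type proportions are compared between pathological stage
groups with a two-sided Wilcoxon rank-sum test (exact null distribution for
group sizes <= 10, normal approximation with tie correction otherwise) and
summarised with the conventional star notation: NS p > 0.05, * p < 0.05,
** p < 0.01, *** p < 0.001.  The four serrated-lesion stages (HP, SSL,
SSLD, TSA) can be merged into a single "SL" group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SL_STAGES = ("HP", "SSL", "SSLD", "TSA")


def star_for_p(p: float | None) -> str:
    if p is None or np.isnan(p):
        return "NA"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass
class PairwiseTestResult:
    cell_type: str
    stage_pair: tuple[str, str]
    statistic: float | None
    p_value: float | None
    star: str
    untestable: bool = False


def proportions_by_sample(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cell-type proportions over all types present anywhere.

    Returns rows (sample_id, stage, cell_type, n_cells, proportion); a type
    absent from a sample gets an explicit proportion-0 row.
    """
    for col in ("sample_id", "stage", "cell_type"):
        if cells[col].isna().any():
            raise ValueError(f"cells table has missing values in {col}")
    counts = (
        cells.groupby(["sample_id", "stage", "cell_type"], observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    all_types = sorted(cells["cell_type"].unique())
    sample_stage = cells[["sample_id", "stage"]].drop_duplicates()
    full = sample_stage.merge(pd.DataFrame({"cell_type": all_types}), how="cross")
    table = full.merge(counts, on=["sample_id", "stage", "cell_type"], how="left")
    table["n_cells"] = table["n_cells"].fillna(0).astype(int)
    totals = table.groupby("sample_id")["n_cells"].transform("sum")
    table["proportion"] = table["n_cells"] / totals
    return table.sort_values(["sample_id", "cell_type"]).reset_index(drop=True)


def _stage_group(table: pd.DataFrame, stage: str, merge_sl: bool) -> pd.DataFrame:
    if stage == "SL" or (merge_sl and stage in SL_STAGES):
        return table[table["stage"].isin(SL_STAGES)]
    return table[table["stage"] == stage]


def pairwise_stage_test(
    table: pd.DataFrame,
    cell_type: str,
    stage_a: str,
    stage_b: str,
    merge_sl: bool = False,
) -> PairwiseTestResult:
    """Two-sided Wilcoxon rank-sum on per-sample proportions of one type.

    A group with fewer than two samples makes the pair untestable: the
    result is flagged rather than raising.
    """
    sub = table[table["cell_type"] == cell_type]
    x = _stage_group(sub, stage_a, merge_sl)["proportion"].to_numpy()
    y = _stage_group(sub, stage_b, merge_sl)["proportion"].to_numpy()
    if len(x) < 2 or len(y) < 2:
        return PairwiseTestResult(
            cell_type, (stage_a, stage_b), None, None, "NA", untestable=True
        )
    method = "exact" if max(len(x), len(y)) <= 10 and not _has_ties(x, y) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return PairwiseTestResult(
        cell_type,
        (stage_a, stage_b),
        float(res.statistic),
        float(res.pvalue),
        star_for_p(float(res.pvalue)),
    )


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def all_pairwise_tests(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    merge_sl: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Run every (cell_type, stage pair) test; optional BH across types.

    Stars are mapped from unadjusted p-values by default, matching the
    uncorrected star convention; ``bh_correct=True`` adds a p_adj column
    and maps stars from it instead.
    """
    from statsmodels.stats.multitest import multipletests

    rows = []
    for ct in sorted(table["cell_type"].unique()):
        for a, b in pairs:
            r = pairwise_stage_test(table, ct, a, b, merge_sl=merge_sl)
            rows.append(
                {
                    "cell_type": r.cell_type,
                    "stage_a": a,
                    "stage_b": b,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "star": r.star,
                    "untestable": r.untestable,
                }
            )
    out = pd.DataFrame(rows)
    if bh_correct and out["p_value"].notna().any():
        mask = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        adj[mask.to_numpy()] = multipletests(
            out.loc[mask, "p_value"], method="fdr_bh"
        )[1]
        out["p_adj"] = adj
        out["star"] = [star_for_p(p) for p in out["p_adj"]]
    return out
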