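"""Canned study-condition experiments on synthetic cohorts.

Each function simulates a cohort under fixed study conditions, runs the
relevant slice of the pipeline and returns the headline quantities:
continuum-position recovery, hurdle-test null calibration, CNV arm
detection and stage-wise burden testing, program-score recovery and
composition-test calibration.  They are the single source used by both the
test suite and the results-reproduction script.

Study conditions (fixed here, not tuning knobs):

* continuum recovery — 12 samples (two per stage; the two normal samples
  anchor the reference), 150 target-subtype cells per sample, 2000 genes of
  which 200 carry slopes of 1-3 log2 units, NB dispersion 0.5;
* null DE — two 150-cell groups from one NB model, 5000 genes, for the
  uniformity check; many small 1000-gene/100-cell replicates for the
  Monte-Carlo FDR estimate;
* CNV — the study cohort layout (13 normal, 4 HP, 5 SSL, 1 SSLD, 5 TSA,
  10 tumor samples) at 150 cells/sample; a single 7p gain (ratio 1.5) in
  tumor cells for arm detection, and a stage-graded burden (7p gain in
  lesions, 7p/5q/17p/18q events in tumors) for the stage comparison;
* programs — +1 natural-log-unit elevation over 50 genes in planted masks;
* composition — two 10-sample stage groups with identical multinomial
  proportions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cnv import arm_events, cnv_score, relative_expression, score_group_test, smooth_by_position
from .composition import pairwise_stage_test
from .continuum import hurdle_de, order_samples, profile_all_samples, select_continuum_genes
from .preprocess import normalize
from .programs import assign_phase, score_programs
from .simulate import CNVSegment, ProgramDef, SimConfig, generate_dataset

LN_UNIT = 1 / np.log(2)  # +1 natural-log unit, in log2 units

#: The study cohort layout: samples per pathological stage.
COHORT = {"normal": 13, "HP": 4, "SSL": 5, "SSLD": 1, "TSA": 5, "tumor": 10}

#: The window covering on 2000-gene data the same genomic fraction that the
#: conventional 101-gene window covers on a whole transcriptome.
DESK_WINDOW = 15


def continuum_recovery(seed: int) -> dict:
    """Recover planted progression scores on the default 12-sample cohort.

    Returns the Spearman correlation between recovered continuum positions
    and the planted scores, plus bookkeeping.
    """
    ds, truth = generate_dataset(SimConfig(seed=seed))
    norm = normalize(ds)
    profile = profile_all_samples(norm)
    stages = ds.cells.drop_duplicates("sample_id").set_index("sample_id")["stage"]
    result = order_samples(profile, stages)
    ids = list(result.position)
    rho, _ = stats.spearmanr(
        [result.position[s] for s in ids], [truth.s_true[s] for s in ids]
    )
    return {
        "rho": float(rho),
        "n_samples": len(ids),
        "n_selected": len(result.selected_genes),
        "profile": profile,
        "truth": truth,
        "result": result,
    }


def selection_fidelity(profile: pd.DataFrame, alpha: float = 0.05, min_samples: int = 2) -> dict:
    """Exhaustively re-check the continuum-gene selection rule."""
    selected = select_continuum_genes(profile, alpha=alpha, min_samples=min_samples)
    counts = profile[profile["p_adj"] < alpha].groupby("gene")["sample_id"].nunique()
    violations = [g for g in selected if counts.get(g, 0) < min_samples]
    missed = [
        g for g, k in counts.items() if k >= min_samples and g not in set(selected)
    ]
    return {
        "n_selected": len(selected),
        "n_violations": len(violations) + len(missed),
    }


def _null_pair(seed: int, n_cells: int, n_genes: int):
    cfg = SimConfig(
        n_samples_per_stage={"normal": 1, "SSL": 1},
        n_cells_per_sample=n_cells,
        n_genes=n_genes,
        n_continuum_genes=0,
        slope_range=(0.0, 0.0),
        seed=seed,
    )
    ds, _ = generate_dataset(cfg)
    norm = normalize(ds)
    a = norm.values[(norm.cells["stage"] == "SSL").to_numpy()]
    b = norm.values[(norm.cells["stage"] == "normal").to_numpy()]
    return a, b


def de_null_calibration(seed: int, n_genes: int = 5000, n_cells: int = 150) -> dict:
    """KS uniformity of hurdle p-values on a no-effect simulation."""
    a, b = _null_pair(seed, n_cells, n_genes)
    res = hurdle_de(a, b)
    p = res.loc[res["tested"], "p_value"].dropna().to_numpy()
    d, _ = stats.kstest(p, "uniform")
    return {
        "ks_distance": float(d),
        "n_tested": int(len(p)),
        "frac_below_05": float((p < 0.05).mean()),
    }


def de_null_fdr(seed: int, n_reps: int = 200, n_genes: int = 1000, n_cells: int = 100) -> dict:
    """Monte-Carlo E[FDP] of the BH-selected set under the complete null.

    Every rejection under the null is false, so the per-replicate FDP is 1
    if anything is rejected and 0 otherwise; the average over replicates
    estimates the realised FDR of the procedure.
    """
    fdps = []
    for rep in range(n_reps):
        a, b = _null_pair(seed * 100_000 + rep, n_cells, n_genes)
        res = hurdle_de(a, b)
        p = res.loc[res["tested"], "p_value"].dropna().to_numpy()
        n_rej = int(multipletests(p, alpha=0.05, method="fdr_bh")[0].sum())
        fdps.append(1.0 if n_rej > 0 else 0.0)
    return {"empirical_fdr": float(np.mean(fdps)), "n_reps": n_reps}


def _cnv_profile(ds, window=DESK_WINDOW):
    norm = normalize(ds)
    ref_mask = (norm.cells["stage"] == "normal").to_numpy()
    centered = relative_expression(norm, ref_mask, cap=3.0)
    return smooth_by_position(
        centered,
        norm.cells,
        norm.genes,
        window=window,
        cap=3.0,
        reference_cells=norm.cells["barcode"][ref_mask].tolist(),
    )


def cnv_arm_detection(seed: int) -> dict:
    """Single planted 7p gain (ratio 1.5) in tumor cells: arm percentages."""
    cfg = SimConfig(
        n_samples_per_stage=COHORT,
        n_genes=2000,
        n_continuum_genes=0,
        slope_range=(0.0, 0.0),
        cnv_segments=[CNVSegment(arm="7p", copy_ratio=1.5, stages=["tumor"])],
        seed=seed,
    )
    ds, _ = generate_dataset(cfg)
    profile = _cnv_profile(ds)
    ev = arm_events(profile, gain_thr=0.1, loss_thr=0.1)
    sev = ev[ev["arm"] == "7p"]
    tumor = sev[sev["sample_id"].str.startswith("tumor")]["pct_gain"]
    norm_s = sev[sev["sample_id"].str.startswith("normal")]["pct_gain"]
    return {
        "tumor_pct_gain_min": float(tumor.min()),
        "tumor_pct_gain_mean": float(tumor.mean()),
        "normal_pct_gain_max": float(norm_s.max()),
        "n_samples": int(ev["sample_id"].nunique()),
    }


def cnv_stage_burden(seed: int) -> dict:
    """Stage-graded CNV burden: Kruskal–Wallis of per-cell scores across
    normal / SL / tumor (lesions carry a 7p gain; tumors add the events
    typical of colorectal carcinoma: 5q, 17p and 18q)."""
    sl = ["HP", "SSL", "SSLD", "TSA"]
    cfg = SimConfig(
        n_samples_per_stage=COHORT,
        n_genes=2000,
        n_continuum_genes=0,
        slope_range=(0.0, 0.0),
        cnv_segments=[
            CNVSegment(arm="7p", copy_ratio=1.4, stages=sl),
            CNVSegment(arm="7p", copy_ratio=1.5, stages=["tumor"]),
            CNVSegment(arm="5q", copy_ratio=0.67, stages=["tumor"]),
            CNVSegment(arm="17p", copy_ratio=0.67, stages=["tumor"]),
            CNVSegment(arm="18q", copy_ratio=0.67, stages=["tumor"]),
        ],
        seed=seed,
    )
    ds, _ = generate_dataset(cfg)
    profile = _cnv_profile(ds)
    scores = cnv_score(profile)
    scores["stage3"] = scores["stage"].replace({s: "SL" for s in sl})
    h, p = score_group_test(scores, "stage3")
    means = scores.groupby("stage3")["cnv_score"].mean()
    return {
        "kruskal_p": float(p),
        "kruskal_h": float(h),
        "graded": bool(means["normal"] < means["SL"] < means["tumor"]),
    }


def program_recovery(seed: int) -> dict:
    """Planted EMT / S / G2M programs: module-score contrast and phase calls."""
    cfg = SimConfig(
        n_samples_per_stage={"normal": 2, "SSL": 2, "tumor": 2},
        n_genes=2000,
        n_continuum_genes=0,
        slope_range=(0.0, 0.0),
        program_defs={
            "EMT": ProgramDef(50, LN_UNIT, 0.3),
            "S": ProgramDef(50, LN_UNIT, 0.2),
            "G2M": ProgramDef(50, LN_UNIT, 0.2),
        },
        seed=seed,
    )
    ds, truth = generate_dataset(cfg)
    norm = normalize(ds)
    sets = {k: v["genes"] for k, v in truth.program_membership.items()}
    scores = score_programs(norm, sets, seed=seed)
    emt = scores[scores["program"] == "EMT"].set_index("cell_id")["score"]
    masked = emt.index.isin(truth.program_membership["EMT"]["cells"])
    gap = float(emt[masked].mean() - emt[~masked].mean())
    phases = assign_phase(scores[scores["program"].isin(["S", "G2M"])])
    g2m_only = set(truth.program_membership["G2M"]["cells"]) - set(
        truth.program_membership["S"]["cells"]
    )
    sub = phases[phases["cell_id"].isin(g2m_only)]
    return {
        "emt_score_gap": gap,
        "g2m_recovery": float((sub["phase"] == "G2M").mean()),
        "n_g2m_cells": int(len(sub)),
    }


def composition_null_calibration(seed: int, n_reps: int = 1000) -> dict:
    """Type-I error of the pairwise rank-sum test on equal-proportion
    stages: 10 samples per stage, 200 cells each, three cell types."""
    rng = np.random.default_rng(seed)
    probs = np.array([0.5, 0.3, 0.2])
    rejections = 0
    tested = 0
    for _ in range(n_reps):
        rows = []
        for stage, n_samples in (("normal", 10), ("tumor", 10)):
            counts = rng.multinomial(200, probs, size=n_samples)
            for i in range(n_samples):
                for ct, c in zip("ABC", counts[i]):
                    rows.append(
                        {
                            "sample_id": f"{stage}_{i}",
                            "stage": stage,
                            "cell_type": ct,
                            "n_cells": int(c),
                            "proportion": c / 200.0,
                        }
                    )
        table = pd.DataFrame(rows)
        res = pairwise_stage_test(table, "A", "normal", "tumor")
        if res.p_value is not None:
            tested += 1
            rejections += res.p_value < 0.05
    return {"rejection_rate": rejections / tested, "n_reps": tested}
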