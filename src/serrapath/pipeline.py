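"""Pipeline orchestration: simulate (or load) -> qc -> composition -> cnv ->
score -> continuum from a single YAML config, with deterministic outputs and
a machine-readable run report.

Every stage writes '#'-provenance-headed TSVs into the output directory;
re-running with the same config and seed rewrites byte-identical files
(timestamps live only in the log).  A single global seed is fanned out to a
named substream per stage, so toggling one stage never perturbs another's
randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import all_pairwise_tests, proportions_by_sample
from .cnv import arm_events, cnv_score, relative_expression, score_group_test, smooth_by_position
from .continuum import gene_trends, order_samples, profile_all_samples
from .io import STAGES, CountDataset, read_counts, read_gmt, write_json, write_table
from .preprocess import normalize, qc_filter
from .programs import assign_phase, score_programs
from .simulate import CNVSegment, ProgramDef, SimConfig, generate_dataset, write_dataset

logger = logging.getLogger(__name__)

_STAGE_NAMES = ("simulate", "qc", "composition", "cnv", "score", "continuum")

_SCHEMA: dict[str, dict] = {
    "seed": None,
    "stages": {name: None for name in _STAGE_NAMES},
    "input": {"counts_dir": None},
    "simulate": {
        "n_samples_per_stage": None,
        "n_cells_per_sample": None,
        "n_genes": None,
        "n_continuum_genes": None,
        "slope_range": None,
        "progression_scores": None,
        "cnv_segments": None,
        "program_defs": None,
        "cell_type_fractions": None,
        "baseline_mean_lognormal": None,
        "nb_dispersion": None,
        "libsize_lognormal": None,
    },
    "qc": {"min_genes": None, "max_mito_pct": None, "mito_prefix": None},
    "normalize": {"scale": None},
    "composition": {"pairs": None, "merge_sl": None, "bh_correct": None},
    "cnv": {
        "reference_stage": None,
        "reference_cell_type": None,
        "window": None,
        "cap": None,
        "gain_thr": None,
        "loss_thr": None,
    },
    "score": {"gmt": None, "programs": None, "n_bins": None, "n_ctrl": None,
              "s_program": None, "g2m_program": None},
    "continuum": {
        "target_subtype": None,
        "reference_stage": None,
        "alpha": None,
        "min_samples": None,
        "min_cells": None,
        "min_pct": None,
        "axis": None,
        "depth_adjust": None,
    },
}


class ConfigValidationError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigValidationError(["config root must be a mapping"])
    return cfg


def validate_config(config: dict | str | Path) -> list[str]:
    """Full schema + cross-field validation without executing stages.

    Returns the list of errors (empty when the config is valid); unknown
    keys are errors, never silently ignored.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    errors: list[str] = []
    for key, val in config.items():
        if key not in _SCHEMA:
            errors.append(f"unknown key {key!r}")
            continue
        if _SCHEMA[key] is not None:
            if not isinstance(val, dict):
                errors.append(f"{key!r} must be a mapping")
                continue
            for sub in val:
                if sub not in _SCHEMA[key]:
                    errors.append(f"unknown key {key}.{sub}")

    def get(block, key, default=None):
        return config.get(block, {}).get(key, default) if isinstance(config.get(block, {}), dict) else default

    alpha = get("continuum", "alpha", 0.05)
    if not (isinstance(alpha, (int, float)) and 0 < alpha <= 1):
        errors.append("continuum.alpha must be in (0,1]")
    min_samples = get("continuum", "min_samples", 2)
    if not (isinstance(min_samples, int) and min_samples >= 1):
        errors.append("continuum.min_samples must be an integer >= 1")
    axis = get("continuum", "axis", "PC2")
    if axis not in ("PC2", "arclength"):
        errors.append("continuum.axis must be 'PC2' or 'arclength'")
    window = get("cnv", "window", 101)
    if not (isinstance(window, int) and window >= 1 and window % 2 == 1):
        errors.append("cnv.window must be an odd integer >= 1")
    mg = get("qc", "min_genes", 200)
    if not (isinstance(mg, int) and mg >= 0):
        errors.append("qc.min_genes must be a nonnegative integer")
    mito = get("qc", "max_mito_pct", 20)
    if not (isinstance(mito, (int, float)) and 0 <= mito <= 100):
        errors.append("qc.max_mito_pct must be in [0,100]")
    scale = get("normalize", "scale", 1e4)
    if not (isinstance(scale, (int, float)) and scale > 0):
        errors.append("normalize.scale must be > 0")
    seed = config.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed must be an integer")
    sim_stages = get("simulate", "n_samples_per_stage")
    if sim_stages is not None:
        bad = set(sim_stages) - set(STAGES)
        if bad:
            errors.append(f"simulate.n_samples_per_stage: unknown stages {sorted(bad)}")
    counts_dir = get("input", "counts_dir")
    if counts_dir is not None and not Path(counts_dir).is_dir():
        errors.append(f"input.counts_dir does not exist: {counts_dir}")
    gmt = get("score", "gmt")
    if gmt is not None and not Path(gmt).is_file():
        errors.append(f"score.gmt does not exist: {gmt}")
    return errors


def stage_seed(global_seed: int, stage: str) -> int:
    """Named per-stage substream: stable, independent of other stages."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sim_config_from_block(block: dict, seed: int) -> SimConfig:
    kwargs = dict(block)
    if "slope_range" in kwargs:
        kwargs["slope_range"] = tuple(kwargs["slope_range"])
    if "baseline_mean_lognormal" in kwargs:
        kwargs["baseline_mean_lognormal"] = tuple(kwargs["baseline_mean_lognormal"])
    if "libsize_lognormal" in kwargs:
        kwargs["libsize_lognormal"] = tuple(kwargs["libsize_lognormal"])
    if "cnv_segments" in kwargs:
        kwargs["cnv_segments"] = [
            CNVSegment(
                arm=s[0], copy_ratio=s[1],
                cell_types=s[2] if len(s) > 2 else "all",
                stages=s[3] if len(s) > 3 else ["tumor"],
            )
            for s in kwargs["cnv_segments"]
        ]
    if "program_defs" in kwargs:
        kwargs["program_defs"] = {
            name: ProgramDef(
                gene_count=v[0], log2_elevation=v[1], cell_fraction=v[2],
                cell_types=v[3] if len(v) > 3 else "all",
                stages=v[4] if len(v) > 4 else "all",
            )
            for name, v in kwargs["program_defs"].items()
        }
    return SimConfig(seed=seed, **kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the enabled stages in dependency order; returns the report.

    A failing stage halts its dependents but the partial report is still
    written.  With simulated input, recovery metrics against the planted
    truth are computed automatically.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    errors = validate_config(config)
    if errors:
        raise ConfigValidationError(errors)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed", 0)
    toggles = {name: config.get("stages", {}).get(name, True) for name in _STAGE_NAMES}
    report: dict = {
        "version": __version__,
        "seed": seed,
        "stages": {},
        "metrics": {},
        "outputs": {},
    }
    prov_base = {"serrapath_version": __version__, "seed": seed}

    def record(stage: str, status: str, **extra):
        report["stages"][stage] = {"status": status, **extra}

    def emit(name: str, df: pd.DataFrame, stage_params: dict):
        path = out / name
        write_table(df, path, provenance={**prov_base, **stage_params})
        report["outputs"][name] = _sha256(path)

    truth = None
    ds: CountDataset | None = None

    # --- simulate / load ----------------------------------------------------
    if toggles["simulate"]:
        sim_block = dict(config.get("simulate", {}))
        sim = _sim_config_from_block(sim_block, stage_seed(seed, "simulate"))
        ds, truth = generate_dataset(sim)
        write_dataset(ds, truth, out / "sim_data")
        for f in ("matrix.mtx", "features.tsv", "barcodes.tsv", "cells.tsv", "truth.json"):
            report["outputs"][f"sim_data/{f}"] = _sha256(out / "sim_data" / f)
        record("simulate", "ok", n_cells=ds.n_cells, n_genes=ds.n_genes)
    else:
        counts_dir = config.get("input", {}).get("counts_dir")
        if counts_dir is None:
            record("simulate", "skipped")
            _finalize(report, out)
            return report
        ds = read_counts(counts_dir)
        truth_path = Path(counts_dir) / "truth.json"
        if truth_path.exists():
            from .simulate import SimTruth

            truth = SimTruth.from_dict(json.loads(truth_path.read_text()))
        record("simulate", "skipped (loaded counts)", n_cells=ds.n_cells, n_genes=ds.n_genes)

    # --- qc + normalize -----------------------------------------------------
    if toggles["qc"]:
        qc_block = config.get("qc", {})
        n_before = ds.n_cells
        ds = qc_filter(
            ds,
            min_genes=qc_block.get("min_genes", 200),
            max_mito_pct=qc_block.get("max_mito_pct", 20),
            mito_prefix=qc_block.get("mito_prefix", "MT-"),
        )
        record("qc", "ok", n_cells_before=n_before, n_cells_kept=ds.n_cells)
        report["metrics"]["n_cells_kept"] = ds.n_cells
    else:
        record("qc", "skipped")
    norm = normalize(ds, scale=config.get("normalize", {}).get("scale", 1e4))

    # --- composition --------------------------------------------------------
    if toggles["composition"]:
        try:
            comp_block = config.get("composition", {})
            table = proportions_by_sample(ds.cells)
            emit("proportions.tsv", table, {"stage": "composition"})
            pairs = [tuple(p) for p in comp_block.get("pairs", [["normal", "SL"], ["SL", "tumor"]])]
            tests = all_pairwise_tests(
                table,
                pairs,
                merge_sl=comp_block.get("merge_sl", True),
                bh_correct=comp_block.get("bh_correct", False),
            )
            emit("composition_tests.tsv", tests, {"stage": "composition", "pairs": pairs})
            record("composition", "ok", n_tests=len(tests))
        except Exception as e:  # halt this branch, keep the run alive
            logger.exception("composition stage failed")
            record("composition", f"failed: {e}")
    else:
        record("composition", "skipped")

    # --- cnv ----------------------------------------------------------------
    if toggles["cnv"]:
        try:
            cnv_block = config.get("cnv", {})
            ref_stage = cnv_block.get("reference_stage", "normal")
            ref_ct = cnv_block.get("reference_cell_type")
            ref_mask = (norm.cells["stage"] == ref_stage).to_numpy()
            if ref_ct is not None:
                ref_mask &= (norm.cells["cell_type"] == ref_ct).to_numpy()
            window = cnv_block.get("window", 101)
            cap = cnv_block.get("cap", 3.0)
            centered = relative_expression(norm, ref_mask, cap=cap)
            profile = smooth_by_position(
                centered,
                norm.cells,
                norm.genes,
                window=window,
                cap=cap,
                reference_cells=norm.cells["barcode"][ref_mask].tolist(),
            )
            scores = cnv_score(profile)
            emit("cnv_scores.tsv", scores, {"stage": "cnv", "window": window, "cap": cap})
            events = arm_events(
                profile,
                gain_thr=cnv_block.get("gain_thr", 0.1),
                loss_thr=cnv_block.get("loss_thr", 0.1),
            )
            emit("arm_events.tsv", events, {"stage": "cnv", "window": window})
            h, p = score_group_test(scores, "stage")
            record("cnv", "ok", kruskal_h=h, kruskal_p=p)
            report["metrics"]["cnv_stage_kruskal_p"] = p
        except Exception as e:
            logger.exception("cnv stage failed")
            record("cnv", f"failed: {e}")
    else:
        record("cnv", "skipped")

    # --- score --------------------------------------------------------------
    if toggles["score"]:
        try:
            score_block = config.get("score", {})
            gmt_path = score_block.get("gmt")
            if gmt_path:
                coll = read_gmt(gmt_path)
                sets = {name: coll.genes(name) for name in coll.sets}
            elif truth is not None and truth.program_membership:
                sets = {
                    name: m["genes"] for name, m in truth.program_membership.items()
                }
            else:
                sets = {}
            wanted = score_block.get("programs")
            if wanted:
                sets = {k: v for k, v in sets.items() if k in wanted}
            if not sets:
                record("score", "skipped (no gene sets)")
            else:
                scores = score_programs(
                    norm,
                    sets,
                    n_bins=score_block.get("n_bins", 25),
                    n_ctrl=score_block.get("n_ctrl", 100),
                    seed=stage_seed(seed, "score"),
                )
                emit("module_scores.tsv", scores, {"stage": "score", "programs": sorted(sets)})
                s_name = score_block.get("s_program", "S")
                g2m_name = score_block.get("g2m_program", "G2M")
                if s_name in sets and g2m_name in sets:
                    phases = assign_phase(
                        scores[scores["program"].isin([s_name, g2m_name])],
                        s_program=s_name,
                        g2m_program=g2m_name,
                    )
                    emit("phases.tsv", phases, {"stage": "score"})
                record("score", "ok", programs=sorted(sets))
        except Exception as e:
            logger.exception("score stage failed")
            record("score", f"failed: {e}")
    else:
        record("score", "skipped")

    # --- continuum ----------------------------------------------------------
    if toggles["continuum"]:
        try:
            cont = config.get("continuum", {})
            profile = profile_all_samples(
                norm,
                target_subtype=cont.get("target_subtype", "SLC1"),
                reference_stage=cont.get("reference_stage", "normal"),
                min_cells=cont.get("min_cells", 10),
                min_pct=cont.get("min_pct", 0.05),
                depth_adjust=cont.get("depth_adjust", True),
            )
            emit("log2fc_profiles.tsv", profile, {"stage": "continuum"})
            stages_map = ds.cells.drop_duplicates("sample_id").set_index("sample_id")["stage"]
            result = order_samples(
                profile,
                stages_map,
                alpha=cont.get("alpha", 0.05),
                min_samples=cont.get("min_samples", 2),
                reference_stage=cont.get("reference_stage", "normal"),
            )
            positions = pd.DataFrame(
                {
                    "sample_id": list(result.position),
                    "stage": [stages_map[s] for s in result.position],
                    "position": [result.position[s] for s in result.position],
                    "PC1": result.pc_coords["PC1"].reindex(list(result.position)).to_numpy(),
                    "PC2": result.pc_coords["PC2"].reindex(list(result.position)).to_numpy(),
                }
            ).sort_values("position")
            emit(
                "continuum_positions.tsv",
                positions,
                {
                    "stage": "continuum",
                    "alpha": cont.get("alpha", 0.05),
                    "min_samples": cont.get("min_samples", 2),
                    "n_selected_genes": len(result.selected_genes),
                },
            )
            axis = cont.get("axis", "PC2")
            if axis == "PC2":
                axis_values = result.pc_coords["PC2"]
            else:
                axis_values = pd.Series(result.position)
            trends = gene_trends(profile, axis_values, genes=result.selected_genes)
            emit("gene_trends.tsv", trends, {"stage": "continuum", "axis": axis})
            write_json(
                {
                    "curve": result.curve.tolist(),
                    "explained_variance": list(result.explained_variance),
                    "converged": result.converged,
                    "orientation_anchor": result.orientation_anchor,
                    "selected_genes": result.selected_genes,
                },
                out / "curve.json",
            )
            report["outputs"]["curve.json"] = _sha256(out / "curve.json")
            record(
                "continuum",
                "ok",
                n_selected_genes=len(result.selected_genes),
                converged=result.converged,
            )
            report["metrics"]["n_selected_genes"] = len(result.selected_genes)
            if truth is not None and truth.s_true:
                from scipy.stats import spearmanr

                common = [s for s in result.position if s in truth.s_true]
                if len(common) >= 4:
                    rho, _ = spearmanr(
                        [result.position[s] for s in common],
                        [truth.s_true[s] for s in common],
                    )
                    report["metrics"]["continuum_truth_spearman"] = float(rho)
        except Exception as e:
            logger.exception("continuum stage failed")
            record("continuum", f"failed: {e}")
    else:
        record("continuum", "skipped")

    _finalize(report, out)
    return report


def _finalize(report: dict, out: Path) -> None:
    write_json(report, out / "report.json")
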