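"""Negative-binomial scRNA-seq simulator with planted ground truth.

Emulates a multi-sample serrated-pathway cohort: each sample carries a latent
progression score ``s`` in [0, 1] (normal mucosa at 0, carcinoma at 1) that
drives monotone log2 fold changes in a designated subset of "continuum"
genes; chromosome-arm copy-number segments multiply expression in designated
cell subsets; gene programs (e.g. EMT, S-phase, G2M-phase) elevate their
member genes in designated cells.  Counts are negative-binomial with
per-cell lognormal library-size variation.

Every planted effect is recorded in a :class:`SimTruth` so downstream
estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ARMS, STAGES, CountDataset, write_counts, write_json

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The simulation configuration violates its invariants."""


@dataclass
class CNVSegment:
    """A planted arm-level copy-number event.

    ``copy_ratio`` multiplies the expected expression of every gene on
    ``arm`` in cells whose type is in ``cell_types`` ("all" for any) and
    whose sample stage is in ``stages``.
    """

    arm: str
    copy_ratio: float
    cell_types: list[str] | str = "all"
    stages: list[str] = field(default_factory=lambda: ["tumor"])

    def __post_init__(self) -> None:
        if self.copy_ratio <= 0:
            raise ConfigError(f"copy_ratio must be > 0, got {self.copy_ratio}")
        if self.arm not in ARMS:
            raise ConfigError(f"unknown arm {self.arm!r}")


@dataclass
class ProgramDef:
    """A planted gene program: ``gene_count`` genes elevated by
    ``log2_elevation`` (log2 units) in a random ``cell_fraction`` of the
    eligible cells (optionally restricted to given cell types / stages)."""

    gene_count: int
    log2_elevation: float
    cell_fraction: float
    cell_types: list[str] | str = "all"
    stages: list[str] | str = "all"

    def __post_init__(self) -> None:
        if not 0 < self.cell_fraction <= 1:
            raise ConfigError("cell_fraction must be in (0, 1]")
        if self.gene_count < 1:
            raise ConfigError("gene_count must be >= 1")


@dataclass
class SimConfig:
    """Study design of a simulated cohort.

    Defaults emulate a 12-sample serrated-pathway cohort (two samples per
    pathological stage) of one malignant epithelial subtype, 150 cells per
    sample, 2000 genes of which 200 follow the malignant continuum with
    slopes of 1-3 log2 units over the full progression.
    """

    n_samples_per_stage: dict[str, int] = field(
        default_factory=lambda: {s: 2 for s in STAGES}
    )
    n_cells_per_sample: int = 150
    n_genes: int = 2000
    n_continuum_genes: int = 200
    slope_range: tuple[float, float] = (1.0, 3.0)
    progression_scores: dict[str, float] | str = "auto"
    cnv_segments: list[CNVSegment] = field(default_factory=list)
    program_defs: dict[str, ProgramDef] = field(default_factory=dict)
    cell_type_fractions: dict[str, float] = field(
        default_factory=lambda: {"SLC1": 1.0}
    )
    baseline_mean_lognormal: tuple[float, float] = (-1.5, 1.2)
    nb_dispersion: float = 0.5
    libsize_lognormal: tuple[float, float] = (0.0, 0.3)
    seed: int = 0

    def validate(self) -> None:
        bad = set(self.n_samples_per_stage) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stages {sorted(bad)}")
        n_program = sum(p.gene_count for p in self.program_defs.values())
        if self.n_continuum_genes + n_program > self.n_genes:
            raise ConfigError(
                f"gene budget exceeded: {self.n_continuum_genes} continuum + "
                f"{n_program} program genes > {self.n_genes} total"
            )
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.slope_range[0] > self.slope_range[1] or self.slope_range[0] < 0:
            raise ConfigError("slope_range must be 0 <= lo <= hi (magnitudes)")
        if isinstance(self.progression_scores, dict):
            for s, v in self.progression_scores.items():
                if not 0 <= v <= 1:
                    raise ConfigError(f"progression score of {s} outside [0,1]")


@dataclass
class SimTruth:
    """Planted parameters: what a recovery test should estimate back."""

    s_true: dict[str, float]
    beta: dict[str, float]
    cnv_truth: list[dict]
    program_membership: dict[str, dict]

    def to_dict(self) -> dict:
        return {
            "s_true": self.s_true,
            "beta": self.beta,
            "cnv_truth": self.cnv_truth,
            "program_membership": self.program_membership,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            s_true=d["s_true"],
            beta=d["beta"],
            cnv_truth=d["cnv_truth"],
            program_membership=d["program_membership"],
        )


def synthetic_gene_annotation(n_genes: int, seed: int = 0) -> pd.DataFrame:
    """Assign ``n_genes`` genes to chromosome arms 1p..22q.

    Every arm receives at least one gene; positions are strictly increasing
    within a chromosome (p-arm genes precede q-arm genes).  Deterministic
    for a fixed seed.
    """
    if n_genes < len(ARMS):
        raise ConfigError(
            f"n_genes={n_genes} cannot cover all {len(ARMS)} chromosome arms"
        )
    rng = np.random.default_rng(seed)
    extra = rng.multinomial(n_genes - len(ARMS), np.full(len(ARMS), 1 / len(ARMS)))
    counts = 1 + extra
    rows = []
    gene_idx = 0
    for chrom in range(1, 23):
        pos = 0
        for arm_letter in ("p", "q"):
            arm = f"{chrom}{arm_letter}"
            k = counts[ARMS.index(arm)]
            for _ in range(k):
                pos += int(rng.integers(10_000, 1_000_000))
                start = pos
                end = start + int(rng.integers(500, 50_000))
                pos = end
                rows.append(
                    {
                        "gene_id": f"G{gene_idx:05d}",
                        "gene_name": f"G{gene_idx:05d}",
                        "chromosome": str(chrom),
                        "start": start,
                        "end": end,
                        "arm": arm,
                    }
                )
                gene_idx += 1
    return pd.DataFrame(rows)


def _auto_scores(samples: pd.DataFrame) -> dict[str, float]:
    """Stage-ranked equispaced scores on [0, 1]; within-stage ties broken
    by sample index so every sample gets a distinct position."""
    order = sorted(
        samples["sample_id"],
        key=lambda s: (STAGES.index(samples.set_index("sample_id").loc[s, "stage"]), s),
    )
    n = len(order)
    if n == 1:
        return {order[0]: 0.0}
    return {s: i / (n - 1) for i, s in enumerate(order)}


def generate_dataset(config: SimConfig) -> tuple[CountDataset, SimTruth]:
    """Draw a cohort of NB counts with the configured planted structure.

    The NB mean of cell *c*, gene *g* is::

        libsize_c * baseline_g * 2^(beta_g * s_sample(c))
                  * copy_ratio   (if c in a CNV mask and g on its arm)
                  * 2^elevation  (if c and g belong to a program)

    with Var = mu + mu^2 * dispersion.  Bit-reproducible for a fixed seed.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    ss_ann, ss_assign, ss_noise = ss.spawn(3)
    rng_assign = np.random.default_rng(ss_assign)
    rng_noise = np.random.default_rng(ss_noise)

    ann_seed = int(ss_ann.generate_state(1)[0] % 2**31)
    genes = synthetic_gene_annotation(config.n_genes, seed=ann_seed)

    # --- cohort layout -----------------------------------------------------
    sample_rows = []
    for stage in STAGES:
        for i in range(config.n_samples_per_stage.get(stage, 0)):
            sample_rows.append({"sample_id": f"{stage}_{i + 1}", "stage": stage})
    samples = pd.DataFrame(sample_rows)
    if samples.empty:
        raise ConfigError("no samples configured")

    if config.progression_scores == "auto":
        s_true = _auto_scores(samples)
    else:
        s_true = dict(config.progression_scores)
        missing = set(samples["sample_id"]) - set(s_true)
        if missing:
            raise ConfigError(f"progression_scores missing samples {sorted(missing)}")

    cells = samples.loc[samples.index.repeat(config.n_cells_per_sample)].reset_index(
        drop=True
    )
    n_cells = len(cells)
    within = cells.groupby("sample_id").cumcount()
    cells["barcode"] = [
        f"{sid}_c{j:04d}" for sid, j in zip(cells["sample_id"], within)
    ]
    type_names = list(config.cell_type_fractions)
    type_p = np.array([config.cell_type_fractions[t] for t in type_names], float)
    type_p /= type_p.sum()
    cells["cell_type"] = rng_assign.choice(type_names, size=n_cells, p=type_p)
    cells = cells[["barcode", "sample_id", "stage", "cell_type"]]

    # --- gene roles --------------------------------------------------------
    cnv_arms = {seg.arm for seg in config.cnv_segments}
    on_cnv_arm = genes["arm"].isin(cnv_arms).to_numpy()
    eligible = np.flatnonzero(~on_cnv_arm)  # continuum genes avoid CNV arms
    lo, hi = config.slope_range
    beta = np.zeros(config.n_genes)
    beta_map: dict[str, float] = {}
    if config.n_continuum_genes > 0 and hi > 0:
        if len(eligible) < config.n_continuum_genes:
            raise ConfigError("not enough genes outside CNV arms for the continuum")
        cont_idx = rng_assign.choice(
            eligible, size=config.n_continuum_genes, replace=False
        )
        mags = rng_assign.uniform(max(lo, 1e-12), hi, size=config.n_continuum_genes)
        signs = rng_assign.choice([-1.0, 1.0], size=config.n_continuum_genes)
        beta[cont_idx] = mags * signs
        beta_map = {
            genes["gene_id"].iloc[i]: float(beta[i]) for i in np.sort(cont_idx)
        }

    taken = beta != 0
    program_membership: dict[str, dict] = {}
    prog_gene_idx: dict[str, np.ndarray] = {}
    prog_cell_mask: dict[str, np.ndarray] = {}
    for name, pdef in config.program_defs.items():
        pool = np.flatnonzero(~taken & ~on_cnv_arm)
        if len(pool) < pdef.gene_count:
            raise ConfigError(f"not enough free genes for program {name}")
        gidx = rng_assign.choice(pool, size=pdef.gene_count, replace=False)
        taken[gidx] = True
        eligible_cells = np.ones(n_cells, dtype=bool)
        if pdef.cell_types != "all":
            eligible_cells &= cells["cell_type"].isin(pdef.cell_types).to_numpy()
        if pdef.stages != "all":
            eligible_cells &= cells["stage"].isin(pdef.stages).to_numpy()
        elig_idx = np.flatnonzero(eligible_cells)
        if len(elig_idx) == 0:
            raise ConfigError(f"program {name}: no eligible cells")
        n_masked = max(1, int(round(pdef.cell_fraction * len(elig_idx))))
        cidx = rng_assign.choice(elig_idx, size=n_masked, replace=False)
        cmask = np.zeros(n_cells, dtype=bool)
        cmask[cidx] = True
        prog_gene_idx[name] = np.sort(gidx)
        prog_cell_mask[name] = cmask
        program_membership[name] = {
            "genes": genes["gene_id"].iloc[np.sort(gidx)].tolist(),
            "cells": cells["barcode"][cmask].tolist(),
            "log2_elevation": pdef.log2_elevation,
        }

    cnv_truth = []
    cnv_masks: list[tuple[np.ndarray, np.ndarray, float]] = []
    for seg in config.cnv_segments:
        gmask = (genes["arm"] == seg.arm).to_numpy()
        if not gmask.any():
            raise ConfigError(f"planted arm {seg.arm} absent from annotation")
        cmask = cells["stage"].isin(seg.stages).to_numpy()
        if seg.cell_types != "all":
            cmask &= cells["cell_type"].isin(seg.cell_types).to_numpy()
        cnv_masks.append((cmask, gmask, seg.copy_ratio))
        cnv_truth.append(
            {
                "arm": seg.arm,
                "copy_ratio": seg.copy_ratio,
                "cells": cells["barcode"][cmask].tolist(),
                "genes": genes["gene_id"][gmask].tolist(),
            }
        )

    # --- mean structure and NB sampling ------------------------------------
    mu_b, sd_b = config.baseline_mean_lognormal
    baseline = rng_assign.lognormal(mu_b, sd_b, size=config.n_genes)
    mu_l, sd_l = config.libsize_lognormal
    libsize = rng_noise.lognormal(mu_l, sd_l, size=n_cells)

    s_cell = cells["sample_id"].map(s_true).to_numpy(float)
    mean = baseline[None, :] * np.exp2(beta[None, :] * s_cell[:, None])
    for cmask, gmask, ratio in cnv_masks:
        mean[np.ix_(cmask, gmask)] *= ratio
    for name, pdef in config.program_defs.items():
        mean[np.ix_(prog_cell_mask[name], prog_gene_idx[name])] *= 2.0**pdef.log2_elevation
    mean *= libsize[:, None]

    if config.nb_dispersion == 0:
        counts = rng_noise.poisson(mean)
    else:
        r = 1.0 / config.nb_dispersion
        lam = rng_noise.gamma(shape=r, scale=mean * config.nb_dispersion)
        counts = rng_noise.poisson(lam)

    ds = CountDataset(counts=sp.csr_matrix(counts), cells=cells, genes=genes)
    truth = SimTruth(
        s_true={k: float(v) for k, v in s_true.items()},
        beta=beta_map,
        cnv_truth=cnv_truth,
        program_membership=program_membership,
    )
    return ds, truth


def write_dataset(ds: CountDataset, truth: SimTruth, directory: str | Path) -> None:
    """Write the triplet layout plus truth.json."""
    write_counts(ds, directory)
    write_json(truth.to_dict(), Path(directory) / "truth.json")
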