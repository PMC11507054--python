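"""Cell quality-control filtering and library-size log-normalization.

All downstream expression statistics operate on the
:class:`NormalizedMatrix`: ln(1 + count * scale / libsize) per cell, with
scale 10,000 by default.  QC drops cells with too few detected genes or too
high a mitochondrial fraction (mitochondrial genes recognised by gene-name
prefix, "MT-" by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountDataset

logger = logging.getLogger(__name__)


class QCError(ValueError):
    pass


@dataclass
class NormalizedMatrix:
    """Cells x genes matrix of ln(1 + count * scale / libsize)."""

    values: np.ndarray
    cells: pd.DataFrame
    genes: pd.DataFrame
    scale: float = 1e4
    provenance: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def cell_mask(self, **criteria) -> np.ndarray:
        """Boolean mask of cells matching all (column, value-or-list) pairs."""
        mask = np.ones(self.n_cells, dtype=bool)
        for col, val in criteria.items():
            vals = val if isinstance(val, (list, tuple, set)) else [val]
            mask &= self.cells[col].isin(vals).to_numpy()
        return mask


def qc_filter(
    ds: CountDataset,
    min_genes: int = 200,
    max_mito_pct: float = 20.0,
    mito_prefix: str = "MT-",
) -> CountDataset:
    """Keep cells with >= ``min_genes`` detected genes and mitochondrial
    fraction <= ``max_mito_pct`` percent.

    Raises :class:`QCError` if every cell of any sample is removed, since
    per-sample analyses would then be undefined.
    """
    counts = ds.counts.tocsr()
    detected = counts.getnnz(axis=1)
    libsize = np.asarray(counts.sum(axis=1)).ravel()
    mito_genes = ds.genes["gene_name"].str.startswith(mito_prefix).to_numpy()
    if mito_genes.any():
        mito_counts = np.asarray(counts[:, mito_genes].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(libsize > 0, mito_counts / np.maximum(libsize, 1), 0.0)
    else:
        mito_frac = np.zeros(ds.n_cells)

    keep = (detected >= min_genes) & (mito_frac <= max_mito_pct / 100.0)

    removed = ds.cells.loc[~keep].groupby("sample_id").size()
    for sid, n in removed.items():
        logger.info("qc_filter: removed %d cells from %s", n, sid)
    kept_per_sample = ds.cells.loc[keep].groupby("sample_id").size()
    dead = set(ds.cells["sample_id"]) - set(kept_per_sample.index)
    if dead:
        raise QCError(f"QC removed every cell of sample(s) {sorted(dead)}")
    return ds.subset_cells(keep)


def normalize(ds: CountDataset, scale: float = 1e4) -> NormalizedMatrix:
    """ln(1 + count * scale / libsize); requires every cell libsize > 0."""
    counts = ds.counts.tocsr()
    libsize = np.asarray(counts.sum(axis=1)).ravel()
    if (libsize == 0).any():
        bad = ds.cells["barcode"][libsize == 0].head(5).tolist()
        raise QCError(
            f"zero-libsize cells (e.g. {bad}); run qc_filter before normalize"
        )
    dense = counts.toarray().astype(float)
    values = np.log1p(dense * (scale / libsize[:, None]))
    return NormalizedMatrix(
        values=values,
        cells=ds.cells.reset_index(drop=True),
        genes=ds.genes,
        scale=scale,
        provenance={"normalize.scale": scale},
    )
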