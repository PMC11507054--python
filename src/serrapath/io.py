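"""Reading and writing the standard on-disk formats the pipeline touches.

The universal expression input is the 10x-style triplet layout:
``matrix.mtx`` (MatrixMarket coordinate, genes as rows, cells as columns),
``features.tsv`` (gene annotation with genomic coordinates and chromosome-arm
labels), ``barcodes.tsv`` and a ``cells.tsv`` metadata table.  Gene sets are
read from GMT.  Ground-truth parameters of simulated datasets round-trip
through JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Pathological stages of serrated-pathway progression, in biological order:
#: normal mucosa, hyperplastic polyp, sessile serrated lesion, SSL with
#: dysplasia, traditional serrated adenoma, carcinoma.
STAGES = ("normal", "HP", "SSL", "SSLD", "TSA", "tumor")

#: Chromosome arms 1p..22q (acrocentric p-arms included; unplaced genes
#: carry the sentinel "NA").
ARMS = tuple(f"{c}{a}" for c in range(1, 23) for a in ("p", "q"))

FEATURE_COLUMNS = ("gene_id", "gene_name", "chromosome", "start", "end", "arm")
CELL_COLUMNS = ("barcode", "sample_id", "stage", "cell_type")


class FormatError(ValueError):
    """A file violated its format contract or the dataset invariants."""


@dataclass
class CountDataset:
    """Raw counts plus cell metadata and gene annotation.

    ``counts`` is cells x genes (CSR); ``cells`` has one row per cell with
    columns barcode / sample_id / stage / cell_type; ``genes`` has one row
    per gene with gene_id / gene_name / chromosome / start / end / arm.
    """

    counts: sp.csr_matrix
    cells: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise FormatError(
                f"matrix is {self.counts.shape} but metadata describes "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        if (self.counts.data < 0).any():
            raise FormatError("counts must be nonnegative")
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise FormatError(f"cells table missing columns {missing}")
        dup = self.cells["barcode"][self.cells["barcode"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate barcodes: {sorted(set(dup))[:10]}")
        bad_stage = set(self.cells["stage"]) - set(STAGES)
        if bad_stage:
            raise FormatError(f"unknown stage labels: {sorted(bad_stage)}")
        bad_arm = set(self.genes["arm"]) - set(ARMS) - {"NA"}
        if bad_arm:
            raise FormatError(f"unknown arm labels: {sorted(bad_arm)}")

    def subset_cells(self, mask: np.ndarray) -> "CountDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountDataset(
            counts=self.counts[idx],
            cells=self.cells.iloc[idx].reset_index(drop=True),
            genes=self.genes,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. EMT and the S / G2M cell-cycle programs."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]

    def add(self, name: str, description: str, genes: list[str]) -> None:
        seen: dict[str, None] = {}
        for g in genes:
            if g in seen:
                logger.warning("gene set %s: duplicate gene %s dropped", name, g)
            seen[g] = None
        if not seen:
            raise FormatError(f"gene set {name} is empty")
        self.sets[name] = (description, list(seen))


def read_counts(directory: str | Path, transpose: bool = False) -> CountDataset:
    """Load matrix.mtx + features.tsv + barcodes.tsv (+ cells.tsv).

    The matrix is stored genes x cells (the dominant single-cell dialect);
    ``transpose=True`` accommodates a cells x genes file.  Raises
    :class:`FormatError` on dimension mismatches, duplicate barcodes or
    unknown stage labels, naming the offending record.
    """
    d = Path(directory)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (d / name).exists():
            raise FormatError(f"missing {name} in {d}")
    try:
        mat = scipy.io.mmread(d / "matrix.mtx")
    except ValueError as e:
        raise FormatError(f"matrix.mtx: {e}") from e
    mat = sp.csr_matrix(mat)
    if not transpose:
        mat = mat.T.tocsr()  # stored genes x cells -> cells x genes

    genes = pd.read_csv(
        d / "features.tsv", sep="\t", header=None, names=FEATURE_COLUMNS
    )
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0]
    if len(genes) != mat.shape[1]:
        raise FormatError(
            f"features.tsv has {len(genes)} genes but matrix has {mat.shape[1]}"
        )
    if len(barcodes) != mat.shape[0]:
        raise FormatError(
            f"barcodes.tsv has {len(barcodes)} cells but matrix has {mat.shape[0]}"
        )

    cells_path = d / "cells.tsv"
    if cells_path.exists():
        cells = pd.read_csv(cells_path, sep="\t")
        missing = [c for c in CELL_COLUMNS if c not in cells.columns]
        if missing:
            raise FormatError(f"cells.tsv missing columns {missing}")
        cells = cells.set_index("barcode").reindex(barcodes.values)
        if cells["sample_id"].isna().any():
            absent = cells.index[cells["sample_id"].isna()][:10].tolist()
            raise FormatError(f"barcodes absent from cells.tsv: {absent}")
        cells = cells.reset_index().rename(columns={"index": "barcode"})
        cells.columns = ["barcode"] + list(cells.columns[1:])
    else:
        cells = pd.DataFrame(
            {
                "barcode": barcodes.values,
                "sample_id": "sample_1",
                "stage": "normal",
                "cell_type": "unknown",
            }
        )
    return CountDataset(counts=mat, cells=cells, genes=genes)


def write_counts(ds: CountDataset, directory: str | Path) -> None:
    """Write the triplet layout (genes x cells mtx) plus cells.tsv."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(d / "matrix.mtx", sp.coo_matrix(ds.counts.T), field="integer")
    ds.genes.to_csv(d / "features.tsv", sep="\t", header=False, index=False)
    ds.cells[["barcode"]].to_csv(d / "barcodes.tsv", sep="\t", header=False, index=False)
    ds.cells.to_csv(d / "cells.tsv", sep="\t", index=False)


def read_gmt(path: str | Path, uppercase: bool = False) -> GeneSetCollection:
    """Parse a GMT file: one set per line, fields name, description, genes...

    Duplicate genes within a set are dropped with a warning; a line with
    fewer than three fields raises :class:`FormatError` with its number.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if uppercase:
                genes = [g.upper() for g in genes]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name} has no genes")
            coll.add(name, desc, genes)
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in coll.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_json(obj: object, path: str | Path) -> None:
    class _Encoder(json.JSONEncoder):
        def default(self, o):  # numpy scalars/arrays -> plain python
            if isinstance(o, np.integer):
                return int(o)
            if isinstance(o, np.floating):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return super().default(o)

    Path(path).write_text(json.dumps(obj, indent=2, cls=_Encoder) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """TSV with '#'-prefixed provenance lines, the universal output dialect.

    Floats are rendered with a fixed repr so identical inputs produce
    byte-identical files.
    """
    lines = []
    for k, v in (provenance or {}).items():
        lines.append(f"# {k}: {v}")
    body = df.to_csv(sep="\t", index=False, float_format="%.10g")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else "") + body)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
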