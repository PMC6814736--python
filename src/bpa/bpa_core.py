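"""The activity transform: per-cell rank signatures -> gene-set NES z-scores.

Each cell's log-expression column is ranked over ALL genes in the matrix
(zeros form a tie block with averaged ranks), ranks are scaled as
r / (N + 1) and mapped through the standard-normal quantile function. A
gene set's normalized enrichment score (NES) is the sum of its members'
quantiles divided by sqrt(set size) — the analytic z-score of the mean
member quantile, i.e. rank-based enrichment specialized to unsigned,
uniformly weighted sets. Under the null the NES is approximately standard
normal, so scores can be merged across datasets without renormalization.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import norm, rankdata

from bpa.geneset_io import GeneSet, GeneSetCollection, restrict_to_universe

logger = logging.getLogger(__name__)

RANK_SCALING_NOTE = "rank r scaled as r/(N+1); ties averaged; zeros included"


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of log-scale (non-negative, finite) expression."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    log_base_note: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if sparse.issparse(self.values):
            self.values = np.asarray(self.values.todense(), dtype=float)
        else:
            self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative (log scale)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, log_base_note: str = ""
    ) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            cell_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            log_base_note=log_base_note,
        )

    @classmethod
    def read_tsv(cls, path: str | Path, sep: str = "\t") -> "ExpressionMatrix":
        """Read a dense genes-in-rows matrix with a header of cell ids."""
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls.from_dataframe(df)

    @classmethod
    def read_mtx(
        cls,
        mtx_path: str | Path,
        features_path: str | Path,
        barcodes_path: str | Path,
    ) -> "ExpressionMatrix":
        """Read MatrixMarket MTX (genes x cells) with sidecar id files."""
        from scipy.io import mmread

        mat = mmread(str(mtx_path))
        genes = [line.split("\t")[0] for line in _read_lines(features_path)]
        cells = list(_read_lines(barcodes_path))
        if sparse.issparse(mat):
            mat = mat.toarray()
        return cls(gene_ids=genes, cell_ids=cells, values=np.asarray(mat, dtype=float))

    def write_tsv(self, path: str | Path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep)


def _read_lines(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


@dataclass
class RankSignature:
    """Standard-normal quantiles of a cell's scaled expression ranks."""

    gene_ids: list[str]
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if len(self.gene_ids) != self.z.shape[0]:
            raise ValueError("gene_ids and z length mismatch")


@dataclass
class BPAMatrix:
    """Gene sets x cells normalized enrichment scores with cell annotations."""

    set_names: list[str]
    cell_ids: list[str]
    nes: np.ndarray
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.set_names = list(self.set_names)
        self.cell_ids = list(self.cell_ids)
        self.nes = np.asarray(self.nes, dtype=float)
        if self.nes.shape != (len(self.set_names), len(self.cell_ids)):
            raise ValueError(
                f"nes shape {self.nes.shape} does not match "
                f"{len(self.set_names)} sets x {len(self.cell_ids)} cells"
            )
        if len(set(self.set_names)) != len(self.set_names):
            raise ValueError("duplicate set names")
        if not np.all(np.isfinite(self.nes)):
            raise ValueError("NES values must be finite")
        if self.annotations is None or len(self.annotations) == 0:
            self.annotations = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            self.annotations = self.annotations.copy()
            missing = set(self.cell_ids) - set(self.annotations.index.astype(str))
            if missing:
                raise ValueError(
                    f"annotations missing {len(missing)} cell ids, e.g. "
                    f"{sorted(missing)[:3]}"
                )
            self.annotations = self.annotations.loc[self.cell_ids]

    @property
    def shape(self) -> tuple[int, int]:
        return self.nes.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.nes, index=self.set_names, columns=self.cell_ids)

    def write_tsv(self, path: str | Path) -> None:
        """Write NES as TSV; provenance + annotations go to a sidecar JSON."""
        path = Path(path)
        self.to_dataframe().to_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        payload = {
            "provenance": self.provenance,
            "annotations": self.annotations.reset_index().to_dict(orient="list"),
        }
        sidecar.write_text(json.dumps(payload, indent=2, default=str) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BPAMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        annotations = pd.DataFrame()
        provenance: dict = {}
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        if sidecar.exists():
            payload = json.loads(sidecar.read_text())
            provenance = payload.get("provenance", {})
            ann = payload.get("annotations")
            if ann:
                annotations = pd.DataFrame(ann).set_index("cell_id")
                annotations.index = annotations.index.astype(str)
        return cls(
            set_names=[str(s) for s in df.index],
            cell_ids=[str(c) for c in df.columns],
            nes=df.to_numpy(dtype=float),
            annotations=annotations,
            provenance=provenance,
        )


def _rank_quantiles(values: np.ndarray) -> np.ndarray:
    """Column-wise: average-tie ranks, scaled r/(N+1), normal quantiles."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    ranks = rankdata(values, method="average", axis=0)
    return norm.ppf(ranks / (n + 1.0))


def signature_from_expression(
    column: np.ndarray | pd.Series,
    gene_ids: list[str] | None = None,
) -> RankSignature:
    """Rank-quantile signature of one cell's log-expression column.

    Ties (including the drop-out zero block) receive the mean of their rank
    positions, which keeps the quantiles symmetric: in a tie-free column they
    sum exactly to zero.
    """
    if isinstance(column, pd.Series):
        if gene_ids is None:
            gene_ids = [str(g) for g in column.index]
        column = column.to_numpy(dtype=float)
    column = np.asarray(column, dtype=float)
    if column.ndim != 1:
        raise ValueError("expected a single per-gene column")
    if column.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if not np.all(np.isfinite(column)):
        raise ValueError("signature values must be finite")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(column.shape[0])]
    if np.all(column == column[0]):
        warnings.warn("all expression values identical; flat (all-zero) signature")
        return RankSignature(gene_ids=list(gene_ids), z=np.zeros_like(column))
    z = _rank_quantiles(column[:, None])[:, 0]
    return RankSignature(gene_ids=list(gene_ids), z=z)


def area_nes(sig: RankSignature, gs: GeneSet) -> float:
    """NES of one gene set against one signature: sum(z_members) / sqrt(n).

    The set must already be restricted to the signature's genes (use
    ``restrict_to_universe``); a member absent from the signature is a
    contract violation.
    """
    index = {g: i for i, g in enumerate(sig.gene_ids)}
    try:
        idx = [index[g] for g in gs.genes]
    except KeyError as exc:
        raise ValueError(
            f"gene set {gs.name!r} contains gene {exc.args[0]!r} absent from the "
            "signature; restrict the collection to the expression universe first"
        ) from None
    return float(sig.z[idx].sum() / np.sqrt(len(idx)))


def bpa_transform(
    expr: ExpressionMatrix,
    coll: GeneSetCollection,
    min_overlap: int = 5,
    annotations: pd.DataFrame | None = None,
    relative: bool = False,
) -> BPAMatrix:
    """Transform an expression matrix into a sets x cells NES matrix.

    Cells are processed independently: the result for cell c depends only on
    column c. ``relative=True`` subtracts the dataset-average signature
    before ranking; this makes scores depend on dataset composition and is
    off by default (the absolute signature is what keeps datasets mergeable).
    """
    restricted = restrict_to_universe(coll, expr.gene_ids, min_overlap=min_overlap)
    if len(restricted) == 0:
        overlaps = {
            name: sum(1 for g in coll.get(name).genes if g in set(expr.gene_ids))
            for name in coll.names
        }
        raise ValueError(
            f"no gene set has >= {min_overlap} genes in the expression matrix; "
            f"per-set overlap counts: {overlaps}"
        )
    values = expr.values
    if relative:
        values = values - values.mean(axis=1, keepdims=True)
    z = _rank_quantiles(values)

    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    rows, cols, sqrt_n = [], [], []
    for si, s in enumerate(restricted):
        for g in s.genes:
            rows.append(si)
            cols.append(gene_index[g])
        sqrt_n.append(np.sqrt(len(s)))
    membership = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(restricted), len(expr.gene_ids))
    )
    nes = (membership @ z) / np.array(sqrt_n)[:, None]

    prov = {
        "collection": restricted.provenance,
        "rank_scaling": RANK_SCALING_NOTE,
        "relative_signature": relative,
        "log_base_note": expr.log_base_note,
        "n_cells": len(expr.cell_ids),
        "n_genes": len(expr.gene_ids),
    }
    return BPAMatrix(
        set_names=restricted.names,
        cell_ids=expr.cell_ids,
        nes=nes,
        annotations=annotations if annotations is not None else pd.DataFrame(),
        provenance=prov,
    )


def select_by_sd(bpa: BPAMatrix, top_k: int) -> BPAMatrix:
    """Keep the top_k sets by sample SD of NES across cells.

    Rows are returned in decreasing-SD order; ties broken by set name so the
    selection is deterministic.
    """
    n_sets = len(bpa.set_names)
    if not (1 <= top_k <= n_sets):
        raise ValueError(f"top_k must be in [1, {n_sets}], got {top_k}")
    sd = bpa.nes.std(axis=1, ddof=1) if bpa.nes.shape[1] > 1 else np.zeros(n_sets)
    order = sorted(range(n_sets), key=lambda i: (-sd[i], bpa.set_names[i]))
    keep = order[:top_k]
    prov = dict(bpa.provenance)
    prov["sd_selection"] = {"top_k": top_k, "n_before": n_sets}
    return BPAMatrix(
        set_names=[bpa.set_names[i] for i in keep],
        cell_ids=bpa.cell_ids,
        nes=bpa.nes[keep],
        annotations=bpa.annotations,
        provenance=prov,
    )
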