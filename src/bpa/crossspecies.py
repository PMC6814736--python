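"""Cross-dataset/species integration: NES merging, ortholog collapse, DTW.

Because NES values are z-scores, matrices from different datasets or
species are merged by intersecting gene-set names and concatenating
columns — values pass through bit-identically, with no rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from bpa.bpa_core import BPAMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class OrthologTable:
    """Two-column gene symbol mapping between species A and B."""

    pairs: list[tuple[str, str]]
    one_to_many_a: list[str] = field(default_factory=list)
    one_to_many_b: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = [(str(a), str(b)) for a, b in self.pairs]
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate ortholog pairs")
        count_a: dict[str, int] = {}
        count_b: dict[str, int] = {}
        for a, b in self.pairs:
            count_a[a] = count_a.get(a, 0) + 1
            count_b[b] = count_b.get(b, 0) + 1
        self.one_to_many_a = sorted(a for a, c in count_a.items() if c > 1)
        self.one_to_many_b = sorted(b for b, c in count_b.items() if c > 1)
        if self.one_to_many_a or self.one_to_many_b:
            logger.info(
                "ortholog table has one-to-many mappings: %d (A), %d (B)",
                len(self.one_to_many_a),
                len(self.one_to_many_b),
            )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OrthologTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] != 2:
            raise ValueError(f"ortholog table must have 2 columns, got {df.shape[1]}")
        return cls(pairs=[tuple(r) for r in df.itertuples(index=False)])

    def write_tsv(self, path: str | Path, names: tuple[str, str] = ("gene_a", "gene_b")) -> None:
        pd.DataFrame(self.pairs, columns=list(names)).to_csv(path, sep="\t", index=False)


@dataclass
class DTWResult:
    """Optimal dynamic-time-warping cost and path between two sequences."""

    cost: float
    path: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("DTW cost must be non-negative")
        if not self.path:
            raise ValueError("DTW path must be non-empty")


def merge_bpa(matrices: list[BPAMatrix]) -> BPAMatrix:
    """Merge NES matrices on the intersection of their set names.

    Row order follows the first matrix; columns are concatenated in input
    order; NES values are copied unchanged. Raises if the intersection is
    empty, reporting pairwise overlap sizes.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices to merge")
    shared = set(matrices[0].set_names)
    for m in matrices[1:]:
        shared &= set(m.set_names)
    if not shared:
        overlaps = {
            (i, j): len(set(matrices[i].set_names) & set(matrices[j].set_names))
            for i in range(len(matrices))
            for j in range(i + 1, len(matrices))
        }
        raise ValueError(
            f"no gene set names shared by all matrices; pairwise overlaps: {overlaps}"
        )
    row_order = [n for n in matrices[0].set_names if n in shared]
    blocks = []
    cell_ids: list[str] = []
    annotations = []
    for k, m in enumerate(matrices):
        idx = [m.set_names.index(n) for n in row_order]
        blocks.append(m.nes[idx])
        cell_ids.extend(m.cell_ids)
        ann = m.annotations.copy()
        ann.index = ann.index.astype(str)
        if "dataset" not in ann.columns:
            ann["dataset"] = f"dataset{k}"
        annotations.append(ann)
        logger.info(
            "merge_bpa: matrix %d retained %d/%d sets", k, len(row_order), len(m.set_names)
        )
    merged_ann = pd.concat(annotations, axis=0)
    merged_ann.index.name = "cell_id"
    return BPAMatrix(
        set_names=row_order,
        cell_ids=cell_ids,
        nes=np.concatenate(blocks, axis=1),
        annotations=merged_ann,
        provenance={
            "merged_from": [m.provenance for m in matrices],
            "n_shared_sets": len(row_order),
        },
    )


def collapse_orthologs(
    expr: ExpressionMatrix,
    table: OrthologTable,
    direction: str = "a_to_b",
) -> ExpressionMatrix:
    """Rename genes into the other species' namespace via the mapping table.

    Unmapped genes are dropped; several source genes mapping to the same
    target are averaged. ``direction`` is ``"a_to_b"`` (rename the table's
    first-column symbols into the second column) or ``"b_to_a"``.
    """
    if not table.pairs:
        raise ValueError("ortholog table is empty")
    if direction == "a_to_b":
        mapping_pairs = table.pairs
    elif direction == "b_to_a":
        mapping_pairs = [(b, a) for a, b in table.pairs]
    else:
        raise ValueError(f"direction must be 'a_to_b' or 'b_to_a', got {direction!r}")
    mapping: dict[str, list[str]] = {}
    for src, dst in mapping_pairs:
        mapping.setdefault(src, []).append(dst)

    target_rows: dict[str, list[int]] = {}
    dropped = 0
    for i, g in enumerate(expr.gene_ids):
        if g not in mapping:
            dropped += 1
            continue
        for dst in mapping[g]:
            target_rows.setdefault(dst, []).append(i)
    if not target_rows:
        raise ValueError("no gene of the expression matrix is present in the table")

    targets = list(target_rows)
    out = np.empty((len(targets), len(expr.cell_ids)))
    collided = 0
    for r, t in enumerate(targets):
        rows = target_rows[t]
        if len(rows) > 1:
            collided += 1
        out[r] = expr.values[rows].mean(axis=0)
    logger.info(
        "collapse_orthologs: %d genes dropped (unmapped), %d targets averaged "
        "from collisions",
        dropped,
        collided,
    )
    note = expr.log_base_note
    suffix = f"; ortholog-collapsed ({direction}, dropped={dropped}, collided={collided})"
    return ExpressionMatrix(
        gene_ids=targets,
        cell_ids=expr.cell_ids,
        values=out,
        log_base_note=note + suffix,
    )


def _pairwise_dist(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    """lenA x lenB matrix of distances between stage profiles."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.ndim == 2 and a.shape[1] != b.shape[1]:
        raise ValueError(
            f"stage profiles have mismatched feature spaces: "
            f"{a.shape[1]} vs {b.shape[1]}"
        )
    diff = a[:, None, :] - b[None, :, :]
    if metric == "euclidean":
        return np.sqrt((diff**2).sum(axis=2))
    if metric == "cityblock":
        return np.abs(diff).sum(axis=2)
    raise ValueError(f"unknown metric {metric!r}")


def dtw_align(seqA, seqB, metric: str = "euclidean") -> DTWResult:
    """Global dynamic time warping with steps {(1,0), (0,1), (1,1)}.

    No window constraint. Ties during backtracking prefer the diagonal
    step, then (1,0). Scalar sequences are treated as 1-D profiles.
    """
    a = np.asarray(seqA, dtype=float)
    b = np.asarray(seqB, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("sequences must be non-empty")
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    d = _pairwise_dist(a, b, metric)
    la, lb = d.shape
    acc = np.full((la, lb), np.inf)
    acc[0, 0] = d[0, 0]
    for i in range(la):
        for j in range(lb):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0 and j > 0:
                best = acc[i - 1, j - 1]
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            acc[i, j] = d[i, j] + best
    # backtrack: prefer diagonal, then (1,0), then (0,1)
    path = [(la - 1, lb - 1)]
    i, j = la - 1, lb - 1
    while (i, j) != (0, 0):
        candidates = []
        if i > 0 and j > 0:
            candidates.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            candidates.append((acc[i - 1, j], (i - 1, j)))
        if j > 0:
            candidates.append((acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(candidates, key=lambda c: c[0])
        path.append((i, j))
    path.reverse()
    return DTWResult(cost=float(acc[la - 1, lb - 1]), path=path)


def stage_profiles(
    bpa: BPAMatrix,
    stage_labels,
    stage_order: list | None = None,
    agg: str = "mean",
) -> np.ndarray:
    """Aggregate cells into ordered per-stage profiles (rows = stages).

    Default aggregation is the per-stage mean NES vector; ``agg="median"``
    is available. Stages appear in ``stage_order`` if given, else in first
    occurrence order of the labels.
    """
    labels = [str(s) for s in stage_labels]
    if len(labels) != len(bpa.cell_ids):
        raise ValueError("stage labels must cover all cells")
    if stage_order is None:
        stage_order = list(dict.fromkeys(labels))
    fn = {"mean": np.mean, "median": np.median}[agg]
    rows = []
    for stage in stage_order:
        cols = [i for i, s in enumerate(labels) if s == str(stage)]
        if not cols:
            raise ValueError(f"stage {stage!r} has no cells")
        rows.append(fn(bpa.nes[:, cols], axis=1))
    return np.vstack(rows)
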