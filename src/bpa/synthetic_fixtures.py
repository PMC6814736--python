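"""Synthetic test-data generators.

Cell-type signal is injected through gene sets (member genes of a type's
"active" sets get a mean shift), so ground truth lives in activity space
by construction. Values are Gaussian in log space and floored at zero;
rank-based downstream code does not need count-level realism. All
generators are deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from bpa.bpa_core import ExpressionMatrix
from bpa.geneset_io import GeneSet, GeneSetCollection
from bpa.crossspecies import OrthologTable


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic generators."""

    n_cell_types: int = 3
    cells_per_type: int = 100
    n_genes: int = 2000
    n_sets: int = 30
    genes_per_set: int = 60
    activity_effect: float = 1.0  # mean log-expression shift of active-set members
    batch_shift: float = 0.3  # SD of the additive per-gene batch offset
    noise_sd: float = 0.5
    dropout_rate_target: float = 0.8
    seed: int = 7
    n_batches: int = 2
    baseline_mean: float = 2.5
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "n_cell_types",
            "cells_per_type",
            "n_genes",
            "n_sets",
            "genes_per_set",
            "n_batches",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.genes_per_set > self.n_genes:
            raise ValueError("genes_per_set exceeds n_genes")
        for name in ("activity_effect", "batch_shift", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (0.0 <= self.dropout_rate_target <= 1.0):
            raise ValueError("dropout_rate_target must be a fraction")


def _check_disjoint_feasible(spec: FixtureSpec) -> None:
    if spec.n_sets * spec.genes_per_set > spec.n_genes:
        raise ValueError(
            f"infeasible spec: {spec.n_sets} disjoint sets of "
            f"{spec.genes_per_set} genes exceed {spec.n_genes} genes"
        )


def _set_type_assignment(spec: FixtureSpec) -> list[int]:
    """Which cell type each gene set marks (block assignment)."""
    per_type = spec.n_sets // spec.n_cell_types
    assignment = []
    for s in range(spec.n_sets):
        assignment.append(min(s // max(per_type, 1), spec.n_cell_types - 1))
    return assignment


def _latent_activity(spec: FixtureSpec) -> np.ndarray:
    """Sets x cell-types activity indicator (1 where a set is active)."""
    act = np.zeros((spec.n_sets, spec.n_cell_types))
    for s, t in enumerate(_set_type_assignment(spec)):
        act[s, t] = 1.0
    return act


def _gene_blocks(spec: FixtureSpec) -> list[np.ndarray]:
    return [
        np.arange(s * spec.genes_per_set, (s + 1) * spec.genes_per_set)
        for s in range(spec.n_sets)
    ]


def make_celltype_fixture(
    spec: FixtureSpec,
) -> tuple[ExpressionMatrix, GeneSetCollection, pd.DataFrame]:
    """Multi-cell-type, multi-batch expression matrix with matched gene sets.

    Each cell type is marked by a disjoint block of gene sets whose member
    genes are shifted up by ``activity_effect`` in that type. Batches add a
    per-gene Gaussian offset of SD ``batch_shift`` shared by all cells of
    the batch. Returns the matrix, the marker collection, and annotations
    (cell_id, cell_type, dataset) carrying the ground truth.
    """
    _check_disjoint_feasible(spec)
    rng = np.random.default_rng(spec.seed)
    n_cells = spec.n_cell_types * spec.cells_per_type
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)

    cell_types = np.repeat(np.arange(spec.n_cell_types), spec.cells_per_type)
    batches = np.tile(
        np.arange(spec.n_batches),
        int(np.ceil(n_cells / spec.n_batches)),
    )[:n_cells]

    mean = np.tile(baseline[:, None], (1, n_cells))
    activity = _latent_activity(spec)
    blocks = _gene_blocks(spec)
    for s, block in enumerate(blocks):
        for t in range(spec.n_cell_types):
            if activity[s, t]:
                mean[np.ix_(block, cell_types == t)] += spec.activity_effect

    batch_offsets = rng.normal(0.0, spec.batch_shift, size=(spec.n_genes, spec.n_batches))
    mean += batch_offsets[:, batches]

    values = np.maximum(mean + rng.normal(0.0, spec.noise_sd, size=mean.shape), 0.0)

    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    expr = ExpressionMatrix(
        gene_ids=genes,
        cell_ids=cell_ids,
        values=values,
        log_base_note=f"synthetic log-scale (seed={spec.seed})",
    )
    sets = [
        GeneSet(
            name=f"SET{s:03d}",
            description=f"marker set for type{_set_type_assignment(spec)[s]}",
            genes=tuple(genes[i] for i in blocks[s]),
        )
        for s in range(spec.n_sets)
    ]
    coll = GeneSetCollection(sets=sets, provenance={"source": "synthetic", "filters": []})
    annotations = pd.DataFrame(
        {
            "cell_type": [f"type{t}" for t in cell_types],
            "dataset": [f"batch{b}" for b in batches],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return expr, coll, annotations


def make_two_species_fixture(
    spec: FixtureSpec,
    shared_activity_fraction: float = 0.8,
) -> tuple[
    tuple[ExpressionMatrix, ExpressionMatrix],
    tuple[GeneSetCollection, GeneSetCollection],
    pd.DataFrame,
]:
    """Two datasets over disjoint gene namespaces sharing set NAMES.

    Gene symbols are prefixed ``gA_``/``gB_`` so the raw matrices share no
    genes. The collections share set names; in each species only a
    ``shared_activity_fraction`` of a set's members respond to the latent
    cell-type activity (the rest are inert), emulating partial conceptual
    overlap of same-named sets. Each species gets an independent per-gene
    batch offset of SD ``batch_shift``.
    """
    if not (0.0 < shared_activity_fraction <= 1.0):
        raise ValueError("shared_activity_fraction must be in (0, 1]")
    _check_disjoint_feasible(spec)
    rng = np.random.default_rng(spec.seed)
    blocks = _gene_blocks(spec)
    activity = _latent_activity(spec)
    n_cells = spec.n_cell_types * spec.cells_per_type
    cell_types = np.repeat(np.arange(spec.n_cell_types), spec.cells_per_type)

    exprs, colls, anns = [], [], []
    for prefix, species in (("gA_", "speciesA"), ("gB_", "speciesB")):
        genes = [f"{prefix}{i:05d}" for i in range(spec.n_genes)]
        baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
        mean = np.tile(baseline[:, None], (1, n_cells))
        for s, block in enumerate(blocks):
            n_responding = max(int(round(shared_activity_fraction * block.size)), 1)
            responding = rng.choice(block, size=n_responding, replace=False)
            for t in range(spec.n_cell_types):
                if activity[s, t]:
                    mean[np.ix_(responding, cell_types == t)] += spec.activity_effect
        mean += rng.normal(0.0, spec.batch_shift, size=(spec.n_genes, 1))
        values = np.maximum(mean + rng.normal(0.0, spec.noise_sd, size=mean.shape), 0.0)
        cell_ids = [f"{species}_cell{i:05d}" for i in range(n_cells)]
        exprs.append(
            ExpressionMatrix(
                gene_ids=genes,
                cell_ids=cell_ids,
                values=values,
                log_base_note=f"synthetic {species} (seed={spec.seed})",
            )
        )
        sets = [
            GeneSet(
                name=f"SET{s:03d}",
                description=f"{species} members",
                genes=tuple(genes[i] for i in blocks[s]),
                species_tag=species,
            )
            for s in range(spec.n_sets)
        ]
        colls.append(
            GeneSetCollection(
                sets=sets,
                species_tag=species,
                provenance={"source": f"synthetic:{species}", "filters": []},
            )
        )
        anns.append(
            pd.DataFrame(
                {
                    "cell_type": [f"type{t}" for t in cell_types],
                    "dataset": species,
                    "species": species,
                },
                index=pd.Index(cell_ids, name="cell_id"),
            )
        )
    annotations = pd.concat(anns)
    return (exprs[0], exprs[1]), (colls[0], colls[1]), annotations


def make_ortholog_table(spec: FixtureSpec) -> OrthologTable:
    """One-to-one gA_i <-> gB_i mapping matching the two-species fixture."""
    pairs = [(f"gA_{i:05d}", f"gB_{i:05d}") for i in range(spec.n_genes)]
    return OrthologTable(pairs=pairs)


def make_stage_fixture(
    n_stages_a: int,
    n_stages_b: int,
    warp: list[int],
    spec: FixtureSpec,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Two staged trajectories related by a known monotone warp.

    ``warp[j]`` gives the stage of grid A that stage j of grid B samples;
    it must be monotone non-decreasing, start at 0 and end at
    ``n_stages_a - 1`` (so a ground-truth global alignment path exists).
    Profiles are points on a smooth latent curve in ``n_sets`` dimensions
    plus Gaussian noise of SD ``noise_sd``. Returns (profiles_a,
    profiles_b, true_path).
    """
    warp = [int(w) for w in warp]
    if len(warp) != n_stages_b:
        raise ValueError("warp must give an A-stage for every B stage")
    if any(b < a for a, b in zip(warp, warp[1:])):
        raise ValueError("warp must be monotone non-decreasing")
    if warp[0] != 0 or warp[-1] != n_stages_a - 1:
        raise ValueError("warp must span the full A grid (start 0, end last stage)")
    if set(warp) != set(range(n_stages_a)):
        raise ValueError("warp must visit every A stage for a valid global path")
    rng = np.random.default_rng(spec.seed)
    d = spec.n_sets
    # smooth latent curve: random direction + sinusoidal wiggle per dim
    direction = rng.normal(size=d)
    direction /= np.linalg.norm(direction)
    phase = rng.uniform(0, 2 * np.pi, size=d)
    freq = rng.uniform(0.5, 1.5, size=d)

    def f(t: float) -> np.ndarray:
        return 3.0 * t * direction + np.sin(2 * np.pi * freq * t + phase)

    t_a = np.linspace(0.0, 1.0, n_stages_a)
    profiles_a = np.vstack([f(t) for t in t_a])
    profiles_b = np.vstack([f(t_a[w]) for w in warp])
    profiles_a += rng.normal(0.0, spec.noise_sd, size=profiles_a.shape)
    profiles_b += rng.normal(0.0, spec.noise_sd, size=profiles_b.shape)
    true_path = [(warp[j], j) for j in range(n_stages_b)]
    return profiles_a, profiles_b, true_path


def with_seed(spec: FixtureSpec, seed: int) -> FixtureSpec:
    """Convenience: a copy of the spec with only the seed changed."""
    return replace(spec, seed=seed)
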