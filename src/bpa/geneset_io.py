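"""Gene set collections: GMT I/O, size/name filtering, universe restriction.

Gene symbols are matched case-sensitively and exactly; cross-species
comparison happens at the gene-set *name* level, never at the gene level,
so no symbol normalization is attempted here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)


class GMTParseError(ValueError):
    """Raised when a GMT file line cannot be parsed."""


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered, duplicate-free set of gene symbols."""

    name: str
    description: str
    genes: tuple[str, ...]
    species_tag: str = ""
    collection_tag: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """A list of gene sets sharing a species tag, with filter provenance."""

    sets: list[GeneSet]
    species_tag: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dupes}")
        for s in self.sets:
            if s.species_tag and self.species_tag and s.species_tag != self.species_tag:
                raise ValueError(
                    f"set {s.name!r} species tag {s.species_tag!r} "
                    f"differs from collection tag {self.species_tag!r}"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def get(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def sizes(self) -> dict[str, int]:
        return {s.name: len(s) for s in self.sets}

    def _derive(self, sets: list[GeneSet], step: dict) -> "GeneSetCollection":
        prov = dict(self.provenance)
        prov.setdefault("filters", [])
        prov["filters"] = list(prov["filters"]) + [step]
        return GeneSetCollection(sets=sets, species_tag=self.species_tag, provenance=prov)


def _dedup_preserving_order(symbols: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for s in symbols:
        seen.setdefault(s, None)
    return tuple(seen)


def read_gmt(
    path: str | Path,
    species_tag: str = "",
    collection_tag: str = "",
) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, gene symbols...).

    Duplicate gene symbols within a line are deduplicated preserving first
    occurrence. Duplicate set names raise :class:`ValueError`; a line with
    fewer than three fields raises :class:`GMTParseError` naming the line.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen_names: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = _dedup_preserving_order(g for g in fields[2:] if g)
            if name in seen_names:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen_names.add(name)
            sets.append(
                GeneSet(
                    name=name,
                    description=description,
                    genes=genes,
                    species_tag=species_tag,
                    collection_tag=collection_tag,
                )
            )
    return GeneSetCollection(
        sets=sets,
        species_tag=species_tag,
        provenance={"source": str(path), "filters": []},
    )


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; provenance goes to a sidecar JSON."""
    path = Path(path)
    with path.open("w") as fh:
        for s in coll:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps(coll.provenance, indent=2) + "\n")


def filter_by_size(
    coll: GeneSetCollection, min_size: int, max_size: int
) -> GeneSetCollection:
    """Keep sets with min_size <= |genes| <= max_size (both ends inclusive)."""
    if not (1 <= min_size <= max_size):
        raise ValueError(f"invalid size window [{min_size}, {max_size}]")
    kept = [s for s in coll if min_size <= len(s) <= max_size]
    if not kept:
        logger.warning(
            "size window [%d, %d] retained no gene sets (of %d)",
            min_size,
            max_size,
            len(coll),
        )
    return coll._derive(
        kept,
        {
            "op": "filter_by_size",
            "min_size": min_size,
            "max_size": max_size,
            "inclusive": True,
            "n_before": len(coll),
            "n_after": len(kept),
        },
    )


def keep_upregulated(coll: GeneSetCollection, suffix: str = "_UP") -> GeneSetCollection:
    """Keep sets whose name ends with ``suffix`` (case-sensitive).

    The default matches the MSigDB convention for paired up/down immunologic
    signatures; an empty suffix is the identity.
    """
    kept = [s for s in coll if s.name.endswith(suffix)]
    if not kept:
        logger.warning("suffix %r matched no gene set names", suffix)
    return coll._derive(
        kept,
        {
            "op": "keep_upregulated",
            "suffix": suffix,
            "n_before": len(coll),
            "n_after": len(kept),
        },
    )


def restrict_to_universe(
    coll: GeneSetCollection,
    universe: Iterable[str],
    min_overlap: int = 5,
) -> GeneSetCollection:
    """Intersect each set with the measured-gene universe.

    Sets whose post-intersection size falls below ``min_overlap`` are dropped
    (below ~5 members the enrichment score is dominated by a handful of
    quantile draws and is not a meaningful ensemble average).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    kept: list[GeneSet] = []
    original_sizes: dict[str, int] = {}
    retained_sizes: dict[str, int] = {}
    dropped: list[str] = []
    for s in coll:
        genes = tuple(g for g in s.genes if g in universe)
        original_sizes[s.name] = len(s)
        if len(genes) < min_overlap:
            dropped.append(s.name)
            continue
        retained_sizes[s.name] = len(genes)
        kept.append(replace(s, genes=genes))
    if dropped:
        logger.info(
            "restrict_to_universe dropped %d sets below overlap %d",
            len(dropped),
            min_overlap,
        )
    return coll._derive(
        kept,
        {
            "op": "restrict_to_universe",
            "min_overlap": min_overlap,
            "universe_size": len(universe),
            "original_sizes": original_sizes,
            "retained_sizes": retained_sizes,
            "dropped": dropped,
        },
    )
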