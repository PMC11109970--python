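"""Gene set collections: GMT I/O, validation, filtering and randomization.

A gene set collection defines the sparse connectivity of the encoder: each
gene set becomes one bottleneck neuron connected only to its member genes.
The filters implemented here mirror the curation applied before training a
production model: drop sets outside a size window, drop sets that share most
of their genes with another set (near-duplicate sets make the learned scores
depend on the weight initialization), and build size-matched random controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "filter_by_size",
    "filter_by_overlap",
    "random_collection",
]


class GmtParseError(ValueError):
    """Raised when a GMT file is malformed."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene set: identifier, free-text description, ordered member genes."""

    id: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("gene set id must be non-empty")
        if len(self.genes) < 1:
            raise ValueError(f"gene set {self.id!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.id!r} contains duplicate genes")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered collection of gene sets with unique ids."""

    sets: tuple[GeneSet, ...]
    gene_universe: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sets]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene set ids: {dupes}")
        universe = sorted({g for s in self.sets for g in s.genes})
        object.__setattr__(self, "gene_universe", tuple(universe))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.id == set_id:
                return s
        raise KeyError(set_id)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sets]

    @property
    def sizes(self) -> list[int]:
        return [s.size for s in self.sets]

    def subset(self, keep_ids: Iterable[str]) -> "GeneSetCollection":
        """Collection restricted to ``keep_ids``, preserving the current order."""
        keep = set(keep_ids)
        unknown = keep - set(self.ids)
        if unknown:
            raise KeyError(f"unknown gene set ids: {sorted(unknown)}")
        return GeneSetCollection(tuple(s for s in self.sets if s.id in keep))


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (tab-separated: id, description, member genes...).

    Duplicate genes within a line are dropped with a warning; duplicate set
    ids or lines with fewer than three fields are errors.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            set_id, description, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                warnings.warn(
                    f"{path}: line {lineno}: set {set_id!r} has duplicate genes; deduplicated",
                    stacklevel=2,
                )
            if set_id in seen:
                raise GmtParseError(f"{path}: line {lineno}: duplicate set id {set_id!r}")
            seen.add(set_id)
            sets.append(GeneSet(set_id, description, tuple(deduped)))
    return GeneSetCollection(tuple(sets))


def write_gmt(col: GeneSetCollection, path) -> None:
    """Write a collection in GMT format; inverse of :func:`read_gmt`."""
    with open(path, "w") as fh:
        for s in col.sets:
            fh.write("\t".join([s.id, s.description, *s.genes]) + "\n")


def _effective_sizes(col: GeneSetCollection, universe: Sequence[str] | None) -> list[int]:
    if universe is None:
        return col.sizes
    uni = set(universe)
    return [sum(g in uni for g in s.genes) for s in col.sets]


def filter_by_size(
    col: GeneSetCollection,
    min_genes: int = 10,
    max_genes: int = 30,
    *,
    strict_min: bool = True,
    gene_universe: Sequence[str] | None = None,
) -> GeneSetCollection:
    """Keep gene sets whose size lies in the configured window.

    With ``strict_min=True`` (default) a set is kept when
    ``min_genes < size <= max_genes`` — i.e. "more than ``min_genes`` genes"
    and "at most ``max_genes``". Sizes are evaluated after intersecting with
    ``gene_universe`` when one is supplied (genes missing from the expression
    data do not count).
    """
    if not 1 <= min_genes <= max_genes:
        raise ValueError(f"require 1 <= min_genes <= max_genes, got {min_genes}, {max_genes}")
    sizes = _effective_sizes(col, gene_universe)
    lower_ok = (lambda n: n > min_genes) if strict_min else (lambda n: n >= min_genes)
    kept = tuple(s for s, n in zip(col.sets, sizes) if lower_ok(n) and n <= max_genes)
    if not kept:
        warnings.warn("size filter removed every gene set", stacklevel=2)
    return GeneSetCollection(kept)


def _shared_fraction(a: frozenset, b: frozenset, denominator: str) -> float:
    inter = len(a & b)
    if denominator == "min":
        return inter / min(len(a), len(b))
    if denominator == "jaccard":
        return inter / len(a | b)
    raise ValueError(f"unknown overlap denominator {denominator!r}")


def filter_by_overlap(
    col: GeneSetCollection,
    max_shared_fraction: float = 0.5,
    *,
    denominator: str = "min",
) -> GeneSetCollection:
    """Remove gene sets until no pair shares more than ``max_shared_fraction`` of genes.

    The shared fraction of a pair is |A∩B| / min(|A|,|B|) by default (flags
    nested sets), or Jaccard with ``denominator="jaccard"``. Removal is greedy
    and deterministic: repeatedly drop the set with the most violating
    partners, breaking ties by larger size and then by lexicographically
    later id.
    """
    if not 0 < max_shared_fraction <= 1:
        raise ValueError("max_shared_fraction must be in (0, 1]")
    members = {s.id: frozenset(s.genes) for s in col.sets}
    ids = list(members)
    viol: dict[str, set[str]] = {i: set() for i in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if _shared_fraction(members[a], members[b], denominator) > max_shared_fraction:
                viol[a].add(b)
                viol[b].add(a)
    removed: set[str] = set()
    while True:
        active = [i for i in ids if i not in removed and viol[i]]
        if not active:
            break
        worst = max(active, key=lambda i: (len(viol[i]), len(members[i]), i))
        removed.add(worst)
        for other in viol[worst]:
            viol[other].discard(worst)
        viol[worst] = set()
    return GeneSetCollection(tuple(s for s in col.sets if s.id not in removed))


def random_collection(template: GeneSetCollection, seed: int) -> GeneSetCollection:
    """Size-matched random control collection.

    Preserves the multiset of set sizes of ``template`` (in order) and draws
    genes without replacement within each set from the template's gene
    universe. Reproducible under ``seed``.
    """
    if len(template) == 0:
        raise ValueError("template collection is empty")
    rng = np.random.default_rng(seed)
    universe = np.asarray(template.gene_universe, dtype=object)
    sets = []
    for s in template.sets:
        genes = rng.choice(universe, size=s.size, replace=False)
        sets.append(GeneSet(s.id, f"random control for {s.id}", tuple(genes.tolist())))
    return GeneSetCollection(tuple(sets))
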