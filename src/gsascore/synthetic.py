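"""Synthetic expression data with known gene-set latent structure.

The generator draws one latent factor per gene set (standard normal per
sample, optionally shifted per pseudo-tissue stratum) and builds each
member gene as a signed loading times its factor(s) plus Gaussian noise:

    x_g = sum_{j : g in set j} lambda_gj * f_j + eps,   eps ~ N(0, sigma^2)

with sigma^2 = 1 / snr (factor variance over noise variance). Loadings are
signed by default so fixtures exercise gene sets whose genes move in
opposite directions. Background genes are pure noise. The emitted matrix is
standardized per gene by default, so fixtures enter the pipeline exactly as
real (VST + z-scored) data would; the ground truth (factors, loadings,
memberships) is returned for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, standardize
from .genesets import GeneSet, GeneSetCollection

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "make_duplicate_sets"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the simulator.

    ``overlap_fraction > 0`` arranges sets into consecutive pairs
    (set 1 & 2, set 3 & 4, ...) sharing that fraction of their genes; shared
    genes load on both factors. ``n_overlap_pairs`` limits the overlap to
    the first so many pairs (default: every pair), leaving the remaining
    sets disjoint. ``n_strata`` adds pseudo-tissue labels that shift each
    factor's mean per stratum.

    ``resample_seed`` draws a fresh cohort (new factors and noise) from the
    *same* biology (memberships, loadings, stratum offsets, all governed by
    ``seed``) — two cohorts that differ only in their samples, for
    consistency studies.
    """

    n_samples: int = 500
    n_sets: int = 20
    genes_per_set: int | tuple[int, ...] = 25
    n_background_genes: int = 100
    overlap_fraction: float = 0.0
    n_overlap_pairs: int | None = None
    loading_low: float = 0.3
    loading_high: float = 1.0
    signed_loadings: bool = True
    snr: float = 3.0
    n_strata: int = 1
    standardize_output: bool = True
    seed: int = 0
    resample_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_sets < 1:
            raise ValueError("n_samples >= 2 and n_sets >= 1 required")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if self.n_strata < 1:
            raise ValueError("n_strata must be >= 1")

    @property
    def set_sizes(self) -> tuple[int, ...]:
        if isinstance(self.genes_per_set, int):
            return (self.genes_per_set,) * self.n_sets
        if len(self.genes_per_set) != self.n_sets:
            raise ValueError("genes_per_set list length must equal n_sets")
        return tuple(self.genes_per_set)

    @property
    def noise_sd(self) -> float:
        return float(1.0 / np.sqrt(self.snr))


@dataclass(frozen=True)
class GroundTruth:
    """Latent factors, loadings and memberships behind a generated matrix."""

    factors: pd.DataFrame  # samples x sets
    loadings: pd.DataFrame  # long format: gene, set, loading
    memberships: dict[str, tuple[str, ...]] = field(default_factory=dict)
    strata: tuple[str, ...] = ()


def generate(cfg: GeneratorConfig) -> tuple[ExpressionMatrix, GeneSetCollection, GroundTruth]:
    """Draw an expression matrix, its gene set collection, and the ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    sample_seed = cfg.seed if cfg.resample_seed is None else cfg.resample_seed
    rng_samples = np.random.default_rng(np.random.SeedSequence([int(sample_seed), 1]))
    sizes = cfg.set_sizes

    # gene membership; overlapping pairs share the leading genes of the pair
    gene_counter = 0
    memberships: dict[str, list[str]] = {}
    set_ids = [f"SET{j + 1:03d}" for j in range(cfg.n_sets)]
    for j, set_id in enumerate(set_ids):
        n_shared = 0
        genes: list[str] = []
        pair_overlaps = cfg.overlap_fraction > 0 and (
            cfg.n_overlap_pairs is None or j // 2 < cfg.n_overlap_pairs
        )
        if pair_overlaps and j % 2 == 1:
            prev = memberships[set_ids[j - 1]]
            n_shared = int(round(cfg.overlap_fraction * min(sizes[j], sizes[j - 1])))
            genes.extend(prev[:n_shared])
        for _ in range(sizes[j] - n_shared):
            gene_counter += 1
            genes.append(f"G{gene_counter:05d}")
        memberships[set_id] = genes
    background = [f"B{i + 1:05d}" for i in range(cfg.n_background_genes)]
    gene_ids = list(dict.fromkeys(g for genes in memberships.values() for g in genes)) + background

    # loadings
    load_rows = []
    loading_map: dict[tuple[str, str], float] = {}
    for set_id in set_ids:
        for g in memberships[set_id]:
            lam = rng.uniform(cfg.loading_low, cfg.loading_high)
            if cfg.signed_loadings and rng.random() < 0.5:
                lam = -lam
            loading_map[(g, set_id)] = lam
            load_rows.append({"gene": g, "set": set_id, "loading": lam})

    # strata and factors
    strata_labels = tuple(f"T{(i % cfg.n_strata) + 1}" for i in range(cfg.n_samples))
    offsets = (
        rng.normal(0.0, 1.0, size=(cfg.n_strata, cfg.n_sets)) if cfg.n_strata > 1 else
        np.zeros((1, cfg.n_sets))
    )
    stratum_idx = np.array([int(lab[1:]) - 1 for lab in strata_labels])
    factors = rng_samples.normal(0.0, 1.0, size=(cfg.n_samples, cfg.n_sets)) + offsets[stratum_idx]

    values = rng_samples.normal(0.0, cfg.noise_sd, size=(cfg.n_samples, len(gene_ids)))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for j, set_id in enumerate(set_ids):
        for g in memberships[set_id]:
            values[:, gene_pos[g]] += loading_map[(g, set_id)] * factors[:, j]

    sample_ids = tuple(f"S{i + 1:04d}" for i in range(cfg.n_samples))
    x = ExpressionMatrix(values, sample_ids, tuple(gene_ids))
    if cfg.standardize_output:
        x = standardize(x)
    col = GeneSetCollection(
        tuple(
            GeneSet(set_id, f"synthetic gene set {set_id}", tuple(memberships[set_id]))
            for set_id in set_ids
        )
    )
    truth = GroundTruth(
        factors=pd.DataFrame(factors, index=list(sample_ids), columns=set_ids),
        loadings=pd.DataFrame(load_rows),
        memberships={k: tuple(v) for k, v in memberships.items()},
        strata=strata_labels,
    )
    return x, col, truth


def make_duplicate_sets(
    col: GeneSetCollection,
    ids: list[str],
    seed: int = 0,
    *,
    shared_fraction: float = 1.0,
    suffix: str = "_dup",
) -> GeneSetCollection:
    """Append near-duplicate copies of named sets — the adversarial fixture.

    Each duplicate shares ``round(shared_fraction * size)`` genes with its
    original; the remainder is drawn (seeded, without replacement) from the
    collection's gene universe outside the original set. Duplicated and
    heavily overlapping sets carry redundant information, which is exactly
    what destroys score replicability across initializations.
    """
    if not 0.0 < shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    new_sets = list(col.sets)
    for set_id in ids:
        original = col[set_id]  # raises KeyError on unknown id
        n_shared = int(round(shared_fraction * original.size))
        n_shared = max(n_shared, 1)
        shared = list(original.genes[:n_shared])
        pool = [g for g in col.gene_universe if g not in set(original.genes)]
        n_extra = original.size - n_shared
        if n_extra > len(pool):
            raise ValueError(f"not enough genes outside {set_id!r} to build a duplicate")
        extra = rng.choice(np.asarray(pool, dtype=object), size=n_extra, replace=False).tolist()
        new_sets.append(
            GeneSet(set_id + suffix, f"near-duplicate of {set_id}", tuple(shared + extra))
        )
    return GeneSetCollection(tuple(new_sets))
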