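"""Robustness, consistency and representativity diagnostics.

Replicability quantifies how much a gene set's scores depend on the weight
initialization: for each set it is the minimum, over all pairs of training
runs differing only in seed, of the absolute Spearman correlation between
the two score vectors (absolute, because the score sign is arbitrary).
Representativity is the fraction of variance of the standardized expression
matrix explained by the full score matrix in the redundancy-analysis sense.
The pruning loop retrains with several seeds and removes gene sets whose
replicability falls below a threshold — near-duplicate sets are the typical
casualty, because the network can share a latent factor between them in an
initialization-dependent way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, standardize
from .genesets import GeneSetCollection
from .network import ArchitectureConfig
from .scoring import ScoreMatrix, compute_gsas

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicabilityReport",
    "ConsistencyReport",
    "PCAgreement",
    "replicability",
    "definition_consistency",
    "representativity",
    "pc_agreement",
    "prune_by_replicability",
]


@dataclass(frozen=True)
class ReplicabilityReport:
    """Per-set minimum |Spearman rho| across initialization pairs."""

    per_set: pd.Series  # index: set ids, values in [0, 1]
    pairwise: dict[str, np.ndarray]  # set id -> n_runs x n_runs |rho| matrix
    n_initializations: int

    def below(self, threshold: float) -> list[str]:
        return self.per_set.index[self.per_set < threshold].tolist()


def replicability(runs: Sequence[ScoreMatrix]) -> ReplicabilityReport:
    """Replicability of every gene set across >=2 training runs.

    Runs must share sample and set ids. Constant score vectors (undefined
    rank correlation) contribute 0, so pathological sets are flagged as
    non-replicable rather than NaN.
    """
    if len(runs) < 2:
        raise ValueError("replicability needs at least two runs")
    first = runs[0]
    for r in runs[1:]:
        if r.sample_ids != first.sample_ids:
            raise ValueError("runs have mismatched sample ids")
        if r.set_ids != first.set_ids:
            raise ValueError("runs have mismatched set ids")
    n_runs = len(runs)
    set_ids = first.set_ids
    # average ranks (ties averaged), then Pearson on ranks == Spearman
    ranked = [stats.rankdata(r.values, axis=0) for r in runs]
    centered = [rk - rk.mean(axis=0) for rk in ranked]
    norms = [np.linalg.norm(c, axis=0) for c in centered]
    constant_seen = False
    pairwise: dict[str, np.ndarray] = {s: np.eye(n_runs) for s in set_ids}
    for a in range(n_runs):
        for b in range(a + 1, n_runs):
            denom = norms[a] * norms[b]
            with np.errstate(invalid="ignore", divide="ignore"):
                rho = np.abs((centered[a] * centered[b]).sum(axis=0) / denom)
            bad = ~np.isfinite(rho)
            if bad.any():
                constant_seen = True
                rho[bad] = 0.0
            for j, s in enumerate(set_ids):
                pairwise[s][a, b] = pairwise[s][b, a] = rho[j]
    if constant_seen:
        logger.warning("constant score vector(s) encountered; replicability set to 0")
    per_set = pd.Series(
        {s: float(m[np.triu_indices(n_runs, k=1)].min()) for s, m in pairwise.items()},
        name="replicability",
    )
    return ReplicabilityReport(per_set, pairwise, n_runs)


_CATEGORY_THRESHOLDS = (("equivalent", 0.9), ("high", 0.7), ("low_inter", 0.0))


def _categorize(r: float) -> str:
    if not np.isfinite(r):
        return "uncomputable"
    for name, thr in _CATEGORY_THRESHOLDS:
        if r > thr:
            return name
    return "opposite"


@dataclass(frozen=True)
class ConsistencyReport:
    """Score replicability and definition consistency between two populations."""

    table: pd.DataFrame  # columns: set, definition_consistency, category, score_replicability

    def category_counts(self) -> pd.Series:
        return self.table["category"].value_counts()


def _gene_score_profile(
    x: ExpressionMatrix, scores: ScoreMatrix, genes: list[str], j: int
) -> np.ndarray:
    idx = [x.gene_ids.index(g) for g in genes]
    g = x.values[:, idx]
    s = scores.values[:, [j]]
    gc = g - g.mean(axis=0)
    sc = s - s.mean(axis=0)
    denom = np.linalg.norm(gc, axis=0) * np.linalg.norm(sc)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (gc * sc).sum(axis=0) / denom


def definition_consistency(
    x_a: ExpressionMatrix,
    scores_a: ScoreMatrix,
    x_b: ExpressionMatrix,
    scores_b: ScoreMatrix,
    col: GeneSetCollection,
) -> ConsistencyReport:
    """How similarly a model's scores are defined in two datasets.

    For each gene set, the definition in a dataset is the profile of Pearson
    correlations between member-gene expression and the set's score; the
    definition consistency is the Pearson correlation between the two
    profiles over the member genes present in both datasets. Sets with
    fewer than 3 shared member genes are flagged uncomputable. When the two
    score matrices share sample ids, the per-set Pearson correlation of the
    scores themselves (score replicability) is reported as well.
    """
    if scores_a.set_ids != scores_b.set_ids:
        raise ValueError("score matrices come from different set lists")
    if x_a.n_samples < 3 or x_b.n_samples < 3:
        raise ValueError("each dataset needs at least 3 samples")
    shared_samples = [s for s in scores_a.sample_ids if s in set(scores_b.sample_ids)]
    pos_a = {s: i for i, s in enumerate(scores_a.sample_ids)}
    pos_b = {s: i for i, s in enumerate(scores_b.sample_ids)}
    rows = []
    for j, set_id in enumerate(scores_a.set_ids):
        genes = [
            g for g in col[set_id].genes if g in set(x_a.gene_ids) and g in set(x_b.gene_ids)
        ]
        if len(genes) < 3:
            consistency = float("nan")
        else:
            prof_a = _gene_score_profile(x_a, scores_a, genes, j)
            prof_b = _gene_score_profile(x_b, scores_b, genes, j)
            ok = np.isfinite(prof_a) & np.isfinite(prof_b)
            if ok.sum() < 3:
                consistency = float("nan")
            else:
                consistency = float(stats.pearsonr(prof_a[ok], prof_b[ok]).statistic)
        score_rep = float("nan")
        if len(shared_samples) >= 3:
            sa = scores_a.values[[pos_a[s] for s in shared_samples], j]
            sb = scores_b.values[[pos_b[s] for s in shared_samples], j]
            if np.std(sa) > 0 and np.std(sb) > 0:
                score_rep = float(stats.pearsonr(sa, sb).statistic)
        rows.append(
            {
                "set": set_id,
                "definition_consistency": consistency,
                "category": _categorize(consistency),
                "score_replicability": score_rep,
            }
        )
    return ConsistencyReport(pd.DataFrame(rows))


def representativity(x: ExpressionMatrix, s: ScoreMatrix) -> float:
    """Variance of the expression matrix explained by the scores (RDA statistic).

    Every gene column is regressed on the score columns by least squares
    (rank-revealing, so collinear scores are handled); the statistic is the
    summed variance of the fitted values over the summed total variance,
    which is the redundancy-analysis proportion of explained inertia.
    """
    if x.sample_ids != s.sample_ids:
        raise ValueError("expression and score matrices have different samples")
    if not x.standardized:
        raise ValueError("representativity expects a standardized expression matrix")
    xc = x.values - x.values.mean(axis=0)
    sc = s.values - s.values.mean(axis=0)
    total = float(np.sum(xc**2))
    if total == 0:
        raise ValueError("expression matrix has zero variance")
    coef, _, rank, _ = np.linalg.lstsq(sc, xc, rcond=None)
    if rank < sc.shape[1]:
        logger.info("score matrix is rank deficient (rank %d of %d)", rank, sc.shape[1])
    fitted = sc @ coef
    return float(np.sum(fitted**2) / total)


@dataclass(frozen=True)
class PCAgreement:
    """|Pearson r| between top principal components of two matrices."""

    matrix: np.ndarray  # k x k, rows = expression PCs, columns = score PCs
    max_per_pc: np.ndarray  # per expression PC, max |r| over score PCs
    explained_variance_x: np.ndarray
    explained_variance_s: np.ndarray


def pc_agreement(x: ExpressionMatrix, s: ScoreMatrix, k: int = 10) -> PCAgreement:
    """Correlate the top-k PC score vectors of the expression and score matrices."""
    if x.sample_ids != s.sample_ids:
        raise ValueError("expression and score matrices have different samples")
    limit = min(x.n_samples, x.n_genes, len(s.set_ids))
    if k > limit:
        raise ValueError(f"k={k} exceeds the maximum number of components {limit}")

    def pcs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = values - values.mean(axis=0)
        u, sv, _ = np.linalg.svd(c, full_matrices=False)
        var = sv**2 / max(values.shape[0] - 1, 1)
        return u[:, :k] * sv[:k], var[:k] / max(var.sum(), np.finfo(float).tiny)

    px, evx = pcs(x.values)
    ps, evs = pcs(s.values)
    px = px - px.mean(axis=0)
    ps = ps - ps.mean(axis=0)
    nx = np.linalg.norm(px, axis=0)
    ns = np.linalg.norm(ps, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(px.T @ ps / np.outer(nx, ns))
    corr = np.nan_to_num(corr)
    return PCAgreement(corr, corr.max(axis=1), evx, evs)


def prune_by_replicability(
    col: GeneSetCollection,
    x: ExpressionMatrix,
    arch: ArchitectureConfig | None = None,
    cfg=None,
    *,
    n_seeds: int = 6,
    threshold: float = 0.7,
    max_rounds: int = 1,
) -> tuple[GeneSetCollection, list[dict]]:
    """Drop gene sets whose scores depend on the weight initialization.

    Each round trains ``n_seeds`` models differing only in seed, computes
    scores for the *full* input matrix (training and validation samples),
    measures replicability, and removes sets below ``threshold``. With
    ``max_rounds > 1`` the loop retrains on the pruned collection until all
    surviving sets pass. Returns the pruned collection and a per-round
    history (replicability series and dropped ids).
    """
    from .training import TrainingConfig, train_full

    cfg = cfg or TrainingConfig()
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    if not x.standardized:
        x = standardize(x)
    history: list[dict] = []
    current = col
    for round_no in range(1, max_rounds + 1):
        runs = []
        for i in range(n_seeds):
            run_seed = int(
                np.random.SeedSequence([int(cfg.seed), 4, round_no, i]).generate_state(1)[0]
                % (2**31)
            )
            model, _ = train_full(current, x, arch, replace(cfg, seed=run_seed))
            runs.append(compute_gsas(model, x))
        report = replicability(runs)
        dropped = report.below(threshold)
        history.append(
            {
                "round": round_no,
                "replicability": report.per_set,
                "dropped": dropped,
                "n_sets_before": len(current),
                "n_sets_after": len(current) - len(dropped),
            }
        )
        if not dropped:
            break
        keep = [i for i in current.ids if i not in set(dropped)]
        if not keep:
            raise ValueError("pruning removed every gene set")
        current = current.subset(keep)
    return current, history
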