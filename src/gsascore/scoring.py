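"""Scoring new datasets and extracting per-gene interpretability measures.

A trained model is applied to any expression matrix: the data are
standardized (if not already), aligned to the model's gene universe (absent
genes imputed at the standardized mean of 0) and pushed through the encoder.
Gene relevance summarizes how much each gene contributes to the scores it
participates in: the marginal relevance of a gene within a set is its
absolute encoder weight divided by the sum of absolute weights in the set,
and the total relevance is the sum of marginals over all sets containing
the gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, align_to_model, standardize
from .network import GsasModel, encode_values

__all__ = ["ScoreMatrix", "compute_gsas", "gene_relevance", "top_genes"]


@dataclass(frozen=True)
class ScoreMatrix:
    """Samples x gene sets activity scores (pre-activation encoder outputs)."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    set_ids: tuple[str, ...]
    model_fingerprint: str = ""
    imputed_fraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "set_ids", tuple(map(str, self.set_ids)))
        if values.shape != (len(self.sample_ids), len(self.set_ids)):
            raise ValueError("score matrix shape inconsistent with id lists")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite score values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.set_ids))

    def to_long_frame(self) -> pd.DataFrame:
        df = self.to_frame().reset_index(names="sample_id")
        return df.melt(id_vars="sample_id", var_name="set_id", value_name="gsas")


def compute_gsas(
    model: GsasModel,
    x: ExpressionMatrix,
    *,
    imputation_warn_fraction: float = 0.2,
) -> ScoreMatrix:
    """Gene set activity scores of ``x`` under a trained model.

    ``x`` may contain any superset/subset of the model's genes; it is
    standardized within the query dataset when not already flagged and then
    aligned to the model. A warning is emitted for every gene set with more
    than ``imputation_warn_fraction`` of its member genes absent from ``x``
    (their contribution is imputed as 0, the standardized mean).
    """
    if not x.standardized:
        x = standardize(x)
    aligned, missing = align_to_model(x, model.gene_ids)
    missing_set = set(missing)
    present = np.array([g not in missing_set for g in model.gene_ids], dtype=np.float64)
    set_sizes = model.mask.sum(axis=0)
    imputed = 1.0 - (model.mask * present[:, None]).sum(axis=0) / set_sizes
    imputed_fraction = {s: float(f) for s, f in zip(model.set_ids, imputed)}
    high = [s for s, f in imputed_fraction.items() if f > imputation_warn_fraction]
    if high:
        warnings.warn(
            f"{len(high)} gene set(s) have >{imputation_warn_fraction:.0%} of their genes "
            f"imputed (absent from the input): {high[:5]}{'...' if len(high) > 5 else ''}",
            stacklevel=2,
        )
    values = encode_values(model, aligned.values)
    return ScoreMatrix(
        values, x.sample_ids, model.set_ids, model.fingerprint(), imputed_fraction
    )


def gene_relevance(model: GsasModel) -> pd.DataFrame:
    """Per-(gene, set) marginal relevance and per-gene total relevance.

    Weights are taken in absolute value; within each gene set the marginals
    sum to 1 (unless the set's weights are all zero, which yields zeros and
    a warning). Returns a long-format frame with columns gene, set, weight,
    marginal_relevance, total_relevance, n_sets.
    """
    W = model.encoder_weights
    absW = np.abs(W) * model.mask
    col_sums = absW.sum(axis=0)
    zero_cols = col_sums == 0
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} gene set(s) have all-zero weights; "
            "their marginal relevances are reported as 0",
            stacklevel=2,
        )
    marginal = absW / np.where(zero_cols, 1.0, col_sums)[None, :]
    total = marginal.sum(axis=1)
    n_sets_per_gene = model.mask.sum(axis=1).astype(int)
    genes_idx, sets_idx = np.nonzero(model.mask)
    gene_arr = np.asarray(model.gene_ids, dtype=object)
    set_arr = np.asarray(model.set_ids, dtype=object)
    return pd.DataFrame(
        {
            "gene": gene_arr[genes_idx],
            "set": set_arr[sets_idx],
            "weight": W[genes_idx, sets_idx],
            "marginal_relevance": marginal[genes_idx, sets_idx],
            "total_relevance": total[genes_idx],
            "n_sets": n_sets_per_gene[genes_idx],
        }
    )


def top_genes(model: GsasModel, set_id: str, k: int | None = None) -> pd.DataFrame:
    """Genes of a set ranked by |weight| (signed weights reported).

    Ties in |weight| are broken lexicographically by gene id. ``k`` larger
    than the set (or None) returns the whole set.
    """
    if set_id not in model.set_ids:
        raise KeyError(f"unknown gene set id {set_id!r}")
    j = model.set_ids.index(set_id)
    rows = np.flatnonzero(model.mask[:, j])
    genes = [model.gene_ids[i] for i in rows]
    weights = model.encoder_weights[rows, j]
    order = sorted(range(len(genes)), key=lambda i: (-abs(weights[i]), genes[i]))
    if k is not None:
        order = order[: max(k, 0)]
    return pd.DataFrame(
        {"gene": [genes[i] for i in order], "weight": [weights[i] for i in order]}
    )
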