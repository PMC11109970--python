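"""Expression matrices: I/O, per-gene standardization, alignment to a model.

The pipeline consumes continuous, pre-normalized expression values (e.g. VST
or log-scale); raw counts should be variance-stabilized upstream. Internally
everything is samples x genes, float64.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_matrix",
    "write_matrix",
    "standardize",
    "align_to_model",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Samples x genes numeric matrix with ids and a standardization flag.

    ``constant_genes`` records genes that had zero variance when the matrix
    was standardized (their columns are all-zero afterwards).
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    standardized: bool = False
    constant_genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        if values.ndim != 2:
            raise ValueError("values must be 2-D (samples x genes)")
        if values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {values.shape} inconsistent with {len(self.sample_ids)} samples "
                f"x {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.gene_ids))

    def subset_samples(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx],
            sample_ids=tuple(np.asarray(self.sample_ids, dtype=object)[idx].tolist()),
        )


def _from_frame(df: pd.DataFrame, orientation: str, standardized: bool) -> ExpressionMatrix:
    if orientation == "genes_by_samples":
        df = df.T
    elif orientation != "samples_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    values = df.to_numpy(dtype=np.float64)
    return ExpressionMatrix(
        values, tuple(map(str, df.index)), tuple(map(str, df.columns)), standardized=standardized
    )


def read_matrix(path, orientation: str = "samples_by_genes") -> ExpressionMatrix:
    """Read an expression matrix from delimited text (TSV/CSV) or HDF5.

    ``orientation`` states how the *file* is laid out; the returned matrix is
    always samples x genes. Non-numeric or non-finite cells are errors.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as fh:
            values = np.asarray(fh["values"], dtype=np.float64)
            sample_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["sample_ids"][()]]
            gene_ids = [g.decode() if isinstance(g, bytes) else str(g) for g in fh["gene_ids"][()]]
            standardized = bool(fh.attrs.get("standardized", False))
        df = pd.DataFrame(values, index=sample_ids, columns=gene_ids)
        return _from_frame(df, orientation, standardized)
    sep = "," if path.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        df = df.astype(np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in expression matrix: {exc}") from exc
    if df.isna().to_numpy().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}")
    return _from_frame(df, orientation, standardized=False)


def write_matrix(x: ExpressionMatrix, path) -> None:
    """Write samples x genes to TSV/CSV (labels included) or HDF5."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=x.values)
            fh.create_dataset("sample_ids", data=np.array(x.sample_ids, dtype="S"))
            fh.create_dataset("gene_ids", data=np.array(x.gene_ids, dtype="S"))
            fh.attrs["standardized"] = x.standardized
        return
    sep = "," if path.endswith(".csv") else "\t"
    x.to_frame().to_csv(path, sep=sep)


def standardize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each gene to mean 0 and standard deviation 1 across samples.

    Uses the population standard deviation (denominator n). Genes with zero
    variance are set to all-zero, recorded in ``constant_genes`` and warned
    about. Requires at least two samples and a not-yet-standardized input.
    """
    if x.standardized:
        raise ValueError("matrix is already standardized")
    if x.n_samples < 2:
        raise ValueError("standardization requires >= 2 samples")
    mean = x.values.mean(axis=0)
    sd = x.values.std(axis=0)  # ddof=0
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    values = (x.values - mean) / sd_safe
    if constant.any():
        names = tuple(np.asarray(x.gene_ids, dtype=object)[constant].tolist())
        warnings.warn(
            f"{constant.sum()} constant gene(s) set to zero after standardization: "
            f"{list(names[:5])}{'...' if len(names) > 5 else ''}",
            stacklevel=2,
        )
        values[:, constant] = 0.0
    else:
        names = ()
    return ExpressionMatrix(values, x.sample_ids, x.gene_ids, standardized=True, constant_genes=names)


def align_to_model(
    x: ExpressionMatrix, model_genes: Sequence[str]
) -> tuple[ExpressionMatrix, tuple[str, ...]]:
    """Reorder columns to a model's gene universe; impute absent genes with 0.

    Zero is the per-gene mean of standardized data, so missing genes are
    imputed at their expected value. Genes of ``x`` not in ``model_genes``
    are dropped. Returns the aligned matrix and the tuple of imputed gene
    ids; raises when the gene overlap is empty.
    """
    if not x.standardized:
        raise ValueError("align_to_model expects a standardized matrix")
    model_genes = [str(g) for g in model_genes]
    pos = {g: i for i, g in enumerate(x.gene_ids)}
    shared = [g for g in model_genes if g in pos]
    if not shared:
        raise ValueError("no overlap between input genes and model genes")
    values = np.zeros((x.n_samples, len(model_genes)))
    src = [pos[g] for g in shared]
    dst = [i for i, g in enumerate(model_genes) if g in pos]
    values[:, dst] = x.values[:, src]
    missing = tuple(g for g in model_genes if g not in pos)
    aligned = ExpressionMatrix(
        values, x.sample_ids, tuple(model_genes), standardized=True, constant_genes=x.constant_genes
    )
    return aligned, missing
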