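"""Scikit-learn style estimator wrapping the gene set autoencoder.

``GeneSetAutoencoder`` is a transformer: ``fit`` runs the three-step
training on a samples x genes matrix, ``transform`` returns gene set
activity scores. It composes with sklearn pipelines and model selection
(``get_params``/``set_params``/``clone`` work as usual); the functional
modules (:mod:`gsascore.training`, :mod:`gsascore.scoring`, ...) remain the
thin procedural surface underneath.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .expression import ExpressionMatrix
from .genesets import GeneSetCollection
from .network import ArchitectureConfig
from .scoring import compute_gsas, gene_relevance
from .training import TrainingConfig, train_full

__all__ = ["GeneSetAutoencoder"]


class GeneSetAutoencoder(BaseEstimator, TransformerMixin):
    """Sparsely-connected autoencoder producing gene set activity scores.

    Parameters
    ----------
    gene_sets
        The :class:`~gsascore.genesets.GeneSetCollection` defining the
        encoder connectivity (one bottleneck neuron per set).
    variant, decoder_hidden_units, encoder_neurons_per_set, dropout_rate,
    hidden_activation, encoder_bias, decoder_bias
        Architecture options; see :class:`~gsascore.network.ArchitectureConfig`.
    step?_epochs, step?_lr, batch_size, validation_fraction
        Three-step training schedule; see
        :class:`~gsascore.training.TrainingConfig`.
    random_state
        Seed for every source of randomness (initialization, splitting,
        batch shuffling, dropout).

    Attributes
    ----------
    model_ : GsasModel
        The trained network (weights, mask, ids, provenance).
    trace_ : TrainingTrace
        Per-step, per-epoch reconstruction MSE.
    feature_names_in_ : ndarray of gene ids seen during fit.
    set_ids_ : list of gene set ids (transform output columns).
    """

    def __init__(
        self,
        gene_sets: GeneSetCollection | None = None,
        *,
        variant: str = "geneset",
        decoder_hidden_units: int = 1000,
        encoder_neurons_per_set: int = 10,
        dropout_rate: float = 0.0,
        hidden_activation: str = "tanh",
        encoder_bias: bool = False,
        decoder_bias: bool = True,
        step1_epochs: int = 100,
        step2_epochs: int = 50,
        step3_epochs: int = 100,
        step1_lr: float = 1e-2,
        step2_lr: float = 1e-3,
        step3_lr: float = 1e-4,
        batch_size: int = 64,
        validation_fraction: float = 0.2,
        random_state: int = 0,
    ) -> None:
        self.gene_sets = gene_sets
        self.variant = variant
        self.decoder_hidden_units = decoder_hidden_units
        self.encoder_neurons_per_set = encoder_neurons_per_set
        self.dropout_rate = dropout_rate
        self.hidden_activation = hidden_activation
        self.encoder_bias = encoder_bias
        self.decoder_bias = decoder_bias
        self.step1_epochs = step1_epochs
        self.step2_epochs = step2_epochs
        self.step3_epochs = step3_epochs
        self.step1_lr = step1_lr
        self.step2_lr = step2_lr
        self.step3_lr = step3_lr
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _arch(self) -> ArchitectureConfig:
        return ArchitectureConfig(
            variant=self.variant,
            decoder_hidden_units=self.decoder_hidden_units,
            encoder_neurons_per_set=self.encoder_neurons_per_set,
            dropout_rate=self.dropout_rate,
            hidden_activation=self.hidden_activation,
            encoder_bias=self.encoder_bias,
            decoder_bias=self.decoder_bias,
        )

    def _training_config(self, strata) -> TrainingConfig:
        return TrainingConfig(
            step1_epochs=self.step1_epochs,
            step2_epochs=self.step2_epochs,
            step3_epochs=self.step3_epochs,
            step1_lr=self.step1_lr,
            step2_lr=self.step2_lr,
            step3_lr=self.step3_lr,
            batch_size=self.batch_size,
            validation_fraction=self.validation_fraction,
            strata=tuple(strata) if strata is not None else None,
            seed=self.random_state,
        )

    @staticmethod
    def _as_matrix(X, genes, standardized: bool) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return ExpressionMatrix(
                X.to_numpy(dtype=np.float64),
                tuple(map(str, X.index)),
                tuple(map(str, X.columns)),
                standardized=standardized,
            )
        X = np.asarray(X, dtype=np.float64)
        if genes is None:
            raise ValueError("pass `genes` (or a DataFrame/ExpressionMatrix) so columns can be named")
        samples = tuple(f"sample{i}" for i in range(X.shape[0]))
        return ExpressionMatrix(X, samples, tuple(map(str, genes)), standardized=standardized)

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y=None, *, genes=None, strata=None, standardized: bool = False):
        """Train on a samples x genes matrix (array, DataFrame or ExpressionMatrix)."""
        if self.gene_sets is None:
            raise ValueError("gene_sets must be provided")
        x = self._as_matrix(X, genes, standardized)
        cfg = self._training_config(strata)
        self.model_, self.trace_ = train_full(self.gene_sets, x, self._arch(), cfg)
        self.feature_names_in_ = np.asarray(self.model_.gene_ids, dtype=object)
        self.n_features_in_ = len(self.feature_names_in_)
        self.set_ids_ = list(self.model_.set_ids)
        return self

    def transform(self, X, *, genes=None, standardized: bool = False) -> np.ndarray:
        """Gene set activity scores for new data (samples x sets array)."""
        self._check_fitted()
        x = self._as_matrix(X, genes if genes is not None else self.feature_names_in_, standardized)
        return compute_gsas(self.model_, x).values

    def score_frame(self, X, *, genes=None, standardized: bool = False) -> pd.DataFrame:
        """Like :meth:`transform` but labeled (samples x set ids DataFrame)."""
        self._check_fitted()
        x = self._as_matrix(X, genes if genes is not None else self.feature_names_in_, standardized)
        return compute_gsas(self.model_, x).to_frame()

    def inverse_transform(self, S) -> np.ndarray:
        """Reconstructed (standardized) expression from scores."""
        self._check_fitted()
        from .network import decode

        return decode(self.model_, np.asarray(S, dtype=np.float64))

    def gene_relevance(self) -> pd.DataFrame:
        self._check_fitted()
        return gene_relevance(self.model_)

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("this GeneSetAutoencoder instance is not fitted yet")

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "model_")
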