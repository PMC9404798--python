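"""scikit-learn style estimator facade over the federated trainer.

``FedAARClassifier`` is a classifier for windowed multi-channel time series
(X of shape ``(n_windows, window_len, n_channels)``) whose ``fit`` runs a
federated simulation: samples are split into clients by the ``groups``
argument (one client per distinct group, e.g. one animal or farm per group)
and trained for ``rounds`` communication rounds with the selected algorithm.
It composes with sklearn model selection (``get_params``/``set_params``,
``clone``) and scoring.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import ClientDataset
from .federation import FedConfig, evaluate, train
from .nn import ConvNet, ModelSpec
from .plu import PLUHyper

__all__ = ["FedAARClassifier"]


class FedAARClassifier(BaseEstimator, ClassifierMixin):
    """Federated activity classifier with prototype guidance and gradient
    refinement.

    Parameters mirror the federated protocol: ``algorithm`` picks the variant
    (``fedavg``, ``plu_only``, ``gra_only``, ``fedaar``), ``lambda_pgreg``
    weights the prototype-guidance penalty, and the optimiser settings apply
    to each client's local Adam steps.

    Attributes (after ``fit``)
    --------------------------
    classes_ : original class labels in sorted order
    global_params_ : flat vector of the selected global model's weights
    round_logs_ : list of per-round records (losses, refinement counts, metrics)
    model_spec_ : the resolved architecture specification
    """

    def __init__(
        self,
        algorithm: str = "fedaar",
        rounds: int = 30,
        architecture: str = "small_cnn",
        feature_dim: int = 32,
        hidden: tuple[int, int] = (16, 32),
        kernel_size: int = 5,
        lambda_pgreg: float = 0.05,
        local_epochs: int = 1,
        batch_size: int = 256,
        learning_rate: float = 5e-5,
        weight_decay: float = 0.15,
        lr_decay_factor: float = 0.1,
        lr_decay_every: int = 20,
        eval_every: int = 1,
        seed: int = 0,
    ):
        self.algorithm = algorithm
        self.rounds = rounds
        self.architecture = architecture
        self.feature_dim = feature_dim
        self.hidden = hidden
        self.kernel_size = kernel_size
        self.lambda_pgreg = lambda_pgreg
        self.local_epochs = local_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.lr_decay_factor = lr_decay_factor
        self.lr_decay_every = lr_decay_every
        self.eval_every = eval_every
        self.seed = seed

    # -- helpers -----------------------------------------------------------

    def _validate_X(self, X: np.ndarray, fitted: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(
                "X must be 3-D: (n_windows, window_len, n_channels); "
                f"got shape {X.shape}"
            )
        if fitted and X.shape[1:] != (self.model_spec_.window_len, self.model_spec_.n_channels):
            raise ValueError(
                f"X windows of shape {X.shape[1:]} do not match the fitted "
                f"model ({self.model_spec_.window_len}, {self.model_spec_.n_channels})"
            )
        return X

    def _encode(self, y: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.classes_, y) + 1

    # -- sklearn API -------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        groups: Optional[Sequence] = None,
        eval_set: Optional[tuple[np.ndarray, np.ndarray]] = None,
    ) -> "FedAARClassifier":
        """Fit the federated model.

        ``groups`` assigns each window to a client (default: one single
        client, i.e. plain centralised training of the same model).
        ``eval_set`` is an optional held-out ``(X, y)`` used to select the
        best-round checkpoint by test accuracy, emulating leave-one-subject-out
        evaluation with the unseen subject as the test set.
        """
        X = self._validate_X(X)
        y = np.asarray(y)
        if y.shape != (X.shape[0],):
            raise ValueError("y must be 1-D with one label per window")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        y_enc = self._encode(y)

        if groups is None:
            groups = np.zeros(len(y), dtype=int)
        groups = np.asarray(groups)
        clients = [
            ClientDataset(X[groups == g], y_enc[groups == g], client_id=str(g))
            for g in np.unique(groups)
        ]

        test = None
        if eval_set is not None:
            Xt, yt = eval_set
            Xt = self._validate_X(np.asarray(Xt))
            unknown = set(np.unique(yt)) - set(self.classes_)
            if unknown:
                raise ValueError(f"eval_set contains unseen labels {sorted(unknown)}")
            test = ClientDataset(Xt, self._encode(np.asarray(yt)), "eval")

        spec = ModelSpec(
            n_classes=int(self.classes_.size),
            window_len=X.shape[1],
            architecture=self.architecture,
            feature_dim=self.feature_dim,
            n_channels=X.shape[2],
            hidden=tuple(self.hidden),
            kernel_size=self.kernel_size,
            init_seed=self.seed,
        )
        cfg = FedConfig(
            model=spec,
            algorithm=self.algorithm,
            rounds=self.rounds,
            plu=PLUHyper(
                lambda_pgreg=self.lambda_pgreg,
                local_epochs=self.local_epochs,
                batch_size=self.batch_size,
                learning_rate=self.learning_rate,
                weight_decay=self.weight_decay,
                lr_decay_factor=self.lr_decay_factor,
                lr_decay_every=self.lr_decay_every,
            ),
            eval_every=self.eval_every,
            seed=self.seed,
        )
        self.model_spec_ = spec
        self.global_params_, self.round_logs_ = train(cfg, clients, test)
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def _model(self) -> ConvNet:
        check_is_fitted(self, "global_params_")
        net = ConvNet(self.model_spec_)
        net.set_flat_params(self.global_params_)
        return net

    def predict(self, X: np.ndarray) -> np.ndarray:
        net = self._model()
        X = self._validate_X(X, fitted=True)
        return self.classes_[net.predict(X) - 1]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        net = self._model()
        X = self._validate_X(X, fitted=True)
        logits = np.concatenate(
            [net.forward(X[s : s + 1024]) for s in range(0, len(X), 1024)]
        )
        shifted = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(shifted)
        return p / p.sum(axis=1, keepdims=True)

    def extract_features(self, X: np.ndarray) -> np.ndarray:
        """Penultimate-layer feature vectors (n_windows, feature_dim), e.g.
        for external embedding plots."""
        net = self._model()
        X = self._validate_X(X, fitted=True)
        return np.concatenate(
            [net.features(X[s : s + 1024]) for s in range(0, len(X), 1024)]
        )

    def evaluate(self, X: np.ndarray, y: np.ndarray) -> dict:
        """Macro precision/recall/F1 and accuracy (percent) on (X, y)."""
        net = self._model()
        X = self._validate_X(X, fitted=True)
        ds = ClientDataset(X, self._encode(np.asarray(y)), "eval")
        return evaluate(net, ds)
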