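"""Scikit-learn style estimators for the multi-task network and baselines.

:class:`MultiTaskNeuralRegressor` is the central model: a shared ReLU trunk
with one small branch per phenotype, trained with a masked mean-squared
error so that a sample updates shared layers and exactly the branches for
which it carries labels.  :class:`SingleTaskMLPRegressor` is the matched
single-output network (identical layer sizes, one branch) and
:class:`LinearL2Regressor` the matched linear model (all hidden layers
removed, L2-penalized), both trained with the same masked objective
restricted to their task.

Missing labels are encoded as NaN in ``y``; the observed mask is derived
from them, which keeps the estimators drop-in compatible with sklearn
model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import MaskedMLP, masked_mse, train_network

#: The hyperparameter grid searched during model tuning: kernel L2 penalty,
#: gradient clip norm for Adam, and learning rate (2 x 2 x 2 = 8 configs).
DEFAULT_GRID = tuple(
    {"l2": l2, "clip_norm": cn, "learning_rate": lr}
    for l2 in (1e-3, 1e-5)
    for cn in (0.1, 0.01)
    for lr in (1e-3, 1e-4)
)


class _BaseNeuralRegressor(BaseEstimator, RegressorMixin):
    def __init__(
        self,
        shared_widths=(256, 100),
        branch_widths=(50,),
        dropout=0.1,
        learning_rate=1e-3,
        l2=1e-5,
        clip_norm=0.1,
        epochs=200,
        batch_size=20,
        random_state=0,
    ):
        self.shared_widths = shared_widths
        self.branch_widths = branch_widths
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.l2 = l2
        self.clip_norm = clip_norm
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    _n_tasks = 1

    def _validate_arch(self):
        pass

    def _fit_masked(self, X, Y, mask):
        X = np.asarray(X, dtype=float)
        self._validate_arch()
        self.n_features_in_ = X.shape[1]
        self.net_ = MaskedMLP(
            input_dim=X.shape[1],
            shared_widths=self.shared_widths,
            branch_widths=self.branch_widths,
            n_tasks=self._n_tasks,
            dropout=self.dropout,
            seed=self.random_state,
        )
        self.training_log_ = train_network(
            self.net_,
            X,
            Y,
            mask,
            learning_rate=self.learning_rate,
            l2=self.l2,
            clip_norm=self.clip_norm,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.random_state,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=float)
        preds = self.net_.predict(X)
        return preds[:, 0] if self._n_tasks == 1 else preds

    def transform(self, X):
        """Last-shared-layer embedding (the supervised representation)."""
        check_is_fitted(self, "net_")
        return self.net_.shared_forward(np.asarray(X, dtype=float))

    def score(self, X, y):
        """Negative masked MSE (higher is better), over observed cells."""
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        preds = self.predict(X)
        if preds.ndim == 1:
            preds = preds[:, None]
        mask = ~np.isnan(y)
        return -masked_mse(preds, np.where(mask, y, 0.0), mask)


class MultiTaskNeuralRegressor(_BaseNeuralRegressor):
    """Multi-task network predicting all six phenotypes simultaneously.

    ``fit(X, Y)`` expects ``Y`` of shape (n_samples, n_tasks) with NaN for
    unobserved labels.  Every output is produced for every sample at
    predict time regardless of label availability at train time.
    """

    def __init__(
        self,
        shared_widths=(256, 100),
        branch_widths=(50,),
        n_tasks=6,
        dropout=0.1,
        learning_rate=1e-3,
        l2=1e-5,
        clip_norm=0.1,
        epochs=200,
        batch_size=20,
        random_state=0,
    ):
        super().__init__(
            shared_widths, branch_widths, dropout, learning_rate, l2,
            clip_norm, epochs, batch_size, random_state,
        )
        self.n_tasks = n_tasks

    @property
    def _n_tasks(self):
        return self.n_tasks

    def _validate_arch(self):
        if len(self.shared_widths) < 2 or len(self.branch_widths) < 1:
            raise ValueError(
                "the multi-task architecture requires >=2 shared layers and "
                ">=1 task-specific hidden layer"
            )

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != self.n_tasks:
            raise ValueError(f"y must be (n_samples, {self.n_tasks})")
        mask = ~np.isnan(y)
        return self._fit_masked(X, np.where(mask, y, 0.0), mask)

    @property
    def embedding_dim_(self):
        return self.shared_widths[-1]


class SingleTaskMLPRegressor(_BaseNeuralRegressor):
    """Single-output network with the same layer sizes as the multi-task
    model but only one task branch; trained on one phenotype's labels."""

    def fit(self, X, y):
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        mask = ~np.isnan(y)
        return self._fit_masked(X, np.where(mask, y, 0.0), mask)


class LinearL2Regressor(_BaseNeuralRegressor):
    """The linear baseline: a single L2-penalized dense map input -> 1,
    i.e. the single-task model with all hidden layers removed, trained with
    the same masked loss and optimizer."""

    def __init__(
        self,
        learning_rate=1e-3,
        l2=1e-5,
        clip_norm=0.1,
        epochs=200,
        batch_size=20,
        random_state=0,
    ):
        super().__init__(
            shared_widths=(),
            branch_widths=(),
            dropout=0.0,
            learning_rate=learning_rate,
            l2=l2,
            clip_norm=clip_norm,
            epochs=epochs,
            batch_size=batch_size,
            random_state=random_state,
        )

    def get_params(self, deep=True):
        return {
            "learning_rate": self.learning_rate,
            "l2": self.l2,
            "clip_norm": self.clip_norm,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "random_state": self.random_state,
        }

    def fit(self, X, y):
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        mask = ~np.isnan(y)
        return self._fit_masked(X, np.where(mask, y, 0.0), mask)

    @property
    def coef_(self):
        check_is_fitted(self, "net_")
        return self.net_.branches[0][0][0][:, 0]

    @property
    def intercept_(self):
        check_is_fitted(self, "net_")
        return float(self.net_.branches[0][0][1][0])


def build_baseline(kind: str, task_index: int | None = None, **params):
    """Construct a baseline estimator: ``single_task_mlp`` or ``linear``.

    ``task_index`` is carried as metadata only (which phenotype column the
    caller should train it on); estimators themselves are single-output.
    """
    if kind == "single_task_mlp":
        est = SingleTaskMLPRegressor(**params)
    elif kind == "linear":
        est = LinearL2Regressor(**params)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    est.task_index = task_index
    return est
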