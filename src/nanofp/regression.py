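"""Regression families mapping probe free energies to all other molecules.

Given a free-energy matrix, a small set of probe ("feature") molecules is
chosen and, per nanomaterial, the probes' adsorption free energies form
the feature vector while every other molecule's free energy is a response.
Three model families are supported:

``LR``
    Ordinary least squares with intercept, fit independently per response.
``AdaBoost``
    AdaBoost.R2 boosting with depth-3 regression trees as weak learners,
    50 iterations, linear loss, prediction by weighted median — fit
    independently per response.
``NN``
    One hidden layer of 10 tanh units with linear outputs, L2 penalty,
    trained jointly over all responses with the Adam optimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import AdaBoostRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor
from sklearn.tree import DecisionTreeRegressor

__all__ = ["RegressorSpec", "FittedModel", "fit", "predict"]

FAMILIES = ("LR", "AdaBoost", "NN")


@dataclass
class RegressorSpec:
    """Declarative choice of model family plus its hyperparameters.

    Hyperparameters (with defaults) by family:

    * AdaBoost: ``n_estimators`` 50, ``max_depth`` 3, ``loss`` "linear"
    * NN: ``hidden_units`` 10, ``activation`` "tanh", ``alpha`` (L2) 1e-4,
      ``max_iter`` 2000, ``learning_rate_init`` 1e-2 (suited to
      tens-of-kJ/mol targets without feature scaling), ``tol`` 1e-6
    """

    family: str = "LR"
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")


@dataclass
class FittedModel:
    """A trained mapping from probe free energies to response free energies."""

    spec: RegressorSpec
    feature_ids: list[str]
    response_ids: list[str]
    _estimators: Any  # per-response list (LR/AdaBoost) or a single joint NN
    converged: bool = True

    def coefficients(self) -> dict[str, dict[str, float]]:
        """LR only: per-response {feature: coefficient} plus 'intercept'."""
        if self.spec.family != "LR":
            raise ValueError("coefficient table is defined for the LR family only")
        table = {}
        for resp, est in zip(self.response_ids, self._estimators):
            row = {f: float(c) for f, c in zip(self.feature_ids, est.coef_)}
            row["intercept"] = float(est.intercept_)
            table[resp] = row
        return table


def fit(spec: RegressorSpec, X: np.ndarray, Y: np.ndarray,
        feature_ids: list[str] | None = None,
        response_ids: list[str] | None = None) -> FittedModel:
    """Fit the chosen family on materials x features -> materials x responses.

    LR and AdaBoost fit one independent model per response column; the NN
    is one joint multi-output network.  All inputs are kJ/mol and used
    unscaled.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite training values")
    feature_ids = feature_ids or [f"f{i}" for i in range(X.shape[1])]
    response_ids = response_ids or [f"y{i}" for i in range(Y.shape[1])]
    hp = dict(spec.hyperparameters)
    converged = True

    if spec.family == "LR":
        if X.shape[0] < X.shape[1] + 1:
            warnings.warn(
                "fewer materials than features+1: OLS design is rank-deficient, "
                "returning the least-norm solution",
                stacklevel=2,
            )
        ests = [LinearRegression().fit(X, Y[:, j]) for j in range(Y.shape[1])]
    elif spec.family == "AdaBoost":
        base = DecisionTreeRegressor(max_depth=hp.pop("max_depth", 3))
        ests = [
            AdaBoostRegressor(
                estimator=base,
                n_estimators=hp.get("n_estimators", 50),
                loss=hp.get("loss", "linear"),
                random_state=spec.seed + j,
            ).fit(X, Y[:, j])
            for j in range(Y.shape[1])
        ]
    else:  # NN
        nn = MLPRegressor(
            hidden_layer_sizes=(hp.get("hidden_units", 10),),
            activation=hp.get("activation", "tanh"),
            solver="adam",
            alpha=hp.get("alpha", 1e-4),
            learning_rate_init=hp.get("learning_rate_init", 1e-2),
            max_iter=hp.get("max_iter", 2000),
            tol=hp.get("tol", 1e-6),
            random_state=spec.seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            nn.fit(X, Y if Y.shape[1] > 1 else Y.ravel())
            converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        ests = nn
    return FittedModel(
        spec=spec,
        feature_ids=list(feature_ids),
        response_ids=list(response_ids),
        _estimators=ests,
        converged=converged,
    )


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Predict materials x responses free energies (kJ/mol); deterministic."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.feature_ids):
        raise ValueError(
            f"expected {len(model.feature_ids)} feature columns "
            f"({model.feature_ids}), got {X.shape[1]}"
        )
    if model.spec.family == "NN":
        out = model._estimators.predict(X)
        if out.ndim == 1:
            out = out[:, None]
        return out
    return np.column_stack([est.predict(X) for est in model._estimators])
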