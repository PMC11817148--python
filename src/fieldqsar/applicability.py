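"""Leverage-based applicability domain (Williams plot data).

Leverage is the hat-matrix diagonal computed in the model's latent-score
space with an intercept column — the standard choice for PLS, giving
Σh = A + 1 over the training set — rather than in the raw descriptor
space whose thousands of columns make the hat matrix singular.  A
compound is a structural outlier when h exceeds the warning leverage
h* = 3p′/n (p′ = number of latent variables) and a response outlier
when its standardized residual exceeds 3 in magnitude.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pls import PLSModel, predict


def warning_leverage(n_train: int, p_prime: int) -> float:
    """Warning leverage h* = 3·p′/n_train."""
    if n_train <= 0 or p_prime < 1:
        raise ValueError("need n_train > 0 and p_prime >= 1")
    return 3.0 * p_prime / n_train


def leverages(
    model: PLSModel, X_train: np.ndarray, X_query: np.ndarray | None = None
) -> np.ndarray:
    """Hat values h = 1/n + t(T_trainᵀT_train)⁻¹tᵀ in latent-score space."""
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    T_train = model.scores(X_train)
    try:
        M = np.linalg.inv(T_train.T @ T_train)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular score covariance; reduce components") from exc
    T_q = T_train if X_query is None else model.scores(np.atleast_2d(np.asarray(X_query, dtype=float)))
    return 1.0 / len(X_train) + np.einsum("ij,jk,ik->i", T_q, M, T_q)


@dataclass
class ADReport:
    """Williams-plot data: per-compound leverage and standardized residual."""

    table: pd.DataFrame  # ligand_id, set_label, leverage, std_residual, flags
    h_star: float
    residual_sd: float
    n_components: int

    def to_csv(self, path: str | Path) -> None:
        """Write the per-compound table plus a JSON sidecar with h*."""
        path = Path(path)
        self.table.to_csv(path, index=False, float_format="%.6g")
        sidecar = {
            "h_star": self.h_star,
            "residual_sd": self.residual_sd,
            "n_components": self.n_components,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(sidecar, sort_keys=True)
        )

    @property
    def all_in_domain(self) -> bool:
        return not (
            self.table["structural_outlier"].any()
            or self.table["response_outlier"].any()
        )


def williams_table(
    model: PLSModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    train_ids: list[str] | None = None,
    test_ids: list[str] | None = None,
    p_prime: int | None = None,
) -> ADReport:
    """Leverages and standardized residuals for training and test compounds.

    The residual scale is the training-set estimate
    s = √(SSE_train/(n − A − 1)); test residuals are standardized by the
    same s.  h* uses p′ = the number of latent variables by default.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    y_train = np.asarray(y_train, dtype=float).ravel()
    n, A = len(y_train), model.n_components
    if n <= A + 1:
        raise ValueError("need n_train > A + 1 for a residual scale")

    resid_train = y_train - predict(model, X_train)
    residual_sd = math.sqrt(float(resid_train @ resid_train) / (n - A - 1))
    if residual_sd <= 0:
        raise ValueError("zero residual standard deviation")
    h_star = warning_leverage(n, p_prime if p_prime is not None else A)

    frames = []
    h_train = leverages(model, X_train)
    frames.append(pd.DataFrame({
        "ligand_id": train_ids if train_ids is not None else [f"train{i}" for i in range(n)],
        "set_label": "train",
        "leverage": h_train,
        "std_residual": resid_train / residual_sd,
    }))
    if X_test is not None:
        X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
        y_test = np.asarray(y_test, dtype=float).ravel()
        resid_test = y_test - predict(model, X_test)
        frames.append(pd.DataFrame({
            "ligand_id": test_ids if test_ids is not None else [f"test{i}" for i in range(len(y_test))],
            "set_label": "test",
            "leverage": leverages(model, X_train, X_test),
            "std_residual": resid_test / residual_sd,
        }))
    table = pd.concat(frames, ignore_index=True)
    table["structural_outlier"] = table["leverage"] > h_star
    table["response_outlier"] = table["std_residual"].abs() > 3.0
    return ADReport(table=table, h_star=h_star, residual_sd=residual_sd, n_components=A)
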