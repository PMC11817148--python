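"""Partial least squares regression of activity on field descriptors.

NIPALS with mean-centered X and y and no per-column scaling: molecular
field columns share kcal/mol units, so autoscaling would inflate noise
columns (per-field block scaling is available via ``scale="block"``).
The component count is chosen by k-fold cross-validated Q² =
1 − PRESS/SS_tot; ties go to the smaller model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500
DEFAULT_CV_SEED = 20250124


@dataclass
class PLSModel:
    """A fitted PLS model in the original (retained) column space."""

    n_components: int
    column_means: np.ndarray  # (p,)
    y_mean: float
    x_weights: np.ndarray  # W, (p, A)
    x_loadings: np.ndarray  # P, (p, A)
    y_loadings: np.ndarray  # q, (A,)
    coefficients: np.ndarray  # (p,)
    intercept: float
    r2_train: float
    column_scales: np.ndarray | None = None  # (p,) if block scaling used
    q2: float | None = None
    component_trace: dict[int, float] = dc_field(default_factory=dict)
    cv_seed: int | None = None
    fold_count: int = 5

    @property
    def rotations(self) -> np.ndarray:
        """R = W(PᵀW)⁻¹: centered rows · R gives the latent scores."""
        return self.x_weights @ np.linalg.inv(self.x_loadings.T @ self.x_weights)

    def scores(self, X: np.ndarray) -> np.ndarray:
        Xc = X - self.column_means
        if self.column_scales is not None:
            Xc = Xc / self.column_scales
        return Xc @ self.rotations

    # --- persistence -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_components": self.n_components,
            "column_means": self.column_means.tolist(),
            "y_mean": self.y_mean,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "r2_train": self.r2_train,
            "column_scales": None if self.column_scales is None else self.column_scales.tolist(),
            "q2": self.q2,
            "component_trace": {str(k): v for k, v in self.component_trace.items()},
            "cv_seed": self.cv_seed,
            "fold_count": self.fold_count,
        }
        Path(path).write_text(json.dumps(doc, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        d = json.loads(Path(path).read_text())
        return cls(
            n_components=d["n_components"],
            column_means=np.asarray(d["column_means"]),
            y_mean=d["y_mean"],
            x_weights=np.asarray(d["x_weights"]),
            x_loadings=np.asarray(d["x_loadings"]),
            y_loadings=np.asarray(d["y_loadings"]),
            coefficients=np.asarray(d["coefficients"]),
            intercept=d["intercept"],
            r2_train=d["r2_train"],
            column_scales=None if d["column_scales"] is None else np.asarray(d["column_scales"]),
            q2=d["q2"],
            component_trace={int(k): v for k, v in d["component_trace"].items()},
            cv_seed=d["cv_seed"],
            fold_count=d["fold_count"],
        )


def _block_scales(X: np.ndarray, field_kind: np.ndarray | None) -> np.ndarray:
    """Per-field block scale: each field block gets unit pooled variance."""
    scales = np.ones(X.shape[1])
    if field_kind is None:
        return scales
    for kind in np.unique(field_kind):
        cols = field_kind == kind
        pooled = np.sqrt(np.mean(X[:, cols].var(axis=0, ddof=0)))
        if pooled > 0:
            scales[cols] = pooled
    return scales


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    A: int,
    scale: str = "none",
    field_kind: np.ndarray | None = None,
) -> PLSModel:
    """Fit an A-component NIPALS PLS model of y on X.

    X and y are mean-centered; with ``scale="block"`` each field block
    is additionally divided by its pooled standard deviation.
    Coefficients are folded back to the original column space, so
    prediction is ``intercept + X·coefficients``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y row counts differ")
    if A < 1:
        raise ValueError("need at least one component")
    if n < A + 2:
        raise ValueError(f"need at least A+2={A + 2} training rows, got {n}")
    if np.std(y) == 0:
        raise ValueError("y has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    scales = None
    if scale == "block":
        scales = _block_scales(X, field_kind)
        Xc = Xc / scales
    elif scale != "none":
        raise ValueError(f"unknown scale mode {scale!r}")
    yc = y - y_mean

    W = np.empty((p, A))
    P = np.empty((p, A))
    q = np.empty(A)
    Xd, yd = Xc.copy(), yc.copy()
    for a in range(A):
        # NIPALS inner loop; for a single response it converges in one pass
        u = yd.copy()
        w = np.zeros(p)
        for _ in range(NIPALS_MAX_ITER):
            w_new = Xd.T @ u
            norm = np.linalg.norm(w_new)
            if norm < 1e-12:
                raise ValueError(
                    f"component {a + 1} exceeds the rank of X (deflated X'y vanished)"
                )
            w_new /= norm
            if np.linalg.norm(w_new - w) < NIPALS_TOL:
                w = w_new
                break
            w = w_new
            t = Xd @ w
            u = yd * (yd @ t) / max(t @ t, 1e-300)  # single-y u-update
        t = Xd @ w
        tt = t @ t
        if tt < 1e-12:
            raise ValueError(f"component {a + 1} exceeds the rank of X (zero score)")
        p_a = Xd.T @ t / tt
        q_a = yd @ t / tt
        Xd = Xd - np.outer(t, p_a)
        yd = yd - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a

    R = W @ np.linalg.inv(P.T @ W)
    beta = R @ q
    if scales is not None:
        beta = beta / scales
    intercept = y_mean - x_mean @ beta

    y_hat = intercept + X @ beta
    sse = float(np.sum((y - y_hat) ** 2))
    sst = float(np.sum((y - y_mean) ** 2))
    return PLSModel(
        n_components=A,
        column_means=x_mean,
        y_mean=y_mean,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=beta,
        intercept=float(intercept),
        r2_train=1.0 - sse / sst,
        column_scales=scales,
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted activities: intercept + X·coefficients."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(model.coefficients):
        raise ValueError(
            f"column mismatch: model has {len(model.coefficients)}, "
            f"input has {X_new.shape[1]}"
        )
    return model.intercept + X_new @ model.coefficients


def _fold_indices(n: int, folds: int, seed: int | None) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def cross_validate_q2(
    X: np.ndarray,
    y: np.ndarray,
    A: int,
    folds: int = 5,
    seed: int | None = DEFAULT_CV_SEED,
    scale: str = "none",
    field_kind: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """k-fold cross-validated Q² = 1 − PRESS/SS_tot and per-fold PRESS.

    Fold membership comes from a seeded uniform shuffle into parts as
    equal as possible; SS_tot uses the mean of the full training y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if folds < 2 or folds > n:
        raise ValueError("folds must be between 2 and n")
    parts = _fold_indices(n, folds, seed)
    if min(n - len(part) for part in parts) < A + 2:
        raise ValueError("some fold leaves fewer than A+2 training rows")

    press = np.empty(folds)
    for k, test_idx in enumerate(parts):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        model = fit_pls(X[mask], y[mask], A, scale=scale, field_kind=field_kind)
        press[k] = np.sum((y[test_idx] - predict(model, X[test_idx])) ** 2)
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(press.sum()) / sst, press


def select_n_components(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int | None = DEFAULT_CV_SEED,
    max_A: int | None = None,
    scale: str = "none",
    field_kind: np.ndarray | None = None,
) -> PLSModel:
    """Fit A = 1..max_A, keep the model with the highest Q² (ties → smaller A).

    The returned model is refitted on all rows and carries q2,
    component_trace, cv_seed and fold_count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if max_A is None:
        max_A = min(10, n - 2)
    if max_A < 1:
        raise ValueError("max_A must be at least 1")

    trace: dict[int, float] = {}
    best_A, best_q2 = None, -np.inf
    for A in range(1, max_A + 1):
        try:
            q2, _ = cross_validate_q2(X, y, A, folds, seed, scale, field_kind)
        except ValueError:
            break  # rank or fold-size exhausted
        trace[A] = q2
        if q2 > best_q2:  # strict: ties keep the smaller A
            best_A, best_q2 = A, q2
    if best_A is None:
        raise ValueError("no candidate component count could be cross-validated")

    model = fit_pls(X, y, best_A, scale=scale, field_kind=field_kind)
    model.q2 = best_q2
    model.component_trace = trace
    model.cv_seed = seed
    model.fold_count = folds
    return model
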