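"""External-validation battery for QSAR models (Golbraikh–Tropsha style).

Given observed and predicted activities for an external test set, the
battery computes the squared Pearson correlation r², the through-origin
regression statistics in both axis orientations (r0², k0 for observed
on predicted; r0′², k0′ for predicted on observed), their closeness
ratios, and the rm² metrics, then applies the standard thresholds:

    Q² > 0.5,  r² > 0.6,
    (r²−r0²)/r² < 0.1  or  (r²−r0′²)/r² < 0.1,
    0.85 ≤ k0 ≤ 1.15  or  0.85 ≤ k0′ ≤ 1.15,
    |r0² − r0′²| < 0.3,  rm² > 0.5,  rm′² > 0.5.

The axis convention is pinned by the slope arithmetic: k0 regresses
observed on predicted through the origin, k0 = Σ(y_obs·y_pred)/Σ(y_pred²).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class ValidationReport:
    r2: float
    r0_2: float
    r0p_2: float
    k0: float
    k0p: float
    ratio_r0: float
    ratio_r0p: float
    diff_r0: float
    rm2: float
    rm2p: float
    q2: float | None = None
    checks: dict[str, bool | None] = field(default_factory=dict)
    overall_pass: bool | None = None

    def to_dict(self) -> dict:
        return {
            "r2": self.r2, "r0_2": self.r0_2, "r0p_2": self.r0p_2,
            "k0": self.k0, "k0p": self.k0p,
            "ratio_r0": self.ratio_r0, "ratio_r0p": self.ratio_r0p,
            "diff_r0": self.diff_r0, "rm2": self.rm2, "rm2p": self.rm2p,
            "q2": self.q2, "checks": self.checks, "overall_pass": self.overall_pass,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1))

    def __str__(self) -> str:  # human-readable table
        rows = [
            ("Q2(cv)", self.q2), ("r2", self.r2),
            ("r0^2", self.r0_2), ("r0'^2", self.r0p_2),
            ("(r2-r0^2)/r2", self.ratio_r0), ("(r2-r0'^2)/r2", self.ratio_r0p),
            ("|r0^2-r0'^2|", self.diff_r0),
            ("k0", self.k0), ("k0'", self.k0p),
            ("rm^2", self.rm2), ("rm'^2", self.rm2p),
        ]
        lines = [f"{name:<16}{'' if v is None else format(v, '.3f')}" for name, v in rows]
        if self.overall_pass is not None:
            lines.append(f"{'overall':<16}{'PASS' if self.overall_pass else 'FAIL'}")
        return "\n".join(lines)


def regression_through_origin(y: Sequence[float], x: Sequence[float]) -> tuple[float, float]:
    """Slope and determination coefficient of y on x forced through the origin.

    k = Σ(y·x)/Σ(x²); r0² = 1 − Σ(y − kx)²/Σ(y − ȳ)².
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    sxx = float(x @ x)
    if sxx <= 0:
        raise ValueError("x is identically zero")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise ValueError("y has zero variance")
    k = float(y @ x) / sxx
    r0_2 = 1.0 - float(np.sum((y - k * x) ** 2)) / sst
    return k, r0_2


def external_metrics(
    y_obs: Sequence[float], y_pred: Sequence[float], q2: float | None = None
) -> ValidationReport:
    """Compute the full external-validation battery on (observed, predicted)."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or len(y_obs) < 3:
        raise ValueError("need at least 3 (observed, predicted) pairs")
    if np.std(y_obs) == 0 or np.std(y_pred) == 0:
        raise ValueError("constant observed or predicted vector")

    r = np.corrcoef(y_obs, y_pred)[0, 1]
    r2 = float(r * r)
    k0, r0_2 = regression_through_origin(y_obs, y_pred)
    k0p, r0p_2 = regression_through_origin(y_pred, y_obs)
    rm2 = r2 * (1.0 - math.sqrt(max(0.0, r2 - r0_2)))
    rm2p = r2 * (1.0 - math.sqrt(max(0.0, r2 - r0p_2)))
    report = ValidationReport(
        r2=r2, r0_2=r0_2, r0p_2=r0p_2, k0=k0, k0p=k0p,
        ratio_r0=(r2 - r0_2) / r2, ratio_r0p=(r2 - r0p_2) / r2,
        diff_r0=abs(r0_2 - r0p_2), rm2=rm2, rm2p=rm2p, q2=q2,
    )
    return gt_check(report)


def gt_check(report: ValidationReport) -> ValidationReport:
    """Apply the threshold battery; q2 check is None (N/A) when q2 absent."""
    checks: dict[str, bool | None] = {
        "q2_gt_0.5": None if report.q2 is None else bool(report.q2 > 0.5),
        "r2_gt_0.6": bool(report.r2 > 0.6),
        "ratio_r0_lt_0.1": bool(report.ratio_r0 < 0.1 or report.ratio_r0p < 0.1),
        "slope_in_0.85_1.15": bool(
            0.85 <= report.k0 <= 1.15 or 0.85 <= report.k0p <= 1.15
        ),
        "diff_r0_lt_0.3": bool(report.diff_r0 < 0.3),
        "rm2_gt_0.5": bool(report.rm2 > 0.5),
        "rm2p_gt_0.5": bool(report.rm2p > 0.5),
    }
    report.checks = checks
    report.overall_pass = all(v for v in checks.values() if v is not None)
    return report


def residual_table(
    exp: pd.DataFrame | Sequence[float],
    pred: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-ligand residuals (experimental − predicted).

    Accepts either a DataFrame with ``pic50_exp``/``pic50_pred`` columns
    (any id/label columns pass through) or two aligned vectors.
    """
    if isinstance(exp, pd.DataFrame):
        df = exp.copy()
        if "pic50_exp" not in df.columns or "pic50_pred" not in df.columns:
            raise ValueError("need pic50_exp and pic50_pred columns")
        if df["pic50_pred"].isna().any():
            missing = df.index[df["pic50_pred"].isna()].tolist()
            raise ValueError(f"missing prediction for rows {missing}")
    else:
        if pred is None:
            raise ValueError("predicted values required")
        exp = np.asarray(exp, dtype=float)
        pred = np.asarray(pred, dtype=float)
        if exp.shape != pred.shape:
            raise ValueError("experimental/predicted length mismatch")
        df = pd.DataFrame({"pic50_exp": exp, "pic50_pred": pred})
    df["residual"] = df["pic50_exp"] - df["pic50_pred"]
    return df
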