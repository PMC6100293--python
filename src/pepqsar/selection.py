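"""Stepwise-regression variable screening and collinearity diagnostics.

Classic forward-entry / backward-removal stepwise OLS on standardized
(centered, unit-variance) descriptors and response. At each cycle the
candidate with the smallest partial-F p-value enters if that p-value is at
most the significance-to-enter threshold; included variables whose
partial-F p-value reaches the significance-to-remove threshold are then
removed, largest p first. Thresholds are probability-of-F levels (the
0.05 / 0.10 defaults of the major statistics packages), not raw F values.

Collinearity of the screened set is validated with variance inflation
factors, VIF = 1 / (1 - r^2), where r^2 is the coefficient of
determination of one selected variable regressed on the others; a
variable with VIF below 5 is conventionally treated as uncorrelated with
the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StepRecord:
    action: str  # "enter" or "remove"
    variable: str
    f_statistic: float
    p_value: float


@dataclass
class SelectionResult:
    """Outcome of a stepwise screen: ordered variables, step log, VIFs."""

    selected: list[str]
    steps: list[StepRecord]
    alpha_enter: float
    alpha_remove: float
    vifs: dict[str, float] = field(default_factory=dict)
    truncated: bool = False  # hit the rows-2 variable budget

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "steps": [
                {
                    "action": s.action,
                    "variable": s.variable,
                    "f": s.f_statistic,
                    "p": s.p_value,
                }
                for s in self.steps
            ],
            "alpha_enter": self.alpha_enter,
            "alpha_remove": self.alpha_remove,
            "vifs": self.vifs,
            "truncated": self.truncated,
        }


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of no-intercept OLS (data pre-centered)."""
    if X.shape[1] == 0:
        return float(y @ y)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def _partial_f(rss_reduced: float, rss_full: float, df_resid_full: int) -> tuple[float, float]:
    """Partial F and p-value for adding one variable (1 numerator df)."""
    gain = max(rss_reduced - rss_full, 0.0)
    # numerically exact fits: treat a vanishing residual as "nothing left to
    # explain" rather than infinitely significant noise-chasing
    tol = 1e-9 * max(rss_reduced, 1.0)
    if df_resid_full <= 0:
        return (math.inf, 0.0) if gain > tol else (0.0, 1.0)
    denom = rss_full / df_resid_full
    if denom <= tol:
        return (math.inf, 0.0) if gain > tol else (0.0, 1.0)
    f = gain / denom
    return f, float(stats.f.sf(f, 1, df_resid_full))


def stepwise_select(
    X: pd.DataFrame,
    y: Sequence[float],
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> SelectionResult:
    """Forward-entry / backward-removal stepwise OLS screen.

    ``X`` is the autoscaled descriptor matrix, ``y`` the autoscaled
    activities. Residual degrees of freedom account for the implicitly
    fitted intercept (the data are centered), i.e. a model with k
    variables on n rows has n - k - 1 residual df. Ties between equal
    p-values break toward the earlier column, making the screen fully
    deterministic. The screen stops when no action fires, when an entry
    would immediately re-enter the variable just removed (oscillation
    guard), or when the variable count reaches rows - 2 (logged via
    ``truncated``).

    Parameters mirror the conventional stepwise defaults: probability-of-F
    to enter 0.05 and to remove 0.10.
    """
    if X.shape[1] == 0:
        raise ValueError("empty descriptor matrix")
    n = len(X)
    yv = np.asarray(y, dtype=float)
    if len(yv) != n:
        raise ValueError("X and y have different numbers of rows")
    if n < 3:
        raise ValueError("need at least 3 rows for stepwise selection")
    if alpha_enter > alpha_remove:
        raise ValueError(
            f"significance-to-enter ({alpha_enter}) must not exceed "
            f"significance-to-remove ({alpha_remove})"
        )

    columns = list(X.columns)
    Xv = {c: X[c].to_numpy(dtype=float) for c in columns}
    selected: list[str] = []
    steps: list[StepRecord] = []
    truncated = False
    last_removed: str | None = None
    rss_current = float(yv @ yv)

    def design(cols: list[str]) -> np.ndarray:
        if not cols:
            return np.empty((n, 0))
        return np.column_stack([Xv[c] for c in cols])

    while True:
        acted = False
        # --- entry phase ---
        if len(selected) >= n - 2:
            truncated = True
        else:
            best: tuple[float, float, str] | None = None  # (p, f, var)
            df_full = n - (len(selected) + 1) - 1
            for c in columns:
                if c in selected:
                    continue
                rss_with = _rss(design(selected + [c]), yv)
                f, p = _partial_f(rss_current, rss_with, df_full)
                if best is None or p < best[0]:
                    best = (p, f, c)
            if best is not None and best[0] <= alpha_enter:
                p, f, var = best
                if var == last_removed:
                    break  # oscillation: would re-enter what was just removed
                selected.append(var)
                rss_current = _rss(design(selected), yv)
                steps.append(StepRecord("enter", var, f, p))
                acted = True

        # --- removal phase ---
        while len(selected) > 1:
            df_full = n - len(selected) - 1
            worst: tuple[float, float, str] | None = None
            for v in selected:
                others = [c for c in selected if c != v]
                rss_without = _rss(design(others), yv)
                f, p = _partial_f(rss_without, rss_current, df_full)
                if worst is None or p > worst[0]:
                    worst = (p, f, v)
            if worst is None or worst[0] < alpha_remove:
                break
            p, f, var = worst
            if steps and steps[-1].action == "enter" and steps[-1].variable == var:
                # entering and immediately removing the same variable:
                # classic stepwise livelock; undo and stop
                selected.remove(var)
                rss_current = _rss(design(selected), yv)
                steps.append(StepRecord("remove", var, f, p))
                return SelectionResult(
                    selected, steps, alpha_enter, alpha_remove, truncated=truncated
                )
            selected.remove(var)
            rss_current = _rss(design(selected), yv)
            steps.append(StepRecord("remove", var, f, p))
            last_removed = var
            acted = True

        if not acted or truncated:
            break

    return SelectionResult(selected, steps, alpha_enter, alpha_remove, truncated=truncated)


def vif(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors of each column regressed on the others.

    Input columns should be centered (autoscaled). Exact collinearity
    (r^2 = 1 within tolerance) is reported as ``inf``, never capped.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 variables")
    if len(X) <= len(cols):
        raise ValueError("VIF needs more rows than variables")
    out: dict[str, float] = {}
    for v in cols:
        target = X[v].to_numpy(dtype=float)
        target = target - target.mean()
        ss = float(target @ target)
        if ss <= 0:
            raise ValueError(f"column {v} is constant")
        others = np.column_stack(
            [X[c].to_numpy(dtype=float) - X[c].mean() for c in cols if c != v]
        )
        r2 = 1.0 - _rss(others, target) / ss
        out[v] = math.inf if 1.0 - r2 < 1e-12 else max(1.0 / (1.0 - r2), 1.0)
    return out


@dataclass(frozen=True)
class CollinearityReport:
    passed: bool
    vif_limit: float
    offenders: dict[str, float]


def check_selection(result: SelectionResult, vif_limit: float = 5.0) -> CollinearityReport:
    """Pass iff every recorded VIF is below ``vif_limit``; list offenders."""
    if not result.vifs:
        raise ValueError("SelectionResult has no VIFs; run vif() first")
    offenders = {v: value for v, value in result.vifs.items() if not value < vif_limit}
    return CollinearityReport(passed=not offenders, vif_limit=vif_limit, offenders=offenders)
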