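"""Error statistics for FD validation: MSE, MAE, MAE% and SEE.

Conventions (fixed here because the field's usage is loose):

* MSE is the *mean signed error*, ``mean(estimate - truth)`` — not the mean
  squared error.  Systematic underestimation therefore yields a negative MSE.
* MAE% averages per-observation absolute percent errors,
  ``mean(100 * |est - true| / true)`` — not MAE divided by the mean truth.
* SEE defaults to the RMSE about the ground truth, ``sqrt(sum(e^2) / n)``;
  the regression-convention ``n - 2`` denominator is available via
  ``see_ddof=2`` for comparability with regression-style reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .tolerance import FaceDepthModel, facial_height_change_pct


class ErrorMetrics(NamedTuple):
    mse_mm: float
    mae_mm: float
    mae_pct: float
    see_mm: float


@dataclass(frozen=True)
class ErrorSummary:
    """Grouped error statistics over (estimate, truth) pairs."""

    group_keys: dict
    n: int
    mse_mm: float
    mae_mm: float
    mae_pct: float
    see_mm: float


def error_metrics(
    estimates_mm: Sequence[float],
    truths_mm: Sequence[float],
    see_ddof: int = 0,
) -> ErrorMetrics:
    """Compute (MSE, MAE, MAE%, SEE) for paired estimates and ground truths."""
    est = np.asarray(estimates_mm, dtype=float)
    true = np.asarray(truths_mm, dtype=float)
    if est.shape != true.shape or est.ndim != 1 or est.size == 0:
        raise ConfigError("estimates and truths must be equal-length non-empty 1-D")
    if not np.all(true > 0):
        raise ConfigError("ground-truth distances must be > 0")
    if see_ddof not in (0, 2):
        raise ConfigError("see_ddof must be 0 (RMSE form) or 2 (regression form)")
    if see_ddof and est.size <= see_ddof:
        raise ConfigError(f"need n > {see_ddof} observations for see_ddof={see_ddof}")
    err = est - true
    return ErrorMetrics(
        mse_mm=float(np.mean(err)),
        mae_mm=float(np.mean(np.abs(err))),
        mae_pct=float(np.mean(100.0 * np.abs(err) / true)),
        see_mm=float(np.sqrt(np.sum(err**2) / (est.size - see_ddof))),
    )


def summarize(
    table: pd.DataFrame,
    group_by: Optional[Sequence[str]] = None,
    est_col: str = "fd_est_mm",
    true_col: str = "fd_true_mm",
    see_ddof: int = 0,
) -> pd.DataFrame:
    """Grouped error summary table, one row per group in deterministic order.

    ``group_by`` may be any subset of the table's columns (camera, lens
    label, view, distance, ...); ``None`` summarises the whole table as a
    single group.
    """
    for col in (est_col, true_col):
        if col not in table.columns:
            raise ConfigError(f"summary input lacks required column {col!r}")
    keys = list(group_by or [])
    for key in keys:
        if key not in table.columns:
            raise ConfigError(f"unknown group key {key!r}")

    def _one(df: pd.DataFrame) -> dict:
        m = error_metrics(df[est_col].to_numpy(), df[true_col].to_numpy(), see_ddof)
        return {"n": len(df), **m._asdict()}

    if not keys:
        out = pd.DataFrame([_one(table)])
    else:
        records = []
        for key_vals, df in table.groupby(keys, sort=True, dropna=False):
            if not isinstance(key_vals, tuple):
                key_vals = (key_vals,)
            records.append({**dict(zip(keys, key_vals)), **_one(df)})
        out = pd.DataFrame(records)
    out["n"] = out["n"].astype(int)
    return out


def tolerance_table(
    table: pd.DataFrame,
    depth_model: FaceDepthModel,
    threshold_pct: float = 1.0,
    group_by: Sequence[str] = ("camera_name", "fd_true_mm"),
    est_col: str = "fd_est_mm",
    true_col: str = "fd_true_mm",
) -> pd.DataFrame:
    """Per-group perspective-tolerance grid: pass fraction and all-pass flag.

    Every group is emitted, including all-pass ones, so the output is a
    complete grid over the grouping keys.
    """
    for col in (est_col, true_col):
        if col not in table.columns:
            raise ConfigError(f"tolerance input lacks required column {col!r}")
    keys = list(group_by)
    for key in keys:
        if key not in table.columns:
            raise ConfigError(f"unknown group key {key!r}")
    work = table.copy()
    work["_pass"] = [
        facial_height_change_pct(t, e, depth_model) <= threshold_pct
        for e, t in zip(work[est_col], work[true_col])
    ]
    out = (
        work.groupby(keys, sort=True, dropna=False)["_pass"]
        .agg(n="size", pass_fraction="mean", all_pass="all")
        .reset_index()
    )
    out["pass_fraction"] = out["pass_fraction"].astype(float)
    out["all_pass"] = out["all_pass"].astype(bool)
    return out


def plot_signed_error(
    summary: pd.DataFrame,
    out_path,
    series_col: str = "camera_name",
    distance_col: str = "fd_true_mm",
    value_col: str = "mse_mm",
) -> None:
    """Signed-error-vs-distance plot, one line per camera/lens series."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for name, grp in summary.groupby(series_col):
        grp = grp.sort_values(distance_col)
        ax.plot(grp[distance_col] / 1000.0, grp[value_col], marker="o", label=str(name))
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("ground-truth focus distance (m)")
    ax.set_ylabel(f"{value_col} (mm)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
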