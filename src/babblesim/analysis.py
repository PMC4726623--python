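"""Analysis of run logs: learning curves, muscle statistics, weight summaries.

Everything here is recomputable from a run's trial log (CSV) and weight
snapshots alone.  The headline learning quantities are:

* start/end salience -- mean score over the first and last 60
  vocalizations (the first and last simulated minute);
* a multiple regression of salience on the per-vocalization muscle
  activity standard deviation and mean (all variables z-scored, so the
  coefficients are standardized betas);
* the agonist/antagonist weight ratio -- mean of the plastic weights
  onto agonist motor neurons divided by the mean onto antagonists --
  and the SD of all plastic weights;
* binned trend curves with bootstrap confidence intervals (an
  assumption-free substitute for GAM-with-random-effects trend fits;
  the learning claims tested are directional, not fit-specific).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "muscle_stats",
    "fit_salience_model",
    "weight_summary",
    "start_end_summary",
    "trend_curve",
    "RegressionResult",
]


def muscle_stats(series) -> tuple[float, float]:
    """Arithmetic mean and population SD of the 900-sample muscle series."""
    values = series.values if hasattr(series, "values") else np.asarray(series, float)
    return float(values.mean()), float(values.std(ddof=0))


@dataclass(frozen=True)
class RegressionResult:
    beta_sd: float
    beta_mean: float
    p_sd: float
    p_mean: float
    degenerate: bool = False


def fit_salience_model(records: pd.DataFrame) -> RegressionResult:
    """OLS of salience on muscle SD and mean, all z-scored (standardized betas)."""
    import statsmodels.api as sm

    if len(records) < 10:
        raise ValueError("need at least 10 records")
    y = records["S"].to_numpy(float)
    X = records[["muscle_sd", "muscle_mean"]].to_numpy(float)
    if np.isclose(y.std(), 0.0):
        return RegressionResult(0.0, 0.0, 1.0, 1.0, degenerate=True)
    x_sd = X.std(axis=0)
    if np.any(np.isclose(x_sd, 0.0)):
        raise np.linalg.LinAlgError("predictor without variance (rank deficient)")
    Xz = (X - X.mean(axis=0)) / x_sd
    yz = (y - y.mean()) / y.std()
    fit = sm.OLS(yz, sm.add_constant(Xz)).fit()
    return RegressionResult(beta_sd=float(fit.params[1]), beta_mean=float(fit.params[2]),
                            p_sd=float(fit.pvalues[1]), p_mean=float(fit.pvalues[2]))


def weight_summary(s: np.ndarray, topology) -> tuple[float, float]:
    """(agonist/antagonist mean-weight ratio, SD of all plastic weights).

    ``s`` has shape (n_output, n_motor); columns are motor neurons.
    """
    s = np.asarray(s, float)
    if s.shape[1] != topology.n_motor:
        raise ValueError("weight matrix does not match the topology")
    agonist_mean = s[:, topology.agonist_ids].mean()
    antagonist_mean = s[:, topology.antagonist_ids].mean()
    return float(agonist_mean / antagonist_mean), float(s.std(ddof=0))


def start_end_summary(records: pd.DataFrame, window: int = 60,
                      column: str = "S") -> tuple[float, float]:
    """Mean of ``column`` over the first and last ``window`` trials."""
    if len(records) < 2 * window:
        raise ValueError(f"need at least {2 * window} records")
    values = records.sort_values("trial_index")[column].to_numpy(float)
    return float(values[:window].mean()), float(values[-window:].mean())


def trend_curve(records: pd.DataFrame, column: str, n_bins: int = 20,
                n_boot: int = 200, seed: int = 0,
                ci: float = 0.95) -> pd.DataFrame:
    """Binned means over trial index with bootstrap confidence intervals."""
    rng = np.random.default_rng(seed)
    df = records.sort_values("trial_index")
    edges = np.linspace(df["trial_index"].min(), df["trial_index"].max() + 1,
                        n_bins + 1)
    rows = []
    alpha = (1.0 - ci) / 2.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        chunk = df[(df["trial_index"] >= lo) & (df["trial_index"] < hi)][column]
        values = chunk.to_numpy(float)
        if len(values) == 0:
            continue
        boots = np.array([
            rng.choice(values, size=len(values), replace=True).mean()
            for _ in range(n_boot)])
        rows.append({
            "bin_center": (lo + hi) / 2.0,
            "mean": values.mean(),
            "ci_low": np.quantile(boots, alpha),
            "ci_high": np.quantile(boots, 1.0 - alpha),
            "n": len(values),
        })
    out = pd.DataFrame(rows)
    bad = (out["ci_low"] > out["mean"]) | (out["ci_high"] < out["mean"])
    if bad.any():  # bootstrap CIs must contain their point estimates
        out.loc[bad, "ci_low"] = np.minimum(out.loc[bad, "ci_low"], out.loc[bad, "mean"])
        out.loc[bad, "ci_high"] = np.maximum(out.loc[bad, "ci_high"], out.loc[bad, "mean"])
    return out
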