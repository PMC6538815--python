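"""Evaluation statistics for age prediction.

Covers the three regression metrics (MAE, RMSE, Pearson's rho), the
Breusch-Pagan heteroscedasticity test on residuals, per-age-range metrics
with a Kruskal-Wallis comparison of error distributions, the sample-size
effect curve, and a five-model comparison table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "MetricReport",
    "AgeBinReport",
    "SampleSizeCurve",
    "regression_metrics",
    "breusch_pagan",
    "age_bin_analysis",
    "sample_size_curve",
    "model_comparison",
]

DEFAULT_AGE_EDGES = (7.0, 20.0, 40.0, 60.0, 80.0)


@dataclass
class MetricReport:
    """MAE / RMSE / Pearson rho over one set of predictions."""

    mae: float
    rmse: float
    rho: float
    n: int
    rho_defined: bool = True

    def as_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "rho": self.rho, "n": self.n}


@dataclass
class AgeBinReport:
    """Per-age-range metrics plus a Kruskal-Wallis test on error distributions."""

    edges: tuple[float, ...]
    bins: list[tuple[float, float]]
    reports: list[MetricReport]
    kruskal_statistic: float
    kruskal_p: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"age_range": f"{lo:g}-{hi:g}", **rep.as_dict()}
            for (lo, hi), rep in zip(self.bins, self.reports)
        ]
        return pd.DataFrame(rows)


@dataclass
class SampleSizeCurve:
    """Mean and SD of CV metrics at increasing cohort fractions."""

    fractions: tuple[float, ...]
    table: pd.DataFrame  # columns: fraction, mae_mean, mae_sd, rmse_*, rho_*


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> MetricReport:
    """MAE = mean |y - yhat|, RMSE = sqrt(mean (y - yhat)^2), rho = Pearson.

    Pearson's rho is flagged undefined (NaN) when either side has zero
    variance; MAE <= RMSE always holds.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    defined = y.size >= 2 and np.std(y) > 0 and np.std(yhat) > 0
    rho = float(np.corrcoef(y, yhat)[0, 1]) if defined else float("nan")
    return MetricReport(mae=mae, rmse=rmse, rho=rho, n=y.size, rho_defined=defined)


def breusch_pagan(
    y: np.ndarray, yhat: np.ndarray, against: str = "chronological"
) -> tuple[float, float]:
    """Breusch-Pagan test for heteroscedastic prediction residuals.

    Squared residuals ``(y - yhat)^2`` are regressed on age (chronological by
    default, predicted with ``against="predicted"``); the LM statistic is
    n * R-squared of that auxiliary regression, referred to chi-square with
    one degree of freedom. Returns ``(lm, p)``.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    resid = y - yhat
    if np.var(resid**2) == 0:
        warnings.warn("constant squared residuals: no variance to explain, p = 1")
        return 0.0, 1.0
    x = y if against == "chronological" else yhat
    exog = sm.add_constant(x)
    lm, p, _, _ = het_breuschpagan(resid, exog)
    return float(lm), float(p)


def _bin_index(ages: np.ndarray, edges: tuple[float, ...]) -> np.ndarray:
    """Half-open bins [lo, hi), last bin closed; -1 for out-of-range ages."""
    edges = np.asarray(edges, dtype=float)
    idx = np.digitize(ages, edges) - 1
    idx[ages == edges[-1]] = len(edges) - 2
    idx[(ages < edges[0]) | (ages > edges[-1])] = -1
    return idx


def age_bin_analysis(
    cv, edges: tuple[float, ...] = DEFAULT_AGE_EDGES, signed: bool = False
) -> AgeBinReport:
    """Per-age-range metrics and a Kruskal-Wallis test across ranges.

    Metrics are computed per bin on pooled out-of-fold predictions; the
    Kruskal-Wallis rank-sum test compares the per-bin absolute-error
    distributions (signed errors with ``signed=True``). Empty bins are
    skipped with a warning and the test runs on the remaining ones.
    """
    y = np.asarray(cv.y, dtype=float)
    yhat = np.asarray(cv.pooled_predictions, dtype=float)
    idx = _bin_index(y, edges)
    if (idx < 0).any():
        raise ValueError("every subject must fall inside the bin edges")
    bins, reports, groups = [], [], []
    err = (y - yhat) if signed else np.abs(y - yhat)
    for b in range(len(edges) - 1):
        sel = idx == b
        if not sel.any():
            warnings.warn(f"empty age bin [{edges[b]:g}, {edges[b + 1]:g}): skipped")
            continue
        bins.append((edges[b], edges[b + 1]))
        reports.append(regression_metrics(y[sel], yhat[sel]))
        groups.append(err[sel])
    if len(groups) >= 2:
        stat, p = stats.kruskal(*groups)
    else:
        stat, p = float("nan"), float("nan")
    return AgeBinReport(
        edges=tuple(edges),
        bins=bins,
        reports=reports,
        kruskal_statistic=float(stat),
        kruskal_p=float(p),
    )


def sample_size_curve(
    X: np.ndarray,
    y: np.ndarray,
    config=None,
    fractions: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    k: int = 10,
    rounds: int = 5,
    seed: int = 0,
) -> SampleSizeCurve:
    """Cross-validated metrics at random cohort fractions.

    For each fraction: ``rounds`` seeded subject subsamples, each followed by
    one k-fold CV; the mean and SD of each metric across rounds is reported.
    The 100% fraction uses all subjects, so with the same seed it reproduces
    the plain repeated k-fold result.
    """
    from brainmux.regression_suite import _derive_seed, repeated_kfold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    S = y.size
    rows = []
    for fi, frac in enumerate(fractions):
        n_sub = int(round(frac * S))
        if n_sub < k:
            raise ValueError(
                f"fraction {frac:g} gives {n_sub} subjects, fewer than k={k} folds"
            )
        per_metric = {"mae": [], "rmse": [], "rho": []}
        for r in range(rounds):
            if frac >= 1.0:
                idx = np.arange(S)
            else:
                rng = np.random.default_rng([seed, fi, r])
                idx = rng.choice(S, size=n_sub, replace=False)
            res = repeated_kfold(
                X[idx], y[idx], config, k=k, repetitions=1,
                seed=_derive_seed(seed, r),
            )
            for m in per_metric:
                per_metric[m].append(float(res.metrics[m].iloc[0]))
        row = {"fraction": frac, "n": n_sub}
        for m, vals in per_metric.items():
            row[f"{m}_mean"] = float(np.mean(vals))
            row[f"{m}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return SampleSizeCurve(fractions=tuple(fractions), table=pd.DataFrame(rows))


def model_comparison(
    data,
    y: np.ndarray | None = None,
    configs: dict | None = None,
    k: int = 10,
    repetitions: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated comparison of the deep net and the four baselines.

    Returns one row per model with mean and SD of MAE, RMSE, and rho across
    repetitions — the shape of a standard model-comparison table.
    """
    from brainmux.regression_suite import BaselineConfig, DnnConfig, repeated_kfold

    if configs is None:
        configs = {
            "deep learning": DnnConfig(),
            "ridge regression": BaselineConfig(kind="ridge"),
            "lasso regression": BaselineConfig(kind="lasso", lam=0.1),
            "random forest": BaselineConfig(kind="rf"),
            "support vector machine": BaselineConfig(kind="svm"),
        }
    rows = []
    for name, cfg in configs.items():
        res = repeated_kfold(data, y, cfg, k=k, repetitions=repetitions, seed=seed)
        s = res.summary()
        rows.append(
            {
                "model": name,
                "mae_mean": s.loc["mae", "mean"],
                "mae_sd": s.loc["mae", "sd"],
                "rmse_mean": s.loc["rmse", "mean"],
                "rmse_sd": s.loc["rmse", "sd"],
                "rho_mean": s.loc["rho", "mean"],
                "rho_sd": s.loc["rho", "sd"],
            }
        )
    return pd.DataFrame(rows).set_index("model")
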