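"""Cluster-aware interval estimation.

The inferential unit is the home local authority: the bootstrap resamples
whole clusters with replacement (same number of clusters as observed),
re-labels repeated clusters so they stay distinct, and re-runs the entire
estimation chain — propensity model included — inside each replicate.
Percentile intervals are the default.  A sandwich cluster-robust SE is also
provided for single model fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd


@dataclass
class BootstrapResult:
    replicates: pd.DataFrame  # one column per named estimate
    point: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    se: pd.Series
    n_failed: int
    seed: Optional[int]
    B: int

    def ci(self, name: str) -> tuple[float, float]:
        return float(self.ci_low[name]), float(self.ci_high[name])


def resample_clusters(
    table: pd.DataFrame, rng: np.random.Generator, cluster_col: str = "cluster_id"
) -> pd.DataFrame:
    """One cluster-bootstrap replicate of ``table``.

    Draws G clusters with replacement and concatenates their pupils,
    relabelling each draw as a fresh cluster id so a cluster sampled twice
    contributes two distinct clusters downstream.
    """
    groups = table.groupby(cluster_col).indices  # positional row indices
    cids = list(groups)
    draws = rng.choice(len(cids), size=len(cids), replace=True)
    parts, labels = [], []
    for new_id, j in enumerate(draws):
        idx = groups[cids[j]]
        parts.append(idx)
        labels.append(np.full(len(idx), new_id))
    out = table.iloc[np.concatenate(parts)].copy()
    out[cluster_col] = np.concatenate(labels)
    return out.reset_index(drop=True)


def cluster_bootstrap(
    table: pd.DataFrame,
    estimator: Callable[[pd.DataFrame], Union[float, dict, pd.Series]],
    B: int = 1000,
    seed: Optional[int] = None,
    cluster_col: str = "cluster_id",
    alpha: float = 0.05,
    max_fail_frac: float = 0.05,
) -> BootstrapResult:
    """Percentile cluster bootstrap of an arbitrary estimation chain.

    ``estimator`` maps a table to a number or a named collection of
    numbers and is re-run from scratch on every replicate.  Replicates that
    raise are logged and dropped; more than ``max_fail_frac`` failures is a
    hard error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")

    def _as_series(v) -> pd.Series:
        if isinstance(v, pd.Series):
            return v.astype(float)
        if isinstance(v, dict):
            return pd.Series(v, dtype=float)
        return pd.Series({"estimate": float(v)})

    point = _as_series(estimator(table))
    rng = np.random.default_rng(seed)
    reps, n_failed = [], 0
    for _ in range(B):
        rep_table = resample_clusters(table, rng, cluster_col=cluster_col)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reps.append(_as_series(estimator(rep_table)))
        except Exception:  # noqa: BLE001 - replicate failure is data, not a bug
            n_failed += 1
    if n_failed > max_fail_frac * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed (> {max_fail_frac:.0%})"
        )
    rep_df = pd.DataFrame(reps).reset_index(drop=True)
    # order statistics (no interpolation) so ratio CIs computed on the log
    # scale exponentiate to exactly the same interval
    lo = rep_df.quantile(alpha / 2, interpolation="lower")
    hi = rep_df.quantile(1 - alpha / 2, interpolation="higher")
    se = rep_df.std(ddof=1)
    return BootstrapResult(
        replicates=rep_df, point=point, ci_low=lo, ci_high=hi, se=se,
        n_failed=n_failed, seed=seed, B=B,
    )


def cluster_robust_se(model_result, cluster_ids) -> pd.Series:
    """Cluster-sandwich standard errors for a fitted statsmodels result.

    Aggregates score contributions by cluster with the usual G/(G-1)
    small-sample factor; with singleton clusters this reduces to the
    heteroskedasticity-robust SE.
    """
    groups = pd.Series(np.asarray(cluster_ids))
    if groups.nunique() < 2:
        raise ValueError("need at least two clusters")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        robust = model_result.get_robustcov_results(
            cov_type="cluster", groups=groups.to_numpy(), use_correction=True
        )
    names = model_result.params.index if hasattr(model_result.params, "index") else None
    return pd.Series(np.asarray(robust.bse), index=names)
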