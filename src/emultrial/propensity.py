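"""Pairwise propensity-score models, overlap diagnostics, positivity gating.

Each treatment contrast (exposed level, reference level) restricts the
cohort to its two arms; a binary logistic model of exposed-vs-reference on
the MCIM confounder design (continuous terms linear + quadratic) yields the
propensity scores.  Overlap is summarised per PS decile and gated: a decile
well populated by one arm but empty in the other fails positivity, in which
case the contrast is refused rather than extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import CovariateSpec, build_design, drop_collinear


class SeparationError(RuntimeError):
    """Logistic fit separated; names the suspicious covariate columns."""


@dataclass(frozen=True)
class TreatmentContrast:
    exposed: str
    reference: str

    def __str__(self) -> str:
        return f"{self.exposed} vs {self.reference}"


@dataclass
class PropensityResult:
    contrast: TreatmentContrast
    ps: pd.Series  # indexed like the two-arm subset
    exposed_indicator: pd.Series
    model_result: object
    design_columns: list[str]
    winsorised: bool = False
    dropped_columns: list[str] = field(default_factory=list)

    def overlap(self, n_bins: int = 10) -> pd.DataFrame:
        return overlap_summary(self, n_bins=n_bins)


def subset_contrast(table: pd.DataFrame, contrast: TreatmentContrast) -> pd.DataFrame:
    """Rows observed in one of the two compared arms, in original order."""
    mask = table["treatment"].isin([contrast.exposed, contrast.reference])
    if not mask.any():
        raise ValueError(f"no pupils in arms of contrast {contrast}")
    sub = table[mask].copy()
    for arm in (contrast.exposed, contrast.reference):
        if not (sub["treatment"] == arm).any():
            raise ValueError(f"arm {arm!r} empty for contrast {contrast}")
    return sub


def fit_ps_model(
    table: pd.DataFrame,
    contrast: TreatmentContrast,
    spec: Optional[CovariateSpec] = None,
    quadratic: bool = True,
    design: Optional[pd.DataFrame] = None,
    winsorise: Optional[tuple[float, float]] = None,
) -> PropensityResult:
    """Binary logistic PS model on the arm-restricted subset.

    ``design=None`` builds the full MCIM confounder design; pass an explicit
    design (e.g. intercept-only) for deliberately misspecified models.
    ``winsorise=(lo, hi)`` optionally clips the fitted PS at those
    percentiles (off by default; no trimming is applied otherwise).
    """
    sub = subset_contrast(table, contrast)
    y = (sub["treatment"] == contrast.exposed).astype(float)
    if design is None:
        X = build_design(sub, spec=spec, quadratic=quadratic)
    else:
        X = design.loc[sub.index]
    X = drop_collinear(X)
    # rare dummy levels present in only one arm have no finite log-odds;
    # drop them (their pupils keep all other covariates) instead of letting
    # a handful of cells separate the fit
    dropped: list[str] = []
    yv = y.to_numpy()
    for col in list(X.columns):
        v = X[col].to_numpy()
        ones = v == 1.0
        if not np.array_equal(np.unique(v), np.array([0.0, 1.0])):
            continue
        n_ones = int(ones.sum())
        if n_ones < max(20, 0.005 * len(X)) and (
            yv[ones].sum() == 0 or yv[ones].sum() == n_ones
        ):
            dropped.append(col)
    if dropped:
        warnings.warn(
            "dropping sparse single-arm PS design columns: " + ", ".join(dropped)
        )
        X = X.drop(columns=dropped)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=200, wls_method="qr")
        except Exception as exc:  # noqa: BLE001 - diagnose then re-raise
            raise SeparationError(f"PS model failed for {contrast}: {exc}") from exc
    # scale-aware separation check: a coefficient is suspicious when one
    # SD of its covariate moves the linear predictor by > 15 logits
    sds = X.std(ddof=0)
    offenders = [
        c
        for c in X.columns
        if c != "const" and sds[c] > 0 and abs(res.params[c]) * sds[c] > 15.0
    ]
    if offenders:
        raise SeparationError(
            "possible separation in PS model; offending covariates: "
            + ", ".join(offenders)
        )
    ps = pd.Series(np.asarray(res.fittedvalues), index=sub.index, name="ps")
    winsorised = False
    if winsorise is not None:
        lo, hi = np.percentile(ps, winsorise)
        ps = ps.clip(lo, hi)
        winsorised = True
    eps = 1e-12
    ps = ps.clip(eps, 1 - eps)
    return PropensityResult(
        contrast=contrast,
        ps=ps,
        exposed_indicator=y.astype(int),
        model_result=res,
        design_columns=list(X.columns),
        winsorised=winsorised,
        dropped_columns=dropped,
    )


def overlap_summary(ps_result: PropensityResult, n_bins: int = 10) -> pd.DataFrame:
    """Counts per PS decile (fixed [0,1] bins) and arm, plus range rows."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    ps = ps_result.ps.to_numpy()
    a = ps_result.exposed_indicator.to_numpy()
    bin_idx = np.clip(np.digitize(ps, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        rows.append(
            {
                "bin": f"[{edges[b]:.1f},{edges[b + 1]:.1f})",
                "lo": edges[b],
                "hi": edges[b + 1],
                "n_reference": int(np.sum((bin_idx == b) & (a == 0))),
                "n_exposed": int(np.sum((bin_idx == b) & (a == 1))),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["ps_min"] = {
        "reference": float(ps[a == 0].min()),
        "exposed": float(ps[a == 1].min()),
    }
    out.attrs["ps_max"] = {
        "reference": float(ps[a == 0].max()),
        "exposed": float(ps[a == 1].max()),
    }
    out.attrs["shared_support"] = (
        float(max(ps[a == 0].min(), ps[a == 1].min())),
        float(min(ps[a == 0].max(), ps[a == 1].max())),
    )
    return out


def positivity_check(
    overlap_table: pd.DataFrame,
    min_per_cell: int = 5,
    max_unsupported_frac: float = 0.05,
    sparse_share: float = 0.002,
) -> str:
    """``pass`` / ``warn`` / ``fail`` positivity gate on the decile table.

    A decile is *unsupported* for an arm when the other arm holds less
    than ``sparse_share`` of its pupils there (an empty cross-arm cell is
    the extreme case) despite having at least ``min_per_cell`` pupils
    overall.  The gate fails when more than ``max_unsupported_frac`` of
    either arm's pupils sit in unsupported deciles — the automated,
    sample-size-stable stand-in for judging "very poor overlap" from the
    plotted PS densities; 2-5 % of unsupported mass warns.
    """
    nr = overlap_table["n_reference"].to_numpy(dtype=float)
    ne = overlap_table["n_exposed"].to_numpy(dtype=float)
    status = "pass"
    for a, b in ((nr, ne), (ne, nr)):
        if a.sum() == 0 or b.sum() < min_per_cell:
            return "fail"
        sparse = b / b.sum() < sparse_share
        if np.any(sparse & (a > 0)):
            frac = a[sparse].sum() / a.sum()
            if frac > max_unsupported_frac:
                return "fail"
            if frac > 0.02:
                status = "warn"
    return status


# ---------------------------------------------------------------------------
# Post-lasso nuisance selection
# ---------------------------------------------------------------------------

_FAMILIES = {
    "logistic": sm.families.Binomial,
    "poisson": sm.families.Poisson,
    "gaussian": sm.families.Gaussian,
}


def lasso_select(
    design: pd.DataFrame,
    response,
    family: str = "logistic",
    n_folds: int = 10,
    seed: Optional[int] = None,
    forced: Sequence[str] = ("const",),
    offset=None,
    n_alphas: int = 12,
) -> dict:
    """Cross-validated L1 selection; returns the surviving covariate set.

    Columns are standardised internally; ``forced`` columns (intercept and,
    for outcome models, the treatment indicator) carry zero penalty and are
    always retained.  The penalty is chosen at minimum mean out-of-fold
    deviance over a log-spaced grid; an all-zero selection falls back to the
    forced set with a warning.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown lasso family {family!r}")
    y = np.asarray(response, dtype=float)
    X = design.copy()
    scale = X.std(ddof=0).replace(0.0, 1.0)
    keep_scale = {c: 1.0 for c in forced if c in X}
    for c in keep_scale:
        scale[c] = 1.0
    Xs = X / scale
    fam = _FAMILIES[family]()
    penalise = np.array([0.0 if c in forced else 1.0 for c in X.columns])

    # alpha_max: smallest penalty zeroing every penalised coefficient
    mu0 = np.full_like(y, y.mean()) if family != "logistic" else np.full_like(y, y.mean())
    resid = y - mu0
    grad = np.abs(Xs.to_numpy().T @ resid) / len(y)
    amax = max(grad[penalise > 0].max(), 1e-6) * 1.1
    alphas = np.logspace(np.log10(amax), np.log10(amax * 1e-3), n_alphas)

    rng = np.random.default_rng(seed)
    fold = rng.integers(0, n_folds, size=len(y))
    offs = None if offset is None else np.asarray(offset, dtype=float)

    def _fit(Xa, ya, off, alpha, start=None):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = sm.GLM(ya, Xa, family=fam, offset=off)
            return m.fit_regularized(
                alpha=alpha * penalise, L1_wt=1.0, maxiter=100,
                start_params=start, cnvrg_tol=1e-7,
            )

    # warm-start down the penalty path within each fold
    mean_dev = np.zeros(len(alphas))
    for f in range(n_folds):
        tr, te = fold != f, fold == f
        start = None
        for i, alpha in enumerate(alphas):
            res = _fit(Xs[tr], y[tr], None if offs is None else offs[tr], alpha, start)
            start = np.asarray(res.params)
            eta = Xs[te].to_numpy() @ start
            if offs is not None:
                eta = eta + offs[te]
            mu = fam.link.inverse(eta)
            mean_dev[i] += fam.deviance(y[te], mu)
    mean_dev /= len(y)
    best_alpha = float(alphas[int(np.argmin(mean_dev))])

    start = None
    for alpha in alphas:
        res = _fit(Xs, y, offs, alpha, start)
        start = np.asarray(res.params)
        if alpha <= best_alpha:
            break
    coefs = pd.Series(np.asarray(res.params), index=X.columns)
    selected = [
        c for c in X.columns if c in forced or abs(coefs[c]) > 1e-8
    ]
    if set(selected) <= set(forced) and len(selected) == len([c for c in forced if c in X]):
        warnings.warn("lasso selected no covariates; falling back to forced terms")
    return {
        "selected": selected,
        "alpha": best_alpha,
        "cv_deviance": np.asarray(mean_dev),
        "alphas": alphas,
    }
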