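"""Model design matrices on the missing-covariate-indicator parameterisation.

One place defines which covariates are categorical (entering as full dummy
sets with an explicit ``Unknown`` level where maskable) and which are
continuous (entering linear + quadratic, zero-filled with a paired
missingness indicator).  Both the propensity and the outcome models build
their matrices here, so every fit sees the same confounder surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: categorical confounders: column -> (reference level, maskable)
CATEGORICAL: dict[str, tuple[str, bool]] = {
    "gender": ("Female", False),
    "gest_age": ("39 weeks or more", True),
    "birthweight": ("2500g-3499g", True),
    "maternal_age": ("25-29", True),
    "ethnic_group": ("White", False),
    "language": ("English", False),
    "idaci_quintile": ("3.0", True),
    "academic_year": ("2008.0", False),
    "cleft_type": ("Cleft lip only", False),
}

#: numeric 0/1 confounders entering as-is
BINARY: tuple[str, ...] = ("fsm", "chronic_any", "chronic_mental", "nursery")

#: continuous confounders: column -> maskable
CONTINUOUS: dict[str, bool] = {
    "eyfsp_z": True,
    "relative_age_months": False,
    "prior_hosp_rate": False,
    "school_sen_prop": False,
    "school_fsm_prop": False,
}

#: transforms applied to continuous covariates before entering models
#: (skewed nonnegative rates enter on the log scale)
CONTINUOUS_TRANSFORMS = {"prior_hosp_rate": np.log1p}


@dataclass
class CovariateSpec:
    categorical: dict[str, tuple[str, bool]] = field(default_factory=lambda: dict(CATEGORICAL))
    binary: Sequence[str] = BINARY
    continuous: dict[str, bool] = field(default_factory=lambda: dict(CONTINUOUS))

    def names(self) -> list[str]:
        return list(self.categorical) + list(self.binary) + list(self.continuous)

    def maskable(self) -> list[str]:
        return [c for c, (_, m) in self.categorical.items() if m] + [
            c for c, m in self.continuous.items() if m
        ]


DEFAULT_SPEC = CovariateSpec()


def build_design(
    table: pd.DataFrame,
    spec: Optional[CovariateSpec] = None,
    quadratic: bool = True,
    add_const: bool = True,
) -> pd.DataFrame:
    """MCIM design matrix for the confounders of ``table``.

    Categorical maskable covariates contribute an ``Unknown`` dummy;
    continuous maskable covariates are zero-filled and paired with a
    ``*_miss`` indicator.  ``quadratic=True`` adds squared terms for the
    continuous covariates (the propensity-model convention).
    """
    spec = spec or DEFAULT_SPEC
    cols: dict[str, np.ndarray] = {}
    if add_const:
        cols["const"] = np.ones(len(table))
    for name, (ref, maskable) in spec.categorical.items():
        raw = table[name]
        flag_col = f"miss_{name}"
        miss = raw.isna().to_numpy()
        if flag_col in table:
            miss = miss | table[flag_col].astype(bool).to_numpy()
        vals = raw.astype(object).where(~miss, other="Unknown")
        vals = vals.map(_level_str)
        levels = sorted({v for v in vals if v != "Unknown"})
        for lev in levels:
            if lev == ref:
                continue
            cols[f"{name}[{lev}]"] = (vals == lev).to_numpy(dtype=float)
        if maskable:
            cols[f"{name}[Unknown]"] = miss.astype(float)
    for name in spec.binary:
        cols[name] = table[name].astype(float).to_numpy()
    for name, maskable in spec.continuous.items():
        raw = table[name].astype(float)
        if name in CONTINUOUS_TRANSFORMS:
            raw = CONTINUOUS_TRANSFORMS[name](raw)
        flag_col = f"miss_{name}"
        miss = raw.isna().to_numpy()
        if flag_col in table:
            miss = miss | table[flag_col].astype(bool).to_numpy()
        filled = raw.fillna(0.0).to_numpy()
        filled = np.where(miss, 0.0, filled)
        cols[name] = filled
        if quadratic:
            cols[f"{name}_sq"] = filled**2
        if maskable:
            cols[f"{name}_miss"] = miss.astype(float)
    X = pd.DataFrame(cols, index=table.index)
    return X


def _level_str(v) -> str:
    # numeric-coded categorical levels (e.g. IDACI quintiles, years) print
    # identically whether they arrive as int, float or string
    if isinstance(v, (int, np.integer)):
        return str(float(v))
    return str(v)


def drop_collinear(X: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    """Drop columns (near-)collinear with earlier ones.

    Works on the Gram matrix, so the cost is O(n k^2 + k^3) with a small
    constant; earlier columns win ties, keeping the intercept and treatment
    terms when dummies sum to them.
    """
    arr = X.to_numpy(dtype=float)
    G = arr.T @ arr
    k = G.shape[0]
    scale = float(np.max(np.diag(G)))
    keep: list[int] = []
    for j in range(k):
        gjj = G[j, j]
        if gjj <= tol * scale:
            continue
        if keep:
            Gkk = G[np.ix_(keep, keep)]
            gj = G[np.ix_(keep, [j])]
            sol = np.linalg.solve(Gkk + np.eye(len(keep)) * (1e-12 * scale), gj)
            resid = gjj - float((gj.T @ sol).item())
            if resid <= tol * max(gjj, tol * scale):
                continue
        keep.append(j)
    return X.iloc[:, keep]
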