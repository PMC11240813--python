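"""Linear models, a random-intercept mixed model, and chi-square tests.

The fixed-effect machinery uses treatment (dummy) coding against declared
reference levels and solves least squares through a QR decomposition.
The mixed model is restricted maximum likelihood with one random
intercept, profiled down to a one-dimensional search over the variance
ratio; fixed-effect t-tests use residual degrees of freedom (a documented
simplification of Satterthwaite's approximation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps


@dataclass
class ModelSpec:
    """Declarative model description.

    ``factors`` maps factor column -> reference level (e.g. hierarchy ->
    "dominant", treatment -> "control"); ``covariates`` are continuous
    columns entered as-is; ``interactions`` is a list of factor-column
    pairs whose dummy products are added.
    """

    response: str
    factors: dict[str, str] = field(default_factory=dict)
    covariates: list[str] = field(default_factory=list)
    random_intercept: str | None = None
    interactions: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class FitResult:
    table: pd.DataFrame  # term, estimate, se, t, df, p
    n: int
    method: str
    sigma2: float
    extra: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Design matrix with intercept, reference-coded dummies, covariates
    and (optionally) factor-by-factor interaction columns.

    Rows with missing response or predictors are dropped (logged by the
    count in the returned frame's attrs).
    """
    used = [spec.response, *spec.factors, *spec.covariates]
    if spec.random_intercept:
        used.append(spec.random_intercept)
    df = data[used].dropna().reset_index(drop=True)
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["Intercept"]
    dummies: dict[str, dict[str, np.ndarray]] = {}
    for factor, ref in spec.factors.items():
        levels = sorted(map(str, df[factor].unique()))
        if str(ref) not in levels:
            raise ValueError(f"reference level {ref!r} absent from factor {factor!r}")
        dummies[factor] = {}
        for lvl in levels:
            if lvl == str(ref):
                continue
            col = (df[factor].astype(str) == lvl).to_numpy(float)
            dummies[factor][lvl] = col
            cols.append(col)
            names.append(f"{factor}[{lvl}]")
    for cov in spec.covariates:
        cols.append(df[cov].to_numpy(float))
        names.append(cov)
    for fa, fb in spec.interactions:
        for la, ca in dummies[fa].items():
            for lb, cb in dummies[fb].items():
                cols.append(ca * cb)
                names.append(f"{fa}[{la}]:{fb}[{lb}]")
    X = np.column_stack(cols)
    return X, names, df


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    aliased = [names[j] for j in range(len(names)) if diag[j] <= tol]
    if aliased:
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def fit_linear_model(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Ordinary least squares with coefficient t-tests (residual df)."""
    X, names, df = build_design(data, spec)
    y = df[spec.response].to_numpy(float)
    _check_rank(X, names)
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    n, p = X.shape
    dof = n - p
    sigma2 = float(resid @ resid / dof) if dof > 0 else 0.0
    Rinv = np.linalg.inv(R)
    cov = sigma2 * (Rinv @ Rinv.T)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * sps.t.sf(np.abs(t), dof) if dof > 0 else np.full(p, np.nan)
    table = pd.DataFrame(
        {"term": names, "estimate": beta, "se": se, "t": t, "df": dof, "p": pvals}
    )
    return FitResult(table=table, n=n, method="ols", sigma2=sigma2)


def fit_random_intercept_model(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """REML fit of ``y = X beta + b_group + e`` with one random intercept.

    The criterion is profiled to the variance ratio ``lambda =
    var(b) / var(e)`` and minimized by bounded scalar search on
    ``log10(lambda)``.  Group-wise Woodbury identities keep the cost
    linear in n.
    """
    if not spec.random_intercept:
        raise ValueError("spec.random_intercept is required")
    X, names, df = build_design(data, spec)
    y = df[spec.response].to_numpy(float)
    _check_rank(X, names)
    groups = df[spec.random_intercept].to_numpy()
    n, p = X.shape
    idx_by_group = [np.flatnonzero(groups == g) for g in pd.unique(groups)]

    def _gls(lam: float):
        A = np.zeros((p, p))
        b = np.zeros(p)
        logdet_v = 0.0
        for idx in idx_by_group:
            Xg, yg = X[idx], y[idx]
            ng = len(idx)
            shrink = lam / (1.0 + ng * lam)
            logdet_v += np.log1p(ng * lam)
            xs, ys = Xg.sum(axis=0), yg.sum()
            A += Xg.T @ Xg - shrink * np.outer(xs, xs)
            b += Xg.T @ yg - shrink * xs * ys
        beta = np.linalg.solve(A, b)
        rss = 0.0
        for idx in idx_by_group:
            rg = y[idx] - X[idx] @ beta
            ng = len(idx)
            shrink = lam / (1.0 + ng * lam)
            rss += rg @ rg - shrink * rg.sum() ** 2
        return beta, A, rss, logdet_v

    def neg2_reml(log10_lam: float) -> float:
        lam = 10.0**log10_lam
        _, A, rss, logdet_v = _gls(lam)
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0 or rss <= 0:
            return np.inf
        return (n - p) * np.log(rss) + logdet_v + logdet_a

    res = optimize.minimize_scalar(
        neg2_reml, bounds=(-8.0, 8.0), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"REML optimization failed: {res}")
    # a boundary solution at the lower bound means essentially lambda = 0
    lam = 10.0**res.x
    crit0 = neg2_reml(-12.0)
    if crit0 <= res.fun:
        lam = 0.0
    beta, A, rss, _ = _gls(lam)
    dof = n - p
    sigma2_e = rss / dof
    cov = sigma2_e * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(t), dof)
    table = pd.DataFrame(
        {"term": names, "estimate": beta, "se": se, "t": t, "df": dof, "p": pvals}
    )
    return FitResult(
        table=table,
        n=n,
        method="reml",
        sigma2=float(sigma2_e),
        extra={
            "var_random_intercept": float(lam * sigma2_e),
            "var_residual": float(sigma2_e),
            "lambda": float(lam),
            "optimizer": {"x": float(res.x), "fun": float(res.fun), "nit": int(res.nfev)},
        },
    )


def chi_square_counts(
    observed, expected_proportions=None
) -> tuple[float, int, float]:
    """Pearson chi-square for count data.

    With a 2-D ``observed`` and no expected proportions, tests
    independence of the margins with df = (r-1)(c-1).  With 1-D counts
    and ``expected_proportions``, tests goodness of fit with df = k-1.
    """
    obs = np.asarray(observed, float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if expected_proportions is not None:
        props = np.asarray(expected_proportions, float)
        if obs.ndim != 1:
            raise ValueError("expected proportions require 1-D counts")
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("expected proportions must sum to 1")
        exp = obs.sum() * props
        dof = obs.size - 1
    else:
        if obs.ndim != 2:
            raise ValueError("independence test requires a 2-D count matrix")
        rows, cols = obs.sum(axis=1), obs.sum(axis=0)
        exp = np.outer(rows, cols) / obs.sum()
        dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if ((exp == 0) & (obs > 0)).any():
        raise ValueError("expected count of 0 with observed > 0; merge categories")
    mask = exp > 0
    stat = float((((obs - exp) ** 2)[mask] / exp[mask]).sum())
    p = float(sps.chi2.sf(stat, dof)) if dof > 0 else np.nan
    return stat, dof, p
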