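"""Survey-weighted logit and linear-probability estimation.

Point estimates maximize the weighted Bernoulli pseudo-log-likelihood (or
weighted least squares for the identity link); variances use the sandwich
estimator with scores summed within PSU clusters and the small-sample
correction ``G/(G-1) * (N-1)/(N-K)``.  With every observation its own
cluster this correction collapses to ``N/(N-K)``, i.e. the clustered
covariance reduces exactly to the HC1 heteroskedasticity-robust covariance.

Weights are normalized to sum to the number of observations before fitting;
this leaves point estimates unchanged and stabilizes the pseudo-likelihood
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import qr
from scipy.special import expit
from scipy.stats import norm

from .errors import NotConvergedError, RankError, SeparationError, ValidationError
from .survey import DesignMatrix, MicroData, ModelSpec, INTERCEPT, NONPOOR, POOR

__all__ = [
    "LogitFit",
    "ProportionTest",
    "fit_logit",
    "fit_linear_probability",
    "predict_prob",
    "odds_ratios",
    "proportion_diff_test",
    "significance_stars",
]

_SCORE_TOL = 1e-8
_LL_RTOL = 1e-10
_BETA_LIMIT = 50.0


@dataclass
class LogitFit:
    """Coefficients and cluster-robust covariance for one benchmark group."""

    benchmark: str  # "poor" | "nonpoor" | "pooled" (free-form labels allowed)
    beta: np.ndarray
    vcov: np.ndarray
    columns: list[str]
    column_blocks: list[str]
    n_obs: int
    n_clusters: int
    loglik: float
    converged: bool
    link: str  # "logit" | "identity"

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def require_converged(self) -> None:
        if not self.converged:
            raise NotConvergedError(f"fit for benchmark {self.benchmark!r} did not converge")


def _normalized_weights(w: np.ndarray) -> np.ndarray:
    return w * (len(w) / w.sum())


def _check_rank(X: np.ndarray, w: np.ndarray, columns) -> None:
    Xw = X * np.sqrt(w)[:, None]
    _, R, piv = qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        raise RankError([columns[j] for j in sorted(piv[rank:])])


def _cluster_sandwich(bread: np.ndarray, scores: np.ndarray, psu: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """Sandwich covariance with scores summed within clusters; returns (vcov, G)."""
    _, inv = np.unique(psu, return_inverse=True)
    g = inv.max() + 1
    n = scores.shape[0]
    S = np.zeros((g, scores.shape[1]))
    np.add.at(S, inv, scores)
    meat = S.T @ S
    if g > 1 and n > k:
        c = (g / (g - 1)) * ((n - 1) / (n - k))
    else:
        c = 1.0
    return c * bread @ meat @ bread, int(g)


def _weighted_loglik(y, xb, w) -> float:
    # log F(xb) = -log(1+e^{-xb});  log(1-F(xb)) = -log(1+e^{xb})
    return float(np.sum(w * (y * xb - np.logaddexp(0.0, xb))))


def fit_logit(dm: DesignMatrix, benchmark: str = "pooled", max_iter: int = 60) -> LogitFit:
    """Newton-Raphson weighted logit with PSU-cluster-robust covariance.

    Convergence is declared when the maximum absolute score falls below 1e-8
    or the relative log-likelihood change drops below 1e-10; iterations then
    continue (polishing) while the score keeps shrinking, so fitted group
    means match observed means to near machine precision.
    """
    X, y = dm.values, dm.y
    w = _normalized_weights(dm.weights)
    n, k = X.shape
    if y.min() == y.max():
        raise SeparationError(INTERCEPT)
    _check_rank(X, w, dm.columns)

    beta = np.zeros(k)
    ll = _weighted_loglik(y, X @ beta, w)
    converged = False
    for _ in range(max_iter):
        xb = X @ beta
        p = expit(xb)
        score = X.T @ (w * (y - p))
        max_score = np.max(np.abs(score))
        if max_score < 1e-13:
            converged = True
            break
        W = w * p * (1.0 - p)
        H = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:  # saturated probabilities
            raise SeparationError(dm.columns[int(np.argmax(np.abs(beta)))]) from exc
        # halving line search keeps the pseudo-loglik monotone
        new_ll = -np.inf
        for _ in range(30):
            cand = beta + step
            new_ll = _weighted_loglik(y, X @ cand, w)
            if new_ll >= ll - 1e-14:
                break
            step *= 0.5
        beta = beta + step
        if np.max(np.abs(beta)) > _BETA_LIMIT:
            raise SeparationError(dm.columns[int(np.argmax(np.abs(beta)))])
        rel = abs(new_ll - ll) / max(1.0, abs(ll))
        if max_score < _SCORE_TOL or rel < _LL_RTOL:
            converged = True
        ll = new_ll
        if converged and max_score < 1e-13:
            break

    xb = X @ beta
    p = expit(xb)
    W = w * p * (1.0 - p)
    H = X.T @ (X * W[:, None])
    bread = np.linalg.inv(H)
    scores = (w * (y - p))[:, None] * X
    vcov, g = _cluster_sandwich(bread, scores, dm.psu, k)

    return LogitFit(
        benchmark=benchmark,
        beta=beta,
        vcov=vcov,
        columns=list(dm.columns),
        column_blocks=list(dm.column_blocks),
        n_obs=n,
        n_clusters=g,
        loglik=_weighted_loglik(y, xb, w),
        converged=converged,
        link="logit",
    )


def fit_linear_probability(dm: DesignMatrix, benchmark: str = "pooled") -> LogitFit:
    """Weighted least squares on the binary outcome, cluster-robust covariance."""
    X, y = dm.values, dm.y
    w = _normalized_weights(dm.weights)
    n, k = X.shape
    _check_rank(X, w, dm.columns)

    XtW = X.T * w
    H = XtW @ X
    beta = np.linalg.solve(H, XtW @ y)
    resid = y - X @ beta
    bread = np.linalg.inv(H)
    scores = (w * resid)[:, None] * X
    vcov, g = _cluster_sandwich(bread, scores, dm.psu, k)

    return LogitFit(
        benchmark=benchmark,
        beta=beta,
        vcov=vcov,
        columns=list(dm.columns),
        column_blocks=list(dm.column_blocks),
        n_obs=n,
        n_clusters=g,
        loglik=float(-0.5 * np.sum(w * resid**2)),
        converged=True,
        link="identity",
    )


def predict_prob(fit: LogitFit, X, return_clipped: bool = False):
    """Predicted outcome probabilities for rows of ``X`` (DesignMatrix or array).

    Identity-link predictions are clipped to [0, 1]; pass
    ``return_clipped=True`` to also get the count of clipped rows.
    """
    if isinstance(X, DesignMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != fit.beta.size:
        raise ValidationError(
            f"design has {X.shape[1]} columns, fit expects {fit.beta.size}"
        )
    xb = X @ fit.beta
    if fit.link == "logit":
        p = expit(xb)
        n_clipped = 0
    else:
        p = np.clip(xb, 0.0, 1.0)
        n_clipped = int(np.sum((xb < 0.0) | (xb > 1.0)))
    return (p, n_clipped) if return_clipped else p


def odds_ratios(fit: LogitFit, level: float = 0.95):
    """Per-coefficient odds ratios with Wald intervals (logit link only)."""
    if fit.link != "logit":
        raise ValidationError("odds ratios are only defined for the logit link")
    z = norm.ppf(0.5 + level / 2.0)
    se = fit.se
    import pandas as pd

    return pd.DataFrame(
        {
            "column": fit.columns,
            "odds_ratio": np.exp(fit.beta),
            "ci_low": np.exp(fit.beta - z * se),
            "ci_high": np.exp(fit.beta + z * se),
        }
    )


def significance_stars(p: float) -> str:
    """Star mapping at the 10/5/1% levels."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


@dataclass
class ProportionTest:
    variable: str
    level: object
    poor_share: float
    poor_sd: float
    nonpoor_share: float
    nonpoor_sd: float
    differential: float  # nonpoor - poor
    se: float
    z: float
    p_value: float
    stars: str
    n_poor: int
    n_nonpoor: int


def _share_and_var(x: np.ndarray, w: np.ndarray, psu: np.ndarray, cluster: bool):
    wt = w / w.sum()
    share = float(wt @ x)
    resid = wt * (x - share)
    if cluster:
        _, inv = np.unique(psu, return_inverse=True)
        agg = np.zeros(inv.max() + 1)
        np.add.at(agg, inv, resid)
        var = float(np.sum(agg**2))
    else:
        var = float(np.sum(resid**2))
    return share, var


def proportion_diff_test(
    micro: MicroData,
    spec: ModelSpec,
    variable: str,
    level=None,
    cluster: bool = False,
) -> ProportionTest:
    """Two-sided z-test of equal weighted proportions between wealth groups.

    ``variable`` names a covariate block (or the outcome); for categorical
    blocks ``level`` selects the level whose share is compared.  The
    differential is nonpoor minus poor; the test uses the unpooled variance,
    with an optional PSU-cluster adjustment.
    """
    df = micro.frame
    if "group" not in df.columns:
        raise ValidationError("wealth groups not assigned")
    if variable == spec.outcome_name:
        obs = np.ones(len(df), dtype=bool)
        x = df[variable].to_numpy(dtype=float)
        if level is None:
            level = 1
    else:
        block = spec.block(variable)
        if level is None:
            if block.kind != "binary":
                raise ValidationError(f"level required for categorical block {variable!r}")
            level = block.coded_levels[0]
        vals = df[variable].astype(str).str.strip()
        obs = (~(df[variable].isna() | (vals == ""))).to_numpy()
        x = (vals == str(level)).to_numpy().astype(float)

    out = {}
    for grp in (POOR, NONPOOR):
        m = (df["group"] == grp).to_numpy() & obs
        if not m.any():
            raise ValidationError(f"group {grp!r} is empty for variable {variable!r}")
        share, var = _share_and_var(
            x[m], df["weight"].to_numpy(dtype=float)[m], df["psu"].astype(str).to_numpy()[m], cluster
        )
        out[grp] = (share, var, int(m.sum()))

    diff = out[NONPOOR][0] - out[POOR][0]
    se = float(np.sqrt(out[POOR][1] + out[NONPOOR][1]))
    if diff == 0.0:
        z, p = 0.0, 1.0
    elif se == 0.0:
        z, p = np.inf * np.sign(diff), 0.0
    else:
        z = diff / se
        p = float(2.0 * norm.sf(abs(z)))
    return ProportionTest(
        variable=variable,
        level=level,
        poor_share=out[POOR][0],
        poor_sd=float(np.sqrt(out[POOR][0] * (1 - out[POOR][0]))),
        nonpoor_share=out[NONPOOR][0],
        nonpoor_sd=float(np.sqrt(out[NONPOOR][0] * (1 - out[NONPOOR][0]))),
        differential=diff,
        se=se,
        z=float(z),
        p_value=p,
        stars=significance_stars(p),
        n_poor=out[POOR][2],
        n_nonpoor=out[NONPOOR][2],
    )
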