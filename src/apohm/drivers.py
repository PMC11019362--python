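"""Poisson background models and exact-test driver calling for hotspots.

Hotspot positions are split into two groups: outside hairpin loops (only
TpC-context sites are tested, as these are the canonical APOBEC substrate)
and inside loops (TpC plus ApC/CpC/GpC context, to capture didymi).  For each
focal hotspot the recurrence of the *remaining* hotspots is modeled as a
Poisson process — a log-link Poisson regression of per-site mutation count on
DNA accessibility decile (plus hairpin delta-G and the didymi loop-motif flag
for in-loop sites), stratified by trinucleotide for TpC sites.  The expected
count at the focal site's covariates feeds an exact (upper-tail) Poisson
test, and p values are Benjamini-Hochberg corrected per group; drivers are
sites with adjusted p < 0.05.

Strata with fewer than two background sites fall back to a model without the
trinucleotide stratification.  Because refitting the GLM for every focal site
is quadratic in catalog size, large strata use an exact closed form
(intercept-only) or a one-step Newton leave-one-out downdate for covariate
models; small strata and :func:`fit_background` refit exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

OUTSIDE_LOOP = "outside_loop"
IN_LOOP = "in_loop"
TPC_TRINUCLEOTIDES = ("TCA", "TCC", "TCG", "TCT")
DRIVER_ALPHA = 0.05


def exact_poisson_test(n_obs, lam):
    """Upper-tail exact Poisson p value, P(X >= n_obs) for X ~ Poisson(lam).

    Computed with the stable survival function; accepts scalars or arrays.
    """
    lam_arr = np.asarray(lam, float)
    if np.any(lam_arr <= 0):
        raise ValueError("lambda must be positive")
    n_arr = np.asarray(n_obs)
    if np.any(n_arr < 0):
        raise ValueError("n_obs must be non-negative")
    p = stats.poisson.sf(n_arr - 1, lam_arr)
    return float(p) if np.isscalar(n_obs) and np.isscalar(lam) else p


def bh_adjust(pvals, groups=None):
    """Benjamini-Hochberg step-up adjusted p values, optionally per group.

    Returns adjusted values in the original order; within each group the
    adjusted values are monotone with the p-value ranks and >= the raw p.
    """
    p = np.asarray(pvals, float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    out = np.empty_like(p)
    if groups is None:
        group_ids = np.zeros(len(p), int)
    else:
        _, group_ids = np.unique(np.asarray(groups), return_inverse=True)
    for g in np.unique(group_ids):
        idx = np.where(group_ids == g)[0]
        sub = p[idx]
        m = len(sub)
        order = np.argsort(sub, kind="mergesort")
        ranked = sub[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.maximum(np.minimum(adj, 1.0), sub[order])  # adj >= raw p exactly
        result = np.empty(m)
        result[order] = adj
        out[idx] = result
    return out


@dataclass
class PoissonBackgroundModel:
    """A fitted background model for one focal site (or one stratum).

    ``coefficients`` align with ``covariates`` (intercept first).  ``lambda_``
    for a site is ``exp(x @ coefficients)``.
    """

    group: str
    stratum: str
    covariates: tuple
    coefficients: np.ndarray
    n_background: int
    log_likelihood: float
    fallback: bool = False  # True when the trinucleotide stratum was too thin
    intercept_only: bool = False

    def predict(self, row) -> float:
        x = _row_design(row, self.covariates)
        return float(np.exp(x @ self.coefficients))


def _covariate_names(group: str) -> tuple:
    if group == OUTSIDE_LOOP:
        return ("const", "accessibility_decile")
    return ("const", "accessibility_decile", "delta_g", "loop_pattern")


def _design(df: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = []
    for name in covariates:
        if name == "const":
            cols.append(np.ones(len(df)))
        else:
            cols.append(df[name].to_numpy(float))
    return np.column_stack(cols)


def _row_design(row, covariates: Sequence[str]) -> np.ndarray:
    return np.array(
        [1.0 if c == "const" else float(row[c]) for c in covariates]
    )


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    from scipy.special import gammaln

    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))


def _fit_glm(y: np.ndarray, X: np.ndarray, covariates: tuple, max_iter: int = 100):
    """Fit a Poisson GLM; returns (beta, covariates, llf, intercept_only).

    Covariate columns without variation are dropped; non-convergence falls
    back to the intercept-only closed form with a warning.
    """
    keep = [0] + [
        j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0
    ]
    Xk = X[:, keep]
    names = tuple(covariates[j] for j in keep)
    if Xk.shape[1] == 1:
        mu = np.full(len(y), y.mean())
        return np.array([np.log(mu[0])]), ("const",), _poisson_loglik(y, mu), True
    import warnings

    import statsmodels.api as sm

    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, Xk, family=sm.families.Poisson()).fit(maxiter=max_iter)
        if not np.all(np.isfinite(res.params)):
            raise ValueError("non-finite coefficients")
        return np.asarray(res.params), names, float(res.llf), False
    except Exception as exc:  # pragma: no cover - defensive fallback
        logger.warning("Poisson GLM failed (%s); intercept-only fallback", exc)
        mu = np.full(len(y), y.mean())
        return np.array([np.log(mu[0])]), ("const",), _poisson_loglik(y, mu), True


def _stratum_label(row) -> str:
    if row["context_group"] == "TpC":
        return row["trinucleotide"]
    return row["context_group"]


def _stratum_labels(df: pd.DataFrame) -> pd.Series:
    return pd.Series(
        np.where(df["context_group"].eq("TpC"), df["trinucleotide"], df["context_group"]),
        index=df.index,
    )


def _group_frame(catalog: pd.DataFrame, group: str) -> pd.DataFrame:
    in_loop = catalog["in_loop"].astype(bool)
    if group == OUTSIDE_LOOP:
        sub = catalog[~in_loop & (catalog["context_group"] == "TpC")]
    elif group == IN_LOOP:
        sub = catalog[
            in_loop & catalog["context_group"].isin(["TpC", "ApC", "CpC", "GpC"])
        ]
    else:
        raise ValueError(f"unknown group {group!r}")
    return sub


def fit_background(
    catalog: pd.DataFrame,
    focal_index,
    group: str,
    stratify: bool = True,
) -> PoissonBackgroundModel:
    """Exact leave-one-out background model for one focal site.

    The focal site is excluded from its own background; TpC sites are
    stratified by trinucleotide unless the stratum holds fewer than two
    background sites, in which case the model is refit on the whole group
    without the trinucleotide stratification (``fallback=True``).
    """
    sub = _group_frame(catalog, group)
    if focal_index not in sub.index:
        raise KeyError(f"focal site {focal_index} is not testable in group {group}")
    focal = sub.loc[focal_index]
    covariates = _covariate_names(group)
    background = sub.drop(index=focal_index)
    fallback = False
    if stratify:
        stratum = _stratum_label(focal)
        strat_bg = (
            background[_stratum_labels(background) == stratum]
            if len(background)
            else background
        )
        if len(strat_bg) >= 2:
            background = strat_bg
        else:
            fallback = True
            stratum = "pooled"
    else:
        stratum = "pooled"
    if len(background) < 2:
        raise ValueError("fewer than 2 background sites in the whole group")
    y = background["n_mut"].to_numpy(float)
    X = _design(background, covariates)
    beta, names, llf, intercept_only = _fit_glm(y, X, covariates)
    return PoissonBackgroundModel(
        group=group, stratum=stratum, covariates=names, coefficients=beta,
        n_background=len(background), log_likelihood=llf,
        fallback=fallback, intercept_only=intercept_only,
    )


def _loo_lambdas_exact(sub: pd.DataFrame, covariates: tuple) -> np.ndarray:
    lams = np.empty(len(sub))
    for k, idx in enumerate(sub.index):
        bg = sub.drop(index=idx)
        beta, names, _, _ = _fit_glm(
            bg["n_mut"].to_numpy(float), _design(bg, covariates), covariates
        )
        lams[k] = np.exp(_row_design(sub.loc[idx], names) @ beta)
    return lams


def _loo_lambdas_onestep(sub: pd.DataFrame, covariates: tuple) -> np.ndarray:
    """One-step Newton (jackknife) leave-one-out expected counts.

    For the intercept-only model this reduces to the exact closed form
    (sum(y) - y_i) / (m - 1); for covariate models it applies the standard
    one-step downdate  beta_(i) = beta - (X'WX)^-1 x_i (y_i - mu_i)/(1 - h_i).
    """
    y = sub["n_mut"].to_numpy(float)
    X = _design(sub, covariates)
    beta, names, _, intercept_only = _fit_glm(y, X, covariates)
    m = len(y)
    if intercept_only or len(names) == 1:
        return (y.sum() - y) / (m - 1)
    Xk = _design(sub, names)
    eta = Xk @ beta
    mu = np.exp(eta)
    XtWX = Xk.T @ (Xk * mu[:, None])
    Vinv = np.linalg.pinv(XtWX)
    a = np.einsum("ij,jk,ik->i", Xk, Vinv, Xk)  # x_i' Vinv x_i
    h = np.clip(mu * a, None, 0.999)
    eta_loo = eta - a * (y - mu) / (1 - h)
    return np.exp(eta_loo)


def call_drivers(
    catalog: pd.DataFrame,
    alpha: float = DRIVER_ALPHA,
    stratify: bool = True,
    exact_loo_max: int = 500,
) -> pd.DataFrame:
    """Leave-one-out background fit, exact Poisson test, and per-group BH.

    Returns one row per tested site: chrom, pos, group, stratum, n_obs,
    lambda_expected, p, adj_p, is_driver, fallback.  Sites outside loops that
    are not in TpC context are never tested.  Strata of size <= ``exact_loo_max``
    use an exact per-site refit; larger strata use the one-step downdate.
    """
    pieces = []
    for group in (OUTSIDE_LOOP, IN_LOOP):
        sub = _group_frame(catalog, group)
        if sub.empty:
            logger.warning("no testable sites in group %s", group)
            continue
        if len(sub) < 3:
            logger.warning("group %s has too few sites to model; skipped", group)
            continue
        covariates = _covariate_names(group)
        if stratify:
            labels = _stratum_labels(sub)
        else:
            labels = pd.Series("pooled", index=sub.index)
        sizes = labels.value_counts()
        # a focal site needs >= 2 background sites in its stratum
        thin = {s for s, n in sizes.items() if n < 3}
        strat_of = labels.where(~labels.isin(thin), other="pooled")
        lam = pd.Series(np.nan, index=sub.index)
        fallback = pd.Series(False, index=sub.index)
        for stratum in strat_of.unique():
            if stratum == "pooled":
                rows = sub  # pooled model is fit on the whole group
                targets = sub.index[strat_of == "pooled"]
                fallback.loc[targets] = stratify
            else:
                rows = sub[labels == stratum]
                targets = rows.index
            if len(rows) <= exact_loo_max:
                lams = _loo_lambdas_exact(rows, covariates)
            else:
                lams = _loo_lambdas_onestep(rows, covariates)
            lam_rows = pd.Series(lams, index=rows.index)
            lam.loc[targets] = lam_rows.loc[targets]
        n_obs = sub["n_mut"].to_numpy(float)
        pvals = exact_poisson_test(n_obs.astype(int), lam.to_numpy())
        pieces.append(
            pd.DataFrame(
                {
                    "chrom": sub["chrom"].to_numpy(),
                    "pos": sub["pos"].to_numpy(),
                    "group": group,
                    "stratum": strat_of.to_numpy(),
                    "n_obs": n_obs.astype(int),
                    "lambda_expected": lam.to_numpy(),
                    "p": np.atleast_1d(pvals),
                    "fallback": fallback.to_numpy(),
                },
                index=sub.index,
            )
        )
    if not pieces:
        return pd.DataFrame(
            columns=[
                "chrom", "pos", "group", "stratum", "n_obs", "lambda_expected",
                "p", "adj_p", "is_driver", "fallback",
            ]
        )
    out = pd.concat(pieces)
    out["adj_p"] = bh_adjust(out["p"].to_numpy(), groups=out["group"].to_numpy())
    out["is_driver"] = out["adj_p"] < alpha
    return out.sort_index()


def mcfadden_r2(log_likelihood: float, null_log_likelihood: float) -> float:
    """McFadden's pseudo R-squared, 1 - logLik(model) / logLik(null)."""
    if null_log_likelihood == 0:
        raise ValueError("null model log-likelihood is zero; R2 undefined")
    return 1.0 - log_likelihood / null_log_likelihood
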