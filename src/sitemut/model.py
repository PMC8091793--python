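"""Negative-binomial regression, likelihood-ratio tests, fold changes, FDR.

The count model is

    n_mut ~ NegBin( offset(log(n_posits)) + triNucMutClass
                    + log1p(MbpRate) [+ coFac] + isSite [+ isSite:coFac] )

with a log link.  The mutation-class factor enters as a one-hot block (the
intercept is absorbed into it), which keeps the normal equations
block-diagonal: the class block contributes a diagonal and only the handful of
dense covariates need a small Schur-complement solve.  Coefficients are fit by
IRLS and the dispersion by 1-D maximum likelihood on the shape parameter,
alternating to joint convergence (tolerance 1e-8, at most 100 outer rounds).
The ``theta`` reported is the NB shape (variance = mu + mu^2/theta).

Significance of the site term (and of the cofactor interaction) comes from a
chi-square likelihood-ratio test between nested fits.  Fold changes are
estimated by sampling: site-row counts are drawn from the fitted negative
binomial with the site effect removed, and the observed site total is divided
by the median of the sampled totals; the 2.5th/97.5th percentiles of the
samples give the confidence interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2

from . import trinuc

log = logging.getLogger(__name__)

_ALPHA_MIN = 1e-8  # below this the model is treated as exactly Poisson
_ETA_CAP = 30.0
_TOL = 1e-8
_MAX_OUTER = 100
_MAX_IRLS = 100


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood; Poisson limit below the alpha floor."""
    mu = np.clip(mu, 1e-12, None)
    if alpha < _ALPHA_MIN:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _irls(y, offset, cls_idx, n_cls, Xd, alpha, beta_c, beta_d):
    """Weighted-least-squares IRLS exploiting the one-hot class block."""
    k = Xd.shape[1]
    for _ in range(_MAX_IRLS):
        eta = beta_c[cls_idx] + (Xd @ beta_d if k else 0.0) + offset
        eta = np.clip(eta, -_ETA_CAP, _ETA_CAP)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        wz = w * z
        A = np.bincount(cls_idx, weights=w, minlength=n_cls) + 1e-12
        rc = np.bincount(cls_idx, weights=wz, minlength=n_cls)
        if k:
            B = np.stack(
                [np.bincount(cls_idx, weights=w * Xd[:, j], minlength=n_cls)
                 for j in range(k)],
                axis=1,
            )
            C = Xd.T @ (w[:, None] * Xd)
            rd = Xd.T @ wz
            Ainv = 1.0 / A
            S = C - B.T @ (B * Ainv[:, None])
            rhs = rd - B.T @ (rc * Ainv)
            new_d = np.linalg.solve(S + 1e-12 * np.eye(k), rhs)
            new_c = Ainv * (rc - B @ new_d)
        else:
            new_d = beta_d
            new_c = rc / A
        new_c = np.clip(new_c, -_ETA_CAP, _ETA_CAP)
        delta = max(
            np.max(np.abs(new_c - beta_c)),
            np.max(np.abs(new_d - beta_d)) if k else 0.0,
        )
        beta_c, beta_d = new_c, new_d
        if delta < _TOL:
            return beta_c, beta_d, True
    return beta_c, beta_d, False


def _dense_cov(y, offset, cls_idx, n_cls, Xd, alpha, beta_c, beta_d):
    """Wald covariance of the dense coefficients (Schur complement of Fisher info)."""
    k = Xd.shape[1]
    if not k:
        return np.zeros((0, 0))
    eta = np.clip(beta_c[cls_idx] + Xd @ beta_d + offset, -_ETA_CAP, _ETA_CAP)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    A = np.bincount(cls_idx, weights=w, minlength=n_cls) + 1e-12
    B = np.stack(
        [np.bincount(cls_idx, weights=w * Xd[:, j], minlength=n_cls) for j in range(k)],
        axis=1,
    )
    C = Xd.T @ (w[:, None] * Xd)
    S = C - B.T @ (B / A[:, None])
    return np.linalg.inv(S + 1e-12 * np.eye(k))


@dataclass
class FittedNB:
    """A converged negative-binomial fit of the stratified count table."""

    class_levels: np.ndarray
    class_coefs: np.ndarray
    dense_names: list
    dense_coefs: np.ndarray
    dense_se: dict
    theta: float
    alpha: float
    log_likelihood: float
    converged: bool
    fallback_used: str  # "none" | "poisson"
    mu: np.ndarray
    n_obs: int
    y_sum: int
    n_params: int

    @property
    def coefficients(self) -> dict:
        out = {"intercept": float(self.class_coefs[0])}
        for lev, c in zip(self.class_levels[1:], self.class_coefs[1:]):
            out[f"class:{trinuc.CLASS_LABELS[int(lev)]}"] = float(c - self.class_coefs[0])
        for name, c in zip(self.dense_names, self.dense_coefs):
            out[name] = float(c)
        return out

    def coef(self, name: str) -> float:
        return self.dense_coefs[self.dense_names.index(name)]


def fit_nb(
    table: pd.DataFrame,
    include_site: bool = True,
    include_cofac: bool = False,
    include_interaction: bool = False,
    include_mbp: bool = True,
    warm: FittedNB | None = None,
) -> FittedNB:
    """Maximum-likelihood NB fit of a regression table.

    The class factor always enters (absorbing the intercept); ``include_mbp``
    adds log1p(mbp_rate), ``include_site`` the site indicator, ``include_cofac``
    the cofactor main effect and ``include_interaction`` the site-by-cofactor
    product (which requires the cofactor).  On non-convergence the fit is
    retried from Poisson-initialized coefficients; if that also fails the
    Poisson fit is returned flagged ``fallback_used='poisson'``.
    """
    if include_interaction and not include_cofac:
        raise ValueError("interaction requires the cofactor term")
    y_all = table["n_mut"].to_numpy(dtype=np.float64)
    npos_all = table["n_posits"].to_numpy(dtype=np.float64)
    if (npos_all <= 0).any():
        raise ValueError("zero-opportunity rows must be dropped before fitting")
    if include_site and table["is_site"].nunique() < 2:
        raise ValueError("table must contain both site and flank rows")
    # rows of classes with zero total count are inert at the ML solution
    # (their coefficient diverges to -inf and their likelihood term to 0);
    # dropping them keeps the alternation numerically stable
    cls_all = table["class_id"].to_numpy()
    _, inv_all = np.unique(cls_all, return_inverse=True)
    cls_tot = np.bincount(inv_all, weights=y_all)
    keep = cls_tot[inv_all] > 0
    if not keep.any():
        mu0 = np.zeros(len(y_all))
        return FittedNB(
            class_levels=np.unique(cls_all), class_coefs=np.full(len(cls_tot), -_ETA_CAP),
            dense_names=[], dense_coefs=np.zeros(0), dense_se={},
            theta=np.inf, alpha=0.0, log_likelihood=0.0, converged=True,
            fallback_used="none", mu=mu0, n_obs=len(y_all), y_sum=0,
            n_params=len(cls_tot) + 1,
        )
    y = y_all[keep]
    npos = npos_all[keep]
    offset = np.log(npos)
    levels, cls_idx = np.unique(cls_all[keep], return_inverse=True)
    n_cls = len(levels)
    table = table[keep]
    dense_names, cols = [], []
    if include_mbp:
        mbp = np.log1p(table["mbp_rate"].to_numpy(dtype=np.float64))
        if np.ptp(mbp) > 1e-12:  # constant column is collinear with the class block
            dense_names.append("log1p_mbp_rate")
            cols.append(mbp)
    if include_cofac:
        dense_names.append("cofac")
        cols.append(table["cofac"].to_numpy(dtype=np.float64))
    if include_site:
        dense_names.append("is_site")
        cols.append(table["is_site"].to_numpy(dtype=np.float64))
    if include_interaction:
        dense_names.append("is_site:cofac")
        cols.append(
            table["is_site"].to_numpy(dtype=np.float64)
            * table["cofac"].to_numpy(dtype=np.float64)
        )
    Xd = np.column_stack(cols) if cols else np.empty((len(y), 0))

    def init_beta():
        ysum = np.bincount(cls_idx, weights=y, minlength=n_cls)
        esum = np.bincount(cls_idx, weights=npos, minlength=n_cls)
        bc = np.log((ysum + 0.5) / esum)
        bd = np.zeros(len(dense_names))
        if warm is not None and list(warm.class_levels) == list(levels):
            bc = warm.class_coefs.copy()
            for j, name in enumerate(dense_names):
                if name in warm.dense_names:
                    bd[j] = warm.coef(name)
        return bc, bd

    def run(bc, bd):
        alpha = _ALPHA_MIN
        ll = -np.inf
        converged = False
        for _ in range(_MAX_OUTER):
            bc, bd, _ok = _irls(y, offset, cls_idx, n_cls, Xd, alpha, bc, bd)
            eta = np.clip(bc[cls_idx] + (Xd @ bd if len(dense_names) else 0.0) + offset,
                          -_ETA_CAP, _ETA_CAP)
            mu = np.exp(eta)
            res = minimize_scalar(
                lambda la: -nb_loglik(y, mu, float(np.exp(la))),
                bounds=(np.log(_ALPHA_MIN) - 2.0, 6.0),
                method="bounded",
                options={"xatol": 1e-10},
            )
            # snap to exact Poisson when dispersion buys (essentially) no
            # likelihood: near the boundary the profile is flat and the NB
            # evaluation jitters, which would stall the outer tolerance check
            ll_pois = nb_loglik(y, mu, 0.0)
            alpha = float(np.exp(res.x))
            if -res.fun - ll_pois < 1e-3:
                alpha = 0.0
            ll_new = nb_loglik(y, mu, alpha)
            if abs(ll_new - ll) < _TOL:
                converged = True
                ll = ll_new
                break
            ll = ll_new
        return bc, bd, alpha, mu, ll, converged

    bc0, bd0 = init_beta()
    bc, bd, alpha, mu, ll, converged = run(bc0.copy(), bd0.copy())
    fallback = "none"
    if not converged:
        # retry from a clean Poisson-initialized state
        bc_p, bd_p, _ = _irls(y, offset, cls_idx, n_cls, Xd, 0.0, *init_beta())
        bc, bd, alpha, mu, ll, converged = run(bc_p, bd_p)
        if not converged:
            fallback = "poisson"
            alpha = 0.0
            bc, bd, _ = _irls(y, offset, cls_idx, n_cls, Xd, 0.0, *init_beta())
            eta = np.clip(bc[cls_idx] + (Xd @ bd if len(dense_names) else 0.0) + offset,
                          -_ETA_CAP, _ETA_CAP)
            mu = np.exp(eta)
            ll = nb_loglik(y, mu, 0.0)
            log.warning("NB fit did not converge; Poisson fallback used")
    cov = _dense_cov(y, offset, cls_idx, n_cls, Xd, alpha, bc, bd)
    se = {name: float(np.sqrt(max(cov[j, j], 0.0))) for j, name in enumerate(dense_names)}
    theta = 1.0 / alpha if alpha > 0 else np.inf
    mu_full = np.zeros(len(keep))
    mu_full[keep] = mu
    return FittedNB(
        class_levels=levels,
        class_coefs=bc,
        dense_names=dense_names,
        dense_coefs=bd,
        dense_se=se,
        theta=theta,
        alpha=alpha,
        log_likelihood=ll,
        converged=converged or fallback == "poisson",
        fallback_used=fallback,
        mu=mu_full,
        n_obs=int(len(keep)),
        y_sum=int(y.sum()),
        n_params=n_cls + len(dense_names) + 1,
    )


def lrt(null_fit: FittedNB, alt_fit: FittedNB, df: int = 1) -> float:
    """Upper-tail chi-square p-value of twice the log-likelihood gain."""
    if null_fit.n_obs != alt_fit.n_obs or null_fit.y_sum != alt_fit.y_sum:
        raise ValueError("null and alternative fits use different tables")
    dev = 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood)
    if dev < 0:
        if dev < -1e-6:
            warnings.warn(f"negative deviance {dev:.3g} clamped to 0")
        dev = 0.0
    return float(chi2.sf(dev, df))


def estimate_fold_change(
    fit: FittedNB,
    table: pd.DataFrame,
    n_draws: int = 1000,
    seed: int | np.random.Generator = 1,
):
    """Sampling-based fold change of observed vs expected site mutations.

    Site-row expectations are the fitted means with any site-term contribution
    (is_site and its interaction) removed, i.e. the count the model predicts
    had sites mutated like their flanks.  Each of ``n_draws`` rounds samples
    every site-row count from NB(mean, theta) and sums them; the fold change
    is the observed site total over the median sampled total, with the CI
    mapped so that it covers the fold change:
    (observed/P97.5, observed/P2.5).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = (table["is_site"] == 1).to_numpy()
    observed = float(table.loc[mask, "n_mut"].sum())
    mu = fit.mu[mask].copy()
    drop = 0.0
    if "is_site" in fit.dense_names:
        drop = drop + fit.coef("is_site")
    if "is_site:cofac" in fit.dense_names:
        drop = drop + fit.coef("is_site:cofac") * table.loc[mask, "cofac"].to_numpy()
    mu = mu * np.exp(-drop)
    if fit.alpha < _ALPHA_MIN:
        draws = rng.poisson(lam=np.broadcast_to(mu, (n_draws, len(mu)))).sum(axis=1)
    else:
        r = 1.0 / fit.alpha
        p = r / (r + mu)
        draws = rng.negative_binomial(
            n=np.broadcast_to(r, (n_draws, len(mu))),
            p=np.broadcast_to(p, (n_draws, len(mu))),
        ).sum(axis=1)
    med = float(np.median(draws))
    p_low, p_high = np.percentile(draws, [2.5, 97.5])
    def ratio(a, b):
        return float(a / b) if b > 0 else float("inf")
    if observed == 0:
        warnings.warn("observed site total is 0; fold change degenerate")
        return 0.0, 0.0, ratio(observed, p_low) if p_low > 0 else 0.0
    return ratio(observed, med), ratio(observed, p_high), ratio(observed, p_low)


@dataclass
class RM2Result:
    """Site-enrichment test result for one mutation subset."""

    subset: str
    p_site: float
    coef_site: float
    fc: float
    fc_ci: tuple
    n_mut_site: int
    n_mut_flank: int
    n_sites: int | None = None
    fdr: float = np.nan
    converged: bool = True
    fallback_used: str = "none"

    def to_row(self) -> dict:
        return {
            "subset": self.subset,
            "p": self.p_site,
            "q": self.fdr,
            "coef": self.coef_site,
            "fc": self.fc,
            "ci_low": self.fc_ci[0],
            "ci_high": self.fc_ci[1],
            "n_sites": self.n_sites,
            "n_mut_site": self.n_mut_site,
            "n_mut_flank": self.n_mut_flank,
            "converged": self.converged,
            "fallback_used": self.fallback_used,
        }


def rm2_test(
    table: pd.DataFrame,
    n_draws: int = 1000,
    seed: int | np.random.Generator = 1,
    include_mbp: bool = True,
    fc_expectation: str = "alt",
    subset: str = "total",
    n_sites: int | None = None,
) -> RM2Result:
    """Likelihood-ratio test of the site term plus fold-change estimate.

    ``fc_expectation`` selects which fit provides the sampling expectations:
    the site-term-removed alternative fit (default) or the null fit.
    ``n_draws=0`` skips fold-change estimation (fc reported as NaN).
    """
    has_cofac = bool(table.attrs.get("has_cofac")) and table["cofac"].nunique() > 1
    null_fit = fit_nb(table, include_site=False, include_cofac=has_cofac,
                      include_mbp=include_mbp)
    alt_fit = fit_nb(table, include_site=True, include_cofac=has_cofac,
                     include_mbp=include_mbp, warm=null_fit)
    p = lrt(null_fit, alt_fit, df=1)
    if n_draws > 0:
        src = alt_fit if fc_expectation == "alt" else null_fit
        fc, lo, hi = estimate_fold_change(src, table, n_draws=n_draws, seed=seed)
    else:
        fc, lo, hi = np.nan, np.nan, np.nan
    site_mask = (table["is_site"] == 1).to_numpy()
    return RM2Result(
        subset=subset,
        p_site=p,
        coef_site=float(alt_fit.coef("is_site")),
        fc=fc,
        fc_ci=(lo, hi),
        n_mut_site=int(table.loc[site_mask, "n_mut"].sum()),
        n_mut_flank=int(table.loc[~site_mask, "n_mut"].sum()),
        n_sites=n_sites,
        converged=null_fit.converged and alt_fit.converged,
        fallback_used=(
            "poisson"
            if "poisson" in (null_fit.fallback_used, alt_fit.fallback_used)
            else "none"
        ),
    )


@dataclass
class InteractionResult:
    """Cofactor-interaction test plus per-group validation fits."""

    p_site: float
    coef_site: float
    p_interaction: float
    coef_interaction: float
    fc: float = np.nan
    fc_ci: tuple = (np.nan, np.nan)
    group_results: dict = field(default_factory=dict)  # cofac level -> RM2Result
    converged: bool = True

    def is_hit(self, q_site: float, alpha: float = 0.05) -> bool:
        """Hit rule: significant adjusted main effect, unadjusted interaction
        p < 0.05, and positive site and interaction coefficients."""
        return (
            q_site < alpha
            and self.p_interaction < 0.05
            and self.coef_site > 0
            and self.coef_interaction > 0
        )


def test_cofactor_interaction(
    table: pd.DataFrame,
    seed: int | np.random.Generator = 1,
    n_draws: int = 1000,
    include_mbp: bool = True,
    per_group: bool = True,
) -> InteractionResult:
    """Test whether localized enrichment differs between cofactor groups.

    Fits the nested sequence (no site) -> (+ isSite) -> (+ isSite:coFac), all
    with the cofactor main effect; reports the main-effect LRT p and the
    unadjusted interaction LRT p.  ``per_group`` additionally runs the plain
    site test separately within each tumour group for validation.
    """
    if not table.attrs.get("has_cofac") or table["cofac"].nunique() < 2:
        raise ValueError("table must carry both cofactor levels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m0 = fit_nb(table, include_site=False, include_cofac=True, include_mbp=include_mbp)
    m1 = fit_nb(table, include_site=True, include_cofac=True, include_mbp=include_mbp,
                warm=m0)
    m2 = fit_nb(table, include_site=True, include_cofac=True, include_interaction=True,
                include_mbp=include_mbp, warm=m1)
    p_site = lrt(m0, m1, df=1)
    p_int = lrt(m1, m2, df=1)
    fc, lo, hi = (np.nan, np.nan, np.nan)
    if n_draws > 0:
        fc, lo, hi = estimate_fold_change(m1, table, n_draws=n_draws, seed=rng)
    groups = {}
    if per_group:
        for level in (0, 1):
            sub = table[table["cofac"] == level].copy()
            sub.attrs["has_cofac"] = False
            groups[level] = rm2_test(
                sub, n_draws=n_draws, seed=rng, include_mbp=include_mbp,
                subset=f"cofac={level}",
            )
    return InteractionResult(
        p_site=p_site,
        coef_site=float(m2.coef("is_site")),
        p_interaction=p_int,
        coef_interaction=float(m2.coef("is_site:cofac")),
        fc=fc,
        fc_ci=(lo, hi),
        group_results=groups,
        converged=all(m.converged for m in (m0, m1, m2)),
    )


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
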