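"""Logistic regression (IRLS), Wald odds ratios, closed-form 2x2 ORs,
per-SNP association, and Spearman correlation screening.

The logistic fitter is a plain Newton/IRLS maximum-likelihood routine with an
explicit numerical contract: convergence when the relative change in
log-likelihood drops below ``tol`` (default 1e-10, max 100 iterations), a hard
error on rank-deficient designs, and a flagged (non-converged) result when
complete separation drives a coefficient beyond +/-15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .panel import GenotypeMatrix

SEPARATION_BOUND = 15.0


class RankDeficientDesign(ValueError):
    pass


@dataclass
class LogisticFit:
    term_names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    separation: bool = False

    def coef(self, term: str) -> float:
        return float(self.coefficients[self._index(term)])

    def se(self, term: str) -> float:
        return float(self.standard_errors[self._index(term)])

    def _index(self, term: str) -> int:
        try:
            return self.term_names.index(term)
        except ValueError:
            raise KeyError(f"unknown model term {term!r}") from None


def _log_likelihood(X, y, beta):
    eta = X @ beta
    # log(sigmoid) computed stably: -log(1 + exp(-|eta|)) variants
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    term_names: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by iteratively reweighted least
    squares.

    ``X`` must include its own intercept column and be full rank; ``y`` is a
    non-constant 0/1 vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]
    if len(term_names) != p:
        raise ValueError("term_names length does not match design")
    if y.min() == y.max():
        raise ValueError("outcome vector is constant")

    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify columns involved in the collinearity via QR pivoting
        _, r = np.linalg.qr(X)
        small = np.flatnonzero(np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max())
        names = [term_names[j] for j in small] or term_names
        raise RankDeficientDesign(f"design is rank deficient; collinear terms: {names}")

    beta = np.zeros(p)
    ll_old = _log_likelihood(X, y, beta)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        w = mu * (1.0 - mu)
        # guard against exactly-0 weights at extreme fitted probabilities
        w = np.clip(w, 1e-12, None)
        XtW = X.T * w
        hessian = XtW @ X
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(hessian, score)
        except np.linalg.LinAlgError:
            separation = True
            break
        beta = beta + step
        ll_new = _log_likelihood(X, y, beta)
        if np.abs(beta).max() > SEPARATION_BOUND:
            separation = True
            break
        if abs(ll_new - ll_old) < tol * (abs(ll_old) + tol):
            ll_old = ll_new
            converged = True
            break
        ll_old = ll_new

    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    return LogisticFit(
        term_names=list(term_names),
        coefficients=beta,
        standard_errors=se,
        covariance=cov,
        log_likelihood=ll_old,
        n_iterations=it,
        converged=converged and not separation,
        separation=separation,
    )


def wald_or(fit: LogisticFit, term: str, level: float = 0.95):
    """Odds ratio, Wald CI and two-sided normal p for one model term."""
    b, se = fit.coef(term), fit.se(term)
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = 2.0 * stats.norm.sf(abs(b) / se) if se > 0 else 0.0
    return float(np.exp(b)), float(np.exp(b - z * se)), float(np.exp(b + z * se)), float(p)


def or_2x2(
    cases_exposed: int,
    controls_exposed: int,
    cases_ref: int,
    controls_ref: int,
    level: float = 0.95,
):
    """Closed-form odds ratio for a 2x2 table with Wald CI and p.

    or = (cases_exposed * controls_ref) / (controls_exposed * cases_ref);
    se(log or) = sqrt(sum of reciprocal counts).  Zero cells are rejected
    (use the logistic route or a continuity correction instead).
    """
    counts = (cases_exposed, controls_exposed, cases_ref, controls_ref)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    if any(c == 0 for c in counts):
        raise ValueError(
            "zero cell in 2x2 table; fit the logistic model or apply a continuity "
            "correction instead of the closed form"
        )
    log_or = np.log(cases_exposed * controls_ref / (controls_exposed * cases_ref))
    se = np.sqrt(sum(1.0 / c for c in counts))
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = 2.0 * stats.norm.sf(abs(log_or) / se)
    return (
        float(np.exp(log_or)),
        float(np.exp(log_or - z * se)),
        float(np.exp(log_or + z * se)),
        float(p),
    )


def per_snp_association(genotypes: GenotypeMatrix, y: np.ndarray) -> pd.DataFrame:
    """Univariable logistic association of status on each SNP's dosage.

    Returns one row per SNP: control effect-allele frequency (mean control
    dosage / 2), OR with 95% Wald CI and p.  Monomorphic SNPs are flagged and
    left without an estimate.
    """
    y = np.asarray(y)
    if len(y) != genotypes.n_individuals:
        raise ValueError("status vector does not align with genotype rows")
    rows = []
    for j, rsid in enumerate(genotypes.snp_ids):
        dose = genotypes.dosages[:, j]
        ok = ~np.isnan(dose)
        d, yy = dose[ok], y[ok]
        eaf = float(np.nanmean(dose[ok & (y == 0)]) / 2.0) if (ok & (y == 0)).any() else np.nan
        if np.nanmin(d) == np.nanmax(d):
            rows.append({"rsid": rsid, "eaf_controls": eaf, "or": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                         "flag": "monomorphic"})
            continue
        X = np.column_stack([np.ones(len(d)), d])
        fit = fit_logistic(X, yy, ["intercept", "dosage"])
        orr, lo, hi, p = wald_or(fit, "dosage")
        rows.append({"rsid": rsid, "eaf_controls": eaf, "or": orr,
                     "ci_low": lo, "ci_high": hi, "p": p,
                     "flag": "" if fit.converged else "non-converged"})
    return pd.DataFrame(rows)


def spearman_screen(
    factors: pd.DataFrame,
    restrict_to: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Pair-wise Spearman rank correlations over the given columns.

    Uses mid-rank tie handling and pairwise-complete observations; p-values
    come from the two-sided t approximation.  ``restrict_to`` is a boolean
    row mask (e.g. controls only).  Constant columns are flagged with an
    undefined correlation.
    """
    if restrict_to is not None:
        factors = factors.loc[np.asarray(restrict_to, dtype=bool)]
    cols = list(factors.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = factors[cols[i]], factors[cols[j]]
            ok = a.notna() & b.notna()
            if ok.sum() < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({cols[i]}, {cols[j]})")
            x, z = a[ok].to_numpy(float), b[ok].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(z) == 0:
                rows.append({"factor_a": cols[i], "factor_b": cols[j],
                             "rho": np.nan, "p": np.nan, "n": int(ok.sum()),
                             "flag": "constant"})
                continue
            rho, p = stats.spearmanr(x, z)
            rows.append({"factor_a": cols[i], "factor_b": cols[j],
                         "rho": float(rho), "p": float(p), "n": int(ok.sum()),
                         "flag": ""})
    return pd.DataFrame(rows)
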