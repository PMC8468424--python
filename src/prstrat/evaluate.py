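"""Evaluation surface for the integrated risk model.

Covers quantile-bin odds-ratio tables (the decile stratification of the
predicted risk probability), the Hosmer–Lemeshow goodness-of-fit test, AUC
with the DeLong variance and CI, threshold sensitivity/specificity, and the
multivariable model combining the PRS with the ten classical risk factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import LogisticFit, fit_logistic, or_2x2, wald_or
from .panel import FFTP_BANDS, NULLIPAROUS_CODE, RISK_FACTORS


@dataclass
class StratumResult:
    bin_index: int
    n_controls: int
    n_cases: int
    pct_controls: float
    pct_cases: float
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p: float | None
    is_reference: bool
    flag: str = ""


@dataclass
class CalibrationResult:
    chi2: float
    df: int
    p: float
    table: pd.DataFrame  # per-group n, observed and expected case counts


@dataclass
class DiscriminationResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float


@dataclass
class IntegratedModelResult:
    fit: LogisticFit
    discrimination: DiscriminationResult
    calibration: CalibrationResult
    sensitivity: float
    specificity: float
    decile_table: list[StratumResult]
    p_hat: np.ndarray = field(repr=False, default=None)


def stratified_or_table(
    bins: np.ndarray, y: np.ndarray, ref_bin: int
) -> list[StratumResult]:
    """Per-bin counts, status-group percentages, and ORs against a reference bin.

    The OR for bin b is the 2x2 closed form (cases_b * controls_ref) /
    (controls_b * cases_ref) — identical to the logistic point estimate with a
    bin indicator — with Wald CI and two-sided p.  Bins lacking either status
    are flagged and carry no estimate.
    """
    bins = np.asarray(bins)
    y = np.asarray(y)
    labels = np.unique(bins)
    cases_ref = int(((bins == ref_bin) & (y == 1)).sum())
    controls_ref = int(((bins == ref_bin) & (y == 0)).sum())
    if ref_bin not in labels or cases_ref == 0 or controls_ref == 0:
        raise ValueError(f"reference bin {ref_bin} must contain both cases and controls")
    total_cases = int((y == 1).sum())
    total_controls = int((y == 0).sum())

    out = []
    for b in labels:
        n_cases = int(((bins == b) & (y == 1)).sum())
        n_controls = int(((bins == b) & (y == 0)).sum())
        row = StratumResult(
            bin_index=int(b),
            n_controls=n_controls,
            n_cases=n_cases,
            pct_controls=100.0 * n_controls / total_controls,
            pct_cases=100.0 * n_cases / total_cases,
            odds_ratio=None,
            ci_low=None,
            ci_high=None,
            p=None,
            is_reference=(b == ref_bin),
        )
        if b == ref_bin:
            row.odds_ratio = 1.0
        elif n_cases == 0 or n_controls == 0:
            row.flag = "empty-status"
        else:
            orr, lo, hi, p = or_2x2(n_cases, n_controls, cases_ref, controls_ref)
            row.odds_ratio, row.ci_low, row.ci_high, row.p = orr, lo, hi, p
        out.append(row)
    return out


def strata_frame(table: list[StratumResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin": [r.bin_index for r in table],
            "n_controls": [r.n_controls for r in table],
            "pct_controls": [r.pct_controls for r in table],
            "n_cases": [r.n_cases for r in table],
            "pct_cases": [r.pct_cases for r in table],
            "or": [r.odds_ratio for r in table],
            "ci_low": [r.ci_low for r in table],
            "ci_high": [r.ci_high for r in table],
            "p": [r.p for r in table],
            "reference": [r.is_reference for r in table],
        }
    )


def hosmer_lemeshow(
    p_hat: np.ndarray, y: np.ndarray, n_groups: int = 10
) -> CalibrationResult:
    """Hosmer–Lemeshow chi-square calibration test.

    Individuals are sorted by predicted probability and split into
    ``n_groups`` near-equal groups; identical probabilities never straddle a
    boundary (the boundary shifts to the next distinct value).  The statistic
    sums (O-E)^2/E over the event and non-event cells of every group and is
    referred to chi-square with n_groups - 2 degrees of freedom.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(p_hat)
    if n < n_groups:
        raise ValueError("fewer observations than groups")
    if (p_hat <= 0).any() or (p_hat >= 1).any():
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")

    order = np.argsort(p_hat, kind="mergesort")
    ps, ys = p_hat[order], y[order]
    # nominal boundaries, then shifted forward past runs of tied probabilities
    bounds = [round(n * g / n_groups) for g in range(1, n_groups)]
    adjusted = []
    for b in bounds:
        while 0 < b < n and ps[b] == ps[b - 1]:
            b += 1
        if adjusted and b <= adjusted[-1]:
            continue
        if b < n:
            adjusted.append(b)
    edges = [0] + adjusted + [n]

    chi2 = 0.0
    rows = []
    for g in range(len(edges) - 1):
        lo, hi = edges[g], edges[g + 1]
        n_g = hi - lo
        obs = float(ys[lo:hi].sum())
        exp = float(ps[lo:hi].sum())
        if exp <= 0 or exp >= n_g:
            raise ValueError(
                "a calibration group has zero expected events or non-events; "
                "use fewer groups"
            )
        chi2 += (obs - exp) ** 2 / exp + ((n_g - obs) - (n_g - exp)) ** 2 / (n_g - exp)
        rows.append({"group": g + 1, "n": n_g, "observed": obs, "expected": exp})

    df = len(edges) - 1 - 2
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return CalibrationResult(chi2=float(chi2), df=df, p=p, table=pd.DataFrame(rows))


def auc_delong(scores: np.ndarray, y: np.ndarray, level: float = 0.95) -> DiscriminationResult:
    """AUC (Mann–Whitney, ties counted 1/2) with the DeLong variance and a
    Wald CI clipped to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    cases = scores[y == 1]
    controls = scores[y == 0]
    m, n = len(cases), len(controls)
    if m == 0 or n == 0:
        raise ValueError("both cases and controls are required")

    # midrank placements: V10[i] = P(case_i > control) with ties 1/2, etc.
    all_scores = np.concatenate([cases, controls])
    ranks_all = stats.rankdata(all_scores)  # midranks
    ranks_cases = stats.rankdata(cases)
    ranks_controls = stats.rankdata(controls)
    v10 = (ranks_all[:m] - ranks_cases) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_controls) / m
    auc = float(v10.mean())

    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return DiscriminationResult(
        auc=auc,
        se=se,
        ci_low=float(max(0.0, auc - z * se)),
        ci_high=float(min(1.0, auc + z * se)),
    )


def sens_spec(p_hat: np.ndarray, y: np.ndarray, threshold: float = 0.5):
    """Sensitivity and specificity at a probability threshold (positive iff
    p_hat >= threshold)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y)
    cases = y == 1
    controls = y == 0
    if not cases.any() or not controls.any():
        raise ValueError("both cases and controls are required")
    positive = p_hat >= threshold
    sensitivity = float(positive[cases].mean())
    specificity = float((~positive[controls]).mean())
    return sensitivity, specificity


def build_integrated_design(cohort: pd.DataFrame, prs_scores: np.ndarray):
    """Design matrix for the multivariable model: intercept + PRS + the ten
    classical risk factors.

    The age-at-FFTP ordinal enters as indicator contrasts for bands 1-4, with
    nulliparous women folded into the reference band 0.  Continuous factors
    enter linearly; binary factors as 0/1 indicators.
    """
    n = len(cohort)
    cols = [np.ones(n), np.asarray(prs_scores, dtype=float)]
    names = ["intercept", "prs"]
    for factor in RISK_FACTORS:
        x = cohort[factor].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"missing values in {factor}; run the complete-case filter first")
        if factor == "age_fftp_cat":
            band = np.where(x == NULLIPAROUS_CODE, 0.0, x)
            for b in FFTP_BANDS[1:]:
                cols.append((band == b).astype(float))
                names.append(f"age_fftp_cat_{b}")
        else:
            cols.append(x)
            names.append(factor)
    return np.column_stack(cols), names


def decile_bins(p_hat: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Quantile bins of the pooled predicted-probability distribution.

    Cut-points are the k/n_bins type-7 quantiles of the whole sample (cases
    and controls pooled); assignment uses half-open [lower, upper) intervals
    with the last bin closed above.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    cuts = np.quantile(p_hat, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(cuts, p_hat, side="right") + 1


def integrated_model(
    cohort: pd.DataFrame,
    prs_scores: np.ndarray,
    n_bins: int = 10,
    ref_bin: int = 5,
    threshold: float = 0.5,
    hl_groups: int = 10,
) -> IntegratedModelResult:
    """Fit and evaluate the multivariable PRS + risk-factor model.

    Fits the logistic model on complete-case inputs, bins fitted probabilities
    into deciles of the whole analysis sample, and evaluates the decile OR
    table (5th decile reference), Hosmer–Lemeshow calibration, DeLong AUC and
    threshold sensitivity/specificity.
    """
    y = cohort["status"].to_numpy()
    X, names = build_integrated_design(cohort, prs_scores)
    fit = fit_logistic(X, y, names)
    from scipy.special import expit

    p_hat = expit(X @ fit.coefficients)
    bins = decile_bins(p_hat, n_bins)
    table = stratified_or_table(bins, y, ref_bin)
    discrimination = auc_delong(p_hat, y)
    calibration = hosmer_lemeshow(p_hat, y, hl_groups)
    sensitivity, specificity = sens_spec(p_hat, y, threshold)
    return IntegratedModelResult(
        fit=fit,
        discrimination=discrimination,
        calibration=calibration,
        sensitivity=sensitivity,
        specificity=specificity,
        decile_table=table,
        p_hat=p_hat,
    )


def cross_validated_auc(
    cohort: pd.DataFrame,
    prs_scores: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
) -> DiscriminationResult:
    """Out-of-fold AUC of the integrated model.

    The apparent (in-sample) AUC of a freely fitted multivariable model is
    optimistic — under a null generating model it sits above 0.5 by an
    overfitting term that shrinks with n.  K-fold cross-validation removes
    that optimism: each individual's predicted probability comes from a model
    fitted without them, and the DeLong machinery is applied to the pooled
    out-of-fold predictions.
    """
    y = cohort["status"].to_numpy()
    X, names = build_integrated_design(cohort, prs_scores)
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    fold = rng.permutation(len(y)) % n_folds
    p_hat = np.empty(len(y))
    for k in range(n_folds):
        train = fold != k
        fit = fit_logistic(X[train], y[train], names)
        p_hat[~train] = expit(X[~train] @ fit.coefficients)
    return auc_delong(p_hat, y)


def roc_coordinates(scores: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """ROC curve coordinates (FPR, TPR) at every distinct score threshold."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    thresholds = np.unique(scores)[::-1]
    cases = (y == 1).sum()
    controls = (y == 0).sum()
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for t in thresholds:
        positive = scores >= t
        rows.append(
            {
                "threshold": float(t),
                "fpr": float((positive & (y == 0)).sum() / controls),
                "tpr": float((positive & (y == 1)).sum() / cases),
            }
        )
    return pd.DataFrame(rows)
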