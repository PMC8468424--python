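"""Synthetic case-control cohort generator.

Emulates a retrospective (case-control) breast-cancer study: a prospective
population model — Hardy–Weinberg genotypes at published allele frequencies,
independently drawn classical risk factors, and a logistic disease model —
sampled by rejection until fixed case and control quotas are met.  The
generating truth (all log-ORs, the calibrated intercept, the seed) is returned
alongside the data so downstream estimators can be tested for parameter
recovery.

Default quotas are 1109 cases and 1177 controls; default SNP effects are the
natural logs of the published per-allele odds ratios of the 15-SNP panel.
Covariate marginals and effects are a documented plausible set (the source
study prints none) and are fully configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .panel import (
    COHORT_COLUMNS,
    NULLIPAROUS_CODE,
    GenotypeMatrix,
    SnpRecord,
    load_panel,
    weights_from_panel,
)
import pandas as pd


@dataclass
class BinaryFactor:
    prevalence: float
    beta: float


@dataclass
class ContinuousFactor:
    mean: float
    sd: float
    beta: float  # per unit, applied to the deviation from `mean`


@dataclass
class OrdinalFactor:
    """5-year age-at-FFTP bands among parous women; beta is per band."""

    probs: tuple[float, ...]
    beta: float


def default_covariate_spec() -> dict:
    """Plausible marginals and effects for the 10 classical risk factors.

    These values are a synthetic, documented choice (rates typical of
    Mediterranean screening-age cohorts; modest effect sizes of the usual
    sign) — they are not estimates from any study.
    """
    return {
        "menopausal": BinaryFactor(prevalence=0.65, beta=math.log(1.2)),
        "age_menarche": ContinuousFactor(mean=13.0, sd=1.5, beta=math.log(0.95)),
        "parous": BinaryFactor(prevalence=0.85, beta=math.log(0.8)),
        "age_fftp_cat": OrdinalFactor(
            probs=(0.15, 0.35, 0.30, 0.15, 0.05), beta=math.log(1.10)
        ),
        "breastfed": BinaryFactor(prevalence=0.60, beta=math.log(0.85)),
        "height_cm": ContinuousFactor(mean=162.0, sd=6.0, beta=math.log(1.01)),
        "bmi": ContinuousFactor(mean=27.0, sd=4.5, beta=math.log(1.02)),
        "hrt": BinaryFactor(prevalence=0.20, beta=math.log(1.2)),
        "smoker": BinaryFactor(prevalence=0.25, beta=math.log(1.1)),
        "family_history": BinaryFactor(prevalence=0.12, beta=math.log(1.8)),
    }


@dataclass
class SimulationSpec:
    """Full description of one synthetic cohort draw."""

    n_cases: int = 1109
    n_controls: int = 1177
    panel: list[SnpRecord] | None = None
    snp_betas: list[float] | None = None
    covariate_spec: dict = field(default_factory=default_covariate_spec)
    prevalence: float | None = 0.1  # target population prevalence
    intercept: float | None = None  # fixed logistic intercept (overrides prevalence)
    missing_rates: dict = field(default_factory=dict)
    seed: int = 0
    max_draws: int = 2_000_000

    def __post_init__(self) -> None:
        if self.panel is None:
            self.panel = load_panel()
        if self.snp_betas is None:
            self.snp_betas = [w.beta for w in weights_from_panel(self.panel)]
        if len(self.snp_betas) != len(self.panel):
            raise ValueError("snp_betas length does not match panel")
        if not all(np.isfinite(self.snp_betas)):
            raise ValueError("snp_betas must be finite")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("case and control quotas must be >= 1")
        if self.intercept is None and self.prevalence is None:
            raise ValueError("need either a fixed intercept or a target prevalence")
        if self.prevalence is not None and not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        for rate in self.missing_rates.values():
            if not 0.0 <= rate <= 1.0:
                raise ValueError("missing rates must lie in [0, 1]")

    def to_yaml(self, path) -> None:
        doc = {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "snp_betas": [float(b) for b in self.snp_betas],
            "prevalence": self.prevalence,
            "intercept": self.intercept,
            "missing_rates": {k: float(v) for k, v in self.missing_rates.items()},
            "seed": self.seed,
            "covariates": {
                name: vars(fac) if not isinstance(fac, OrdinalFactor)
                else {"probs": list(fac.probs), "beta": fac.beta}
                for name, fac in self.covariate_spec.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        cov = {}
        for name, entry in (doc.get("covariates") or {}).items():
            if "probs" in entry:
                cov[name] = OrdinalFactor(probs=tuple(entry["probs"]), beta=entry["beta"])
            elif "prevalence" in entry:
                cov[name] = BinaryFactor(**entry)
            else:
                cov[name] = ContinuousFactor(**entry)
        kwargs = {k: doc[k] for k in
                  ("n_cases", "n_controls", "snp_betas", "prevalence", "intercept",
                   "missing_rates", "seed") if k in doc and doc[k] is not None}
        if cov:
            kwargs["covariate_spec"] = cov
        return cls(**kwargs)


# ---------------------------------------------------------------------------


def simulate_genotypes(n: int, mafs, seed: int) -> GenotypeMatrix:
    """Hardy–Weinberg genotypes: each dosage ~ Binomial(2, maf), independent."""
    mafs = np.asarray(mafs, dtype=float)
    if ((mafs < 0) | (mafs > 0.5)).any():
        raise ValueError("minor-allele frequencies must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, mafs, size=(n, len(mafs))).astype(float)
    ids = [f"ind{i:07d}" for i in range(n)]
    snp_ids = [f"snp{j}" for j in range(len(mafs))]
    return GenotypeMatrix(ids, snp_ids, dosages)


def simulate_covariates(n: int, covariate_spec: dict, seed: int) -> pd.DataFrame:
    """Draw the 10 classical risk factors from their stated marginals.

    Breastfeeding is generated only for parous women (0 otherwise); nulliparous
    women receive the distinct nulliparous age-at-FFTP code.
    """
    rng = np.random.default_rng(seed)
    out = {}
    parous = None
    for name in ("menopausal", "age_menarche", "parous", "age_fftp_cat",
                 "breastfed", "height_cm", "bmi", "hrt", "smoker", "family_history"):
        fac = covariate_spec[name]
        if name == "parous":
            parous = rng.binomial(1, fac.prevalence, n)
            out[name] = parous.astype(float)
        elif name == "age_fftp_cat":
            probs = np.asarray(fac.probs, dtype=float)
            cats = rng.choice(len(probs), size=n, p=probs / probs.sum())
            out[name] = np.where(parous == 1, cats, NULLIPAROUS_CODE).astype(float)
        elif name == "breastfed":
            bf = rng.binomial(1, fac.prevalence, n)
            out[name] = np.where(parous == 1, bf, 0).astype(float)
        elif isinstance(fac, BinaryFactor):
            out[name] = rng.binomial(1, fac.prevalence, n).astype(float)
        else:
            out[name] = rng.normal(fac.mean, fac.sd, n)
    return pd.DataFrame(out)


def covariate_linear_predictor(covariates: pd.DataFrame, covariate_spec: dict) -> np.ndarray:
    """Risk-factor contribution to the logistic linear predictor.

    Continuous factors contribute beta * (x - mean) so the intercept retains a
    baseline-risk interpretation; the ordinal FFTP factor contributes beta *
    band with the nulliparous code folded into band 0 (contribution 0).
    """
    eta = np.zeros(len(covariates))
    for name, fac in covariate_spec.items():
        x = covariates[name].to_numpy(dtype=float)
        if isinstance(fac, ContinuousFactor):
            eta += fac.beta * (x - fac.mean)
        elif isinstance(fac, OrdinalFactor):
            band = np.where(x == NULLIPAROUS_CODE, 0.0, x)
            eta += fac.beta * band
        else:
            eta += fac.beta * x
    return eta


def calibrate_intercept(spec: SimulationSpec, eta_sample: np.ndarray) -> float:
    """Intercept giving the target population prevalence, by root bracketing
    on a Monte Carlo sample of the non-intercept linear predictor."""
    target = spec.prevalence

    def gap(c: float) -> float:
        return float(expit(c + eta_sample).mean()) - target

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise RuntimeError("prevalence calibration failed to bracket the intercept")
    return float(brentq(gap, lo, hi, xtol=1e-10))


def _draw_population(spec: SimulationSpec, n: int, seed: int):
    mafs = [rec.published_eaf for rec in spec.panel]
    geno = simulate_genotypes(n, mafs, seed)
    geno.snp_ids = [rec.rsid for rec in spec.panel]
    cov = simulate_covariates(n, spec.covariate_spec, seed + 1)
    eta0 = geno.dosages @ np.asarray(spec.snp_betas) + covariate_linear_predictor(
        cov, spec.covariate_spec
    )
    return geno, cov, eta0


def simulate_cohort(spec: SimulationSpec):
    """Rejection-sample a case-control cohort from the population model.

    Returns (cohort DataFrame, GenotypeMatrix, truth dict).  The cohort has
    exactly ``spec.n_cases`` cases and ``spec.n_controls`` controls, cases
    first; ids are fresh and shared between the two tables.  The truth dict
    records every generating parameter for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.intercept is not None:
        intercept = float(spec.intercept)
    else:
        _, _, eta_cal = _draw_population(spec, 50_000, int(rng.integers(2**31 - 1)))
        intercept = calibrate_intercept(spec, eta_cal)

    need_cases, need_controls = spec.n_cases, spec.n_controls
    got_cases = got_controls = 0
    kept_geno, kept_cov, kept_status = [], [], []
    drawn = 0
    batch = max(4 * (need_cases + need_controls), 1000)
    while got_cases < need_cases or got_controls < need_controls:
        if drawn >= spec.max_draws:
            raise RuntimeError(
                f"case/control quota unreachable within {spec.max_draws} draws "
                f"(have {got_cases}/{need_cases} cases, {got_controls}/{need_controls} controls)"
            )
        n = min(batch, spec.max_draws - drawn)
        geno, cov, eta0 = _draw_population(spec, n, int(rng.integers(2**31 - 1)))
        drawn += n
        y = rng.binomial(1, expit(intercept + eta0))
        take = np.zeros(n, dtype=bool)
        case_idx = np.flatnonzero(y == 1)[: need_cases - got_cases]
        ctrl_idx = np.flatnonzero(y == 0)[: need_controls - got_controls]
        take[case_idx] = True
        take[ctrl_idx] = True
        got_cases += len(case_idx)
        got_controls += len(ctrl_idx)
        kept_geno.append(geno.dosages[take])
        kept_cov.append(cov.loc[take])
        kept_status.append(y[take])

    dosages = np.vstack(kept_geno)
    covariates = pd.concat(kept_cov, ignore_index=True)
    status = np.concatenate(kept_status)
    order = np.argsort(-status, kind="stable")  # cases first, draw order within
    dosages, status = dosages[order], status[order]
    covariates = covariates.iloc[order].reset_index(drop=True)

    ids = [f"sub{i:06d}" for i in range(len(status))]
    genotypes = GenotypeMatrix(ids, [rec.rsid for rec in spec.panel], dosages)
    cohort = covariates.copy()
    cohort.insert(0, "status", status)
    cohort.insert(0, "individual_id", ids)
    cohort = cohort[COHORT_COLUMNS]

    truth = {
        "snp_betas": {rec.rsid: float(b) for rec, b in zip(spec.panel, spec.snp_betas)},
        "covariate_betas": {name: fac.beta for name, fac in spec.covariate_spec.items()},
        "intercept": intercept,
        "prevalence_target": spec.prevalence,
        "seed": spec.seed,
        "n_population_drawn": drawn,
    }
    return cohort, genotypes, truth


def inject_missingness(cohort: pd.DataFrame, missing_rates: dict, seed: int) -> pd.DataFrame:
    """Set each field missing independently at its stated rate (status never)."""
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for field_name, rate in missing_rates.items():
        if field_name in ("status", "individual_id"):
            raise ValueError(f"cannot inject missingness into {field_name}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError("missing rate outside [0, 1]")
        mask = rng.random(len(out)) < rate
        out.loc[mask, field_name] = np.nan
    return out


def inject_genotype_missingness(matrix: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set each dosage missing independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("missing rate outside [0, 1]")
    rng = np.random.default_rng(seed)
    dosages = matrix.dosages.copy()
    dosages[rng.random(dosages.shape) < rate] = np.nan
    return GenotypeMatrix(list(matrix.individual_ids), list(matrix.snp_ids), dosages)
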