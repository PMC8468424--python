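"""Polygenic risk score computation, summaries, and control-anchored binning.

The score for an individual is the weighted allele count

    PRS = sum_k beta_k * x_k,

where x_k in {0, 1, 2} counts copies of the published minor allele of SNP k
and beta_k is the natural log of that SNP's published per-allele odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypeMatrix, PrsWeight

MISSING_POLICIES = ("expected_dosage", "zero", "drop_individual")


@dataclass(frozen=True)
class PrsResult:
    individual_id: str
    score: float
    n_imputed: int


def compute_prs(
    genotypes: GenotypeMatrix,
    weights: list[PrsWeight],
    missing_policy: str = "expected_dosage",
    status: np.ndarray | None = None,
    published_mafs: list[float] | None = None,
) -> list[PrsResult]:
    """Score every individual.

    Missing dosages are handled per policy: ``expected_dosage`` fills
    2 * (control minor-allele frequency), computed from the supplied cohort's
    controls via ``status`` (0/1 per row of the matrix) or, failing that, from
    ``published_mafs``; ``zero`` fills 0; ``drop_individual`` omits individuals
    with any missing dosage.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    by_rsid = {w.rsid: w for w in weights}
    absent = [rsid for rsid in by_rsid if rsid not in genotypes.snp_ids]
    if absent:
        raise ValueError(f"weights without matching genotype column: {absent}")
    cols = [genotypes.snp_ids.index(rsid) for rsid in by_rsid]
    dosages = genotypes.dosages[:, cols]
    betas = np.array([w.beta for w in by_rsid.values()])

    missing = np.isnan(dosages)
    filled = dosages.copy()
    if missing.any():
        if missing_policy == "zero":
            filled[missing] = 0.0
        elif missing_policy == "expected_dosage":
            fill = _expected_dosage_fill(dosages, status, published_mafs, list(by_rsid))
            filled[missing] = np.broadcast_to(fill, dosages.shape)[missing]

    scores = filled @ betas
    n_imputed = missing.sum(axis=1)
    results = []
    for i, ind in enumerate(genotypes.individual_ids):
        if missing_policy == "drop_individual" and n_imputed[i] > 0:
            continue
        results.append(PrsResult(ind, float(scores[i]), int(n_imputed[i])))
    return results


def _expected_dosage_fill(dosages, status, published_mafs, rsids) -> np.ndarray:
    if status is not None:
        controls = dosages[np.asarray(status) == 0]
        freq = np.nanmean(controls, axis=0) / 2.0
        if np.isnan(freq).any():
            bad = [rsids[j] for j in np.flatnonzero(np.isnan(freq))]
            raise ValueError(f"no observed control dosages to impute from for {bad}")
        return 2.0 * freq
    if published_mafs is not None:
        return 2.0 * np.asarray(published_mafs, dtype=float)
    raise ValueError(
        "expected_dosage imputation needs control status or published MAFs"
    )


def scores_frame(results: list[PrsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in results],
            "score": [r.score for r in results],
            "n_imputed": [r.n_imputed for r in results],
        }
    )


def summarize_prs(results: list[PrsResult], status: pd.Series | np.ndarray) -> pd.DataFrame:
    """Mean and sample SD of the score per status group and overall.

    ``status`` aligns with ``results`` by position (one entry per scored
    individual, 0 = control, 1 = case).
    """
    scores = np.array([r.score for r in results])
    status = np.asarray(status)
    if len(status) != len(scores):
        raise ValueError("status does not align with scores")
    rows = []
    for label, mask in (("controls", status == 0), ("cases", status == 1), ("overall", slice(None))):
        grp = scores[mask]
        if grp.size == 0:
            raise ValueError(f"empty group: {label}")
        rows.append({"group": label, "n": int(grp.size), "mean": float(grp.mean()),
                     "sd": float(grp.std(ddof=1)) if grp.size > 1 else 0.0})
    return pd.DataFrame(rows)


def control_quantile_bins(
    scores: np.ndarray, status: np.ndarray, n_bins: int = 4
) -> np.ndarray:
    """Assign every individual to a quantile bin anchored on the controls.

    Cut-points are the k/n_bins quantiles (k = 1..n_bins-1) of the CONTROL
    score distribution, computed with linear interpolation of the empirical
    distribution (the "type 7" convention).  Bin b (1-based) is the half-open
    interval [cut_{b-1}, cut_b); the last bin is closed above, so any case
    scoring beyond the control range still lands in an extreme bin.
    """
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    controls = scores[status == 0]
    if len(np.unique(controls)) < n_bins:
        raise ValueError("too few distinct control scores to form the requested bins")
    cuts = np.quantile(controls, np.arange(1, n_bins) / n_bins)
    if len(np.unique(cuts)) < len(cuts):
        raise ValueError("degenerate control distribution: tied quantile cut-points")
    # searchsorted(side="right") puts a score equal to a cut-point in the
    # upper bin, i.e. intervals are [lower, upper).
    return np.searchsorted(cuts, scores, side="right") + 1


def standardized_scores(scores: np.ndarray, status: np.ndarray) -> np.ndarray:
    """Score rescaled to control-SD units (control mean subtracted).

    Emitted alongside the raw score because per-unit odds ratios for a PRS are
    conventionally reported on either scale.
    """
    scores = np.asarray(scores, dtype=float)
    controls = scores[np.asarray(status) == 0]
    sd = controls.std(ddof=1)
    if sd == 0:
        raise ValueError("control scores have zero variance")
    return (scores - controls.mean()) / sd
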