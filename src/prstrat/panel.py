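"""SNP panel, genotype and cohort data model with readers/writers.

The panel is a fixed set of 15 GWAS-identified breast-cancer susceptibility
SNPs.  Each record carries the published (source-consortium) effect-allele
frequency and per-allele odds ratio; the effect allele is always the published
minor allele (frequency in (0, 0.5]), so PRS weights attach to a stable allele
orientation regardless of the frequency observed in any analysis cohort.

Genotypes are additive minor-allele dosages in {0, 1, 2}, stored as floats
with NaN marking missingness.  The cohort table holds case/control status plus
ten classical breast-cancer risk factors.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")
VALID_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X"])

#: Columns of a cohort table: identifier, outcome, and the 10 classical risk
#: factors.  ``age_fftp_cat`` is an ordinal 5-year band (0..4) with a distinct
#: nulliparous code (NULLIPAROUS_CODE).
COHORT_COLUMNS = [
    "individual_id",
    "status",
    "menopausal",
    "age_menarche",
    "parous",
    "age_fftp_cat",
    "breastfed",
    "height_cm",
    "bmi",
    "hrt",
    "smoker",
    "family_history",
]

RISK_FACTORS = COHORT_COLUMNS[2:]

BINARY_FACTORS = ["menopausal", "parous", "breastfed", "hrt", "smoker", "family_history"]
CONTINUOUS_FACTORS = ["age_menarche", "height_cm", "bmi"]

#: Ordinal code for "never had a full-term pregnancy" in age_fftp_cat.  In the
#: integrated risk model this code is folded into band 0 (the reference band).
NULLIPAROUS_CODE = 5
FFTP_BANDS = (0, 1, 2, 3, 4)

_PANEL_COLUMNS = [
    "chrom",
    "rsid",
    "pos_b37",
    "ref_allele",
    "effect_allele",
    "eaf_published",
    "or_published",
    "p_published",
]


class PanelError(ValueError):
    """Invalid SNP panel contents."""


@dataclass(frozen=True)
class SnpRecord:
    """One panel SNP with its published frequency and effect size."""

    rsid: str
    chromosome: str
    position: int
    reference_allele: str
    effect_allele: str
    published_eaf: float
    published_or: float
    published_p: float

    def __post_init__(self) -> None:
        if self.reference_allele not in VALID_ALLELES:
            raise PanelError(f"{self.rsid}: invalid reference allele {self.reference_allele!r}")
        if self.effect_allele not in VALID_ALLELES:
            raise PanelError(f"{self.rsid}: invalid effect allele {self.effect_allele!r}")
        if self.reference_allele == self.effect_allele:
            raise PanelError(f"{self.rsid}: reference and effect allele are identical")
        if str(self.chromosome) not in VALID_CHROMOSOMES:
            raise PanelError(f"{self.rsid}: invalid chromosome {self.chromosome!r}")
        if not 0.0 < self.published_eaf <= 0.5:
            raise PanelError(
                f"{self.rsid}: published effect-allele frequency {self.published_eaf} "
                "outside (0, 0.5]; the effect allele must be the published minor allele"
            )
        if not self.published_or > 0:
            raise PanelError(f"{self.rsid}: published OR must be positive")
        if not 0.0 < self.published_p <= 1.0:
            raise PanelError(f"{self.rsid}: published p-value outside (0, 1]")


@dataclass(frozen=True)
class PrsWeight:
    """Log-OR weight for one SNP's minor allele."""

    rsid: str
    minor_allele: str
    beta: float


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive minor-allele dosages.

    ``dosages`` is a float array with entries in {0, 1, 2} and NaN for
    missing genotypes; column order follows ``snp_ids``.
    """

    individual_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.individual_ids) or m != len(self.snp_ids):
            raise ValueError("dosage shape does not match id lists")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage {bad!r} outside {{0,1,2}}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def n_missing(self) -> int:
        return int(np.isnan(self.dosages).sum())

    def subset_rows(self, mask: np.ndarray) -> "GenotypeMatrix":
        ids = [i for i, keep in zip(self.individual_ids, mask) if keep]
        return GenotypeMatrix(ids, list(self.snp_ids), self.dosages[np.asarray(mask, bool)])


def default_panel_path():
    """Path to the packaged 15-SNP panel fixture (TSV)."""
    return importlib.resources.files("prstrat.data") / "panel_snps15.tsv"


def load_panel(path=None) -> list[SnpRecord]:
    """Load a SNP panel table, defaulting to the packaged 15-SNP fixture.

    Records are validated and returned sorted by (chromosome, position),
    chromosomes in karyotype order (1..22, X).
    """
    if path is None:
        path = default_panel_path()
    with open(path) as fh:
        table = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    missing_cols = set(_PANEL_COLUMNS) - set(table.columns)
    if missing_cols:
        raise PanelError(f"panel file missing columns: {sorted(missing_cols)}")
    if table["rsid"].duplicated().any():
        dups = table.loc[table["rsid"].duplicated(), "rsid"].tolist()
        raise PanelError(f"duplicate rsid(s) in panel: {dups}")
    records = [
        SnpRecord(
            rsid=row.rsid,
            chromosome=str(row.chrom),
            position=int(row.pos_b37),
            reference_allele=row.ref_allele,
            effect_allele=row.effect_allele,
            published_eaf=float(row.eaf_published),
            published_or=float(row.or_published),
            published_p=float(row.p_published),
        )
        for row in table.itertuples()
    ]

    def chrom_key(rec: SnpRecord):
        c = rec.chromosome
        return (23, rec.position) if c == "X" else (int(c), rec.position)

    return sorted(records, key=chrom_key)


def weights_from_panel(panel: list[SnpRecord]) -> list[PrsWeight]:
    """PRS weights: minor allele = published effect allele, beta = ln(published OR)."""
    weights = []
    for rec in panel:
        beta = math.log(rec.published_or)
        weights.append(PrsWeight(rsid=rec.rsid, minor_allele=rec.effect_allele, beta=beta))
    return weights


def panel_to_frame(panel: list[SnpRecord]) -> pd.DataFrame:
    """Panel as a DataFrame in the fixture's column layout."""
    rows = [dataclasses.asdict(rec) for rec in panel]
    df = pd.DataFrame(rows)
    return df.rename(
        columns={
            "chromosome": "chrom",
            "position": "pos_b37",
            "reference_allele": "ref_allele",
            "published_eaf": "eaf_published",
            "published_or": "or_published",
            "published_p": "p_published",
        }
    )[_PANEL_COLUMNS]


# ---------------------------------------------------------------------------
# genotype I/O


def read_genotypes(
    path,
    dialect: str,
    panel: list[SnpRecord],
    missing_marker: str = "NA",
) -> GenotypeMatrix:
    """Read a genotype table and align it to the panel.

    ``csv`` dialect: an ``id`` column plus one integer dosage column per rsID,
    counting copies of the panel minor allele.  ``plink_raw`` dialect: PLINK
    .raw layout (FID IID PAT MAT SEX PHENOTYPE then ``<rsid>_<allele>``
    columns, NA missing); when the counted allele in the header differs from
    the panel's minor allele the dosages are flipped (d -> 2 - d) and the flip
    recorded in the returned matrix's ``flipped_snps`` attribute.

    Raises if any panel SNP is absent or a dosage falls outside {0, 1, 2}.
    """
    if dialect == "csv":
        table = pd.read_csv(path, na_values=[missing_marker], keep_default_na=False)
        id_col = "id" if "id" in table.columns else table.columns[0]
        ids = table[id_col].astype(str).tolist()
        allele_of = {c: None for c in table.columns if c != id_col}
    elif dialect == "plink_raw":
        table = pd.read_csv(path, sep=r"\s+", na_values=["NA"], keep_default_na=False)
        meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if not set(meta).issubset(table.columns):
            raise ValueError("plink_raw file lacks the FID/IID/.../PHENOTYPE header")
        ids = table["IID"].astype(str).tolist()
        allele_of = {}
        for col in table.columns:
            if col in meta:
                continue
            rsid, _, allele = col.rpartition("_")
            if not rsid or allele not in VALID_ALLELES:
                raise ValueError(f"malformed plink_raw SNP column {col!r}")
            allele_of[col] = allele
            table = table.rename(columns={col: rsid})
            allele_of[rsid] = allele_of.pop(col)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")

    panel_minor = {rec.rsid: rec.effect_allele for rec in panel}
    absent = [rsid for rsid in panel_minor if rsid not in table.columns]
    if absent:
        raise ValueError(f"panel SNPs absent from genotype file: {absent}")

    snp_ids = [rec.rsid for rec in panel]
    dosages = table[snp_ids].to_numpy(dtype=float)
    bad = ~(np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"dosage {dosages[i, j]!r} outside {{0,1,2}} at row {i}, SNP {snp_ids[j]}"
        )

    flipped = []
    for j, rsid in enumerate(snp_ids):
        counted = allele_of.get(rsid)
        if counted is not None and counted != panel_minor[rsid]:
            dosages[:, j] = 2.0 - dosages[:, j]
            flipped.append(rsid)

    matrix = GenotypeMatrix(ids, snp_ids, dosages)
    matrix.flipped_snps = flipped
    return matrix


def write_genotypes(matrix: GenotypeMatrix, path, missing_marker: str = "NA") -> None:
    """Write a genotype matrix in the csv dialect (counted allele = panel minor)."""
    df = pd.DataFrame(matrix.dosages, columns=matrix.snp_ids)
    df = df.map(lambda v: missing_marker if np.isnan(v) else str(int(v)))
    df.insert(0, "id", matrix.individual_ids)
    df.to_csv(path, index=False)


def write_genotypes_plink_raw(
    matrix: GenotypeMatrix, panel: list[SnpRecord], path
) -> None:
    """Write a genotype matrix in the plink_raw dialect, counting the panel
    minor allele (header ``<rsid>_<allele>``), NA for missing."""
    minor = {rec.rsid: rec.effect_allele for rec in panel}
    header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + [
        f"{rsid}_{minor[rsid]}" for rsid in matrix.snp_ids
    ]
    with open(path, "w") as fh:
        fh.write(" ".join(header) + "\n")
        for i, ind in enumerate(matrix.individual_ids):
            row = [ind, ind, "0", "0", "2", "-9"]
            for v in matrix.dosages[i]:
                row.append("NA" if np.isnan(v) else str(int(v)))
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# cohort I/O


def read_cohort(path, missing_marker: str = "NA") -> pd.DataFrame:
    """Read a cohort CSV with the 12 documented columns.

    Status is coerced to {0, 1} (hard error otherwise).  Rows violating the
    "breastfeeding only among parous women" invariant have breastfed set to
    missing; the number of repairs is stored in ``df.attrs['breastfed_repairs']``.
    """
    df = pd.read_csv(path, na_values=[missing_marker], keep_default_na=False)
    if df.empty:
        raise ValueError(f"cohort file {path} is empty")
    missing_cols = set(COHORT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"cohort file missing columns: {sorted(missing_cols)}")
    df = df[COHORT_COLUMNS].copy()
    df["individual_id"] = df["individual_id"].astype(str)

    status = pd.to_numeric(df["status"], errors="coerce")
    if status.isna().any() or not status.isin([0, 1]).all():
        bad = df.loc[~status.isin([0, 1]), "status"].tolist()[:5]
        raise ValueError(f"unknown status code(s): {bad}")
    df["status"] = status.astype(int)

    for col in RISK_FACTORS:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    violates = (df["parous"] == 0) & df["breastfed"].notna() & (df["breastfed"] != 0)
    df.loc[violates, "breastfed"] = np.nan
    df.attrs["breastfed_repairs"] = int(violates.sum())
    return df


def write_cohort(df: pd.DataFrame, path, missing_marker: str = "NA") -> None:
    df.to_csv(path, index=False, na_rep=missing_marker)


def complete_case_filter(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix | None,
    required_fields: list[str] | None = None,
):
    """Restrict to individuals with complete observations in the required fields.

    Returns the filtered cohort, the row-matched genotype matrix (or None),
    and a report dict with removed counts by field and by case/control status.
    When genotypes are supplied, a missing dosage at any panel SNP also makes
    the row incomplete (field ``genotype``).
    """
    if required_fields is None:
        required_fields = RISK_FACTORS
    cohort = cohort.reset_index(drop=True)
    incomplete = pd.DataFrame(index=cohort.index)
    for field in required_fields:
        incomplete[field] = cohort[field].isna()
    if genotypes is not None:
        order = pd.Index(genotypes.individual_ids)
        if not order.equals(pd.Index(cohort["individual_id"])):
            raise ValueError("cohort and genotype individual ids do not align")
        incomplete["genotype"] = np.isnan(genotypes.dosages).any(axis=1)

    drop = incomplete.any(axis=1)
    report = {
        "n_input": int(len(cohort)),
        "n_removed": int(drop.sum()),
        "n_kept": int((~drop).sum()),
        "removed_by_field": {f: int(incomplete[f].sum()) for f in incomplete.columns},
        "removed_by_status": {
            "controls": int((drop & (cohort["status"] == 0)).sum()),
            "cases": int((drop & (cohort["status"] == 1)).sum()),
        },
    }
    kept = ~drop
    filtered_cohort = cohort.loc[kept].reset_index(drop=True)
    filtered_geno = genotypes.subset_rows(kept.to_numpy()) if genotypes is not None else None
    return filtered_cohort, filtered_geno, report
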