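"""Cohort inputs: phenotypes, gene panel, genotypes, exclusion regions.

The case definition is high myopia (HM) in school-aged children: spherical
equivalent refraction (SER) of -6.00 diopters or worse in both eyes together
with a decimal visual acuity below 1.0.  SER is derived from the refraction
measurement as ``sphere + cylinder / 2``.  HM cases are further split into
three severity strata:

* CHM (common high myopia):   -8.00 D <= SER <= -6.00 D
* UM  (ultra myopia):        -10.00 D <= SER <  -8.00 D
* EM  (extreme myopia):                  SER <  -10.00 D

and into three school-grade bands (primary / junior / senior), derived from
age when no explicit grade column is provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenePanelEntry",
    "Cohort",
    "CohortValidationError",
    "SEVERITY_LABELS",
    "GRADE_BANDS",
    "INHERITANCE_MODES",
    "PANEL_CATEGORIES",
    "compute_ser",
    "assign_severity",
    "assign_grade_band",
    "load_panel",
    "load_phenotypes",
    "write_phenotypes",
    "load_lcr",
    "read_cohort",
]

SEVERITY_LABELS = ("CHM", "UM", "EM")
GRADE_BANDS = ("primary", "junior", "senior")
INHERITANCE_MODES = ("AD", "AR", "XL")
PANEL_CATEGORIES = ("nonsyndromic_HM", "eye_syndrome", "systemic_syndrome")

PHENOTYPE_COLUMNS = [
    "sample_id", "age", "grade", "sex",
    "sphere_r", "cyl_r", "va_r", "sphere_l", "cyl_l", "va_l",
]

HM_SER_THRESHOLD = -6.0
HM_VA_THRESHOLD = 1.0

X_CHROMS = frozenset({"X", "chrX"})


class CohortValidationError(ValueError):
    """Raised when an input file violates the cohort contract."""


@dataclass(frozen=True)
class GenePanelEntry:
    """One panel gene with its inheritance mode and disease category."""

    symbol: str
    mode: str        # AD | AR | XL
    category: str    # nonsyndromic_HM | eye_syndrome | systemic_syndrome

    def __post_init__(self) -> None:
        if self.mode not in INHERITANCE_MODES:
            raise CohortValidationError(
                f"unknown inheritance mode {self.mode!r} for gene {self.symbol}")
        if self.category not in PANEL_CATEGORIES:
            raise CohortValidationError(
                f"unknown category {self.category!r} for gene {self.symbol}")


def compute_ser(sphere: float, cylinder: float) -> float:
    """Spherical equivalent refraction: sphere + cylinder / 2, in diopters.

    Cylinder is expected in minus-cylinder convention (<= 0); a positive
    cylinder is accepted with a warning so that plus-cylinder data are not
    silently misread.
    """
    if not (math.isfinite(sphere) and math.isfinite(cylinder)):
        raise CohortValidationError(
            f"non-finite refraction values sphere={sphere} cylinder={cylinder}")
    if cylinder > 0:
        warnings.warn(
            f"cylinder {cylinder} > 0: expected minus-cylinder convention",
            stacklevel=2)
    return sphere + cylinder / 2.0


def assign_severity(ser: float) -> str | None:
    """Map an SER value (diopters) to CHM / UM / EM, or None when not HM.

    Boundaries follow the half-open convention: SER of exactly -8.00 D is
    CHM, exactly -10.00 D is UM.
    """
    if not math.isfinite(ser):
        raise CohortValidationError(f"non-finite SER {ser}")
    if ser > HM_SER_THRESHOLD:
        return None
    if ser >= -8.0:
        return "CHM"
    if ser >= -10.0:
        return "UM"
    return "EM"


def assign_grade_band(age: float) -> str:
    """School grade band from age: <=11 primary, 12-14 junior, >=15 senior."""
    if age is None or (isinstance(age, float) and math.isnan(age)):
        raise CohortValidationError("missing age and no grade column")
    if not 5 <= age <= 20:
        warnings.warn(f"age {age} outside the expected school range 5-20",
                      stacklevel=2)
    if age <= 11:
        return "primary"
    if age <= 14:
        return "junior"
    return "senior"


def load_panel(path: str | Path) -> list[GenePanelEntry]:
    """Read a gene-panel TSV with columns symbol / mode / category."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise CohortValidationError(f"empty panel: {path}")
    required = {"symbol", "mode", "category"}
    missing = required - set(df.columns)
    if missing:
        raise CohortValidationError(
            f"panel {path} missing columns: {sorted(missing)}")
    dups = df["symbol"][df["symbol"].duplicated()].tolist()
    if dups:
        raise CohortValidationError(f"duplicate panel symbols: {sorted(set(dups))}")
    entries = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            entries.append(GenePanelEntry(row.symbol, row.mode, row.category))
        except CohortValidationError as exc:
            raise CohortValidationError(f"{path} line {i}: {exc}") from exc
    return entries


def _derive_phenotype_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for eye in ("r", "l"):
        df[f"ser_{eye}"] = [
            compute_ser(s, c)
            for s, c in zip(df[f"sphere_{eye}"], df[f"cyl_{eye}"])
        ]
    if "grade" in df.columns and df["grade"].notna().all():
        bad = set(df["grade"]) - set(GRADE_BANDS)
        if bad:
            raise CohortValidationError(f"unknown grade labels: {sorted(bad)}")
        df["grade_band"] = df["grade"]
    else:
        df["grade_band"] = [assign_grade_band(a) for a in df["age"]]
    return df


def load_phenotypes(path: str | Path, *, eligibility_check: bool = True) -> pd.DataFrame:
    """Read the phenotype TSV and derive per-eye SER, severity and grade band.

    With ``eligibility_check`` (the default), samples must satisfy the HM
    case definition (SER <= -6.00 D in both eyes and VA < 1.0); violations
    raise, listing the offending samples.  Disable only for synthetic
    edge-case inputs.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(PHENOTYPE_COLUMNS) - {"grade"} - set(df.columns)
    if missing:
        raise CohortValidationError(
            f"phenotype table {path} missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise CohortValidationError(f"duplicate sample ids: {dups}")
    df = _derive_phenotype_columns(df)
    if eligibility_check:
        bad = df[
            (df["ser_r"] > HM_SER_THRESHOLD) | (df["ser_l"] > HM_SER_THRESHOLD)
            | (df["va_r"] >= HM_VA_THRESHOLD) | (df["va_l"] >= HM_VA_THRESHOLD)
        ]
        if not bad.empty:
            raise CohortValidationError(
                "samples failing HM eligibility (SER <= -6 D both eyes, VA < 1.0): "
                + ", ".join(bad["sample_id"].astype(str).tolist()[:10]))
    return df.set_index("sample_id", drop=False)


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    """Write a phenotype table back to TSV (derived columns dropped)."""
    cols = [c for c in PHENOTYPE_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def severity_for_eye(df: pd.DataFrame, eye: str = "right") -> pd.Series:
    """Severity stratum per sample using the configured eye's SER.

    ``eye`` is one of right / left / mean / worse; ``worse`` takes the more
    myopic (more negative) eye.
    """
    if eye == "right":
        ser = df["ser_r"]
    elif eye == "left":
        ser = df["ser_l"]
    elif eye == "mean":
        ser = (df["ser_r"] + df["ser_l"]) / 2.0
    elif eye == "worse":
        ser = np.minimum(df["ser_r"], df["ser_l"])
    else:
        raise CohortValidationError(f"unknown eye choice {eye!r}")
    return pd.Series([assign_severity(s) for s in ser], index=df.index, name="severity")


def load_lcr(path: str | Path) -> dict[str, IntervalTree]:
    """Read a BED (0-based, half-open) of low-complexity regions per chrom."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CohortValidationError(f"{path} line {lineno}: malformed BED line")
            chrom, start, end = parts[0], parts[1], parts[2]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise CohortValidationError(
                    f"{path} line {lineno}: non-integer BED coordinates") from exc
            if end_i <= start_i:
                raise CohortValidationError(
                    f"{path} line {lineno}: empty/inverted interval")
            trees.setdefault(chrom, IntervalTree()).addi(start_i, end_i)
    return trees


@dataclass
class Cohort:
    """Sample x variant genotype matrix with phenotypes.

    Multi-allelic VCF records are decomposed at load: each alternate allele
    becomes one row of ``variants`` and genotypes are recoded as alt-allele
    counts for that allele (0/1/2, -1 missing).  Allelic depths are split
    per allele (ad_ref = depth of REF, ad_alt = depth of that ALT).
    """

    samples: list[str]
    phenotypes: pd.DataFrame
    variants: pd.DataFrame          # chrom, pos, ref, alt, filter_status
    counts: np.ndarray              # (n_variants, n_samples) int8, -1 = missing
    dp: np.ndarray                  # (n_variants, n_samples) int32
    gq: np.ndarray                  # int32
    ad_ref: np.ndarray              # int32
    ad_alt: np.ndarray              # int32
    male: np.ndarray = field(default=None)  # (n_samples,) bool

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> pd.Series:
        v = self.variants
        return (v["chrom"].astype(str) + ":" + v["pos"].astype(str)
                + ":" + v["ref"] + ":" + v["alt"])


_INT_MISSING = -2147483648  # htslib sentinel for absent integer FORMAT values


def _fmt_int(arr, n: int, n_cols: int = 1) -> np.ndarray:
    """Normalise a cyvcf2 FORMAT array to int32 with -1 for missing."""
    if arr is None:
        return np.full((n, n_cols), -1, dtype=np.int32)
    a = np.asarray(arr)
    if a.ndim == 1:
        a = a[:, None]
    a = a.astype(np.int64, copy=True)
    a[(a == _INT_MISSING) | (a < 0)] = -1
    return a.astype(np.int32)


def read_cohort(
    vcf_path: str | Path,
    phenotypes: str | Path | pd.DataFrame,
    *,
    eligibility_check: bool = True,
) -> Cohort:
    """Load a multi-sample VCF plus phenotypes into an aligned cohort.

    Every VCF sample must be present in the phenotype table; the genotype
    matrix follows the VCF sample order.  Multi-allelic records are
    decomposed into one biallelic row per alternate allele.
    """
    from cyvcf2 import VCF

    if isinstance(phenotypes, (str, Path)):
        pheno = load_phenotypes(phenotypes, eligibility_check=eligibility_check)
    else:
        pheno = phenotypes

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in pheno.index]
    if missing:
        raise CohortValidationError(
            "VCF samples absent from phenotype table: " + ", ".join(missing[:10]))
    pheno = pheno.loc[samples]

    n = len(samples)
    rows = []
    counts_l, dp_l, gq_l, adr_l, ada_l = [], [], [], [], []
    for rec in vcf:
        gt = rec.genotype.array()          # (n, ploidy+1); last col = phase
        alleles = gt[:, :-1]
        any_missing = (alleles < 0).any(axis=1)
        dp = _fmt_int(rec.format("DP"), n)[:, 0]
        gq = _fmt_int(rec.format("GQ"), n)[:, 0]
        n_alleles = 1 + len(rec.ALT)
        ad = _fmt_int(rec.format("AD"), n, n_alleles)
        filt = rec.FILTER or "PASS"
        for k, alt in enumerate(rec.ALT):
            cnt = (alleles == k + 1).sum(axis=1).astype(np.int8)
            cnt[any_missing] = -1
            rows.append((rec.CHROM, rec.POS, rec.REF, alt, filt))
            counts_l.append(cnt)
            dp_l.append(dp)
            gq_l.append(gq)
            adr_l.append(ad[:, 0])
            ada_l.append(ad[:, k + 1] if ad.shape[1] > k + 1
                         else np.full(n, -1, dtype=np.int32))
    vcf.close()

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                           "filter_status"])
    shape = (len(variants), n)
    male = (pheno["sex"] == "male").to_numpy()
    return Cohort(
        samples=samples,
        phenotypes=pheno,
        variants=variants,
        counts=(np.vstack(counts_l) if rows else np.empty(shape, np.int8)),
        dp=(np.vstack(dp_l) if rows else np.empty(shape, np.int32)),
        gq=(np.vstack(gq_l) if rows else np.empty(shape, np.int32)),
        ad_ref=(np.vstack(adr_l) if rows else np.empty(shape, np.int32)),
        ad_alt=(np.vstack(ada_l) if rows else np.empty(shape, np.int32)),
        male=male,
    )
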