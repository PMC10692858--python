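"""Variant filter cascade: site prefilter, genotype QC, rarity, consequence
class and inheritance-mode consistency.

The cascade keeps rare, putatively large-effect alleles in panel genes:

1. site prefilter — VQSR ``PASS`` only, outside low-complexity regions;
2. genotype QC — calls with DP < 10 or GQ < 20, and heterozygous calls with
   allele balance outside (0.2, 0.8), are masked to missing;
3. in-cohort allele frequency from the post-QC genotypes;
4. rarity — every external database MAF and the in-cohort AF must be
   <= 0.005 (absent from a database counts as frequency 0);
5. consequence class — protein-truncating (PTV: frameshift, splice
   acceptor/donor, stop gained, start lost), synonymous (negative control)
   or other; variants on a user-supplied known-variant list bypass the PTV
   requirement only;
6. inheritance-mode consistency — single heterozygous hits in autosomal
   recessive genes and homozygous hits in autosomal dominant genes are
   excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import Cohort, CohortValidationError, GenePanelEntry, X_CHROMS

logger = logging.getLogger(__name__)

__all__ = [
    "PTV_TERMS",
    "QcThresholds",
    "GenotypeCall",
    "AnnotatedVariant",
    "site_prefilter",
    "genotype_qc",
    "cohort_af",
    "format_maf",
    "rarity_filter",
    "classify_consequence",
    "inheritance_filter",
    "load_annotations",
    "load_known_variants",
    "known_variant_match",
    "apply_filter_cascade",
    "CascadeResult",
]

PTV_TERMS = frozenset({
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "start_lost",
})

_KNOWN_TERMS = PTV_TERMS | {
    "synonymous_variant", "missense_variant", "stop_lost", "inframe_deletion",
    "inframe_insertion", "intron_variant", "5_prime_UTR_variant",
    "3_prime_UTR_variant", "splice_region_variant", "upstream_gene_variant",
    "downstream_gene_variant", "protein_altering_variant",
}
_warned_terms: set[str] = set()

MAF_COLUMNS = ("maf_1kg", "maf_esp", "maf_gnomad")

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence_terms", "transcript",
    "hgvs_c", "hgvs_p", "lof_confidence", "maf_1kg", "maf_esp", "maf_gnomad",
]


@dataclass(frozen=True)
class QcThresholds:
    """Per-genotype QC cutoffs; all comparisons are strict."""

    dp_min: int = 10
    gq_min: int = 20
    ab_low: float = 0.2
    ab_high: float = 0.8


@dataclass(frozen=True)
class GenotypeCall:
    """One sample x variant genotype observation."""

    sample_id: str
    zygosity: str            # hom_ref | het | hom_alt | hemi | missing
    dp: int
    gq: int
    ad_ref: int = 0
    ad_alt: int = 0

    @property
    def allele_balance(self) -> float | None:
        total = self.ad_ref + self.ad_alt
        return self.ad_alt / total if total > 0 else None


@dataclass(frozen=True)
class AnnotatedVariant:
    """Site + allele with annotations consumed from the annotation table."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    consequence_terms: frozenset = frozenset()
    lof_confidence: str | None = None   # HC | LC | None
    maf_1kg: float | None = None
    maf_esp: float | None = None
    maf_gnomad: float | None = None
    cohort_af: float = 0.0

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def external_mafs(self) -> tuple:
        return (self.maf_1kg, self.maf_esp, self.maf_gnomad)

    @property
    def consequence_class(self) -> str:
        return classify_consequence(self.consequence_terms)


def site_prefilter(filter_status: str, chrom: str, pos: int,
                   lcr: Mapping | None = None) -> bool:
    """True iff the site passed VQSR and lies outside low-complexity regions.

    ``pos`` is the 1-based VCF coordinate; LCR intervals are 0-based
    half-open BED intervals.
    """
    if filter_status != "PASS":
        return False
    if lcr:
        tree = lcr.get(chrom)
        if tree is not None and tree.overlaps_point(pos - 1):
            return False
    return True


def genotype_qc(call: GenotypeCall, thresholds: QcThresholds = QcThresholds()
                ) -> GenotypeCall:
    """Mask a low-certainty genotype to missing; idempotent.

    A call is masked when DP < dp_min, GQ < gq_min, or — for heterozygous
    calls only — the allele balance is above ab_high or below ab_low.
    A het call with zero total allelic depth cannot be balance-checked and
    is masked.
    """
    if call.zygosity == "missing":
        return call
    if call.dp < thresholds.dp_min or call.gq < thresholds.gq_min:
        return replace(call, zygosity="missing")
    if call.zygosity == "het":
        ab = call.allele_balance
        if ab is None:
            logger.warning("het call %s with zero allelic depth masked",
                           call.sample_id)
            return replace(call, zygosity="missing")
        if ab > thresholds.ab_high or ab < thresholds.ab_low:
            return replace(call, zygosity="missing")
    return call


def cohort_af(calls: Sequence[GenotypeCall], n_samples: int | None = None,
              *, chrom: str = "1", male: Mapping[str, bool] | None = None
              ) -> float | None:
    """In-cohort alternate allele frequency from post-QC genotype calls.

    The allele number counts two alleles per non-missing diploid sample;
    on (non-PAR) X, males contribute one allele and a hemizygous alternate
    counts one.  Returns None when every call is missing.
    """
    ac = 0
    an = 0
    on_x = chrom in X_CHROMS
    for call in calls:
        if call.zygosity == "missing":
            continue
        is_male = bool(male and male.get(call.sample_id, False))
        if on_x and (is_male or call.zygosity == "hemi"):
            an += 1
            ac += 1 if call.zygosity in ("het", "hom_alt", "hemi") else 0
        else:
            an += 2
            ac += {"hom_ref": 0, "het": 1, "hom_alt": 2}.get(call.zygosity, 0)
    if an == 0:
        return None
    return ac / an


def format_maf(af: float) -> str:
    """Render an allele frequency the way variant tables print it, e.g.
    8.045e-05 -> '8.05e-05'."""
    return f"{af:.2e}"


def rarity_filter(variant: AnnotatedVariant, threshold: float = 0.005) -> bool:
    """Keep iff every available external MAF and the in-cohort AF are
    <= threshold.  A MAF absent from a database is treated as 0 (never
    observed)."""
    for maf in variant.external_mafs:
        if maf is not None and maf > threshold:
            return False
    return variant.cohort_af <= threshold


def classify_consequence(terms: Iterable[str]) -> str:
    """PTV / synonymous / other from a set of consequence terms.

    Any protein-truncating term wins; synonymous applies only in the absence
    of a PTV term.  Unknown terms are treated as other (logged once each).
    """
    terms = set(terms)
    for t in terms - _KNOWN_TERMS:
        if t not in _warned_terms:
            logger.warning("unknown consequence term %r treated as 'other'", t)
            _warned_terms.add(t)
    if terms & PTV_TERMS:
        return "PTV"
    if "synonymous_variant" in terms:
        return "synonymous"
    return "other"


def inheritance_filter(
    hits: Sequence[tuple[str, str]],
    mode: str,
    *,
    sex: str | None = None,
    xl_female_dominant: bool = False,
) -> list[tuple[str, str]]:
    """Keep the hits in one sample x gene consistent with the gene's mode.

    ``hits`` is a list of (variant_key, zygosity) already past QC, rarity
    and consequence filters.  Rules:

    * AD — heterozygous hits qualify; homozygous-alternate hits do not.
    * AR — homozygous-alternate hits qualify; a heterozygous hit qualifies
      only when the sample carries >= 2 distinct hits in the gene (presumed
      compound heterozygous; genotypes are unphased).
    * XL — males: hemizygous alternate qualifies (a homozygous-alternate
      call on X in a male is read as hemizygous); females follow the AR
      rule, or the AD rule when the gene is configured female-limited
      dominant.
    """
    if mode not in ("AD", "AR", "XL"):
        raise CohortValidationError(f"unknown inheritance mode {mode!r}")

    def _ar_rule(pairs):
        multi = len({k for k, _ in pairs}) >= 2
        out = []
        for key, zyg in pairs:
            if zyg == "hom_alt" or (zyg == "het" and multi):
                out.append((key, zyg))
        return out

    if mode == "AD":
        return [(k, z) for k, z in hits if z == "het"]
    if mode == "AR":
        return _ar_rule(hits)
    # XL
    if sex == "male":
        return [(k, z) for k, z in hits if z in ("hemi", "hom_alt")]
    if xl_female_dominant:
        return [(k, z) for k, z in hits if z in ("het", "hom_alt")]
    return _ar_rule(hits)


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Read the per-allele annotation TSV keyed by chrom/pos/ref/alt."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = ({"chrom", "pos", "ref", "alt", "gene", "consequence_terms"}
               - set(df.columns))
    if missing:
        raise CohortValidationError(
            f"annotation table {path} missing columns: {sorted(missing)}")
    for col in MAF_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    if "lof_confidence" not in df.columns:
        df["lof_confidence"] = None
    df["key"] = (df["chrom"].astype(str) + ":" + df["pos"].astype(str)
                 + ":" + df["ref"] + ":" + df["alt"])
    if df["key"].duplicated().any():
        raise CohortValidationError(
            f"duplicate alleles in annotation table {path}")
    return df


def load_known_variants(path: str | Path) -> set[str]:
    """Read the known-variant list TSV into a set of allele keys."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "ref", "alt"} - set(df.columns)
    if missing:
        raise CohortValidationError(
            f"known-variant list {path} missing columns: {sorted(missing)}")
    keys = (df["chrom"].astype(str) + ":" + df["pos"].astype(str)
            + ":" + df["ref"] + ":" + df["alt"])
    if keys.duplicated().any():
        raise CohortValidationError(f"duplicate keys in known-variant list {path}")
    return set(keys)


def known_variant_match(variant: AnnotatedVariant | str, known: set[str]) -> bool:
    """Exact chrom/pos/ref/alt membership in the known-variant list."""
    key = variant if isinstance(variant, str) else variant.key
    return key in known


# ---------------------------------------------------------------------------
# Vectorised cascade over a whole cohort
# ---------------------------------------------------------------------------

@dataclass
class CascadeResult:
    """Outputs of the filter cascade.

    ``hits`` holds qualifying PTV / known-variant hits (one row per sample x
    allele); ``control_hits`` the synonymous negative-control hits processed
    through the identical cascade; ``variants`` a per-allele audit of which
    stage each allele survived.
    """

    hits: pd.DataFrame
    control_hits: pd.DataFrame
    variants: pd.DataFrame

    HIT_COLUMNS = ["sample_id", "key", "chrom", "pos", "ref", "alt",
                   "gene", "zygosity", "basis"]


def _empty_hits() -> pd.DataFrame:
    return pd.DataFrame(columns=CascadeResult.HIT_COLUMNS)


def mask_low_quality(cohort: Cohort, thresholds: QcThresholds = QcThresholds()
                     ) -> np.ndarray:
    """Vectorised genotype-QC mask over the cohort matrix.

    Returns the alt-allele count matrix with masked calls set to -1.
    Matches :func:`genotype_qc` call-by-call.
    """
    counts = cohort.counts.astype(np.int8, copy=True)
    observed = counts >= 0
    bad = (cohort.dp < thresholds.dp_min) | (cohort.gq < thresholds.gq_min)
    het = counts == 1
    tot = cohort.ad_ref + cohort.ad_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.where(tot > 0, cohort.ad_alt / np.maximum(tot, 1), np.nan)
    bad_ab = het & (np.isnan(ab) | (ab > thresholds.ab_high)
                    | (ab < thresholds.ab_low))
    counts[observed & (bad | bad_ab)] = -1
    return counts


def cohort_af_matrix(cohort: Cohort, counts: np.ndarray) -> np.ndarray:
    """Per-variant in-cohort AF from a (possibly masked) count matrix.

    Autosomes: AN = 2 x non-missing samples.  X: males contribute one
    allele; a male alt call counts one alternate allele.
    """
    observed = counts >= 0
    cnt = np.where(observed, counts, 0).astype(np.int64)
    on_x = cohort.variants["chrom"].isin(X_CHROMS).to_numpy()
    male = cohort.male
    ploidy = np.where(male[None, :] & on_x[:, None], 1, 2)
    an = (observed * ploidy).sum(axis=1)
    ac = np.where(ploidy == 1, np.minimum(cnt, 1), cnt).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
    return af


def _zygosity_labels(counts_col: np.ndarray, on_x: bool, male: np.ndarray
                     ) -> np.ndarray:
    zyg = np.full(counts_col.shape, "hom_ref", dtype=object)
    zyg[counts_col == 1] = "het"
    zyg[counts_col == 2] = "hom_alt"
    if on_x:
        zyg[(counts_col >= 1) & male] = "hemi"
    zyg[counts_col < 0] = "missing"
    return zyg


def apply_filter_cascade(
    cohort: Cohort,
    annotations: pd.DataFrame,
    panel: Sequence[GenePanelEntry],
    *,
    lcr: Mapping | None = None,
    known: set[str] | None = None,
    thresholds: QcThresholds = QcThresholds(),
    maf_threshold: float = 0.005,
    xl_female_dominant_genes: Iterable[str] = (),
) -> CascadeResult:
    """Run the whole cascade (site, genotype QC, rarity, consequence,
    inheritance) and return candidate hits prior to ACMG classification."""
    known = known or set()
    xl_fd = set(xl_female_dominant_genes)
    mode_by_gene = {g.symbol: g.mode for g in panel}

    var = cohort.variants.copy()
    var["key"] = cohort.variant_keys()
    ann = annotations.set_index("key")
    var = var.join(ann[["gene", "consequence_terms", "lof_confidence",
                        *MAF_COLUMNS]], on="key")

    counts = mask_low_quality(cohort, thresholds)
    var["cohort_af"] = cohort_af_matrix(cohort, counts)

    var["site_pass"] = [
        site_prefilter(f, c, p, lcr)
        for f, c, p in zip(var["filter_status"], var["chrom"], var["pos"])
    ]
    var["rare"] = [
        all(m <= maf_threshold for m in (m1, me, mg) if pd.notna(m))
        and (pd.notna(af) and af <= maf_threshold)
        for m1, me, mg, af in zip(var["maf_1kg"], var["maf_esp"],
                                  var["maf_gnomad"], var["cohort_af"])
    ]
    var["consequence_class"] = [
        classify_consequence(str(t).split(",")) if pd.notna(t) else "other"
        for t in var["consequence_terms"]
    ]
    var["known"] = var["key"].isin(known)
    var["on_panel"] = var["gene"].isin(mode_by_gene)
    var["candidate"] = (
        var["site_pass"] & var["rare"] & var["on_panel"]
        & (var["known"] | var["consequence_class"].isin(["PTV", "synonymous"]))
    )

    male = cohort.male
    sample_arr = np.asarray(cohort.samples, dtype=object)
    cand_rows = []
    for idx in np.flatnonzero(var["candidate"].to_numpy()):
        row = var.iloc[idx]
        on_x = row["chrom"] in X_CHROMS
        col = counts[idx]
        carriers = np.flatnonzero(col >= 1)
        if carriers.size == 0:
            continue
        zyg = _zygosity_labels(col, on_x, male)
        for s in carriers:
            cand_rows.append((
                sample_arr[s], row["key"], row["chrom"], row["pos"],
                row["ref"], row["alt"], row["gene"], zyg[s],
                row["consequence_class"], bool(row["known"]),
            ))

    cand = pd.DataFrame(
        cand_rows,
        columns=["sample_id", "key", "chrom", "pos", "ref", "alt", "gene",
                 "zygosity", "consequence_class", "is_known"],
    )

    sex_by_sample = cohort.phenotypes["sex"].to_dict()

    def _run_inheritance(df: pd.DataFrame) -> pd.DataFrame:
        if df.empty:
            return df
        keep_idx: list[int] = []
        for (sample, gene), grp in df.groupby(["sample_id", "gene"], sort=False):
            mode = mode_by_gene[gene]
            pairs = list(zip(grp["key"], grp["zygosity"]))
            kept = set(inheritance_filter(
                pairs, mode, sex=sex_by_sample.get(sample),
                xl_female_dominant=gene in xl_fd))
            for i, pair in zip(grp.index, pairs):
                if pair in kept:
                    keep_idx.append(i)
        return df.loc[keep_idx]

    main = cand[cand["is_known"] | (cand["consequence_class"] == "PTV")]
    ctrl = cand[~cand["is_known"] & (cand["consequence_class"] == "synonymous")]
    main = _run_inheritance(main).copy()
    ctrl = _run_inheritance(ctrl).copy()

    if not main.empty:
        main["basis"] = np.where(main["is_known"], "known_variant", "PTV")
    else:
        main = main.assign(basis=pd.Series(dtype=object))
    ctrl = ctrl.assign(basis="synonymous") if not ctrl.empty else \
        ctrl.assign(basis=pd.Series(dtype=object))

    cols = CascadeResult.HIT_COLUMNS
    audit_cols = ["key", "chrom", "pos", "ref", "alt", "gene",
                  "consequence_class", "filter_status", "site_pass",
                  "cohort_af", "rare", "known", "on_panel", "candidate"]
    return CascadeResult(
        hits=main[cols].reset_index(drop=True) if not main.empty else _empty_hits(),
        control_hits=(ctrl[cols].reset_index(drop=True)
                      if not ctrl.empty else _empty_hits()),
        variants=var[audit_cols],
    )
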