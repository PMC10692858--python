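"""Synthetic case-only high-myopia cohorts with known ground truth.

Everything the pipeline consumes — multi-sample VCF, phenotype table,
annotation table, gene panel, low-complexity BED, known-variant list —
is generated from a seeded configuration, together with a per-call ground
truth stating which hits must survive the full filter cascade.  Severity
strata receive different carrier probabilities (defaults 7.66% / 8.70% /
11.90% for CHM / UM / EM), while rare synonymous negative-control variants
are placed at a severity-flat rate.

The bundled 75-gene panel (``data/reference_panel.synthetic.tsv``) is a
synthetic reconstruction of a high-myopia diagnostic panel — 16
nonsyndromic HM genes, 27 eye-syndrome genes, 32 systemic-syndrome genes —
with plausible inheritance modes; it is not a curated clinical resource.
"""

from __future__ import annotations

import importlib.resources
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import (GRADE_BANDS, SEVERITY_LABELS, GenePanelEntry,
                        load_panel)
from .variant_filters import AnnotatedVariant, GenotypeCall

__all__ = [
    "CARRIER_PROB_DEFAULTS",
    "GRADE_PROPORTIONS",
    "StratumSpec",
    "GeneratorConfig",
    "GeneratedCohort",
    "reference_panel_path",
    "load_reference_panel",
    "default_strata",
    "generate",
    "simulate_carrier_counts",
    "corrupt_for_qc",
    "make_paper_counts_fixture",
    "make_acmg_spectrum_fixture",
]

# Stratum-specific carrier probabilities: the study conditions this
# generator emulates (yield rising with myopia severity).
CARRIER_PROB_DEFAULTS = {"CHM": 0.0766, "UM": 0.0870, "EM": 0.1190}

# Grade-band mix of a school-age HM cohort (primary / junior / senior).
GRADE_PROPORTIONS = {"primary": 0.0571, "junior": 0.3170, "senior": 0.6259}

MALE_FRACTION = 0.5274

SEVERITY_SER_BOUNDS = {"CHM": (-8.0, -6.0), "UM": (-10.0, -8.0),
                       "EM": (-15.0, -10.0)}

_BASES = ("A", "C", "G", "T")

_PTV_TERM_CHOICES = ("stop_gained", "frameshift_variant",
                     "splice_acceptor_variant", "splice_donor_variant",
                     "start_lost")


@dataclass(frozen=True)
class StratumSpec:
    grade: str
    severity: str
    n: int
    carrier_prob: float


@dataclass
class GeneratorConfig:
    """Knobs of the cohort simulator.

    ``qc_corruption`` is the fraction of alternate-allele genotype calls
    pushed below a QC threshold (DP, GQ or allele balance, chosen at
    random); corrupted calls are flagged in the ground truth so tests can
    assert exactly which calls the QC stage must mask.
    """

    seed: int = 0
    strata: list[StratumSpec] = None
    panel: list[GenePanelEntry] = None
    known_fraction: float = 0.49       # carriers explained by a known variant
    syn_rate: float = 0.05             # severity-flat synonymous control rate
    decoy_prob: float = 0.15           # per-sample non-qualifying decoy rate
    qc_corruption: float = 0.0
    mean_dp: int = 60
    ar_comphet_prob: float = 0.5       # AR carriers: compound het vs hom
    n_known_variants: int = 36
    n_common_decoys: int = 5
    n_vqsr_fail_decoys: int = 3
    n_lcr_decoys: int = 3
    n_multiallelic_decoys: int = 2

    def __post_init__(self) -> None:
        if self.strata is None:
            self.strata = default_strata()
        if self.panel is None:
            self.panel = load_reference_panel()
        for s in self.strata:
            if not 0.0 <= s.carrier_prob <= 1.0:
                raise ValueError(f"carrier_prob out of [0,1] in {s}")
        if sum(s.n for s in self.strata) <= 0:
            raise ValueError("total cohort size must be positive")


def reference_panel_path() -> Path:
    return Path(importlib.resources.files("panelyield") / "data"
                / "reference_panel.synthetic.tsv")


def load_reference_panel() -> list[GenePanelEntry]:
    return load_panel(reference_panel_path())


def default_strata(n_per_severity: int = 2000) -> list[StratumSpec]:
    """Nine grade x severity strata: each severity group of size
    ``n_per_severity`` split across grade bands by the cohort's grade mix,
    with the severity-specific default carrier probability."""
    out = []
    for sev in SEVERITY_LABELS:
        p = CARRIER_PROB_DEFAULTS[sev]
        counts = _largest_remainder(n_per_severity,
                                    [GRADE_PROPORTIONS[g] for g in GRADE_BANDS])
        for g, n in zip(GRADE_BANDS, counts):
            out.append(StratumSpec(g, sev, n, p))
    return out


def _largest_remainder(total: int, props: list[float]) -> list[int]:
    raw = [total * p / sum(props) for p in props]
    base = [int(x) for x in raw]
    rem = total - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return base


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_AGE_RANGES = {"primary": (7, 11), "junior": (12, 14), "senior": (15, 18)}


@dataclass
class GeneratedCohort:
    """Paths of the emitted files plus the per-call ground truth."""

    outdir: Path
    vcf_path: Path
    phenotype_path: Path
    annotation_path: Path
    panel_path: Path
    lcr_path: Path
    known_path: Path
    truth_path: Path
    truth: pd.DataFrame
    config: GeneratorConfig

    def expected_hits(self) -> pd.DataFrame:
        """Ground-truth qualifying main hits (PTV + known basis)."""
        t = self.truth
        return t[t["expected_qualify"]]

    def expected_control_hits(self) -> pd.DataFrame:
        t = self.truth
        return t[t["expected_control"]]


class _Registry:
    """Variant and call ledger used while building one cohort."""

    def __init__(self, panel, rng):
        self.rng = rng
        self.variants: list[dict] = []
        self.calls: list[dict] = []
        self.panel = panel
        self._chrom_slots: dict[str, int] = {}
        self._gene_locus: dict[str, tuple[str, int]] = {}
        self._gene_offset: dict[str, int] = {}
        for i, g in enumerate(panel):
            chrom = "chrX" if g.mode == "XL" else f"chr{(i % 22) + 1}"
            slot = self._chrom_slots.get(chrom, 0)
            self._chrom_slots[chrom] = slot + 1
            self._gene_locus[g.symbol] = (chrom, 1_000_000 * (slot + 1))
            self._gene_offset[g.symbol] = 0

    def _next_pos(self, gene: str) -> tuple[str, int]:
        chrom, base = self._gene_locus[gene]
        self._gene_offset[gene] += 7
        return chrom, base + self._gene_offset[gene]

    def new_variant(self, gene: str, terms: str, *, lof: str | None = None,
                    mafs: tuple = (None, None, None), filter_status: str = "PASS",
                    known: bool = False, chrom: str | None = None,
                    pos: int | None = None, ref: str | None = None,
                    alt: str | None = None, multi_group: int | None = None) -> int:
        if chrom is None or pos is None:
            chrom, pos = self._next_pos(gene)
        if ref is None:
            if "frameshift_variant" in terms:
                ref = "".join(self.rng.choice(_BASES, 2))
                alt = ref[0]
            else:
                ref = str(self.rng.choice(_BASES))
                alt = str(self.rng.choice([b for b in _BASES if b != ref]))
        self.variants.append(dict(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, terms=terms,
            lof=lof, maf_1kg=mafs[0], maf_esp=mafs[1], maf_gnomad=mafs[2],
            filter_status=filter_status, known=known, multi_group=multi_group,
        ))
        return len(self.variants) - 1

    def add_call(self, var_idx: int, sample_idx: int, gcode: int, role: str) -> None:
        self.calls.append(dict(var=var_idx, sample=sample_idx, gcode=gcode,
                               role=role, corrupt=None))


def _rare_mafs(rng) -> tuple:
    """External MAFs for an injected rare allele: each database either has
    never seen it (None) or records a log-uniform frequency <= 5e-3."""
    out = []
    for _ in range(3):
        if rng.random() < 0.5:
            out.append(None)
        else:
            out.append(float(10 ** rng.uniform(-6, np.log10(5e-3))))
    return tuple(out)


def _common_mafs(rng) -> tuple:
    return (float(rng.uniform(0.01, 0.5)), None, float(rng.uniform(0.01, 0.5)))


def generate(config: GeneratorConfig, outdir: str | Path) -> GeneratedCohort:
    """Write a complete synthetic cohort into ``outdir``.

    Deterministic: a fixed config (including seed) yields byte-identical
    files.  Carriers receive a qualifying hit consistent with the chosen
    gene's inheritance mode (AD: one het PTV; AR: hom or two distinct het
    PTVs; XL male: hemizygous; XL female: AR-style) or a known variant.
    Non-carriers may receive non-qualifying decoys (single AR het, AD hom,
    externally common alleles, off-class missense) and every sample may
    carry a severity-flat rare synonymous control allele.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    reg = _Registry(panel, rng)

    ad_genes = [g.symbol for g in panel if g.mode == "AD"]
    mode_by_gene = {g.symbol: g.mode for g in panel}

    # --- samples -----------------------------------------------------------
    samples = []
    for spec in config.strata:
        lo, hi = SEVERITY_SER_BOUNDS[spec.severity]
        a_lo, a_hi = _AGE_RANGES[spec.grade]
        for _ in range(spec.n):
            i = len(samples)
            ser_r = float(rng.uniform(lo, hi))
            ser_l = float(rng.uniform(lo, hi))
            cyl_r = round(float(rng.uniform(-3, 0)), 2)
            cyl_l = round(float(rng.uniform(-3, 0)), 2)
            samples.append(dict(
                sample_id=f"S{i + 1:06d}",
                age=int(rng.integers(a_lo, a_hi + 1)),
                grade=spec.grade,
                sex="male" if rng.random() < MALE_FRACTION else "female",
                severity=spec.severity,
                sphere_r=ser_r - cyl_r / 2, cyl_r=cyl_r,
                va_r=round(float(rng.uniform(0.1, 0.8)), 2),
                sphere_l=ser_l - cyl_l / 2, cyl_l=cyl_l,
                va_l=round(float(rng.uniform(0.1, 0.8)), 2),
                carrier=bool(rng.random() < spec.carrier_prob),
            ))
    n_total = len(samples)
    if any(s.n * s.carrier_prob < 1 and s.carrier_prob > 0
           for s in config.strata):
        import warnings
        warnings.warn("some strata too small to realise their carrier "
                      "probability reliably", stacklevel=2)

    # --- shared variant pools ---------------------------------------------
    # Known variants live in AD genes so a single het call qualifies; each
    # is shared by at most `cap` carriers to keep its in-cohort AF <= 0.005.
    known_pool = []
    for j in range(config.n_known_variants):
        gene = ad_genes[j % len(ad_genes)]
        v = reg.new_variant(gene, "missense_variant", mafs=_rare_mafs(rng),
                            known=True)
        known_pool.append(v)
    known_cap = max(1, int(0.005 * 2 * n_total))
    known_usage = {v: 0 for v in known_pool}

    common_pool = [
        reg.new_variant(rng.choice(ad_genes),
                        str(rng.choice(_PTV_TERM_CHOICES)), lof="HC",
                        mafs=_common_mafs(rng))
        for _ in range(config.n_common_decoys)
    ]
    vqsr_pool = [
        reg.new_variant(rng.choice(ad_genes),
                        str(rng.choice(_PTV_TERM_CHOICES)), lof="HC",
                        mafs=_rare_mafs(rng),
                        filter_status="VQSRTrancheSNP99.90to100.00")
        for _ in range(config.n_vqsr_fail_decoys)
    ]

    # Low-complexity zone on chr1, clear of every gene locus.
    lcr_interval = ("chr1", 6_000_000, 6_001_000)   # BED half-open, 0-based
    chr1_ad = next(g for g in ad_genes
                   if reg._gene_locus[g][0] == "chr1")
    lcr_pool = []
    for j in range(config.n_lcr_decoys):
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        lcr_pool.append(reg.new_variant(
            chr1_ad, str(rng.choice(_PTV_TERM_CHOICES)), lof="HC",
            mafs=_rare_mafs(rng), chrom="chr1", pos=6_000_001 + 11 * j,
            ref=ref, alt=alt))

    multi_pool = []
    for j in range(config.n_multiallelic_decoys):
        gene = str(rng.choice(ad_genes))
        chrom, pos = reg._next_pos(gene)
        ref = str(rng.choice(_BASES))
        alts = rng.choice([b for b in _BASES if b != ref], 2, replace=False)
        for alt in alts:
            multi_pool.append(reg.new_variant(
                gene, "missense_variant", mafs=_rare_mafs(rng), chrom=chrom,
                pos=pos, ref=ref, alt=str(alt), multi_group=j))

    # --- per-sample allele placement --------------------------------------
    genes_hit: list[set] = [set() for _ in range(n_total)]

    def _pick_gene(i, pool):
        free = [g for g in pool if g not in genes_hit[i]]
        return str(rng.choice(free))

    all_genes = [g.symbol for g in panel]
    for i, s in enumerate(samples):
        if s["carrier"]:
            if rng.random() < config.known_fraction:
                open_known = [v for v in known_pool if known_usage[v] < known_cap]
                if open_known:
                    v = int(rng.choice(open_known))
                    known_usage[v] += 1
                    reg.add_call(v, i, 1, "known")
                    genes_hit[i].add(reg.variants[v]["gene"])
                    continue
            gene = _pick_gene(i, all_genes)
            mode = mode_by_gene[gene]
            genes_hit[i].add(gene)
            if mode == "AD":
                v = reg.new_variant(gene, str(rng.choice(_PTV_TERM_CHOICES)),
                                    lof="HC", mafs=_rare_mafs(rng))
                reg.add_call(v, i, 1, "PTV")
            elif mode == "AR" or (mode == "XL" and s["sex"] == "female"):
                if rng.random() < config.ar_comphet_prob:
                    for _ in range(2):
                        v = reg.new_variant(gene,
                                            str(rng.choice(_PTV_TERM_CHOICES)),
                                            lof="HC", mafs=_rare_mafs(rng))
                        reg.add_call(v, i, 1, "PTV")
                else:
                    v = reg.new_variant(gene, str(rng.choice(_PTV_TERM_CHOICES)),
                                        lof="HC", mafs=_rare_mafs(rng))
                    reg.add_call(v, i, 2, "PTV")
            else:   # XL male: hemizygous alternate, emitted as 1/1
                v = reg.new_variant(gene, str(rng.choice(_PTV_TERM_CHOICES)),
                                    lof="HC", mafs=_rare_mafs(rng))
                reg.add_call(v, i, 2, "PTV")
        elif rng.random() < config.decoy_prob:
            kind = str(rng.choice(["ar_single_het", "ad_hom", "common", "other"]))
            if kind == "ar_single_het":
                ar_genes = [g.symbol for g in panel if g.mode == "AR"]
                gene = _pick_gene(i, ar_genes)
                v = reg.new_variant(gene, str(rng.choice(_PTV_TERM_CHOICES)),
                                    lof="HC", mafs=_rare_mafs(rng))
                reg.add_call(v, i, 1, "decoy_ar_single")
            elif kind == "ad_hom":
                gene = _pick_gene(i, ad_genes)
                v = reg.new_variant(gene, str(rng.choice(_PTV_TERM_CHOICES)),
                                    lof="HC", mafs=_rare_mafs(rng))
                reg.add_call(v, i, 2, "decoy_ad_hom")
            elif kind == "common":
                v = int(rng.choice(common_pool))
                reg.add_call(v, i, 1, "decoy_common")
                gene = reg.variants[v]["gene"]
            else:
                gene = _pick_gene(i, all_genes)
                v = reg.new_variant(gene, "missense_variant",
                                    mafs=_rare_mafs(rng))
                reg.add_call(v, i, 1, "decoy_other")
            genes_hit[i].add(gene)
        # severity-flat synonymous negative control
        if rng.random() < config.syn_rate:
            gene = _pick_gene(i, ad_genes)
            genes_hit[i].add(gene)
            v = reg.new_variant(gene, "synonymous_variant",
                                mafs=_rare_mafs(rng))
            reg.add_call(v, i, 1, "synonymous")

    for pool, role in ((vqsr_pool, "decoy_vqsr"), (lcr_pool, "decoy_lcr"),
                       (multi_pool, "decoy_multiallelic")):
        for v in pool:
            for i in rng.choice(n_total, size=2, replace=False):
                reg.add_call(v, int(i), 1, role)

    # --- QC corruption -----------------------------------------------------
    for call in reg.calls:
        if config.qc_corruption > 0 and rng.random() < config.qc_corruption:
            modes = ["dp", "gq", "ab"] if call["gcode"] == 1 else ["dp", "gq"]
            call["corrupt"] = str(rng.choice(modes))

    # --- per-call sequencing stats ----------------------------------------
    for call in reg.calls:
        dp = int(max(20, rng.poisson(config.mean_dp)))
        gq = int(rng.integers(30, 100))
        if call["corrupt"] == "dp":
            dp = int(rng.integers(1, 10))
        elif call["corrupt"] == "gq":
            gq = int(rng.integers(0, 20))
        if call["gcode"] == 1:
            if call["corrupt"] == "ab":
                frac = int(max(0, round(0.1 * dp))) if rng.random() < 0.5 \
                    else dp - int(max(1, round(0.1 * dp)))
                ad_alt = frac
            else:
                ad_alt = int(round(dp * rng.uniform(0.3, 0.7)))
                ad_alt = min(max(ad_alt, 1), dp - 1) if dp > 1 else dp
        else:
            ad_alt = dp
        call.update(dp=dp, gq=gq, ad_ref=dp - ad_alt, ad_alt=ad_alt)

    male_arr = np.array([s["sex"] == "male" for s in samples])
    truth = _finalize_truth(reg, samples, male_arr, mode_by_gene, lcr_interval)

    paths = _write_files(config, reg, samples, truth, lcr_interval, outdir)
    return GeneratedCohort(outdir=outdir, truth=truth, config=config, **paths)


def _finalize_truth(reg, samples, male, mode_by_gene, lcr_interval
                    ) -> pd.DataFrame:
    """Recompute, constructively, which injected calls must survive the
    cascade: QC masking, site prefilter, post-QC in-cohort AF, consequence
    class / known status, and the per-gene inheritance rule."""
    n_total = len(samples)
    lcr_chrom, lcr_start, lcr_end = lcr_interval

    calls_by_var: dict[int, list[dict]] = {}
    for c in reg.calls:
        calls_by_var.setdefault(c["var"], []).append(c)

    af = {}
    for v_idx, v in enumerate(reg.variants):
        on_x = v["chrom"] == "chrX"
        an = int((np.where(male, 1, 2) if on_x else np.full(n_total, 2)).sum())
        ac = 0
        for c in calls_by_var.get(v_idx, []):
            contrib = 1 if (on_x and male[c["sample"]]) else 2
            if c["corrupt"] is not None:
                an -= contrib
                continue
            ac += min(c["gcode"], contrib)
        af[v_idx] = ac / an if an > 0 else float("nan")

    def _site_ok(v):
        if v["filter_status"] != "PASS":
            return False
        return not (v["chrom"] == lcr_chrom
                    and lcr_start <= v["pos"] - 1 < lcr_end)

    def _rare_ok(v, v_idx):
        for m in (v["maf_1kg"], v["maf_esp"], v["maf_gnomad"]):
            if m is not None and m > 0.005:
                return False
        return af[v_idx] <= 0.005

    rows = []
    for c in reg.calls:
        v = reg.variants[c["var"]]
        on_x = v["chrom"] == "chrX"
        is_male = bool(male[c["sample"]])
        if on_x and is_male and c["gcode"] >= 1:
            zyg = "hemi"
        else:
            zyg = "het" if c["gcode"] == 1 else "hom_alt"
        is_ptv = v["terms"] in _PTV_TERM_CHOICES or any(
            t in v["terms"] for t in _PTV_TERM_CHOICES)
        candidate_main = (c["corrupt"] is None and _site_ok(v)
                          and _rare_ok(v, c["var"])
                          and (v["known"] or is_ptv))
        candidate_ctrl = (c["corrupt"] is None and _site_ok(v)
                          and _rare_ok(v, c["var"])
                          and v["terms"] == "synonymous_variant"
                          and not v["known"])
        rows.append(dict(
            sample_id=samples[c["sample"]]["sample_id"],
            key=f"{v['chrom']}:{v['pos']}:{v['ref']}:{v['alt']}",
            chrom=v["chrom"], pos=v["pos"], ref=v["ref"], alt=v["alt"],
            gene=v["gene"], zygosity=zyg, role=c["role"],
            corrupted=c["corrupt"] is not None,
            candidate_main=candidate_main, candidate_ctrl=candidate_ctrl,
        ))
    truth = pd.DataFrame(rows)
    if truth.empty:
        truth = pd.DataFrame(columns=[
            "sample_id", "key", "chrom", "pos", "ref", "alt", "gene",
            "zygosity", "role", "corrupted", "candidate_main",
            "candidate_ctrl", "expected_qualify", "expected_control"])
        return truth

    def _inherit(group: pd.DataFrame, mode: str, sex: str) -> pd.Series:
        multi = group["key"].nunique() >= 2
        if mode == "AD":
            return group["zygosity"] == "het"
        if mode == "XL" and sex == "male":
            return group["zygosity"].isin(["hemi", "hom_alt"])
        # AR, or XL female (recessive reading)
        return (group["zygosity"] == "hom_alt") | \
               ((group["zygosity"] == "het") & multi)

    sex_by_id = {s["sample_id"]: s["sex"] for s in samples}
    qualify = pd.Series(False, index=truth.index)
    main = truth[truth["candidate_main"]]
    for (sid, gene), grp in main.groupby(["sample_id", "gene"], sort=False):
        ok = _inherit(grp, mode_by_gene[gene], sex_by_id[sid])
        qualify.loc[grp.index[ok]] = True
    control = pd.Series(False, index=truth.index)
    ctrl = truth[truth["candidate_ctrl"]]
    for (sid, gene), grp in ctrl.groupby(["sample_id", "gene"], sort=False):
        ok = _inherit(grp, mode_by_gene[gene], sex_by_id[sid])
        control.loc[grp.index[ok]] = True
    truth["expected_qualify"] = qualify
    truth["expected_control"] = control
    return truth


_CHROM_ORDER = {f"chr{i}": i for i in range(1, 23)} | {"chrX": 23}


def _write_files(config, reg, samples, truth, lcr_interval, outdir: Path
                 ) -> dict:
    rng = np.random.default_rng(config.seed + 104729)  # write-side noise only
    n = len(samples)
    sample_ids = [s["sample_id"] for s in samples]

    # phenotypes ------------------------------------------------------------
    pheno = pd.DataFrame(samples)[
        ["sample_id", "age", "grade", "sex", "sphere_r", "cyl_r", "va_r",
         "sphere_l", "cyl_l", "va_l"]]
    phenotype_path = outdir / "phenotypes.tsv"
    pheno.to_csv(phenotype_path, sep="\t", index=False)

    # panel / LCR / known ----------------------------------------------------
    panel_path = outdir / "panel.tsv"
    pd.DataFrame([(g.symbol, g.mode, g.category) for g in config.panel],
                 columns=["symbol", "mode", "category"]
                 ).to_csv(panel_path, sep="\t", index=False)

    lcr_path = outdir / "lcr.bed"
    with open(lcr_path, "w") as fh:
        fh.write("{}\t{}\t{}\n".format(*lcr_interval))

    known_path = outdir / "known_variants.tsv"
    known_rows = [(v["chrom"], v["pos"], v["ref"], v["alt"], "reported")
                  for v in reg.variants if v["known"]]
    pd.DataFrame(known_rows, columns=["chrom", "pos", "ref", "alt",
                                      "source_label"]
                 ).to_csv(known_path, sep="\t", index=False)

    # annotations ------------------------------------------------------------
    ann_rows = []
    for v in reg.variants:
        ann_rows.append((
            v["chrom"], v["pos"], v["ref"], v["alt"], v["gene"], v["terms"],
            f"ENST{zlib.crc32(v['gene'].encode()) % 10 ** 11:011d}",
            f"c.{v['pos'] % 9999 + 1}{v['ref']}>{v['alt']}", "p.?",
            v["lof"] or "", v["maf_1kg"], v["maf_esp"], v["maf_gnomad"]))
    ann = pd.DataFrame(ann_rows, columns=[
        "chrom", "pos", "ref", "alt", "gene", "consequence_terms",
        "transcript", "hgvs_c", "hgvs_p", "lof_confidence",
        "maf_1kg", "maf_esp", "maf_gnomad"])
    annotation_path = outdir / "annotations.tsv"
    ann.to_csv(annotation_path, sep="\t", index=False)

    # VCF --------------------------------------------------------------------
    records: dict[tuple, list[int]] = {}
    for idx, v in enumerate(reg.variants):
        key = (v["chrom"], v["pos"], v["ref"],
               v["multi_group"] if v["multi_group"] is not None else f"b{idx}")
        records.setdefault(key, []).append(idx)
    ordered = sorted(records.items(),
                     key=lambda kv: (_CHROM_ORDER[kv[0][0]], kv[0][1]))

    calls_by_var: dict[int, list[dict]] = {}
    for c in reg.calls:
        calls_by_var.setdefault(c["var"], []).append(c)

    vcf_path = outdir / "cohort.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelyield-synthetic-cohort\n")
        for chrom in sorted(_CHROM_ORDER, key=_CHROM_ORDER.get):
            fh.write(f"##contig=<ID={chrom},length=250000000>\n")
        fh.write('##FILTER=<ID=VQSRTrancheSNP99.90to100.00,'
                 'Description="VQSR tranche failure">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                 'Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for (chrom, pos, ref, _), var_idxs in ordered:
            alts = [reg.variants[i]["alt"] for i in var_idxs]
            filt = reg.variants[var_idxs[0]]["filter_status"]
            n_alt = len(alts)
            dp0 = int(max(20, rng.poisson(config.mean_dp)))
            default = f"0/0:{dp0}:99:{dp0}" + ",0" * n_alt
            col = np.full(n, default, dtype=object)
            for k, v_idx in enumerate(var_idxs, start=1):
                for c in calls_by_var.get(v_idx, []):
                    gt = f"0/{k}" if c["gcode"] == 1 else f"{k}/{k}"
                    ad = ["0"] * (n_alt + 1)
                    ad[0] = str(c["ad_ref"])
                    ad[k] = str(c["ad_alt"])
                    col[c["sample"]] = \
                        f"{gt}:{c['dp']}:{c['gq']}:{','.join(ad)}"
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{','.join(alts)}\t100\t"
                     f"{filt}\t.\tGT:DP:GQ:AD\t" + "\t".join(col) + "\n")

    truth_path = outdir / "ground_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    return dict(vcf_path=vcf_path, phenotype_path=phenotype_path,
                annotation_path=annotation_path, panel_path=panel_path,
                lcr_path=lcr_path, known_path=known_path,
                truth_path=truth_path)


# ---------------------------------------------------------------------------
# light-weight helpers for statistics and worked examples
# ---------------------------------------------------------------------------

def simulate_carrier_counts(rng, n_per_severity: int = 2000,
                            probs: dict | None = None
                            ) -> tuple[list[int], list[int]]:
    """Carrier counts per severity group drawn from the generator's
    carrier model (binomial per stratum), without materialising files."""
    probs = probs or CARRIER_PROB_DEFAULTS
    r = [int(rng.binomial(n_per_severity, probs[s])) for s in SEVERITY_LABELS]
    return r, [n_per_severity] * len(SEVERITY_LABELS)


def corrupt_for_qc(calls: list[GenotypeCall], rates: dict, seed: int
                   ) -> tuple[list[GenotypeCall], list[bool]]:
    """Push a random fraction of calls below the QC thresholds.

    ``rates`` maps mode ('dp', 'gq', 'ab') to a per-call corruption
    probability; returns the corrupted calls and a parallel flag list so
    tests can assert exactly which calls downstream QC must mask.
    AB corruption applies only to heterozygous calls.
    """
    rng = np.random.default_rng(seed)
    out, flags = [], []
    for call in calls:
        new = call
        flagged = False
        if rng.random() < rates.get("dp", 0.0):
            new = replace(new, dp=int(rng.integers(0, 10)))
            flagged = True
        elif rng.random() < rates.get("gq", 0.0):
            new = replace(new, gq=int(rng.integers(0, 20)))
            flagged = True
        elif new.zygosity == "het" and rng.random() < rates.get("ab", 0.0):
            total = max(new.dp, 10)
            new = replace(new, ad_alt=int(0.1 * total),
                          ad_ref=total - int(0.1 * total))
            flagged = True
        out.append(new)
        flags.append(flagged)
    return out, flags


@dataclass(frozen=True)
class PaperCountsFixture:
    """Published carrier/stratum counts for exact worked examples.

    Encodes the printed numerators and denominators of the reference
    cohort (6215 HM schoolchildren) so the yield engine can be exercised
    against known output without any sequence data.
    """

    total_n: int = 6215
    males: int = 3278
    any_carriers: int = 964
    ptv_carriers: int = 506
    known_carriers: int = 490
    col18a1_missense_carriers: int = 240      # of total_n
    col18a1_known_carriers: int = 241         # of known_carriers
    bbs4_ptv_carriers: int = 61               # of ptv_carriers
    known_nonsyndromic_carriers: int = 34     # of total_n
    ptv_nonsyndromic_carriers: int = 63       # of total_n
    primary_em_n: int = 35
    primary_em_carriers: int = 8
    primary_um_yield: float = 0.1290
    primary_chm_yield: float = 0.0478


def make_paper_counts_fixture() -> PaperCountsFixture:
    return PaperCountsFixture()


def make_acmg_spectrum_fixture() -> list[AnnotatedVariant]:
    """271 synthetic annotated variants whose automatic evidence yields the
    reference class spectrum: 237 P/LP, 32 VUS, 2 B."""
    variants = []
    for i in range(237):    # truncating, absent from all databases -> PVS1+PM2
        variants.append(AnnotatedVariant(
            chrom="chr1", pos=10_000 + i, ref="C", alt="T", gene="ZNF644",
            consequence_terms=frozenset({"stop_gained"}), lof_confidence="HC"))
    for i in range(32):     # missense, absent everywhere -> PM2 only
        variants.append(AnnotatedVariant(
            chrom="chr2", pos=20_000 + i, ref="G", alt="A", gene="LRP2",
            consequence_terms=frozenset({"missense_variant"})))
    for i in range(2):      # common missense -> BA1
        variants.append(AnnotatedVariant(
            chrom="chr3", pos=30_000 + i, ref="A", alt="G", gene="FBN1",
            consequence_terms=frozenset({"missense_variant"}),
            maf_gnomad=0.12))
    return variants
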