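"""End-to-end orchestration: load inputs, run the filter cascade, classify,
compute yields, and write the report bundle.

Stages compose through plain TSV/JSON intermediates so they can be run
separately (``filter`` -> ``classify`` -> ``yield`` -> ``report``) or as a
single ``run``; both routes produce identical outputs for identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import acmg, variant_filters as vf, yield_stats as ys
from .cohort_io import load_lcr, load_panel, load_phenotypes, read_cohort
from .variant_filters import AnnotatedVariant, QcThresholds

__all__ = ["RunConfig", "run_full", "stage_filter", "stage_classify",
           "stage_yield", "write_report"]


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    The config is serialised verbatim into the output directory so every
    report carries its full provenance.
    """

    vcf: str
    phenotypes: str
    annotations: str
    panel: str
    out_dir: str
    lcr: str | None = None
    known_variants: str | None = None
    evidence: str | None = None
    eye: str = "right"
    dp_min: int = 10
    gq_min: int = 20
    ab_low: float = 0.2
    ab_high: float = 0.8
    maf_threshold: float = 0.005
    pm2_threshold: float = 1e-4
    bs1_threshold: float = 0.005
    ba1_threshold: float = 0.05
    include_benign: bool = False
    xl_female_dominant_genes: list = field(default_factory=list)
    alpha: float = 0.05
    n_tests: int = 4
    yates: bool = False
    eligibility_check: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def thresholds(self) -> QcThresholds:
        return QcThresholds(self.dp_min, self.gq_min, self.ab_low, self.ab_high)

    def acmg_config(self) -> acmg.AcmgConfig:
        return acmg.AcmgConfig(
            pm2_threshold=self.pm2_threshold,
            bs1_threshold=self.bs1_threshold,
            ba1_threshold=self.ba1_threshold,
            include_benign=self.include_benign,
        )


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def _require(path: str | None, what: str) -> None:
    if path is not None and not Path(path).exists():
        raise PipelineError(f"{what} not found: {path}")


def stage_filter(config: RunConfig) -> vf.CascadeResult:
    """Load inputs and run the full filter cascade (pre-ACMG)."""
    _require(config.vcf, "VCF")
    _require(config.phenotypes, "phenotype table")
    _require(config.annotations, "annotation table")
    _require(config.panel, "gene panel")
    _require(config.lcr, "LCR BED")
    _require(config.known_variants, "known-variant list")

    cohort = read_cohort(config.vcf, config.phenotypes,
                         eligibility_check=config.eligibility_check)
    annotations = vf.load_annotations(config.annotations)
    panel = load_panel(config.panel)
    lcr = load_lcr(config.lcr) if config.lcr else None
    known = (vf.load_known_variants(config.known_variants)
             if config.known_variants else set())
    result = vf.apply_filter_cascade(
        cohort, annotations, panel,
        lcr=lcr, known=known,
        thresholds=config.thresholds(),
        maf_threshold=config.maf_threshold,
        xl_female_dominant_genes=config.xl_female_dominant_genes,
    )
    return result


def stage_classify(hits: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """ACMG-classify the distinct alleles among the hits and attach the
    class to every hit row; drops benign-side hits unless configured to
    keep them."""
    annotations = vf.load_annotations(config.annotations)
    panel = load_panel(config.panel)
    if hits.empty:
        out = hits.copy()
        out["acmg_class"] = pd.Series(dtype=object)
        return out
    ann = annotations.set_index("key")
    user_ev = (acmg.load_user_evidence(config.evidence)
               if config.evidence else None)
    variants = []
    for key in hits["key"].unique():
        row = ann.loc[key]
        terms = frozenset(str(row["consequence_terms"]).split(","))
        variants.append(AnnotatedVariant(
            chrom=str(row["chrom"]), pos=int(row["pos"]), ref=row["ref"],
            alt=row["alt"], gene=row["gene"], consequence_terms=terms,
            lof_confidence=row["lof_confidence"] or None,
            maf_1kg=_maybe(row["maf_1kg"]), maf_esp=_maybe(row["maf_esp"]),
            maf_gnomad=_maybe(row["maf_gnomad"])))
    table = acmg.classify_batch(variants, panel, config.acmg_config(), user_ev)
    out = hits.merge(table[["key", "acmg_class"]], on="key", how="left")
    if not config.include_benign:
        out = out[~out["acmg_class"].isin(["B", "LB"])].reset_index(drop=True)
    return out


def _maybe(x):
    return None if pd.isna(x) else float(x)


def stage_yield(hits: pd.DataFrame, control_hits: pd.DataFrame,
                config: RunConfig) -> dict:
    phenotypes = load_phenotypes(config.phenotypes,
                                 eligibility_check=config.eligibility_check)
    return ys.analyze_yields(
        hits, control_hits, phenotypes,
        eye=config.eye, alpha=config.alpha, n_tests=config.n_tests,
        yates=config.yates,
    )


def _jsonable(obj):
    if isinstance(obj, (ys.StratumYield, ys.TrendResult, ys.ChiSqResult)):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.Series):
        return None     # per-sample flags are not serialised into stats.json
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def write_report(stats: dict, out_dir: str | Path) -> None:
    """Write yields TSV, stats JSON and a plain-text summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ys.strata_frame(stats["strata"]).to_csv(out / "yields.tsv", sep="\t",
                                            index=False)
    payload = {k: _jsonable(v) for k, v in stats.items()}
    with open(out / "stats.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    with open(out / "summary.txt", "w") as fh:
        fh.write(render_summary(stats))


def render_summary(stats: dict) -> str:
    lines = ["involved-variants yield summary", "=" * 32]
    for s in stats["strata"]:
        pct = "NA" if s.yield_pct is None else f"{s.yield_pct:.2f}%"
        lines.append(f"{s.label:<16} n={s.n:<7} carriers={s.carriers:<6} "
                     f"yield={pct}")
    tr = stats.get("trend_overall")
    if tr is not None:
        lines.append(f"severity trend (CA): Z={tr.z:.4f}  p={tr.p:.4g}")
    for g, t in stats.get("trend_by_grade", {}).items():
        if t is not None:
            lines.append(f"  {g:<8} Z={t.z:.4f}  p={t.p:.4g}")
    ctrl = stats.get("control", {}).get("trend")
    if ctrl is not None:
        lines.append(f"synonymous control trend: Z={ctrl.z:.4f}  p={ctrl.p:.4g}")
    lines.append(f"multiple-testing threshold: p < {stats['p_threshold']:.4g} "
                 f"({stats['alpha']} / {stats['n_tests']} tests)")
    return "\n".join(lines) + "\n"


def run_full(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; deterministic for
    fixed inputs and config."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cascade = stage_filter(config)
    classified = stage_classify(cascade.hits, config)
    classified.to_csv(out / "qualifying_hits.tsv", sep="\t", index=False)
    cascade.control_hits.to_csv(out / "control_hits.tsv", sep="\t", index=False)
    cascade.variants.to_csv(out / "variant_audit.tsv", sep="\t", index=False)

    if not classified.empty:
        acmg_table = (classified.groupby("acmg_class")["key"].nunique()
                      .rename("n_variants").reset_index())
    else:
        acmg_table = pd.DataFrame(columns=["acmg_class", "n_variants"])
    acmg_table.to_csv(out / "acmg_class_counts.tsv", sep="\t", index=False)

    stats = stage_yield(classified, cascade.control_hits, config)
    write_report(stats, out)

    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return {"hits": classified, "control_hits": cascade.control_hits,
            "stats": stats, "out_dir": out}
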