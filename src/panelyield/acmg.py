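"""ACMG 2015 variant classification: evidence assignment and combining rules.

Classification combines coded evidence criteria into one of five classes —
Pathogenic (P), Likely pathogenic (LP), Uncertain significance (VUS),
Likely benign (LB), Benign (B).  The pathogenic-side codes are PVS1 (very
strong), PS1-PS4 (strong), PM1-PM6 (moderate) and PP1-PP5 (supporting);
the benign side has BA1 (stand-alone), BS1-BS4 (strong) and BP1-BP7
(supporting).

Only the codes derivable from this pipeline's inputs are assigned
automatically:

* PVS1 — protein-truncating consequence in a gene where loss of function
  is the accepted disease mechanism;
* PM2 — absent from, or extremely rare (<= 1e-4 by default) in, the
  external population databases;
* BA1 / BS1 — external frequency above 5% / above the rare-variant
  threshold.

All other codes require segregation, de novo, functional or phenotype
evidence the cohort does not carry and are accepted from a user-supplied
evidence table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort_io import GenePanelEntry
from .variant_filters import AnnotatedVariant

__all__ = [
    "VALID_CODES",
    "AcmgConfig",
    "AcmgError",
    "validate_codes",
    "assign_evidence",
    "combine",
    "classify_batch",
    "load_user_evidence",
]

VALID_CODES = frozenset(
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
    | {"BA1"}
    | {f"BS{i}" for i in range(1, 5)}
    | {f"BP{i}" for i in range(1, 8)}
)


class AcmgError(ValueError):
    """Invalid evidence input."""


@dataclass(frozen=True)
class AcmgConfig:
    """Thresholds and gene flags for automatic evidence assignment.

    ``lof_mechanism_genes`` lists the genes for which PVS1 applies to a
    truncating allele; None means every panel gene is treated as having a
    loss-of-function mechanism.
    """

    lof_mechanism_genes: frozenset | None = None
    pm2_threshold: float = 1e-4
    bs1_threshold: float = 0.005
    ba1_threshold: float = 0.05
    include_benign: bool = False   # count B/LB variants as qualifying?

    def is_lof_gene(self, symbol: str | None) -> bool:
        if symbol is None:
            return False
        return self.lof_mechanism_genes is None or symbol in self.lof_mechanism_genes


def validate_codes(codes: Iterable[str]) -> frozenset:
    codes = frozenset(codes)
    unknown = codes - VALID_CODES
    if unknown:
        raise AcmgError(f"unknown ACMG evidence codes: {sorted(unknown)}")
    return codes


def assign_evidence(
    variant: AnnotatedVariant,
    gene: GenePanelEntry | None = None,
    config: AcmgConfig = AcmgConfig(),
    user_codes: Iterable[str] = (),
) -> frozenset:
    """Automatic frequency/LoF evidence plus user-supplied codes."""
    user = list(user_codes)
    if len(user) != len(set(user)):
        dups = sorted({c for c in user if user.count(c) > 1})
        raise AcmgError(f"duplicate user-supplied evidence codes: {dups}")
    codes = set(validate_codes(user))

    symbol = gene.symbol if gene is not None else variant.gene
    mafs = [m for m in variant.external_mafs if m is not None]
    if variant.consequence_class == "PTV" and config.is_lof_gene(symbol):
        codes.add("PVS1")
    if all(m <= config.pm2_threshold for m in mafs):
        codes.add("PM2")
    if any(m > config.ba1_threshold for m in mafs):
        codes.add("BA1")
    elif any(m > config.bs1_threshold for m in mafs):
        codes.add("BS1")
    return frozenset(codes)


def combine(evidence: Iterable[str]) -> str:
    """Combine ACMG evidence codes into P / LP / VUS / LB / B.

    Implements the 2015 combining table.  When rules fire on both the
    pathogenic and the benign side the evidence is contradictory and the
    class is VUS; when no rule fires the class is VUS.
    """
    codes = validate_codes(evidence)
    pvs = "PVS1" in codes
    ps = sum(1 for c in codes if c.startswith("PS"))
    pm = sum(1 for c in codes if c.startswith("PM"))
    pp = sum(1 for c in codes if c.startswith("PP"))
    ba = "BA1" in codes
    bs = sum(1 for c in codes if c.startswith("BS"))
    bp = sum(1 for c in codes if c.startswith("BP"))

    pathogenic = (
        (pvs and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2)
                         or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba or bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return "VUS"
    if pathogenic:
        return "P"
    if likely_pathogenic:
        return "LP"
    if benign:
        return "B"
    if likely_benign:
        return "LB"
    return "VUS"


def load_user_evidence(path: str | Path) -> dict[str, list[str]]:
    """Read an optional evidence TSV (chrom, pos, ref, alt, code) into a
    mapping allele key -> codes.  Duplicate (allele, code) rows raise."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "ref", "alt", "code"} - set(df.columns)
    if missing:
        raise AcmgError(f"evidence table {path} missing columns: {sorted(missing)}")
    df["key"] = (df["chrom"].astype(str) + ":" + df["pos"].astype(str)
                 + ":" + df["ref"] + ":" + df["alt"])
    if df.duplicated(subset=["key", "code"]).any():
        raise AcmgError(f"duplicate (variant, code) rows in {path}")
    return df.groupby("key")["code"].apply(list).to_dict()


def classify_batch(
    variants: Sequence[AnnotatedVariant],
    panel: Sequence[GenePanelEntry] = (),
    config: AcmgConfig = AcmgConfig(),
    user_evidence: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Classify a batch of variants; deterministic, one row per variant.

    Returns columns key / gene / evidence (comma-joined, sorted) /
    acmg_class.
    """
    user_evidence = user_evidence or {}
    by_symbol = {g.symbol: g for g in panel}
    rows = []
    for v in variants:
        gene = by_symbol.get(v.gene)
        ev = assign_evidence(v, gene, config, user_evidence.get(v.key, ()))
        rows.append((v.key, v.gene, ",".join(sorted(ev)), combine(ev)))
    return pd.DataFrame(rows, columns=["key", "gene", "evidence", "acmg_class"])
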