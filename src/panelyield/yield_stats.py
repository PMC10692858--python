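"""Diagnostic-yield tables and trend statistics.

The "involved variants yield" of a stratum is the fraction of its samples
carrying at least one qualifying hit.  Yields are stratified by myopia
severity (CHM < UM < EM), school grade band, and — as a sensitivity
analysis — by the eye whose SER defines severity.  Trends in yield across
the ordered severity groups are tested with the Cochran-Armitage test;
pairwise contrasts use the Pearson chi-square on 2x2 tables; rare
synonymous variants processed through the identical cascade serve as the
negative control, expected to show no trend.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import GRADE_BANDS, SEVERITY_LABELS, severity_for_eye

__all__ = [
    "StratumYield",
    "TrendResult",
    "ChiSqResult",
    "carrier_flags",
    "carrier_table",
    "cochran_armitage",
    "chisq_2x2",
    "yield_ratio",
    "bonferroni_threshold",
    "negative_control",
    "analyze_yields",
]

DEFAULT_SEVERITY_SCORES = {"CHM": 1.0, "UM": 2.0, "EM": 3.0}


@dataclass(frozen=True)
class StratumYield:
    """Carrier count and yield for one stratum."""

    label: str
    n: int
    carriers: int

    def __post_init__(self) -> None:
        if not 0 <= self.carriers <= self.n:
            raise ValueError(
                f"stratum {self.label}: carriers {self.carriers} outside [0, {self.n}]")

    @property
    def proportion(self) -> float | None:
        return self.carriers / self.n if self.n > 0 else None

    @property
    def yield_pct(self) -> float | None:
        p = self.proportion
        return round(100.0 * p, 2) if p is not None else None


@dataclass(frozen=True)
class TrendResult:
    """Cochran-Armitage trend statistic (signed) with two-sided p-value."""

    z: float
    p: float
    scores: tuple
    degenerate: bool = False


@dataclass(frozen=True)
class ChiSqResult:
    chi2: float
    p: float
    dof: int = 1


def carrier_flags(hits: pd.DataFrame, samples: Sequence[str],
                  basis_filter: str = "all") -> pd.Series:
    """Per-sample carrier status (>= 1 hit passing the basis filter).

    ``basis_filter``: all | known_only | ptv_only | synonymous_control.
    """
    if basis_filter == "all":
        keep = hits
    elif basis_filter == "known_only":
        keep = hits[hits["basis"] == "known_variant"]
    elif basis_filter == "ptv_only":
        keep = hits[hits["basis"] == "PTV"]
    elif basis_filter == "synonymous_control":
        keep = hits[hits["basis"] == "synonymous"]
    else:
        raise ValueError(f"unknown basis filter {basis_filter!r}")
    carriers = set(keep["sample_id"]) if not keep.empty else set()
    return pd.Series([s in carriers for s in samples], index=list(samples),
                     name="carrier")


def carrier_table(
    hits: pd.DataFrame,
    phenotypes: pd.DataFrame,
    *,
    basis_filter: str = "all",
    eye: str = "right",
) -> tuple[pd.Series, list[StratumYield]]:
    """Carrier flags plus per-stratum yields.

    Strata are the marginal severity groups (by the configured eye), the
    marginal grade bands, each grade x severity cell, and the overall
    cohort.  Empty strata are reported with n = 0 and undefined yield and
    are excluded from any downstream trend test.
    """
    flags = carrier_flags(hits, list(phenotypes.index), basis_filter)
    severity = severity_for_eye(phenotypes, eye)
    grade = phenotypes["grade_band"]

    out = [StratumYield("overall", len(flags), int(flags.sum()))]
    for sev in SEVERITY_LABELS:
        m = severity == sev
        out.append(StratumYield(sev, int(m.sum()), int(flags[m].sum())))
    for g in GRADE_BANDS:
        m = grade == g
        out.append(StratumYield(g, int(m.sum()), int(flags[m].sum())))
    for g in GRADE_BANDS:
        for sev in SEVERITY_LABELS:
            m = (grade == g) & (severity == sev)
            out.append(StratumYield(f"{g}/{sev}", int(m.sum()),
                                    int(flags[m].sum())))
    return flags, out


def cochran_armitage(
    carriers: Sequence[int],
    totals: Sequence[int],
    scores: Sequence[float] | None = None,
) -> TrendResult:
    """Cochran-Armitage test for a linear trend in proportions.

    Z = sum_i t_i (r_i - n_i R/N) /
        sqrt( (R/N)(1-R/N) [sum_i t_i^2 n_i - (sum_i t_i n_i)^2 / N] )

    with group carrier counts r_i, sizes n_i, scores t_i (default 1, 2, 3,
    ...), N = sum n_i and R = sum r_i.  Z is positive when the proportion
    increases with the score; the p-value is two-sided from the standard
    normal.  Degenerate inputs (all carriers or none) give Z = 0, p = 1.
    """
    r = np.asarray(carriers, dtype=float)
    n = np.asarray(totals, dtype=float)
    if r.shape != n.shape or r.ndim != 1:
        raise ValueError("carriers and totals must be 1-d and equal length")
    keep = n > 0
    if keep.sum() < 2:
        raise ValueError("need at least two non-empty groups for a trend test")
    if not keep.all():
        warnings.warn("empty groups excluded from trend test", stacklevel=2)
    t = (np.arange(1, len(n) + 1, dtype=float) if scores is None
         else np.asarray(scores, dtype=float))
    r, n, t = r[keep], n[keep], t[keep]
    if np.any(r < 0) or np.any(r > n):
        raise ValueError("carrier counts outside [0, n]")

    N = n.sum()
    R = r.sum()
    pbar = R / N
    if R == 0 or R == N:
        warnings.warn("degenerate trend table (all or no carriers)", stacklevel=2)
        return TrendResult(0.0, 1.0, tuple(t), degenerate=True)
    num = float(np.sum(t * (r - n * pbar)))
    bracket = float(np.sum(t * t * n) - np.sum(t * n) ** 2 / N)
    var = pbar * (1 - pbar) * bracket
    if var <= 0:
        return TrendResult(0.0, 1.0, tuple(t), degenerate=True)
    z = num / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return TrendResult(z, min(p, 1.0), tuple(t))


def chisq_2x2(a: int, b: int, c: int, d: int, *, yates: bool = False
              ) -> ChiSqResult:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], 1 df.

    Continuity correction is off by default (``yates`` enables it).
    A zero row or column margin raises.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("negative cell counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=yates)
    return ChiSqResult(float(chi2), float(p), int(dof))


def yield_ratio(y1: float, y2: float) -> float | None:
    """Ratio of two yields; None (undefined) when the reference is 0."""
    if y2 == 0:
        return None
    return y1 / y2


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Multiple-testing threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def _severity_trend(strata: Iterable[StratumYield], labels=SEVERITY_LABELS,
                    scores=None) -> TrendResult | None:
    by_label = {s.label: s for s in strata}
    picked = [by_label[l] for l in labels if l in by_label and by_label[l].n > 0]
    if len(picked) < 2:
        return None
    t = ([DEFAULT_SEVERITY_SCORES.get(s.label.split("/")[-1], i + 1)
          for i, s in enumerate(picked)] if scores is None else scores)
    return cochran_armitage([s.carriers for s in picked],
                            [s.n for s in picked], t)


def negative_control(hits_synonymous: pd.DataFrame, phenotypes: pd.DataFrame,
                     *, eye: str = "right") -> dict:
    """Synonymous-variant yields and severity trend, labelled as control."""
    flags, strata = carrier_table(hits_synonymous, phenotypes,
                                  basis_filter="synonymous_control", eye=eye)
    trend = _severity_trend(strata)
    return {"label": "synonymous_control", "strata": strata, "trend": trend,
            "flags": flags}


def analyze_yields(
    hits: pd.DataFrame,
    control_hits: pd.DataFrame,
    phenotypes: pd.DataFrame,
    *,
    eye: str = "right",
    alpha: float = 0.05,
    n_tests: int = 4,
    yates: bool = False,
) -> dict:
    """Full statistics bundle: stratified yields, severity trends overall
    and within each grade band, grade x severity contrasts, the synonymous
    negative control, per-eye sensitivity yields, and the multiple-testing
    threshold (alpha / n_tests; the default 0.05 / 4 covers right eye,
    left eye, PTV and synonymous analyses)."""
    result: dict = {"eye": eye,
                    "alpha": alpha,
                    "n_tests": n_tests,
                    "p_threshold": bonferroni_threshold(alpha, n_tests)}

    _, strata = carrier_table(hits, phenotypes, basis_filter="all", eye=eye)
    by_label = {s.label: s for s in strata}
    result["strata"] = strata
    result["trend_overall"] = _severity_trend(strata)

    grade_trends: dict[str, TrendResult | None] = {}
    for g in GRADE_BANDS:
        grade_trends[g] = _severity_trend(
            strata, labels=[f"{g}/{s}" for s in SEVERITY_LABELS])
    result["trend_by_grade"] = grade_trends

    contrasts = {}
    em = by_label.get("primary/EM")
    for other_label in ("primary/UM", "primary/CHM"):
        other = by_label.get(other_label)
        if em and other and em.n > 0 and other.n > 0 and \
                (em.carriers + other.carriers) > 0 and \
                (em.n - em.carriers + other.n - other.carriers) > 0:
            chi = chisq_2x2(em.carriers, em.n - em.carriers,
                            other.carriers, other.n - other.carriers,
                            yates=yates)
            ratio = (yield_ratio(em.proportion, other.proportion)
                     if other.proportion else None)
            contrasts[f"primary_EM_vs_{other_label.split('/')[1]}"] = {
                "chi2": chi, "ratio": ratio}
    result["contrasts"] = contrasts

    result["control"] = negative_control(control_hits, phenotypes, eye=eye)

    sensitivity = {}
    for e in ("right", "left"):
        _, s = carrier_table(hits, phenotypes, basis_filter="all", eye=e)
        sensitivity[e] = {"strata": s, "trend": _severity_trend(s)}
    result["per_eye"] = sensitivity
    return result


def strata_frame(strata: Sequence[StratumYield]) -> pd.DataFrame:
    """Tabulate strata as a TSV-ready DataFrame."""
    return pd.DataFrame(
        [(s.label, s.n, s.carriers, s.yield_pct) for s in strata],
        columns=["stratum", "n", "carriers", "yield_pct"],
    )
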