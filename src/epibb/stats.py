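"""2x2 contingency tables, classification metrics and odds-ratio statistics.

Two table conventions are supported:

* *pattern-vs-rest*: subjects matching a genotype combination against all
  remaining ("Other") subjects — TP = matching cases, FP = matching
  controls, FN/TN = the rest of each group;
* *genotype-vs-reference*: one SNP's genotype stratum against its code-1
  reference stratum, all other subjects excluded.

Metrics are correctness CC = (TP+TN)/total, sensitivity SN = TP/(TP+FN),
specificity SP = TN/(TN+FP), their unweighted mean ("Average"), and the
odds ratio OR = TP*TN / (FN*FP).  Any quantity whose computation hits a
zero denominator (or a zero cell, for the OR) is *not estimable* and is
reported as ``None`` in the API, rendered ``"N.E"`` in reports; computation
never raises on degenerate cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Optional

import numpy as np
from scipy import stats as sps

from .bound import MatchCounts
from .genotypes import GenotypeDataset, genotype_counts

__all__ = [
    "NOT_ESTIMABLE",
    "ContingencyTable",
    "ClassificationMetrics",
    "MetricsResult",
    "pattern_vs_rest_table",
    "genotype_vs_reference_table",
    "classification_metrics",
    "odds_ratio",
    "odds_ratio_ci",
    "association_p_value",
    "compute_metrics",
    "round_half_away",
]

#: string used for not-estimable values in rendered reports
NOT_ESTIMABLE = "N.E"


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/FN/TN cells; for pattern-vs-rest, tp+fn = C and fp+tn = N."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        """Rows = (matching, other), columns = (cases, controls)."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=np.int64)

    def swapped_roles(self) -> "ContingencyTable":
        """Case and control roles exchanged (OR inverts)."""
        return ContingencyTable(tp=self.fp, fp=self.tp, fn=self.tn, tn=self.fn)


class ClassificationMetrics(NamedTuple):
    cc: Optional[float]
    sn: Optional[float]
    sp: Optional[float]
    average: Optional[float]


@dataclass(frozen=True)
class MetricsResult:
    """The full per-combination report row statistics.

    ``average`` follows the report convention: it is suppressed (None)
    whenever the odds ratio is not estimable, mirroring how a zero-cell row
    is printed.
    """

    cc: Optional[float]
    sn: Optional[float]
    sp: Optional[float]
    average: Optional[float]
    odds_ratio: Optional[float]
    ci: Optional[tuple[float, float]]
    p_value: Optional[float]
    ci_method: str
    p_method: str


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------


def pattern_vs_rest_table(counts: MatchCounts, n_cases: int, n_controls: int) -> ContingencyTable:
    """Matching subjects vs the remaining ("Other") subjects of each group."""
    tp, fp = counts.cases_matched, counts.controls_matched
    if tp > n_cases or fp > n_controls:
        raise ValueError("match counts exceed group totals")
    return ContingencyTable(tp=tp, fp=fp, fn=n_cases - tp, tn=n_controls - fp)


def genotype_vs_reference_table(
    dataset: GenotypeDataset,
    snp_index: int,
    genotype_code: int,
    reference_code: int = 1,
) -> ContingencyTable:
    """One genotype stratum of a SNP against the reference stratum.

    Subjects carrying any other code (or missing) are excluded entirely.
    """
    if genotype_code == reference_code:
        raise ValueError("genotype_code and reference_code must differ")
    for code in (genotype_code, reference_code):
        if code not in (1, 2, 3):
            raise ValueError(f"genotype code {code} not in {{1, 2, 3}}")
    tallies = genotype_counts(dataset, snp_index)
    fp, tp = tallies[genotype_code]
    tn, fn = tallies[reference_code]
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def classification_metrics(table: ContingencyTable) -> ClassificationMetrics:
    """CC, SN, SP and their unweighted mean; None where a denominator is 0."""
    cc = _ratio(table.tp + table.tn, table.total)
    sn = _ratio(table.tp, table.tp + table.fn)
    sp = _ratio(table.tn, table.tn + table.fp)
    if None in (cc, sn, sp):
        average = None
    else:
        average = (cc + sn + sp) / 3
    return ClassificationMetrics(cc=cc, sn=sn, sp=sp, average=average)


def odds_ratio(table: ContingencyTable, zero_correction: bool = False) -> Optional[float]:
    """OR = TP*TN / (FN*FP); None on any zero cell unless corrected.

    With ``zero_correction`` the Haldane-Anscombe +0.5 is added to every
    cell before the ratio is taken.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    if zero_correction:
        return (tp + 0.5) * (tn + 0.5) / ((fn + 0.5) * (fp + 0.5))
    if 0 in (tp, fp, fn, tn):
        return None
    return tp * tn / (fn * fp)


def odds_ratio_ci(
    table: ContingencyTable,
    level: float = 0.95,
    method: str = "exact",
    zero_correction: bool = False,
) -> Optional[tuple[float, float]]:
    """Confidence interval for the odds ratio.

    ``woolf``: exp(ln OR +/- z * sqrt(1/tp + 1/fp + 1/fn + 1/tn)) — the
    log-OR normal approximation; not estimable on any zero cell unless the
    +0.5 correction is applied.

    ``exact``: the conditional exact interval based on the noncentral
    hypergeometric distribution, bracketing the conditional MLE odds ratio;
    handles zero cells without correction.
    """
    if method == "woolf":
        cells = (table.tp, table.fp, table.fn, table.tn)
        if zero_correction:
            cells = tuple(c + 0.5 for c in cells)
        elif 0 in cells:
            return None
        tp, fp, fn, tn = cells
        z = sps.norm.ppf(0.5 + level / 2)
        log_or = math.log(tp * tn / (fn * fp))
        se = math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
        return (math.exp(log_or - z * se), math.exp(log_or + z * se))
    if method == "exact":
        if min(table.tp + table.fn, table.fp + table.tn) == 0:
            return None
        if min(table.tp + table.fp, table.fn + table.tn) == 0:
            return None
        res = sps.contingency.odds_ratio(table.as_array(), kind="conditional")
        ci = res.confidence_interval(confidence_level=level)
        return (float(ci.low), float(ci.high))
    raise ValueError(f"unknown CI method {method!r}")


def association_p_value(
    table: ContingencyTable, method: str = "fisher_two_sided"
) -> Optional[float]:
    """Two-sided association p-value for a 2x2 table; None on degenerate margins."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return None
    if method == "fisher_two_sided":
        return float(sps.fisher_exact(arr, alternative="two-sided").pvalue)
    if method in ("chi2", "chi2_yates"):
        res = sps.chi2_contingency(arr, correction=(method == "chi2_yates"))
        return float(res.pvalue)
    raise ValueError(f"unknown p-value method {method!r}")


def compute_metrics(
    table: ContingencyTable,
    ci_method: str = "exact",
    p_method: str = "fisher_two_sided",
    ci_level: float = 0.95,
    zero_correction: bool = False,
) -> MetricsResult:
    """Assemble the full report-row statistics with N.E propagation.

    Per the report convention, a not-estimable odds ratio also suppresses
    the Average column.
    """
    cm = classification_metrics(table)
    or_ = odds_ratio(table, zero_correction=zero_correction)
    ci = odds_ratio_ci(
        table, level=ci_level, method=ci_method, zero_correction=zero_correction
    )
    p = association_p_value(table, method=p_method)
    average = cm.average if or_ is not None else None
    return MetricsResult(
        cc=cm.cc,
        sn=cm.sn,
        sp=cm.sp,
        average=average,
        odds_ratio=or_,
        ci=ci,
        p_value=p,
        ci_method=ci_method,
        p_method=p_method,
    )
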