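"""Pattern matching and the signed case/control count-difference bound.

A subject *matches* a combination iff its genotype code equals the pattern
code at every SNP of the combination; a missing code (0) never matches.
The bound of a combination is

    bound = (# matching controls) - (# matching cases)

A positive bound marks a low-risk pattern (over-represented in controls), a
negative bound a high-risk pattern (over-represented in cases); reports print
the difference as a magnitude in the direction's own convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeDataset, SnpCombination

__all__ = [
    "LOW_RISK",
    "HIGH_RISK",
    "NEUTRAL",
    "MatchCounts",
    "BoundValue",
    "match_mask",
    "match_counts",
    "bound_value",
    "directional_diff",
]

LOW_RISK = "low_risk"
HIGH_RISK = "high_risk"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class MatchCounts:
    """Numbers of control and case subjects matching a combination."""

    controls_matched: int
    cases_matched: int

    def __post_init__(self) -> None:
        if self.controls_matched < 0 or self.cases_matched < 0:
            raise ValueError("match counts must be non-negative")


@dataclass(frozen=True)
class BoundValue:
    """Signed count difference with its risk-direction classification.

    ``reported_diff`` follows the printed convention: controls - cases for a
    low-risk pattern, cases - controls for a high-risk one (always >= 0).
    """

    signed_diff: int
    direction: str
    reported_diff: int


def match_mask(dataset: GenotypeDataset, combo: SnpCombination) -> np.ndarray:
    """Boolean per-subject vector: code equality at every combination SNP."""
    if combo.snp_indices[-1] >= dataset.n_snps:
        raise IndexError(
            f"combination SNP index {combo.snp_indices[-1]} out of range "
            f"[0, {dataset.n_snps})"
        )
    sub = dataset.genotypes[:, list(combo.snp_indices)]
    return (sub == np.asarray(combo.genotype_pattern, dtype=np.int8)).all(axis=1)


def match_counts(dataset: GenotypeDataset, combo: SnpCombination) -> MatchCounts:
    """Tally matching subjects separately by phenotype."""
    hit = match_mask(dataset, combo)
    return MatchCounts(
        controls_matched=int(np.count_nonzero(hit & dataset.control_mask)),
        cases_matched=int(np.count_nonzero(hit & dataset.case_mask)),
    )


def bound_value(counts: MatchCounts) -> BoundValue:
    """Signed bound and direction; a zero difference is classified neutral."""
    signed = counts.controls_matched - counts.cases_matched
    if signed > 0:
        return BoundValue(signed_diff=signed, direction=LOW_RISK, reported_diff=signed)
    if signed < 0:
        return BoundValue(signed_diff=signed, direction=HIGH_RISK, reported_diff=-signed)
    return BoundValue(signed_diff=0, direction=NEUTRAL, reported_diff=0)


def directional_diff(counts: MatchCounts, direction: str) -> int:
    """The count difference oriented for one search direction.

    Positive values favour the given direction; patterns enriched the other
    way come out negative and rank below neutral ones.
    """
    signed = counts.controls_matched - counts.cases_matched
    if direction == LOW_RISK:
        return signed
    if direction == HIGH_RISK:
        return -signed
    raise ValueError(f"direction must be {LOW_RISK!r} or {HIGH_RISK!r}")
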