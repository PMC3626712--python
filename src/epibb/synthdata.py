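"""Seeded case-control genotype simulators and exact fixture reconstruction.

Two generators:

* :func:`simulate_dataset` — i.i.d. background genotypes per SNP with an
  optional *planted* multi-SNP pattern: each case (control) is forced to
  carry the full planted pattern with probability ``p_case`` (``p_control``),
  otherwise all its genotypes are plain background draws, which may still
  match the pattern by chance.  The realized per-subject match probability
  is therefore ``p + (1 - p) * q`` with ``q`` the product of the pattern
  codes' background frequencies.  No linkage disequilibrium is modelled.

* :func:`dataset_from_counts` — deterministic reconstruction of a dataset in
  which a given combination matches exactly the requested numbers of cases
  and controls; used to rebuild datasets behind printed contingency counts.

The default cohort shape (220 cases, 334 controls, 7 SNPs) mirrors the
breast-cancer case-control study the package's report formats are modelled
on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .bound import MatchCounts, match_counts
from .genotypes import CASE, CONTROL, GenotypeDataset, SnpCombination

__all__ = ["SimulationParams", "simulate_dataset", "dataset_from_counts"]

#: genotype-state frequencies for a typical common variant (roughly
#: Hardy-Weinberg with minor-allele frequency ~0.35)
DEFAULT_BACKGROUND = (0.45, 0.40, 0.15)


@dataclass
class SimulationParams:
    """Settings for :func:`simulate_dataset`.

    ``background`` is one 3-vector of genotype-code frequencies applied to
    every SNP, or a per-SNP sequence of such vectors.  ``planted`` is an
    optional ``(combo, p_case, p_control)`` triple giving the forced-match
    probabilities per subject.
    """

    n_cases: int = 220
    n_controls: int = 334
    n_snps: int = 7
    background: Sequence = DEFAULT_BACKGROUND
    planted: Optional[tuple[SnpCombination, float, float]] = None
    missing_rate: float = 0.0
    seed: int = 0

    def background_matrix(self) -> np.ndarray:
        """Per-SNP (n_snps, 3) frequency matrix, validated."""
        arr = np.asarray(self.background, dtype=float)
        if arr.ndim == 1:
            arr = np.tile(arr, (self.n_snps, 1))
        if arr.shape != (self.n_snps, 3):
            raise ValueError(
                f"background must be a 3-vector or ({self.n_snps}, 3) matrix"
            )
        if (arr < 0).any() or not np.allclose(arr.sum(axis=1), 1.0):
            raise ValueError("background frequencies must be >= 0 and sum to 1")
        return arr

    def validate(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_snps) < 1:
            raise ValueError("n_cases, n_controls and n_snps must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        self.background_matrix()
        if self.planted is not None:
            combo, p_case, p_control = self.planted
            if combo.snp_indices[-1] >= self.n_snps:
                raise ValueError("planted combination index out of range")
            if not (0 <= p_case <= 1 and 0 <= p_control <= 1):
                raise ValueError("planted match probabilities must be in [0, 1]")


def simulate_dataset(params: SimulationParams) -> GenotypeDataset:
    """Draw a seeded case-control dataset, optionally with a planted pattern."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    freqs = params.background_matrix()
    n = params.n_controls + params.n_cases
    phen = np.concatenate(
        [
            np.full(params.n_controls, CONTROL, dtype=np.int8),
            np.full(params.n_cases, CASE, dtype=np.int8),
        ]
    )
    geno = np.empty((n, params.n_snps), dtype=np.int8)
    for j in range(params.n_snps):
        geno[:, j] = rng.choice((1, 2, 3), size=n, p=freqs[j])
    if params.planted is not None:
        combo, p_case, p_control = params.planted
        p = np.where(phen == CASE, p_case, p_control)
        forced = rng.random(n) < p
        for pos, snp in enumerate(combo.snp_indices):
            geno[forced, snp] = combo.genotype_pattern[pos]
    if params.missing_rate > 0:
        missing = rng.random(geno.shape) < params.missing_rate
        geno[missing] = 0
    return GenotypeDataset(
        subject_ids=tuple(f"S{i:04d}" for i in range(n)),
        phenotype=phen,
        genotypes=geno,
        snp_names=tuple(f"snp{j + 1}" for j in range(params.n_snps)),
    )


def dataset_from_counts(
    combo: SnpCombination,
    counts: MatchCounts,
    n_cases: int,
    n_controls: int,
    n_snps: Optional[int] = None,
    filler_code: int = 1,
    seed: Optional[int] = None,
) -> GenotypeDataset:
    """Reconstruct a dataset where ``combo`` matches exactly ``counts``.

    The first ``controls_matched`` controls and ``cases_matched`` cases carry
    the pattern; every other subject carries the pattern with the FIRST
    combination SNP's code cyclically shifted, so it differs in exactly one
    position.  Non-combination SNPs are set to ``filler_code``, or drawn from
    the default background when a ``seed`` is given.
    """
    if counts.cases_matched > n_cases or counts.controls_matched > n_controls:
        raise ValueError("requested match counts exceed group totals")
    if n_snps is None:
        n_snps = combo.snp_indices[-1] + 1
    if combo.snp_indices[-1] >= n_snps:
        raise ValueError("combination index out of range for n_snps")
    if filler_code not in (1, 2, 3):
        raise ValueError("filler_code must be in {1, 2, 3}")

    n = n_controls + n_cases
    phen = np.concatenate(
        [
            np.full(n_controls, CONTROL, dtype=np.int8),
            np.full(n_cases, CASE, dtype=np.int8),
        ]
    )
    if seed is None:
        geno = np.full((n, n_snps), filler_code, dtype=np.int8)
    else:
        rng = np.random.default_rng(seed)
        geno = rng.choice(
            (1, 2, 3), size=(n, n_snps), p=DEFAULT_BACKGROUND
        ).astype(np.int8)
    for pos, snp in enumerate(combo.snp_indices):
        geno[:, snp] = combo.genotype_pattern[pos]
    # break the match at the first combination SNP for non-matching subjects
    first_snp = combo.snp_indices[0]
    shifted = combo.genotype_pattern[0] % 3 + 1
    matchers = np.zeros(n, dtype=bool)
    matchers[: counts.controls_matched] = True
    matchers[n_controls : n_controls + counts.cases_matched] = True
    geno[~matchers, first_snp] = shifted

    dataset = GenotypeDataset(
        subject_ids=tuple(f"S{i:04d}" for i in range(n)),
        phenotype=phen,
        genotypes=geno,
        snp_names=tuple(f"snp{j + 1}" for j in range(n_snps)),
    )
    assert match_counts(dataset, combo) == counts  # construction self-check
    return dataset
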