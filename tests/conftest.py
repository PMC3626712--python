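import numpy as np
import pytest

from epibb import GenotypeDataset, MatchCounts, SnpCombination
from epibb.synthdata import SimulationParams, dataset_from_counts, simulate_dataset

#: cohort totals used by the printed-table fixtures
N_CASES = 220
N_CONTROLS = 334


@pytest.fixture
def low_risk_pair_dataset():
    """Dataset realizing the printed two-SNP low-risk pair: SNPs (3, 4)
    pattern 1-1 matching 137 controls / 69 cases out of 334 / 220."""
    return dataset_from_counts(
        SnpCombination((2, 3), (1, 1)),
        MatchCounts(controls_matched=137, cases_matched=69),
        n_cases=N_CASES,
        n_controls=N_CONTROLS,
        n_snps=7,
        seed=11,
    )


@pytest.fixture
def high_risk_pair_dataset():
    """Dataset realizing the printed two-SNP high-risk pair: SNPs (4, 7)
    pattern 2-3 matching 4 controls / 11 cases out of 334 / 220."""
    return dataset_from_counts(
        SnpCombination((3, 6), (2, 3)),
        MatchCounts(controls_matched=4, cases_matched=11),
        n_cases=N_CASES,
        n_controls=N_CONTROLS,
        n_snps=7,
        seed=13,
    )


def random_dataset(seed, n_cases=40, n_controls=60, n_snps=5, missing_rate=0.0):
    return simulate_dataset(
        SimulationParams(
            n_cases=n_cases,
            n_controls=n_controls,
            n_snps=n_snps,
            missing_rate=missing_rate,
            seed=seed,
        )
    )


def single_snp_dataset(code_counts, n_cases, n_controls, n_snps=1, snp_names=None):
    """Dataset whose first SNP has the given {code: (controls, cases)}
    tallies; remaining subjects (if any) get the missing code."""
    controls = []
    cases = []
    for code, (n_ctrl, n_case) in code_counts.items():
        controls += [code] * n_ctrl
        cases += [code] * n_case
    controls += [0] * (n_controls - len(controls))
    cases += [0] * (n_cases - len(cases))
    col = np.array(controls + cases, dtype=np.int8)
    geno = np.ones((len(col), n_snps), dtype=np.int8)
    geno[:, 0] = col
    phen = np.array([0] * n_controls + [1] * n_cases, dtype=np.int8)
    return GenotypeDataset(
        subject_ids=tuple(f"S{i}" for i in range(len(col))),
        phenotype=phen,
        genotypes=geno,
        snp_names=tuple(snp_names or (f"snp{j + 1}" for j in range(n_snps))),
    )
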