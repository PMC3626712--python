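"""Case-control genotype containers and tabular genotype I/O.

Genotypes at each SNP are coded ``1``/``2``/``3`` for the three states of an
unphased biallelic marker (conventionally reference homozygote, heterozygote,
alternate homozygote) and ``0`` for missing.  The codes are treated as opaque
states throughout the package: the search and statistics only ever test code
equality, never allele identity.

A subject with a missing code at any SNP of a combination can never match
that combination, but stays in the case/control denominators — the cohort
totals ``C`` (cases) and ``N`` (controls) are constants of a dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CASE",
    "CONTROL",
    "GenotypeDataset",
    "SnpCombination",
    "GenotypeParseError",
    "DatasetValidationError",
    "read_genotype_table",
    "write_genotype_table",
    "genotype_counts",
]

#: phenotype codes used internally
CASE: int = 1
CONTROL: int = 0

_DIALECTS = ("csv", "tsv", "plink_raw_like")


class GenotypeParseError(ValueError):
    """A genotype file cell or header could not be interpreted."""


class DatasetValidationError(ValueError):
    """A dataset violates the container invariants."""


@dataclass(frozen=True)
class SnpCombination:
    """A set of SNPs each fixed to one genotype code.

    Parameters
    ----------
    snp_indices
        Strictly increasing 0-based column indices, length ``m >= 1``.
    genotype_pattern
        Length-``m`` genotype codes, each in ``{1, 2, 3}`` (never the
        missing code ``0``).
    """

    snp_indices: tuple[int, ...]
    genotype_pattern: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_indices", tuple(int(i) for i in self.snp_indices))
        object.__setattr__(
            self, "genotype_pattern", tuple(int(g) for g in self.genotype_pattern)
        )
        if len(self.snp_indices) < 1:
            raise DatasetValidationError("a combination needs at least one SNP")
        if len(self.snp_indices) != len(self.genotype_pattern):
            raise DatasetValidationError(
                "snp_indices and genotype_pattern must have equal length"
            )
        if any(b <= a for a, b in zip(self.snp_indices, self.snp_indices[1:])):
            raise DatasetValidationError("snp_indices must be strictly increasing")
        if min(self.snp_indices) < 0:
            raise DatasetValidationError("snp_indices must be non-negative")
        if any(g not in (1, 2, 3) for g in self.genotype_pattern):
            raise DatasetValidationError("pattern codes must be in {1, 2, 3}")

    @property
    def order(self) -> int:
        """Number of SNPs in the combination."""
        return len(self.snp_indices)

    def label(self, one_based: bool = True) -> str:
        """Human-readable form, e.g. ``SNPs (3, 4) 1-1`` (1-based as printed)."""
        off = 1 if one_based else 0
        idx = ", ".join(str(i + off) for i in self.snp_indices)
        pat = "-".join(str(g) for g in self.genotype_pattern)
        return f"SNPs ({idx}) {pat}"


@dataclass(frozen=True, eq=False)
class GenotypeDataset:
    """Subjects x SNPs genotype-code matrix with case/control labels.

    Attributes
    ----------
    subject_ids
        Opaque per-subject identifiers, row order preserved from input.
    phenotype
        int8 array, ``1`` = case, ``0`` = control.
    genotypes
        ``(n_subjects, n_snps)`` int8 array with cells in ``{0, 1, 2, 3}``.
    snp_names
        Column labels (e.g. rsIDs).
    """

    subject_ids: tuple[str, ...]
    phenotype: np.ndarray
    genotypes: np.ndarray
    snp_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subject_ids", tuple(str(s) for s in self.subject_ids))
        object.__setattr__(self, "snp_names", tuple(str(s) for s in self.snp_names))
        phen = np.asarray(self.phenotype, dtype=np.int8)
        geno = np.asarray(self.genotypes, dtype=np.int8)
        if geno.ndim != 2:
            raise DatasetValidationError("genotypes must be a 2-D matrix")
        object.__setattr__(self, "phenotype", phen)
        object.__setattr__(self, "genotypes", geno)
        if not (len(self.subject_ids) == phen.shape[0] == geno.shape[0]):
            raise DatasetValidationError(
                "subject_ids, phenotype and genotype rows must agree in length"
            )
        if geno.shape[1] != len(self.snp_names):
            raise DatasetValidationError("genotype columns must match snp_names")
        if not np.isin(phen, (CASE, CONTROL)).all():
            raise DatasetValidationError("phenotype labels must be 0/1")
        if geno.size and not ((geno >= 0) & (geno <= 3)).all():
            bad = np.argwhere((geno < 0) | (geno > 3))[0]
            raise DatasetValidationError(
                f"genotype code out of range at row {bad[0]}, column "
                f"{self.snp_names[bad[1]]!r}"
            )
        if self.n_cases < 1 or self.n_controls < 1:
            raise DatasetValidationError(
                "dataset must contain at least one case and one control"
            )
        phen.setflags(write=False)
        geno.setflags(write=False)

    # -- derived constants ------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        """C — the number of case subjects."""
        return int(np.count_nonzero(self.phenotype == CASE))

    @property
    def n_controls(self) -> int:
        """N — the number of control subjects."""
        return int(np.count_nonzero(self.phenotype == CONTROL))

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotype == CASE

    @property
    def control_mask(self) -> np.ndarray:
        return self.phenotype == CONTROL

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.subject_ids == other.subject_ids
            and self.snp_names == other.snp_names
            and np.array_equal(self.phenotype, other.phenotype)
            and np.array_equal(self.genotypes, other.genotypes)
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_PHENO_MAP: Mapping[str, int] = {
    "case": CASE,
    "control": CONTROL,
    "1": CASE,
    "0": CONTROL,
}


def _check_dialect(dialect: str) -> None:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


def read_genotype_table(path: str | Path, dialect: str = "csv") -> GenotypeDataset:
    """Read a case-control genotype table.

    ``csv``/``tsv``: header ``subject_id,phenotype,<snp1>,...``; phenotype in
    {case, control, 1, 0}; genotype cells integers in {0,1,2,3}.

    ``plink_raw_like``: whitespace-delimited with a header containing a
    ``PHENOTYPE`` column (2 = case, 1 = control); every column after it is a
    SNP dosage in {0,1,2} recoded to {1,2,3}, with ``NA`` for missing (-> 0).
    The subject id is the ``IID`` column if present, else the first column.
    """
    _check_dialect(dialect)
    path = Path(path)
    if dialect == "plink_raw_like":
        return _read_plink_raw_like(path)
    sep = "," if dialect == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if "phenotype" not in cols:
        raise GenotypeParseError(f"{path}: missing required 'phenotype' column")
    id_col = "subject_id" if "subject_id" in cols else cols[0]
    snp_cols = [c for c in cols if c not in (id_col, "phenotype")]
    phen = _parse_phenotypes(df["phenotype"], path)
    geno = _parse_genotype_cells(df[snp_cols], snp_cols, path, lo=0, hi=3)
    return GenotypeDataset(
        subject_ids=tuple(df[id_col].astype(str)),
        phenotype=phen,
        genotypes=geno,
        snp_names=tuple(snp_cols),
    )


def _read_plink_raw_like(path: Path) -> GenotypeDataset:
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if "PHENOTYPE" not in cols:
        raise GenotypeParseError(f"{path}: missing required 'PHENOTYPE' column")
    snp_cols = cols[cols.index("PHENOTYPE") + 1 :]
    id_col = "IID" if "IID" in cols else cols[0]
    raw = df["PHENOTYPE"].to_numpy()
    phen = np.empty(len(raw), dtype=np.int8)
    for i, v in enumerate(raw):
        if v == "2":
            phen[i] = CASE
        elif v == "1":
            phen[i] = CONTROL
        else:
            raise GenotypeParseError(
                f"{path}: row {i}: PHENOTYPE {v!r} not in {{1, 2}}"
            )
    dosage = df[snp_cols].replace("NA", "-1")
    geno = _parse_genotype_cells(dosage, snp_cols, path, lo=-1, hi=2)
    geno = (geno + 1).astype(np.int8)  # dosage 0/1/2 -> 1/2/3, NA(-1) -> 0
    return GenotypeDataset(
        subject_ids=tuple(df[id_col].astype(str)),
        phenotype=phen,
        genotypes=geno,
        snp_names=tuple(snp_cols),
    )


def _parse_phenotypes(col: pd.Series, path: Path) -> np.ndarray:
    out = np.empty(len(col), dtype=np.int8)
    for i, v in enumerate(col):
        key = str(v).strip().lower()
        if key not in _PHENO_MAP:
            raise GenotypeParseError(
                f"{path}: row {i}: phenotype {v!r} not in {{case, control, 1, 0}}"
            )
        out[i] = _PHENO_MAP[key]
    return out


def _parse_genotype_cells(
    df: pd.DataFrame, snp_cols: list[str], path: Path, lo: int, hi: int
) -> np.ndarray:
    if not snp_cols:
        return np.empty((len(df), 0), dtype=np.int8)
    geno = np.empty((len(df), len(snp_cols)), dtype=np.int8)
    for j, name in enumerate(snp_cols):
        for i, v in enumerate(df[name]):
            try:
                code = int(str(v).strip())
            except ValueError:
                raise GenotypeParseError(
                    f"{path}: row {i}, column {name!r}: non-integer genotype {v!r}"
                ) from None
            if not lo <= code <= hi:
                raise GenotypeParseError(
                    f"{path}: row {i}, column {name!r}: genotype {code} out of range"
                )
            geno[i, j] = code
    return geno


def write_genotype_table(
    dataset: GenotypeDataset, path: str | Path, dialect: str = "csv"
) -> None:
    """Write a dataset so that :func:`read_genotype_table` round-trips it."""
    _check_dialect(dialect)
    path = Path(path)
    if dialect == "plink_raw_like":
        df = pd.DataFrame({"IID": dataset.subject_ids})
        df["PHENOTYPE"] = np.where(dataset.phenotype == CASE, 2, 1)
        for j, name in enumerate(dataset.snp_names):
            col = dataset.genotypes[:, j].astype(object)
            df[name] = [("NA" if c == 0 else str(int(c) - 1)) for c in col]
        df.to_csv(path, sep=" ", index=False)
        return
    sep = "," if dialect == "csv" else "\t"
    df = pd.DataFrame({"subject_id": dataset.subject_ids})
    df["phenotype"] = np.where(dataset.phenotype == CASE, "case", "control")
    for j, name in enumerate(dataset.snp_names):
        df[name] = dataset.genotypes[:, j]
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# per-SNP genotype tallies
# ---------------------------------------------------------------------------


def genotype_counts(
    dataset: GenotypeDataset, snp_index: int
) -> dict[int, tuple[int, int]]:
    """Per-genotype ``(controls, cases)`` count pairs for codes 1, 2, 3.

    The three pairs plus the missing-code tally sum to ``(N, C)`` exactly.
    """
    if not 0 <= snp_index < dataset.n_snps:
        raise IndexError(f"snp_index {snp_index} out of range [0, {dataset.n_snps})")
    col = dataset.genotypes[:, snp_index]
    out: dict[int, tuple[int, int]] = {}
    for code in (1, 2, 3):
        hit = col == code
        out[code] = (
            int(np.count_nonzero(hit & dataset.control_mask)),
            int(np.count_nonzero(hit & dataset.case_mask)),
        )
    return out
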