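"""scikit-learn style estimators wrapping the combination search.

Both estimators consume a ``(n_subjects, n_snps)`` genotype-code matrix
``X`` (codes 0-3) and a binary phenotype ``y`` (1/"case" = case,
0/"control" = control), and expose the ranked per-level winners as fitted
attributes.  ``IBBFSSearch.transform`` turns a genotype matrix into binary
match-indicator features for the best final-level combination per searched
direction, so the search composes with sklearn pipelines as a feature
constructor.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .bound import HIGH_RISK, LOW_RISK
from .genotypes import CASE, CONTROL, GenotypeDataset
from .search import (
    LevelResult,
    SearchConfig,
    SearchNode,
    exhaustive_best,
    ibbfs_search,
    paper_beam_rule,
)

__all__ = ["IBBFSSearch", "ExhaustiveSearch"]

BeamSpec = Union[str, int, Callable[[int, int], int]]


def _as_dataset(X, y, snp_names: Optional[Sequence[str]]) -> GenotypeDataset:
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D genotype-code matrix")
    if X.dtype.kind == "f":
        if not np.isfinite(X).all() or (X != np.rint(X)).any():
            raise ValueError("genotype codes must be integers in {0, 1, 2, 3}")
        X = X.astype(np.int8)
    y = np.asarray(y)
    labels = np.empty(len(y), dtype=np.int8)
    for i, v in enumerate(y):
        s = str(v).strip().lower()
        if s in ("1", "case", "1.0"):
            labels[i] = CASE
        elif s in ("0", "control", "0.0"):
            labels[i] = CONTROL
        else:
            raise ValueError(f"unrecognised phenotype label {v!r}")
    names = tuple(snp_names) if snp_names is not None else tuple(
        f"snp{j + 1}" for j in range(X.shape[1])
    )
    return GenotypeDataset(
        subject_ids=tuple(str(i) for i in range(X.shape[0])),
        phenotype=labels,
        genotypes=X,
        snp_names=names,
    )


def _resolve_beam(beam: BeamSpec) -> Callable[[int, int], int]:
    if callable(beam):
        return beam
    if beam == "paper":
        return paper_beam_rule
    if beam == "inf":
        return lambda n, m: 10**9
    if isinstance(beam, int):
        if beam < 1:
            raise ValueError("integer beam width must be >= 1")
        return lambda n, m, w=beam: w
    raise ValueError(f"beam must be 'paper', 'inf', an int or a callable, got {beam!r}")


class IBBFSSearch(TransformerMixin, BaseEstimator):
    """Beam-guided branch-and-bound search for risk genotype combinations.

    Parameters
    ----------
    min_order, max_order
        Range of combination sizes searched; the lowest level is evaluated
        exhaustively.  ``max_order=None`` searches up to all SNPs.
    direction
        ``"low_risk"``, ``"high_risk"`` or ``"both"`` (separate beams).
    beam
        ``"paper"`` (retain ``n - m + 1`` parents per level), ``"inf"``
        (retain everything; the search degenerates to exhaustive), an
        integer width, or a callable ``(n_snps, level) -> int``.
    prune_empty
        Cut off combinations matching zero cases and zero controls.
    cutoff_bound
        Winner threshold B: oriented differences must exceed it.

    Attributes
    ----------
    level_results_ : dict[str, list[LevelResult]]
        Per-direction ranked winners for every searched level.
    best_combinations_ : dict[str, SearchNode | None]
        The top final-level winner per direction (None if the level has no
        winner above the cutoff).
    nodes_evaluated_ : dict[str, dict[int, int]]
        Per-direction, per-level count of evaluated combinations.
    n_features_in_ : int
    """

    def __init__(
        self,
        min_order: int = 2,
        max_order: Optional[int] = None,
        direction: str = "both",
        beam: BeamSpec = "paper",
        prune_empty: bool = True,
        cutoff_bound: int = 0,
        snp_names: Optional[Sequence[str]] = None,
    ):
        self.min_order = min_order
        self.max_order = max_order
        self.direction = direction
        self.beam = beam
        self.prune_empty = prune_empty
        self.cutoff_bound = cutoff_bound
        self.snp_names = snp_names

    def _config(self) -> SearchConfig:
        return SearchConfig(
            min_order=self.min_order,
            max_order=self.max_order,
            direction=self.direction,
            beam_width_rule=_resolve_beam(self.beam),
            prune_empty=self.prune_empty,
            cutoff_bound=self.cutoff_bound,
        )

    def fit(self, X, y):
        dataset = _as_dataset(X, y, self.snp_names)
        self.n_features_in_ = dataset.n_snps
        self.dataset_ = dataset
        self.level_results_ = ibbfs_search(dataset, self._config())
        self.best_combinations_ = {
            d: (levels[-1].nodes[0] if levels[-1].nodes else None)
            for d, levels in self.level_results_.items()
        }
        self.nodes_evaluated_ = {
            d: {lr.level: lr.nodes_evaluated for lr in levels}
            for d, levels in self.level_results_.items()
        }
        return self

    def transform(self, X) -> np.ndarray:
        """Binary match indicators for each direction's best combination."""
        check_is_fitted(self, "level_results_")
        X = np.asarray(X, dtype=np.int8)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} SNPs, expected {self.n_features_in_}"
            )
        cols = []
        for node in self.best_combinations_.values():
            if node is None:
                cols.append(np.zeros(X.shape[0], dtype=np.int8))
                continue
            sub = X[:, list(node.combo.snp_indices)]
            pattern = np.asarray(node.combo.genotype_pattern, dtype=np.int8)
            cols.append((sub == pattern).all(axis=1).astype(np.int8))
        return np.column_stack(cols) if cols else np.empty((X.shape[0], 0), np.int8)


class ExhaustiveSearch(BaseEstimator):
    """Exhaustive per-level ranking of every genotype combination.

    The oracle counterpart of :class:`IBBFSSearch`: guarantees the global
    per-level optimum by evaluating all ``C(n, m) * 3^m`` candidates.
    """

    def __init__(
        self,
        min_order: int = 2,
        max_order: Optional[int] = None,
        direction: str = "both",
        cutoff_bound: int = 0,
        snp_names: Optional[Sequence[str]] = None,
    ):
        self.min_order = min_order
        self.max_order = max_order
        self.direction = direction
        self.cutoff_bound = cutoff_bound
        self.snp_names = snp_names

    def fit(self, X, y):
        dataset = _as_dataset(X, y, self.snp_names)
        self.n_features_in_ = dataset.n_snps
        self.dataset_ = dataset
        max_order = self.max_order if self.max_order is not None else dataset.n_snps
        if not 2 <= self.min_order <= max_order <= dataset.n_snps:
            raise ValueError("need 2 <= min_order <= max_order <= n_snps")
        if self.direction == "both":
            directions = (LOW_RISK, HIGH_RISK)
        elif self.direction in (LOW_RISK, HIGH_RISK):
            directions = (self.direction,)
        else:
            raise ValueError(f"invalid direction {self.direction!r}")
        self.level_results_ = {
            d: [
                exhaustive_best(dataset, m, d, cutoff_bound=self.cutoff_bound)
                for m in range(self.min_order, max_order + 1)
            ]
            for d in directions
        }
        self.best_combinations_ = {
            d: (levels[-1].nodes[0] if levels[-1].nodes else None)
            for d, levels in self.level_results_.items()
        }
        self.nodes_evaluated_ = {
            d: {lr.level: lr.nodes_evaluated for lr in levels}
            for d, levels in self.level_results_.items()
        }
        return self
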