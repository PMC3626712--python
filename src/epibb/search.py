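"""Level-wise branch-and-bound search with beam-style feature selection.

The search looks for genotype combinations (one fixed code per chosen SNP)
whose matched-subject counts differ maximally between cases and controls.
It proceeds level by level (level = number of SNPs in the combination):

* the lowest order (default 2) is evaluated exhaustively;
* at each subsequent level, only the top ``r`` surviving combinations per
  risk direction are expanded, with ``r = n - m + 1`` by default (``n`` SNPs
  total, ``m`` the current level) — the feature-selection rule;
* expansion is *anchored*: a retained parent is extended by every unused SNP
  with each of its three genotype codes, preserving the parent's pattern;
* children matching nobody (zero cases AND zero controls) are cut off —
  match counts are anti-monotone in the SNP set, so such a node's whole
  subtree is empty.

The two risk directions keep separate beams so that neither can starve the
other.  An exhaustive per-level oracle is provided for cross-checking, along
with closed-form candidate counting: choosing ``m`` of ``n`` SNPs with three
states each gives ``C(n, m) * 3^m`` candidates per level.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterator, Optional

import numpy as np

from .bound import (
    HIGH_RISK,
    LOW_RISK,
    BoundValue,
    MatchCounts,
    bound_value,
    directional_diff,
    match_mask,
)
from .genotypes import GenotypeDataset, SnpCombination

__all__ = [
    "SearchNode",
    "SearchConfig",
    "LevelResult",
    "paper_beam_rule",
    "enumerate_combinations",
    "es_count",
    "es_total",
    "exhaustive_best",
    "ibbfs_search",
    "expand_node",
]


def paper_beam_rule(n_snps: int, level: int) -> int:
    """Default beam width: retain ``n - m + 1`` parents when expanding level m."""
    return n_snps - level + 1


@dataclass(frozen=True)
class SearchNode:
    """A search-tree node: a combination with its counts and bound."""

    combo: SnpCombination
    counts: MatchCounts
    bound: BoundValue
    parent: Optional["SearchNode"] = None

    @property
    def level(self) -> int:
        return self.combo.order


@dataclass
class SearchConfig:
    """Settings for :func:`ibbfs_search`.

    ``beam_width_rule`` maps ``(n_snps, level)`` to the number of parents
    retained per direction when expanding that level; ``None`` selects the
    default ``n - m + 1`` rule.  ``cutoff_bound`` (B) is the winner threshold:
    combinations whose oriented difference does not exceed B are never
    reported as winners (they may still ride the beam).
    """

    min_order: int = 2
    max_order: Optional[int] = None
    direction: str = "both"
    beam_width_rule: Optional[Callable[[int, int], int]] = None
    prune_empty: bool = True
    cutoff_bound: int = 0

    def resolve(self, n_snps: int) -> "SearchConfig":
        """Validate against a dataset width and fill defaults."""
        max_order = self.max_order if self.max_order is not None else n_snps
        if not 2 <= self.min_order <= max_order <= n_snps:
            raise ValueError(
                f"need 2 <= min_order <= max_order <= n_snps, got "
                f"{self.min_order}, {max_order}, {n_snps}"
            )
        if self.direction not in (LOW_RISK, HIGH_RISK, "both"):
            raise ValueError(f"invalid direction {self.direction!r}")
        rule = self.beam_width_rule or paper_beam_rule
        for m in range(self.min_order, max_order):
            if rule(n_snps, m) < 1:
                raise ValueError(f"beam width < 1 at level {m}")
        return SearchConfig(
            min_order=self.min_order,
            max_order=max_order,
            direction=self.direction,
            beam_width_rule=rule,
            prune_empty=self.prune_empty,
            cutoff_bound=self.cutoff_bound,
        )

    @property
    def directions(self) -> tuple[str, ...]:
        if self.direction == "both":
            return (LOW_RISK, HIGH_RISK)
        return (self.direction,)


@dataclass
class LevelResult:
    """Ranked winners for one level and direction.

    ``nodes`` is best-first by the direction's reported difference, ties
    broken by smaller SNP-index tuple then smaller genotype-pattern tuple.
    ``nodes_evaluated`` counts distinct combinations whose match counts were
    computed for this level (in this direction's search).
    """

    level: int
    direction: str
    nodes: list[SearchNode]
    nodes_evaluated: int


# ---------------------------------------------------------------------------
# candidate counting / enumeration
# ---------------------------------------------------------------------------


def es_count(n: int, m: int) -> int:
    """Candidates at one level of an exhaustive search: C(n, m) * 3^m."""
    if not 2 <= m <= n:
        raise ValueError(f"need 2 <= m <= n, got m={m}, n={n}")
    return math.comb(n, m) * 3**m


def es_total(n: int) -> int:
    """Total exhaustive-search candidates over orders 2..n."""
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    return sum(es_count(n, m) for m in range(2, n + 1))


def enumerate_combinations(n_snps: int, order: int) -> Iterator[SnpCombination]:
    """All combinations of the given order, lexicographic in (indices, pattern)."""
    if not 1 <= order <= n_snps:
        raise ValueError(f"need 1 <= order <= n_snps, got {order}, {n_snps}")
    for idx in itertools.combinations(range(n_snps), order):
        for pattern in itertools.product((1, 2, 3), repeat=order):
            yield SnpCombination(snp_indices=idx, genotype_pattern=pattern)


# ---------------------------------------------------------------------------
# vectorised per-subset counting
# ---------------------------------------------------------------------------


def _subset_pattern_counts(
    dataset: GenotypeDataset, idx: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """(controls, cases) counts for every one of the 3^m patterns of a subset.

    Patterns are base-3 encoded with the first SNP most significant, so the
    flat index order is the lexicographic pattern order of
    :func:`enumerate_combinations`.  Rows with a missing code on the subset
    match no pattern and are excluded.
    """
    m = len(idx)
    sub = dataset.genotypes[:, list(idx)].astype(np.int64)
    complete = (sub > 0).all(axis=1)
    powers = 3 ** np.arange(m - 1, -1, -1, dtype=np.int64)
    enc = ((sub[complete] - 1) * powers).sum(axis=1)
    phen = dataset.phenotype[complete]
    n_pat = 3**m
    controls = np.bincount(enc[phen == 0], minlength=n_pat)
    cases = np.bincount(enc[phen == 1], minlength=n_pat)
    return controls, cases


def _decode_pattern(code: int, m: int) -> tuple[int, ...]:
    out = []
    for _ in range(m):
        out.append(code % 3 + 1)
        code //= 3
    return tuple(reversed(out))


def _all_nodes_at_order(
    dataset: GenotypeDataset, order: int, prune_empty: bool
) -> tuple[list[SearchNode], int]:
    """Evaluate every combination of one order; returns (nodes, n evaluated)."""
    nodes: list[SearchNode] = []
    evaluated = 0
    for idx in itertools.combinations(range(dataset.n_snps), order):
        controls, cases = _subset_pattern_counts(dataset, idx)
        evaluated += len(controls)
        for code in range(len(controls)):
            fp, tp = int(controls[code]), int(cases[code])
            if prune_empty and fp == 0 and tp == 0:
                continue
            counts = MatchCounts(controls_matched=fp, cases_matched=tp)
            nodes.append(
                SearchNode(
                    combo=SnpCombination(idx, _decode_pattern(code, order)),
                    counts=counts,
                    bound=bound_value(counts),
                )
            )
    return nodes, evaluated


def _rank_key(direction: str) -> Callable[[SearchNode], tuple]:
    def key(node: SearchNode) -> tuple:
        return (
            -directional_diff(node.counts, direction),
            node.combo.snp_indices,
            node.combo.genotype_pattern,
        )

    return key


def _level_result(
    nodes: list[SearchNode], level: int, direction: str, evaluated: int, cutoff: int
) -> list[SearchNode]:
    """Direction-oriented winners: oriented diff strictly above the cutoff."""
    winners = [n for n in nodes if directional_diff(n.counts, direction) > cutoff]
    winners.sort(key=_rank_key(direction))
    return winners


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------


def exhaustive_best(
    dataset: GenotypeDataset, order: int, direction: str, cutoff_bound: int = 0
) -> LevelResult:
    """Rank ALL combinations of one order for one direction (global optimum).

    ``nodes_evaluated`` equals ``es_count(n_snps, order)``.
    """
    if direction not in (LOW_RISK, HIGH_RISK):
        raise ValueError(f"direction must be {LOW_RISK!r} or {HIGH_RISK!r}")
    nodes, evaluated = _all_nodes_at_order(dataset, order, prune_empty=True)
    winners = _level_result(nodes, order, direction, evaluated, cutoff_bound)
    return LevelResult(
        level=order, direction=direction, nodes=winners, nodes_evaluated=evaluated
    )


# ---------------------------------------------------------------------------
# node expansion
# ---------------------------------------------------------------------------


def _expand_rows(
    dataset: GenotypeDataset,
    parent: SearchNode,
    rows: np.ndarray,
    prune_empty: bool,
) -> Iterator[tuple[SearchNode, np.ndarray]]:
    """Children of one node, counting only over the parent's matched rows.

    Match counts are anti-monotone, so a child's matches are exactly the
    parent's matched subjects carrying the appended code.
    """
    used = set(parent.combo.snp_indices)
    phen = dataset.phenotype
    for snp in range(dataset.n_snps):
        if snp in used:
            continue
        col = dataset.genotypes[rows, snp]
        for code in (1, 2, 3):
            child_rows = rows[col == code]
            fp = int(np.count_nonzero(phen[child_rows] == 0))
            tp = len(child_rows) - fp
            if prune_empty and fp == 0 and tp == 0:
                continue
            pos = int(np.searchsorted(parent.combo.snp_indices, snp))
            idx = (
                parent.combo.snp_indices[:pos]
                + (snp,)
                + parent.combo.snp_indices[pos:]
            )
            pattern = (
                parent.combo.genotype_pattern[:pos]
                + (code,)
                + parent.combo.genotype_pattern[pos:]
            )
            counts = MatchCounts(controls_matched=fp, cases_matched=tp)
            child = SearchNode(
                combo=SnpCombination(idx, pattern),
                counts=counts,
                bound=bound_value(counts),
                parent=parent,
            )
            yield child, child_rows


def expand_node(
    node: SearchNode, dataset: GenotypeDataset, prune_empty: bool = True
) -> list[SearchNode]:
    """All one-SNP extensions of a node (anchored expansion).

    Child counts equal full-dataset match counts of the child combination.
    """
    if node.level >= dataset.n_snps:
        raise ValueError("node already uses every SNP")
    rows = np.flatnonzero(match_mask(dataset, node.combo))
    return [child for child, _ in _expand_rows(dataset, node, rows, prune_empty)]


# ---------------------------------------------------------------------------
# the beam-guided branch-and-bound search
# ---------------------------------------------------------------------------


def ibbfs_search(
    dataset: GenotypeDataset, config: SearchConfig | None = None
) -> dict[str, list[LevelResult]]:
    """Run the level-wise beam-guided branch-and-bound search.

    Returns one list of :class:`LevelResult` per searched direction, levels
    ``min_order..max_order`` in order.  The lowest level is exhaustive; each
    later level expands the direction's top-``r`` surviving nodes.
    """
    cfg = (config or SearchConfig()).resolve(dataset.n_snps)
    n = dataset.n_snps
    base_nodes, base_evaluated = _all_nodes_at_order(
        dataset, cfg.min_order, cfg.prune_empty
    )
    row_cache: dict[tuple, np.ndarray] = {}

    results: dict[str, list[LevelResult]] = {}
    for direction in cfg.directions:
        winners = _level_result(
            base_nodes, cfg.min_order, direction, base_evaluated, cfg.cutoff_bound
        )
        levels = [
            LevelResult(cfg.min_order, direction, winners, base_evaluated)
        ]
        ranked_all = sorted(base_nodes, key=_rank_key(direction))
        for m in range(cfg.min_order, cfg.max_order):
            r = cfg.beam_width_rule(n, m)
            beam = ranked_all[:r]
            children: dict[tuple, tuple[SearchNode, np.ndarray]] = {}
            evaluated = 0
            for parent in beam:
                key = (parent.combo.snp_indices, parent.combo.genotype_pattern)
                rows = row_cache.get(key)
                if rows is None:
                    rows = np.flatnonzero(match_mask(dataset, parent.combo))
                for child, child_rows in _expand_rows(
                    dataset, parent, rows, cfg.prune_empty
                ):
                    ckey = (child.combo.snp_indices, child.combo.genotype_pattern)
                    if ckey in children:
                        continue
                    evaluated += 1
                    children[ckey] = (child, child_rows)
            for ckey, (_, child_rows) in children.items():
                row_cache[ckey] = child_rows
            child_nodes = [node for node, _ in children.values()]
            winners = _level_result(
                child_nodes, m + 1, direction, evaluated, cfg.cutoff_bound
            )
            levels.append(LevelResult(m + 1, direction, winners, evaluated))
            ranked_all = sorted(child_nodes, key=_rank_key(direction))
        results[direction] = levels
    return results
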