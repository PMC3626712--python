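# Methods

## Model and scoring

The unit of analysis is a *genotype combination*: an ordered set of SNP
columns, each fixed to one of three unphased genotype codes (1/2/3; 0 marks
a missing call). A subject matches a combination iff its code equals the
pattern code at every combination SNP; missing codes never match, but the
subject stays in the denominators — the case total `C` and control total `N`
are constants of the dataset, never re-computed per combination. Codes are
opaque states: the method needs only state equality, so no allele identity,
frequency or Hardy–Weinberg structure is inferred.

Each combination is scored by the raw count difference
`bound = controls_matched − cases_matched`. Raw counts (not group-size
normalised) are used deliberately: with unequal groups the statistic is
biased toward the larger group's direction, which is why the two risk
directions are searched independently rather than on one signed scale. A
positive bound classifies the pattern low-risk, a negative bound high-risk,
and reports print the magnitude in each direction's own convention. A zero
difference is classified *neutral* and ranks below any non-zero bound in
both directions (only positive and negative maxima are defined concepts in
this scheme; neutral patterns are never winners).

## Search procedure

The search is level-synchronous over combination orders `m`:

1. **Base level (order 2, always exhaustive).** Every `C(n,2)·3²` pair
   pattern is counted in one vectorised pass per SNP pair (base-3 encoding
   of the two codes, `bincount` per phenotype). Candidates matching nobody
   are cut off (`prune_empty`): by anti-monotonicity their subtrees are
   empty.
2. **Beam selection.** Per direction, surviving nodes are ranked by the
   direction-oriented difference (descending), ties broken by smaller
   SNP-index tuple then smaller pattern tuple, and the top
   `r = beam_width_rule(n, m)` are retained as parents. The default rule is
   `r = n − m + 1` with `m` the parent level; `"inf"` degenerates to an
   exhaustive level-wise scan, and any callable can be supplied.
3. **Anchored expansion.** Each parent is extended by every unused SNP with
   each of its three codes, preserving the parent pattern. Child counts are
   computed only over the parent's matched rows (anti-monotonicity makes
   this exact); children reachable from several parents are de-duplicated,
   and `nodes_evaluated` counts distinct children per level and direction.
4. **Winners.** Per level and direction, children whose oriented difference
   strictly exceeds the cut-off `B` (default 0) are reported best-first.
   Nodes at or below `B` are never winners but may still occupy beam slots,
   since their extensions can recross the threshold. `B` is static; no
   dynamic bound tightening is applied, because observed-maximum tightening
   would prune the low-magnitude high-order winners this analysis is
   explicitly interested in (reported differences as small as 3 subjects).

Backtracking/traversal order within a level does not affect the returned
set, only the evaluation order, so the simpler level-synchronous
implementation is used; determinism is guaranteed by the fixed expansion
order (parents in rank order, SNPs ascending, codes ascending) and the total
tie-break. Beam selection is global per level per direction (not per
parent). With the default beam the search is approximate: its per-level
winner can only ever be at most as good as the exhaustive oracle's, a
property asserted in the test suite, with exact equality under an infinite
beam.

`ExhaustiveSearch` / `exhaustive_best` provide the per-level global optimum
(`C(n, m)·3^m` evaluations) as the independent oracle, and
`es_count`/`es_total` give the closed-form candidate counts.

## Statistics

Winners are graded on the 2×2 *pattern-vs-rest* table (TP = matching cases,
FP = matching controls, FN = C − TP, TN = N − FP); baseline per-SNP rows use
the *genotype-vs-reference* table (one genotype stratum vs the code-1
stratum, all other subjects excluded). Metrics: CC = (TP+TN)/total,
SN = TP/(TP+FN), SP = TN/(TN+FP), their unweighted mean ("Average"), and
OR = TP·TN/(FN·FP).

Not-estimable (N.E) semantics: any zero denominator makes the affected
metric None; a zero cell makes the OR None (unless the Haldane–Anscombe
+0.5 correction is enabled); and in assembled report rows a not-estimable OR
also suppresses the Average, matching the convention of the report layout
this package mirrors. Computation never raises on degenerate tables.

Interval and p-value defaults are the exact conditional methods: the CI is
the exact conditional (noncentral-hypergeometric) interval around the
conditional MLE odds ratio (scipy), the p-value the two-sided Fisher exact
test. Woolf's log-OR normal interval and Pearson/Yates χ² are available as
options. The exact conditional CI reproduces reference lower bounds to
±0.002 on the tables checked; upper bounds on very sparse tables are
method-sensitive (mid-p style calculators give narrower intervals), so CI
values are treated as tolerance-checked, with the OR point estimates exact.
Report rounding is 3 decimal places, ties away from zero, mirroring printed
epidemiological tables; infinite CI bounds render as N.E.

## Synthetic data

`simulate_dataset` emulates the structure of a 220-case / 334-control,
7-SNP candidate-gene cohort (the package default). Genotypes are i.i.d. per
SNP from background state frequencies (default 0.45/0.40/0.15, roughly
Hardy–Weinberg at minor-allele frequency ≈ 0.35). An optional planted
pattern forces, per subject, a full-pattern match with probability `p_case`
(cases) or `p_control` (controls); non-forced subjects keep plain background
draws, which may match by chance, so the realized match probability is
`p + (1 − p)·q` with `q` the product of the pattern codes' background
frequencies — this is what makes the null (`p = 0`) expectation purely
background-driven. Missing calls are masked uniformly at random afterwards,
so a high missing rate can erode planted matches. Not modelled, hence not
demonstrated by passing tests: linkage disequilibrium and haplotype
structure, population stratification, genotyping error correlated with
phenotype, covariates. `dataset_from_counts` deterministically reconstructs
a dataset in which a given combination matches exact target counts
(non-matching subjects differ at the first combination SNP via a cyclic
code shift); it is the fixture builder behind the reference-statistics
checks.

## Problem sizes and defaults

The test suite and acceptance checks run at the scales the method is meant
for: cohorts of ~200–554 subjects, 4–7 SNPs, orders 2–7. Oracle-equivalence
checks use 20 seeded 200-subject datasets at n ≤ 6; recovery power uses 100
seeded replicates of the default cohort with an order-3 pattern at
penetrance-like match rates `p_case = 0.25`, `p_control = 0.02` (a strong
but not deterministic enrichment: ≈ 60 expected carrier cases vs ≈ 15
carrier controls). Tunables: `min_order`/`max_order` (2..n), `direction`,
`beam` (`"paper"`, `"inf"`, int, callable), `prune_empty`, `cutoff_bound B`
(subjects), `top_k` report rows per level (default 3), CI/p method,
`zero_correction`, and the simulator's group sizes, background frequencies,
planted triple, `missing_rate` and `seed`.

## Known limitations

* The beam search is a heuristic: no optimality guarantee below an infinite
  beam, and a direction's lineage can die out if no superset of its beam
  survives the cut-off.
* Raw-count scoring favours the larger group; comparisons across cohorts of
  different sizes should use the OR, not the bound.
* No multiple-testing correction is applied to the per-row p-values (by
  design: the statistics battery mirrors a report layout, not an inference
  procedure).
* Designed for candidate-panel scales (tens of SNPs); no index structures
  for genome-wide inputs.
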