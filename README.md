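# epibb

Search for multi-SNP genotype combinations that separate cases from controls
in candidate-gene association studies, and grade each combination as a high-
or low-risk marker with odds-ratio and classification statistics.

## The problem

Statistical epistasis — joint multi-locus effects that single-SNP tests miss
— is usually operationalised in case-control data as *genotype-combination
enrichment*: a set of SNPs, each fixed to one genotype state, whose carriers
are over-represented among cases (high risk) or among controls (low risk).
Scanning all combinations is exponential: choosing `m` of `n` SNPs with
three genotype states each gives `C(n, m) · 3^m` candidates per order, e.g.
16 362 candidates for orders 2–7 over just 7 SNPs.

`epibb` implements a level-wise branch-and-bound with beam-style feature
selection. Each combination *i* is scored by the count-difference bound

    bound_i = Σₙ Check_controlₙ(i) − Σ_c Check_case_c(i)

— matched controls minus matched cases, where a subject matches iff its
genotype code equals the pattern at every SNP of the combination. A positive
maximal bound marks a low-risk pattern, a negative maximal bound (largest
case excess) a high-risk one. The search exploits two facts:

* **anti-monotonicity** — adding a SNP can only shrink the matched sets, so
  a combination matching nobody is cut off with its entire subtree;
* **feature selection** — after the exhaustive two-SNP level, only the top
  `r = n − m + 1` combinations per direction are expanded (anchored: every
  unused SNP × each of its three codes, parent pattern preserved).

Each winner is then graded with a 2×2 pattern-vs-rest table (TP = matching
cases, FP = matching controls, FN/TN = the rest of each group):

    CC = (TP+TN)/total   SN = TP/(TP+FN)   SP = TN/(TN+FP)
    OR = TP·TN / (FN·FP)

with exact (conditional) or Woolf confidence intervals, Fisher or χ²
p-values, and `N.E` (not estimable) propagation on zero cells. An exhaustive
per-level oracle (`ExhaustiveSearch`) is included for cross-checking, plus a
seeded simulator of planted-pattern case-control cohorts.

## Worked example

Simulate a 220-case / 334-control, 7-SNP cohort with a planted order-3
high-risk pattern (SNPs 2, 4, 6 with genotypes 2-1-3, carried by 25% of
cases and 2% of controls), then search orders 2–3:

```sh
epibb simulate --out cohort.csv --seed 42 --planted "2-4-6:2-1-3:0.25:0.02"
epibb search --input cohort.csv --out-dir reports --max-order 3
```

`reports/search_high_risk.tsv` (columns abridged):

```
level  snp_indices  genotype_pattern  control_matched  diff  OR      CI_low  CI_high  p_value
2      2,6          2-3               18               55    8.718   4.916   16.043   0.000
2      4,6          1-3               25               55    7.063   4.231   12.033   0.000
2      2,4          2-1               55               36    3.578   2.368   5.420    0.000
3      2,4,6        2-1-3             12               57    12.262  6.322   25.525   0.000
```

The planted triple is recovered as the level-3 winner: 69 of 220 cases and
12 of 334 controls carry 2-1-3 at SNPs (2, 4, 6), a case excess (`diff`) of
57 and an odds ratio of 12.26 (95% CI 6.32–25.53) against everyone else.
Its two-SNP sub-patterns lead level 2, which is how the beam finds it.

The same search as a scikit-learn estimator:

```python
from epibb import IBBFSSearch, read_genotype_table

ds = read_genotype_table("cohort.csv")
est = IBBFSSearch(direction="high_risk", max_order=3).fit(ds.genotypes, ds.phenotype)
node = est.best_combinations_["high_risk"]
print(node.combo.label(), node.counts, node.bound.reported_diff)
# SNPs (2, 4, 6) 2-1-3 MatchCounts(controls_matched=12, cases_matched=69) 57
print(est.nodes_evaluated_["high_risk"])
# {2: 189, 3: 80}   — vs 945 order-3 candidates for an exhaustive scan
```

`est.transform(X)` yields binary carrier-indicator features for the winning
pattern, so the search composes with sklearn pipelines. Other subcommands:
`epibb exhaustive` (oracle report + node-count comparison), `epibb
pair-grid` (3×3 odds-ratio grid for one SNP pair), `epibb stats TP FP FN TN`
(direct 2×2 entry). Reports print SNP positions 1-based; the Python API is
0-based.

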