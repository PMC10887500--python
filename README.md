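# ypedigree

Automated analysis of Y-chromosomal short tandem repeat (Y-STR) haplotypes
in male pedigrees, for forensic, genealogical and population geneticists.
Y-STRs are transmitted along the patriline and mutate by whole repeat
units; with rapidly mutating (RM) Y-STRs even closely related men can be
distinguished, but interpreting that variation across a family tree by
hand quickly becomes error-prone. This package automates the pipeline:

- **Meiotic distances** — parse pedigrees in Trivial Graph Format (TGF,
  father→son edges, labelled nodes = genotyped men) and count the meioses
  separating every genotyped pair; untyped men contribute only path length.
- **Conservative mutation counting** — under the stepwise mutation model a
  difference of *d* repeats between two alleles is explained by *d*
  single-step mutations (15 vs 17 → 2 events). Multi-copy loci are
  compared through a difference matrix solved by minimum-weight bipartite
  matching after harmonizing copy numbers, giving the minimum number of
  mutations that explains the pair. From these counts the package derives
  male relative differentiation rates (share of pairs at a given meiotic
  distance showing ≥1 difference) with exact Clopper–Pearson 95%
  confidence intervals, and the median number of pairwise differences as a
  diversity summary.
- **Mutation-rate estimation** — a Sankoff-style minimum-cost ancestral
  state reconstruction places mutations on the pedigree (father–son
  multi-step changes count once; the same change across untyped
  intermediates decomposes into single steps), infers the founder
  haplotype, counts covered meioses, and pools events/meioses across
  pedigrees into locus-specific rates μ̂ = events / meioses with exact CIs.
  Pedigree drawings are emitted as Graphviz DOT with one colour per
  reconstructed haplotype (founder in white) and a mutation legend.
- **Dendrograms** — complete-linkage clustering of the pairwise distance
  d(a,b) = Σ_m n_m(a,b)·w_m with optional weights w_m = −log₁₀(μ_m), so
  slowly mutating loci, whose variants are rarely recurrent, dominate the
  deep structure; cluster count chosen by silhouette score.
- **Pair simulation** — per locus, the deviation of a pair separated by
  *g* meioses from their common ancestral state is a *g*-step Markov chain
  on non-negative states: from 0, stay/±1-step/±2-step with
  1−μ / 0.97μ / 0.03μ (0.94μ/0.06μ for DYF1000); from a nonzero state the
  mutation mass is halved and becomes directional.
- **Meiotic-distance classification** — scikit-learn classifiers trained
  on simulated pairs by double cross-validation (outer stratified K folds,
  inner randomized hyper-parameter search), reporting accuracy, macro
  precision/recall/F1 and Matthews correlation, and at prediction time a
  probability for every meiotic distance in the configured range plus
  nested 85/95/99% confidence ranges grown outward from the modal
  distance.

## Worked example

A three-generation pedigree — a founder `G` with sons `A`, `B`, and
grandsons `C`,`D` (via `A`) and `E`,`F` (via `B`) — in TGF:

```
1 G
2 A
3 B
4 C
5 D
6 E
7 F
#
1 2
1 3
2 4
2 5
3 6
3 7
```

```python
>>> from ypedigree import parse_tgf, meiotic_distances
>>> recs = meiotic_distances(parse_tgf(open("worked.tgf").read(), "worked"))
>>> from collections import Counter
>>> Counter(r.meioses for r in recs)
Counter({2: 7, 1: 6, 3: 4, 4: 4})
>>> sum(1 for r in recs if r.meioses == 2 and r.lineal)
4
```

The 21 pairs split into 6 father–son pairs (1 meiosis), 7 pairs at 2
meioses (4 lineal grandfather–grandson pairs plus 3 brother pairs), 4
uncle–nephew pairs (3 meioses) and 4 cousin pairs (4 meioses).

Counting mutations and estimating a rate:

```python
>>> from ypedigree import count_single_copy, count_multi_copy
>>> count_single_copy(15, 17)          # two single steps, not one two-step
2
>>> count_multi_copy((22.0, 25.0), (22.0, 23.0, 25.0), 3)
1
```

The same workflow from the shell (`mpt fixtures` generates a synthetic
demo dataset so no external data are needed):

```bash
mpt fixtures --out-dir demo --seed 7
mpt distances --tgf-dir demo --out demo/distances.tsv
mpt pairwise  --haplotypes demo/haplotypes.csv --distances demo/distances.tsv \
              --out-prefix demo/pw
mpt ratecalc  --tgf-dir demo --haplotypes demo/haplotypes.csv --out-prefix demo/rc
mpt dendrogram --diffs demo/pw_differences.tsv --out-prefix demo/dd
mpt simulate  --rates demo/model_config.csv --generations 1:13 --n 1000 \
              --seed 42 --out demo/train.csv
mpt build-models --train demo/train.csv --families random_forest --k 5 --j 50 \
              --seed 42 --out demo/bundle.joblib
mpt predict   --model demo/bundle.joblib --features demo/pw_prediction_input.csv \
              --out demo/predictions.csv
```

`demo/rc_rates.tsv` then holds one row per marker
(`marker, mutations, meioses, rate, ci_low, ci_high`), and
`demo/predictions.csv` one row per pair with per-distance probabilities
and `85_min … 99_max` range columns.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, by running the package end to end, the pair counts of the
worked three-generation pedigree above (distance module on the TGF
document) and the empirical two-step share among mutated single-meiosis
transmissions of the pair simulator (100 000 simulated pairs, default and
DYF1000-style step splits), and writes them as JSON.
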