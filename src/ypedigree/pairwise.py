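"""Conservative pairwise mutation counting between Y-STR haplotypes.

Counting follows the stepwise mutation model: a difference of d whole
repeat units between two alleles is explained by d single-step mutations
(two single steps rather than one two-step).  Multi-copy loci are compared
through a difference matrix solved by minimum-weight bipartite matching
after harmonizing copy numbers within the comparison pool.  On top of the
counts the module computes male relative differentiation rates with exact
Clopper-Pearson binomial confidence intervals, and the median number of
pairwise differences as a haplotype-diversity summary.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import beta

from .haplotypes import HaplotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "count_single_copy",
    "harmonize_copies",
    "count_multi_copy",
    "pairwise_differences",
    "clopper_pearson",
    "differentiation_rates",
    "median_pairwise_differences",
    "write_prediction_input",
]

META_COLUMNS = ["pedigree_id", "sample_a", "sample_b"]


def count_single_copy(a: float, b: float, warn: bool = True) -> int:
    """Mutations separating two alleles of a single-copy locus.

    Whole-repeat differences count one mutation per repeat step; a
    fractional offset (e.g. 15 vs 15.2, incompatible microvariant ladders)
    cannot arise from stepwise mutation and is counted as a single event
    with a warning.
    """
    tenths = round(abs(a - b) * 10)
    if tenths == 0:
        return 0
    if tenths % 10:
        if warn:
            logger.warning(
                "non-stepwise allele difference %s vs %s counted as 1 mutation", a, b
            )
        return 1
    return tenths // 10


def harmonize_copies(
    genotypes: dict[str, tuple[float, ...]],
) -> tuple[int, dict[str, tuple[float, ...]]]:
    """Harmonized copy number for one marker across a comparison pool.

    The individual with the most observed copies fixes the assumed copy
    count C.  Samples with fewer alleles must be padded to C by duplicating
    their own observed alleles; which allele is duplicated is left open here
    and resolved per compared pair by :func:`count_multi_copy`.
    Returns (C, genotypes unchanged).
    """
    if not genotypes:
        raise ValueError("harmonize_copies requires at least one sample")
    c = max(len(alleles) for alleles in genotypes.values())
    return c, genotypes


def _paddings(alleles: tuple[float, ...], c: int):
    """All distinct multisets of size c obtained by duplicating own alleles."""
    short = c - len(alleles)
    if short < 0:
        raise ValueError(f"genotype {alleles} has more than {c} copies")
    if short == 0:
        yield alleles
        return
    seen = set()
    for extra in itertools.combinations_with_replacement(sorted(set(alleles)), short):
        padded = tuple(sorted(alleles + extra))
        if padded not in seen:
            seen.add(padded)
            yield padded


def count_multi_copy(
    alleles_a: tuple[float, ...], alleles_b: tuple[float, ...], c: int | None = None
) -> int:
    """Minimum mutations separating two multi-copy genotypes.

    Both allele lists are padded to the harmonized copy count ``c`` (every
    admissible padding duplicates one of the sample's own alleles), and for
    each padding pair the difference matrix of single-copy step counts is
    solved by minimum-weight perfect matching; the count is the minimum
    over all paddings — the most conservative explanation of the variation.
    """
    if c is None:
        c = max(len(alleles_a), len(alleles_b))
    best = None
    for pad_a in _paddings(alleles_a, c):
        for pad_b in _paddings(alleles_b, c):
            cost = np.empty((c, c), dtype=float)
            for i, a in enumerate(pad_a):
                for j, b in enumerate(pad_b):
                    cost[i, j] = count_single_copy(a, b, warn=False)
            rows, cols = linear_sum_assignment(cost)
            total = int(cost[rows, cols].sum())
            if best is None or total < best:
                best = total
    assert best is not None
    return best


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def pairwise_differences(
    table: HaplotypeTable, within: str = "pedigree"
) -> pd.DataFrame:
    """Per-marker conservative mutation counts for every unordered pair.

    ``within="pedigree"`` compares pairs inside each pedigree (copy numbers
    harmonized per pedigree); ``within="all"`` pools every sample into one
    comparison set — the population mode used for diversity analyses.
    Returns a wide DataFrame: pedigree_id, sample_a, sample_b, one count
    column per marker (multi-copy loci as one combined column), and total.
    """
    table.validate_complete()
    if within == "pedigree":
        pools = [(ped, ped) for ped in table.pedigree_ids()]
    elif within == "all":
        pools = [("all", None)]
    else:
        raise ValueError(f"within must be 'pedigree' or 'all', got {within!r}")

    rows = []
    for pool_id, ped_filter in pools:
        if ped_filter is None:
            sub = table.data
            sample_keys = [
                f"{p}:{s}" if _has_duplicate_samples(table) else s
                for p, s in table.samples
            ]
            key_of = dict(zip(table.samples, sample_keys))
        else:
            sub = table.data[table.data["pedigree_id"] == ped_filter]
            key_of = {(p, s): s for p, s in table.samples if p == ped_filter}

        samples = list(key_of.keys())
        # per marker: harmonized copy count over the pool, then pair counts
        per_marker: dict[str, dict[tuple[str, str], int]] = {}
        for marker in table.markers:
            marker_rows = sub[sub["marker"] == marker]
            geno = {
                key_of[(p, s)]: a
                for p, s, a in marker_rows[
                    ["pedigree_id", "sample_id", "alleles"]
                ].itertuples(index=False, name=None)
            }
            c, _ = harmonize_copies(geno)
            counts: dict[tuple[str, str], int] = {}
            keys = [key_of[ps] for ps in samples]
            for i, ka in enumerate(keys):
                for kb in keys[i + 1 :]:
                    if c == 1:
                        n = count_single_copy(geno[ka][0], geno[kb][0])
                    else:
                        n = count_multi_copy(geno[ka], geno[kb], c)
                    counts[_pair_key(ka, kb)] = n
            per_marker[marker] = counts

        keys = [key_of[ps] for ps in samples]
        for i, ka in enumerate(keys):
            for kb in keys[i + 1 :]:
                pair = _pair_key(ka, kb)
                marker_counts = [per_marker[m][pair] for m in table.markers]
                rows.append([pool_id, pair[0], pair[1], *marker_counts, sum(marker_counts)])

    return pd.DataFrame(rows, columns=META_COLUMNS + list(table.markers) + ["total"])


def _has_duplicate_samples(table: HaplotypeTable) -> bool:
    ids = [s for _, s in table.samples]
    return len(set(ids)) != len(ids)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n.

    Based on Beta-distribution quantiles; the lower bound is 0 when k=0 and
    the upper bound 1 when k=n.
    """
    if n < 1:
        raise ValueError("clopper_pearson requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def differentiation_rates(
    diffs: pd.DataFrame, distances: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Male relative differentiation rate per meiotic distance.

    Joins pair differences to meiotic distances on (pedigree, unordered
    pair) and reports, per distance pooled over all pedigrees plus an
    ``all`` row: number of pairs, number differentiated (total >= 1), the
    rate, and its exact binomial confidence interval.  Pairs without a
    matching distance are excluded with a warning.
    """
    dist_keyed = {
        (row.pedigree_id, *_pair_key(row.sample_a, row.sample_b)): row.meioses
        for row in distances.itertuples(index=False)
    }
    meioses = []
    unmatched = 0
    for row in diffs.itertuples(index=False):
        key = (row.pedigree_id, *_pair_key(row.sample_a, row.sample_b))
        if key in dist_keyed:
            meioses.append(dist_keyed[key])
        else:
            meioses.append(None)
            unmatched += 1
    if unmatched:
        logger.warning(
            "%d pair(s) in the difference table have no meiotic distance; excluded",
            unmatched,
        )
    work = diffs.assign(meioses=meioses).dropna(subset=["meioses"])
    if work.empty:
        logger.warning("no pairs shared between differences and distances")
        return pd.DataFrame(
            columns=["meioses", "n_pairs", "n_differentiated", "rate", "ci_low", "ci_high"]
        )

    def _row(label, group):
        n = len(group)
        k = int((group["total"] >= 1).sum())
        low, high = clopper_pearson(k, n, alpha)
        return [label, n, k, k / n, low, high]

    rows = [
        _row(int(m), group)
        for m, group in work.groupby(work["meioses"].astype(int), sort=True)
    ]
    rows.append(_row("all", work))
    return pd.DataFrame(
        rows, columns=["meioses", "n_pairs", "n_differentiated", "rate", "ci_low", "ci_high"]
    )


def median_pairwise_differences(diffs: pd.DataFrame) -> float:
    """Median of the total pairwise difference counts (diversity summary)."""
    if diffs.empty:
        raise ValueError("median of an empty difference table is undefined")
    return float(diffs["total"].median())


def write_prediction_input(
    diffs: pd.DataFrame, markers: list[str], path: str | Path | None = None
) -> pd.DataFrame:
    """Feature table for the meiotic-distance prediction module.

    One row per pair, one column per marker in the table's stable marker
    order, values = per-marker mutation counts; column-compatible with the
    simulator's training output for the same marker set.
    """
    missing = [m for m in markers if m not in diffs.columns]
    if missing:
        raise ValueError(f"difference table lacks marker column(s) {missing}")
    out = diffs[META_COLUMNS + list(markers)].copy()
    if path is not None:
        out.to_csv(path, index=False)
    return out
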