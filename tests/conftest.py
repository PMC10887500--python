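"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by brute force (exhaustive
enumeration, BFS) and never call the implementation paths they check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ypedigree.haplotypes import COLUMNS, HaplotypeTable
from ypedigree.pedigree_graph import PedigreeGraph, parse_tgf

# Three-generation worked pedigree: a founder with two sons, each of whom
# has two sons; all seven men genotyped.
FIG_TREE_TGF = "1 G\n2 A\n3 B\n4 C\n5 D\n6 E\n7 F\n#\n1 2\n1 3\n2 4\n2 5\n3 6\n3 7\n"


@pytest.fixture
def fig_tree() -> PedigreeGraph:
    return parse_tgf(FIG_TREE_TGF, "fig_tree")


def make_table(rows: list[tuple[str, str, str, tuple[float, ...]]]) -> HaplotypeTable:
    """Build a HaplotypeTable from (pedigree, sample, marker, alleles) rows."""
    return HaplotypeTable(pd.DataFrame(rows, columns=COLUMNS))


def single_copy_table(
    pedigree_id: str, genotypes: dict[str, dict[str, float]]
) -> HaplotypeTable:
    """sample -> {marker -> allele} convenience constructor."""
    rows = [
        (pedigree_id, sample, marker, (float(allele),))
        for sample, markers in genotypes.items()
        for marker, allele in markers.items()
    ]
    return make_table(rows)


# ---------------------------------------------------------------------------
# oracle: multi-copy counting by exhaustive enumeration


def brute_force_multi_copy(
    alleles_a: tuple[float, ...], alleles_b: tuple[float, ...], c: int
) -> int:
    """Minimum mutations over all paddings x all copy permutations."""

    def paddings(alleles):
        short = c - len(alleles)
        if short == 0:
            return {tuple(sorted(alleles))}
        return {
            tuple(sorted(alleles + extra))
            for extra in itertools.combinations_with_replacement(alleles, short)
        }

    def steps(a, b):
        tenths = round(abs(a - b) * 10)
        if tenths == 0:
            return 0
        return tenths // 10 if tenths % 10 == 0 else 1

    best = None
    for pa in paddings(alleles_a):
        for pb in paddings(alleles_b):
            for perm in itertools.permutations(range(c)):
                total = sum(steps(pa[i], pb[perm[i]]) for i in range(c))
                if best is None or total < best:
                    best = total
    return best


# ---------------------------------------------------------------------------
# oracle: minimum mutation cost by exhaustive ancestral-state enumeration


def brute_force_placement_cost(
    ped: PedigreeGraph, observed: dict[str, float]
) -> int:
    """Exhaustive minimum over all state assignments to untyped nodes.

    ``observed`` maps node ids (not labels) of genotyped nodes to their
    allele.  Works on the subtree spanning the genotyped nodes of a single
    connected component; states range over the integer ladder spanning the
    observed alleles +/- 2 repeats.
    """
    und = ped.graph.to_undirected(as_view=True)
    nodes = set(observed)
    obs_ids = list(observed)
    for other in obs_ids[1:]:
        nodes.update(nx.shortest_path(und, obs_ids[0], other))
    span_edges = [(u, v) for u, v in ped.graph.edges if u in nodes and v in nodes]
    free = [n for n in nodes if n not in observed]
    lo = min(observed.values()) - 2
    hi = max(observed.values()) + 2
    states = [lo + k for k in range(int(hi - lo) + 1)]

    def edge_cost(u, v, assignment):
        su, sv = assignment[u], assignment[v]
        if u in observed and v in observed:
            return 0 if su == sv else 1
        return abs(int(round(su - sv)))

    best = None
    for combo in itertools.product(states, repeat=len(free)):
        assignment = dict(observed)
        assignment.update(zip(free, combo))
        total = sum(edge_cost(u, v, assignment) for u, v in span_edges)
        if best is None or total < best:
            best = total
    return best


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240215)
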