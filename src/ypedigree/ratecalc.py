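"""Pedigree-aware Y-STR mutation-rate estimation.

Given a pedigree structure and the genotypes of its typed members, this
module places the minimum number of stepwise mutations on the family tree
that explains the observed variation, infers the founder (most recent
common ancestor) haplotype, counts the meioses covered by the typed pairs,
and turns event and meiosis totals into locus-specific mutation rates with
exact binomial confidence intervals.

The placement is a bottom-up minimum-cost ancestral-state reconstruction
(Sankoff dynamic programming) over the subtree spanning the genotyped men.
Costs encode the stepwise mutation model with one asymmetry: an allele
difference observed directly between a genotyped father and his genotyped
son is a single event no matter its size (they are separated by one
meiosis), whereas the same difference across a chain of untyped men
decomposes into independent single-step events.  Ties are resolved by
placing events as close to the pedigree root as possible, so a variant
shared by a branch is attributed to the earliest transmission that can
carry it.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .haplotypes import HaplotypeTable, format_alleles
from .pairwise import clopper_pearson, count_single_copy
from . import pairwise as _pairwise

logger = logging.getLogger(__name__)

__all__ = [
    "MutationEvent",
    "AncestralHaplotype",
    "covered_meioses",
    "place_mutations",
    "infer_founder_haplotype",
    "estimate_rates",
    "render_pedigree",
]


@dataclass(frozen=True)
class MutationEvent:
    """One mutation placed on a father->son edge of a pedigree."""

    pedigree_id: str
    marker: str
    edge: tuple[str, str]  # (father node id, son node id)
    step: float  # signed repeat-unit change, never 0
    allele_from: float
    allele_to: float


@dataclass
class AncestralHaplotype:
    """Founder haplotype inferred for a pedigree root (drawn in white)."""

    pedigree_id: str
    states: dict[str, tuple[float, ...]]  # marker -> allele multiset


# ---------------------------------------------------------------------------
# covered meioses


def _component_subtrees(ped) -> list[tuple[nx.DiGraph, list[str]]]:
    """(component as DiGraph view, genotyped node ids) per weak component."""
    out = []
    for comp in nx.weakly_connected_components(ped.graph):
        sub = ped.graph.subgraph(comp)
        genotyped = [n for n in comp if ped.is_genotyped(n)]
        out.append((sub, genotyped))
    return out


def _spanning_subtree(sub: nx.DiGraph, genotyped: list[str]) -> nx.DiGraph:
    """Minimal subtree containing all genotyped nodes (union of pair paths)."""
    und = sub.to_undirected(as_view=True)
    keep_nodes: set[str] = set(genotyped)
    if len(genotyped) >= 2:
        base = genotyped[0]
        paths = nx.single_source_shortest_path(und, base)
        for other in genotyped[1:]:
            keep_nodes.update(paths[other])
        # paths between non-base pairs are contained in the union of
        # base->a and base->b paths on a tree, so this union is complete
    return sub.subgraph(keep_nodes)


def covered_meioses(ped) -> int:
    """Meioses covered by all genotyped pairs: edge count of the subtree
    spanning the genotyped men (0 when fewer than two are typed)."""
    total = 0
    for sub, genotyped in _component_subtrees(ped):
        if len(genotyped) < 2:
            continue
        total += _spanning_subtree(sub, genotyped).number_of_edges()
    return total


# ---------------------------------------------------------------------------
# mutation placement (single-copy chains)


def _step_cost(a: float, b: float) -> int:
    """Stepwise cost of a state change across one untyped transmission."""
    return count_single_copy(a, b, warn=False)


def _candidate_states(observed: list[float]) -> list[float]:
    """Integer-step ladders around each observed allele, +/-2 margin."""
    states: set[float] = set()
    for a in observed:
        for k in range(-2, 3):
            states.add(round(a + k, 1))
    return sorted(states)


def _sankoff_chain(
    tree: nx.DiGraph,
    observed: dict[str, float],
    genotyped: set[str],
) -> tuple[int, dict[str, float]]:
    """Minimum-cost ancestral-state assignment for one allele chain.

    ``observed`` fixes the state of genotyped nodes.  Edge cost is 1 for any
    difference between two genotyped endpoints, else the stepwise distance.
    Returns (total cost, state per node) with rootward tie-breaking.
    """
    states = _candidate_states(sorted(set(observed.values())))
    root = next(n for n in tree.nodes if tree.in_degree(n) == 0)
    order = list(nx.dfs_postorder_nodes(tree, root))
    big = float("inf")

    def edge_cost(u: str, v: str, su: float, sv: float) -> int:
        if u in genotyped and v in genotyped:
            return 0 if su == sv else 1
        return _step_cost(su, sv)

    cost: dict[str, dict[float, float]] = {}
    for node in order:
        if node in genotyped:
            cost[node] = {s: (0 if s == observed[node] else big) for s in states}
        else:
            cost[node] = {s: 0.0 for s in states}
        for child in tree.successors(node):
            for s in states:
                if cost[node][s] == big:
                    continue
                cost[node][s] += min(
                    edge_cost(node, child, s, t) + cost[child][t] for t in states
                )

    # root state: min cost, then carried by the most genotyped individuals,
    # then smallest allele value for determinism
    best = min(cost[root].values())
    support = {s: sum(1 for v in observed.values() if v == s) for s in states}
    root_state = min(
        (s for s in states if cost[root][s] == best),
        key=lambda s: (-support[s], s),
    )

    assignment = {root: root_state}
    for node in nx.dfs_preorder_nodes(tree, root):
        s = assignment[node]
        for child in tree.successors(node):
            # rootward rule: among cost ties take the child state with the
            # least remaining subtree cost, pushing the change onto this
            # (topmost possible) edge
            assignment[child] = min(
                (t for t in states),
                key=lambda t: (
                    edge_cost(node, child, s, t) + cost[child][t],
                    cost[child][t],
                    abs(t - s),
                    t,
                ),
            )
    return int(best), assignment


def _events_from_assignment(
    tree: nx.DiGraph,
    assignment: dict[str, float],
    genotyped: set[str],
    pedigree_id: str,
    marker: str,
) -> list[MutationEvent]:
    events = []
    for u, v in tree.edges:
        su, sv = assignment[u], assignment[v]
        if su == sv:
            continue
        if u in genotyped and v in genotyped:
            # one directly observed event, whatever its step size
            events.append(
                MutationEvent(pedigree_id, marker, (u, v), round(sv - su, 1), su, sv)
            )
            continue
        tenths = round(abs(sv - su) * 10)
        if tenths % 10:  # non-stepwise microvariant change: single event
            events.append(
                MutationEvent(pedigree_id, marker, (u, v), round(sv - su, 1), su, sv)
            )
            continue
        direction = 1.0 if sv > su else -1.0
        state = su
        for _ in range(tenths // 10):
            events.append(
                MutationEvent(
                    pedigree_id, marker, (u, v), direction, state, round(state + direction, 1)
                )
            )
            state = round(state + direction, 1)
    return events


# ---------------------------------------------------------------------------
# multi-copy slot alignment


def _sorted_match_cost(a: tuple[float, ...], b: tuple[float, ...]) -> int:
    """Optimal stepwise matching cost of two equal-size multisets (sorted
    order is an optimal assignment for 1-D step costs)."""
    return sum(_step_cost(x, y) for x, y in zip(sorted(a), sorted(b)))


def _copy_slots(
    genotypes: dict[str, tuple[float, ...]], c: int
) -> dict[str, tuple[float, ...]]:
    """Pad each genotype to c copies and align copies into rank slots.

    The copy-richest individual anchors the alignment; every other sample
    takes the self-duplication padding minimising its stepwise cost against
    that anchor, and slot k holds each sample's k-th smallest allele.
    """
    anchor_id = max(genotypes, key=lambda s: (len(genotypes[s]), s))
    anchor = tuple(sorted(genotypes[anchor_id]))
    slots = {}
    for sample, alleles in genotypes.items():
        best = min(
            _pairwise._paddings(alleles, c),
            key=lambda pad: (_sorted_match_cost(pad, anchor), pad),
        )
        slots[sample] = tuple(sorted(best))
    return slots


# ---------------------------------------------------------------------------
# public operations


def place_mutations(
    ped, table: HaplotypeTable, marker: str
) -> tuple[list[MutationEvent], tuple[float, ...], dict[str, tuple[float, ...]]]:
    """Place the minimum number of stepwise mutations for one marker.

    Returns (events, ancestral allele multiset, per-node state assignment
    over the spanning subtree).  Multi-copy loci are harmonized to the
    pedigree-wide copy count and each copy slot is reconstructed as an
    independent single-copy chain.
    """
    if marker not in table.markers:
        raise KeyError(f"marker {marker!r} not present in the haplotype table")
    geno_by_label = table.genotypes(ped.pedigree_id, marker)
    label_of = ped.labels
    missing = [lab for lab in label_of.values() if lab not in geno_by_label]
    if missing:
        raise KeyError(
            f"no genotype at {marker!r} for sample(s) {missing} of pedigree "
            f"{ped.pedigree_id!r}"
        )

    events: list[MutationEvent] = []
    ancestral: tuple[float, ...] = ()
    assignment: dict[str, tuple[float, ...]] = {}
    best_component_size = -1

    for sub, genotyped in _component_subtrees(ped):
        if not genotyped:
            continue
        span = _spanning_subtree(sub, genotyped)
        observed = {n: geno_by_label[label_of[n]] for n in genotyped}
        c = max(len(a) for a in observed.values())
        slots = _copy_slots(observed, c)
        genotyped_set = set(genotyped)

        comp_states: dict[str, list[float]] = {n: [] for n in span.nodes}
        comp_root: list[float] = []
        for k in range(c):
            chain_obs = {n: slots[n][k] for n in genotyped}
            if span.number_of_edges() == 0:
                node = genotyped[0]
                comp_states[node].append(chain_obs[node])
                comp_root.append(chain_obs[node])
                continue
            _, chain_assignment = _sankoff_chain(span, chain_obs, genotyped_set)
            suffix = f"_{chr(ord('a') + k)}" if c > 1 else ""
            events.extend(
                _events_from_assignment(
                    span, chain_assignment, genotyped_set, ped.pedigree_id, marker + suffix
                )
            )
            root = next(n for n in span.nodes if span.in_degree(n) == 0)
            comp_root.append(chain_assignment[root])
            for n in span.nodes:
                comp_states[n].append(chain_assignment[n])

        comp_assignment = {n: tuple(sorted(v)) for n, v in comp_states.items()}
        if len(genotyped) > best_component_size:
            best_component_size = len(genotyped)
            ancestral = tuple(sorted(comp_root))
        assignment.update(comp_assignment)

    return events, ancestral, assignment


def infer_founder_haplotype(ped, table: HaplotypeTable) -> AncestralHaplotype:
    """Founder haplotype: per-marker ancestral states assembled across loci."""
    states = {}
    for marker in table.markers:
        _, ancestral, _ = place_mutations(ped, table, marker)
        states[marker] = ancestral
    return AncestralHaplotype(pedigree_id=ped.pedigree_id, states=states)


def estimate_rates(
    pedigrees: list[tuple[object, HaplotypeTable]], alpha: float = 0.05
) -> pd.DataFrame:
    """Locus-specific mutation rates pooled over pedigrees.

    Per marker: total placed events and total covered meioses summed across
    all pedigrees; rate = events / meioses with an exact Clopper-Pearson
    confidence interval (meioses treated as Bernoulli trials — an
    approximation when one meiosis carries several events).
    """
    if not pedigrees:
        raise ValueError("estimate_rates requires at least one pedigree")
    markers = list(pedigrees[0][1].markers)
    meioses_total = sum(covered_meioses(ped) for ped, _ in pedigrees)
    if meioses_total == 0:
        raise ValueError("zero covered meioses: no pedigree has two genotyped members")
    rows = []
    for marker in markers:
        n_events = 0
        for ped, table in pedigrees:
            events, _, _ = place_mutations(ped, table, marker)
            n_events += len(events)
        k = min(n_events, meioses_total)  # CI clamp for multi-event meioses
        low, high = clopper_pearson(k, meioses_total, alpha)
        rows.append(
            [marker, n_events, meioses_total, n_events / meioses_total, low, high]
        )
    return pd.DataFrame(
        rows, columns=["marker", "mutations", "meioses", "rate", "ci_low", "ci_high"]
    )


# ---------------------------------------------------------------------------
# pedigree drawing (DOT emission; layout is left to Graphviz)

_PALETTE = [
    "#a6cee3", "#b2df8a", "#fb9a99", "#fdbf6f", "#cab2d6", "#ffff99",
    "#1f78b4", "#33a02c", "#e31a1c", "#ff7f00", "#6a3d9a", "#b15928",
    "#8dd3c7", "#bebada", "#fccde5", "#d9d9d9", "#bc80bd", "#ccebc5",
]


def render_pedigree(
    ped, table: HaplotypeTable
) -> tuple[str, pd.DataFrame]:
    """Draw a pedigree as a DOT document with a mutation legend table.

    Each distinct reconstructed haplotype (state vector over all markers)
    receives one fill colour; the founder haplotype is white.  Edges that
    carry events are labelled M1, M2, ... and resolved in the returned
    legend table (label, marker, step, allele_from, allele_to).
    """
    all_events: list[MutationEvent] = []
    node_vectors: dict[str, list[tuple[float, ...]]] = {}
    founder_vector: list[tuple[float, ...]] = []
    for marker in table.markers:
        events, ancestral, assignment = place_mutations(ped, table, marker)
        all_events.extend(events)
        founder_vector.append(ancestral)
        for node, state in assignment.items():
            node_vectors.setdefault(node, []).append(state)

    founder_key = tuple(founder_vector)
    haplotype_keys: dict[tuple, str] = {founder_key: "white"}
    palette = itertools.cycle(_PALETTE)
    colors: dict[str, str] = {}
    for node, vector in node_vectors.items():
        key = tuple(vector)
        if key not in haplotype_keys:
            haplotype_keys[key] = next(palette)
        colors[node] = haplotype_keys[key]

    by_edge: dict[tuple[str, str], list[str]] = {}
    legend_rows = []
    for i, ev in enumerate(all_events, start=1):
        label = f"M{i}"
        by_edge.setdefault(ev.edge, []).append(label)
        legend_rows.append(
            [
                label,
                ev.marker,
                ev.step,
                format_alleles((ev.allele_from,)),
                format_alleles((ev.allele_to,)),
            ]
        )
    legend = pd.DataFrame(
        legend_rows, columns=["label", "marker", "step", "allele_from", "allele_to"]
    )

    lines = [f'digraph "{ped.pedigree_id}" {{', "  node [style=filled];"]
    for node in ped.graph.nodes:
        label = ped.label(node) or ""
        fill = colors.get(node, "white" if node in node_vectors else "lightgray")
        shape = "box" if ped.is_genotyped(node) else "ellipse"
        lines.append(
            f'  "{node}" [label="{label}", fillcolor="{fill}", shape={shape}];'
        )
    for u, v in ped.graph.edges:
        attrs = ""
        if (u, v) in by_edge:
            attrs = f' [label="{",".join(by_edge[(u, v)])}"]'
        lines.append(f'  "{u}" -> "{v}"{attrs};')
    lines.append("}")
    return "\n".join(lines) + "\n", legend
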