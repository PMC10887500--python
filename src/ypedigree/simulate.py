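"""Stepwise-mutation simulation of male relative pairs.

A pair of men separated by g meioses is modelled per locus as a g-step
Markov chain over non-negative "deviation states": the number of repeat
units by which the allele deviates from the ground state (the founder
allele), direction unknown.  From state 0 a transmission stays with
probability 1 - mu, moves one step with p_1step and two steps with p_2step
(default split 0.97 mu / 0.03 mu; the DYF1000 multi-copy locus mixes tri-
and hexanucleotide repeats whose step sizes cannot be told apart, so it
uses 0.94 mu / 0.06 mu).  From a nonzero state the mutation probabilities
are halved and become directional: equal mass toward and away from the
ground state, so from state 1 a backward step to 0 and a forward step to 2
are equally likely.  States never go negative; the impossible backward
two-step from state 1 donates its mass to the backward one-step.

Each meiotic distance is simulated with fresh chains from state 0 (the
chain for distance g is not an extension of stored distance g-1 draws).
Copies of a multi-copy locus run at mu / copies each and are summed into
one per-marker column, so the output is column-compatible with the
pairwise module's prediction input.

The module also provides the forward counterpart used for synthetic data:
evolving actual allele values down a pedigree under the same per-locus
model, which yields genotype tables for testing the rate-estimation
machinery against known truth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .haplotypes import COLUMNS, HaplotypeTable
from .pedigree_graph import PedigreeGraph

__all__ = [
    "LocusModel",
    "MutationModelConfig",
    "load_model_config",
    "simulate_chain",
    "simulate_pairs",
    "random_pedigree",
    "simulate_pedigree_genotypes",
    "DEFAULT_TWO_STEP_FRACTION",
    "DYF1000_TWO_STEP_FRACTION",
]

DEFAULT_TWO_STEP_FRACTION = 0.03
DYF1000_TWO_STEP_FRACTION = 0.06

_COPY_SUFFIX = re.compile(r"^(?P<base>.+)_(?P<copy>[a-z])$")


@dataclass(frozen=True)
class LocusModel:
    """Per-locus transmission probabilities: no mutation, 1-step, 2-step."""

    name: str  # copy name, e.g. DYF399S1_a; single-copy loci unsuffixed
    p_none: float
    p_1step: float
    p_2step: float

    def __post_init__(self):
        total = self.p_none + self.p_1step + self.p_2step
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"probabilities for locus {self.name!r} sum to {total!r}, not 1"
            )
        if min(self.p_none, self.p_1step, self.p_2step) < 0:
            raise ValueError(f"negative probability for locus {self.name!r}")

    @property
    def rate(self) -> float:
        return self.p_1step + self.p_2step

    @property
    def base_marker(self) -> str:
        m = _COPY_SUFFIX.match(self.name)
        return m.group("base") if m else self.name

    @classmethod
    def from_rate(cls, name: str, rate: float, two_step_fraction: float | None = None):
        """Split a total mutation rate into 1-step/2-step probabilities."""
        if rate < 0 or rate > 1:
            raise ValueError(f"mutation rate for {name!r} must lie in [0, 1]")
        if two_step_fraction is None:
            base = name
            m = _COPY_SUFFIX.match(name)
            if m:
                base = m.group("base")
            two_step_fraction = (
                DYF1000_TWO_STEP_FRACTION
                if base.upper() == "DYF1000"
                else DEFAULT_TWO_STEP_FRACTION
            )
        return cls(
            name=name,
            p_none=1.0 - rate,
            p_1step=(1.0 - two_step_fraction) * rate,
            p_2step=two_step_fraction * rate,
        )


@dataclass
class MutationModelConfig:
    """Validated per-locus models with multi-copy groups by _a-z suffix."""

    loci: list[LocusModel]

    @property
    def markers(self) -> list[str]:
        """Base marker names (copies collapsed), in config order."""
        return list(dict.fromkeys(locus.base_marker for locus in self.loci))

    @property
    def copy_groups(self) -> dict[str, list[LocusModel]]:
        groups: dict[str, list[LocusModel]] = {}
        for locus in self.loci:
            groups.setdefault(locus.base_marker, []).append(locus)
        return groups

    @classmethod
    def from_rates(
        cls,
        rates: dict[str, float],
        copies: dict[str, int] | None = None,
        two_step_fractions: dict[str, float] | None = None,
    ) -> "MutationModelConfig":
        """Build a config from total per-marker rates.

        ``copies`` gives the copy number of multi-copy markers (default 1);
        each copy runs at total rate / copies with an _a.. suffix.
        """
        copies = copies or {}
        two_step_fractions = two_step_fractions or {}
        loci = []
        for marker, rate in rates.items():
            c = copies.get(marker, 1)
            frac = two_step_fractions.get(marker)
            if c == 1:
                loci.append(LocusModel.from_rate(marker, rate, frac))
            else:
                for k in range(c):
                    loci.append(
                        LocusModel.from_rate(
                            f"{marker}_{chr(ord('a') + k)}", rate / c, frac
                        )
                    )
        return cls(loci)


def load_model_config(path: str | Path) -> MutationModelConfig:
    """Read a marker configuration CSV.

    Two layouts are accepted: ``locus,p_none,p_1step,p_2step`` with explicit
    probabilities, or ``locus,rate`` with total rates split automatically
    (0.97/0.03; 0.94/0.06 for DYF1000 copies).  Multi-copy loci appear as
    one row per copy with _a-z suffixes.
    """
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    loci = []
    if {"p_none", "p_1step", "p_2step"} <= set(df.columns):
        for row in df.itertuples(index=False):
            loci.append(
                LocusModel(
                    name=str(row.locus).strip(),
                    p_none=float(row.p_none),
                    p_1step=float(row.p_1step),
                    p_2step=float(row.p_2step),
                )
            )
    elif "rate" in df.columns:
        for row in df.itertuples(index=False):
            loci.append(LocusModel.from_rate(str(row.locus).strip(), float(row.rate)))
    else:
        raise ValueError(
            "model config needs columns locus,p_none,p_1step,p_2step or locus,rate"
        )
    return MutationModelConfig(loci)


def simulate_chain(
    locus: LocusModel,
    g: int,
    rng: np.random.Generator,
    n: int = 1,
    initial: np.ndarray | None = None,
) -> np.ndarray:
    """Final deviation states of ``n`` independent g-meiosis chains.

    ``initial`` overrides the ground-state start (used to probe single
    transitions from nonzero states); entries must be non-negative.
    """
    if g < 1:
        raise ValueError("a pair must be separated by at least one meiosis")
    if initial is None:
        state = np.zeros(n, dtype=np.int64)
    else:
        state = np.asarray(initial, dtype=np.int64).copy()
        if (state < 0).any():
            raise ValueError("deviation states cannot be negative")
        n = state.size
    p_none, p1, p2 = locus.p_none, locus.p_1step, locus.p_2step
    for _ in range(g):
        u = rng.random(n)
        delta = np.zeros(n, dtype=np.int64)
        zero = state == 0
        # ground state: undirected, full mutation mass
        delta[zero & (u >= p_none) & (u < p_none + p1)] = 1
        delta[zero & (u >= p_none + p1)] = 2
        # nonzero state: halved and directional
        nz = ~zero
        c1 = p_none + p1 / 2  # forward 1
        c2 = c1 + p1 / 2  # backward 1
        c3 = c2 + p2 / 2  # forward 2
        delta[nz & (u >= p_none) & (u < c1)] = 1
        delta[nz & (u >= c1) & (u < c2)] = -1
        delta[nz & (u >= c2) & (u < c3)] = 2
        back2 = nz & (u >= c3)
        # backward 2 from state 1 would go negative: reassigned to -1
        delta[back2] = np.where(state[back2] >= 2, -2, -1)
        state = state + delta
    assert (state >= 0).all()
    return state


def simulate_pairs(
    config: MutationModelConfig,
    generations: list[int],
    n_per_generation: int,
    seed: int,
) -> pd.DataFrame:
    """Simulated training pairs: per-marker deviation counts by distance.

    For every meiotic distance g a fresh set of ``n_per_generation`` chains
    is run per locus; copies of a multi-copy marker are summed into one
    column.  Deterministic for a fixed seed.  Columns: generation, then the
    base marker names in config order.
    """
    if n_per_generation < 1:
        raise ValueError("n_per_generation must be >= 1")
    if not generations:
        raise ValueError("generations must be non-empty")
    rng = np.random.default_rng(seed)
    frames = []
    for g in generations:
        data = {"generation": np.full(n_per_generation, g, dtype=np.int64)}
        for marker, group in config.copy_groups.items():
            total = np.zeros(n_per_generation, dtype=np.int64)
            for locus in group:
                total += simulate_chain(locus, g, rng, n=n_per_generation)
            data[marker] = total
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# forward simulation on pedigrees (synthetic ground truth)


def random_pedigree(
    n_nodes: int,
    n_genotyped: int,
    rng: np.random.Generator,
    pedigree_id: str = "sim",
) -> PedigreeGraph:
    """Random rooted father->son tree with a random genotyped subset.

    Node i's father is drawn uniformly from nodes 0..i-1 (a random
    recursive tree); ``n_genotyped`` nodes get labels S<node>.
    """
    if not 1 <= n_genotyped <= n_nodes:
        raise ValueError("need 1 <= n_genotyped <= n_nodes")
    ped = PedigreeGraph(pedigree_id=pedigree_id)
    labelled = set(rng.choice(n_nodes, size=n_genotyped, replace=False).tolist())
    for i in range(n_nodes):
        ped.add_node(str(i), label=f"S{i}" if i in labelled else "")
    for i in range(1, n_nodes):
        father = int(rng.integers(0, i))
        ped.add_edge(str(father), str(i))
    ped.validate()
    return ped


def _transmit(
    allele: float, locus: LocusModel, rng: np.random.Generator
) -> float:
    """One father->son transmission of an actual allele value (signed steps)."""
    u = rng.random()
    if u < locus.p_none:
        return allele
    sign = 1.0 if rng.random() < 0.5 else -1.0
    step = 1.0 if u < locus.p_none + locus.p_1step else 2.0
    return round(allele + sign * step, 1)


def simulate_pedigree_genotypes(
    ped: PedigreeGraph,
    config: MutationModelConfig,
    founder: dict[str, tuple[float, ...]] | None = None,
    rng: np.random.Generator | None = None,
) -> HaplotypeTable:
    """Evolve allele values down a pedigree and report genotyped members.

    Every edge applies one transmission per locus copy under the locus
    model (mutation direction uniform).  ``founder`` assigns root allele
    multisets per base marker; by default every copy starts at repeat 15.
    Returns a complete HaplotypeTable for the labelled nodes.
    """
    rng = rng or np.random.default_rng()
    groups = config.copy_groups
    if founder is None:
        founder = {m: tuple([15.0] * len(g)) for m, g in groups.items()}

    roots = [n for n in ped.graph.nodes if ped.graph.in_degree(n) == 0]
    states: dict[str, dict[str, list[float]]] = {
        root: {m: list(founder[m]) for m in groups} for root in roots
    }
    records = []
    for root in roots:
        for father, son in nx.bfs_edges(ped.graph, root):
            son_state = {}
            for marker, group in groups.items():
                son_state[marker] = [
                    _transmit(a, locus, rng)
                    for a, locus in zip(states[father][marker], group)
                ]
            states[son] = son_state
    for node in ped.graph.nodes:
        if not ped.is_genotyped(node):
            continue
        for marker in groups:
            records.append(
                (
                    ped.pedigree_id,
                    ped.label(node),
                    marker,
                    tuple(sorted(states[node][marker])),
                )
            )
    table = HaplotypeTable(pd.DataFrame(records, columns=COLUMNS))
    table.markers = list(groups.keys())
    return table
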