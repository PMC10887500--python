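"""Male pedigrees in Trivial Graph Format and pairwise meiotic distances.

A pedigree is a forest of rooted trees with directed father->son edges.
Nodes carrying a label are genotyped individuals; unlabelled nodes are
ungenotyped men who only contribute to path lengths.  TGF is the plain-text
interchange format used by graph editors such as yEd: node lines
(``id [label]``), a single ``#`` separator line, then edge lines
(``from_id to_id [ignored label]``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PedigreeGraph",
    "PairDistanceRecord",
    "TGFParseError",
    "parse_tgf",
    "read_tgf",
    "read_tgf_dir",
    "write_tgf",
    "meiotic_distances",
    "distances_frame",
]


class TGFParseError(ValueError):
    """Raised for malformed TGF documents; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class PairDistanceRecord:
    """Meiotic distance between two genotyped males of one pedigree.

    ``meioses`` is the number of edges on the unique tree path between the
    two men; ``lineal`` is True iff one is a patrilineal ancestor of the
    other (the path runs monotonically father->son).
    """

    pedigree_id: str
    sample_a: str
    sample_b: str
    meioses: int
    lineal: bool


@dataclass
class PedigreeGraph:
    """Directed father->son forest with genotyped/ungenotyped node flags.

    Backed by a :class:`networkx.DiGraph`; node attribute ``label`` holds
    the sample identifier of genotyped men ('' for ungenotyped nodes).
    """

    pedigree_id: str
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def node_ids(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def label(self, node_id: str) -> str:
        return self.graph.nodes[node_id].get("label", "")

    def is_genotyped(self, node_id: str) -> bool:
        return bool(self.label(node_id))

    @property
    def genotyped_nodes(self) -> list[str]:
        return [n for n in self.graph.nodes if self.is_genotyped(n)]

    @property
    def labels(self) -> dict[str, str]:
        """node_id -> sample label for genotyped nodes only."""
        return {n: self.label(n) for n in self.genotyped_nodes}

    def add_node(self, node_id: str, label: str = "") -> None:
        self.graph.add_node(str(node_id), label=label.strip())

    def add_edge(self, father_id: str, son_id: str) -> None:
        self.graph.add_edge(str(father_id), str(son_id))

    def validate(self) -> None:
        """Check the forest invariants; raise :class:`TGFParseError` otherwise."""
        for node in self.graph.nodes:
            if self.graph.in_degree(node) > 1:
                fathers = sorted(self.graph.predecessors(node))
                raise TGFParseError(
                    f"node {node!r} has {len(fathers)} fathers ({', '.join(fathers)}); "
                    "a pedigree node may have at most one incoming edge"
                )
        # with at most one father per node, acyclicity of the directed graph
        # is exactly the forest property (incl. the antiparallel 2-cycle)
        if len(self.graph) and not nx.is_directed_acyclic_graph(self.graph):
            raise TGFParseError(
                f"pedigree {self.pedigree_id!r} contains a cycle; "
                "each connected component must be a tree"
            )
        seen: dict[str, str] = {}
        for node in self.genotyped_nodes:
            lab = self.label(node)
            if lab in seen:
                raise TGFParseError(
                    f"label {lab!r} appears on nodes {seen[lab]!r} and {node!r}; "
                    "labels must be unique within a pedigree"
                )
            seen[lab] = node

    def roots(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.in_degree(n) == 0]


def parse_tgf(text: str, pedigree_id: str = "pedigree") -> PedigreeGraph:
    """Parse a TGF document into a validated :class:`PedigreeGraph`.

    Node section: one node per line, ``id`` optionally followed by a label
    (everything after the first whitespace).  A line holding ``#`` separates
    nodes from edges.  Edge lines: ``father_id son_id``; any trailing edge
    label is ignored.  Edge direction is father->son.
    """
    ped = PedigreeGraph(pedigree_id=pedigree_id)
    in_edges = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if not in_edges and line.split(maxsplit=1)[0] == "#":
            in_edges = True
            continue
        if not in_edges:
            parts = line.split(maxsplit=1)
            node_id = parts[0]
            label = parts[1].strip() if len(parts) > 1 else ""
            if node_id in ped.graph.nodes:
                raise TGFParseError(f"duplicate node id {node_id!r}", lineno)
            ped.add_node(node_id, label)
        else:
            parts = line.split()
            if len(parts) < 2:
                raise TGFParseError(
                    f"malformed edge line {line!r}; expected 'father_id son_id'", lineno
                )
            father, son = parts[0], parts[1]
            for endpoint in (father, son):
                if endpoint not in ped.graph.nodes:
                    raise TGFParseError(
                        f"edge references unknown node {endpoint!r}", lineno
                    )
            ped.add_edge(father, son)
    ped.validate()
    return ped


def read_tgf(path: str | Path, pedigree_id: str | None = None) -> PedigreeGraph:
    """Read one pedigree from a ``.tgf`` file; pedigree id defaults to the stem."""
    path = Path(path)
    return parse_tgf(path.read_text(), pedigree_id or path.stem)


def read_tgf_dir(directory: str | Path) -> list[PedigreeGraph]:
    """Read every ``*.tgf`` file in a directory (one pedigree per file)."""
    directory = Path(directory)
    files = sorted(directory.glob("*.tgf"))
    if not files:
        raise FileNotFoundError(f"no .tgf files found in {directory}")
    return [read_tgf(f) for f in files]


def write_tgf(ped: PedigreeGraph) -> str:
    """Serialize a pedigree back to TGF; round-trips through :func:`parse_tgf`."""
    lines = []
    for node in ped.graph.nodes:
        label = ped.label(node)
        lines.append(f"{node} {label}".rstrip())
    lines.append("#")
    for father, son in ped.graph.edges:
        lines.append(f"{father} {son}")
    return "\n".join(lines) + "\n"


def _ancestors_with_depth(graph: nx.DiGraph, node: str) -> dict[str, int]:
    """Patrilineal ancestors of ``node`` (inclusive) -> meioses up to them."""
    out = {node: 0}
    current = node
    depth = 0
    while True:
        preds = list(graph.predecessors(current))
        if not preds:
            return out
        current = preds[0]
        depth += 1
        out[current] = depth


def meiotic_distances(ped: PedigreeGraph) -> list[PairDistanceRecord]:
    """All pairwise meiotic distances between genotyped males.

    One record per unordered genotyped pair in the same connected component;
    distance = edges on the unique undirected tree path, with ungenotyped
    nodes counted only as path steps.  Genotyped pairs split across
    components are skipped with a warning.
    """
    genotyped = ped.genotyped_nodes
    # distance(a, b) = depth(a) + depth(b) - 2 * depth(mrca): walk each
    # node's ancestor chain once, then intersect chains per pair.
    chains = {n: _ancestors_with_depth(ped.graph, n) for n in genotyped}
    records: list[PairDistanceRecord] = []
    skipped = 0
    for i, a in enumerate(genotyped):
        for b in genotyped[i + 1 :]:
            common = chains[a].keys() & chains[b].keys()
            if not common:
                skipped += 1
                continue
            mrca = min(common, key=lambda n: chains[a][n])
            da, db = chains[a][mrca], chains[b][mrca]
            records.append(
                PairDistanceRecord(
                    pedigree_id=ped.pedigree_id,
                    sample_a=ped.label(a),
                    sample_b=ped.label(b),
                    meioses=da + db,
                    lineal=(da == 0 or db == 0),
                )
            )
    if skipped:
        logger.warning(
            "pedigree %s: skipped %d genotyped pair(s) in disconnected components",
            ped.pedigree_id,
            skipped,
        )
    return records


def distances_frame(pedigrees: Iterable[PedigreeGraph]) -> pd.DataFrame:
    """Meiotic distances for several pedigrees as one tidy table."""
    rows: Iterator[PairDistanceRecord] = (
        rec for ped in pedigrees for rec in meiotic_distances(ped)
    )
    df = pd.DataFrame(
        [(r.pedigree_id, r.sample_a, r.sample_b, r.meioses, r.lineal) for r in rows],
        columns=["pedigree_id", "sample_a", "sample_b", "meioses", "lineal"],
    )
    return df
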