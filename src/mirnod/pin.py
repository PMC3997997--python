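"""Protein-interaction subnetworks around each candidate miRNA's targets.

For a candidate miRNA, the regulated protein-interaction network (PIN) is the
one-hop expansion of its exclusive targets inside a reference PPI graph:

* **N0** — exclusive targets that are present as nodes in the PPI;
* **N1** — direct PPI neighbors of N0 genes, excluding N0 itself;
* **N2** — the merged network size, N0 + N1.

The exported subnetwork contains the miRNA→N0 regulatory edges plus the PPI
edges with at least one endpoint in N0 (pure star expansion); edges internal
to N1 are excluded by default and can be added with ``include_n1_edges``.
Gene identifiers must match the interaction database verbatim — there is no
identifier mapping service, and mismatches simply fall outside N0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = ["PINetwork", "load_ppi", "build_pin", "export_pin", "import_pin", "pin_summary_row"]

ROLE_MIRNA = "mirna"
ROLE_TARGET = "target"
ROLE_NEIGHBOR = "neighbor"
EDGE_REGULATORY = "regulatory"
EDGE_PPI = "ppi"


@dataclass
class PINetwork:
    mirna_id: str
    n0_genes: frozenset[str]
    n1_genes: frozenset[str]
    regulatory_edges: frozenset[tuple[str, str]]    # (mirna, n0 gene)
    ppi_edges: frozenset[tuple[str, str]]           # sorted endpoint pairs

    @property
    def n0(self) -> int:
        return len(self.n0_genes)

    @property
    def n1(self) -> int:
        return len(self.n1_genes)

    @property
    def n2(self) -> int:
        return self.n0 + self.n1


def load_ppi(path: str | Path) -> nx.Graph:
    """Load a two-column TSV edge list into an undirected simple graph.

    Self-loops are dropped (count kept in ``G.graph['n_self_loops_dropped']``)
    and reciprocal/duplicate rows collapse to one edge. ``#`` comments and
    blank lines are skipped; a malformed line raises with its line number.
    """
    path = Path(path)
    g = nx.Graph()
    dropped = 0
    with io.open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}: line {lineno}: expected two tab-separated node ids"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                dropped += 1
                continue
            g.add_edge(a, b)
    g.graph["n_self_loops_dropped"] = dropped
    return g


def build_pin(
    mirna_id: str,
    exclusive_targets: Iterable[str],
    ppi: nx.Graph,
    include_n1_edges: bool = False,
) -> PINetwork:
    """One-hop PIN expansion of a miRNA's exclusive targets."""
    targets = set(exclusive_targets)
    n0 = {g for g in targets if g in ppi}
    n1: set[str] = set()
    for g in n0:
        n1.update(ppi.neighbors(g))
    n1 -= n0
    edges: set[tuple[str, str]] = set()
    for g in n0:
        for nb in ppi.neighbors(g):
            edges.add(tuple(sorted((g, nb))))
    if include_n1_edges:
        for a in n1:
            for b in ppi.neighbors(a):
                if b in n1:
                    edges.add(tuple(sorted((a, b))))
    return PINetwork(
        mirna_id=mirna_id,
        n0_genes=frozenset(n0),
        n1_genes=frozenset(n1),
        regulatory_edges=frozenset((mirna_id, g) for g in n0),
        ppi_edges=frozenset(edges),
    )


def export_pin(pin: PINetwork, path: str | Path, format: str = "tsv") -> list[Path]:
    """Write a PIN as node/edge tables (``tsv``) or as ``graphml``.

    Node roles are ``mirna`` / ``target`` (N0) / ``neighbor`` (N1); edge
    types are ``regulatory`` (miRNA→target) or ``ppi``. The TSV format
    writes ``<path>.nodes.tsv`` and ``<path>.edges.tsv``.
    """
    path = Path(path)
    if format == "tsv":
        nodes_path = path.with_name(path.name + ".nodes.tsv")
        edges_path = path.with_name(path.name + ".edges.tsv")
        with io.open(nodes_path, "w", encoding="utf-8") as fh:
            fh.write("node\trole\n")
            fh.write(f"{pin.mirna_id}\t{ROLE_MIRNA}\n")
            for g in sorted(pin.n0_genes):
                fh.write(f"{g}\t{ROLE_TARGET}\n")
            for g in sorted(pin.n1_genes):
                fh.write(f"{g}\t{ROLE_NEIGHBOR}\n")
        with io.open(edges_path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\ttype\n")
            for m, g in sorted(pin.regulatory_edges):
                fh.write(f"{m}\t{g}\t{EDGE_REGULATORY}\n")
            for a, b in sorted(pin.ppi_edges):
                fh.write(f"{a}\t{b}\t{EDGE_PPI}\n")
        return [nodes_path, edges_path]
    if format == "graphml":
        g = nx.Graph()
        g.add_node(pin.mirna_id, role=ROLE_MIRNA)
        for n in pin.n0_genes:
            g.add_node(n, role=ROLE_TARGET)
        for n in pin.n1_genes:
            g.add_node(n, role=ROLE_NEIGHBOR)
        for m, t in pin.regulatory_edges:
            g.add_edge(m, t, type=EDGE_REGULATORY)
        for a, b in pin.ppi_edges:
            g.add_edge(a, b, type=EDGE_PPI)
        nx.write_graphml(g, path)
        return [path]
    raise ValueError(f"unsupported export format {format!r}")


def import_pin(path: str | Path) -> PINetwork:
    """Load a PIN previously written by :func:`export_pin` (tsv format)."""
    path = Path(path)
    nodes_path = path.with_name(path.name + ".nodes.tsv")
    edges_path = path.with_name(path.name + ".edges.tsv")
    mirna_id = ""
    n0: set[str] = set()
    n1: set[str] = set()
    with io.open(nodes_path, "r", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            node, role = line.rstrip("\n").split("\t")
            if role == ROLE_MIRNA:
                mirna_id = node
            elif role == ROLE_TARGET:
                n0.add(node)
            elif role == ROLE_NEIGHBOR:
                n1.add(node)
    reg: set[tuple[str, str]] = set()
    ppi_edges: set[tuple[str, str]] = set()
    with io.open(edges_path, "r", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            a, b, kind = line.rstrip("\n").split("\t")
            if kind == EDGE_REGULATORY:
                reg.add((a, b))
            else:
                ppi_edges.add(tuple(sorted((a, b))))
    return PINetwork(mirna_id, frozenset(n0), frozenset(n1),
                     frozenset(reg), frozenset(ppi_edges))


def pin_summary_row(pin: PINetwork, nod: int) -> dict[str, object]:
    """Summary-table row (mirna, nod, n0, n1, n2) for one candidate's PIN."""
    return {"mirna": pin.mirna_id, "nod": nod, "n0": pin.n0, "n1": pin.n1, "n2": pin.n2}
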