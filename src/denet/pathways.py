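"""Pathway graph parsing (SIF / minimal XGMML) and merging into one network.

Individual pathway graphs are merged into a single undirected simple graph
equivalent to a triangular adjacency matrix: nodes are gene products, an
edge records a functional interaction, and every edge remembers which
pathways contributed it.  Interaction-type tokens are carried as metadata
but ignored by all computations.

Gene identity is exact string match after case-folding (upper-case by
default), because pathway databases mix symbol capitalizations.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .de_sets import DESetCollection
from .expression import condition_name

__all__ = [
    "Pathway",
    "PathwayCollection",
    "BioNetwork",
    "read_sif",
    "read_xgmml",
    "write_sif",
    "select_pathways",
    "merge_pathways",
    "annotate_de",
    "pathways_per_gene",
    "write_network",
    "read_network",
]

logger = logging.getLogger(__name__)


def _fold(gene: str, case_fold: bool) -> str:
    return gene.upper() if case_fold else gene


@dataclass(frozen=True)
class Pathway:
    """A named pathway: a gene-symbol node set plus undirected edges.

    Edges are unordered pairs with no self-loops; ``edge_types`` maps an
    edge to the interaction tokens seen for it in the source file.
    """

    id: str
    name: str
    nodes: frozenset[str]
    edges: frozenset[frozenset[str]]
    edge_types: Mapping[frozenset[str], frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"pathway {self.id}: self-loop or malformed edge {set(e)}")
            if not e <= self.nodes:
                raise ValueError(f"pathway {self.id}: edge {set(e)} has endpoint outside node set")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g


def read_sif(
    path: str | Path,
    pathway_id: str | None = None,
    name: str | None = None,
    case_fold: bool = True,
) -> Pathway:
    """Parse a SIF interaction file into a Pathway.

    Lines are ``nodeA<TAB>type<TAB>nodeB [nodeC ...]``; a space-delimited
    dialect is accepted when no tab is present.  One-token lines declare
    isolated nodes.  Self-loops are dropped with a warning; duplicate and
    reversed edges are collapsed.
    """
    path = Path(path)
    pathway_id = pathway_id or path.stem
    nodes: set[str] = set()
    edges: set[frozenset[str]] = set()
    types: dict[frozenset[str], set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            tokens = [t.strip() for t in tokens if t.strip()]
            if len(tokens) == 1:
                nodes.add(_fold(tokens[0], case_fold))
                continue
            if len(tokens) == 2:
                raise ValueError(f"{path}:{lineno}: malformed SIF line (2 fields): {line!r}")
            src, itype, targets = tokens[0], tokens[1], tokens[2:]
            src = _fold(src, case_fold)
            nodes.add(src)
            for tgt in targets:
                tgt = _fold(tgt, case_fold)
                nodes.add(tgt)
                if tgt == src:
                    logger.warning("%s:%d: dropping self-loop on %s", path, lineno, src)
                    continue
                e = frozenset((src, tgt))
                edges.add(e)
                types.setdefault(e, set()).add(itype)
    return Pathway(
        pathway_id, name or pathway_id, frozenset(nodes), frozenset(edges),
        {e: frozenset(t) for e, t in types.items()},
    )


def write_sif(pathway_or_edges, path: str | Path, default_type: str = "pp") -> None:
    """Write edges (and isolated nodes) in SIF format, deterministically sorted."""
    if isinstance(pathway_or_edges, Pathway):
        edges = pathway_or_edges.edges
        nodes = pathway_or_edges.nodes
        types = pathway_or_edges.edge_types
    else:
        edges = {frozenset(e) for e in pathway_or_edges}
        nodes = {n for e in edges for n in e}
        types = {}
    covered = {n for e in edges for n in e}
    with open(path, "w", encoding="utf-8") as fh:
        for e in sorted(edges, key=lambda e: tuple(sorted(e))):
            a, b = sorted(e)
            itype = sorted(types.get(e, {default_type}))[0]
            fh.write(f"{a}\t{itype}\t{b}\n")
        for n in sorted(nodes - covered):
            fh.write(f"{n}\n")


def read_xgmml(
    path: str | Path,
    pathway_id: str | None = None,
    name: str | None = None,
    case_fold: bool = True,
) -> Pathway:
    """Parse a minimal XGMML subset: node labels/ids and edge endpoints.

    Anything beyond ``<node>`` labels and ``<edge>`` source/target is
    ignored.  The contract matches :func:`read_sif`: undirected,
    deduplicated, no self-loops.
    """
    path = Path(path)
    pathway_id = pathway_id or path.stem
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"unparseable XGMML document {path}: {exc}") from exc
    root = tree.getroot()
    graph_name = name or root.get("label") or pathway_id

    id_to_label: dict[str, str] = {}
    nodes: set[str] = set()
    edges: set[frozenset[str]] = set()
    types: dict[frozenset[str], set[str]] = {}
    for el in root.iter():
        tag = el.tag.rsplit("}", 1)[-1]
        if tag == "node":
            label = el.get("label") or el.get("id")
            if label is None:
                raise ValueError(f"{path}: node element without label or id")
            label = _fold(label, case_fold)
            if el.get("id") is not None:
                id_to_label[el.get("id")] = label
            nodes.add(label)
    for el in root.iter():
        tag = el.tag.rsplit("}", 1)[-1]
        if tag == "edge":
            src, tgt = el.get("source"), el.get("target")
            if src is None or tgt is None:
                raise ValueError(f"{path}: edge element missing source/target")
            a = id_to_label.get(src, _fold(src, case_fold))
            b = id_to_label.get(tgt, _fold(tgt, case_fold))
            nodes.update((a, b))
            if a == b:
                logger.warning("%s: dropping self-loop on %s", path, a)
                continue
            e = frozenset((a, b))
            edges.add(e)
            if el.get("label"):
                types.setdefault(e, set()).add(el.get("label"))
    return Pathway(
        pathway_id, graph_name, frozenset(nodes), frozenset(edges),
        {e: frozenset(t) for e, t in types.items()},
    )


@dataclass(frozen=True)
class PathwayCollection:
    """An ordered list of pathways with unique ids."""

    pathways: tuple[Pathway, ...]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pathways]
        if len(ids) != len(set(ids)):
            dupes = sorted({x for x in ids if ids.count(x) > 1})
            raise ValueError(f"duplicate pathway id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, i):
        return self.pathways[i]

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, case_fold: bool = True) -> "PathwayCollection":
        """Load pathways listed in a TSV manifest (pathway_id, name, file).

        File paths are resolved relative to the manifest; ``.xgmml`` files
        go through the XGMML parser, everything else through SIF.
        """
        manifest_path = Path(manifest_path)
        df = pd.read_csv(manifest_path, sep="\t")
        pws = []
        for _, row in df.iterrows():
            fpath = manifest_path.parent / str(row["file"])
            reader = read_xgmml if fpath.suffix.lower() == ".xgmml" else read_sif
            pws.append(reader(fpath, pathway_id=str(row["pathway_id"]),
                              name=str(row.get("name", row["pathway_id"])), case_fold=case_fold))
        return cls(tuple(pws))

    def write(self, directory: str | Path) -> Path:
        """Write one SIF per pathway plus a manifest TSV; returns the manifest path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for p in self.pathways:
            fname = f"{p.id}.sif"
            write_sif(p, directory / fname)
            rows.append((p.id, p.name, fname))
        manifest = directory / "manifest.tsv"
        pd.DataFrame(rows, columns=["pathway_id", "name", "file"]).to_csv(
            manifest, sep="\t", index=False
        )
        return manifest


@dataclass
class BioNetwork:
    """The merged biological network: an undirected simple graph.

    Node names are (case-folded) gene symbols.  Edge attribute
    ``pathways`` records provenance (which pathway files contributed the
    edge); node attribute ``de`` holds per-condition fold-change signs once
    :func:`annotate_de` has run.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"network contains self-loop(s): {loops[:5]}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def adjacency(self) -> tuple[pd.DataFrame, list[str]]:
        """Dense symmetric boolean adjacency with a stable node order."""
        order = sorted(self.graph.nodes)
        a = nx.to_numpy_array(self.graph, nodelist=order, dtype=bool)
        return pd.DataFrame(a, index=order, columns=order), order


def select_pathways(
    coll: PathwayCollection, de_genes: Iterable[str], case_fold: bool = True
) -> PathwayCollection:
    """Keep exactly the pathways containing at least one DE gene, in order."""
    de = {_fold(g, case_fold) for g in de_genes}
    return PathwayCollection(tuple(p for p in coll if p.nodes & de))


def merge_pathways(coll: PathwayCollection) -> BioNetwork:
    """Union the pathway graphs into one simple network with edge provenance."""
    if len(coll) == 0:
        raise ValueError("cannot merge an empty pathway collection")
    g = nx.Graph()
    for p in coll:
        g.add_nodes_from(p.nodes)
        for e in p.edges:
            a, b = tuple(e)
            if g.has_edge(a, b):
                g[a][b]["pathways"].add(p.id)
                g[a][b]["types"] |= set(p.edge_types.get(e, ()))
            else:
                g.add_edge(a, b, pathways={p.id}, types=set(p.edge_types.get(e, ())))
    return BioNetwork(g)


def annotate_de(
    net: BioNetwork, coll: DESetCollection, case_fold: bool = True
) -> tuple[BioNetwork, dict[str, set[str]]]:
    """Attach per-condition DE flags to network nodes.

    DE genes absent from the network are returned in the unmapped report
    (condition label -> gene set); they are never added as isolated nodes,
    so degree statistics reflect pathway content only.
    """
    unmapped: dict[str, set[str]] = {}
    for node in net.graph.nodes:
        net.graph.nodes[node].setdefault("de", {})
    for cond in coll.conditions:
        label = condition_name(*cond)
        for gene, sgn in coll.sets[cond].items():
            g = _fold(gene, case_fold)
            if g in net.graph:
                net.graph.nodes[g]["de"][label] = sgn
            else:
                unmapped.setdefault(label, set()).add(gene)
    return net, unmapped


def de_nodes(net: BioNetwork, condition: str | None = None) -> set[str]:
    """Nodes flagged DE (in a given condition, or in any if None)."""
    out = set()
    for n, data in net.graph.nodes(data=True):
        flags = data.get("de", {})
        if (condition is None and flags) or (condition is not None and condition in flags):
            out.add(n)
    return out


def pathways_per_gene(
    coll: PathwayCollection, genes: Iterable[str], case_fold: bool = True
) -> tuple[pd.Series, int]:
    """Per-gene pathway-membership counts and the pathways hit by the set.

    Returns (Series gene -> number of pathways containing it, number of
    pathways containing at least one queried gene).
    """
    genes = list(genes)
    folded = {g: _fold(g, case_fold) for g in genes}
    counts = {g: 0 for g in genes}
    hit: set[str] = set()
    for p in coll:
        for g in genes:
            if folded[g] in p.nodes:
                counts[g] += 1
                hit.add(p.id)
    return pd.Series(counts, name="n_pathways"), len(hit)


def write_network(
    net: BioNetwork,
    edge_path: str | Path,
    node_path: str | Path,
    provenance_path: str | Path | None = None,
) -> None:
    """Write the network as SIF edges + a node-attribute TSV.

    The node table always has a degree column; per-condition DE sign
    columns are added when annotations are present.  An optional
    edge-provenance TSV maps each edge to its contributing pathway ids.
    """
    edges = {frozenset(e) for e in net.graph.edges}
    write_sif(Pathway("network", "network", frozenset(net.graph.nodes), frozenset(edges)), edge_path)

    conds = sorted({c for _, d in net.graph.nodes(data=True) for c in d.get("de", {})})
    rows = []
    for n in sorted(net.graph.nodes):
        row = {"node": n, "degree": net.graph.degree[n]}
        flags = net.graph.nodes[n].get("de", {})
        for c in conds:
            row[c] = flags.get(c, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(node_path, sep="\t", index=False)

    if provenance_path is not None:
        prows = []
        for a, b, data in sorted(net.graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
            a, b = sorted((a, b))
            prows.append({"node_a": a, "node_b": b,
                          "pathways": ",".join(sorted(data.get("pathways", ())))})
        pd.DataFrame(prows).to_csv(provenance_path, sep="\t", index=False)


def read_network(edge_path: str | Path, node_path: str | Path) -> BioNetwork:
    """Read back a network written by :func:`write_network`."""
    pw = read_sif(edge_path, pathway_id="network")
    g = pw.to_networkx()
    attrs = pd.read_csv(node_path, sep="\t")
    cond_cols = [c for c in attrs.columns if c not in ("node", "degree")]
    for _, row in attrs.iterrows():
        node = str(row["node"])
        if node not in g:
            g.add_node(node)
        flags = {c: int(row[c]) for c in cond_cols if int(row[c]) != 0}
        g.nodes[node]["de"] = flags
    for a, b in g.edges:
        g[a][b].setdefault("pathways", {"network"})
    return BioNetwork(g)
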