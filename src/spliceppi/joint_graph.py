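"""The joint PPI-DDI graph.

Nodes are (gene, Pfam domain) units identified as ``"<entrez>/<pfam>"``.
An edge exists only when both conditions hold: the two Pfam families are a
known DDI *and* the two parent genes are PPI partners.  One node is created
per (gene, family) even if the family occurs multiple times on one protein:
DDI evidence is family-level, so duplicated domain copies collapse (a known
limitation for duplicated-domain cases).

PPIs without any supporting DDI contribute no joint edges but are retained
in a side index (``ppi_pairs``) — network-level analysis needs them for
edges labelled plain "PPI".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx

from .annotation import AnnotationStore, Isoform
from .interaction_sources import DDIRecord, PPIRecord, canonical_pair

logger = logging.getLogger(__name__)


def node_id(entrez: str, pfam: str) -> str:
    return f"{entrez}/{pfam}"


def split_node_id(nid: str) -> tuple[str, str]:
    entrez, _, pfam = nid.partition("/")
    return entrez, pfam


class JointGraph:
    """Wrapper around an undirected :class:`networkx.Graph` of domain units."""

    def __init__(self, graph: nx.Graph | None = None,
                 ppi_pairs: set[tuple[str, str]] | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        #: all PPI gene pairs, including those with no joint edge
        self.ppi_pairs: set[tuple[str, str]] = set(ppi_pairs or ())
        self._pair_index: dict[tuple[str, str], list[tuple[str, str]]] = {}
        self._reindex()

    def _reindex(self) -> None:
        self._pair_index.clear()
        for u, v in self.graph.edges():
            pair = canonical_pair(split_node_id(u)[0], split_node_id(v)[0])
            self._pair_index.setdefault(pair, []).append((u, v) if u <= v else (v, u))
        for edges in self._pair_index.values():
            edges.sort()

    # -- queries ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def joint_edges_between(self, gene_a: str, gene_b: str) -> list[tuple[str, str]]:
        """All joint edges whose parent genes are the given pair."""
        return list(self._pair_index.get(canonical_pair(gene_a, gene_b), []))

    def joint_partners(self, entrez: str) -> list[str]:
        """Genes connected to ``entrez`` by at least one joint edge."""
        partners = set()
        for a, b in self._pair_index:
            if a == entrez:
                partners.add(b)
            elif b == entrez:
                partners.add(a)
        return sorted(partners)

    def ppi_partners(self, entrez: str) -> list[str]:
        partners = set()
        for a, b in self.ppi_pairs:
            if a == entrez:
                partners.add(b)
            elif b == entrez:
                partners.add(a)
        return sorted(partners)


@dataclass(frozen=True)
class ViewEdge:
    """One joint edge as seen from a query gene/isoform."""

    node_query: str
    node_partner: str
    query_pfam: str
    partner_pfam: str
    missing: bool  # query-side family absent from the queried isoform


@dataclass
class ProteinView:
    """A gene's joint neighbourhood, optionally isoform-resolved.

    When built for an isoform, edges whose query-side domain family is not
    annotated on that isoform are flagged ``missing`` — the red-triangle /
    dashed-edge pattern of an interaction lost to splicing.
    """

    gene: str
    isoform_id: str | None
    partners: dict[str, list[ViewEdge]]

    @property
    def flagged_partners(self) -> list[str]:
        return sorted(p for p, edges in self.partners.items() if any(e.missing for e in edges))


def build_joint_graph(
    ppi: Mapping[tuple[str, str], PPIRecord],
    ddi: Mapping[tuple[str, str], DDIRecord],
    store: AnnotationStore,
) -> JointGraph:
    """Construct the joint graph from PPIs, merged DDIs and annotation.

    Nodes are restricted to families actually annotated on some isoform of
    genes that appear in the PPI network; each edge requires both a PPI
    between the parent genes and a DDI between the families.
    """
    g = nx.Graph()
    if not ppi or not ddi:
        logger.warning("empty %s input: joint graph has no edges",
                       "PPI" if not ppi else "DDI")
    ppi_genes = sorted({x for pair in ppi for x in pair})
    complements = {gene: sorted(store.gene_domain_complement(gene)) for gene in ppi_genes}
    for gene in ppi_genes:
        for pfam in complements[gene]:
            g.add_node(node_id(gene, pfam), gene=gene, pfam=pfam)

    n_ppi_supported = 0
    n_ppi_multi = 0
    for ga, gb in sorted(ppi):
        n_pair_edges = 0
        for pa in complements.get(ga, ()):  # noqa: B007 — double loop is the definition
            for pb in complements.get(gb, ()):
                key = canonical_pair(pa, pb)
                if key in ddi:
                    rec = ddi[key]
                    u, v = node_id(ga, pa), node_id(gb, pb)
                    if not g.has_edge(u, v):
                        g.add_edge(u, v, sources=",".join(sorted(rec.sources)),
                                   confidence=rec.confidence)
                        n_pair_edges += 1
        if n_pair_edges >= 1:
            n_ppi_supported += 1
        if n_pair_edges >= 2:
            n_ppi_multi += 1

    jg = JointGraph(g, set(ppi))
    logger.info(
        "joint graph: %d nodes, %d edges; %d/%d PPIs with >=1 DDI, %d with >=2",
        jg.n_nodes, jg.n_edges, n_ppi_supported, len(ppi), n_ppi_multi,
    )
    return jg


def protein_view(
    jg: JointGraph,
    store: AnnotationStore,
    gene: str | None = None,
    isoform: Isoform | str | None = None,
) -> ProteinView:
    """Per-partner joint edges of a gene, flagged against an isoform if given."""
    iso_obj: Isoform | None = None
    if isoform is not None:
        iso_obj = store.isoform(isoform) if isinstance(isoform, str) else isoform
        gene = iso_obj.gene.entrez_id
    if gene is None:
        raise ValueError("provide a gene or an isoform")
    present = store.pfam_set(iso_obj) if iso_obj is not None else None

    partners: dict[str, list[ViewEdge]] = {}
    for partner in jg.joint_partners(gene):
        edges = []
        for u, v in jg.joint_edges_between(gene, partner):
            gu, pu = split_node_id(u)
            gv, pv = split_node_id(v)
            if gu == gene:
                q_node, p_node, q_pfam, p_pfam = u, v, pu, pv
            else:
                q_node, p_node, q_pfam, p_pfam = v, u, pv, pu
            if gene == partner and present is not None:
                # self-interaction: both sides live on the queried isoform
                missing = not {pu, pv} <= present
            else:
                missing = present is not None and q_pfam not in present
            edges.append(ViewEdge(q_node, p_node, q_pfam, p_pfam, missing))
        partners[partner] = edges
    return ProteinView(
        gene=gene,
        isoform_id=iso_obj.transcript_id if iso_obj is not None else None,
        partners=partners,
    )


def domain_view(jg: JointGraph, pfam_id: str) -> nx.Graph:
    """Domain-centric subgraph: every node carrying ``pfam_id`` plus partners.

    This is the family's interactome independent of any particular protein;
    an empty graph when the family is annotated on no gene in the network.
    """
    centers = [n for n, data in jg.graph.nodes(data=True) if data["pfam"] == pfam_id]
    keep = set(centers)
    for c in centers:
        keep.update(jg.graph.neighbors(c))
    return jg.graph.subgraph(keep).copy()


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_graph(jg: JointGraph, path, fmt: str = "graphml") -> Path:
    """Write the joint graph; GraphML preserves attributes losslessly."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(jg.graph, path, named_key_ids=True)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tsources\tconfidence\n")
            for u, v, data in sorted(jg.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data.get('sources', '')}\t{data.get('confidence', 'NA')}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def import_graph(path, fmt: str = "graphml") -> JointGraph:
    path = Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        return JointGraph(nx.Graph(g))
    if fmt == "tsv":
        g = nx.Graph()
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                u, v, sources, confidence = line.rstrip("\n").split("\t")
                for n in (u, v):
                    gene, pfam = split_node_id(n)
                    g.add_node(n, gene=gene, pfam=pfam)
                g.add_edge(u, v, sources=sources, confidence=confidence)
        return JointGraph(g)
    raise ValueError(f"unknown import format {fmt!r}")
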