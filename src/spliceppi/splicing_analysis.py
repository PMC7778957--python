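"""Isoform-, exon- and network-level analysis of splicing effects on PPIs.

Isoform level: each PPI of the parent gene is scored by the fraction of its
mediating joint (DDI-supported) edges whose query-side domain family is
still annotated on the isoform — a score of 1 means all structural evidence
retained, 0 means all lost.  Scoring is deliberately fractional rather than
all-or-nothing: when several domain pairs mediate one PPI, losing a single
domain may already disrupt the interaction, so partial losses are reported
as partial scores.

Exon level: domains overlapping an exon (by >= 1 coding base) are treated
as lost with the exon, and each partner is reported with the fraction of
joint edges that loss removes, plus a flag for structure-derived interface
residues encoded by the exon.

Network level: a transcript list (optionally expression-filtered, strictly
above the threshold) is expanded to genes; edges between listed genes are
labelled "PPI-DDI" when joint edges exist (weighted by the retained
fraction over the listed isoforms) and "PPI" otherwise.  A domain counts as
missing only when absent from every listed isoform of its gene while being
annotated on some unlisted isoform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .annotation import AnnotationStore, Isoform, domain_to_exons
from .errors import AmbiguousExonError, NoStructuralAnnotation
from .joint_graph import JointGraph, split_node_id
from .structure_interface import PositionSpecificPPI

logger = logging.getLogger(__name__)

EXPRESSION_THRESHOLD = 1.0  # transcripts strictly above are "abundant"


# ---------------------------------------------------------------------------
# Isoform-level scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionScore:
    """Fraction of mediating DDIs retained by an isoform for one PPI."""

    query: str          # transcript id
    partner: str        # partner gene (Entrez)
    n_ddi_total: int
    n_ddi_retained: int

    def __post_init__(self):
        if self.n_ddi_total < 1:
            raise ValueError("scored edges require >= 1 joint edge")
        if not 0 <= self.n_ddi_retained <= self.n_ddi_total:
            raise ValueError("retained count out of range")

    @property
    def score(self) -> float:
        return self.n_ddi_retained / self.n_ddi_total

    @property
    def n_ddi_missing(self) -> int:
        return self.n_ddi_total - self.n_ddi_retained


def _edge_retained(u: str, v: str, gene: str, partner: str, present: set[str]) -> bool:
    """Is a joint edge retained by an isoform of ``gene`` with families ``present``?

    For a self-interaction (gene == partner) both sides live on the query
    isoform, so both families must be present; otherwise only the
    query-side family is judged (the partner is evaluated at gene level).
    """
    gu, pu = split_node_id(u)
    gv, pv = split_node_id(v)
    if gene == partner:
        return pu in present and pv in present
    query_pfam = pu if gu == gene else pv
    return query_pfam in present


def score_interaction(
    isoform: Isoform | str,
    partner_gene: str,
    graph: JointGraph,
    store: AnnotationStore,
) -> InteractionScore:
    """Score one (isoform, partner) PPI edge by retained joint edges.

    Raises :class:`NoStructuralAnnotation` when the gene pair has no joint
    edges — an unscorable interaction, which is *not* the same as a score
    of 0 (all structural evidence lost).
    """
    iso = store.isoform(isoform) if isinstance(isoform, str) else isoform
    gene = iso.gene.entrez_id
    edges = graph.joint_edges_between(gene, partner_gene)
    if not edges:
        raise NoStructuralAnnotation(gene, partner_gene)
    present = store.pfam_set(iso)
    retained = sum(_edge_retained(u, v, gene, partner_gene, present) for u, v in edges)
    return InteractionScore(iso.transcript_id, partner_gene, len(edges), retained)


@dataclass
class IsoformReport:
    """Full isoform-level view: scores, missing domains, exon layout."""

    transcript_id: str
    gene: str
    scores: dict[str, InteractionScore]      # partner gene -> score
    ppi_only_partners: list[str]             # PPI partners without DDI support
    missing_domains: list[str]               # families lost vs the gene complement
    exon_domains: dict[str, list[str]]       # exon id -> overlapping families


def isoform_report(
    isoform: Isoform | str,
    graph: JointGraph,
    store: AnnotationStore,
) -> IsoformReport:
    """Score every PPI partner of the isoform's gene and list domain losses."""
    iso = store.isoform(isoform) if isinstance(isoform, str) else isoform
    gene = iso.gene.entrez_id
    joint_partners = set(graph.joint_partners(gene))
    scores = {p: score_interaction(iso, p, graph, store) for p in sorted(joint_partners)}
    ppi_only = [p for p in graph.ppi_partners(gene) if p not in joint_partners]
    missing = sorted(store.gene_domain_complement(gene) - store.pfam_set(iso))
    layout: dict[str, list[str]] = {}
    for exon in iso.exons:
        fams = {d.pfam_id for d in store.exon_domains(iso, exon.exon_id)}
        layout[exon.exon_id] = sorted(fams)
    return IsoformReport(iso.transcript_id, gene, scores, ppi_only, missing, layout)


# ---------------------------------------------------------------------------
# Exon-level analysis
# ---------------------------------------------------------------------------

@dataclass
class PartnerImpact:
    n_ddi_total: int
    n_ddi_affected: int

    @property
    def fraction_lost(self) -> float:
        return self.n_ddi_affected / self.n_ddi_total


@dataclass
class ExonReport:
    """Effect of losing one exon on the parent gene's interactions."""

    exon_id: str
    gene: str
    domains: list[str]                       # families overlapping the exon
    isoforms: list[str]                      # transcripts containing the exon
    affected: dict[str, PartnerImpact]       # partner -> impact
    interface_evidence: dict[str, bool]      # partner -> residue-level support

    @property
    def affected_partners(self) -> list[str]:
        return sorted(p for p, imp in self.affected.items() if imp.n_ddi_affected > 0)


def exon_report(
    store: AnnotationStore,
    graph: JointGraph,
    exon_id: str | None = None,
    gene: str | None = None,
    coords: tuple[int, int] | None = None,
    position_network: PositionSpecificPPI | None = None,
) -> ExonReport:
    """Report domains and interactions affected by the loss of one exon.

    The exon is given either by id or by gene + genomic coordinates (which
    must overlap exactly one annotated exon of that gene).  Any domain with
    a sequence overlap with the exon counts as lost with it; per partner
    the fraction of joint edges mediated by those domains is reported.  An
    interface-evidence flag is set per partner when the position-specific
    network has at least one contact residue encoded by this exon — this
    can fire even for exons outside every annotated domain.
    """
    if exon_id is not None:
        entrez = store.gene_of_exon(exon_id)
    elif gene is not None and coords is not None:
        exon = store.find_exon_by_coords(gene, *coords)
        exon_id = exon.exon_id
        entrez = store.gene_of_exon(exon_id)
    else:
        raise AmbiguousExonError("provide an exon id or gene + coordinates")

    lost_fams: set[str] = set()
    transcripts = store.transcripts_with_exon(exon_id)
    for tid in transcripts:
        iso = store.isoform(tid)
        for d in store.domains_of(iso):
            if exon_id in domain_to_exons(iso, d):
                lost_fams.add(d.pfam_id)

    affected: dict[str, PartnerImpact] = {}
    for partner in graph.joint_partners(entrez):
        edges = graph.joint_edges_between(entrez, partner)
        n_hit = 0
        for u, v in edges:
            gu, pu = split_node_id(u)
            gv, pv = split_node_id(v)
            if entrez == partner:
                hit = pu in lost_fams or pv in lost_fams
            else:
                query_pfam = pu if gu == entrez else pv
                hit = query_pfam in lost_fams
            n_hit += hit
        affected[partner] = PartnerImpact(len(edges), n_hit)

    evidence: dict[str, bool] = {}
    if position_network is not None:
        for ga, gb in position_network.gene_pairs():
            if entrez not in (ga, gb):
                continue
            partner = gb if ga == entrez else ga
            evidence[partner] = position_network.exon_has_evidence(exon_id, entrez, partner)

    return ExonReport(exon_id, entrez, sorted(lost_fams), transcripts, affected, evidence)


# ---------------------------------------------------------------------------
# Network-level analysis
# ---------------------------------------------------------------------------

@dataclass
class Subnetwork:
    """Condition-specific interaction subnetwork for a transcript list.

    ``graph`` nodes are genes (Entrez keys) with their retained transcripts
    as an attribute; edges carry ``label`` ("PPI" or "PPI-DDI") and, for
    PPI-DDI edges, ``weight`` = retained fraction in [0, 1].
    """

    graph: nx.Graph
    unresolved: list[str]
    excluded_transcripts: list[str]
    missing_domains: dict[str, list[str]]    # gene -> families lost by the list


def resolve_inputs(ids, store: AnnotationStore) -> tuple[list[str], list[str]]:
    """Expand mixed gene/transcript/protein ids to transcript ids.

    Gene ids (Entrez or Ensembl) expand to all isoforms of the gene.
    Unresolvable ids are returned separately (lenient mode: the run
    continues and reports them).
    """
    transcripts: set[str] = set()
    unresolved: list[str] = []
    for raw in ids:
        raw = str(raw).strip()
        if not raw:
            continue
        if raw in store.isoforms:
            transcripts.add(raw)
            continue
        try:
            transcripts.add(store.isoform_by_protein(raw).transcript_id)
            continue
        except KeyError:
            pass
        try:
            entrez = store.idmap.to_entrez(raw)
            isoforms = store.isoforms_of_gene(entrez)
            if isoforms:
                transcripts.update(i.transcript_id for i in isoforms)
                continue
        except KeyError:
            pass
        unresolved.append(raw)
    return sorted(transcripts), unresolved


def extract_subnetwork(
    inputs,
    store: AnnotationStore,
    graph: JointGraph,
    expression: "pd.DataFrame | str | Path | None" = None,
    threshold: float = EXPRESSION_THRESHOLD,
) -> Subnetwork:
    """Build the weighted, labelled subnetwork for an id list.

    When an expression table (transcript_id, expression) is given, only
    transcripts with expression strictly above ``threshold`` are retained;
    a transcript absent from the table counts as not expressed.
    """
    transcripts, unresolved = resolve_inputs(inputs, store)
    if unresolved:
        logger.warning("%d input ids could not be resolved: %s",
                       len(unresolved), ", ".join(unresolved))

    excluded: list[str] = []
    if expression is not None:
        if not isinstance(expression, pd.DataFrame):
            expression = pd.read_csv(expression, sep="\t")
        expr = dict(zip(expression["transcript_id"].astype(str),
                        expression["expression"].astype(float)))
        kept = [t for t in transcripts if expr.get(t, 0.0) > threshold]
        excluded = [t for t in transcripts if t not in set(kept)]
        transcripts = kept

    listed_pfams: dict[str, set[str]] = {}
    listed_transcripts: dict[str, list[str]] = {}
    for tid in transcripts:
        iso = store.isoform(tid)
        gene = iso.gene.entrez_id
        listed_pfams.setdefault(gene, set()).update(store.pfam_set(iso))
        listed_transcripts.setdefault(gene, []).append(tid)

    missing_domains = {
        gene: sorted(store.gene_domain_complement(gene) - fams)
        for gene, fams in listed_pfams.items()
    }

    g = nx.Graph()
    for gene in sorted(listed_transcripts):
        g.add_node(gene,
                   transcripts=",".join(sorted(listed_transcripts[gene])),
                   missing_domains=",".join(missing_domains[gene]))
    genes = set(listed_transcripts)
    for ga, gb in sorted(graph.ppi_pairs):
        if ga not in genes or gb not in genes:
            continue
        edges = graph.joint_edges_between(ga, gb)
        if not edges:
            g.add_edge(ga, gb, label="PPI")
            continue
        retained = 0
        for u, v in edges:
            gu, pu = split_node_id(u)
            gv, pv = split_node_id(v)
            if ga == gb:
                ok = pu in listed_pfams[ga] and pv in listed_pfams[ga]
            else:
                pf_a = pu if gu == ga else pv
                pf_b = pv if gv == gb else pu
                ok = pf_a in listed_pfams[ga] and pf_b in listed_pfams[gb]
            retained += ok
        g.add_edge(ga, gb, label="PPI-DDI", weight=retained / len(edges),
                   n_ddi_total=len(edges), n_ddi_retained=retained)
    return Subnetwork(g, unresolved, sorted(excluded), missing_domains)


def filter_subnetwork(sub: Subnetwork, min_weight: float) -> Subnetwork:
    """Drop PPI-DDI edges with weight below ``min_weight``.

    Plain "PPI" edges are never removed (they carry no structural weight).
    ``min_weight`` = 0 is the identity; any strictly positive value removes
    exactly the fully-lost (weight 0) edges and, as it grows, partial
    losses too — at the smallest positive value this reproduces the
    all-or-nothing rule of keeping a PPI only while at least one DDI
    remains.
    """
    g = sub.graph.copy()
    drop = [
        (u, v)
        for u, v, data in g.edges(data=True)
        if data.get("label") == "PPI-DDI" and data.get("weight", 1.0) < min_weight
    ]
    g.remove_edges_from(drop)
    return Subnetwork(g, list(sub.unresolved), list(sub.excluded_transcripts),
                      dict(sub.missing_domains))


# ---------------------------------------------------------------------------
# Report writers (stable ordering -> byte-identical reruns)
# ---------------------------------------------------------------------------

def write_isoform_report(report: IsoformReport, path) -> Path:
    rows = []
    for partner in sorted(report.scores):
        s = report.scores[partner]
        rows.append({"partner": partner, "n_ddi_total": s.n_ddi_total,
                     "n_ddi_retained": s.n_ddi_retained, "score": f"{s.score:.4f}"})
    for partner in report.ppi_only_partners:
        rows.append({"partner": partner, "n_ddi_total": 0,
                     "n_ddi_retained": 0, "score": "NA"})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_exon_report(report: ExonReport, path) -> Path:
    rows = []
    for partner in sorted(report.affected):
        imp = report.affected[partner]
        rows.append({
            "partner": partner,
            "n_ddi_total": imp.n_ddi_total,
            "n_ddi_affected": imp.n_ddi_affected,
            "fraction_lost": f"{imp.fraction_lost:.4f}",
            "interface_evidence": str(report.interface_evidence.get(partner, False)),
        })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_subnetwork(sub: Subnetwork, path, fmt: str = "graphml") -> Path:
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(sub.graph, path, named_key_ids=True)
    elif fmt == "tsv":
        rows = []
        for u, v, data in sorted(sub.graph.edges(data=True)):
            rows.append({
                "gene_a": u, "gene_b": v, "label": data["label"],
                "weight": f"{data['weight']:.4f}" if "weight" in data else "NA",
            })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
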