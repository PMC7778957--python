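"""Gene/transcript/exon annotation model and coordinate conversions.

The model mirrors a Biomart-style export: genes carry an Entrez id (the
internal gene key), transcripts carry an ordered exon chain with per-exon
genomic coding intervals, and Pfam domains are annotated per protein isoform
in amino-acid coordinates.

Coordinate conventions
----------------------
All genomic coordinates are 1-based inclusive (Ensembl/Biomart convention).
CDS coordinates are 1-based along the spliced coding sequence in
transcription order; on the '-' strand the CDS coordinate increases as the
genomic coordinate decreases.  Protein coordinates are 1-based amino-acid
positions.  The stop codon is part of the CDS (so every valid isoform has
CDS length ``3 * protein_length + 3``) but is excluded from protein
coordinate arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import (
    AmbiguousExonError,
    CoordinateError,
    IdMappingError,
    LoadError,
)

logger = logging.getLogger(__name__)

STOP_CODON_LENGTH = 3


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    """A gene keyed by its Entrez id; Ensembl id kept for input resolution."""

    entrez_id: str
    ensembl_id: str
    symbol: str = ""

    def __post_init__(self):
        if not self.entrez_id or not self.ensembl_id:
            raise ValueError("entrez_id and ensembl_id must be non-empty")


@dataclass(frozen=True)
class Exon:
    """A genomic exon; ``start <= end`` regardless of strand."""

    exon_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"exon {self.exon_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"exon {self.exon_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass(frozen=True)
class DomainAnnotation:
    """A Pfam domain interval on a protein isoform (1-based, inclusive)."""

    protein_id: str
    pfam_id: str
    aa_start: int
    aa_end: int

    def __post_init__(self):
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValueError(
                f"domain {self.pfam_id} on {self.protein_id}: bad interval "
                f"[{self.aa_start}, {self.aa_end}]"
            )


@dataclass(frozen=True)
class Isoform:
    """One transcript/protein variant with its exon chain and CDS geometry.

    ``exons`` are in transcription order (rank order); ``cds_segments`` are
    genomic ``(start, end)`` intervals, also in transcription order, jointly
    covering the coding sequence including the stop codon.
    """

    transcript_id: str
    protein_id: str
    gene: Gene
    exons: tuple[Exon, ...]
    cds_segments: tuple[tuple[int, int], ...]
    protein_length: int

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def total_cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def coding_length(self) -> int:
        """CDS length without the stop codon (= 3 x protein_length)."""
        return 3 * self.protein_length

    def exon_by_id(self, exon_id: str) -> Exon:
        for exon in self.exons:
            if exon.exon_id == exon_id:
                return exon
        raise KeyError(exon_id)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        problems = []
        expected = 3 * self.protein_length + STOP_CODON_LENGTH
        if self.total_cds_length != expected:
            problems.append(
                f"{self.transcript_id}: CDS length {self.total_cds_length} != "
                f"3*{self.protein_length}+{STOP_CODON_LENGTH}"
            )
        if self.total_cds_length % 3 != 0:
            problems.append(f"{self.transcript_id}: CDS length not a multiple of 3")
        # every CDS segment must lie inside one exon, in matching order
        for s, e in self.cds_segments:
            if not any(x.start <= s and e <= x.end for x in self.exons):
                problems.append(
                    f"{self.transcript_id}: CDS segment [{s},{e}] outside exons"
                )
        # transcription order: '+' strand ascending, '-' descending
        keys = [s for s, _ in self.cds_segments]
        ordered = keys == sorted(keys) if self.strand == "+" else keys == sorted(keys, reverse=True)
        if not ordered:
            problems.append(f"{self.transcript_id}: CDS segments not in transcription order")
        starts = [x.start for x in self.exons]
        ex_ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ex_ordered:
            problems.append(f"{self.transcript_id}: exons not in transcription order")
        return problems


# ---------------------------------------------------------------------------
# Coordinate conversions
# ---------------------------------------------------------------------------

def aa_to_cds(aa_pos: int) -> tuple[int, int]:
    """Return the 1-based inclusive CDS interval of a residue's codon."""
    if aa_pos < 1:
        raise CoordinateError(f"amino-acid position must be >= 1, got {aa_pos}")
    return (aa_pos - 1) * 3 + 1, aa_pos * 3


def cds_to_genomic(isoform: Isoform, cds_pos: int) -> int:
    """Map a 1-based CDS position to its unique genomic base."""
    if not 1 <= cds_pos <= isoform.total_cds_length:
        raise CoordinateError(
            f"CDS position {cds_pos} out of range 1..{isoform.total_cds_length} "
            f"for transcript {isoform.transcript_id}"
        )
    offset = cds_pos - 1
    for s, e in isoform.cds_segments:
        seg_len = e - s + 1
        if offset < seg_len:
            return s + offset if isoform.strand == "+" else e - offset
        offset -= seg_len
    raise AssertionError("unreachable: CDS walk exhausted")


def genomic_to_cds(isoform: Isoform, genomic_pos: int) -> int:
    """Inverse of :func:`cds_to_genomic` for coding bases."""
    offset = 0
    for s, e in isoform.cds_segments:
        if s <= genomic_pos <= e:
            within = genomic_pos - s if isoform.strand == "+" else e - genomic_pos
            return offset + within + 1
        offset += e - s + 1
    raise CoordinateError(
        f"genomic position {genomic_pos} is not coding in transcript "
        f"{isoform.transcript_id}"
    )


def _cds_interval_to_genomic(isoform: Isoform, c1: int, c2: int) -> list[tuple[int, int]]:
    """Genomic footprint (list of intervals, start<=end) of CDS range [c1, c2]."""
    intervals: list[tuple[int, int]] = []
    offset = 0
    for s, e in isoform.cds_segments:
        seg_len = e - s + 1
        lo = max(c1, offset + 1)
        hi = min(c2, offset + seg_len)
        if lo <= hi:
            if isoform.strand == "+":
                intervals.append((s + (lo - 1 - offset), s + (hi - 1 - offset)))
            else:
                intervals.append((e - (hi - 1 - offset), e - (lo - 1 - offset)))
        offset += seg_len
    return intervals


def aa_range_to_genomic(isoform: Isoform, aa_start: int, aa_end: int) -> list[tuple[int, int]]:
    """Genomic footprint of the codons for residues ``aa_start..aa_end``."""
    if not (1 <= aa_start <= aa_end <= isoform.protein_length):
        raise CoordinateError(
            f"residue range [{aa_start},{aa_end}] outside protein of length "
            f"{isoform.protein_length} ({isoform.protein_id})"
        )
    c1, _ = aa_to_cds(aa_start)
    _, c2 = aa_to_cds(aa_end)
    return _cds_interval_to_genomic(isoform, c1, c2)


def domain_to_exons(isoform: Isoform, domain: DomainAnnotation) -> set[str]:
    """Exons whose genomic span overlaps the domain's codon footprint.

    Overlap is by >= 1 base, so a domain whose codons straddle an exon
    junction reports both exons.  Never empty for a valid domain.
    """
    if domain.protein_id != isoform.protein_id:
        raise CoordinateError(
            f"domain on {domain.protein_id} queried against isoform "
            f"{isoform.protein_id}"
        )
    footprint = aa_range_to_genomic(isoform, domain.aa_start, domain.aa_end)
    hits = {
        exon.exon_id
        for exon in isoform.exons
        for (s, e) in footprint
        if exon.overlaps(s, e)
    }
    assert hits, "valid domain must map to at least one exon"
    return hits


def residue_to_exons(isoform: Isoform, aa_pos: int) -> set[str]:
    """Exons overlapping the codon of one residue (two if codon spans a junction).

    A residue whose codon straddles an exon junction is attributed to all
    overlapping exons: losing either exon destroys the codon.
    """
    footprint = aa_range_to_genomic(isoform, aa_pos, aa_pos)
    return {
        exon.exon_id
        for exon in isoform.exons
        for (s, e) in footprint
        if exon.overlaps(s, e)
    }


# ---------------------------------------------------------------------------
# Id mapping
# ---------------------------------------------------------------------------

class IdMap:
    """Entrez <-> Ensembl gene <-> UniProt mapping table.

    Lookups raise :class:`IdMappingError` when an id is unknown; interaction
    loaders rely on this to fail loudly rather than silently dropping genes.
    """

    def __init__(self, rows: Iterable[tuple[str, str, str]]):
        self._by_entrez: dict[str, tuple[str, str, str]] = {}
        self._by_ensembl: dict[str, str] = {}
        self._by_uniprot: dict[str, str] = {}
        for entrez, ensembl, uniprot in rows:
            self._by_entrez[entrez] = (entrez, ensembl, uniprot)
            self._by_ensembl[ensembl] = entrez
            if uniprot:
                self._by_uniprot[uniprot] = entrez

    def __contains__(self, identifier: str) -> bool:
        try:
            self.to_entrez(identifier)
            return True
        except IdMappingError:
            return False

    def to_entrez(self, identifier: str) -> str:
        """Resolve any of the three id spaces to the Entrez key."""
        if identifier in self._by_entrez:
            return identifier
        if identifier in self._by_ensembl:
            return self._by_ensembl[identifier]
        if identifier in self._by_uniprot:
            return self._by_uniprot[identifier]
        raise IdMappingError(identifier)

    def ensembl_of(self, entrez: str) -> str:
        try:
            return self._by_entrez[entrez][1]
        except KeyError:
            raise IdMappingError(entrez, "ensembl") from None

    def uniprot_of(self, entrez: str) -> str:
        try:
            return self._by_entrez[entrez][2]
        except KeyError:
            raise IdMappingError(entrez, "uniprot") from None

    def rows(self) -> list[tuple[str, str, str]]:
        return sorted(self._by_entrez.values())


# ---------------------------------------------------------------------------
# Annotation store
# ---------------------------------------------------------------------------

class AnnotationStore:
    """Cross-linked container for genes, isoforms, domains and the id map."""

    def __init__(
        self,
        genes: Iterable[Gene],
        isoforms: Iterable[Isoform],
        domains: Iterable[DomainAnnotation],
        idmap: IdMap,
        sequences: Mapping[str, str] | None = None,
    ):
        self.genes: dict[str, Gene] = {g.entrez_id: g for g in genes}
        self.isoforms: dict[str, Isoform] = {i.transcript_id: i for i in isoforms}
        self.idmap = idmap
        self.sequences: dict[str, str] = dict(sequences or {})

        self._by_protein: dict[str, Isoform] = {}
        self._gene_transcripts: dict[str, list[str]] = {}
        self._exon_transcripts: dict[str, list[str]] = {}
        self._exon_gene: dict[str, str] = {}
        for iso in self.isoforms.values():
            self._by_protein[iso.protein_id] = iso
            self._gene_transcripts.setdefault(iso.gene.entrez_id, []).append(iso.transcript_id)
            for exon in iso.exons:
                self._exon_transcripts.setdefault(exon.exon_id, []).append(iso.transcript_id)
                self._exon_gene[exon.exon_id] = iso.gene.entrez_id

        self.domains: dict[str, list[DomainAnnotation]] = {}
        for d in domains:
            self.domains.setdefault(d.protein_id, []).append(d)
        for lst in self.domains.values():
            lst.sort(key=lambda d: (d.aa_start, d.aa_end, d.pfam_id))

        self._validate()

    # -- lookups ----------------------------------------------------------

    def isoform(self, transcript_id: str) -> Isoform:
        return self.isoforms[transcript_id]

    def isoform_by_protein(self, protein_id: str) -> Isoform:
        return self._by_protein[protein_id]

    def isoforms_of_gene(self, entrez_id: str) -> list[Isoform]:
        return [self.isoforms[t] for t in sorted(self._gene_transcripts.get(entrez_id, []))]

    def domains_of(self, isoform: Isoform | str) -> list[DomainAnnotation]:
        protein_id = isoform if isinstance(isoform, str) else isoform.protein_id
        return self.domains.get(protein_id, [])

    def pfam_set(self, isoform: Isoform | str) -> set[str]:
        """Pfam families annotated on an isoform (presence is family-level)."""
        return {d.pfam_id for d in self.domains_of(isoform)}

    def gene_domain_complement(self, entrez_id: str) -> set[str]:
        """Union of Pfam families over all isoforms of a gene (reference set)."""
        out: set[str] = set()
        for iso in self.isoforms_of_gene(entrez_id):
            out |= self.pfam_set(iso)
        return out

    def exon_domains(self, isoform: Isoform, exon_id: str) -> list[DomainAnnotation]:
        """Transpose of :func:`domain_to_exons` for one isoform."""
        return [d for d in self.domains_of(isoform) if exon_id in domain_to_exons(isoform, d)]

    def transcripts_with_exon(self, exon_id: str) -> list[str]:
        return sorted(self._exon_transcripts.get(exon_id, []))

    def gene_of_exon(self, exon_id: str) -> str:
        try:
            return self._exon_gene[exon_id]
        except KeyError:
            raise AmbiguousExonError(f"unknown exon id {exon_id!r}") from None

    def find_exon(self, exon_id: str) -> Exon:
        for t in self._exon_transcripts.get(exon_id, []):
            return self.isoforms[t].exon_by_id(exon_id)
        raise AmbiguousExonError(f"unknown exon id {exon_id!r}")

    def find_exon_by_coords(self, gene_key: str, start: int, end: int) -> Exon:
        """Resolve gene + coordinates to exactly one annotated exon.

        Raises :class:`AmbiguousExonError` listing candidates when the
        interval overlaps zero or more than one distinct exon of the gene.
        """
        entrez = self.idmap.to_entrez(gene_key)
        hits: dict[str, Exon] = {}
        for iso in self.isoforms_of_gene(entrez):
            for exon in iso.exons:
                if exon.overlaps(start, end):
                    hits[exon.exon_id] = exon
        if len(hits) == 1:
            return next(iter(hits.values()))
        if not hits:
            raise AmbiguousExonError(
                f"no annotated exon of gene {gene_key} overlaps {start}-{end}"
            )
        raise AmbiguousExonError(
            f"coordinates {start}-{end} overlap several exons of gene {gene_key}",
            candidates=sorted(hits),
        )

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        problems: list[str] = []
        for iso in self.isoforms.values():
            if iso.gene.entrez_id not in self.genes:
                problems.append(
                    f"{iso.transcript_id}: dangling gene reference {iso.gene.entrez_id}"
                )
            problems.extend(iso.validate())
        for protein_id, domain_list in self.domains.items():
            iso = self._by_protein.get(protein_id)
            if iso is None:
                problems.append(f"domain table references unknown protein {protein_id}")
                continue
            for d in domain_list:
                if d.aa_end > iso.protein_length:
                    problems.append(
                        f"{protein_id}: domain {d.pfam_id} [{d.aa_start},{d.aa_end}] "
                        f"exceeds protein length {iso.protein_length}"
                    )
        for protein_id, seq in self.sequences.items():
            iso = self._by_protein.get(protein_id)
            if iso is not None and len(seq) != iso.protein_length:
                problems.append(
                    f"{protein_id}: sequence length {len(seq)} != annotated "
                    f"protein length {iso.protein_length}"
                )
        if problems:
            raise LoadError("annotation failed validation", problems)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

#: Default column names of the Biomart-style TSV set; override per table via
#: the ``columns`` argument of :func:`load_annotation`.
DEFAULT_COLUMNS: dict[str, dict[str, str]] = {
    "genes": {"entrez_id": "entrez_id", "ensembl_gene_id": "ensembl_gene_id", "symbol": "symbol"},
    "transcripts": {
        "ensembl_gene_id": "ensembl_gene_id",
        "transcript_id": "transcript_id",
        "protein_id": "protein_id",
        "protein_length": "protein_length",
    },
    "exons": {
        "transcript_id": "transcript_id",
        "exon_id": "exon_id",
        "chrom": "chrom",
        "strand": "strand",
        "exon_start": "exon_start",
        "exon_end": "exon_end",
        "rank": "rank",
        "coding_start": "coding_start",
        "coding_end": "coding_end",
    },
    "domains": {
        "protein_id": "protein_id",
        "pfam_id": "pfam_id",
        "aa_start": "aa_start",
        "aa_end": "aa_end",
    },
    "idmap": {
        "entrez_id": "entrez_id",
        "ensembl_gene_id": "ensembl_gene_id",
        "uniprot_id": "uniprot_id",
    },
}

TableLike = "str | Path | pd.DataFrame"


def _read_table(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table.copy()
    return pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)


def load_annotation(
    genes,
    transcripts,
    exons,
    domains,
    idmap,
    sequences: Mapping[str, str] | None = None,
    columns: Mapping[str, Mapping[str, str]] | None = None,
) -> AnnotationStore:
    """Build a validated :class:`AnnotationStore` from Biomart-style tables.

    Each argument is a TSV path or a pre-parsed DataFrame.  ``columns`` maps
    logical field names to the actual column headers per table (merged over
    :data:`DEFAULT_COLUMNS`), so differently exported tables load without
    rewriting.  All invariant checks run here; violations are collected into
    one :class:`LoadError`.
    """
    cols = {t: dict(DEFAULT_COLUMNS[t]) for t in DEFAULT_COLUMNS}
    for table, mapping in (columns or {}).items():
        cols[table].update(mapping)

    problems: list[str] = []

    g = _read_table(genes)
    gc = cols["genes"]
    gene_objs = [
        Gene(row[gc["entrez_id"]], row[gc["ensembl_gene_id"]], row.get(gc["symbol"], ""))
        for row in g.to_dict("records")
    ]
    by_ensembl = {x.ensembl_id: x for x in gene_objs}

    im = _read_table(idmap)
    ic = cols["idmap"]
    idmap_obj = IdMap(
        (row[ic["entrez_id"]], row[ic["ensembl_gene_id"]], row.get(ic["uniprot_id"], ""))
        for row in im.to_dict("records")
    )

    e = _read_table(exons)
    ec = cols["exons"]
    exon_rows: dict[str, list[dict]] = {}
    for row in e.to_dict("records"):
        exon_rows.setdefault(row[ec["transcript_id"]], []).append(row)

    t = _read_table(transcripts)
    tc = cols["transcripts"]
    isoforms: list[Isoform] = []
    for row in t.to_dict("records"):
        tid = row[tc["transcript_id"]]
        gene = by_ensembl.get(row[tc["ensembl_gene_id"]])
        if gene is None:
            problems.append(f"{tid}: unknown gene {row[tc['ensembl_gene_id']]}")
            continue
        rows = exon_rows.get(tid)
        if not rows:
            problems.append(f"{tid}: no exon rows")
            continue
        rows.sort(key=lambda r: int(r[ec["rank"]]))
        ranks = [int(r[ec["rank"]]) for r in rows]
        if any(b <= a for a, b in zip(ranks, ranks[1:])):
            problems.append(f"{tid}: exon ranks not strictly increasing")
            continue
        exon_objs = tuple(
            Exon(
                r[ec["exon_id"]],
                r[ec["chrom"]],
                int(r[ec["exon_start"]]),
                int(r[ec["exon_end"]]),
                r[ec["strand"]],
            )
            for r in rows
        )
        cds = tuple(
            (int(r[ec["coding_start"]]), int(r[ec["coding_end"]]))
            for r in rows
            if r.get(ec["coding_start"], "") not in ("", "NA")
        )
        isoforms.append(
            Isoform(
                transcript_id=tid,
                protein_id=row[tc["protein_id"]],
                gene=gene,
                exons=exon_objs,
                cds_segments=cds,
                protein_length=int(row[tc["protein_length"]]),
            )
        )

    d = _read_table(domains)
    dc = cols["domains"]
    domain_objs = [
        DomainAnnotation(
            row[dc["protein_id"]],
            row[dc["pfam_id"]],
            int(row[dc["aa_start"]]),
            int(row[dc["aa_end"]]),
        )
        for row in d.to_dict("records")
    ]

    if problems:
        raise LoadError("annotation failed validation", problems)
    store = AnnotationStore(gene_objs, isoforms, domain_objs, idmap_obj, sequences)
    logger.info(
        "loaded annotation: %d genes, %d isoforms, %d domain rows",
        len(store.genes), len(store.isoforms), sum(len(v) for v in store.domains.values()),
    )
    return store


def read_protein_fasta(path) -> dict[str, str]:
    """Read isoform protein sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def load_annotation_gtf(gtf_path, genes, domains, idmap, sequences=None,
                        columns=None) -> AnnotationStore:
    """Load transcripts/exons from a GTF instead of the Biomart exon table.

    Requires attributes ``gene_id``, ``transcript_id``, ``exon_id`` and
    ``exon_number`` on exon features and ``protein_id`` on CDS features.
    Genes, domains and the id map still come from TSV tables (a GTF carries
    neither Entrez ids nor Pfam intervals).
    """
    exon_rows = []
    cds_by_tid: dict[str, list[tuple[int, int]]] = {}
    protein_by_tid: dict[str, str] = {}
    gene_by_tid: dict[str, str] = {}
    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, feature, start, end, strand, attrs = f[0], f[2], int(f[3]), int(f[4]), f[6], _parse_gtf_attributes(f[8])
            tid = attrs.get("transcript_id", "")
            if feature == "exon":
                exon_rows.append(
                    {
                        "transcript_id": tid,
                        "exon_id": attrs["exon_id"],
                        "chrom": chrom,
                        "strand": strand,
                        "exon_start": str(start),
                        "exon_end": str(end),
                        "rank": attrs["exon_number"],
                        "coding_start": "",
                        "coding_end": "",
                    }
                )
                gene_by_tid[tid] = attrs["gene_id"]
            elif feature == "CDS":
                cds_by_tid.setdefault(tid, []).append((start, end))
                protein_by_tid[tid] = attrs["protein_id"]
                gene_by_tid[tid] = attrs["gene_id"]

    # fold CDS intervals into the per-exon coding columns
    exon_df = pd.DataFrame(exon_rows)
    for tid, segs in cds_by_tid.items():
        mask = exon_df["transcript_id"] == tid
        for idx in exon_df.index[mask]:
            es, ee = int(exon_df.at[idx, "exon_start"]), int(exon_df.at[idx, "exon_end"])
            for s, e in segs:
                if es <= s and e <= ee:
                    exon_df.at[idx, "coding_start"] = str(s)
                    exon_df.at[idx, "coding_end"] = str(e)

    transcript_rows = []
    gene_df = _read_table(genes)
    gc = DEFAULT_COLUMNS["genes"].copy()
    if columns and "genes" in columns:
        gc.update(columns["genes"])
    ensembl_ids = set(gene_df[gc["ensembl_gene_id"]])
    for tid, segs in sorted(cds_by_tid.items()):
        total = sum(e - s + 1 for s, e in segs)
        gene_id = gene_by_tid[tid]
        if gene_id not in ensembl_ids:
            raise LoadError("GTF references unknown gene", [f"{tid}: {gene_id}"])
        transcript_rows.append(
            {
                "ensembl_gene_id": gene_id,
                "transcript_id": tid,
                "protein_id": protein_by_tid[tid],
                "protein_length": str(total // 3 - 1),
            }
        )
    return load_annotation(
        genes=genes,
        transcripts=pd.DataFrame(transcript_rows),
        exons=exon_df,
        domains=domains,
        idmap=idmap,
        sequences=sequences,
        columns=columns,
    )


def write_annotation(store: AnnotationStore, outdir) -> dict[str, Path]:
    """Dump the store as the normalized TSV set (deterministic ordering)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    genes = pd.DataFrame(
        [
            {"entrez_id": g.entrez_id, "ensembl_gene_id": g.ensembl_id, "symbol": g.symbol}
            for g in sorted(store.genes.values(), key=lambda g: g.entrez_id)
        ]
    )
    transcripts, exons, domains = [], [], []
    for tid in sorted(store.isoforms):
        iso = store.isoforms[tid]
        transcripts.append(
            {
                "ensembl_gene_id": iso.gene.ensembl_id,
                "transcript_id": tid,
                "protein_id": iso.protein_id,
                "protein_length": iso.protein_length,
            }
        )
        for rank, exon in enumerate(iso.exons, start=1):
            seg = next(
                ((s, e) for s, e in iso.cds_segments if exon.start <= s and e <= exon.end),
                None,
            )
            exons.append(
                {
                    "transcript_id": tid,
                    "exon_id": exon.exon_id,
                    "chrom": exon.chrom,
                    "strand": exon.strand,
                    "exon_start": exon.start,
                    "exon_end": exon.end,
                    "rank": rank,
                    "coding_start": seg[0] if seg else "",
                    "coding_end": seg[1] if seg else "",
                }
            )
        for d in store.domains_of(iso):
            domains.append(
                {
                    "protein_id": d.protein_id,
                    "pfam_id": d.pfam_id,
                    "aa_start": d.aa_start,
                    "aa_end": d.aa_end,
                }
            )
    idmap = pd.DataFrame(
        [
            {"entrez_id": a, "ensembl_gene_id": b, "uniprot_id": c}
            for a, b, c in store.idmap.rows()
        ]
    )
    for name, df in (
        ("genes", genes),
        ("transcripts", pd.DataFrame(transcripts)),
        ("exons", pd.DataFrame(exons)),
        ("domains", pd.DataFrame(domains)),
        ("idmap", idmap),
    ):
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths
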