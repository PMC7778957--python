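"""Self-consistent toy datasets for every other module.

The generator produces annotation tables, PPI/DDI tables, protein FASTA,
toy PDB structures, chain assignments and an expression table that satisfy
all load-time invariants — so the whole pipeline is testable without any
download.  Alongside the data it writes a *manifest* of expected results
(joint edges, interaction scores, residue contacts, interface exons)
computed here by plain independent loops that share no code with the main
modules; the manifest is the regression baseline the pipeline must match.

Geometry of toy structures is idealised: one CA atom per residue, chain A
laid out along the x axis at 10 A spacing, chain B far away except for
residues deliberately placed within the engineered contact distance.  This
is sufficient for heavy-atom distance logic; there is no pretence of a
realistic fold, and sequences are random strings over the 20-letter
alphabet.

All randomness flows from the single fixture seed.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
INTRON = 100          # bases between adjacent exons
EXON_SPACING = 10.0   # A between consecutive CA atoms in toy chains
FAR_Y = 1000.0        # baseline y for non-contacting chain-B residues
CONTACT_DIST = 4.0    # default engineered CA-CA distance (< 5 A)


# ---------------------------------------------------------------------------
# Internal records
# ---------------------------------------------------------------------------

@dataclass
class _GeneRec:
    symbol: str
    entrez: str
    ensembl: str
    uniprot: str
    chrom: str
    strand: str
    locus_start: int
    exon_ids: list[str] = field(default_factory=list)
    exon_lengths: list[int] = field(default_factory=list)
    exon_coords: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class _IsoRec:
    transcript_id: str
    protein_id: str
    gene: _GeneRec
    keep: list[int]                       # 1-based master exon indices kept
    protein_length: int
    domains: list[tuple[str, int, int]]   # (pfam, aa_start, aa_end)
    sequence: str

    @property
    def kept_lengths(self) -> list[int]:
        return [self.gene.exon_lengths[i - 1] for i in self.keep]

    @property
    def kept_exon_ids(self) -> list[str]:
        return [self.gene.exon_ids[i - 1] for i in self.keep]


@dataclass
class _StructRec:
    structure_id: str
    chains: list[tuple[str, str, tuple[int, int]]]   # (chain_id, transcript, aa range)
    coords: dict[str, list[tuple[int, float, float, float]]]  # chain -> (chain_idx, x, y, z)
    letters: dict[str, str]


def _residue_exons(iso: _IsoRec, aa: int) -> list[str]:
    """Independent residue->exon walk over kept exon lengths (no genome math)."""
    codon = range(3 * aa - 2, 3 * aa + 1)
    out = []
    offset = 0
    for exon_id, length in zip(iso.kept_exon_ids, iso.kept_lengths):
        lo, hi = offset + 1, offset + length
        if any(lo <= b <= hi for b in codon):
            out.append(exon_id)
        offset += length
    return out


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------

class FixtureBuilder:
    """Assemble a consistent toy dataset gene by gene.

    Exons are laid on a per-gene locus with 100-base introns and are fully
    coding; the last three coding bases of every isoform are its stop
    codon, so an isoform keeping exons with total length ``3*(L+1)``
    encodes ``L`` residues.
    """

    def __init__(self, seed: int = 0):
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.genes: dict[str, _GeneRec] = {}
        self.isoforms: dict[str, _IsoRec] = {}
        self.ppi: list[tuple[str, str]] = []            # entrez pairs as given
        self.ddi_3did: list[tuple[str, str]] = []
        self.ddi_domine: list[tuple[str, str, str]] = []
        self.structures: dict[str, _StructRec] = {}
        self.expression: dict[str, float] = {}
        self._exon_counter = 0

    # -- genes / isoforms -------------------------------------------------

    def add_gene(self, symbol: str, exon_lengths: list[int], strand: str = "+",
                 chrom: str = "1") -> _GeneRec:
        idx = len(self.genes) + 1
        gene = _GeneRec(
            symbol=symbol,
            entrez=str(100 + idx),
            ensembl=f"ENSG{10000000 + idx:011d}",
            uniprot=f"Q{90000 + idx}",
            chrom=chrom,
            strand=strand,
            locus_start=100000 * idx,
        )
        cursor = gene.locus_start
        if strand == "-":
            cursor += sum(exon_lengths) + INTRON * len(exon_lengths) + 1000
        for length in exon_lengths:
            self._exon_counter += 1
            gene.exon_ids.append(f"ENSE{self._exon_counter:011d}")
            gene.exon_lengths.append(length)
            if strand == "+":
                gene.exon_coords.append((cursor, cursor + length - 1))
                cursor += length + INTRON
            else:
                gene.exon_coords.append((cursor - length + 1, cursor))
                cursor -= length + INTRON
        self.genes[symbol] = gene
        return gene

    def add_isoform(self, symbol: str, name: str, keep: list[int],
                    domains: Iterable[tuple[str, int, int]] = ()) -> _IsoRec:
        gene = self.genes[symbol]
        total = sum(gene.exon_lengths[i - 1] for i in keep)
        if total % 3 != 0 or total < 6:
            raise ValueError(f"{name}: kept exon length {total} is not 3*(L+1)")
        length = total // 3 - 1
        domains = sorted(domains, key=lambda d: (d[1], d[2], d[0]))
        for pfam, a, b in domains:
            if not 1 <= a <= b <= length:
                raise ValueError(f"{name}: domain {pfam} [{a},{b}] outside 1..{length}")
        seq = "".join(self.rng.choice(list(AA_ALPHABET), size=length))
        iso = _IsoRec(name, f"{name}.p", gene, list(keep), length, list(domains), seq)
        self.isoforms[name] = iso
        return iso

    # -- interactions -----------------------------------------------------

    def add_ppi(self, symbol_a: str, symbol_b: str) -> None:
        self.ppi.append((self.genes[symbol_a].entrez, self.genes[symbol_b].entrez))

    def add_ddi(self, pfam_a: str, pfam_b: str, source: str = "threedid",
                confidence: str = "HC") -> None:
        if source == "threedid":
            self.ddi_3did.append((pfam_a, pfam_b))
        elif source == "domine":
            self.ddi_domine.append((pfam_a, pfam_b, confidence))
        else:
            raise ValueError(f"unknown DDI source {source!r}")

    def set_expression(self, transcript_id: str, value: float) -> None:
        self.expression[transcript_id] = value

    # -- structures -------------------------------------------------------

    def add_structure(
        self,
        structure_id: str,
        chain_a: tuple[str, str],
        chain_b: tuple[str, str],
        contacts: list[tuple[int, int]],
        distance: float = CONTACT_DIST,
        chain_a_range: tuple[int, int] | None = None,
        chain_b_range: tuple[int, int] | None = None,
    ) -> _StructRec:
        """Two-chain toy structure with engineered CA-CA contacts.

        ``contacts`` pairs isoform residue positions (aa_a, aa_b); each
        chain-B residue may be engineered against at most one chain-A
        residue so contact distances are exactly as requested.  Residue
        ``i`` of chain A sits at (10*i, 0, 0); non-contacting chain-B
        residues sit on a remote baseline.
        """
        (cid_a, tid_a), (cid_b, tid_b) = chain_a, chain_b
        iso_a, iso_b = self.isoforms[tid_a], self.isoforms[tid_b]
        range_a = chain_a_range or (1, iso_a.protein_length)
        range_b = chain_b_range or (1, iso_b.protein_length)
        b_targets = [b for _, b in contacts]
        if len(b_targets) != len(set(b_targets)):
            raise ValueError("each chain-B residue may appear in one contact only")
        engineered = {b: a for a, b in contacts}
        for a, b in contacts:
            if not range_a[0] <= a <= range_a[1] or not range_b[0] <= b <= range_b[1]:
                raise ValueError(f"contact ({a},{b}) outside resolved chain ranges")

        coords: dict[str, list] = {cid_a: [], cid_b: []}
        letters: dict[str, str] = {}
        seq_a = iso_a.sequence[range_a[0] - 1:range_a[1]]
        seq_b = iso_b.sequence[range_b[0] - 1:range_b[1]]
        letters[cid_a], letters[cid_b] = seq_a, seq_b
        for idx, aa in enumerate(range(range_a[0], range_a[1] + 1), start=1):
            coords[cid_a].append((idx, EXON_SPACING * aa, 0.0, 0.0))
        for idx, aa in enumerate(range(range_b[0], range_b[1] + 1), start=1):
            if aa in engineered:
                coords[cid_b].append((idx, EXON_SPACING * engineered[aa], distance, 0.0))
            else:
                coords[cid_b].append((idx, EXON_SPACING * aa, FAR_Y, 0.0))
        rec = _StructRec(
            structure_id,
            [(cid_a, tid_a, range_a), (cid_b, tid_b, range_b)],
            coords,
            letters,
        )
        self.structures[structure_id] = rec
        return rec

    # -- assembly ---------------------------------------------------------

    def build(self) -> "Fixture":
        tables = self._tables()
        manifest = self._manifest()
        sequences = {iso.protein_id: iso.sequence for iso in self.isoforms.values()}
        return Fixture(tables, sequences,
                       {sid: _pdb_text(rec) for sid, rec in sorted(self.structures.items())},
                       manifest)

    def _tables(self) -> dict[str, pd.DataFrame]:
        genes = pd.DataFrame(
            [{"entrez_id": g.entrez, "ensembl_gene_id": g.ensembl, "symbol": g.symbol}
             for g in self.genes.values()]
        )
        idmap = pd.DataFrame(
            [{"entrez_id": g.entrez, "ensembl_gene_id": g.ensembl, "uniprot_id": g.uniprot}
             for g in self.genes.values()]
        )
        transcripts, exons, domains, expression = [], [], [], []
        for tid in sorted(self.isoforms):
            iso = self.isoforms[tid]
            transcripts.append({
                "ensembl_gene_id": iso.gene.ensembl,
                "transcript_id": tid,
                "protein_id": iso.protein_id,
                "protein_length": iso.protein_length,
            })
            for rank, master_idx in enumerate(iso.keep, start=1):
                s, e = iso.gene.exon_coords[master_idx - 1]
                exons.append({
                    "transcript_id": tid,
                    "exon_id": iso.gene.exon_ids[master_idx - 1],
                    "chrom": iso.gene.chrom,
                    "strand": iso.gene.strand,
                    "exon_start": s,
                    "exon_end": e,
                    "rank": rank,
                    "coding_start": s,
                    "coding_end": e,
                })
            for pfam, a, b in iso.domains:
                domains.append({"protein_id": iso.protein_id, "pfam_id": pfam,
                                "aa_start": a, "aa_end": b})
            expression.append({"transcript_id": tid,
                               "expression": self.expression.get(tid, 2.0)})
        ppi = pd.DataFrame([{"gene_a": a, "gene_b": b} for a, b in self.ppi])
        ddi3 = pd.DataFrame([{"pfam_a": a, "pfam_b": b} for a, b in self.ddi_3did])
        ddid = pd.DataFrame([{"pfam_a": a, "pfam_b": b, "confidence": c}
                             for a, b, c in self.ddi_domine])
        assignments = []
        for sid in sorted(self.structures):
            for cid, tid, _ in self.structures[sid].chains:
                assignments.append({"structure_id": sid, "chain_id": cid,
                                    "protein_id": self.isoforms[tid].protein_id})
        return {
            "genes": genes,
            "transcripts": pd.DataFrame(transcripts),
            "exons": pd.DataFrame(exons),
            "domains": pd.DataFrame(domains),
            "idmap": idmap,
            "ppi": ppi,
            "ddi_3did": ddi3 if not ddi3.empty else pd.DataFrame(columns=["pfam_a", "pfam_b"]),
            "ddi_domine": ddid if not ddid.empty else pd.DataFrame(columns=["pfam_a", "pfam_b", "confidence"]),
            "expression": pd.DataFrame(expression),
            "chain_assignments": pd.DataFrame(assignments) if assignments else pd.DataFrame(columns=["structure_id", "chain_id", "protein_id"]),
        }

    # -- independent ground truth (plain loops, no main-module imports) ---

    def _manifest(self) -> dict:
        ppi_pairs = {tuple(sorted(p)) for p in self.ppi}
        ddi_kept = {tuple(sorted(p)) for p in self.ddi_3did}
        for a, b, conf in self.ddi_domine:
            if conf in ("HC", "MC"):
                ddi_kept.add(tuple(sorted((a, b))))

        gene_fams: dict[str, set[str]] = {}
        iso_fams: dict[str, set[str]] = {}
        for iso in self.isoforms.values():
            fams = {pfam for pfam, _, _ in iso.domains}
            iso_fams[iso.transcript_id] = fams
            gene_fams.setdefault(iso.gene.entrez, set()).update(fams)

        joint_edges: list[tuple[str, str, str, str]] = []
        for ga, gb in sorted(ppi_pairs):
            for pa in sorted(gene_fams.get(ga, ())):
                for pb in sorted(gene_fams.get(gb, ())):
                    if tuple(sorted((pa, pb))) in ddi_kept:
                        n1, n2 = f"{ga}/{pa}", f"{gb}/{pb}"
                        edge = (ga, pa, gb, pb) if n1 <= n2 else (gb, pb, ga, pa)
                        if edge not in joint_edges:
                            joint_edges.append(edge)
        joint_edges.sort()

        pair_edges: dict[tuple[str, str], list] = {}
        for ga, pa, gb, pb in joint_edges:
            pair_edges.setdefault(tuple(sorted((ga, gb))), []).append((ga, pa, gb, pb))

        scores: dict[str, dict[str, float]] = {}
        for iso in self.isoforms.values():
            gene = iso.gene.entrez
            present = iso_fams[iso.transcript_id]
            for (x, y), edges in sorted(pair_edges.items()):
                if gene not in (x, y):
                    continue
                partner = y if x == gene else x
                retained = 0
                for ga, pa, gb, pb in edges:
                    if gene == partner:
                        retained += pa in present and pb in present
                    else:
                        qf = pa if ga == gene else pb
                        retained += qf in present
                scores.setdefault(iso.transcript_id, {})[partner] = retained / len(edges)

        contacts: dict[str, dict] = {}
        lifted: dict[str, list] = {}
        interface_exons: dict[str, dict[str, list[str]]] = {}
        for sid in sorted(self.structures):
            rec = self.structures[sid]
            (cid_a, tid_a, range_a), (cid_b, tid_b, range_b) = rec.chains
            pairs = []
            for ia, xa, ya, za in rec.coords[cid_a]:
                for ib, xb, yb, zb in rec.coords[cid_b]:
                    d = math.dist((xa, ya, za), (xb, yb, zb))
                    if d < 5.0:
                        pairs.append([ia, ib, round(d, 6)])
            contacts[sid] = {"chains": [cid_a, cid_b], "pairs": sorted(pairs)}
            iso_a, iso_b = self.isoforms[tid_a], self.isoforms[tid_b]
            pair_key = "|".join(sorted((iso_a.gene.entrez, iso_b.gene.entrez)))
            for ia, ib, d in pairs:
                aa_a = ia + range_a[0] - 1
                aa_b = ib + range_b[0] - 1
                lifted.setdefault(pair_key, []).append(
                    [iso_a.protein_id, aa_a, iso_b.protein_id, aa_b, d])
                ev = interface_exons.setdefault(pair_key, {})
                ev.setdefault(iso_a.gene.entrez, [])
                ev.setdefault(iso_b.gene.entrez, [])
                for exon in _residue_exons(iso_a, aa_a):
                    if exon not in ev[iso_a.gene.entrez]:
                        ev[iso_a.gene.entrez].append(exon)
                for exon in _residue_exons(iso_b, aa_b):
                    if exon not in ev[iso_b.gene.entrez]:
                        ev[iso_b.gene.entrez].append(exon)
        for key in lifted:
            lifted[key].sort()
        for ev in interface_exons.values():
            for gene in ev:
                ev[gene].sort()

        return {
            "seed": self.seed,
            "n_genes": len(self.genes),
            "n_isoforms": len(self.isoforms),
            "n_ppi": len(ppi_pairs),
            "n_ddi_kept": len(ddi_kept),
            "joint_edges": [f"{ga}/{pa}|{gb}/{pb}" for ga, pa, gb, pb in joint_edges],
            "scores": scores,
            "contacts": contacts,
            "lifted_contacts": lifted,
            "interface_exons": interface_exons,
        }


# ---------------------------------------------------------------------------
# PDB writing (via Bio.PDB so files are format-clean)
# ---------------------------------------------------------------------------

def _pdb_text(rec: _StructRec) -> str:
    from Bio.Data.IUPACData import protein_letters_1to3
    from Bio.PDB import PDBIO
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure(rec.structure_id)
    sb.init_model(0)
    serial = 0
    for cid, _, _ in rec.chains:
        sb.init_chain(cid)
        sb.init_seg("    ")
        for (idx, x, y, z), letter in zip(rec.coords[cid], rec.letters[cid]):
            resname = protein_letters_1to3[letter].upper()
            sb.init_residue(resname, " ", idx, " ")
            serial += 1
            sb.init_atom("CA", np.array([x, y, z], dtype=float), 0.0, 1.0,
                         " ", " CA ", serial, element="C")
    out = io.StringIO()
    pdbio = PDBIO()
    pdbio.set_structure(sb.get_structure())
    pdbio.save(out)
    return out.getvalue()


# ---------------------------------------------------------------------------
# Fixture container
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """In-memory toy dataset plus its expected-result manifest."""

    tables: dict[str, pd.DataFrame]
    sequences: dict[str, str]
    pdb_texts: dict[str, str]
    manifest: dict

    def write(self, outdir) -> Path:
        """Write the dataset, manifest and a ready-to-use config.yaml."""
        import yaml

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        with open(outdir / "proteins.fasta", "w") as fh:
            for pid in sorted(self.sequences):
                fh.write(f">{pid}\n{self.sequences[pid]}\n")
        (outdir / "structures").mkdir(exist_ok=True)
        for sid in sorted(self.pdb_texts):
            (outdir / "structures" / f"{sid}.pdb").write_text(self.pdb_texts[sid])
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
        config = {
            "annotation": {
                "genes": "genes.tsv",
                "transcripts": "transcripts.tsv",
                "exons": "exons.tsv",
                "domains": "domains.tsv",
                "idmap": "idmap.tsv",
                "fasta": "proteins.fasta",
            },
            "sources": {
                "ppi": {"path": "ppi.tsv"},
                "ddi": [
                    {"path": "ddi_3did.tsv", "dialect": "threedid"},
                    {"path": "ddi_domine.tsv", "dialect": "domine"},
                ],
            },
            "structures": {
                "dir": "structures",
                "chain_assignments": "chain_assignments.tsv",
            },
            "expression": "expression.tsv",
        }
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)
        return outdir

    # convenience: run the real pipeline on this fixture (NOT ground truth)
    def build_pipeline(self, with_structures: bool = True):
        from . import annotation, interaction_sources, joint_graph, structure_interface

        store = annotation.load_annotation(
            genes=self.tables["genes"],
            transcripts=self.tables["transcripts"],
            exons=self.tables["exons"],
            domains=self.tables["domains"],
            idmap=self.tables["idmap"],
            sequences=self.sequences,
        )
        ppi = interaction_sources.read_ppi(self.tables["ppi"])
        ddi = interaction_sources.merge_ddi(
            interaction_sources.read_ddi_3did(self.tables["ddi_3did"]),
            interaction_sources.read_ddi_domine(self.tables["ddi_domine"]),
        )
        graph = joint_graph.build_joint_graph(ppi, ddi, store)
        posnet = None
        if with_structures and self.pdb_texts:
            posnet = structure_interface.build_position_network(
                {sid: io.StringIO(text) for sid, text in self.pdb_texts.items()},
                self.tables["chain_assignments"],
                store,
            )
        return Pipeline(store, ppi, ddi, graph, posnet)


@dataclass
class Pipeline:
    """Loaded objects for one fixture (the real modules' view of it)."""

    store: object
    ppi: dict
    ddi: dict
    graph: object
    posnet: object | None


def generate_fixture(spec: "FixtureSpec", outdir) -> Fixture:
    """Generate a random fixture from a spec and write it to ``outdir``."""
    fixture = random_fixture(spec)
    fixture.write(outdir)
    return fixture


# ---------------------------------------------------------------------------
# Random fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Tunable recipe for random fixtures; defaults give a small but
    non-trivial interactome (several multi-isoform genes, partial domain
    losses, a couple of engineered-contact structures)."""

    seed: int = 0
    n_genes: int = 8
    isoforms_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (3, 6)
    domains_per_gene: tuple[int, int] = (1, 3)
    domain_min_aa: int = 8
    ppi_density: float = 0.4
    self_ppi_prob: float = 0.05
    ddi_support_prob: float = 0.7
    ddi_noise: int = 4
    lc_rows: int = 3
    n_structures: int = 2
    contacts_per_structure: tuple[int, int] = (3, 8)

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least two genes")
        if self.domain_min_aa < 1:
            raise ValueError("domain_min_aa must be positive")
        for lo, hi in (self.isoforms_per_gene, self.exons_per_transcript,
                       self.domains_per_gene, self.contacts_per_structure):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be (lo, hi) with 1 <= lo <= hi")


def _randint(rng, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def random_fixture(spec: FixtureSpec | None = None, **overrides) -> Fixture:
    """Build a random, fully cross-referenced fixture from a seed."""
    if spec is None:
        spec = FixtureSpec(**overrides)
    elif overrides:
        raise TypeError("pass a FixtureSpec or keyword overrides, not both")
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    b = FixtureBuilder(seed=spec.seed)

    pfam_pool = [f"PF{30000 + k:05d}" for k in range(max(4, spec.n_genes))]
    symbols = [f"GENE{i + 1}" for i in range(spec.n_genes)]

    ref_domains: dict[str, list[tuple[str, int, int]]] = {}
    for sym in symbols:
        n_exons = _randint(rng, *spec.exons_per_transcript)
        lengths = [int(rng.integers(30, 121)) for _ in range(n_exons)]
        total = sum(lengths)
        lengths[-1] += (3 - total % 3) % 3
        strand = "+" if rng.random() < 0.5 else "-"
        b.add_gene(sym, lengths, strand=strand)
        length_aa = sum(lengths) // 3 - 1

        domains: list[tuple[str, int, int]] = []
        n_dom = _randint(rng, *spec.domains_per_gene)
        taken: list[tuple[int, int]] = []
        for _ in range(n_dom * 4):
            if len(domains) == n_dom:
                break
            width = _randint(rng, spec.domain_min_aa, max(spec.domain_min_aa, length_aa // 2))
            start = _randint(rng, 1, max(1, length_aa - width))
            end = min(start + width - 1, length_aa)
            if any(s <= end and start <= e for s, e in taken):
                continue
            taken.append((start, end))
            domains.append((str(rng.choice(pfam_pool)), start, end))
        ref_domains[sym] = domains
        b.add_isoform(sym, f"{sym}-201", keep=list(range(1, n_exons + 1)), domains=domains)

        # alternative isoforms: drop internal exons keeping frame (mod 3)
        n_alt = _randint(rng, *spec.isoforms_per_gene) - 1
        seen_keeps = {tuple(range(1, n_exons + 1))}
        made = 0
        for _ in range(20 * n_alt):
            if made == n_alt or n_exons < 3:
                break
            internal = list(range(2, n_exons))
            n_drop = _randint(rng, 1, max(1, len(internal)))
            drop = set(rng.choice(internal, size=min(n_drop, len(internal)), replace=False).tolist())
            keep = [i for i in range(1, n_exons + 1) if i not in drop]
            total_kept = sum(lengths[i - 1] for i in keep)
            if total_kept % 3 != 0 or total_kept < 6 or tuple(keep) in seen_keeps:
                continue
            seen_keeps.add(tuple(keep))
            made += 1
            alt_domains = _remap_domains(domains, lengths, keep)
            b.add_isoform(sym, f"{sym}-2{made + 1:02d}", keep=keep, domains=alt_domains)

    # PPIs
    for i, sa in enumerate(symbols):
        for sb_ in symbols[i + 1:]:
            if rng.random() < spec.ppi_density:
                b.add_ppi(sa, sb_)
        if rng.random() < spec.self_ppi_prob:
            b.add_ppi(sa, sa)

    # DDIs: supported + noise + low-confidence rows (dropped on load)
    for ea, eb in list(b.ppi):
        sym_a = next(s for s, g in b.genes.items() if g.entrez == ea)
        sym_b = next(s for s, g in b.genes.items() if g.entrez == eb)
        if ref_domains[sym_a] and ref_domains[sym_b] and rng.random() < spec.ddi_support_prob:
            pa = ref_domains[sym_a][_randint(rng, 0, len(ref_domains[sym_a]) - 1)][0]
            pb = ref_domains[sym_b][_randint(rng, 0, len(ref_domains[sym_b]) - 1)][0]
            if rng.random() < 0.5:
                b.add_ddi(pa, pb, "threedid")
            else:
                b.add_ddi(pa, pb, "domine", "HC" if rng.random() < 0.5 else "MC")
    for _ in range(spec.ddi_noise):
        pa, pb = rng.choice(pfam_pool, size=2, replace=True)
        b.add_ddi(str(pa), str(pb), "threedid")
    for _ in range(spec.lc_rows):
        pa, pb = rng.choice(pfam_pool, size=2, replace=True)
        b.add_ddi(str(pa), str(pb), "domine", "LC")

    # structures over random PPI pairs
    hetero_ppis = [(a, bb) for a, bb in b.ppi if a != bb]
    for k in range(min(spec.n_structures, len(hetero_ppis))):
        ea, eb = hetero_ppis[_randint(rng, 0, len(hetero_ppis) - 1)]
        sym_a = next(s for s, g in b.genes.items() if g.entrez == ea)
        sym_b = next(s for s, g in b.genes.items() if g.entrez == eb)
        iso_a, iso_b = b.isoforms[f"{sym_a}-201"], b.isoforms[f"{sym_b}-201"]
        n_contacts = _randint(rng, *spec.contacts_per_structure)
        n_contacts = min(n_contacts, iso_b.protein_length)
        bs = sorted(rng.choice(np.arange(1, iso_b.protein_length + 1),
                               size=n_contacts, replace=False).tolist())
        pairs = [(int(_randint(rng, 1, iso_a.protein_length)), int(bb)) for bb in bs]
        b.add_structure(f"STR{k + 1}", ("A", iso_a.transcript_id),
                        ("B", iso_b.transcript_id), pairs,
                        distance=float(rng.uniform(3.0, 4.8)))

    # expression values bracketing the abundance threshold
    for tid in b.isoforms:
        b.set_expression(tid, float(np.round(rng.uniform(0.0, 3.0), 2)))

    return b.build()


def _remap_domains(domains, lengths, keep) -> list[tuple[str, int, int]]:
    """Recompute domain intervals for an isoform keeping a subset of exons.

    A domain survives only when every exon its codons overlap in the
    reference is kept; its new coordinates follow from the shortened CDS.
    Domains overflowing into the new stop codon are clamped; a domain
    pushed entirely past the new protein end is dropped.
    """
    total_kept = sum(lengths[i - 1] for i in keep)
    new_len = total_kept // 3 - 1
    # reference CDS offset of each exon, and kept-CDS offset of each kept exon
    ref_offsets = np.concatenate([[0], np.cumsum(lengths)])
    kept_set = set(keep)
    out = []
    for pfam, a, e in domains:
        c1, c2 = 3 * a - 2, 3 * e
        covering = [
            i + 1
            for i in range(len(lengths))
            if ref_offsets[i] + 1 <= c2 and c1 <= ref_offsets[i + 1]
        ]
        if not set(covering) <= kept_set:
            continue
        removed_before = sum(lengths[i - 1] for i in range(1, covering[0]) if i not in kept_set)
        nc1, nc2 = c1 - removed_before, c2 - removed_before
        na, ne = (nc1 + 2) // 3, min((nc2 + 2) // 3, new_len)
        if na <= ne and na >= 1:
            out.append((pfam, na, ne))
    return out


# ---------------------------------------------------------------------------
# Named scenarios mirroring the classic splicing case studies
# ---------------------------------------------------------------------------

def scenario_two_domain_partial_loss(seed: int = 0) -> Fixture:
    """Adaptor gene whose PPI is mediated by two DDIs; one isoform loses one.

    The truncated isoform retains 1 of 2 mediating domain pairs, so its
    interaction scores 0.5 while the full-length isoform scores 1.0.
    """
    b = FixtureBuilder(seed)
    b.add_gene("NCK2", [90, 150, 150, 93])
    b.add_isoform("NCK2", "NCK2-201", keep=[1, 2, 3, 4],
                  domains=[("PF00017", 35, 75), ("PF00018", 85, 125)])
    b.add_isoform("NCK2", "NCK2-202", keep=[1, 3, 4],
                  domains=[("PF00018", 35, 75)])
    b.add_gene("PARTNERA", [120, 120, 63], strand="-")
    b.add_isoform("PARTNERA", "PARTNERA-201", keep=[1, 2, 3],
                  domains=[("PF10001", 10, 35), ("PF10002", 45, 90)])
    b.add_ppi("NCK2", "PARTNERA")
    b.add_ddi("PF00017", "PF10001", "threedid")
    b.add_ddi("PF00018", "PF10002", "domine", "HC")
    b.set_expression("NCK2-201", 2.5)
    b.set_expression("NCK2-202", 1.0)   # exactly at the abundance threshold
    b.set_expression("PARTNERA-201", 1.8)
    return b.build()


def scenario_single_domain_loss(seed: int = 0) -> Fixture:
    """Co-chaperone gene whose only mediating domain sits on one exon.

    The isoform skipping that exon loses the sole DDI supporting its PPI
    with the chaperone partner: score 0.0 and a flagged missing edge.
    A toy co-complex structure adds residue-level interface evidence on
    the domain-bearing exon.
    """
    b = FixtureBuilder(seed)
    b.add_gene("BAG1", [120, 90, 150, 63])
    b.add_isoform("BAG1", "BAG1-210", keep=[1, 2, 3, 4],
                  domains=[("PF00240", 10, 40), ("PF02179", 75, 115)])
    b.add_isoform("BAG1", "BAG1-207", keep=[1, 2, 4],
                  domains=[("PF00240", 10, 40)])
    b.add_gene("CHAP1", [150, 150, 93], strand="-")
    b.add_isoform("CHAP1", "CHAP1-201", keep=[1, 2, 3],
                  domains=[("PF00012", 20, 110)])
    b.add_ppi("BAG1", "CHAP1")
    b.add_ddi("PF02179", "PF00012", "threedid")
    b.add_structure("SBAG", ("A", "BAG1-210"), ("B", "CHAP1-201"),
                    contacts=[(80, 40), (81, 41), (82, 42)])
    return b.build()


def scenario_homotypic_self(seed: int = 0) -> Fixture:
    """Adaptor with a homotypic self-interaction plus a heterotypic partner.

    The self-PPI is mediated by the SH2-family domain alone and the partner
    PPI by the SH3-family domain alone; the isoform lacking the SH2 exon
    loses only the self-interaction.
    """
    b = FixtureBuilder(seed)
    b.add_gene("GRB2", [90, 150, 150, 93])
    b.add_isoform("GRB2", "GRB2-201", keep=[1, 2, 3, 4],
                  domains=[("PF00017", 35, 75), ("PF00018", 85, 125)])
    b.add_isoform("GRB2", "GRB2-202", keep=[1, 3, 4],
                  domains=[("PF00018", 35, 75)])
    b.add_gene("PARTNERB", [210, 93], strand="-")
    b.add_isoform("PARTNERB", "PARTNERB-201", keep=[1, 2],
                  domains=[("PF10010", 20, 80)])
    b.add_ppi("GRB2", "GRB2")
    b.add_ppi("GRB2", "PARTNERB")
    b.add_ddi("PF00017", "PF00017", "threedid")
    b.add_ddi("PF00018", "PF10010", "threedid")
    return b.build()


def scenario_hub_exon(seed: int = 0, n_partners: int = 33, n_kinase_mediated: int = 31) -> Fixture:
    """Receptor-kinase gene whose kinase-domain exon mediates most PPIs.

    Of ``n_partners`` structurally annotated partners, ``n_kinase_mediated``
    interact through the kinase-family domain encoded by exon 3; skipping
    that exon affects exactly those partners.
    """
    b = FixtureBuilder(seed)
    b.add_gene("ALK", [150, 120, 300, 93])
    b.add_isoform("ALK", "ALK-201", keep=[1, 2, 3, 4],
                  domains=[("PF01404", 5, 45), ("PF07714", 95, 185)])
    for k in range(1, n_partners + 1):
        sym = f"PARTNER{k:02d}"
        pfam = f"PF{20000 + k:05d}"
        b.add_gene(sym, [150, 93])
        b.add_isoform(sym, f"{sym}-201", keep=[1, 2], domains=[(pfam, 10, 60)])
        b.add_ppi("ALK", sym)
        mediator = "PF07714" if k <= n_kinase_mediated else "PF01404"
        b.add_ddi(mediator, pfam, "threedid")
    return b.build()


def scenario_interface_exon(seed: int = 0) -> Fixture:
    """Receptor exon outside every annotated domain but on a binding interface.

    The short exon 2 encodes residues 61-72; a toy co-complex with the
    ligand places residues 63-65 within contact distance of the ligand
    chain, so the exon carries residue-level interface evidence although
    its domain list is empty.
    """
    b = FixtureBuilder(seed)
    b.add_gene("INSR", [180, 36, 186])
    b.add_isoform("INSR", "INSR-201", keep=[1, 2, 3],
                  domains=[("PF01030", 5, 50)])
    b.add_isoform("INSR", "INSR-202", keep=[1, 3],
                  domains=[("PF01030", 5, 50)])
    b.add_gene("LIGAND1", [120, 33], strand="-")
    b.add_isoform("LIGAND1", "LIGAND1-201", keep=[1, 2],
                  domains=[("PF00049", 5, 45)])
    b.add_ppi("INSR", "LIGAND1")
    b.add_ddi("PF01030", "PF00049", "threedid")
    b.add_structure("SINSR", ("A", "INSR-201"), ("B", "LIGAND1-201"),
                    contacts=[(63, 10), (64, 11), (65, 12)])
    return b.build()


def named_scenarios() -> dict[str, Callable[..., Fixture]]:
    """Catalog of the classic case-study fixtures, each with a manifest."""
    return {
        "two_domain_partial_loss": scenario_two_domain_partial_loss,
        "single_domain_loss": scenario_single_domain_loss,
        "homotypic_self": scenario_homotypic_self,
        "hub_exon": scenario_hub_exon,
        "interface_exon": scenario_interface_exon,
    }
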