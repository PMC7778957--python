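"""Position-specific PPI network from experimentally resolved structures.

Pipeline: align each candidate isoform sequence to a structure chain
(semi-global, accepted above 95% identity), find inter-chain residue pairs
whose minimum heavy-atom distance is strictly below 5 A, lift the chain
residue indices through the alignment into isoform coordinates, and union
contacts over all structures per gene pair.  Interface residues are then
liftable to exons through the annotation module, giving per-exon structural
evidence for each interaction.

Distance convention: "residue within 5 A" is taken as the minimum over all
non-hydrogen atom pairs, strict inequality — the most common interface
definition.  Only the first alternate location of disordered atoms is used;
insertion codes are preserved in residue identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from Bio.SeqUtils import seq1

from .annotation import AnnotationStore, residue_to_exons
from .errors import StructureError
from .interaction_sources import canonical_pair

logger = logging.getLogger(__name__)

CONTACT_CUTOFF = 5.0        # Angstrom, strict '<'
IDENTITY_THRESHOLD = 0.95   # accepted only if identity strictly above


# ---------------------------------------------------------------------------
# Chain extraction
# ---------------------------------------------------------------------------

@dataclass
class ChainResidues:
    """Polymer residues of one chain with heavy-atom coordinates.

    ``sequence[i]`` is the one-letter code of polymer residue ``i+1``;
    ``residue_ids[i]`` keeps the original (resseq, icode) pair.
    """

    chain_id: str
    sequence: str
    residue_ids: list[tuple[int, str]]
    atom_coords: np.ndarray          # (n_atoms, 3)
    atom_residue_index: np.ndarray   # (n_atoms,) 1-based polymer index
    n_unresolved: int = 0


def load_structure(source):
    """Parse a PDB file (path or text handle); model 1 is used if several."""
    parser = PDBParser(QUIET=True)
    if hasattr(source, "read"):
        structure = parser.get_structure("structure", source)
    else:
        structure = parser.get_structure(Path(source).stem, str(source))
    return next(structure.get_models())


def _first_altloc_atoms(residue):
    for atom in residue:
        if atom.is_disordered():
            yield atom.child_dict[sorted(atom.child_dict)[0]]
        else:
            yield atom


def extract_chain(model, chain_id: str) -> ChainResidues:
    """Extract the polymer sequence and heavy-atom coordinates of a chain."""
    if chain_id not in [c.id for c in model]:
        raise StructureError(f"chain {chain_id!r} not present in structure")
    chain = model[chain_id]
    letters: list[str] = []
    residue_ids: list[tuple[int, str]] = []
    coords: list[np.ndarray] = []
    res_index: list[int] = []
    n_unresolved = 0
    for residue in chain:
        hetflag, resseq, icode = residue.id
        if hetflag != " " or not is_aa(residue, standard=False):
            continue
        atoms = [a for a in _first_altloc_atoms(residue) if a.element not in ("H", "D")]
        if not atoms:
            n_unresolved += 1
            continue
        letters.append(seq1(residue.get_resname(), undef_code="X"))
        residue_ids.append((resseq, icode))
        idx = len(letters)
        for a in atoms:
            coords.append(a.coord)
            res_index.append(idx)
    if n_unresolved:
        logger.info("chain %s: %d residues without resolved atoms skipped",
                    chain_id, n_unresolved)
    return ChainResidues(
        chain_id=chain_id,
        sequence="".join(letters),
        residue_ids=residue_ids,
        atom_coords=np.asarray(coords, dtype=float).reshape(-1, 3),
        atom_residue_index=np.asarray(res_index, dtype=int),
        n_unresolved=n_unresolved,
    )


# ---------------------------------------------------------------------------
# Isoform-to-chain alignment
# ---------------------------------------------------------------------------

@dataclass
class ChainMapping:
    """Accepted alignment between an isoform and a structure chain.

    ``pairs`` maps 1-based isoform residue positions to 1-based polymer
    indices in the chain, strictly monotone in both coordinates.
    """

    protein_id: str
    structure_id: str
    chain_id: str
    pairs: list[tuple[int, int]]
    identity: float

    def isoform_to_chain(self) -> dict[int, int]:
        return dict(self.pairs)

    def chain_to_isoform(self) -> dict[int, int]:
        return {c: a for a, c in self.pairs}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    # free end gaps: unresolved chain termini must not penalise identity
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def align_isoform_to_chain(
    isoform_sequence: str,
    chain_sequence: str,
    protein_id: str = "",
    structure_id: str = "",
    chain_id: str = "",
    threshold: float = IDENTITY_THRESHOLD,
) -> ChainMapping | None:
    """Align an isoform sequence to a chain; return a mapping or ``None``.

    Identity = identical aligned positions / alignment columns, where the
    column count excludes terminal free gaps but includes internal gaps.
    The mapping is accepted only when identity is strictly above the
    threshold (0.95 by default).
    """
    if not isoform_sequence or not chain_sequence:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner()
    aln = aligner.align(isoform_sequence, chain_sequence)[0]
    blocks_t, blocks_q = aln.aligned
    if len(blocks_t) == 0:
        return None

    matches = 0
    aligned_cols = 0
    pairs: list[tuple[int, int]] = []
    for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
        for k in range(t1 - t0):
            if isoform_sequence[t0 + k] == chain_sequence[q0 + k]:
                matches += 1
            pairs.append((t0 + k + 1, q0 + k + 1))
        aligned_cols += t1 - t0
    internal_gaps = 0
    for i in range(len(blocks_t) - 1):
        internal_gaps += blocks_t[i + 1][0] - blocks_t[i][1]
        internal_gaps += blocks_q[i + 1][0] - blocks_q[i][1]

    identity = matches / (aligned_cols + internal_gaps)
    if identity <= threshold:
        logger.debug("mapping rejected: identity %.3f <= %.2f", identity, threshold)
        return None
    return ChainMapping(protein_id, structure_id, chain_id, pairs, identity)


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def compute_contacts(
    structure,
    chain_pair: tuple[str, str],
    cutoff: float = CONTACT_CUTOFF,
) -> dict[tuple[int, int], float]:
    """Inter-chain residue contacts of one structure.

    Returns ``{(res_a, res_b): min_distance}`` over 1-based polymer indices
    for residue pairs whose minimum heavy-atom distance is strictly below
    ``cutoff``.  ``structure`` is a PDB path or a parsed model.  A pair of
    identical chain ids is rejected: contacts are inter-chain by definition.
    """
    from scipy.spatial.distance import cdist

    chain_a_id, chain_b_id = chain_pair
    if chain_a_id == chain_b_id:
        raise StructureError("contacts are defined between two distinct chains")
    model = structure if not isinstance(structure, (str, Path)) else load_structure(structure)
    ca = structure_chain(model, chain_a_id)
    cb = structure_chain(model, chain_b_id)
    if ca.atom_coords.size == 0 or cb.atom_coords.size == 0:
        return {}
    dist = cdist(ca.atom_coords, cb.atom_coords)
    out: dict[tuple[int, int], float] = {}
    ii, jj = np.nonzero(dist < cutoff)
    for i, j in zip(ii, jj):
        key = (int(ca.atom_residue_index[i]), int(cb.atom_residue_index[j]))
        d = float(dist[i, j])
        if key not in out or d < out[key]:
            out[key] = d
    return out


def structure_chain(model, chain_id: str) -> ChainResidues:
    """Cached :func:`extract_chain` (models are re-used across chain pairs)."""
    cache = getattr(model, "_spliceppi_chain_cache", None)
    if cache is None:
        cache = {}
        model._spliceppi_chain_cache = cache
    if chain_id not in cache:
        cache[chain_id] = extract_chain(model, chain_id)
    return cache[chain_id]


# ---------------------------------------------------------------------------
# Lifting to isoform coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueContact:
    """An interface residue pair in isoform coordinates (canonical order)."""

    protein_a: str
    aa_a: int
    protein_b: str
    aa_b: int
    structure_id: str
    min_distance: float


def lift_contacts(
    contacts: Mapping[tuple[int, int], float],
    mapping_a: ChainMapping,
    mapping_b: ChainMapping,
) -> list[ResidueContact]:
    """Translate chain-residue contacts into isoform coordinates.

    Contacts involving a chain residue with no alignment pair are dropped
    (their count is logged) — these are typically unresolved or mutated
    positions outside the accepted alignment.
    """
    to_a = mapping_a.chain_to_isoform()
    to_b = mapping_b.chain_to_isoform()
    lifted: list[ResidueContact] = []
    n_dropped = 0
    for (ra, rb), dist in contacts.items():
        aa_a, aa_b = to_a.get(ra), to_b.get(rb)
        if aa_a is None or aa_b is None:
            n_dropped += 1
            continue
        pa, pb = mapping_a.protein_id, mapping_b.protein_id
        if (pa, aa_a) <= (pb, aa_b):
            lifted.append(ResidueContact(pa, aa_a, pb, aa_b,
                                         mapping_a.structure_id, dist))
        else:
            lifted.append(ResidueContact(pb, aa_b, pa, aa_a,
                                         mapping_a.structure_id, dist))
    if n_dropped:
        logger.info("lift: dropped %d contacts on unaligned residues", n_dropped)
    return lifted


# ---------------------------------------------------------------------------
# Position-specific network
# ---------------------------------------------------------------------------

class PositionSpecificPPI:
    """Union of interface contacts over structures, indexed by gene pair."""

    def __init__(self, store: AnnotationStore):
        self.store = store
        # gene pair -> contact key -> (min_distance, structure ids)
        self._contacts: dict[
            tuple[str, str],
            dict[tuple[tuple[str, str, int], tuple[str, str, int]], tuple[float, set[str]]],
        ] = {}
        self._exon_cache: dict[tuple[str, str], dict[str, set[str]]] = {}

    def add(self, contact: ResidueContact) -> None:
        ga = self.store.isoform_by_protein(contact.protein_a).gene.entrez_id
        gb = self.store.isoform_by_protein(contact.protein_b).gene.entrez_id
        pair = canonical_pair(ga, gb)
        side_a = (ga, contact.protein_a, contact.aa_a)
        side_b = (gb, contact.protein_b, contact.aa_b)
        key = (side_a, side_b) if side_a <= side_b else (side_b, side_a)
        bucket = self._contacts.setdefault(pair, {})
        if key in bucket:
            d, structs = bucket[key]
            bucket[key] = (min(d, contact.min_distance),
                           structs | {contact.structure_id})
        else:
            bucket[key] = (contact.min_distance, {contact.structure_id})
        self._exon_cache.pop(pair, None)

    def gene_pairs(self) -> list[tuple[str, str]]:
        return sorted(self._contacts)

    def contacts_for(self, gene_a: str, gene_b: str):
        return dict(self._contacts.get(canonical_pair(gene_a, gene_b), {}))

    def interface_exons(self, gene_a: str, gene_b: str) -> dict[str, set[str]]:
        """Per-gene exon ids carrying interface residues for this pair."""
        pair = canonical_pair(gene_a, gene_b)
        if pair not in self._exon_cache:
            evidence: dict[str, set[str]] = {}
            for (sa, sb) in self._contacts.get(pair, {}):
                for gene, protein_id, aa in (sa, sb):
                    iso = self.store.isoform_by_protein(protein_id)
                    evidence.setdefault(gene, set()).update(residue_to_exons(iso, aa))
            self._exon_cache[pair] = evidence
        return self._exon_cache[pair]

    def exon_has_evidence(self, exon_id: str, gene: str, partner: str) -> bool:
        return exon_id in self.interface_exons(gene, partner).get(gene, set())


def read_chain_assignments(table) -> pd.DataFrame:
    """Chain-assignment TSV: structure_id, chain_id, protein_id per row."""
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    missing = {"structure_id", "chain_id", "protein_id"} - set(df.columns)
    if missing:
        raise StructureError(f"chain assignment table lacks columns {sorted(missing)}")
    return df


def build_position_network(
    structures: Mapping[str, "str | Path"],
    assignments,
    store: AnnotationStore,
    cutoff: float = CONTACT_CUTOFF,
) -> PositionSpecificPPI:
    """Assemble the position-specific PPI network.

    ``structures`` maps structure ids to PDB paths; ``assignments`` names
    the candidate protein(s) per chain — only those candidates are aligned,
    there is no proteome-wide search.  Contacts from all structures are
    unioned per gene pair.
    """
    df = read_chain_assignments(assignments)
    net = PositionSpecificPPI(store)
    for structure_id in sorted(structures):
        model = load_structure(structures[structure_id])
        rows = df[df["structure_id"] == structure_id]
        mappings: dict[str, list[ChainMapping]] = {}
        for row in rows.to_dict("records"):
            protein_id = row["protein_id"]
            seq = store.sequences.get(protein_id)
            if seq is None:
                logger.warning("no sequence for protein %s; chain %s skipped",
                               protein_id, row["chain_id"])
                continue
            chain = structure_chain(model, row["chain_id"])
            mapping = align_isoform_to_chain(
                seq, chain.sequence,
                protein_id=protein_id,
                structure_id=structure_id,
                chain_id=row["chain_id"],
            )
            if mapping is not None:
                mappings.setdefault(row["chain_id"], []).append(mapping)
        chain_ids = sorted(mappings)
        for i, ca in enumerate(chain_ids):
            for cb in chain_ids[i + 1:]:
                contacts = compute_contacts(model, (ca, cb), cutoff)
                if not contacts:
                    continue
                for ma in mappings[ca]:
                    for mb in mappings[cb]:
                        for rc in lift_contacts(contacts, ma, mb):
                            net.add(rc)
    return net


def write_contacts_tsv(net: PositionSpecificPPI, path) -> Path:
    """Contact table: gene, residue, exon(s) and distance per side."""
    store = net.store
    rows = []
    for ga, gb in net.gene_pairs():
        for (sa, sb), (dist, structs) in sorted(net.contacts_for(ga, gb).items()):
            (gene_a, prot_a, aa_a), (gene_b, prot_b, aa_b) = sa, sb
            exons_a = residue_to_exons(store.isoform_by_protein(prot_a), aa_a)
            exons_b = residue_to_exons(store.isoform_by_protein(prot_b), aa_b)
            rows.append(
                {
                    "gene_a": gene_a, "aa_a": aa_a, "exon_a": ",".join(sorted(exons_a)),
                    "gene_b": gene_b, "aa_b": aa_b, "exon_b": ",".join(sorted(exons_b)),
                    "structure": ",".join(sorted(structs)),
                    "distance": f"{dist:.3f}",
                }
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
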