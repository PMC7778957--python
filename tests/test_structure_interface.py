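"""Alignment, contact detection and the position-specific network."""

import io
import math

import pytest

from spliceppi import align_isoform_to_chain, compute_contacts, lift_contacts
from spliceppi.errors import StructureError
from spliceppi.structure_interface import (
    ChainMapping,
    load_structure,
    structure_chain,
)
from spliceppi import synthetic_fixtures as sf

SEQ120 = ("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVK"
          "ALPDAQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVYVDQWDWE")


class TestAlignment:
    def test_identical_sequences_accepted_with_diagonal(self):
        m = align_isoform_to_chain(SEQ120, SEQ120)
        assert m is not None
        assert m.identity == 1.0
        assert m.pairs == [(i, i) for i in range(1, 121)]

    def test_ten_percent_mismatch_rejected(self):
        mutated = list(SEQ120[:100])
        for i in range(0, 100, 10):
            mutated[i] = "W" if mutated[i] != "W" else "Y"
        assert align_isoform_to_chain(SEQ120[:100], "".join(mutated)) is None

    def test_identity_exactly_at_threshold_rejected(self):
        # 19 matches / 20 columns = 0.95: "> 95%" is strict
        seq = SEQ120[:20]
        mutated = ("W" if seq[0] != "W" else "Y") + seq[1:]
        assert align_isoform_to_chain(seq, mutated) is None

    def test_truncated_chain_has_free_end_gaps(self):
        chain = SEQ120[3:100]  # leading 3-residue offset, shortened tail
        m = align_isoform_to_chain(SEQ120, chain)
        assert m is not None and m.identity == 1.0
        assert m.pairs == [(i + 3, i) for i in range(1, len(chain) + 1)]

    def test_internal_unresolved_gap_matches_positional_oracle(self):
        chain = SEQ120[:40] + SEQ120[45:]  # 5-residue unresolved stretch
        m = align_isoform_to_chain(SEQ120, chain)
        assert m is not None
        # brute-force expected mapping: identity before the gap, +5 shift after
        expected = [(i, i) for i in range(1, 41)]
        expected += [(i + 5, i) for i in range(41, len(chain) + 1)]
        assert m.pairs == expected
        assert m.identity == pytest.approx(115 / 120)

    def test_monotone_in_both_coordinates(self):
        chain = SEQ120[:40] + SEQ120[45:]
        m = align_isoform_to_chain(SEQ120, chain)
        aa, ci = zip(*m.pairs)
        assert list(aa) == sorted(aa) and list(ci) == sorted(ci)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_isoform_to_chain("", SEQ120)


def two_residue_pdb(distance: float) -> str:
    """Two single-glycine chains, CA atoms exactly ``distance`` apart."""
    lines = [
        f"ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C",
        f"ATOM      2  CA  GLY B   1       {distance:.3f}   0.000   0.000  1.00  0.00           C",
        "END",
    ]
    return "\n".join(lines) + "\n"


class TestContacts:
    def test_two_glycines_at_four_angstrom(self):
        model = load_structure(io.StringIO(two_residue_pdb(4.0)))
        contacts = compute_contacts(model, ("A", "B"))
        assert contacts == {(1, 1): pytest.approx(4.0)}

    def test_exactly_five_angstrom_excluded(self):
        model = load_structure(io.StringIO(two_residue_pdb(5.0)))
        assert compute_contacts(model, ("A", "B")) == {}

    def test_threshold_boundary_perturbation(self):
        assert compute_contacts(load_structure(io.StringIO(two_residue_pdb(4.99))), ("A", "B"))
        assert not compute_contacts(load_structure(io.StringIO(two_residue_pdb(5.01))), ("A", "B"))

    def test_same_chain_pair_rejected(self):
        model = load_structure(io.StringIO(two_residue_pdb(4.0)))
        with pytest.raises(StructureError):
            compute_contacts(model, ("A", "A"))

    def test_missing_chain_is_lookup_error(self):
        model = load_structure(io.StringIO(two_residue_pdb(4.0)))
        with pytest.raises(StructureError):
            compute_contacts(model, ("A", "Z"))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_heavy_atom_scan(self, seed):
        """Vectorised contact scan equals a plain all-pairs loop."""
        fx = sf.random_fixture(spec=sf.FixtureSpec(seed=seed, n_structures=2))
        for sid, text in fx.pdb_texts.items():
            model = load_structure(io.StringIO(text))
            ca = structure_chain(model, "A")
            cb = structure_chain(model, "B")
            expected = {}
            for i, xa in zip(ca.atom_residue_index, ca.atom_coords):
                for j, xb in zip(cb.atom_residue_index, cb.atom_coords):
                    d = math.dist(xa, xb)
                    if d < 5.0 and (d < expected.get((i, j), 5.0)):
                        expected[(int(i), int(j))] = d
            got = compute_contacts(model, ("A", "B"))
            assert got.keys() == expected.keys()
            for key in expected:
                assert got[key] == pytest.approx(expected[key])
            assert all(d < 5.0 for d in got.values())


class TestLift:
    def make_mapping(self, protein, pairs):
        return ChainMapping(protein, "S1", "A", pairs, 1.0)

    def test_identity_alignment_preserves_positions(self):
        ma = self.make_mapping("P1", [(i, i) for i in range(1, 11)])
        mb = self.make_mapping("P2", [(i, i) for i in range(1, 11)])
        (rc,) = lift_contacts({(3, 7): 4.2}, ma, mb)
        assert (rc.protein_a, rc.aa_a, rc.protein_b, rc.aa_b) == ("P1", 3, "P2", 7)
        assert rc.min_distance == 4.2

    def test_offset_alignment_shifts_positions(self):
        ma = self.make_mapping("P1", [(i + 3, i) for i in range(1, 11)])
        mb = self.make_mapping("P2", [(i, i) for i in range(1, 11)])
        (rc,) = lift_contacts({(2, 5): 3.0}, ma, mb)
        assert (rc.aa_a, rc.aa_b) == (5, 5)

    def test_contact_on_unaligned_residue_dropped(self):
        ma = self.make_mapping("P1", [(1, 1), (2, 2)])
        mb = self.make_mapping("P2", [(1, 1), (2, 2)])
        assert lift_contacts({(5, 1): 3.0}, ma, mb) == []


class TestPositionNetwork:
    def test_contact_union_over_structures(self):
        """The same lifted contact from two structures is stored once."""
        b = sf.FixtureBuilder(seed=0)
        b.add_gene("GA", [150, 93])
        b.add_isoform("GA", "GA-201", keep=[1, 2], domains=[("PF00001", 5, 40)])
        b.add_gene("GB", [150, 93])
        b.add_isoform("GB", "GB-201", keep=[1, 2], domains=[("PF00002", 5, 40)])
        b.add_ppi("GA", "GB")
        b.add_structure("S1", ("A", "GA-201"), ("B", "GB-201"), [(10, 20)])
        b.add_structure("S2", ("A", "GA-201"), ("B", "GB-201"), [(10, 20)], distance=3.5)
        fx = b.build()
        pipe = fx.build_pipeline()
        contacts = pipe.posnet.contacts_for("101", "102")
        assert len(contacts) == 1
        ((dist, structs),) = contacts.values()
        assert structs == {"S1", "S2"}
        assert dist == pytest.approx(3.5)  # minimum over structures

    def test_homodimer_self_contacts_retained(self):
        b = sf.FixtureBuilder(seed=0)
        b.add_gene("GA", [150, 93])
        b.add_isoform("GA", "GA-201", keep=[1, 2], domains=[("PF00001", 5, 40)])
        b.add_ppi("GA", "GA")
        b.add_structure("SDIMER", ("A", "GA-201"), ("B", "GA-201"), [(7, 30)])
        fx = b.build()
        pipe = fx.build_pipeline()
        assert pipe.posnet.gene_pairs() == [("101", "101")]
        assert len(pipe.posnet.contacts_for("101", "101")) == 1

    def test_interface_exon_flags_match_generator_oracle(self, random_pipeline):
        fx, pipe = random_pipeline
        assert pipe.posnet is not None
        for pair_key, expected in fx.manifest["interface_exons"].items():
            ga, gb = pair_key.split("|")
            got = {g: sorted(v) for g, v in pipe.posnet.interface_exons(ga, gb).items()}
            assert got == expected

    def test_all_stored_distances_below_cutoff(self, random_pipeline):
        _, pipe = random_pipeline
        for ga, gb in pipe.posnet.gene_pairs():
            for (d, _structs) in pipe.posnet.contacts_for(ga, gb).values():
                assert d < 5.0

    def test_truncated_chain_lifts_with_offset(self):
        """A chain covering residues 40..90 lifts contacts back to isoform coords."""
        b = sf.FixtureBuilder(seed=0)
        b.add_gene("GA", [300, 93])
        b.add_isoform("GA", "GA-201", keep=[1, 2], domains=[("PF00001", 5, 40)])
        b.add_gene("GB", [150, 93])
        b.add_isoform("GB", "GB-201", keep=[1, 2], domains=[("PF00002", 5, 40)])
        b.add_ppi("GA", "GB")
        b.add_structure("S1", ("A", "GA-201"), ("B", "GB-201"), [(60, 20)],
                        chain_a_range=(40, 90))
        fx = b.build()
        pipe = fx.build_pipeline()
        ((sa, sb),) = pipe.posnet.contacts_for("101", "102").keys()
        sides = {sa, sb}
        assert ("101", "GA-201.p", 60) in sides
        assert ("102", "GB-201.p", 20) in sides
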