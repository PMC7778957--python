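"""Isoform scoring, exon reports and subnetwork extraction."""

import pandas as pd
import pytest

from spliceppi import (
    NoStructuralAnnotation,
    exon_report,
    extract_subnetwork,
    filter_subnetwork,
    isoform_report,
    score_interaction,
)
from spliceppi.annotation import load_annotation
from spliceppi.errors import AmbiguousExonError
from spliceppi.splicing_analysis import write_exon_report, write_subnetwork
from spliceppi import synthetic_fixtures as sf

from conftest import entrez_of


class TestScoreInteraction:
    def test_partial_domain_loss_scores_half(self, nck2):
        """Losing one of two mediating domains halves the retained fraction."""
        fx, pipe = nck2
        partner = entrez_of(fx, "PARTNERA")
        s = score_interaction("NCK2-202", partner, pipe.graph, pipe.store)
        assert (s.n_ddi_total, s.n_ddi_retained, s.score) == (2, 1, 0.5)

    def test_full_isoform_scores_one(self, nck2):
        fx, pipe = nck2
        partner = entrez_of(fx, "PARTNERA")
        assert score_interaction("NCK2-201", partner, pipe.graph, pipe.store).score == 1.0

    def test_sole_mediating_domain_loss_scores_zero(self, bag1):
        fx, pipe = bag1
        chap = entrez_of(fx, "CHAP1")
        assert score_interaction("BAG1-207", chap, pipe.graph, pipe.store).score == 0.0

    def test_missing_nonmediating_domain_does_not_lower_score(self, scenario_fixtures, scenario_pipelines):
        """Only domains that mediate joint edges to this partner count."""
        fx = scenario_fixtures["homotypic_self"]
        pipe = scenario_pipelines["homotypic_self"]
        partner = entrez_of(fx, "PARTNERB")
        # GRB2-202 lost the SH2-family domain, which mediates only the self-PPI
        assert score_interaction("GRB2-202", partner, pipe.graph, pipe.store).score == 1.0

    def test_homotypic_self_interaction_lost_with_domain(self, scenario_fixtures, scenario_pipelines):
        fx = scenario_fixtures["homotypic_self"]
        pipe = scenario_pipelines["homotypic_self"]
        grb2 = entrez_of(fx, "GRB2")
        assert score_interaction("GRB2-202", grb2, pipe.graph, pipe.store).score == 0.0
        assert score_interaction("GRB2-201", grb2, pipe.graph, pipe.store).score == 1.0

    def test_unsupported_pair_is_typed_condition_not_zero(self, nck2):
        fx, pipe = nck2
        nck2_entrez = entrez_of(fx, "NCK2")
        with pytest.raises(NoStructuralAnnotation):
            score_interaction("NCK2-201", nck2_entrez, pipe.graph, pipe.store)

    def test_score_conservation(self, random_pipeline):
        _, pipe = random_pipeline
        for tid in pipe.store.isoforms:
            iso = pipe.store.isoform(tid)
            for partner in pipe.graph.joint_partners(iso.gene.entrez_id):
                s = score_interaction(iso, partner, pipe.graph, pipe.store)
                assert s.n_ddi_retained + s.n_ddi_missing == s.n_ddi_total
                assert 0.0 <= s.score <= 1.0

    def test_matches_generator_oracle_on_scenarios(self, scenario_fixtures, scenario_pipelines):
        for name, fx in scenario_fixtures.items():
            pipe = scenario_pipelines[name]
            for tid, per_partner in fx.manifest["scores"].items():
                for partner, expected in per_partner.items():
                    s = score_interaction(tid, partner, pipe.graph, pipe.store)
                    assert s.score == pytest.approx(expected), (name, tid, partner)


class TestMonotonicity:
    @pytest.mark.parametrize("seed", range(6))
    def test_removing_a_domain_never_raises_scores(self, seed):
        """Dropping any one family from an isoform's annotation can only
        lower (or keep) each of its interaction scores."""
        fx = sf.random_fixture(spec=sf.FixtureSpec(seed=seed, n_structures=0))
        pipe = fx.build_pipeline()
        domains = fx.tables["domains"]
        for tid in sorted(pipe.store.isoforms):
            iso = pipe.store.isoform(tid)
            partners = pipe.graph.joint_partners(iso.gene.entrez_id)
            if not partners:
                continue
            base = {p: score_interaction(iso, p, pipe.graph, pipe.store).score
                    for p in partners}
            for pfam in sorted(pipe.store.pfam_set(iso)):
                reduced = domains[~((domains["protein_id"] == iso.protein_id)
                                    & (domains["pfam_id"] == pfam))]
                store2 = load_annotation(
                    genes=fx.tables["genes"], transcripts=fx.tables["transcripts"],
                    exons=fx.tables["exons"], domains=reduced, idmap=fx.tables["idmap"],
                )
                for p in partners:
                    s2 = score_interaction(store2.isoform(tid), p, pipe.graph, store2)
                    assert s2.score <= base[p] + 1e-12


class TestIsoformReport:
    def test_composes_per_partner_scores(self, nck2):
        fx, pipe = nck2
        report = isoform_report("NCK2-202", pipe.graph, pipe.store)
        partner = entrez_of(fx, "PARTNERA")
        assert set(report.scores) == {partner}
        assert report.scores[partner].score == 0.5
        assert report.missing_domains == ["PF00017"]

    def test_reference_isoform_has_no_missing_domains(self, nck2):
        _, pipe = nck2
        assert isoform_report("NCK2-201", pipe.graph, pipe.store).missing_domains == []

    def test_empty_for_gene_without_ppis(self):
        b = sf.FixtureBuilder(seed=0)
        b.add_gene("LONER", [150, 93])
        b.add_isoform("LONER", "LONER-201", keep=[1, 2], domains=[("PF00001", 5, 40)])
        pipe = b.build().build_pipeline()
        report = isoform_report("LONER-201", pipe.graph, pipe.store)
        assert report.scores == {} and report.ppi_only_partners == []

    def test_ppi_only_partners_listed_separately(self):
        b = sf.FixtureBuilder(seed=0)
        b.add_gene("GA", [150, 93])
        b.add_isoform("GA", "GA-201", keep=[1, 2], domains=[("PF00001", 5, 40)])
        b.add_gene("GB", [150, 93])
        b.add_isoform("GB", "GB-201", keep=[1, 2], domains=[("PF00002", 5, 40)])
        b.add_ppi("GA", "GB")  # a PPI with no DDI support
        pipe = b.build().build_pipeline()
        report = isoform_report("GA-201", pipe.graph, pipe.store)
        assert report.scores == {}
        assert report.ppi_only_partners == ["102"]


class TestExonReport:
    def exon_of(self, pipe, transcript_id, rank):
        return pipe.store.isoform(transcript_id).exons[rank - 1].exon_id

    def test_kinase_exon_affects_31_of_33_partners(self, scenario_pipelines):
        """Skipping the kinase-domain exon hits the 31 kinase-mediated PPIs."""
        pipe = scenario_pipelines["hub_exon"]
        exon3 = self.exon_of(pipe, "ALK-201", 3)
        report = exon_report(pipe.store, pipe.graph, exon_id=exon3)
        assert report.domains == ["PF07714"]
        assert len(report.affected) == 33
        assert len(report.affected_partners) == 31
        for p in report.affected_partners:
            assert report.affected[p].fraction_lost == 1.0

    def test_exon_without_domain_or_evidence_has_empty_affected_list(self, scenario_pipelines):
        pipe = scenario_pipelines["hub_exon"]
        exon4 = self.exon_of(pipe, "ALK-201", 4)
        report = exon_report(pipe.store, pipe.graph, exon_id=exon4)
        assert report.domains == []
        assert report.affected_partners == []

    def test_interface_only_exon_sets_evidence_flag(self, scenario_fixtures, scenario_pipelines):
        """An exon outside every domain can still carry interface residues."""
        fx = scenario_fixtures["interface_exon"]
        pipe = scenario_pipelines["interface_exon"]
        ligand = entrez_of(fx, "LIGAND1")
        exon2 = self.exon_of(pipe, "INSR-201", 2)
        report = exon_report(pipe.store, pipe.graph, exon_id=exon2,
                             position_network=pipe.posnet)
        assert report.domains == []
        assert report.affected_partners == []
        assert report.interface_evidence == {ligand: True}
        assert report.isoforms == ["INSR-201"]  # the skipping isoform lacks it

    def test_lookup_by_gene_and_coordinates(self, scenario_pipelines, scenario_fixtures):
        pipe = scenario_pipelines["two_domain_partial_loss"]
        fx = scenario_fixtures["two_domain_partial_loss"]
        nck2_gene = entrez_of(fx, "NCK2")
        exon2 = pipe.store.isoform("NCK2-201").exons[1]
        report = exon_report(pipe.store, pipe.graph, gene=nck2_gene,
                             coords=(exon2.start, exon2.end))
        assert report.exon_id == exon2.exon_id
        assert report.domains == ["PF00017"]

    def test_ambiguous_coordinates_list_candidates(self, scenario_pipelines, scenario_fixtures):
        pipe = scenario_pipelines["two_domain_partial_loss"]
        fx = scenario_fixtures["two_domain_partial_loss"]
        nck2_gene = entrez_of(fx, "NCK2")
        iso = pipe.store.isoform("NCK2-201")
        span = (iso.exons[0].start, iso.exons[1].end)  # covers two exons
        with pytest.raises(AmbiguousExonError) as err:
            exon_report(pipe.store, pipe.graph, gene=nck2_gene, coords=span)
        assert len(err.value.candidates) == 2

    def test_exon_loss_consistent_with_isoform_scores(self, scenario_fixtures, scenario_pipelines):
        """An interaction lost with exon e also scores below 1 for every
        isoform lacking all of e's domains."""
        for name, pipe in scenario_pipelines.items():
            store = pipe.store
            for tid in sorted(store.isoforms):
                ref = store.isoform(tid)
                for exon in ref.exons:
                    report = exon_report(store, pipe.graph, exon_id=exon.exon_id)
                    lost = set(report.domains)
                    if not lost:
                        continue
                    for iso in store.isoforms_of_gene(ref.gene.entrez_id):
                        if store.pfam_set(iso) & lost:
                            continue
                        for partner in report.affected_partners:
                            s = score_interaction(iso, partner, pipe.graph, store)
                            assert s.score < 1.0, (name, exon.exon_id, iso.transcript_id)


class TestSubnetwork:
    def test_fully_retained_edge_has_weight_one(self, nck2):
        fx, pipe = nck2
        sub = extract_subnetwork(["NCK2-201", "PARTNERA-201"], pipe.store, pipe.graph)
        (data,) = [d for _, _, d in sub.graph.edges(data=True)]
        assert data["label"] == "PPI-DDI" and data["weight"] == 1.0

    def test_listed_truncated_isoform_halves_weight(self, nck2):
        fx, pipe = nck2
        sub = extract_subnetwork(["NCK2-202", "PARTNERA-201"], pipe.store, pipe.graph)
        (data,) = [d for _, _, d in sub.graph.edges(data=True)]
        assert data["weight"] == 0.5
        nck2_gene = entrez_of(fx, "NCK2")
        assert sub.missing_domains[nck2_gene] == ["PF00017"]

    def test_gene_id_expands_to_all_isoforms(self, nck2):
        """Listing the gene includes the full-length isoform: weight 1.0."""
        fx, pipe = nck2
        gene_ens = pipe.store.genes[entrez_of(fx, "NCK2")].ensembl_id
        sub = extract_subnetwork([gene_ens, "PARTNERA-201"], pipe.store, pipe.graph)
        (data,) = [d for _, _, d in sub.graph.edges(data=True)]
        assert data["weight"] == 1.0

    def test_expression_threshold_is_strict(self, nck2):
        """A transcript at exactly the threshold is not abundant."""
        fx, pipe = nck2
        sub = extract_subnetwork(
            ["NCK2-201", "NCK2-202", "PARTNERA-201"], pipe.store, pipe.graph,
            expression=fx.tables["expression"], threshold=1.0,
        )
        assert sub.excluded_transcripts == ["NCK2-202"]  # expression exactly 1.0
        (data,) = [d for _, _, d in sub.graph.edges(data=True)]
        assert data["weight"] == 1.0  # scored from NCK2-201 only

    def test_unresolved_ids_reported_not_fatal(self, nck2):
        _, pipe = nck2
        sub = extract_subnetwork(["NCK2-201", "NOSUCHID"], pipe.store, pipe.graph)
        assert sub.unresolved == ["NOSUCHID"]

    def test_ppi_label_without_structural_evidence(self):
        b = sf.FixtureBuilder(seed=0)
        b.add_gene("GA", [150, 93])
        b.add_isoform("GA", "GA-201", keep=[1, 2], domains=[("PF00001", 5, 40)])
        b.add_gene("GB", [150, 93])
        b.add_isoform("GB", "GB-201", keep=[1, 2], domains=[("PF00002", 5, 40)])
        b.add_ppi("GA", "GB")
        pipe = b.build().build_pipeline()
        sub = extract_subnetwork(["GA-201", "GB-201"], pipe.store, pipe.graph)
        (data,) = [d for _, _, d in sub.graph.edges(data=True)]
        assert data["label"] == "PPI" and "weight" not in data

    @pytest.mark.parametrize("seed", range(3))
    def test_edge_weights_match_brute_force(self, seed):
        """Subnetwork labels/weights equal a from-scratch recomputation."""
        fx = sf.random_fixture(spec=sf.FixtureSpec(seed=seed, n_structures=0))
        pipe = fx.build_pipeline()
        inputs = sorted(pipe.store.isoforms)  # every transcript listed
        sub = extract_subnetwork(inputs, pipe.store, pipe.graph)
        # oracle: list-level family sets per gene, plain loops over manifest edges
        fams = {}
        for tid in inputs:
            iso = pipe.store.isoform(tid)
            fams.setdefault(iso.gene.entrez_id, set()).update(pipe.store.pfam_set(iso))
        pair_edges = {}
        for edge in fx.manifest["joint_edges"]:
            (ga, pa), (gb, pb) = (side.split("/") for side in edge.split("|"))
            pair_edges.setdefault(tuple(sorted((ga, gb))), []).append((ga, pa, gb, pb))
        for u, v, data in sub.graph.edges(data=True):
            pair = tuple(sorted((u, v)))
            if pair not in pair_edges:
                assert data["label"] == "PPI"
                continue
            edges = pair_edges[pair]
            retained = 0
            for ga, pa, gb, pb in edges:
                if ga == gb:
                    retained += pa in fams[ga] and pb in fams[ga]
                else:
                    retained += pa in fams[ga] and pb in fams[gb]
            assert data["label"] == "PPI-DDI"
            assert data["weight"] == pytest.approx(retained / len(edges))
        # every listed PPI pair appears
        for ga, gb in pipe.graph.ppi_pairs:
            if ga in fams and gb in fams:
                assert sub.graph.has_edge(ga, gb)


class TestFilterSubnetwork:
    def test_min_weight_zero_is_identity(self, nck2):
        _, pipe = nck2
        sub = extract_subnetwork(["NCK2-202", "PARTNERA-201"], pipe.store, pipe.graph)
        filtered = filter_subnetwork(sub, 0.0)
        assert set(filtered.graph.edges) == set(sub.graph.edges)

    def test_epsilon_removes_exactly_weight_zero_edges(self, bag1):
        _, pipe = bag1
        sub = extract_subnetwork(["BAG1-207", "CHAP1-201"], pipe.store, pipe.graph)
        (data,) = [d for _, _, d in sub.graph.edges(data=True)]
        assert data["weight"] == 0.0
        assert filter_subnetwork(sub, 1e-9).graph.number_of_edges() == 0

    def test_ppi_labelled_edges_never_removed(self):
        b = sf.FixtureBuilder(seed=0)
        b.add_gene("GA", [150, 93])
        b.add_isoform("GA", "GA-201", keep=[1, 2], domains=[("PF00001", 5, 40)])
        b.add_gene("GB", [150, 93])
        b.add_isoform("GB", "GB-201", keep=[1, 2], domains=[("PF00002", 5, 40)])
        b.add_ppi("GA", "GB")
        pipe = b.build().build_pipeline()
        sub = extract_subnetwork(["GA-201", "GB-201"], pipe.store, pipe.graph)
        assert filter_subnetwork(sub, 0.9).graph.number_of_edges() == 1

    def test_epsilon_filter_equals_all_or_nothing_oracle(self, scenario_fixtures, scenario_pipelines):
        """At minimum positive weight the filter reproduces the rule that a
        PPI survives iff at least one of its DDIs survives."""
        for name, fx in scenario_fixtures.items():
            pipe = scenario_pipelines[name]
            inputs = sorted(pipe.store.isoforms)
            sub = filter_subnetwork(
                extract_subnetwork(inputs, pipe.store, pipe.graph), 1e-9)
            fams = {}
            for tid in inputs:
                iso = pipe.store.isoform(tid)
                fams.setdefault(iso.gene.entrez_id, set()).update(pipe.store.pfam_set(iso))
            pair_edges = {}
            for edge in fx.manifest["joint_edges"]:
                (ga, pa), (gb, pb) = (side.split("/") for side in edge.split("|"))
                pair_edges.setdefault(tuple(sorted((ga, gb))), []).append((ga, pa, gb, pb))
            expected = set()
            for pair, edges in pair_edges.items():
                keep = False
                for ga, pa, gb, pb in edges:
                    if ga == gb:
                        keep |= pa in fams[ga] and pb in fams[ga]
                    else:
                        keep |= pa in fams[ga] and pb in fams[gb]
                if keep:
                    expected.add(pair)
            got = {tuple(sorted((u, v))) for u, v, d in sub.graph.edges(data=True)
                   if d["label"] == "PPI-DDI"}
            assert got == expected, name


class TestDeterminism:
    def test_reports_are_byte_identical_across_runs(self, tmp_path, scenario_pipelines):
        pipe = scenario_pipelines["hub_exon"]
        exon3 = pipe.store.isoform("ALK-201").exons[2].exon_id
        outputs = []
        for run in ("a", "b"):
            report = exon_report(pipe.store, pipe.graph, exon_id=exon3)
            path = tmp_path / f"exon_{run}.tsv"
            write_exon_report(report, path)
            sub = extract_subnetwork(sorted(pipe.store.isoforms), pipe.store, pipe.graph)
            spath = tmp_path / f"net_{run}.graphml"
            write_subnetwork(sub, spath)
            outputs.append((path.read_bytes(), spath.read_bytes()))
        assert outputs[0] == outputs[1]
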