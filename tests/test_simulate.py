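"""The synthetic-data generator: trees, transfers, sequences, reads."""

import json

import numpy as np
import pytest

from hgtscan.model import GTRGammaParams
from hgtscan.simulate import (Clade, Scenario, TransferEvent, generate_dataset,
                              inject_editing, panel_15, panel_33, pseudogenize,
                              revcomp, simulate_alignment,
                              simulate_chimeric_alignment, simulate_gene_tree,
                              simulate_reads, species_tree_15, species_tree_33)


def leaf_depths(clade, acc=0.0):
    if clade.is_leaf:
        return {clade.name: acc}
    out = {}
    for child in clade.children:
        out.update(leaf_depths(child, acc + (clade.age - child.age)))
    return out


def is_ultrametric(clade):
    return np.ptp(list(leaf_depths(clade).values())) < 1e-9


class TestSpeciesTrees:
    @pytest.mark.parametrize("tree,panel,n", [
        (species_tree_15(), panel_15(), 15),
        (species_tree_33(), panel_33(), 33),
    ])
    def test_panels_match_trees(self, tree, panel, n):
        assert len(tree.leaves()) == n
        assert set(tree.leaves()) == set(panel.taxa)
        assert is_ultrametric(tree)
        # every role class populated
        for role in ("outgroup", "reference", "vgt_sister", "host_clade",
                     "current_host", "parasite"):
            assert panel.with_role(role)

    def test_parasites_sister_to_their_autotroph_relative(self):
        tree = species_tree_15()
        clade = tree.find_clade({"Ricinus", "Rafflesia_A", "Rafflesia_B", "Sapria"})
        assert clade.age == 90


class TestGeneTrees:
    def test_no_event_reproduces_species_tree(self, tree15):
        gt = simulate_gene_tree(tree15, None)
        assert sorted(gt.leaves()) == sorted(tree15.leaves())
        assert leaf_depths(gt) == leaf_depths(tree15)

    def test_transfer_nests_parasite_within_hosts(self, tree15):
        ev = TransferEvent("g", frozenset({"Sapria"}),
                           frozenset({"Tetrastigma_A", "Tetrastigma_B"}), 30 / 300)
        gt = simulate_gene_tree(tree15, ev)
        clade = gt.find_clade({"Sapria", "Tetrastigma_A", "Tetrastigma_B"})
        assert clade.age == pytest.approx(30.0)
        assert is_ultrametric(gt)

    def test_transfer_older_than_host_crown_attaches_to_stem(self, tree15):
        # depth 110 is above the host-family crown (95): the parasites
        # must attach as sister to the whole host clade
        parasites = frozenset({"Rafflesia_A", "Rafflesia_B", "Sapria"})
        hosts = frozenset({"Leea", "Vitis", "Tetrastigma_A", "Tetrastigma_B"})
        gt = simulate_gene_tree(tree15, TransferEvent("g", parasites, hosts, 110 / 300))
        joint = gt.find_clade(parasites | hosts)
        assert joint.age == pytest.approx(110.0)
        assert {frozenset(c.leaves()) for c in joint.children} == {parasites, hosts}

    def test_transfer_outside_branch_interval_rejected(self, tree15):
        hosts = frozenset({"Leea", "Vitis", "Tetrastigma_A", "Tetrastigma_B"})
        with pytest.raises(ValueError, match="interval"):
            simulate_gene_tree(tree15, TransferEvent(
                "g", frozenset({"Sapria"}), hosts, 140 / 300))

    def test_recipient_older_than_transfer_rejected(self, tree15):
        parasites = frozenset({"Rafflesia_A", "Rafflesia_B", "Sapria"})
        with pytest.raises(ValueError, match="older"):
            simulate_gene_tree(tree15, TransferEvent(
                "g", parasites, frozenset({"Tetrastigma_A", "Tetrastigma_B"}),
                30 / 300))

    def test_dual_homolog_transfer_keeps_native_copy(self, tree15):
        ev = TransferEvent("g", frozenset({"Sapria"}),
                           frozenset({"Tetrastigma_A", "Tetrastigma_B"}),
                           30 / 300, displaces_native=False)
        gt = simulate_gene_tree(tree15, ev)
        assert "Sapria" in gt.leaves() and "Sapria|hgt" in gt.leaves()


class TestSequenceEvolution:
    def test_zero_branch_lengths_give_identical_rows(self, jc_params):
        t = Clade(age=0.0, children=[Clade("A"), Clade("B"), Clade("C")])
        aln = simulate_alignment(t, jc_params, 50, seed=1)
        assert len(set(aln.rows.values())) == 1

    def test_alignment_length(self, jc_params, tree15):
        aln = simulate_alignment(tree15.scale_to_substitutions(1e-3),
                                 jc_params, 321, seed=1)
        assert all(len(s) == 321 for s in aln.rows.values())

    def test_jc_closed_form_distance(self, jc_params):
        # two taxa separated by total path 0.2: expected p-distance
        # (3/4)(1 - exp(-4*0.2/3)) = 0.17555
        t = Clade(age=0.1, children=[Clade("X"), Clade("Y")])
        aln = simulate_alignment(t.scale_to_substitutions(1.0),
                                 GTRGammaParams.jc(1), 100_000, seed=4)
        x, y = aln.rows["X"], aln.rows["Y"]
        p = sum(a != b for a, b in zip(x, y)) / len(x)
        assert p == pytest.approx(0.75 * (1 - np.exp(-4 * 0.2 / 3)), abs=0.004)

    def test_base_frequencies_converge(self, sim_params):
        t = Clade(age=0.25, children=[Clade("X"), Clade("Y")])
        aln = simulate_alignment(t.scale_to_substitutions(1.0), sim_params,
                                 100_000, seed=8)
        freqs = aln.empirical_freqs()
        assert np.allclose(freqs, sim_params.base_freqs, atol=0.01)

    def test_pseudogenize_injects_internal_stop(self, rng):
        seq = "ATG" + "GCA" * 60 + "TAG"
        out = pseudogenize(seq, rng, n_stops=2)
        codons = [out[i:i + 3] for i in range(3, len(out) - 3, 3)]
        assert any(c in ("TAA", "TAG", "TGA") for c in codons)

    def test_editing_flips_genomic_c_to_cdna_t(self, rng):
        genomic = "ACCGGTTCCA" * 10
        cdna, sites = inject_editing(genomic, rng, 4)
        assert len(sites) == 4
        for pos in sites:
            assert genomic[pos - 1] == "C" and cdna[pos - 1] == "T"


class TestReads:
    def test_zero_depth_emits_nothing(self):
        rs = simulate_reads({"g": "ACGT" * 100}, {"g": 0.0}, 50, 0.0, seed=1)
        assert len(rs) == 0

    def test_poisson_read_count(self):
        rs = simulate_reads({"g": "ACGT" * 2500}, {"g": 50.0}, 100, 0.0, seed=2)
        expected = 50 * 10_000 / 100
        assert abs(len(rs) - expected) < 5 * np.sqrt(expected)

    def test_error_free_reads_are_substrings(self):
        src = "".join(np.random.default_rng(3).choice(list("ACGT"), 2000))
        rs = simulate_reads({"g": src}, {"g": 2.0}, 80, 0.0, seed=3)
        assert len(rs) > 0
        for _, read, _ in rs.reads:
            assert read in src or revcomp(read) in src

    def test_short_source_skipped(self):
        rs = simulate_reads({"short": "ACGT"}, {"short": 10.0}, 100, 0.0, seed=1)
        assert len(rs) == 0


class TestDatasets:
    def test_no_transfers_means_all_vertical(self):
        sim = generate_dataset(Scenario(n_genes=5, frac_transferred=0.0), seed=2)
        assert all(g.history == "vertical" for g in sim.truth.genes.values())

    def test_default_study_counts(self):
        sim = generate_dataset(Scenario(), seed=3)
        histories = [g.history for g in sim.truth.genes.values()]
        assert len(histories) == 20
        assert histories.count("transferred") == 8
        # truth covers every emitted gene exactly once
        assert {a.gene_id for a in sim.alignments} == set(sim.truth.genes)

    def test_same_seed_is_byte_identical(self):
        a = generate_dataset(Scenario(n_genes=4), seed=9)
        b = generate_dataset(Scenario(n_genes=4), seed=9)
        assert [x.rows for x in a.alignments] == [x.rows for x in b.alignments]
        assert {g: t.editing_sites for g, t in a.truth.genes.items()} == \
               {g: t.editing_sites for g, t in b.truth.genes.items()}

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError):
            Scenario(frac_transferred=1.5)

    def test_written_dataset_roundtrips(self, tmp_path):
        sim = generate_dataset(Scenario(n_genes=3), seed=5)
        sim.write(tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert set(truth["genes"]) == set(sim.truth.genes)
        from hgtscan.io import read_fasta
        back = read_fasta(tmp_path / "g000.fasta")
        assert back == sim.alignments[0].rows


class TestChimera:
    def test_regions_and_length(self, tree15, sim_params):
        regions = [("exonA", 0, 300), ("intronAB", 300, 600), ("exonB", 600, 900)]
        ev = TransferEvent("chim", frozenset({"Sapria"}),
                           frozenset({"Tetrastigma_A", "Tetrastigma_B"}), 30 / 300)
        aln = simulate_chimeric_alignment(tree15, ev, sim_params, 1e-3,
                                          regions, {"exonA"}, seed=1)
        assert aln.regions == regions
        assert aln.n_sites == 900
        sub = aln.region_alignment("intronAB")
        assert sub.n_sites == 300
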