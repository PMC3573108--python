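"""Copy number, expression, reading frame, editing, contamination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtscan.evidence import (check_reading_frame, compare_compartments,
                              compute_rpkm, contamination_screen,
                              detect_c2u_editing, estimate_copy_number,
                              p_distance, rpkm_from_reads, welch_t)
from hgtscan.simulate import revcomp, simulate_reads


class TestCopyNumber:
    def test_multimapping_kmer_contributes_nothing(self):
        # the same 25-mer occurs in both genes: reads of it must not count
        shared = "ACGTACGTACGTACGTACGTACGTA"
        genes = {"g1": shared + "GGGGGGGGGGGGGGGGGGGGGGGGG",
                 "g2": shared + "CCCCCCCCCCCCCCCCCCCCCCCCC"}
        records = estimate_copy_number([shared], genes, k=25)
        assert all(r.mapped_kmer_count == 0 for r in records)

    def test_single_mismatch_is_unmapped(self, rng):
        gene = "".join(rng.choice(list("ACGT"), 50))
        read = gene[:25]
        mutated = read[:10] + ("A" if read[10] != "A" else "C") + read[11:]
        recs_exact = estimate_copy_number([read], {"g": gene}, k=25)
        recs_mut = estimate_copy_number([mutated], {"g": gene}, k=25)
        assert recs_exact[0].mapped_kmer_count == 1
        assert recs_mut[0].mapped_kmer_count == 0

    def test_minus_strand_reads_map(self, rng):
        gene = "".join(rng.choice(list("ACGT"), 100))
        read = revcomp(gene[10:60])
        rec = estimate_copy_number([read], {"g": gene}, k=25)[0]
        assert rec.mapped_kmer_count == 2

    def test_depth_recovery_under_uniform_sampling(self):
        rng = np.random.default_rng(12)
        gene = "".join(rng.choice(list("ACGT"), 10_000))
        reads = simulate_reads({"g": gene}, {"g": 50.0}, 100, 0.0, seed=13)
        rec = estimate_copy_number(reads, {"g": gene}, k=25)[0]
        # each 100 bp read yields 4 unique 25-mers: expect 50*4/100 per bp
        assert rec.reads_per_bp == pytest.approx(2.0, rel=0.05)

    def test_read_order_invariance(self, rng):
        gene = "".join(rng.choice(list("ACGT"), 500))
        reads = [gene[i:i + 50] for i in (0, 100, 200, 300)]
        a = estimate_copy_number(reads, {"g": gene}, k=25)[0]
        b = estimate_copy_number(reads[::-1], {"g": gene}, k=25)[0]
        assert a.mapped_kmer_count == b.mapped_kmer_count

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            estimate_copy_number([], {"g": "ACGT"}, k=5)


class TestWelch:
    def test_identical_groups(self):
        r = compare_compartments(
            *[[type("R", (), {"reads_per_bp": v, "gene_id": "g"})()
               for v in (1.0, 2.0, 3.0)] for _ in range(2)])
        assert r.fold == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # Welch on (2,4,6) vs (1,2,3): t = (4-2)/sqrt(4/3 + 1/3) = 1.5492,
        # df = (5/3)^2 / ((4/3)^2/2 + (1/3)^2/2) = 2.9412
        r = welch_t([2, 4, 6], [1, 2, 3])
        assert r.t_statistic == pytest.approx(2 / np.sqrt(5 / 3), abs=1e-4)
        assert r.df == pytest.approx((5 / 3) ** 2 / ((16 / 9 + 1 / 9) / 2), abs=1e-4)
        assert r.fold == pytest.approx(2.0)

    def test_simulated_copy_ratio_recovery(self):
        rng = np.random.default_rng(5)
        genes, depths = {}, {}
        for i in range(20):
            genes[f"m{i}"] = "".join(rng.choice(list("ACGT"), 2000))
            depths[f"m{i}"] = 100.0
            genes[f"n{i}"] = "".join(rng.choice(list("ACGT"), 2000))
            depths[f"n{i}"] = 2.0
        reads = simulate_reads(genes, depths, 100, 0.0, seed=6)
        recs = estimate_copy_number(reads, genes, k=25)
        mito = [r for r in recs if r.gene_id.startswith("m")]
        nuc = [r for r in recs if r.gene_id.startswith("n")]
        w = compare_compartments(mito, nuc)
        assert w.fold == pytest.approx(50.0, rel=0.10)
        assert w.p_value < 1e-6


class TestRpkm:
    def test_unit_case(self):
        assert compute_rpkm({"g": 1000}, {"g": 1000}, 10 ** 6)["g"] == \
            pytest.approx(1000.0)

    def test_linearity(self):
        one = compute_rpkm({"g": 500}, {"g": 700}, 10 ** 6)["g"]
        two = compute_rpkm({"g": 1000}, {"g": 700}, 10 ** 6)["g"]
        assert two == pytest.approx(2 * one)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            compute_rpkm({"g": 10}, {"g": 0}, 100)

    def test_recovery_from_simulated_cdna(self):
        rng = np.random.default_rng(17)
        genes = {f"g{i}": "".join(rng.choice(list("ACGT"), 1500)) for i in range(5)}
        # emit reads so that g0 sits at ~500 RPKM in a 100k-read library
        total = 100_000
        target = {g: 500.0 * (i + 1) for i, g in enumerate(genes)}
        counts = {g: int(round(r * total * 1.5 / 1e6)) for g, r in target.items()}
        reads = []
        for g, n in counts.items():
            starts = rng.integers(0, 1500 - 100 + 1, n)
            reads.extend(genes[g][s:s + 100] for s in starts)
        est = rpkm_from_reads(reads, genes, total_reads=total)
        for g in genes:
            assert est[g] == pytest.approx(target[g], rel=0.10)


class TestReadingFrame:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGAAATAG", "intact"),
        ("ATGTAAAAATAG", "pseudogene"),      # internal stop
        ("ATGAAAA", "pseudogene"),           # frameshift (length % 3 != 0)
        ("ATGAAA", "intact"),                # no trailing stop required
    ])
    def test_frame_calls(self, seq, expected):
        assert check_reading_frame(seq) == expected

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            check_reading_frame("ATG#AATAG")


class TestEditing:
    def test_single_c_to_t(self):
        edited, other = detect_c2u_editing("ACGT", "ATGT")
        assert edited == [2] and other == []

    def test_identical_sequences(self):
        assert detect_c2u_editing("ACGT", "ACGT") == ([], [])

    def test_non_canonical_separated(self):
        edited, other = detect_c2u_editing("ACGA", "ATGG")
        assert edited == [2] and other == [4]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detect_c2u_editing("ACGT", "ACG")

    def test_injection_recovery_at_known_sites(self):
        # the canonical example pattern: edits at 14, 61, 153, 233
        rng = np.random.default_rng(0)
        genomic = list(rng.choice(list("AGT"), 300))
        for pos in (14, 61, 153, 233):
            genomic[pos - 1] = "C"
        genomic = "".join(genomic)
        cdna = list(genomic)
        for pos in (14, 61, 153, 233):
            cdna[pos - 1] = "T"
        edited, other = detect_c2u_editing(genomic, "".join(cdna))
        assert edited == [14, 61, 153, 233] and other == []


class TestDistancesAndContamination:
    def test_quarter_distance(self):
        assert p_distance("AAAA", "AAAT") == pytest.approx(0.25)

    def test_gaps_and_n_ignored(self):
        assert p_distance("AA-N", "AAAT") == pytest.approx(0.0)

    def test_no_comparable_sites(self):
        assert p_distance("--", "AA") is None

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60),
           st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_symmetry_and_identity(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        assert p_distance(a, b) == p_distance(b, a)
        assert (p_distance(a, b) == 0.0) == (a == b)

    def test_identical_transgene_flagged(self):
        host = "ACGTACGTACGTACGT"
        report = contamination_screen(
            {"geneX": (host, host), "geneY": (host, host[:-1] + "A")},
            {"geneX": (host, host[:-2] + "AA")})
        assert report.flagged_identical == ["geneX"]

    def test_diverged_transgenes_exceed_host_pair_distance(self, rng):
        def mutate(seq, n):
            out = list(seq)
            for pos in rng.choice(len(seq), size=n, replace=False):
                out[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[out[pos]]
            return "".join(out)

        base = "".join(rng.choice(list("ACGT"), 600))
        transgenes = {f"g{i}": (mutate(base, 25), base) for i in range(8)}
        hosts = {f"g{i}": (mutate(base, 2), base) for i in range(8)}
        report = contamination_screen(transgenes, hosts)
        assert report.mean_transgene_distance > report.mean_host_distance
        assert report.welch.p_value < 0.05
        assert report.flagged_identical == []
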