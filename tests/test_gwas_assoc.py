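import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mina import (
    GeneRecord,
    LdTable,
    MinaError,
    SnpAssociation,
    assign_snps,
    count_independent,
    dprime,
    read_gene_bed,
    read_gwas,
    replicate,
    significant_snps,
    summarize_gene,
)


def snp(snp_id, pos=1000, p=0.5, chrom="chr1"):
    return SnpAssociation(snp_id=snp_id, chrom=chrom, pos=pos, p_value=p)


GENE = GeneRecord(symbol="TNF", chrom="chr1", start=500_000, end=600_000)


class TestWindows:
    def test_100kb_upstream_snp_assigned(self):
        hits = assign_snps([GENE], [snp("rs1", pos=450_000)])
        assert [s.snp_id for s in hits["TNF"]] == ["rs1"]

    def test_one_base_outside_not_assigned(self):
        assert assign_snps([GENE], [snp("rs1", pos=399_999)])["TNF"] == []
        assert len(assign_snps([GENE], [snp("rs1", pos=400_000)])["TNF"]) == 1

    def test_downstream_boundary(self):
        assert len(assign_snps([GENE], [snp("rs1", pos=700_000)])["TNF"]) == 1
        assert assign_snps([GENE], [snp("rs1", pos=700_001)])["TNF"] == []

    def test_window_clipped_at_position_one(self):
        near_start = GeneRecord(symbol="G", chrom="chr1", start=50_000, end=60_000)
        assert near_start.window() == (1, 160_000)

    def test_overlapping_windows_share_snp(self):
        g1 = GeneRecord(symbol="A", chrom="chr1", start=100_000, end=200_000)
        g2 = GeneRecord(symbol="B", chrom="chr1", start=250_000, end=350_000)
        hits = assign_snps([g1, g2], [snp("rs1", pos=220_000)])
        assert [s.snp_id for s in hits["A"]] == ["rs1"]
        assert [s.snp_id for s in hits["B"]] == ["rs1"]

    def test_chromosome_must_match(self):
        hits = assign_snps([GENE], [snp("rs1", pos=550_000, chrom="chr2")])
        assert hits["TNF"] == []

    def test_zero_window_is_strict_containment(self):
        inside = snp("rs_in", pos=550_000)
        outside = snp("rs_out", pos=499_999)
        hits = assign_snps([GENE], [inside, outside], window_kb=0)
        assert [s.snp_id for s in hits["TNF"]] == ["rs_in"]

    def test_negative_window_rejected(self):
        with pytest.raises(MinaError):
            assign_snps([GENE], [], window_kb=-1)


class TestDprime:
    def test_perfect_coupling(self):
        assert dprime([[50, 0], [0, 50]]) == pytest.approx(1.0)

    def test_independence(self):
        assert dprime([[25, 25], [25, 25]]) == 0.0

    def test_hand_computed_example(self):
        # AB=40, Ab=10, aB=10, ab=40: pAB=.4, pA=pB=.5
        # D = .4 - .25 = .15; D>0 so Dmax = min(.5*.5, .5*.5) = .25
        assert dprime([[40, 10], [10, 40]]) == pytest.approx(0.15 / 0.25)

    def test_negative_d_branch(self):
        # AB=10, Ab=40, aB=40, ab=10: D = .1 - .25 = -.15; Dmax = .25
        assert dprime([[10, 40], [40, 10]]) == pytest.approx(0.6)

    def test_monomorphic_rejected(self):
        with pytest.raises(MinaError, match="monomorphic"):
            dprime([[50, 50], [0, 0]])

    @given(
        counts=st.lists(st.integers(1, 200), min_size=4, max_size=4)
    )
    @settings(max_examples=100, deadline=None)
    def test_always_in_unit_interval(self, counts):
        table = [[counts[0], counts[1]], [counts[2], counts[3]]]
        assert 0.0 <= dprime(table) <= 1.0 + 1e-12

    def test_from_haplotypes_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        haps = rng.integers(0, 2, size=(60, 3))
        haps[:, 2] = haps[:, 1]  # perfect LD pair
        table = LdTable.from_haplotypes(haps, ["a", "b", "c"])
        a, b = haps[:, 0], haps[:, 1]
        counts = [
            [int(((a == 1) & (b == 1)).sum()), int(((a == 1) & (b == 0)).sum())],
            [int(((a == 0) & (b == 1)).sum()), int(((a == 0) & (b == 0)).sum())],
        ]
        assert table.get("a", "b") == pytest.approx(dprime(counts))
        assert table.get("b", "c") == pytest.approx(1.0)


class TestCountIndependent:
    def test_no_ld_all_independent(self):
        snps = [snp(f"rs{i}") for i in range(5)]
        ld = LdTable({(f"rs{i}", f"rs{j}"): 0.3 for i in range(5) for j in range(i + 1, 5)})
        n, clusters = count_independent(snps, ld)
        assert n == 5
        assert len(set(clusters.values())) == 5

    def test_one_pair_linked(self):
        snps = [snp("rs1"), snp("rs2"), snp("rs3")]
        ld = LdTable({("rs1", "rs2"): 0.9, ("rs1", "rs3"): 0.1, ("rs2", "rs3"): 0.1})
        n, clusters = count_independent(snps, ld)
        assert n == 2
        assert clusters["rs1"] == clusters["rs2"] != clusters["rs3"]

    def test_single_snp(self):
        assert count_independent([snp("rs1")], LdTable())[0] == 1

    def test_threshold_inclusive(self):
        snps = [snp("rs1"), snp("rs2")]
        assert count_independent(snps, LdTable({("rs1", "rs2"): 0.8}))[0] == 1
        assert count_independent(snps, LdTable({("rs1", "rs2"): 0.7999}))[0] == 2

    def test_order_invariant(self, rng):
        ids = [f"rs{i}" for i in range(8)]
        ld = LdTable()
        for i in range(8):
            for j in range(i + 1, 8):
                ld.set(ids[i], ids[j], float(rng.uniform()))
        snps = [snp(i) for i in ids]
        base = count_independent(snps, ld)
        for _ in range(5):
            perm = [snps[k] for k in rng.permutation(8)]
            assert count_independent(perm, ld) == base

    def test_missing_pair_policy(self):
        snps = [snp("rs1"), snp("rs2")]
        assert count_independent(snps, LdTable())[0] == 2  # missing_as zero
        with pytest.raises(MinaError, match="no D'"):
            count_independent(snps, LdTable(), missing="error")

    def test_bad_threshold(self):
        with pytest.raises(MinaError):
            count_independent([snp("rs1")], LdTable(), threshold=1.5)

    def test_matches_connected_components_oracle(self, rng):
        """Transitive LD clustering equals graph connected components."""
        for _ in range(30):
            n = int(rng.integers(2, 9))
            ids = [f"rs{i}" for i in range(n)]
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
            ld = LdTable()
            for i, j in g.edges:
                ld.set(ids[i], ids[j], 0.85)
            got, _ = count_independent([snp(i) for i in ids], ld)
            assert got == nx.number_connected_components(g)


class TestSummaries:
    def test_worked_example(self):
        snps = [snp("rs1", p=0.001), snp("rs2", p=0.2), snp("rs3", p=0.04)]
        summary = summarize_gene(GENE, snps, LdTable())  # all independent
        assert summary.n_independent == 3
        assert summary.min_p_raw == pytest.approx(0.001)
        assert summary.min_p_corrected == pytest.approx(0.003)
        assert summary.n_snps_p05 == 2
        assert summary.significant

    def test_single_snp_identity(self):
        summary = summarize_gene(GENE, [snp("rs1", p=0.5)], LdTable())
        assert summary.n_independent == 1
        assert summary.min_p_corrected == pytest.approx(0.5)

    def test_correction_capped_at_one(self):
        snps = [snp(f"rs{i}", p=0.2 if i == 0 else 0.9) for i in range(10)]
        summary = summarize_gene(GENE, snps, LdTable())
        assert summary.min_p_corrected == 1.0

    def test_empty_gene_flagged_untested(self):
        summary = summarize_gene(GENE, [], LdTable())
        assert summary.n_snps_total == 0
        assert not summary.tested
        assert math.isnan(summary.min_p_raw)

    @given(n_ind_extra=st.integers(0, 10))
    @settings(max_examples=20, deadline=None)
    def test_corrected_monotone_in_independent_count(self, n_ind_extra):
        # add unlinked SNPs with large p: n_independent grows, corrected min rises
        base = [snp("rs0", p=0.01)]
        extra = [snp(f"rs{i+1}", p=0.99) for i in range(n_ind_extra)]
        s_small = summarize_gene(GENE, base, LdTable())
        s_large = summarize_gene(GENE, base + extra, LdTable())
        assert s_large.n_independent == 1 + n_ind_extra
        assert s_large.min_p_corrected >= s_small.min_p_corrected - 1e-15


class TestReplication:
    def test_single_candidate_replicates(self):
        carried = significant_snps([GENE], [snp("rs1", pos=550_000, p=0.001)], LdTable())
        table = replicate(carried, [snp("rs1", p=0.01)], LdTable())
        assert table.loc[0, "status"] == "replicated"
        assert table.loc[0, "p_replication_corrected"] == pytest.approx(0.01)

    def test_five_independent_candidates_bonferroni(self):
        snps = [snp(f"rs{i}", pos=550_000 + i, p=0.001) for i in range(5)]
        carried = significant_snps([GENE], snps, LdTable())
        assert len(carried) == 5
        second = [snp("rs0", p=0.02)]
        table = replicate(carried, second, LdTable())
        row = table.set_index("snp_id").loc["rs0"]
        assert row["m_independent"] == 5
        assert row["p_replication_corrected"] == pytest.approx(0.10)
        assert row["status"] == "not_replicated"

    def test_missing_candidate_untested(self):
        carried = significant_snps([GENE], [snp("rs1", pos=550_000, p=0.001)], LdTable())
        table = replicate(carried, [snp("rs_other", p=0.5)], LdTable())
        assert table.loc[0, "status"] == "untested"


class TestReaders:
    def test_bed_is_converted_to_one_based(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t499999\t600000\tTNF\n")
        genes = read_gene_bed(p)
        assert genes[0].start == 500_000 and genes[0].end == 600_000

    def test_gwas_reader_ignores_extra_columns(self, tmp_path):
        p = tmp_path / "gwas.tsv"
        p.write_text("SNP\tCHR\tPOS\tP\tBETA\nrs1\tchr1\t100\t0.5\t1.2\n")
        snps = read_gwas(p)
        assert snps[0].snp_id == "rs1" and snps[0].p_value == 0.5

    def test_zero_p_floored_with_warning(self, tmp_path):
        p = tmp_path / "gwas.tsv"
        p.write_text("SNP\tCHR\tPOS\tP\nrs1\tchr1\t100\t0\nrs2\tchr1\t200\t1e-8\n")
        with pytest.warns(UserWarning, match="floored"):
            snps = read_gwas(p)
        assert snps[0].p_value == pytest.approx(1e-8)

    def test_ld_tsv_round_trip(self, tmp_path):
        p = tmp_path / "ld.tsv"
        p.write_text("SNP_A\tSNP_B\tDPRIME\nrs1\trs2\t0.9\n")
        ld = LdTable.from_tsv(p)
        assert ld.get("rs2", "rs1") == 0.9  # symmetric
        assert ld.get("rs1", "rs3") == 0.0
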