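import networkx as nx
import pytest

from ceafam.errors import ContractError, StructureError
from ceafam.genes import (
    ExonModel,
    FamilyCatalog,
    GeneModel,
    aa_identity,
    call_pseudogene,
    check_splice_sites,
    cluster_n_exons,
    detect_donor_readthrough,
    p_distance,
    pair_receptors,
    read_gene_table,
    write_gene_table,
)
from ceafam.seqio import Sequence
from conftest import random_nt


def _gene(n_seq="ATGAAACCC", l_seq="ATGGCA", n_donor="GT", n_acceptor="AG",
          l_donor="GT", gene_id="g1", species="sp"):
    return GeneModel(
        gene_id=gene_id,
        species=species,
        exons=[
            ExonModel("L", l_seq, "", l_donor, 0, 0),
            ExonModel("N", n_seq, n_acceptor, n_donor, 0, 0),
        ],
    )


class TestSpliceSites:
    def test_canonical_gt_ag(self):
        rep = check_splice_sites(ExonModel("N", "AAA", "AG", "GT", 0, 0))
        assert rep.valid and rep.acceptor_valid and rep.donor_valid

    def test_mutated_donor_invalid(self):
        rep = check_splice_sites(ExonModel("A", "AAA", "AG", "AT", 0, 0))
        assert not rep.donor_valid and not rep.valid

    def test_terminal_ends_skipped(self):
        rep = check_splice_sites(ExonModel("L", "AAA", "", "GT", 0, 0))
        assert rep.valid and not rep.acceptor_checked


class TestPseudogeneCalling:
    def test_stop_in_n_exon(self):
        status, reasons = call_pseudogene(_gene(n_seq="ATGTAACCC"))
        assert status == "pseudogene"
        assert any("stop in N" in r for r in reasons)

    def test_intact_gene(self):
        status, reasons = call_pseudogene(_gene())
        assert status == "gene" and reasons == []

    def test_corrupted_leader_only_matters_in_opossum_mode(self):
        g = _gene(l_seq="ATGTGA")
        assert call_pseudogene(g, mode="default")[0] == "gene"
        assert call_pseudogene(g, mode="opossum")[0] == "pseudogene"

    def test_invalid_n_splice_site(self):
        status, _ = call_pseudogene(_gene(n_donor="AT"))
        assert status == "pseudogene"

    def test_missing_n_exon(self):
        g = GeneModel("g", "sp", [ExonModel("L", "ATG", "", "GT", 0, 0)])
        with pytest.raises(StructureError):
            call_pseudogene(g)

    def test_monotone_adding_lesion_never_rescues(self):
        # a gene already pseudogenized by a stop stays so with a splice lesion
        base = call_pseudogene(_gene(n_seq="ATGTAACCC"))[0]
        worse = call_pseudogene(_gene(n_seq="ATGTAACCC", n_donor="AT"))[0]
        assert base == worse == "pseudogene"


class TestDonorReadthrough:
    def test_two_stops_directly_after_defective_donor(self):
        # the AT|TAG|TGA pattern: codon boundary at the exon end
        exon = ExonModel("A", "ATGGCACCCAT"[:9] + "CAT", "AG", "AT", 0, 0)
        assert len(exon.sequence) % 3 == 0
        rep = detect_donor_readthrough(exon, "TAGTGACCC")
        assert rep.stop_codon_numbers == [1, 2]
        assert rep.stop_nt_offsets == [0, 3]
        assert rep.truncated and rep.product_class == "secreted-truncated"

    def test_carryover_nucleotides_shift_the_frame(self):
        # 1 leftover nt 'T' + "AA..." forms an immediate TAA stop
        exon = ExonModel("A", "ATGGCAT", "AG", "AT", 0, 0)
        rep = detect_donor_readthrough(exon, "AACCCGGG")
        assert rep.stop_codon_numbers == [1]

    def test_no_stop_within_60_nt(self):
        exon = ExonModel("A", "ATGGCACCC", "AG", "AT", 0, 0)
        rep = detect_donor_readthrough(exon, "GCA" * 30)
        assert not rep.truncated and rep.stop_codon_numbers == []

    def test_valid_donor_is_a_contract_error(self):
        exon = ExonModel("A", "ATGGCACCC", "AG", "GT", 0, 0)
        with pytest.raises(ContractError):
            detect_donor_readthrough(exon, "TAGTGA")


class TestClusterCounting:
    def test_threshold_rule_on_three_sequences(self):
        base = "A" * 200
        close = "C" + base[1:]  # 0.5%
        far = "CCCCCCCCCC" + base[10:]  # 5%
        seqs = [Sequence("a", base), Sequence("b", close), Sequence("c", far)]
        clusters, count = cluster_n_exons(seqs, threshold=0.01)
        assert count == 2
        assert sorted(map(sorted, clusters)) == [["a", "b"], ["c"]]

    def test_identical_sequences_one_cluster(self):
        seqs = [Sequence(f"s{i}", "ACGT" * 30) for i in range(4)]
        assert cluster_n_exons(seqs)[1] == 1

    def test_empty_input(self):
        assert cluster_n_exons([]) == ([], 0)

    def test_partition_equals_connected_components_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 10))
            L = 300
            seqs = [Sequence(f"s{i}", random_nt(rng, L)) for i in range(n)]
            clusters, count = cluster_n_exons(seqs, threshold=0.25)
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if p_distance(seqs[i].residues, seqs[j].residues) <= 0.25:
                        g.add_edge(i, j)
            expected = {
                frozenset(seqs[i].id for i in comp)
                for comp in nx.connected_components(g)
            }
            assert {frozenset(c) for c in clusters} == expected
            assert count == len(expected)

    def test_count_monotone_nonincreasing_in_threshold(self, rng):
        seqs = [Sequence(f"s{i}", random_nt(rng, 200)) for i in range(8)]
        counts = [
            cluster_n_exons(seqs, threshold=t)[1] for t in (0.05, 0.15, 0.3, 0.6)
        ]
        assert counts == sorted(counts, reverse=True)


class TestPairReceptors:
    def _catalog(self):
        genes = [
            GeneModel("inh", "sp", [ExonModel("N", "AAA", "AG", "GT", 0, 0)],
                      receptor_class="ITIM_ITSM"),
            GeneModel("act", "sp", [ExonModel("N", "AAA", "AG", "GT", 0, 0)],
                      receptor_class="ITAM_like"),
        ]
        return FamilyCatalog(genes=genes)

    def test_high_identity_pair_emitted(self):
        cands = pair_receptors(self._catalog(), {"inh": "M" * 50, "act": "M" * 49 + "A"})
        assert [(c.inhibitory_gene, c.activating_gene) for c in cands] == [("inh", "act")]
        assert cands[0].n_identity == pytest.approx(0.98)

    def test_identity_floor(self):
        aa = {"inh": "M" * 50, "act": "M" * 25 + "A" * 25}
        assert pair_receptors(self._catalog(), aa, identity_floor=0.80) == []

    def test_order_invariance(self):
        cat = self._catalog()
        aa = {"inh": "M" * 50, "act": "M" * 48 + "AA"}
        fwd = pair_receptors(cat, aa)
        cat.genes.reverse()
        rev = pair_receptors(cat, aa)
        assert [(c.inhibitory_gene, c.activating_gene) for c in fwd] == [
            (c.inhibitory_gene, c.activating_gene) for c in rev
        ]

    def test_pseudogenes_excluded(self):
        cat = self._catalog()
        cat.genes[1].status = "pseudogene"
        assert pair_receptors(cat, {"inh": "M" * 50, "act": "M" * 50}) == []


class TestGeneTable:
    def test_round_trip(self, tmp_path):
        g = _gene()
        g.anchor_class = "secreted"
        path = tmp_path / "genes.tsv"
        write_gene_table([g], path)
        back = read_gene_table(path)
        assert len(back) == 1
        assert back[0].gene_id == g.gene_id
        assert back[0].anchor_class == "secreted"
        assert [(e.exon_type, e.sequence) for e in back[0].exons] == [
            (e.exon_type, e.sequence) for e in g.exons
        ]

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\tspecies\ng1\tsp\n")
        with pytest.raises(StructureError):
            read_gene_table(path)


def test_aa_identity_ignores_gapped_positions():
    assert aa_identity("MK-A", "MKQA") == pytest.approx(1.0)
    assert aa_identity("MKAA", "MKQQ") == pytest.approx(0.5)
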