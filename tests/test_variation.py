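import numpy as np
import pytest

from mitoprofile.errors import AlignmentError
from mitoprofile.seq_io import AnnotatedMitogenome, FeatureRecord, MultipleAlignment
from mitoprofile.variation import (
    VariantCall,
    call_variants,
    classify_coding_effect,
    diversity_stats,
    haplotype_diversity,
    haplotype_network,
    haplotype_partition,
    incidence,
    variability_track,
)

from _oracles import diversity_oracle, mst_union_oracle


def aln_of(rows, ids=None, ref=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return MultipleAlignment(ids=ids, rows=rows, reference_id=ref or ids[0])


class TestCallVariants:
    def test_identical_rows_no_calls(self):
        assert call_variants(aln_of(["ACGT", "ACGT", "ACGT"])) == []

    def test_single_row_rejected(self):
        with pytest.raises(AlignmentError):
            call_variants(aln_of(["ACGT"]))

    def test_toy_alignment_counts_by_kind(self):
        # column 2: A/G transition; column 4: A/T transversion;
        # columns 6-7: a 2 bp gap run in one row -> one indel event
        rows = [
            "TAGCAGGT",
            "TGGCAGGT",
            "TAGCT--T",
        ]
        calls = call_variants(aln_of(rows))
        kinds = sorted(c.kind for c in calls)
        assert kinds == ["indel", "transition", "transversion"]
        indel = next(c for c in calls if c.kind == "indel")
        assert indel.aln_column == 6
        assert indel.carriers == ("s2",)

    def test_multiallelic_column_counts_once(self):
        calls = call_variants(aln_of(["AAA", "AGA", "ATA"]))
        assert len(calls) == 1
        assert set(calls[0].alt_alleles) == {"G", "T"}
        assert calls[0].kind == "transversion"  # not every pair is a transition

    def test_mixed_substitution_and_gap_column_yields_two_calls(self):
        calls = call_variants(aln_of(["CACC", "CGCC", "C-CC"]))
        assert sorted(c.kind for c in calls) == ["indel", "transition"]

    def test_insertion_relative_to_reference(self):
        calls = call_variants(aln_of(["AC--GT", "ACTAGT", "AC--GT"]))
        indel = next(c for c in calls if c.kind == "indel")
        assert indel.ref_position == 2  # anchored on the preceding reference base
        assert indel.insertion_index == 1
        assert indel.carriers == ("s0", "s2")

    def test_ref_position_maps_through_reference_gaps(self):
        rows = ["A--CGT", "ATTCGA", "A--CGA"]
        calls = call_variants(aln_of(rows))
        sub = next(c for c in calls if c.kind != "indel")
        assert sub.aln_column == 6
        assert sub.ref_position == 4  # reference row has 4 bases

    def test_region_annotation(self):
        feats = [FeatureRecord("geneA", "PCG", 1, 3, "H")]
        calls = call_variants(aln_of(["ACGTT", "AGGTT", "ACGTA"]), features=feats)
        by_col = {c.aln_column: c.region for c in calls}
        assert by_col[2] == "geneA" and by_col[5] == "intergenic"


class TestCodingEffect:
    @pytest.fixture()
    def toy(self):
        #        gene: positions 3..11, ATG GCA TAC on H strand
        seq = "TT" + "ATGGCATAC" + "AAA"
        feats = [FeatureRecord("g", "PCG", 3, 11, "H")]
        return AnnotatedMitogenome(id="t", sequence=seq, features=feats), feats

    def make_call(self, pos, ref, alt):
        return VariantCall(
            ref_position=pos, aln_column=pos, kind="transition",
            ref_allele=ref, alt_alleles=(alt,), carriers=("x",),
        )

    def test_fourfold_third_position_synonymous(self, toy):
        genome, feats = toy
        # GCA -> GCG, both alanine
        assert classify_coding_effect(self.make_call(8, "A", "G"), genome, feats) == "synonymous"

    def test_first_position_missense(self, toy):
        genome, feats = toy
        # GCA -> GTA is A -> V
        assert classify_coding_effect(self.make_call(7, "C", "T"), genome, feats) == "missense"

    def test_stop_gained_is_nonsense(self, toy):
        genome, feats = toy
        # TAC -> TAA
        assert classify_coding_effect(self.make_call(11, "C", "A"), genome, feats) == "nonsense"

    def test_outside_pcg_noncoding(self, toy):
        genome, feats = toy
        assert classify_coding_effect(self.make_call(1, "T", "C"), genome, feats) == "noncoding"

    def test_indel_is_na(self, toy):
        genome, feats = toy
        call = VariantCall(
            ref_position=5, aln_column=5, kind="indel",
            ref_allele="A", alt_alleles=("-",), carriers=("x",),
        )
        assert classify_coding_effect(call, genome, feats) == "NA"

    def test_all_single_base_codon_mutants_against_code_table(self):
        """Enumerate the 9 single-base mutants of GCA and check each class."""
        from Bio.Seq import Seq

        seq = "TT" + "ATGGCATAC" + "AAA"
        feats = [FeatureRecord("g", "PCG", 3, 11, "H")]
        genome = AnnotatedMitogenome(id="t", sequence=seq, features=feats)
        codon = "GCA"  # codon 2 of the gene, positions 6..8
        for off in range(3):
            for alt in "ACGT":
                if alt == codon[off]:
                    continue
                mutant = codon[:off] + alt + codon[off + 1 :]
                expected_aa = str(Seq(mutant).translate(table=2))
                expected = (
                    "nonsense" if expected_aa == "*"
                    else "synonymous" if expected_aa == "A"
                    else "missense"
                )
                got = classify_coding_effect(
                    self.make_call(6 + off, codon[off], alt), genome, feats
                )
                assert got == expected, (mutant, expected_aa)

    def test_l_strand_alleles_complemented(self):
        # gene on L strand: H-strand TTACATCAT reads ATG ATG TAA
        seq = "GG" + "TTACATCAT" + "CC"
        feats = [FeatureRecord("g", "PCG", 3, 11, "L")]
        genome = AnnotatedMitogenome(id="t", sequence=seq, features=feats)
        # H-strand T->C at position 8 is A->G at codon 2 pos 2: ATG -> AGG, M -> R
        call = self.make_call(8, "T", "C")
        assert classify_coding_effect(call, genome, feats) == "missense"


class TestIncidence:
    def test_printed_reference_incidence(self):
        assert incidence(54, 16_504) == (305.6, 0.33)

    def test_no_variants_reported_as_none(self):
        assert incidence(0, 100) is None

    def test_single_variant(self):
        assert incidence(1, 100) == (100.0, 1.00)


class TestDiversity:
    def test_printed_haplotype_diversity(self):
        assert haplotype_diversity([2, 1, 1, 1, 1]) == pytest.approx(0.9333, abs=5e-5)

    def test_two_rows_ten_sites_one_difference(self):
        aln = aln_of(["ACGTACGTAC", "ACGTACGTAT"])
        stats = diversity_stats(aln)
        assert stats.pi == pytest.approx(0.1)
        assert stats.k == pytest.approx(1.0)

    def test_equals_pairwise_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        rows = ["".join(rng.choice(list("ACGT-"), size=50, p=[0.24] * 4 + [0.04]))
                for _ in range(5)]
        aln = aln_of(rows)
        pi, k, variable, singleton, informative, m = diversity_oracle(rows)
        stats = diversity_stats(aln)
        assert stats.pi == pytest.approx(pi)
        assert stats.k == pytest.approx(k)
        assert stats.n_variable_sites == variable
        assert stats.n_singleton_sites == singleton
        assert stats.n_parsimony_informative_sites == informative
        assert stats.sites_considered == m
        assert stats.c_index == pytest.approx(1 - variable / m)

    def test_hd_zero_iff_single_haplotype(self):
        aln = aln_of(["ACGT", "ACGT", "ACGT"])
        assert diversity_stats(aln).hd == 0.0
        assert haplotype_diversity([7]) == 0.0

    def test_hd_invariant_to_row_order(self):
        rows = ["AAAA", "AAAT", "AATT", "AAAA"]
        a = diversity_stats(aln_of(rows)).hd
        b = diversity_stats(aln_of(rows[::-1])).hd
        assert a == pytest.approx(b)


class TestHaplotypes:
    def test_identical_rows_one_haplotype(self):
        assert len(haplotype_partition(aln_of(["ACG", "ACG"]))) == 1

    def test_gap_only_difference_merges_unless_indels_included(self):
        rows = ["AC-T", "ACGT"]
        assert len(haplotype_partition(aln_of(rows), include_indels=False)) == 1
        assert len(haplotype_partition(aln_of(rows), include_indels=True)) == 2

    def test_numbered_by_first_occurrence(self):
        part = haplotype_partition(aln_of(["AAA", "AAT", "AAA"]))
        assert part[1] == ["s0", "s2"] and part[2] == ["s1"]


class TestNetwork:
    def test_two_haplotypes_single_weighted_edge(self):
        aln = aln_of(["AAAA", "AATT"])
        net = haplotype_network(haplotype_partition(aln), aln)
        assert net.edges == [(1, 2, 2)]

    def test_three_haplotypes_path_through_light_edges(self):
        # mutual distances 1, 1, 2: the weight-2 edge is in no MST
        aln = aln_of(["AAA", "AAT", "ATT"])
        net = haplotype_network(haplotype_partition(aln), aln)
        assert sorted(net.edges) == [(1, 2, 1), (2, 3, 1)]

    def test_union_of_msts_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(5)]
        aln = aln_of(rows)
        part = haplotype_partition(aln)
        net = haplotype_network(part, aln)
        dists = {}
        hids = sorted(part)
        for i, a in enumerate(hids):
            for b in hids[i + 1 :]:
                ra = rows[aln.ids.index(part[a][0])]
                rb = rows[aln.ids.index(part[b][0])]
                dists[(a, b)] = sum(x != y for x, y in zip(ra, rb))
        assert {(a, b) for a, b, _ in net.edges} == mst_union_oracle(dists)


class TestVariabilityTrack:
    def test_no_variants_gives_conservation_one(self):
        aln = aln_of(["ACGT" * 30, "ACGT" * 30])
        windows, hvs = variability_track(aln, window=20, step=10)
        assert all(w.c_index == 1.0 for w in windows)
        assert hvs == []

    def test_planted_variant_cluster_becomes_single_hvs(self):
        rng = np.random.default_rng(9)
        base = "".join(rng.choice(list("ACGT"), size=300))
        other = list(base)
        for c in range(100, 121, 4):  # dense variants in columns 100-120
            other[c] = "A" if base[c] != "A" else "G"
        aln = aln_of([base, "".join(other)])
        windows, hvs = variability_track(aln, window=50, step=10, hvs_incidence=1 / 25)
        assert len(hvs) == 1
        start, end = hvs[0]
        assert start <= 101 and end >= 121
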