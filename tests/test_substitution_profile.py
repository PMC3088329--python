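import pytest
from hypothesis import given, settings, strategies as st

from numtsieve.seq_core import consensus
from numtsieve.substitution_profile import (
    VariableSite,
    classify_substitution,
    count_extra_stops,
    count_indel_events,
    find_variable_columns,
    gc_content,
    profile_alignment,
)
from conftest import HAND_TABLE_5, make_alignment


def site_for(codon, position, column=None, five_prime=None):
    """Build a VariableSite around one consensus codon for classification."""
    return VariableSite(
        column=column or position,
        consensus_base=codon[position - 1],
        alt_alleles=frozenset("ACGT") - {codon[position - 1]},
        codon_index=1,
        codon_position=position,
        consensus_codon=codon,
        five_prime_base=five_prime,
    )


class TestFindVariableColumns:
    def test_no_variation_gives_empty_list(self):
        aln = make_alignment(["TTATTA", "TTATTA"])
        assert find_variable_columns(aln, consensus(aln)) == []

    def test_single_third_position_site(self, toy_pair):
        cons = consensus(toy_pair)
        assert cons.residues == "TTATTA"  # tie A/G resolves to A
        sites = find_variable_columns(toy_pair, cons)
        assert len(sites) == 1
        s = sites[0]
        assert (s.column, s.consensus_base, s.codon_position) == (3, "A", 3)
        assert s.alt_alleles == frozenset("G")

    def test_ambiguity_only_deviation_not_variable(self):
        aln = make_alignment(["TTACTA", "TTACTA", "TTANTA"])
        assert find_variable_columns(aln, consensus(aln)) == []

    def test_partial_codon_columns_not_classified(self):
        # frame offset 1: column 1 precedes the first complete codon
        aln = make_alignment(["ATTATTA", "CTTATTA"], frame_offset=1)
        sites = find_variable_columns(aln, consensus(aln))
        assert len(sites) == 1
        assert sites[0].codon_position is None


class TestClassify:
    def test_synonymous_third_position_transition(self, code):
        cls = classify_substitution(site_for("TTA", 3), "G", code)
        assert cls.synonymous and cls.transition and not cls.c_to_t

    def test_nonsynonymous_first_position_transition(self, code):
        cls = classify_substitution(site_for("ATA", 1), "G", code)  # Met -> Val
        assert not cls.synonymous and cls.transition

    def test_gpc_context_c_to_t(self, code):
        site = site_for("TTC", 3, column=9, five_prime="G")
        cls = classify_substitution(site, "T", code)
        assert cls.c_to_t and cls.gc_to_gt and cls.transition and cls.synonymous

    def test_c_to_t_without_g_context(self, code):
        site = site_for("TTC", 3, column=9, five_prime="T")
        cls = classify_substitution(site, "T", code)
        assert cls.c_to_t and not cls.gc_to_gt

    def test_stop_creation_is_nonsynonymous(self, code):
        cls = classify_substitution(site_for("TTA", 2), "A", code)  # TTA -> TAA
        assert cls.creates_stop and not cls.synonymous

    def test_synonymous_flag_matches_translate_oracle_all_576_cases(self, code):
        """Exhaustive check against a hand-transcribed translation table."""
        for codon in HAND_TABLE_5:
            for position in (1, 2, 3):
                ref = codon[position - 1]
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    mutated = codon[: position - 1] + alt + codon[position:]
                    expected = HAND_TABLE_5[codon] == HAND_TABLE_5[mutated]
                    cls = classify_substitution(site_for(codon, position), alt, code)
                    assert cls.synonymous == expected, (codon, position, alt)


class TestIndelsAndStops:
    def test_gap_free_alignment_has_no_indels(self, toy_pair):
        assert count_indel_events(toy_pair, consensus(toy_pair)) == (0, 0, 0)

    def test_two_column_gap_is_one_deletion_event(self):
        aln = make_alignment(["ACTTGT", "ACTTGT", "AC--GT"])
        cons = consensus(aln)
        ins, dels, fs = count_indel_events(aln, cons)
        assert (ins, dels) == (0, 1)
        assert fs == 1  # 2 is not a multiple of 3: frameshift

    def test_minority_insertion_is_one_insertion_event(self):
        aln = make_alignment(["ACAAAGT", "AC---GT", "AC---GT"])
        cons = consensus(aln)
        assert cons.residues == "AC---GT"
        ins, dels, fs = count_indel_events(aln, cons)
        assert (ins, dels, fs) == (1, 0, 0)

    def test_no_stops_when_equal_to_consensus(self, code):
        aln = make_alignment(["TTATTG", "TTATTG"])
        assert count_extra_stops(aln, consensus(aln), code) == 0

    def test_single_change_to_stop_counts_once(self, code):
        aln = make_alignment(["TTATTA", "TTATTA", "TAATTA"])
        assert count_extra_stops(aln, consensus(aln), code) == 1

    def test_stop_shared_with_consensus_not_additional(self, code):
        aln = make_alignment(["TTATAA", "TTATAA", "TTGTAA"])
        assert count_extra_stops(aln, consensus(aln), code) == 0


class TestGCContent:
    @pytest.mark.parametrize(
        "residues,expected", [("GGCC", 100.0), ("ATAT", 0.0), ("ACGT", 50.0)]
    )
    def test_simple_compositions(self, residues, expected):
        aln = make_alignment([residues, residues])
        assert gc_content(aln) == expected

    def test_gaps_and_ambiguity_excluded(self):
        aln = make_alignment(["GC-N", "GCTN"])
        assert gc_content(aln) == pytest.approx(100 * 4 / 5)

    def test_undefined_on_no_bases(self):
        aln = make_alignment(["N-", "-N"])
        with pytest.raises(ValueError):
            gc_content(aln)


class TestProfile:
    def test_identical_sequences_zero_counts(self, code):
        aln = make_alignment(["TTATTC", "TTATTC", "TTATTC"])
        counts = profile_alignment(aln, code)
        assert counts.total == 0
        assert counts.gc_percent == pytest.approx(100 / 6)
        assert counts.n_haplotypes == 1  # collapsed

    def test_toy_pair_counts(self, code, toy_pair):
        counts = profile_alignment(toy_pair, code)
        assert (counts.total, counts.pos3, counts.ts3, counts.tv3) == (1, 1, 1, 0)
        assert counts.nonsyn == 0
        assert counts.pos1 == counts.pos2 == 0

    def test_two_alt_alleles_are_two_events(self, code):
        aln = make_alignment(["TTATTA", "TTATTA", "TTGTTA", "TTTTTA"])
        counts = profile_alignment(aln, code)
        assert counts.total == 2  # G (transition) and T (transversion) at col 3
        assert counts.ts3 == 1 and counts.tv3 == 1

    def test_duplicating_haplotypes_changes_nothing(self, code):
        base = ["TTATTACAT", "TTGTTACAT", "TTATTACGT", "TCATTACAT"]
        a = profile_alignment(make_alignment(base), code)
        b = profile_alignment(make_alignment(base + base[:2] * 3), code)
        assert a == b

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_conservation_invariants_on_random_alignments(self, code, data):
        n_seqs = data.draw(st.integers(2, 6))
        n_codons = data.draw(st.integers(4, 12))
        rows = [
            "".join(
                data.draw(st.sampled_from(["A", "C", "G", "T", "-", "N"]))
                for _ in range(3 * n_codons)
            )
            for _ in range(n_seqs)
        ]
        aln = make_alignment(rows)
        try:
            counts = profile_alignment(aln, code)
        except ValueError:
            return  # degenerate draws (all-gap, single haplotype) are out of scope
        counts.check_invariants()
        assert counts.pos1 + counts.pos2 + counts.pos3 == counts.total
        assert counts.ts3 + counts.tv3 == counts.pos3
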