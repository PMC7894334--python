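"""Alignment trimming, similarity, NG86 Ka/Ks and length summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from linfam.seqstats import (
    SeqStatsError,
    _codon_sites,
    _pathway_counts,
    ka_ks,
    length_summary,
    lineage_conservation_stats,
    pairwise_similarity,
    trim_columns,
)


class TestTrimColumns:
    def test_gap_free_alignment_unchanged(self):
        aln = {"a": "ACDE", "b": "ACDK"}
        block = trim_columns(aln)
        assert block.rows == ["ACDE", "ACDK"]
        assert block.column_index == [0, 1, 2, 3]

    def test_threshold_boundary_kept_at_exactly_0_3(self):
        # 10 rows: a column with 3 residues (0.3) is kept, 2 residues (0.2) dropped
        rows = {}
        for i in range(10):
            col_30 = "A" if i < 3 else "-"
            col_20 = "C" if i < 2 else "-"
            rows[f"s{i}"] = "M" + col_30 + col_20
        block = trim_columns(rows, gap_threshold=0.3)
        assert block.column_index == [0, 1]

    def test_threshold_zero_is_identity(self):
        aln = {"a": "A--E", "b": "-C--"}
        block = trim_columns(aln, gap_threshold=0.0)
        assert block.column_index == [0, 1, 2, 3]

    def test_threshold_above_one_drops_everything(self):
        aln = {"a": "ACDE", "b": "AC-E"}
        block = trim_columns(aln, gap_threshold=1.01)
        assert block.column_index == []

    def test_index_map_points_at_original_columns(self):
        aln = {"a": "A-C-E", "b": "A-C-E", "c": "A---E"}
        block = trim_columns(aln, gap_threshold=0.5)
        assert block.column_index == [0, 2, 4]
        assert block.rows[0] == "ACE"

    def test_empty_alignment_rejected(self):
        with pytest.raises(SeqStatsError):
            trim_columns({})


class TestPairwiseSimilarity:
    def test_identical_rows_are_100_percent(self):
        assert pairwise_similarity("ACDE", "ACDE") == 100.0

    def test_three_of_four_matches(self):
        assert pairwise_similarity("ACDE", "ACDK") == 75.0

    def test_gapped_columns_excluded_from_denominator(self):
        assert pairwise_similarity("AC-E", "ACDE") == 100.0

    def test_all_gap_overlap_is_undefined(self):
        assert pairwise_similarity("--AA", "AA--") is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(SeqStatsError):
            pairwise_similarity("AC", "ACD")

    @given(st.text(alphabet="ACDEFG-", min_size=1, max_size=40))
    @settings(max_examples=50, derandomize=True)
    def test_symmetric_and_bounded(self, row):
        rng = np.random.default_rng(len(row))
        other = "".join(rng.permutation(list(row)))
        s1 = pairwise_similarity(row, other)
        s2 = pairwise_similarity(other, row)
        assert s1 == s2
        if s1 is not None:
            assert 0.0 <= s1 <= 100.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_position_by_position_oracle(self, seed):
        rng = np.random.default_rng(seed)
        alpha = list("ACDEFGHIKL-")
        a = "".join(rng.choice(alpha, size=30))
        b = "".join(rng.choice(alpha, size=30))
        cols = [(x, y) for x, y in zip(a, b) if x not in "-." and y not in "-."]
        expected = (
            None if not cols else 100.0 * sum(x == y for x, y in cols) / len(cols)
        )
        assert pairwise_similarity(a, b) == expected


def oracle_pathway_counts(codon_a, codon_b):
    """Independent recursive enumeration of substitution pathways.

    Walks every order of the differing positions depth-first, classifying
    each step; pathways through stop codons are dropped unless all are.
    """
    from linfam.seqstats import _CODON_TABLE

    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    complete = []

    def walk(current, remaining, syn, nonsyn, through_stop):
        if not remaining:
            complete.append((syn, nonsyn, through_stop))
            return
        for pos in remaining:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            step_syn = _CODON_TABLE[nxt] == _CODON_TABLE[current]
            walk(
                nxt,
                [p for p in remaining if p != pos],
                syn + step_syn,
                nonsyn + (not step_syn),
                through_stop or _CODON_TABLE[nxt] == "*",
            )

    walk(codon_a, diffs, 0, 0, False)
    clean = [(s, n) for s, n, stop in complete if not stop]
    use = clean if clean else [(s, n) for s, n, _ in complete]
    return sum(s for s, _ in use) / len(use), sum(n for _, n in use) / len(use)


class TestKaKs:
    def test_identical_cds_zero_rates_undefined_ratio(self):
        result = ka_ks("TTTGGG", "TTTGGG")
        assert result.ka == 0.0 and result.ks == 0.0
        assert result.ratio is None and "ks_zero" in result.flags

    def test_single_synonymous_difference(self):
        # ten codons, one Phe->Phe change: purely synonymous
        a = "TTT" + "GGGACTCCCATGGCAGAAGTATGTCAT"
        b = "TTC" + "GGGACTCCCATGGCAGAAGTATGTCAT"
        result = ka_ks(a, b)
        assert result.syn_diffs == 1.0 and result.nonsyn_diffs == 0.0
        assert result.ka == 0.0 and result.ks > 0.0

    def test_internal_stop_names_codon_index(self):
        with pytest.raises(SeqStatsError, match="codon index 1"):
            ka_ks("TTTTAAGGG", "TTTTACGGG")

    def test_frame_violation_rejected(self):
        with pytest.raises(SeqStatsError, match="divisible by 3"):
            ka_ks("TTTG", "TTTG")

    def test_trailing_stop_codon_ignored(self):
        r1 = ka_ks("TTTGGGTAA", "TTCGGGTGA")
        r2 = ka_ks("TTTGGG", "TTCGGG")
        assert (r1.syn_diffs, r1.nonsyn_diffs) == (r2.syn_diffs, r2.nonsyn_diffs)

    @pytest.mark.parametrize(
        "codon,expected_syn",
        [
            ("TTT", 1 / 3),  # Phe: only third-position TTC is synonymous
            ("CTT", 1.0),  # Leu: fourfold degenerate third position
            ("TGG", 0.0),  # Trp: no synonymous change (TGA is a stop)
            ("ATG", 0.0),  # Met
        ],
    )
    def test_synonymous_site_fractions_match_hand_counts(self, codon, expected_syn):
        syn, nonsyn = _codon_sites(codon)
        assert syn == pytest.approx(expected_syn)
        assert syn + nonsyn == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_pathway_counts_match_recursive_oracle_on_30_codon_pairs(self, seed):
        from linfam.simulate import _NON_STOP

        rng = np.random.default_rng(seed)
        codons_a = rng.choice(_NON_STOP, size=30)
        codons_b = rng.choice(_NON_STOP, size=30)
        for ca, cb in zip(codons_a, codons_b):
            assert _pathway_counts(ca, cb) == pytest.approx(
                oracle_pathway_counts(ca, cb)
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_independent_reference_implementation(self, seed):
        """Cross-check against biopython's NG86 on mutated 200-codon pairs;
        small tolerance covers differing stop-pathway conventions."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        from linfam.seqstats import _CODON_TABLE
        from linfam.simulate import _NON_STOP

        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(_NON_STOP, size=200))
        b = list(a)
        for _ in range(60):
            p = int(rng.integers(len(b)))
            base = "ACGT"[int(rng.integers(4))]
            cand = list(b)
            cand[p] = base
            codon = "".join(cand[p - p % 3 : p - p % 3 + 3])
            if _CODON_TABLE[codon] != "*":
                b = cand
        b = "".join(b)
        mine = ka_ks(a, b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        assert mine.ka == pytest.approx(dn, abs=0.01)
        assert mine.ks == pytest.approx(ds, abs=0.01)


class TestLengthSummary:
    def test_single_sequence(self):
        s = length_summary({"x": "M" * 10})
        assert (s.n, s.min, s.max, s.median) == (1, 10, 10, 10.0)

    def test_even_n_median_is_mean_of_central_pair(self):
        s = length_summary([10, 20, 30, 40])
        assert s.median == 25.0

    def test_short_count_strictly_below_threshold(self):
        s = length_summary([99, 100, 101], short_threshold=100)
        assert s.n_short == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sort_based_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lengths = list(rng.integers(10, 600, size=int(rng.integers(1, 40))))
        s = length_summary(lengths)
        ordered = sorted(lengths)
        n = len(ordered)
        expected_median = (
            ordered[n // 2]
            if n % 2
            else (ordered[n // 2 - 1] + ordered[n // 2]) / 2
        )
        assert (s.min, s.max) == (ordered[0], ordered[-1])
        assert s.median == expected_median

    def test_empty_rejected(self):
        with pytest.raises(SeqStatsError):
            length_summary([])


class TestLineageConservation:
    def test_identical_members_full_similarity(self):
        from linfam.lineages import delineate_lineages
        from linfam.io import CladeMap
        from linfam.trees import read_gene_tree

        tree = read_gene_tree("((x_A1:1,y_B1:1)90:1,z_D1:1);")
        cm = CladeMap({"A1": "A", "B1": "B", "D1": "D"})
        part = delineate_lineages(tree, cm)
        aln = {part.lineages[0].lineage_id: {"x_A1": "MKLV", "y_B1": "MKLV", "z_D1": "MKLV"}}
        stats = lineage_conservation_stats(part, aln)
        assert stats.iloc[0]["median_similarity"] == 100.0
        assert stats.iloc[0]["conserved_len"] == 4

    def test_single_member_lineage_has_undefined_similarity(self):
        from linfam.lineages import delineate_lineages
        from linfam.io import CladeMap
        from linfam.trees import read_gene_tree

        tree = read_gene_tree("((x_A1:1,y_B1:1)90:1,z_D1:1);")
        cm = CladeMap({"A1": "A", "B1": "B", "D1": "D"})
        part = delineate_lineages(tree, cm)
        aln = {part.lineages[0].lineage_id: {"x_A1": "MKLV"}}
        stats = lineage_conservation_stats(part, aln)
        assert stats.iloc[0]["median_similarity"] is None
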