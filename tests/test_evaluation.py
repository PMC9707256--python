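import math
from itertools import combinations

import numpy as np
import pytest

from coessnet import (PathwayReference, load_gmt, write_gmt, filter_reference,
                      lls_score, lls_profile, recall_at_lls, complex_pairs,
                      pcc_all_pairs, SyntheticSpec, generate,
                      generate_reference)
from coessnet.evaluation import LLSProfile


@pytest.fixture
def p1p2_reference():
    """The two-pathway worked reference: P1={A,B,C,D}, P2={E,F}."""
    ref = PathwayReference(pathways={"P1": frozenset("ABCD"),
                                     "P2": frozenset("EF")})
    return filter_reference(ref, min_size=2, max_size=400)


def brute_force_lls(pairs, ref):
    """Independent nested-loop oracle for the log-likelihood score."""
    tp = fp = 0
    for a, b in set(map(frozenset, pairs)):
        a, b = sorted((a, b))
        in_a = {n for n, g in ref.pathways.items() if a in g}
        in_b = {n for n, g in ref.pathways.items() if b in g}
        if not in_a or not in_b:
            continue
        if in_a & in_b:
            tp += 1
        else:
            fp += 1
    annotated = sorted(ref.annotated_genes)
    bp = bn = 0
    for a, b in combinations(annotated, 2):
        shared = any(a in g and b in g for g in ref.pathways.values())
        if shared:
            bp += 1
        else:
            bn += 1
    tp_f, fp_f = float(tp), float(fp)
    if tp == 0 or fp == 0:
        tp_f += 0.5
        fp_f += 0.5
    return math.log2((tp_f / fp_f) / (bp / bn)), tp, fp, tp + fp


class TestGmt:
    def test_two_line_file(self, tmp_path):
        p = tmp_path / "ref.gmt"
        p.write_text("P1\tdesc\tA\tB\tC\nP2\tdesc\tD\tE\n")
        ref = load_gmt(p)
        assert set(ref.pathways) == {"P1", "P2"}
        assert ref.pathways["P1"] == frozenset("ABC")
        assert not ref.filtered

    def test_duplicate_gene_within_line_stored_once(self, tmp_path):
        p = tmp_path / "ref.gmt"
        p.write_text("P1\tdesc\tA\tA\tB\nP2\tdesc\tC\tD\n")
        assert load_gmt(p).pathways["P1"] == frozenset("AB")

    def test_short_line_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "ref.gmt"
        p.write_text("P1\tdesc\tA\tB\nBROKEN\nP2\tdesc\tC\tD\n")
        with caplog.at_level("WARNING"):
            ref = load_gmt(p)
        assert set(ref.pathways) == {"P1", "P2"}
        assert any("skipping" in r.message for r in caplog.records)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "ref.gmt"
        p.write_text("")
        with pytest.raises(ValueError):
            load_gmt(p)

    def test_write_read_round_trip(self, tmp_path):
        ref = PathwayReference(pathways={"P1": frozenset("ABCDE"),
                                         "P2": frozenset("FGHIJ")})
        p = tmp_path / "out.gmt"
        write_gmt(ref, p)
        assert load_gmt(p).pathways == ref.pathways


class TestFilterReference:
    def test_size_filter_removes_small_pathway(self):
        ref = PathwayReference(pathways={"SMALL": frozenset("ABCD"),
                                         "OK": frozenset("ABCDE")})
        out = filter_reference(ref, min_size=5)
        assert set(out.pathways) == {"OK"}

    def test_exclusion_term_matches_substring_case_insensitively(self):
        ref = PathwayReference(pathways={
            "Mitochondrial translation initiation": frozenset("ABCDE"),
            "DNA repair": frozenset("FGHIJ"),
            "Translation": frozenset("KLMNO")})
        out = filter_reference(ref, min_size=2,
                               exclude=["mitochondrial translation"])
        assert set(out.pathways) == {"DNA repair", "Translation"}

    def test_worked_background_counts(self, p1p2_reference):
        # 6 annotated genes -> C(6,2)=15 pairs; within-pathway: C(4,2)+C(2,2-ish)=6+1
        assert p1p2_reference.background_pos == 7
        assert p1p2_reference.background_neg == 8

    def test_all_removed_errors(self):
        ref = PathwayReference(pathways={"P": frozenset("AB")})
        with pytest.raises(ValueError, match="removed"):
            filter_reference(ref, min_size=5)

    def test_overlapping_pathways_background_not_double_counted(self):
        ref = PathwayReference(pathways={"P1": frozenset("ABC"),
                                         "P2": frozenset("BCD")})
        out = filter_reference(ref, min_size=2)
        # pairs sharing a pathway: AB, AC, BC (x2 -> once), BD, CD = 5
        assert out.background_pos == 5
        assert out.background_neg == 1  # only AD


class TestLlsScore:
    def test_worked_example(self, p1p2_reference):
        lls, tp, fp, counted = lls_score([("A", "B"), ("E", "F"), ("A", "E")],
                                         p1p2_reference)
        assert (tp, fp, counted) == (2, 1, 3)
        assert lls == pytest.approx(math.log2(16 / 7), abs=1e-12)
        assert lls == pytest.approx(1.193, abs=1e-3)

    def test_background_ratio_sample_scores_zero(self):
        ref = PathwayReference(pathways={"P1": frozenset("AB"),
                                         "P2": frozenset("CD")})
        ref = filter_reference(ref, min_size=2)
        # background: pos = {AB, CD} = 2, neg = 4 -> odds 1/2.
        # sample with 1 TP and 2 FP has the same odds -> LLS = 0
        lls, *_ = lls_score([("A", "B"), ("A", "C"), ("B", "D")], ref)
        assert lls == pytest.approx(0.0, abs=1e-12)

    def test_unannotated_pair_not_counted_and_all_unannotated_errors(
            self, p1p2_reference):
        lls_all, *_ , counted = lls_score([("A", "B"), ("A", "G")],
                                          p1p2_reference)
        assert counted == 1
        with pytest.raises(ValueError, match="no annotated"):
            lls_score([("A", "G")], p1p2_reference)

    def test_duplicate_pair_counted_once(self, p1p2_reference):
        _, tp, fp, counted = lls_score(
            [("A", "B"), ("B", "A"), ("A", "E")], p1p2_reference)
        assert (tp, fp, counted) == (1, 1, 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_random_references(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(20)]
        pathways = {f"P{k}": frozenset(rng.choice(genes, size=rng.integers(3, 7),
                                                  replace=False))
                    for k in range(4)}
        ref = filter_reference(PathwayReference(pathways=pathways), min_size=2)
        annotated = sorted(ref.annotated_genes)
        pairs = [tuple(rng.choice(genes, size=2, replace=False))
                 for _ in range(20)]
        pairs += [tuple(rng.choice(annotated, size=2, replace=False))
                  for _ in range(10)]
        expected = brute_force_lls(pairs, ref)
        got = lls_score(pairs, ref)
        assert got[1:] == expected[1:]
        assert got[0] == pytest.approx(expected[0], abs=1e-12)


class TestLlsProfile:
    @pytest.fixture
    def module_profile(self):
        m, truth = generate(SyntheticSpec(seed=2))
        ref = filter_reference(generate_reference(truth), min_size=5)
        ranking = pcc_all_pairs(m)
        return lls_profile(ranking, ref, top_n=5000, bin_size=1000), ranking, ref

    def test_bin_count_and_first_bin_identity(self, module_profile):
        profile, _, _ = module_profile
        assert profile.n_bins == 5
        assert profile.cumulative_lls[0] == profile.local_lls[0]

    def test_cumulative_unique_genes_nondecreasing(self, module_profile):
        profile, _, _ = module_profile
        assert (np.diff(profile.cumulative_unique_genes) >= 0).all()

    def test_pooled_bins_equal_last_cumulative(self, module_profile):
        profile, ranking, ref = module_profile
        pooled, *_ = lls_score(ranking.edges.iloc[:5000][["gene_a", "gene_b"]]
                               .itertuples(index=False), ref)
        assert pooled == pytest.approx(profile.cumulative_lls[-1], abs=1e-12)

    def test_early_bins_enriched_over_late_bins(self, module_profile):
        profile, _, _ = module_profile
        assert profile.local_lls[0] > np.nan_to_num(profile.local_lls[-1],
                                                    nan=-np.inf) or \
            math.isnan(profile.local_lls[-1])

    def test_empty_bin_local_is_nan(self):
        # reference annotating only 12 background genes: their 66 pairs are
        # scattered through the ranking, so some bins contain none of them
        m, truth = generate(SyntheticSpec(seed=3))
        genes = m.gene_ids
        ref = filter_reference(PathwayReference(pathways={
            "P1": frozenset(genes[300:306]),
            "P2": frozenset(genes[306:312])}), min_size=2)
        ranking = pcc_all_pairs(m)
        profile = lls_profile(ranking, ref, top_n=20000, bin_size=1000)
        assert np.isnan(profile.local_lls).any()
        assert not np.isnan(profile.cumulative_lls[-1])

    def test_insufficient_ranking_errors(self, small_matrix, p1p2_reference):
        r = pcc_all_pairs(small_matrix)
        with pytest.raises(ValueError, match="pairs"):
            lls_profile(r, p1p2_reference, top_n=1000, bin_size=100)


class TestRecallAtLls:
    @pytest.fixture
    def decreasing_profile(self):
        n = 30
        cumulative = np.linspace(8.0, 2.0, n)  # crosses 4.8 between bins
        return LLSProfile(bin_size=1000,
                          cumulative_lls=cumulative,
                          local_lls=cumulative.copy(),
                          counted_pairs=np.full(n, 100),
                          cumulative_unique_genes=np.arange(50, 50 + n))

    def test_threshold_below_everything_returns_full_network(
            self, decreasing_profile):
        n_pairs, n_genes = recall_at_lls(decreasing_profile, 0.0)
        assert n_pairs == 30 * 1000
        assert n_genes == 79

    def test_threshold_above_everything_returns_zero(self, decreasing_profile):
        assert recall_at_lls(decreasing_profile, 100.0) == (0, 0)

    def test_crossing_profile_returns_last_qualifying_bin(
            self, decreasing_profile):
        # cumulative_lls[i] = 8 - 6i/29 >= 4.8  <=>  i <= 15.47 -> bin 16
        n_pairs, n_genes = recall_at_lls(decreasing_profile, 4.8)
        assert n_pairs == 16 * 1000
        assert n_genes == 50 + 15


class TestComplexPairs:
    def test_hand_enumerated_pairs(self, tmp_path):
        p = tmp_path / "complexes.txt"
        p.write_text("ComplexID,genenames\nC1,A B C\nC2,B C D\n")
        pairs = complex_pairs(p)
        assert set(pairs) == {("A", "B"), ("A", "C"), ("B", "C"),
                              ("B", "D"), ("C", "D")}

    def test_single_member_complex_contributes_nothing(self, tmp_path):
        p = tmp_path / "complexes.txt"
        p.write_text("ComplexID,genenames\nC1,A\nC2,B C\n")
        assert complex_pairs(p) == [("B", "C")]

    def test_empty_gene_field_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "complexes.txt"
        p.write_text("ComplexID,genenames\nC1,\nC2,A B\n")
        with caplog.at_level("WARNING"):
            pairs = complex_pairs(p)
        assert pairs == [("A", "B")]
        assert any("skipping" in r.message for r in caplog.records)

    def test_missing_gene_column_errors(self, tmp_path):
        p = tmp_path / "complexes.txt"
        p.write_text("id,members\nC1,A B\n")
        with pytest.raises(ValueError, match="gene"):
            complex_pairs(p)
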