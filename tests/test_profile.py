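import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_pair
from planaflex.io import RunConfig
from planaflex.profile import (MatchProfile, UndefinedRatioError, build_pairs,
                               classify_columns, filter_pairs,
                               identical_match_ratio, pairs_to_table)
from planaflex.synth import SubstitutionSpectrum, simulate_homolog_pair


class TestClassifyColumns:
    @pytest.mark.parametrize("a,b,expected", [
        ("A", "A", (1, 0, 0, 0)),   # identical
        ("K", "R", (0, 1, 0, 0)),   # BLOSUM62(K,R) = +2 -> homologous
        ("L", "D", (0, 0, 1, 0)),   # BLOSUM62(L,D) = -4 -> mismatch
        ("A", "-", (0, 0, 0, 1)),   # gap column
        ("X", "X", (0, 0, 1, 0)),   # X never counts as identical
        ("*", "*", (0, 0, 1, 0)),   # stops are not residues
    ])
    def test_single_columns(self, a, b, expected):
        prof = classify_columns(a, b)
        assert (prof.i, prof.h, prof.m, prof.g) == expected

    def test_worked_gap_example(self):
        prof = classify_columns("AC-D", "ACED")
        assert (prof.i, prof.h, prof.m, prof.g) == (3, 0, 0, 1)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            classify_columns("AA", "A")

    def test_double_gap_column_rejected(self):
        with pytest.raises(ValueError, match="both rows"):
            classify_columns("A-A", "A-A")

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from("ARNDCQEGHILKMFPSTWYVX*-"),
                              st.sampled_from("ARNDCQEGHILKMFPSTWYVX*-")),
                    min_size=1, max_size=40))
    def test_exhaustive_and_symmetric(self, cols):
        cols = [(a, b) for a, b in cols if not (a == "-" and b == "-")]
        if not cols:
            return
        qa = "".join(a for a, _ in cols)
        sb = "".join(b for _, b in cols)
        prof = classify_columns(qa, sb)
        assert prof.n_columns == len(cols)
        swapped = classify_columns(sb, qa)
        assert (prof.i, prof.h, prof.m, prof.g) == \
            (swapped.i, swapped.h, swapped.m, swapped.g)
        assert prof.region_len_nt == 3 * (prof.i + prof.h + prof.m)


class TestRatio:
    @pytest.mark.parametrize("i,h,expected", [(10, 0, 1.0), (0, 5, 0.0)])
    def test_extremes(self, i, h, expected):
        assert identical_match_ratio(MatchProfile(i, h, 0, 0)) == expected

    def test_worked_example_two_decimal_display(self):
        ratio = identical_match_ratio(MatchProfile(18, 5, 0, 0))
        assert ratio == pytest.approx(18 / 23)
        assert f"{ratio:.2f}" == "0.78"

    def test_undefined_without_i_or_h(self):
        with pytest.raises(UndefinedRatioError):
            identical_match_ratio(MatchProfile(0, 0, 4, 1))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 500), st.integers(0, 500))
    def test_bounds_and_monotonicity(self, i, h):
        if i + h == 0:
            return
        r = identical_match_ratio(MatchProfile(i, h, 0, 0))
        assert 0 <= r <= 1
        assert (r == 1) == (h == 0)
        if h > 0 and i > 0:
            worse = identical_match_ratio(MatchProfile(i, h + 1, 0, 0))
            assert worse < r


class TestFilterCascade:
    def config(self):
        return RunConfig()  # published thresholds: 600 / 1e-30 / 80

    def test_boundary_values_retained(self):
        boundary = make_pair(i=27, h=0, m=0, g=0, evalue=1e-30, query_len_nt=600)
        retained, _ = filter_pairs([boundary], self.config())
        assert retained == [boundary]
        assert boundary.profile.region_len_nt == 81  # 27 residues -> >= 80 nt

    @pytest.mark.parametrize("kwargs,reason", [
        (dict(query_len_nt=599), "query_length"),
        (dict(evalue=1e-29), "evalue"),
        (dict(i=26, h=0, m=0, g=0), "region_length"),  # 78 nt < 80
    ])
    def test_each_criterion_rejects(self, kwargs, reason):
        pair = make_pair(**{**dict(i=27, h=0, m=0, g=0, evalue=1e-30,
                                   query_len_nt=600), **kwargs})
        retained, report = filter_pairs([pair], self.config())
        assert retained == [] and reason in pair.fail_reasons
        assert report.set_index("criterion").loc[reason, "removed"] == 1

    def test_retained_set_matches_independent_conjunction_scan(self, rng):
        pairs = []
        for k in range(200):
            pairs.append(make_pair(
                query_id=f"q{k}",
                i=int(rng.integers(5, 60)), h=int(rng.integers(0, 20)),
                m=int(rng.integers(0, 10)), g=int(rng.integers(0, 5)),
                evalue=float(10.0 ** -rng.integers(10, 60)),
                query_len_nt=int(rng.integers(300, 1200))))
        cfg = self.config()
        retained, report = filter_pairs(pairs, cfg)
        # independent re-scan of the conjunction
        expected = [p for p in pairs
                    if p.query_len_nt >= 600 and p.alignment.evalue <= 1e-30
                    and p.profile.region_len_nt >= 80]
        assert retained == expected
        assert report.removed.sum() == len(pairs)  # removed + retained


class TestBuildPairs:
    def test_queries_find_their_true_homologs_among_decoys(self, desk_config, rng):
        spectrum = SubstitutionSpectrum(0.8, 0.1, 0.1, length_codons=60)
        queries, subjects = [], []
        for g in range(6):
            q, s, _, _ = simulate_homolog_pair(spectrum, 100 + g, f"gene{g}")
            queries.append(q)
            subjects.append(s)
        # unrelated decoy subjects
        for d in range(4):
            _, s, _, _ = simulate_homolog_pair(spectrum, 900 + d, f"decoy{d}")
            subjects.append(s)
        pairs = build_pairs(queries, subjects, config=desk_config)
        assert {p.query_id: p.subject_id for p in pairs} == \
            {f"gene{g}|q": f"gene{g}|s" for g in range(6)}
        table = pairs_to_table(pairs)
        assert set(table.columns) >= {"query_id", "ratio", "passed", "region_nt"}

    def test_all_decoys_yield_no_retained_pairs(self, desk_config):
        spectrum = SubstitutionSpectrum(1.0, 0.0, 0.0, length_codons=60)
        q, _, _, _ = simulate_homolog_pair(spectrum, 1, "real")
        _, s, _, _ = simulate_homolog_pair(spectrum, 2, "other")
        pairs = build_pairs([q], [s], config=desk_config)
        assert [p for p in pairs if p.passed_filters] == []

    def test_empty_input_rejected(self, desk_config):
        with pytest.raises(ValueError):
            build_pairs([], [], config=desk_config)

    def test_column_counts_symmetric_on_gap_free_pairs(self, desk_config):
        spectrum = SubstitutionSpectrum(0.7, 0.2, 0.1, length_codons=80)
        q, s, _, _ = simulate_homolog_pair(spectrum, 42, "g")
        fwd = build_pairs([q], [s], config=desk_config)[0]
        rev = build_pairs([s], [q], config=desk_config)[0]
        assert (fwd.profile.i, fwd.profile.h, fwd.profile.m) == \
            (rev.profile.i, rev.profile.h, rev.profile.m)
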