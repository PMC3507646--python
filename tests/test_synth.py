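import numpy as np
import pytest

from planaflex.align import DEFAULT_SCHEME, six_frame_translate
from planaflex.profile import classify_columns
from planaflex.synth import (SubstitutionSpectrum, conservative_partners,
                             radical_partners, simulate_est_collection,
                             simulate_function_panel, simulate_homolog_pair,
                             simulate_target_datasets,
                             true_alignment_from_log)


class TestSpectrum:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SubstitutionSpectrum(0.5, 0.4, 0.2)

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            SubstitutionSpectrum(1.0, 0.0, 0.0, length_codons=10)

    def test_expected_ratio(self):
        assert SubstitutionSpectrum(0.6, 0.2, 0.2).expected_ratio == \
            pytest.approx(0.75)


class TestPartnerSets:
    def test_cysteine_glycine_proline_have_no_conservative_partner(self):
        partners = conservative_partners(DEFAULT_SCHEME)
        empty = {aa for aa, p in partners.items() if not p}
        assert empty == {"C", "G", "P"}

    def test_every_residue_has_radical_partners(self):
        assert all(radical_partners(DEFAULT_SCHEME).values())


class TestHomologPair:
    def test_pure_identity_spectrum_gives_identical_proteins(self):
        spectrum = SubstitutionSpectrum(1.0, 0.0, 0.0, length_codons=50)
        q, s, expected, _ = simulate_homolog_pair(spectrum, 3)
        assert expected == 1.0
        assert six_frame_translate(q.seq)[1] == six_frame_translate(s.seq)[1]

    def test_no_internal_stops_in_either_sequence(self):
        spectrum = SubstitutionSpectrum(0.4, 0.3, 0.3, length_codons=200)
        q, s, _, _ = simulate_homolog_pair(spectrum, 5)
        assert "*" not in six_frame_translate(q.seq)[1]
        assert "*" not in six_frame_translate(s.seq)[1]

    def test_site_log_audit_radical_and_conservative_scores(self):
        spectrum = SubstitutionSpectrum(0.6, 0.2, 0.2, length_codons=300)
        _, _, _, log = simulate_homolog_pair(spectrum, 11)
        for event in log:
            score = DEFAULT_SCHEME.score(event.aa_query, event.aa_subject)
            if event.kind == "radical":
                assert score <= 0
            elif event.kind == "conservative":
                assert score > 0 and event.aa_query != event.aa_subject
            elif event.kind == "identical":
                assert event.aa_query == event.aa_subject

    def test_binomial_recovery_on_true_alignment(self):
        """Column classification of the generating alignment recovers the
        planted ratio within 3 binomial standard errors."""
        spectrum = SubstitutionSpectrum(0.5, 0.5, 0.0, length_codons=300)
        total_i = total_ih = 0
        for seed in range(20):
            _, _, _, log = simulate_homolog_pair(spectrum, seed)
            prof = classify_columns(*true_alignment_from_log(log))
            total_i += prof.i
            total_ih += prof.i + prof.h
        p_hat = total_i / total_ih
        se = np.sqrt(0.5 * 0.5 / total_ih)
        assert abs(p_hat - 0.5) <= 3 * se

    def test_classification_matches_site_log_exactly(self):
        """Generator oracle: classify_columns on the true alignment equals
        the logged event counts for 100 seeded pairs."""
        spectrum = SubstitutionSpectrum(0.6, 0.25, 0.15, indel_rate=0.02,
                                        length_codons=60)
        for seed in range(100):
            _, _, _, log = simulate_homolog_pair(spectrum, seed)
            prof = classify_columns(*true_alignment_from_log(log))
            kinds = [e.kind for e in log]
            assert prof.i == kinds.count("identical")
            assert prof.h == kinds.count("conservative")
            assert prof.m == kinds.count("radical")
            assert prof.g == kinds.count("insertion") + kinds.count("deletion")

    def test_deterministic_given_seed(self):
        spectrum = SubstitutionSpectrum(0.7, 0.2, 0.1, length_codons=40)
        a = simulate_homolog_pair(spectrum, 99)
        b = simulate_homolog_pair(spectrum, 99)
        assert a[0].seq == b[0].seq and a[1].seq == b[1].seq


class TestFunctionPanel:
    def test_single_function_rejected(self, two_function_spectra):
        only = {"metabolism": two_function_spectra["metabolism"]}
        with pytest.raises(ValueError, match="2 functions"):
            simulate_function_panel(5, only, 0)

    def test_truth_labels_differ(self, two_function_spectra):
        *_, truth = simulate_function_panel(5, two_function_spectra, 0)
        assert truth.high_substitution_functions == {"metabolism"}


class TestTargetDatasets:
    def test_unknown_gene_in_plan_rejected(self):
        spectrum = SubstitutionSpectrum(1.0, 0.0, 0.0, length_codons=30)
        gene, _, _, _ = simulate_homolog_pair(spectrum, 0, "g0")
        with pytest.raises(ValueError, match="unknown gene"):
            simulate_target_datasets([gene], {"d1": {"nope"}}, 0, seed=1)

    def test_empty_dataset_accepted(self):
        spectrum = SubstitutionSpectrum(1.0, 0.0, 0.0, length_codons=30)
        gene, _, _, _ = simulate_homolog_pair(spectrum, 0, "g0")
        datasets, truth = simulate_target_datasets(
            [gene], {"d1": set()}, decoy_count=0, seed=1)
        assert datasets["d1"] == []
        assert truth.presence[(gene.id, "d1")] is False

    def test_genome_like_fragments_homologs(self):
        spectrum = SubstitutionSpectrum(1.0, 0.0, 0.0, length_codons=80)
        gene, _, _, _ = simulate_homolog_pair(spectrum, 0, "g0")
        datasets, _ = simulate_target_datasets(
            [gene], {"d1": {gene.id}}, decoy_count=0, seed=1,
            genome_like={"d1"})
        (rec,) = datasets["d1"]
        assert len(rec.seq) > len(gene.seq)  # spacer inserted


class TestEstCollection:
    def test_singleton_clusters(self):
        records, truth = simulate_est_collection(10, [1] * 10, 0)
        assert len(records) == 10
        assert len(set(truth.cluster_of_est.values())) == 10

    def test_sizes_below_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_est_collection(2, [1, 0], 0)

    def test_byte_identical_across_runs(self):
        a, _ = simulate_est_collection(5, [3, 1, 2, 1, 4], 123)
        b, _ = simulate_est_collection(5, [3, 1, 2, 1, 4], 123)
        assert [(r.id, r.seq) for r in a] == [(r.id, r.seq) for r in b]

    def test_ests_within_one_percent_of_exemplar(self):
        records, truth = simulate_est_collection(3, [4, 4, 4], 7)
        by_cluster = {}
        for rec in records:
            by_cluster.setdefault(truth.cluster_of_est[rec.id], []).append(rec)
        for members in by_cluster.values():
            ref = members[0].seq
            for other in members[1:]:
                diff = sum(a != b for a, b in zip(ref, other.seq))
                assert diff <= 0.02 * len(ref)  # two mutated copies
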