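import math

import numpy as np
import pytest

from aliasclust.cluster import (
    _cv_of_ratios,
    compute_centroid,
    group_variance_report,
    ratio_cv,
    run_clustering,
)
from aliasclust.cluster import test_pair as check_pair  # avoid pytest collection
from aliasclust.errors import DegenerateClusterError, NotTestableError
from aliasclust.io_tables import PeakTable
from aliasclust.preprocess import NormalizedFeature, normalize_feature
from aliasclust.simulate import SimulationConfig, generate_table

from conftest import make_design, make_record, planted_pairs, recovered_pairs


class TestRatioCV:
    def test_perfect_proportionality_gives_zero(self):
        assert ratio_cv([2, 4, 6], [1, 2, 3]) == pytest.approx(0.0)
        lam = 7.3
        b = np.array([1.0, 5.0, 2.0, 9.0])
        assert ratio_cv(lam * b, b) == pytest.approx(0.0)

    def test_oriented_hand_example(self):
        # rule: denominator is the larger-grand-mean vector, here a
        cv = ratio_cv([10, 20, 30], [10, 10, 30])
        assert cv == pytest.approx(0.34641016, abs=1e-7)

    def test_unoriented_hand_example(self):
        # ratios (1, 2, 1): mean 4/3, sd 1/sqrt(3)
        cv = _cv_of_ratios(np.array([10, 20, 30.0]), np.array([10, 10, 30.0]))
        assert cv == pytest.approx((1 / math.sqrt(3)) / (4 / 3), abs=1e-9)
        assert cv == pytest.approx(0.4330127, abs=1e-6)

    def test_small_denominators_excluded_then_infinite(self):
        # 1 of 10 samples has ~zero denominator: excluded, CV still finite
        b = np.array([5.0] * 9 + [1e-15])
        a = 2 * b + np.array([0.1] * 9 + [0.0])
        assert math.isfinite(ratio_cv(b, a))
        # 3 of 10 denominator entries ~zero (> 20% excluded): CV becomes +inf
        a = np.array([10.0] * 7 + [1e-15] * 3)
        b = np.array([5.0] * 10)
        assert ratio_cv(a, b) == math.inf

    def test_too_few_usable_samples(self):
        with pytest.raises(NotTestableError):
            ratio_cv([1.0, 2.0], [1.0, 2.0])
        # denominator (larger grand mean) nearly always ~zero
        with pytest.raises(NotTestableError):
            ratio_cv([1.0, 0.0, 0.0], [0.5, 0.1, 0.2])


class TestTestPair:
    @pytest.fixture
    def pair_and_table(self, tiny_table):
        from aliasclust.alias_search import generate_candidates

        (pair,) = generate_candidates(tiny_table, 1)
        return pair, tiny_table

    def test_proportional_pair_passes(self, pair_and_table):
        pair, table = pair_and_table
        assert check_pair(pair, table, threshold=0.15)

    def test_cv_equal_to_threshold_fails(self, pair_and_table):
        # alias pair in tiny_table has CV = 0: threshold 0 must fail (strict <)
        pair, table = pair_and_table
        assert not check_pair(pair, table, threshold=0.0)
        assert check_pair(pair, table, threshold=1e-6)


class TestComputeCentroid:
    def _feat(self, vec, noise, pid=("f", "s", "e", "m")):
        vec = np.asarray(vec, dtype=float)
        vec = vec - vec.mean()
        vec = vec / np.linalg.norm(vec)
        return NormalizedFeature(peak_id=pid, vector=vec, scale=1.0, noise_var=noise)

    def test_identical_vectors_equal_noise(self):
        v = [1.0, 2.0, 4.0]
        centroid, weights = compute_centroid([self._feat(v, 0.1), self._feat(v, 0.1)])
        assert weights == pytest.approx([0.5, 0.5], abs=1e-12)
        assert centroid == pytest.approx(self._feat(v, 0.1).vector, abs=1e-12)

    def test_inverse_noise_weights_for_identical_vectors(self):
        v = [0.0, 1.0, 5.0, 2.0]
        _, weights = compute_centroid([self._feat(v, 1.0), self._feat(v, 3.0)])
        assert weights == pytest.approx([0.75, 0.25], abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n, d = int(rng.integers(2, 6)), int(rng.integers(4, 9))
            feats = [
                self._feat(rng.normal(size=d), float(rng.uniform(1e-6, 0.5)))
                for _ in range(n)
            ]
            centroid, weights = compute_centroid(feats)

            # independent recomputation of the documented definition
            vs = [f.vector for f in feats]
            ns = [max(f.noise_var, 1e-12) for f in feats]
            w = np.array([1.0 / x for x in ns])
            w = w / w.sum()
            for _pass in range(2):
                c = sum(wi * vi for wi, vi in zip(w, vs))
                c = c - c.mean()
                c = c / np.linalg.norm(c)
                lof = [float(np.sum((vi - c) ** 2)) for vi in vs]
                w = np.array([1.0 / (ni + li) for ni, li in zip(ns, lof)])
                w = w / w.sum()
            c = sum(wi * vi for wi, vi in zip(w, vs))
            c = c - c.mean()
            c = c / np.linalg.norm(c)

            assert weights == pytest.approx(w, rel=1e-10)
            assert centroid == pytest.approx(c, rel=1e-9, abs=1e-12)
            assert float(np.sum(centroid)) == pytest.approx(0.0, abs=1e-9)
            assert float(np.linalg.norm(centroid)) == pytest.approx(1.0, abs=1e-9)

    def test_anticorrelated_members_degenerate(self):
        v = np.array([1.0, -1.0, 0.0])
        feats = [self._feat(v, 0.1), self._feat(-v, 0.1)]
        with pytest.raises(DegenerateClusterError):
            compute_centroid(feats)

    def test_single_member_rejected(self):
        with pytest.raises(DegenerateClusterError):
            compute_centroid([self._feat([1.0, 2.0, 3.0], 0.1)])


class TestRunClustering:
    def test_planted_pair_recovered_with_noise(self):
        cfg = SimulationConfig(
            n_samples=20, n_proteins=1, alias_spec=[[(2, {})]],
            alias_noise_cv=0.05, replicate_noise_cv=0.05, seed=5,
        )
        table, truth = generate_table(cfg)
        result = run_clustering(table, threshold=0.3)
        assert len(result.clusters) == 1
        assert recovered_pairs(result) == planted_pairs(truth)

    def test_no_clusters_below_every_pairwise_cv(self, design3):
        # noisy alias pair: the ratio CV is > 0, so a tiny threshold rejects it
        peaks = [
            make_record(66_000, [1.0, 2.0, 3.0], design3),
            make_record(33_000, [2.1, 3.9, 6.2], design3),
            make_record(7_000, [5.0, 1.0, 2.0], design3),
        ]
        table = PeakTable(peaks, design3)
        result = run_clustering(table, threshold=1e-12)
        assert result.clusters == []
        assert len(result.unclustered) == 3
        assert result.n_features_out == 3
        # the same pair clusters once the threshold clears its CV
        assert len(run_clustering(table, threshold=0.2).clusters) == 1

    def test_three_mutually_passing_peaks_form_one_cluster(self):
        design = make_design(4)
        means = np.array([1.0, 3.0, 2.0, 5.0])
        peaks = [
            make_record(66_000, means, design, pair_delta=0.02),
            make_record(33_000, 0.5 * means, design, pair_delta=0.02),
            make_record(22_000, 0.3 * means, design, pair_delta=0.02),
        ]
        result = run_clustering(PeakTable(peaks, design), threshold=0.1)
        assert len(result.clusters) == 1
        assert len(result.clusters[0].members) == 3
        assert result.clusters[0].cluster_id == "cluster_001"

    def test_feature_conservation_and_disjointness(self):
        cfg = SimulationConfig(n_samples=15, n_proteins=25, seed=9,
                               fractions=("Fx3", "Fx4"), surfaces=("CM10", "H50"))
        table, _ = generate_table(cfg)
        result = run_clustering(table, threshold=0.4)
        seen = set()
        for c in result.clusters:
            for m in c.members:
                assert m not in seen
                seen.add(m)
        assert seen.isdisjoint(result.unclustered)
        assert result.n_features_out == (
            len(table) - result.n_clustered_peaks + len(result.clusters)
        )

    def test_clustered_peak_count_monotone_in_threshold(self):
        cfg = SimulationConfig(n_samples=12, n_proteins=12, seed=2,
                               alias_noise_cv=0.2)
        table, _ = generate_table(cfg)
        counts = [
            run_clustering(table, t).n_clustered_peaks
            for t in (0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert counts == sorted(counts)

    def test_degenerate_peak_excluded_with_warning(self, design3, caplog):
        peaks = [
            make_record(66_000, [1.0, 2.0, 3.0], design3),
            make_record(33_000, [2.0, 4.0, 6.0], design3),
            make_record(7_000, [2.0, 2.0, 2.0], design3),  # constant
        ]
        import logging

        with caplog.at_level(logging.WARNING, logger="aliasclust.cluster"):
            result = run_clustering(PeakTable(peaks, design3), threshold=0.2)
        assert len(result.degenerate) == 1
        assert "constant" in caplog.text
        assert len(result.clusters) == 1


class TestGroupVarianceReport:
    def test_member_vs_itself_and_proportional_members_zero(self):
        design = make_design(8, groups=["g1"] * 4 + ["g2"] * 4)
        means = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 1.5, 2.5, 3.5])
        peaks = [
            make_record(66_000, means, design, pair_delta=0.01),
            make_record(33_000, 0.5 * means, design, pair_delta=0.4),
        ]
        table = PeakTable(peaks, design)
        result = run_clustering(table, threshold=0.2)
        (cluster,) = result.clusters
        report = group_variance_report(cluster, table, design)
        for member, per_group in report.items():
            for g, cv in per_group.items():
                assert cv == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_per_group_recomputation(self):
        design = make_design(10, groups=["g1"] * 5 + ["g2"] * 5)
        rng = np.random.default_rng(3)
        means = rng.uniform(1, 9, size=10)
        noisy = means * rng.uniform(0.95, 1.05, size=10)
        peaks = [
            make_record(66_000, means, design, pair_delta=0.01),
            make_record(33_000, 0.6 * noisy, design, pair_delta=0.02),
        ]
        table = PeakTable(peaks, design)
        result = run_clustering(table, threshold=0.5)
        (cluster,) = result.clusters
        report = group_variance_report(cluster, table, design)
        anchor_id = cluster.members[int(np.argmax(cluster.weights))]
        other_id = next(m for m in cluster.members if m != anchor_id)
        anchor = table.get(anchor_id)
        other = table.get(other_id)
        from aliasclust.preprocess import replicate_means

        am = replicate_means(anchor, design)
        om = replicate_means(other, design)
        for g, sl in (("g1", slice(0, 5)), ("g2", slice(5, 10))):
            expected = ratio_cv(om[sl], am[sl], other.mass_da, anchor.mass_da)
            assert report[other_id][g] == pytest.approx(expected, rel=1e-12)

    def test_small_group_marked_unavailable(self):
        design = make_design(5, groups=["g1", "g1", "g1", "g2", "g2"])
        means = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        peaks = [
            make_record(66_000, means, design, pair_delta=0.01),
            make_record(33_000, 0.5 * means, design, pair_delta=0.02),
        ]
        table = PeakTable(peaks, design)
        result = run_clustering(table, threshold=0.2)
        report = group_variance_report(result.clusters[0], table, design)
        for per_group in report.values():
            assert math.isnan(per_group["g2"])  # 2 samples < 3
            assert math.isfinite(per_group["g1"])
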