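import logging
import math

import numpy as np
import pytest

from fedstrat import (
    ClusterReport,
    CombinedPoints,
    GenotypeMatrix,
    NoisyMetadata,
    aggregate_metadata,
    centralized_benchmark,
    choose_k_elbow,
    cluster_kmeans,
    fit_pca_model,
    hash_sample_ids,
    match_cluster_labels,
    project_samples,
    qc_filter,
    researcher_payload,
    restrict_to_snps,
    score_accuracy,
    score_precision_recall,
    split_federation,
    stratify,
    wcss_curve,
)


def _payload(coords, prefix="s", epsilon=math.inf):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return NoisyMetadata(
        hashed_ids=hash_sample_ids([f"{prefix}{i}" for i in range(n)]),
        coordinates=coords,
        epsilon=epsilon,
        n_components=coords.shape[1],
    )


def _blobs(centers, n_per, spread, seed=0):
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for c, center in enumerate(centers):
        pts.append(center + spread * rng.normal(size=(n_per, len(center))))
        labels += [c] * n_per
    coords = np.vstack(pts)
    return (
        CombinedPoints(
            coords, [f"h{i}" for i in range(len(coords))], ["r"] * len(coords)
        ),
        np.array(labels),
    )


class TestAggregateMetadata:
    def test_row_counts_and_order(self):
        rng = np.random.default_rng(0)
        pa = _payload(rng.normal(size=(20, 2)), "a")
        pb = _payload(rng.normal(size=(18, 2)), "b")
        combined = aggregate_metadata([pa, pb])
        assert combined.n_points == 38
        assert np.array_equal(combined.coordinates[:20], pa.coordinates)
        assert combined.sources[:20] == ["researcher_1"] * 20

    def test_single_payload(self):
        p = _payload(np.zeros((3, 2)))
        combined = aggregate_metadata([p], sources=["only"])
        assert np.array_equal(combined.coordinates, p.coordinates)
        assert combined.sources == ["only"] * 3

    def test_same_hashed_id_across_payloads_kept(self):
        pa = _payload(np.zeros((2, 1)), "x")
        pb = _payload(np.ones((2, 1)), "x")  # identical pseudonyms
        combined = aggregate_metadata([pa, pb])
        assert combined.n_points == 4

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            aggregate_metadata([_payload(np.zeros((2, 1))), _payload(np.zeros((2, 2)), "b")])

    def test_empty_list(self):
        with pytest.raises(ValueError):
            aggregate_metadata([])


class TestWcssCurve:
    def test_k_equals_n_gives_zero(self):
        points, _ = _blobs([(0.0, 0.0)], 5, 1.0)
        curve = wcss_curve(points, 1, 5, seed=0)
        assert curve[5] == pytest.approx(0.0, abs=1e-12)

    def test_non_increasing(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            coords = rng.normal(size=(40, 2))
            points = CombinedPoints(
                coords, [f"h{i}" for i in range(40)], ["r"] * 40
            )
            curve = wcss_curve(points, 1, 8, seed=seed)
            vals = [curve[k] for k in sorted(curve)]
            assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_separated_clusters_elbow_shape(self):
        points, _ = _blobs([(0, 0), (100, 0), (0, 100)], 20, 1.0, seed=1)
        curve = wcss_curve(points, 2, 5, seed=0)
        assert curve[3] < 0.05 * curve[2]
        assert curve[4] > 0.5 * curve[3]

    def test_k_bounds(self):
        points, _ = _blobs([(0.0, 0.0)], 4, 1.0)
        with pytest.raises(ValueError):
            wcss_curve(points, 1, 5, seed=0)
        with pytest.raises(ValueError):
            wcss_curve(points, 0, 3, seed=0)

    def test_deterministic_given_seed(self):
        points, _ = _blobs([(0, 0), (5, 5)], 15, 1.0, seed=2)
        assert wcss_curve(points, 1, 6, seed=7) == wcss_curve(points, 1, 6, seed=7)


class TestChooseKElbow:
    def test_hand_curve(self):
        assert choose_k_elbow({1: 100.0, 2: 10.0, 3: 9.0, 4: 8.5}) == 2

    def test_flat_curve_warns_and_returns_k_min(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert choose_k_elbow({2: 5.0, 3: 5.0, 4: 5.0}) == 2
        assert "flat" in caplog.text

    def test_linear_curve_warns_and_returns_k_min(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert choose_k_elbow({2: 30.0, 3: 20.0, 4: 10.0}) == 2
        assert "linear" in caplog.text

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            choose_k_elbow({2: 10.0, 3: 5.0})

    def test_three_separated_clusters(self):
        points, _ = _blobs([(0, 0), (50, 0), (0, 50)], 25, 1.0, seed=3)
        assert choose_k_elbow(wcss_curve(points, 2, 8, seed=0)) == 3


class TestClusterKmeans:
    def test_two_points_two_clusters(self):
        points = CombinedPoints(np.array([[0.0, 0.0], [5.0, 5.0]]), ["a", "b"], ["r", "r"])
        report = cluster_kmeans(points, 2, seed=0)
        assert report.labels[0] != report.labels[1]
        assert report.inertia == pytest.approx(0.0, abs=1e-12)

    def test_recovers_separated_partition(self):
        points, truth = _blobs([(0, 0), (40, 0), (0, 40)], 20, 0.5, seed=4)
        report = cluster_kmeans(points, 3, seed=0)
        assert score_accuracy(report, truth) == 1.0

    def test_deterministic_given_seed(self):
        points, _ = _blobs([(0, 0), (3, 3)], 20, 1.0, seed=5)
        a = cluster_kmeans(points, 2, seed=9)
        b = cluster_kmeans(points, 2, seed=9)
        assert np.array_equal(a.labels, b.labels)

    def test_labels_canonical_by_size(self):
        points, _ = _blobs([(0, 0), (50, 50)], 10, 0.5, seed=6)
        bigger = CombinedPoints(
            np.vstack([points.coordinates, [[0.2, 0.1]] * 0 + [[0.3, 0.2]]]),
            points.hashed_ids + ["extra"],
            points.sources + ["r"],
        )
        report = cluster_kmeans(bigger, 2, seed=0)
        sizes = [report.cluster_sizes[c] for c in sorted(report.cluster_sizes)]
        assert sizes == sorted(sizes, reverse=True)

    def test_k_too_large(self):
        points, _ = _blobs([(0.0, 0.0)], 3, 1.0)
        with pytest.raises(ValueError):
            cluster_kmeans(points, 4, seed=0)

    def test_report_round_trip(self, tmp_path):
        points, _ = _blobs([(0, 0), (9, 9)], 8, 0.5, seed=7)
        report = stratify(points, k="auto", k_min=2, k_max=5, seed=0)
        report.save(tmp_path / "report.json")
        back = ClusterReport.load(tmp_path / "report.json")
        assert np.array_equal(back.labels, report.labels)
        assert back.cluster_sizes == report.cluster_sizes
        assert back.chosen_k == report.chosen_k
        assert back.wcss_curve == report.wcss_curve
        assert back.ids == report.ids


class TestCentralizedBenchmark:
    def test_public_only(self, cohort3):
        public = qc_filter(cohort3.take_samples(range(100)))  # populations P1, P2
        report = centralized_benchmark([], public, 2, k=2, seed=0)
        assert score_accuracy(report, public.population_labels) == 1.0

    def test_pooling_order_invariance(self, cohort3):
        public = qc_filter(cohort3)
        da = public.take_samples(range(0, 20))
        db = public.take_samples(range(60, 80))
        rest = public.take_samples(
            [i for i in range(150) if not (0 <= i < 20 or 60 <= i < 80)]
        )
        r1 = centralized_benchmark([da, db], rest, 2, k=3, seed=0)
        r2 = centralized_benchmark([db, da], rest, 2, k=3, seed=0)
        lab1 = dict(zip(r1.ids, r1.labels.tolist()))
        lab2 = dict(zip(r2.ids, r2.labels.tolist()))
        ids = sorted(lab1)
        a = [lab1[i] for i in ids]
        b = [lab2[i] for i in ids]
        assert score_accuracy(np.array(a), np.array(b)) == 1.0

    def test_no_noise_federation_matches_benchmark(self, cohort3):
        public, locals_ = split_federation(
            cohort3, None, {"Ra": ["P1", "P2"], "Rb": ["P2", "P3"]},
            {"Ra": 30, "Rb": 30},
        )
        public = qc_filter(public)
        locals_ = {r: restrict_to_snps(g, public.snp_ids) for r, g in locals_.items()}
        model = fit_pca_model(public, 2)
        payloads = [
            researcher_payload(model, locals_[r], math.inf) for r in ("Ra", "Rb")
        ]
        report = stratify(aggregate_metadata(payloads), k=3, seed=0)
        bench = centralized_benchmark(
            [locals_["Ra"], locals_["Rb"]], public, 2, k=3, seed=0
        )
        bench_by_id = dict(zip(bench.ids, bench.labels.tolist()))
        raw = locals_["Ra"].sample_ids + locals_["Rb"].sample_ids
        bench_labels = np.array([bench_by_id[s] for s in raw])
        assert score_accuracy(report, bench_labels) == 1.0


class TestMatching:
    def test_identical_partitions(self):
        labels = np.array([0, 0, 1, 1, 2])
        mapping = match_cluster_labels(labels, labels)
        assert mapping == {0: 0, 1: 1, 2: 2}

    def test_permuted_truth_full_overlap(self):
        pred = np.array([0] * 5 + [1] * 5)
        truth = np.array(["b"] * 5 + ["a"] * 5)
        assert score_accuracy(pred, truth) == 1.0

    def test_hand_contingency(self):
        # contingency [[9,1],[2,8]]: identity matching, overlap 17/20
        pred = np.array([0] * 10 + [1] * 10)
        truth = np.array([0] * 9 + [1] + [0] * 2 + [1] * 8)
        mapping = match_cluster_labels(pred, truth)
        assert mapping == {0: 0, 1: 1}
        assert score_accuracy(pred, truth) == pytest.approx(17 / 20)

    def test_bruteforce_agreement_on_random_partitions(self):
        rng = np.random.default_rng(3)
        from itertools import permutations

        for _ in range(10):
            pred = rng.integers(0, 3, size=30)
            truth = rng.integers(0, 3, size=30)
            best = max(
                np.mean([{0: p[0], 1: p[1], 2: p[2]}.get(x) == t
                         for x, t in zip(pred, truth)])
                for p in permutations(range(3))
            )
            assert score_accuracy(pred, truth) == pytest.approx(best)

    def test_unequal_cluster_counts(self):
        pred = np.array([0, 0, 1, 1, 2, 2])
        truth = np.array(["a", "a", "b", "b", "a", "b"])
        mapping = match_cluster_labels(pred, truth)
        assert sorted(v for v in mapping.values() if v is not None) == ["a", "b"]
        assert sum(v is None for v in mapping.values()) == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            match_cluster_labels(np.array([0, 1]), np.array([0]))


class TestScores:
    def test_perfect(self):
        labels = np.array([0, 1, 0, 1])
        assert score_accuracy(labels, labels) == 1.0
        assert score_precision_recall(labels, labels) == (1.0, 1.0)

    def test_one_mismatch_in_ten(self):
        pred = np.array([0] * 5 + [1] * 5)
        truth = np.array([0] * 5 + [1] * 4 + [0])
        assert score_accuracy(pred, truth) == pytest.approx(0.9)

    def test_eight_of_ten_overlap(self):
        # both clusters: 8 correct of 10 predicted, 8 of 10 true members
        pred = np.array([0] * 10 + [1] * 10)
        truth = np.array(["x"] * 8 + ["y"] * 2 + ["x"] * 2 + ["y"] * 8)
        precision, recall = score_precision_recall(pred, truth)
        assert precision == pytest.approx(0.8)
        assert recall == pytest.approx(0.8)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        pred = rng.integers(0, 3, size=50)
        truth = rng.integers(0, 3, size=50)
        perm = {0: 2, 1: 0, 2: 1}
        pred_perm = np.array([perm[x] for x in pred])
        assert score_accuracy(pred, truth) == score_accuracy(pred_perm, truth)
        assert score_precision_recall(pred, truth) == pytest.approx(
            score_precision_recall(pred_perm, truth)
        )

    def test_bounds_on_random_inputs(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            pred = rng.integers(0, 4, size=40)
            truth = rng.integers(0, 3, size=40)
            p, r = score_precision_recall(pred, truth)
            assert 0.0 <= p <= 1.0 and 0.0 <= r <= 1.0
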