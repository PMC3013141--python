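import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydroxysite.encoding import FeatureDescriptor, FeatureMatrix, KIND_PSSM
from hydroxysite.model import (
    ConfusionCounts,
    compute_metrics,
    jackknife,
    nna_distance,
    nna_predict,
    run_ifs,
)
from hydroxysite.mrmr import RankedFeatureList, rank_maxrel


def matrix_from(values, labels):
    values = np.asarray(values, dtype=float)
    descriptors = [
        FeatureDescriptor(1 + j // 20, KIND_PSSM, sorted("ARNDCQEGHILKMFPSTWYV")[j % 20])
        for j in range(values.shape[1])
    ]
    return FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        descriptors=descriptors,
        values=values,
        labels=np.asarray(labels, dtype=int),
    )


class TestDistance:
    def test_self_distance_is_zero(self):
        assert nna_distance(np.array([1.0, 2, 3]), np.array([1.0, 2, 3])) == pytest.approx(0)

    def test_orthogonal_vectors_have_distance_one(self):
        assert nna_distance(np.array([1.0, 0]), np.array([0.0, 1])) == pytest.approx(1)

    def test_hand_computed_cosines(self):
        assert nna_distance(np.array([1.0, 1]), np.array([5.0, -5])) == pytest.approx(1)
        assert nna_distance(np.array([1.0, 1]), np.array([-1.0, -1])) == pytest.approx(2)

    def test_scale_invariance(self):
        u, v = np.array([1.0, 2, 3]), np.array([3.0, 1, 2])
        assert nna_distance(u, v) == pytest.approx(nna_distance(4.2 * u, 0.1 * v))

    def test_zero_norm_and_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            nna_distance(np.zeros(3), np.ones(3))
        with pytest.raises(ValueError):
            nna_distance(np.ones(2), np.ones(3))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_equals_one_minus_cos_of_the_angle(self, seed):
        """Angle-based oracle on random 2-D vectors."""
        rng = np.random.default_rng(seed)
        a1, a2 = rng.uniform(0, 2 * np.pi, 2)
        r1, r2 = rng.uniform(0.1, 5, 2)
        u = r1 * np.array([np.cos(a1), np.sin(a1)])
        v = r2 * np.array([np.cos(a2), np.sin(a2)])
        assert nna_distance(u, v) == pytest.approx(1 - np.cos(a1 - a2), abs=1e-9)


class TestPredict:
    def test_exact_match_returns_its_label(self):
        train = np.array([[1.0, 0], [0, 1.0]])
        assert nna_predict(np.array([1.0, 0]), train, np.array([1, 0])) == 1

    def test_single_sample_training_set(self):
        assert nna_predict(np.array([3.0, 1]), np.array([[1.0, 9]]), np.array([0])) == 0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(8)
        train = rng.normal(size=(10, 4))
        labels = rng.integers(0, 2, 10)
        for _ in range(20):
            query = rng.normal(size=4)
            dists = [nna_distance(query, t) for t in train]
            expected = labels[int(np.argmin(dists))]
            assert nna_predict(query, train, labels) == expected

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            nna_predict(np.ones(3), np.ones((2, 4)), np.array([0, 1]))


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "counts, sn, sp, ac, mcc",
        [
            # proline benchmark composition: 678 positives, 1356 negatives
            (ConfusionCounts(tp=439, fn=239, tn=1106, fp=250), 0.648, 0.816, 0.760, 0.461),
            # lysine benchmark composition: 108 positives, 216 negatives
            (ConfusionCounts(tp=76, fn=32, tn=190, fp=26), 0.704, 0.880, 0.821, 0.592),
        ],
    )
    def test_benchmark_compositions(self, counts, sn, sp, ac, mcc):
        # counts are reconstructed from rates printed at 0.1% precision,
        # so Sn/Sp match to that rounding; AC and MCC are exact at their
        # own printed precision
        m = compute_metrics(counts)
        assert m.sn == pytest.approx(sn, abs=1e-3)
        assert m.sp == pytest.approx(sp, abs=1e-3)
        assert round(m.ac, 3) == ac
        assert round(m.mcc, 3) == mcc

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=5, fn=0, tn=7, fp=0))
        assert (m.sn, m.sp, m.ac, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_mcc_is_plus_minus_one_iff_diagonal(self):
        anti = compute_metrics(ConfusionCounts(tp=0, fn=5, tn=0, fp=7))
        assert anti.mcc == pytest.approx(-1.0)
        mixed = compute_metrics(ConfusionCounts(tp=4, fn=1, tn=5, fp=2))
        assert abs(mixed.mcc) < 1.0

    def test_zero_denominator_guard(self):
        m = compute_metrics(ConfusionCounts(tp=0, fn=0, tn=4, fp=0))
        assert m.mcc == 0.0
        assert m.sn == 0.0


class TestJackknife:
    def test_duplicate_vectors_per_class_force_correct_neighbours(self):
        values = np.array([[1.0, 0], [1.0, 0], [0, 1.0], [0, 1.0]])
        _, m = jackknife(matrix_from(values, [1, 1, 0, 0]))
        assert m.ac == 1.0

    def test_separated_clusters_are_perfect(self):
        rng = np.random.default_rng(9)
        pos = rng.normal(loc=[10, 10, 0], scale=0.1, size=(8, 3))
        neg = rng.normal(loc=[0, 0, 10], scale=0.1, size=(8, 3))
        _, m = jackknife(matrix_from(np.vstack([pos, neg]), [1] * 8 + [0] * 8))
        assert m.ac == 1.0 and m.mcc == 1.0

    def test_matches_independent_loocv_loop(self):
        rng = np.random.default_rng(10)
        values = rng.normal(size=(20, 5)) + 0.5
        labels = rng.integers(0, 2, 20)
        while len(set(labels)) < 2:
            labels = rng.integers(0, 2, 20)
        counts, _ = jackknife(matrix_from(values, labels))
        tp = fp = tn = fn = 0
        for i in range(20):
            rest = [j for j in range(20) if j != i]
            pred = nna_predict(values[i], values[rest], labels[rest])
            if labels[i] == 1:
                tp, fn = tp + (pred == 1), fn + (pred == 0)
            else:
                tn, fp = tn + (pred == 0), fp + (pred == 1)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (tp, fp, tn, fn)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=(15, 4)) + 1
        labels = np.array([1] * 7 + [0] * 8)
        perm = rng.permutation(15)
        c1, _ = jackknife(matrix_from(values, labels))
        c2, _ = jackknife(matrix_from(values[perm], labels[perm]))
        assert c1 == c2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            jackknife(matrix_from(np.ones((3, 2)), [1, 1, 1]))


class TestIFS:
    @staticmethod
    def ranked_all(matrix):
        return rank_maxrel(matrix, top_n=matrix.n_features)

    def test_max_k_one(self):
        rng = np.random.default_rng(13)
        values = rng.normal(size=(12, 3)) + 2
        labels = np.array([1] * 6 + [0] * 6)
        matrix = matrix_from(values, labels)
        result = run_ifs(matrix, self.ranked_all(matrix), max_k=1)
        assert len(result.per_k) == 1 and result.optimal_k == 1

    def test_full_list_equals_single_jackknife(self):
        rng = np.random.default_rng(14)
        values = rng.normal(size=(18, 6)) + 1
        labels = np.array([1] * 9 + [0] * 9)
        matrix = matrix_from(values, labels)
        result = run_ifs(matrix, self.ranked_all(matrix))
        counts_full, metrics_full = jackknife(matrix)
        k, counts_last, _ = result.per_k[-1]
        assert k == matrix.n_features
        assert counts_last == counts_full

    def test_optimum_is_smallest_peak_k(self):
        rng = np.random.default_rng(15)
        labels = np.repeat([1, 0], 15)
        signal = labels[:, None] * 6.0 + rng.normal(scale=0.5, size=(30, 2))
        noise = rng.normal(size=(30, 4))
        matrix = matrix_from(np.hstack([signal, noise]), labels)
        result = run_ifs(matrix, self.ranked_all(matrix))
        curve = result.curve()
        accs = curve[:, 3]
        assert result.optimal_metrics.ac == accs.max()
        assert result.optimal_k == int(curve[np.argmax(accs), 0])

    def test_per_k_matches_explicit_jackknife_prefixes(self):
        """The incremental IFS loop agrees with de-novo jackknife at each k."""
        rng = np.random.default_rng(16)
        labels = np.repeat([1, 0], 10)
        values = rng.normal(size=(20, 5)) + labels[:, None]
        matrix = matrix_from(values, labels)
        ranked = self.ranked_all(matrix)
        result = run_ifs(matrix, ranked)
        for k, counts, _ in result.per_k:
            expected, _ = jackknife(matrix, ranked.indices[:k])
            assert counts == expected

    def test_ifs_curve_tsv(self, tmp_path):
        rng = np.random.default_rng(17)
        labels = np.repeat([1, 0], 8)
        matrix = matrix_from(rng.normal(size=(16, 4)) + 1, labels)
        result = run_ifs(matrix, self.ranked_all(matrix))
        path = tmp_path / "curve.tsv"
        result.to_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "k\tSn\tSp\tAC\tMCC"
        assert len(lines) == 1 + matrix.n_features
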