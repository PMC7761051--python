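import math

import numpy as np
import pytest
from sklearn.metrics import (
    balanced_accuracy_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
)

from promidiag.chem_similarity import MT, ST
from promidiag.diagnostic_ml import (
    ConfusionCounts,
    CVProtocol,
    KNNConfig,
    RFConfig,
    SVMConfig,
    balance_groups,
    compute_metrics,
    confusion,
    knn_classify,
    roc_auc,
    run_double_cv,
    split_pairs,
    tanimoto_kernel,
)
from promidiag.errors import ConfigError
from promidiag.group_sampling import MTGroup
from tests.conftest import fp_from_bits, random_fingerprints


def make_group(mt, st_list):
    return MTGroup(
        mt=mt,
        targets=tuple(f"t{i}" for i in range(len(st_list))),
        st_by_target={f"t{i}": st for i, st in enumerate(st_list)},
    )


class TestConfigs:
    def test_even_k_rejected(self):
        with pytest.raises(ConfigError):
            KNNConfig(k_grid=(1, 2))

    def test_negative_c_rejected(self):
        with pytest.raises(ConfigError):
            SVMConfig(c_grid=(0.1, -1.0))

    def test_empty_rf_grid_rejected(self):
        with pytest.raises(ConfigError):
            RFConfig(n_estimators_grid=())

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigError):
            CVProtocol(test_fraction=0.0)


class TestBalance:
    def test_counts(self, rng):
        groups = [make_group(f"m{i}", [f"s{i}a", f"s{i}b"]) for i in range(50)]
        pairs = balance_groups(groups, rng)
        assert len(pairs) == 50
        mts = [p[0] for p in pairs]
        assert len(set(mts)) == 50

    def test_single_st_always_chosen(self, rng):
        groups = [make_group("m", ["only"])]
        for _ in range(10):
            assert balance_groups(groups, rng)[0] == ("m", "only")

    def test_uniform_draw_frequencies(self):
        group = make_group("m", ["a", "b", "c"])
        counts = {"a": 0, "b": 0, "c": 0}
        n = 3000
        for seed in range(n):
            _, st = balance_groups([group], np.random.default_rng(seed))[0]
            counts[st] += 1
        for st in counts:
            assert counts[st] / n == pytest.approx(1 / 3, abs=0.04)


class TestSplitPairs:
    def test_80_20(self, rng):
        pairs = [(f"m{i}", f"s{i}") for i in range(100)]
        train, test = split_pairs(pairs, 0.2, rng)
        assert len(train) == 80 and len(test) == 20

    def test_50_50(self, rng):
        pairs = [(f"m{i}", f"s{i}") for i in range(100)]
        train, test = split_pairs(pairs, 0.5, rng)
        assert len(train) == 50 and len(test) == 50

    def test_pair_integrity(self, rng):
        pairs = [(f"m{i}", f"s{i}") for i in range(30)]
        train, test = split_pairs(pairs, 0.2, rng)
        train_ids = {c for p in train for c in p}
        test_ids = {c for p in test for c in p}
        assert not train_ids & test_ids

    def test_too_few_pairs(self, rng):
        with pytest.raises(ValueError):
            split_pairs([("m", "s")] * 4, 0.2, rng)


class TestKNN:
    def test_majority_definition(self):
        train = [fp_from_bits([0, 1]), fp_from_bits([0, 2]), fp_from_bits([9])]
        labels = [MT, MT, ST]
        test = fp_from_bits([0, 1, 2])
        label, score = knn_classify(train, labels, test, 3)
        assert label == MT and score == pytest.approx(2 / 3)

    def test_exact_duplicate_k1(self):
        train = [fp_from_bits([0, 1]), fp_from_bits([5, 6])]
        label, _ = knn_classify(train, [MT, ST], fp_from_bits([0, 1]), 1)
        assert label == MT

    def test_k_exceeds_train(self):
        with pytest.raises(ValueError):
            knn_classify([fp_from_bits([0])], [MT], fp_from_bits([0]), 3)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n_train = int(rng.integers(5, 15))
            ids = [f"c{i}" for i in range(n_train)]
            fps = random_fingerprints(rng, ids + ["q"], n_bits=24, density=0.4)
            labels = [MT if rng.random() < 0.5 else ST for _ in ids]
            k = int(rng.choice([1, 3, 5]))
            train = [fps[i] for i in ids]
            got_label, got_score = knn_classify(train, labels, fps["q"], k, train_ids=ids)
            # oracle: full sort of all neighbors by (distance, id)
            from tests.test_chem_similarity import brute_tanimoto

            ranked = sorted(
                range(n_train),
                key=lambda i: (1.0 - brute_tanimoto(fps[ids[i]], fps["q"]), ids[i]),
            )
            top = ranked[:k]
            frac = sum(1 for i in top if labels[i] == MT) / k
            assert got_score == pytest.approx(frac)
            assert got_label == (MT if frac > 0.5 else ST)

    def test_invariant_to_training_permutation(self, rng):
        ids = [f"c{i}" for i in range(10)]
        fps = random_fingerprints(rng, ids + ["q"], n_bits=24)
        labels = [MT if i % 2 else ST for i in range(10)]
        base = knn_classify([fps[i] for i in ids], labels, fps["q"], 3, train_ids=ids)
        perm = np.random.default_rng(3).permutation(10)
        shuffled = knn_classify(
            [fps[ids[i]] for i in perm], [labels[i] for i in perm], fps["q"], 3,
            train_ids=[ids[i] for i in perm],
        )
        assert base == shuffled


class TestTanimotoKernel:
    def test_diagonal_ones_and_symmetry(self, rng):
        fps = list(random_fingerprints(rng, [f"c{i}" for i in range(10)], density=0.4).values())
        gram = tanimoto_kernel(fps, fps)
        assert np.allclose(np.diag(gram), 1.0)
        assert np.allclose(gram, gram.T)

    def test_psd_on_random_sets(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            fps = list(random_fingerprints(rng, [f"c{i}" for i in range(n)], n_bits=48,
                                           density=float(rng.uniform(0.1, 0.6))).values())
            gram = tanimoto_kernel(fps, fps)
            assert np.linalg.eigvalsh(gram).min() >= -1e-8

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto_kernel([fp_from_bits([0], n_bits=8)], [fp_from_bits([0], n_bits=16)])


class TestConfusionAndMetrics:
    def test_perfect(self):
        cc = confusion([MT] * 5 + [ST] * 5, [MT] * 5 + [ST] * 5)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (5, 5, 0, 0)
        m = compute_metrics(cc)
        assert m.ba == m.f1 == m.precision == m.recall == 1.0
        assert m.mcc == 1.0

    def test_inverted(self):
        cc = confusion([MT] * 5 + [ST] * 5, [ST] * 5 + [MT] * 5)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (0, 0, 5, 5)

    def test_counts_sum_to_n(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 40))
            y = [MT if rng.random() < 0.5 else ST for _ in range(n)]
            p = [MT if rng.random() < 0.5 else ST for _ in range(n)]
            cc = confusion(y, p)
            assert cc.n == n
            assert cc.tp == sum(1 for a, b in zip(y, p) if a == MT and b == MT)

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            confusion([MT], ["bogus"])

    def test_hand_example(self):
        m = compute_metrics(ConfusionCounts(tp=4, fp=1, tn=3, fn=2))
        assert m.precision == pytest.approx(0.8)
        assert m.recall == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(8 / 11)
        assert m.ba == pytest.approx(0.5 * (4 / 6 + 3 / 4))
        assert m.mcc == pytest.approx(10 / math.sqrt(600))

    def test_all_positive_predictor(self):
        cc = confusion([MT] * 5 + [ST] * 5, [MT] * 10)
        m = compute_metrics(cc)
        assert m.ba == pytest.approx(0.5)
        assert m.mcc == 0.0

    def test_empty_confusion(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_agrees_with_sklearn_on_random_tables(self):
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 1000:
            n = int(rng.integers(4, 60))
            y = np.array([1 if rng.random() < 0.5 else 0 for _ in range(n)])
            p = np.array([1 if rng.random() < rng.uniform(0.1, 0.9) else 0 for _ in range(n)])
            if y.min() == y.max():
                continue  # BA undefined without both classes
            checked += 1
            yl = [MT if v else ST for v in y]
            pl = [MT if v else ST for v in p]
            m = compute_metrics(confusion(yl, pl))
            assert m.ba == pytest.approx(balanced_accuracy_score(y, p), abs=1e-12)
            assert m.f1 == pytest.approx(f1_score(y, p, zero_division=0), abs=1e-12)
            assert m.precision == pytest.approx(precision_score(y, p, zero_division=0), abs=1e-12)
            assert m.recall == pytest.approx(recall_score(y, p, zero_division=0), abs=1e-12)
            assert m.mcc == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)


class TestROC:
    def test_perfect_separation(self):
        y = [MT] * 10 + [ST] * 10
        scores = list(np.linspace(0.6, 1.0, 10)) + list(np.linspace(0.0, 0.4, 10))
        assert roc_auc(y, scores) == 1.0

    def test_constant_scores(self):
        y = [MT] * 10 + [ST] * 10
        assert roc_auc(y, [0.5] * 20) == 0.5

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([MT, MT], [0.1, 0.2])

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = [MT if rng.random() < 0.5 else ST for _ in range(n)]
            if MT not in y or ST not in y:
                continue
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # coarse grid forces ties
            pos = [s for s, t in zip(scores, y) if t == MT]
            neg = [s for s, t in zip(scores, y) if t == ST]
            concordant = sum(
                1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
            )
            oracle = concordant / (len(pos) * len(neg))
            assert roc_auc(y, scores) == pytest.approx(oracle, abs=1e-12)


@pytest.fixture(scope="module")
def small_benchmark():
    from promidiag.benchmark import benchmark_sim_config
    from promidiag.group_sampling import GroupSamplingConfig, build_groups
    from promidiag.synthetic_data import simulate_activity, simulate_library

    config = benchmark_sim_config(0.9, 7, n_groups=60)
    rng = np.random.default_rng(7)
    fps, truth = simulate_library(config, rng)
    matrix = simulate_activity((fps, truth), config, rng)
    groups = build_groups(matrix, GroupSamplingConfig(pd_threshold=5, rng_seed=7))
    return groups, fps


class TestDoubleCV:
    def test_output_length_default_protocol(self, small_benchmark):
        groups, fps = small_benchmark
        protocol = CVProtocol(n_external_trials=10, n_internal_trials=2)
        results = run_double_cv(groups, "KNN", fps, protocol=protocol)
        assert len(results) == 10
        assert [r.trial for r in results] == list(range(10))

    def test_strong_signal_beats_chance(self):
        # full benchmark group count; the 60-group fixture is too small for the 0.70 band
        from promidiag.benchmark import benchmark_sim_config
        from promidiag.group_sampling import GroupSamplingConfig, build_groups
        from promidiag.synthetic_data import simulate_activity, simulate_library

        bas = []
        for seed in (7, 8):
            config = benchmark_sim_config(0.9, seed, n_groups=200)
            rng = np.random.default_rng(seed)
            fps, truth = simulate_library(config, rng)
            matrix = simulate_activity((fps, truth), config, rng)
            groups = build_groups(matrix, GroupSamplingConfig(pd_threshold=5, rng_seed=seed))
            protocol = CVProtocol(n_external_trials=5, n_internal_trials=2, rng_seed=seed)
            results = run_double_cv(groups, "SVM", fps, protocol=protocol,
                                    svm_config=SVMConfig(c_grid=(1.0, 100.0)))
            bas.extend(r.metrics.ba for r in results)
        assert float(np.mean(bas)) > 0.70

    def test_chance_level_at_zero_signal(self):
        from promidiag.benchmark import benchmark_sim_config
        from promidiag.group_sampling import GroupSamplingConfig, build_groups
        from promidiag.synthetic_data import simulate_activity, simulate_library

        bas = []
        for seed in (0, 1, 2):
            config = benchmark_sim_config(0.0, seed, n_groups=60)
            rng = np.random.default_rng(seed)
            fps, truth = simulate_library(config, rng)
            matrix = simulate_activity((fps, truth), config, rng)
            groups = build_groups(matrix, GroupSamplingConfig(pd_threshold=5, rng_seed=seed))
            protocol = CVProtocol(n_external_trials=5, n_internal_trials=2, rng_seed=seed)
            results = run_double_cv(groups, "KNN", fps, protocol=protocol)
            bas.extend(r.metrics.ba for r in results)
        assert 0.4 < float(np.mean(bas)) < 0.6

    def test_deterministic_under_seed(self, small_benchmark):
        groups, fps = small_benchmark
        protocol = CVProtocol(n_external_trials=3, n_internal_trials=2, rng_seed=42)
        a = run_double_cv(groups, "KNN", fps, protocol=protocol)
        b = run_double_cv(groups, "KNN", fps, protocol=protocol)
        assert [(r.confusion, r.params) for r in a] == [(r.confusion, r.params) for r in b]

    def test_chosen_params_come_from_grid(self, small_benchmark):
        groups, fps = small_benchmark
        protocol = CVProtocol(n_external_trials=2, n_internal_trials=2)
        knn_cfg = KNNConfig(k_grid=(1, 3))
        for r in run_double_cv(groups, "KNN", fps, protocol=protocol, knn_config=knn_cfg):
            assert r.params["k"] in (1, 3)
        svm_cfg = SVMConfig(c_grid=(1.0,), kernels=("tanimoto",))
        for r in run_double_cv(groups, "SVM", fps, protocol=protocol, svm_config=svm_cfg):
            assert r.params == {"C": 1.0, "kernel": "tanimoto"}

    def test_too_few_groups(self, small_benchmark):
        _, fps = small_benchmark
        groups = [make_group(f"m{i}", [f"s{i}"]) for i in range(5)]
        with pytest.raises(ValueError):
            run_double_cv(groups, "KNN", fps)

    def test_auc_reported(self, small_benchmark):
        groups, fps = small_benchmark
        protocol = CVProtocol(n_external_trials=2, n_internal_trials=2)
        rf_cfg = RFConfig(n_estimators_grid=(20,), min_samples_split_grid=(2,))
        for r in run_double_cv(groups, "RF", fps, protocol=protocol, rf_config=rf_cfg):
            assert 0.0 <= r.metrics.auc <= 1.0
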