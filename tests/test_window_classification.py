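import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.model_selection import GroupKFold

from sweatsense.feature_extraction import WindowSpec
from sweatsense.synthetic_ppg import RunProfile, generate_run
from sweatsense.window_classification import (
    ClassificationError,
    ClassifierParams,
    build_pair_dataset,
    feature_importance,
    gap_sweep,
    grouped_cv_accuracy,
    rank_features,
    sweep_separations,
)

WINDOW = WindowSpec(duration_s=120.0, step_s=30.0)


def noise_dataset(seed, n_runs=12, n_features=20, informative=None):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_runs, n_features))
    y = np.tile([0, 1], n_runs)
    groups = np.repeat(np.arange(n_runs), 2)
    if informative is not None:
        X[:, informative] += 6.0 * y
    cols = [f"970_td_{name}" for name in
            ("mean", "median", "max", "min", "std", "var", "skew",
             "kurtosis", "iqr", "mad", "slope")]
    cols += [f"1450_fd_mean_{i}" for i in range(n_features - len(cols))]
    return pd.DataFrame(X, columns=cols[:n_features]), y, groups


class TestSweepRule:
    def test_stop_rule_matches_enumeration(self):
        # brute-force enumeration of valid (left, right) placements
        for duration, w, s in ((1320.0, 210.0, 20.0), (600.0, 120.0, 30.0),
                               (500.0, 100.0, 50.0)):
            steps = sweep_separations(duration, WindowSpec(w, s))
            k, expected = 0, 0
            while True:
                left = k * s
                right = duration - w - k * s
                if right < left + w:
                    break
                expected += 1
                k += 1
            assert len(steps) == expected

    def test_default_run_yields_23_classifiers(self):
        steps = sweep_separations(1320.0, WindowSpec(210.0, 20.0))
        assert len(steps) == 23

    def test_each_step_moves_both_windows_by_one_step(self):
        steps = sweep_separations(1320.0, WindowSpec(210.0, 20.0))
        for (l0, r0, _), (l1, r1, _) in zip(steps, steps[1:]):
            assert l1 - l0 == pytest.approx(20.0)
            assert r0 - r1 == pytest.approx(20.0)

    def test_separations_strictly_decreasing(self):
        seps = [s for _, _, s in sweep_separations(1320.0, WindowSpec(210.0, 20.0))]
        assert all(a > b for a, b in zip(seps, seps[1:]))

    def test_too_short_run_rejected(self):
        with pytest.raises(ClassificationError):
            sweep_separations(300.0, WindowSpec(210.0, 20.0))


class TestPairDataset:
    def test_balance_and_shape(self, short_runs):
        ds = build_pair_dataset(
            short_runs, WINDOW, 0.0, 480.0, wavelengths=(970, 1450), n_channels=8
        )
        assert len(ds.X) == 2 * len(short_runs)
        assert np.sum(ds.y == 0) == np.sum(ds.y == 1) == len(short_runs)
        assert ds.separation_s == 480.0

    def test_short_runs_skipped_with_warning(self, short_runs, caplog):
        mixed = short_runs + [generate_run(RunProfile(duration_s=400.0), seed=999)]
        with caplog.at_level("WARNING"):
            ds = build_pair_dataset(
                mixed, WINDOW, 0.0, 480.0, wavelengths=(970,), n_channels=8
            )
        assert len(ds.X) == 2 * len(short_runs)
        assert "skipped" in caplog.text


class TestGroupedCV:
    def test_no_run_leaks_across_folds(self):
        X, y, groups = noise_dataset(0, n_runs=16)
        cv = GroupKFold(n_splits=4)
        for train, test in cv.split(X, y, groups):
            assert set(groups[train]).isdisjoint(set(groups[test]))

    def test_determinism(self):
        X, y, groups = noise_dataset(1, n_runs=12, informative=0)
        a = grouped_cv_accuracy(X, y, groups, ClassifierParams(seed=3))
        b = grouped_cv_accuracy(X, y, groups, ClassifierParams(seed=3))
        assert abs(a - b) < 1e-12

    def test_fewer_groups_than_folds_rejected(self):
        X, y, groups = noise_dataset(2, n_runs=3)
        with pytest.raises(ClassificationError):
            grouped_cv_accuracy(X, y, groups, ClassifierParams(), folds=4)

    def test_informative_feature_high_accuracy(self):
        X, y, groups = noise_dataset(3, n_runs=16, informative=4)
        acc = grouped_cv_accuracy(X, y, groups, ClassifierParams(seed=0))
        assert acc > 0.85

    def test_permutation_null_calibration(self):
        # label permutation brings accuracy to chance, within the binomial
        # 95% band for n = 24 paired windows
        X, y, groups = noise_dataset(4, n_runs=12, informative=0)
        rng = np.random.default_rng(5)
        accs = []
        for _ in range(5):
            accs.append(
                grouped_cv_accuracy(
                    X, rng.permutation(y), groups, ClassifierParams(seed=1)
                )
            )
        band = 1.96 * np.sqrt(0.25 / len(y))
        assert abs(np.mean(accs) - 0.5) <= band


@pytest.fixture(scope="module")
def drift_sweep():
    # per-run randomized drift under heavy noise/wander: end-of-run windows
    # separate more clearly the farther apart they are
    rng = np.random.default_rng(0)
    runs = []
    for i in range(12):
        profile = RunProfile(
            duration_s=600.0,
            hr_rest_bpm=120.0,
            hr_peak_bpm=120.0,
            film_onset_s=float(rng.uniform(150.0, 350.0)),
            film_max_um=float(rng.uniform(80.0, 160.0)),
            film_tau_s=200.0,
            noise_scale=25.0,
            baseline_wander=4.0,
        )
        runs.append(generate_run(profile, seed=300 + i))
    return gap_sweep(
        runs,
        WINDOW,
        ClassifierParams(seed=0),
        folds=4,
        wavelengths=(970, 1450),
        include_frequency_domain=False,
    )


class TestGapSweep:
    def test_accuracy_increases_with_separation(self, drift_sweep):
        rho, _ = stats.spearmanr(
            drift_sweep.separations_s, drift_sweep.accuracies
        )
        assert rho > 0

    def test_step_count_matches_rule(self, drift_sweep):
        assert len(drift_sweep.steps) == len(sweep_separations(600.0, WINDOW))

    def test_accuracies_in_unit_interval(self, drift_sweep):
        assert np.all(drift_sweep.accuracies >= 0.0)
        assert np.all(drift_sweep.accuracies <= 1.0)

    def test_too_few_runs_rejected(self, short_runs):
        with pytest.raises(ClassificationError):
            gap_sweep(short_runs[:4], WINDOW, folds=4)

    def test_json_serialization(self, drift_sweep, tmp_path):
        import json

        p = tmp_path / "sweep.json"
        drift_sweep.to_json(p)
        payload = json.loads(p.read_text())
        assert payload["separations_s"] == drift_sweep.separations_s.tolist()


class TestImportance:
    def test_single_informative_feature_ranks_first(self):
        X, y, groups = noise_dataset(6, n_runs=16, informative=7)
        params = ClassifierParams(seed=0)
        model = params.make().fit(X.to_numpy(), y)
        imp = feature_importance(model, X, y, seed=0)
        assert imp.idxmax() == X.columns[7]

    def test_all_noise_rank_instability(self):
        # no feature should be stably most important across seeds
        tops = set()
        for seed in range(10):
            X, y, groups = noise_dataset(100 + seed, n_runs=12)
            model = ClassifierParams(seed=seed).make().fit(X.to_numpy(), y)
            imp = feature_importance(model, X, y, seed=seed)
            tops.add(imp.idxmax())
        assert len(tops) > 1

    def test_rank_features_table_layout(self, short_runs):
        sweep = gap_sweep(
            short_runs,
            WINDOW,
            ClassifierParams(seed=0),
            folds=4,
            wavelengths=(1450,),
            include_frequency_domain=False,
        )
        table = rank_features(sweep, top_k=5)
        assert table.shape[1] == len(sweep.steps)
        assert table.shape[0] >= 5

    def test_top_k_clipped_with_warning(self):
        X, y, groups = noise_dataset(8, n_runs=16, informative=0)
        profile = RunProfile(duration_s=600.0)
        runs = [generate_run(profile, seed=300 + i) for i in range(8)]
        sweep = gap_sweep(
            runs,
            WindowSpec(120.0, 120.0),
            ClassifierParams(seed=0),
            folds=4,
            wavelengths=(1450,),
            include_frequency_domain=False,
        )
        n_features = sweep.steps[0].dataset.X.shape[1]
        with pytest.warns(UserWarning, match="clipped"):
            table = rank_features(sweep, top_k=n_features + 10)
        assert table.shape[0] == n_features
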