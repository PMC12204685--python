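"""Model probing: permutation importance, duration curves, window contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spikeloc as sl
from spikeloc.features import FeatureConfig
from spikeloc.interpret import (
    _permute_columns,
    compare_window_stats,
    duration_sensitivity,
    isi_window_stats,
    permutation_importance_bins,
    permutation_importance_conditions,
)
from spikeloc.models import BalancedLogisticRegression


@pytest.fixture(scope="module")
def planted_bin_task():
    """Synthetic 2-class task where only feature 7 carries information."""
    rng = np.random.default_rng(0)
    n, d = 400, 20
    X = rng.normal(size=(n, d))
    y = np.repeat([0, 1], n // 2)
    X[:, 7] += 2.5 * y
    model = BalancedLogisticRegression(seed=0).fit(X, y)
    return model, X, y


class TestPermutationImportanceBins:
    def test_constant_bin_has_zero_importance(self, planted_bin_task):
        model, X, y = planted_bin_task
        Xc = X.copy()
        Xc[:, 3] = 1.0
        model2 = BalancedLogisticRegression(seed=0).fit(Xc, y)
        imp = permutation_importance_bins(model2, Xc, y, 1, bin_index=3,
                                          n_reps=20, seed=1)
        assert imp == 0.0

    def test_planted_bin_dominates(self, planted_bin_task):
        model, X, y = planted_bin_task
        imps = [
            permutation_importance_bins(model, X, y, 1, bin_index=i,
                                        n_reps=30, seed=2)
            for i in range(X.shape[1])
        ]
        assert int(np.argmax(imps)) == 7
        assert imps[7] > 0.1

    def test_out_of_range_bin_rejected(self, planted_bin_task):
        model, X, y = planted_bin_task
        with pytest.raises(IndexError):
            permutation_importance_bins(model, X, y, 1, bin_index=99)

    def test_absent_class_rejected(self, planted_bin_task):
        model, X, y = planted_bin_task
        with pytest.raises(ValueError, match="absent"):
            permutation_importance_bins(model, X, y, 5, bin_index=0)

    def test_label_randomized_model_importance_near_zero(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 10))
        y = rng.integers(2, size=300)
        model = BalancedLogisticRegression(seed=0).fit(X, y)
        imps = [
            permutation_importance_bins(model, X, y, 1, bin_index=i,
                                        n_reps=30, seed=4)
            for i in range(10)
        ]
        # no feature is informative: mean importance within 3 SE of zero
        assert abs(np.mean(imps)) < 3 * (np.std(imps) / np.sqrt(len(imps)) + 1e-3)


class TestPermutationImportanceConditions:
    def test_block_shuffle_preserves_column_multiset(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 12))
        Xp = _permute_columns(X, [3, 4, 5], rng)
        # block moves as a unit: row multiset of the block is preserved
        a = {tuple(r) for r in X[:, 3:6]}
        b = {tuple(r) for r in Xp[:, 3:6]}
        assert a == b
        np.testing.assert_array_equal(X[:, :3], Xp[:, :3])

    def test_condition_importance_via_planted_block(self, decoding_dataset):
        # build a small cat-psth-like matrix: 4 conditions x 5 bins; class
        # signal only in condition 2's block
        rng = np.random.default_rng(6)
        n = 300
        X = rng.normal(size=(n, 20))
        y = np.repeat([0, 1], n // 2)
        X[:, 10:15] += 1.8 * y[:, None]
        fm = sl.FeatureMatrix(
            representation="cat_psth",
            unit_ids=tuple(f"u{i}" for i in range(n)),
            values=X - X.min(),
            feature_names=tuple(f"f{i}" for i in range(20)),
            meta={"conditions": [(0.0, 1.0), (45.0, 1.0), (90.0, 1.0), (135.0, 1.0)],
                  "bins_per_condition": 5},
        )
        model = BalancedLogisticRegression(seed=0).fit(X, y)
        imps = {
            cond: permutation_importance_conditions(
                model, X, y, 1, cond, fm, n_reps=30, seed=7)
            for cond in fm.meta["conditions"]
        }
        assert max(imps, key=imps.get) == (90.0, 1.0)

    def test_unknown_condition_rejected(self):
        fm = sl.FeatureMatrix(
            representation="cat_psth", unit_ids=("u0",),
            values=np.zeros((1, 4)), feature_names=("a", "b", "c", "d"),
            meta={"conditions": [(0.0, 1.0), (45.0, 1.0)], "bins_per_condition": 2},
        )
        with pytest.raises(ValueError, match="unknown condition"):
            permutation_importance_conditions(None, np.zeros((1, 4)), [0], 0,
                                              (999.0, 1.0), fm)


@pytest.fixture(scope="module")
def trained(decoding_dataset):
    ds = decoding_dataset
    fm = sl.featurize(ds, "isi_dist")
    labels = sl.task_labels(ds, "region").loc[list(fm.unit_ids)]
    rng = np.random.default_rng(8)
    idx = rng.permutation(fm.n_units)
    tr, te = idx[: int(0.8 * fm.n_units)], idx[int(0.8 * fm.n_units):]
    model = BalancedLogisticRegression(seed=0).fit(
        fm.values[tr], labels.iloc[tr].to_numpy()
    )
    test_ids = [fm.unit_ids[i] for i in te]
    return model, ds, test_ids, labels.loc[test_ids]


class TestDurationSensitivity:
    def test_full_duration_matches_untruncated(self, trained):
        model, ds, test_ids, y = trained
        start, stop = ds.stimuli.span("drifting_gratings")
        out = duration_sensitivity(model, ds, test_ids, y, [stop - start])
        # recompute the standard test-set sensitivities directly
        fm = sl.featurize(ds.subset(test_ids), "isi_dist")
        pred = pd.Series(model.predict(fm.values), index=list(fm.unit_ids))
        for cls in sorted(y.unique()):
            expect = float(np.mean(pred[y[y == cls].index] == cls))
            got = out[(out["class_label"] == cls)
                      & (out["duration_s"] == stop - start)]["sensitivity"].iloc[0]
            assert got == pytest.approx(expect)

    def test_overlong_duration_flagged(self, trained):
        model, ds, test_ids, y = trained
        out = duration_sensitivity(model, ds, test_ids, y, [10**6])
        assert out["truncated_to_available"].all()

    def test_short_durations_hurt_on_average(self, trained):
        model, ds, test_ids, y = trained
        start, stop = ds.stimuli.span("drifting_gratings")
        out = duration_sensitivity(model, ds, test_ids, y,
                                   [1.0, 30.0, stop - start])
        mean_by_d = out.groupby("duration_s")["sensitivity"].mean()
        assert mean_by_d.loc[1.0] <= mean_by_d.loc[stop - start] + 0.02
        assert mean_by_d.is_monotonic_increasing or (
            mean_by_d.iloc[-1] >= mean_by_d.iloc[0]
        )

    def test_nonpositive_duration_rejected(self, trained):
        model, ds, test_ids, y = trained
        with pytest.raises(ValueError):
            duration_sensitivity(model, ds, test_ids, y, [0.0])


class TestWindowStats:
    def test_constant_isis_mean_and_zero_variance(self, tiny_dataset):
        # a synthetic unit spiking every 0.25 s
        import dataclasses
        w = (0.2, 0.3)
        u0 = tiny_dataset.units[0]
        st = np.arange(0.1, 200.0, 0.25)
        ds = dataclasses.replace(
            tiny_dataset,
            units=(dataclasses.replace(u0, spike_times_s=st),),
        )
        ws = isi_window_stats(ds, w)
        row = ws.table.iloc[0]
        assert row["mean_s"] == pytest.approx(0.25)
        assert row["variance_s2"] == pytest.approx(0.0, abs=1e-20)

    def test_uniform_isis_give_flat_slope(self):
        # histogram slope of a near-flat region is ~0 by OLS
        rng = np.random.default_rng(9)
        from spikeloc.features import isi_bin_edges, isi_distribution

        cfg = FeatureConfig()
        edges = isi_bin_edges(cfg)
        centers = (edges[:-1] + edges[1:]) / 2
        window = (0.5, 1.0)
        m = (centers >= 0.5) & (centers < 1.0)
        hist = isi_distribution(rng.uniform(0.0, 3.0, 30000), cfg)
        slope = stats.linregress(centers[m], hist[m]).slope
        assert abs(slope) < 0.5  # normalized counts per second

    def test_linear_ramp_matches_closed_form_ols(self, tiny_dataset):
        # build ISIs whose histogram is an exact ramp over [1.0, 1.1)
        import dataclasses
        cfg = FeatureConfig()
        from spikeloc.features import isi_bin_edges

        edges = isi_bin_edges(cfg)
        centers = (edges[:-1] + edges[1:]) / 2
        m = np.flatnonzero((centers >= 1.0) & (centers < 1.1))
        isis = np.concatenate([
            np.full(k + 1, centers[b]) for k, b in enumerate(m)
        ])
        spikes = np.concatenate([[0.0], np.cumsum(isis)])
        u0 = tiny_dataset.units[0]
        sdf = tiny_dataset.stimuli
        ds = dataclasses.replace(
            tiny_dataset, units=(dataclasses.replace(u0, spike_times_s=spikes),)
        )
        ws = isi_window_stats(ds, (1.0, 1.1))
        # closed form: normalized histogram is counts/max = (k+1)/10 on the
        # 10 ramp bins; OLS slope of y = (k+1)/10 against x = centers
        y = (np.arange(10) + 1) / 10
        x = centers[m]
        expect = np.polyfit(x, y, 1)[0]
        assert ws.table.iloc[0]["slope"] == pytest.approx(expect, rel=1e-6)

    def test_unit_without_inwindow_isis_excluded(self, tiny_dataset):
        import dataclasses
        u0 = tiny_dataset.units[0]
        ds = dataclasses.replace(
            tiny_dataset,
            units=(dataclasses.replace(u0, spike_times_s=np.array([0.0, 2.9])),),
        )
        ws = isi_window_stats(ds, (0.0, 1.0))
        assert len(ws.table) == 0


class TestCompareWindowStats:
    def _stats(self, rng, shift=0.0, n=200):
        a = rng.normal(0.0, 1.0, size=(n, 3))
        b = rng.normal(shift, 1.0, size=(n, 3))
        table = pd.DataFrame(
            np.vstack([a, b]), columns=["mean_s", "variance_s2", "slope"],
            index=[f"u{i}" for i in range(2 * n)],
        )
        from spikeloc.interpret import WindowStats
        labels = pd.Series(["x"] * n + ["y"] * n, index=table.index)
        return WindowStats((0.0, 1.0), table), labels

    def test_identical_distributions_small_effect(self):
        rng = np.random.default_rng(10)
        ws, labels = self._stats(rng, shift=0.0)
        out = compare_window_stats(ws, labels, "x")
        assert (out["abs_cohens_d"] < 0.25).all()

    def test_planted_one_sd_shift_gives_d_near_one(self):
        rng = np.random.default_rng(11)
        ws, labels = self._stats(rng, shift=1.0, n=2000)
        out = compare_window_stats(ws, labels, "y")
        np.testing.assert_allclose(out["abs_cohens_d"], 1.0, atol=0.12)
        assert out["significant"].all()

    def test_bonferroni_threshold_is_alpha_over_m(self):
        rng = np.random.default_rng(12)
        ws, labels = self._stats(rng, shift=0.3)
        out = compare_window_stats(ws, labels, "x", alpha=0.05)
        # three statistics -> corrected threshold 0.05/3
        assert (out["significant"] == (out["p"] < 0.05 / 3)).all()
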