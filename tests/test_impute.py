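import numpy as np
import pandas as pd
import pytest

from misonet.datamodel import MultiOmicsDataset, OmicsMatrix, PriorNetwork
from misonet.impute import (
    ImputationError,
    KnnConfig,
    NgMiceConfig,
    knn_impute,
    ngmice_impute,
    ngmice_predictor_sets,
)
from misonet.synthetic import generate_ground_truth, inject_random_missingness, simulate_dataset


def _matrix(arr, columns, layer="expression"):
    arr = np.asarray(arr, dtype=float)
    idx = [f"s{i}" for i in range(arr.shape[0])]
    return OmicsMatrix(layer, pd.DataFrame(arr, index=idx, columns=columns))


class TestKnnImpute:
    def test_complete_matrix_unchanged(self, small_ds):
        m = small_ds.layers["expression"]
        out = knn_impute(m, KnnConfig(k=3))
        assert out.values.equals(m.values)

    def test_observed_entries_bit_identical(self, small_ds):
        ds = inject_random_missingness(small_ds, ["expression"], 0.2, seed=1)
        m = ds.layers["expression"]
        out = knn_impute(m, KnnConfig(k=5))
        mask = m.mask.to_numpy()
        assert np.array_equal(
            out.values.to_numpy()[mask], m.values.to_numpy()[mask]
        )
        assert out.mask.to_numpy().all()

    def test_toy_neighbour_mean_matches_hand_computation(self):
        # f2 and f3 track f1 closely; f4 is far away
        vals = np.array([
            [np.nan, 1.1, 0.9, 10.0],
            [2.0, 2.1, 1.9, 12.0],
            [3.0, 3.1, 2.9, 9.0],
            [4.0, 4.1, 3.9, 11.0],
            [5.0, 5.1, 4.9, 13.0],
        ])
        m = _matrix(vals, ["f1", "f2", "f3", "f4"])
        out = knn_impute(m, KnnConfig(k=2))
        # exhaustive distance computation identifies f2, f3 as the 2 nearest
        obs = ~np.isnan(vals[:, 0])
        dists = {
            j: np.mean((vals[obs, 0] - vals[obs, j]) ** 2) for j in range(1, 4)
        }
        nearest = sorted(dists, key=dists.get)[:2]
        assert set(nearest) == {1, 2}
        expected = np.mean([vals[0, 1], vals[0, 2]])
        assert out.values.iat[0, 0] == pytest.approx(expected)

    def test_rowmax_violation_uses_per_sample_mean(self):
        vals = np.array([
            [np.nan, 1.0, 2.0],
            [np.nan, 2.0, 4.0],
            [np.nan, 3.0, 6.0],
            [1.0, 4.0, 8.0],
            [2.0, 5.0, 10.0],
        ])
        m = _matrix(vals, ["f1", "f2", "f3"])
        out = knn_impute(m, KnnConfig(k=2, rowmax=0.5))
        # f1 is 60% missing -> per-sample mean over observed features
        for i in range(3):
            assert out.values.iat[i, 0] == pytest.approx(np.nanmean(vals[i, 1:]))

    def test_k_all_features_degenerates_to_row_restricted_mean(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(8, 5))
        vals[2, 0] = np.nan
        m = _matrix(vals, [f"f{j}" for j in range(5)])
        out = knn_impute(m, KnnConfig(k=4))
        assert out.values.iat[2, 0] == pytest.approx(np.nanmean(vals[2, 1:]))

    def test_too_few_features_rejected(self):
        vals = np.array([[1.0, np.nan], [2.0, 1.0], [3.0, 2.0]])
        with pytest.raises(ImputationError):
            knn_impute(_matrix(vals, ["a", "b"]), KnnConfig(k=5))

    def test_maxp_split_still_fills_everything(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(20, 30))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        m = _matrix(vals, [f"f{j}" for j in range(30)])
        out = knn_impute(m, KnnConfig(k=3, maxp=10))
        assert out.mask.to_numpy().all()
        obs = ~np.isnan(vals)
        assert np.array_equal(out.values.to_numpy()[obs], vals[obs])


def _corr_dataset(seed=0):
    """Dataset where g0 is strongly tracked by g1, weakly by others."""
    rng = np.random.default_rng(seed)
    n = 60
    g1 = rng.normal(size=n)
    g0 = g1 + 0.1 * rng.normal(size=n)
    rest = rng.normal(size=(n, 4))
    vals = np.column_stack([g0, g1, rest])
    vals[:6, 0] = np.nan
    cols = [f"g{j}" for j in range(6)]
    ds = MultiOmicsDataset({"expression": _matrix(vals, cols)})
    layer_of = {c: "expression" for c in cols}
    return ds, layer_of, vals


class TestNgMicePredictorSets:
    def test_filter_only_path_keeps_all_passing_neighbours(self):
        ds, layer_of, _ = _corr_dataset()
        rng = np.random.default_rng(9)
        # make every other gene correlate with g0 via g1? simpler: neighbours
        # with guaranteed strong correlation: use all columns as neighbours of g0
        edges = {("g0", f"g{j}") for j in range(1, 6)}
        prior = PriorNetwork(edges, layer_of)
        cfg = NgMiceConfig(r_threshold=0.0, k_top=2)
        sets = ngmice_predictor_sets(ds, prior, cfg)
        assert set(sets["g0"]) == {f"g{j}" for j in range(1, 6)}

    def test_top_k_fallback_when_few_neighbours_pass(self):
        ds, layer_of, vals = _corr_dataset()
        prior = PriorNetwork({("g0", "g5")}, layer_of)  # one weak neighbour
        cfg = NgMiceConfig(r_threshold=0.95, k_top=3)
        sets = ngmice_predictor_sets(ds, prior, cfg)
        # fallback: top-3 |r| over all features; g1 must rank first
        df = pd.DataFrame(vals, columns=[f"g{j}" for j in range(6)])
        r = df.corr()["g0"].drop("g0").abs().sort_values(ascending=False)
        assert sets["g0"] == list(r.index[:3])

    def test_fully_observed_features_absent(self):
        ds, layer_of, _ = _corr_dataset()
        prior = PriorNetwork({("g0", "g1")}, layer_of)
        sets = ngmice_predictor_sets(ds, prior, NgMiceConfig())
        assert set(sets) == {"g0"}


class TestNgMiceImpute:
    def test_no_missingness_gives_identical_copies(self, small_ds, small_gt):
        imp = ngmice_impute(small_ds, small_gt.prior, NgMiceConfig(D=3, seed=1))
        assert imp.D == 3
        for c in imp.completed:
            for name in small_ds.layers:
                assert c.layers[name].values.equals(small_ds.layers[name].values)

    def test_observed_entries_identical_and_pmm_in_support(self):
        ds, layer_of, vals = _corr_dataset()
        prior = PriorNetwork({("g0", "g1")}, layer_of)
        imp = ngmice_impute(ds, prior, NgMiceConfig(D=4, seed=2))
        observed_support = vals[~np.isnan(vals[:, 0]), 0]
        for c in imp.completed:
            got = c.layers["expression"].values.to_numpy()
            obs = ~np.isnan(vals)
            assert np.array_equal(got[obs], vals[obs])
            for v in got[:6, 0]:  # imputed cells
                assert v in observed_support  # PMM donor property

    def test_two_seeds_differ_only_at_missing_cells(self):
        ds, layer_of, vals = _corr_dataset()
        prior = PriorNetwork({("g0", "g1")}, layer_of)
        a = ngmice_impute(ds, prior, NgMiceConfig(D=2, seed=1))
        b = ngmice_impute(ds, prior, NgMiceConfig(D=2, seed=99))
        va = a.completed[0].layers["expression"].values.to_numpy()
        vb = b.completed[0].layers["expression"].values.to_numpy()
        obs = ~np.isnan(vals)
        assert np.array_equal(va[obs], vb[obs])
        assert not np.array_equal(va[:6, 0], vb[:6, 0])

    def test_empty_predictor_set_rejected(self):
        vals = np.array([[np.nan, 1.0], [1.0, 2.0], [2.0, 1.5], [3.0, 2.5]])
        ds = MultiOmicsDataset({"expression": _matrix(vals, ["a", "b"])})
        prior = PriorNetwork(set(), {"a": "expression", "b": "expression"})
        cfg = NgMiceConfig(k_top=5)
        # with k_top fallback a predictor always exists; force the error by
        # making the only other column constant (zero variance)
        vals2 = vals.copy()
        vals2[:, 1] = 1.0
        ds2 = MultiOmicsDataset({"expression": _matrix(vals2, ["a", "b"])})
        with pytest.raises(ImputationError):
            ngmice_impute(ds2, prior, cfg)

    def test_methylation_imputations_clipped(self, small_gt):
        ds = simulate_dataset(small_gt, 40, seed=3)
        ds_m = inject_random_missingness(ds, ["methylation"], 0.2, seed=4)
        imp = ngmice_impute(ds_m, small_gt.prior, NgMiceConfig(D=2, seed=5))
        for c in imp.completed:
            meth = c.layers["methylation"].values.to_numpy()
            assert ((meth >= 0) & (meth <= 1)).all()


def test_imputation_rmse_improves_with_predictor_correlation():
    """Masked-then-known RMSE decreases as the true correlation rises."""
    rng = np.random.default_rng(11)
    n = 80
    rmses = []
    for noise in (2.0, 0.5, 0.05):  # decreasing noise = increasing correlation
        g1 = rng.normal(size=n)
        g0 = g1 + noise * rng.normal(size=n)
        vals = np.column_stack([g0, g1, rng.normal(size=(n, 2))])
        truth = vals[:10, 0].copy()
        vals_missing = vals.copy()
        vals_missing[:10, 0] = np.nan
        cols = ["g0", "g1", "g2", "g3"]
        ds = MultiOmicsDataset({"expression": _matrix(vals_missing, cols)})
        prior = PriorNetwork({("g0", "g1")}, {c: "expression" for c in cols})
        imp = ngmice_impute(ds, prior, NgMiceConfig(D=3, seed=7))
        est = np.mean(
            [c.layers["expression"].values.to_numpy()[:10, 0] for c in imp.completed], axis=0
        )
        rmses.append(float(np.sqrt(np.mean((est - truth) ** 2))))
    assert rmses[0] > rmses[1] > rmses[2]
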