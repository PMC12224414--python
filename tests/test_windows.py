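import numpy as np
import pandas as pd
import pytest

from rsldecode import (
    NeuralFeatureMatrix,
    SearchSpec,
    TrialTimeseries,
    WindowSpec,
    average_repetitions,
    boxcar_downsample,
    censor_outliers,
    evaluate_predictions,
    flatten_timeseries,
    make_synthetic_ephys,
    run_study,
    score_reconstruction,
    slice_windows,
)
from rsldecode.errors import RSLError


def _nfm(X, times=None):
    m = X.shape[1]
    times = times if times is not None else list(range(m))
    cmap = [(0, t) for t in times]
    return NeuralFeatureMatrix(X, cmap, [str(i) for i in range(X.shape[0])])


class TestPreprocessing:
    def test_boxcar_means_and_counts(self, rng):
        v = rng.standard_normal((3, 2, 1000))
        out = boxcar_downsample(v, 1000, 100)
        assert out.shape == (3, 2, 100)
        assert np.allclose(out[..., 0], v[..., :10].mean(axis=-1))
        boxcar = np.zeros(10)
        boxcar[-1] = 10.0
        assert boxcar_downsample(boxcar, 1000, 100)[0] == pytest.approx(1.0)

    def test_boxcar_constant_preserved(self):
        v = np.full((2, 1, 50), 3.3)
        assert np.allclose(boxcar_downsample(v, 500, 100), 3.3)

    def test_boxcar_nondivisible_rates_rejected(self):
        with pytest.raises(RSLError):
            boxcar_downsample(np.zeros((1, 1, 100)), 1000, 300)

    def test_average_repetitions(self, rng):
        v = rng.standard_normal((4, 4, 2, 10))
        out = average_repetitions(v)
        assert out.shape == (4, 2, 10)
        assert np.allclose(out, v.mean(axis=1))
        # opposite repetitions cancel
        pair = np.stack([v[:, 0], -v[:, 0]], axis=1)
        assert np.allclose(average_repetitions(pair), 0.0)

    def test_average_repetitions_with_missing(self, rng):
        v = rng.standard_normal((2, 3, 1, 4))
        v[0, 2] = np.nan
        out = average_repetitions(v)
        assert np.allclose(out[0], v[0, :2].mean(axis=0))


class TestCensoring:
    def test_clean_matrix_untouched(self, rng):
        nfm = _nfm(rng.standard_normal((40, 200)))
        out, report = censor_outliers(nfm)
        assert report["removed_columns"] == [] and report["removed_rows"] == []
        assert out.X.shape == (40, 200)

    def test_shifted_column_removed_rows_kept(self, rng):
        X = rng.standard_normal((40, 200))
        X[:, 7] += 100.0
        out, report = censor_outliers(_nfm(X))
        assert report["removed_columns"] == [7]
        assert report["removed_rows"] == []
        assert len(out.column_map) == 199

    def test_column_first_order_protects_the_row(self, rng):
        """A single wild cell inflates both its column and row means; removing
        the column first (then recomputing) must leave the row in place."""
        X = rng.standard_normal((40, 200))
        X[3, 7] += 4000.0
        out, report = censor_outliers(_nfm(X))
        assert report["removed_columns"] == [7]
        assert report["removed_rows"] == []
        assert "3" in out.item_ids

    def test_two_column_shift_is_masked_by_its_own_spread(self):
        # with only two columns the shifted column dominates the spread of
        # the marginal means, so the 5-SD rule keeps both (masking)
        X = np.zeros((5, 2))
        X[:, 0] = 1e9
        out, _ = censor_outliers(_nfm(X))
        assert out.X.shape[1] == 2

    def test_invalid_threshold_rejected(self, rng):
        with pytest.raises(RSLError):
            censor_outliers(_nfm(rng.standard_normal((5, 5))), threshold_sd=0)


class TestWindows:
    def test_opening_spec_widths(self):
        spec = WindowSpec.opening()
        widths = [w for w in spec.widths]
        assert widths == [50.0] + [float(k) for k in range(100, 1001, 100)]
        assert len(spec.windows()) == 11
        assert all(o == 0.0 for o in spec.onsets)

    def test_moving_spec_count_and_equal_sizes(self, ephys):
        spec = WindowSpec.moving()
        assert len(spec.windows()) == 19
        nfm = NeuralFeatureMatrix(ephys.X, ephys.column_map, ephys.item_ids, ephys.domains)
        sizes = {w.X.shape[1] for _, w in slice_windows(nfm, spec)}
        assert sizes == {200}  # 20 electrodes x 10 timepoints of 10 ms

    def test_full_mode_returns_input(self, ephys):
        nfm = NeuralFeatureMatrix(ephys.X, ephys.column_map, ephys.item_ids, ephys.domains)
        out = slice_windows(nfm, WindowSpec.full())
        assert len(out) == 1
        assert out[0][1].X.shape == nfm.X.shape

    def test_empty_window_rejected(self):
        nfm = _nfm(np.zeros((3, 5)), times=[0, 10, 20, 30, 40])
        with pytest.raises(RSLError):
            slice_windows(nfm, WindowSpec("moving", (500.0,), (100.0,)))

    def test_flatten_round_trip_tags(self, rng):
        ts = TrialTimeseries(rng.standard_normal((4, 3, 10)), rate_hz=100)
        nfm = flatten_timeseries(ts)
        assert nfm.X.shape == (4, 30)
        assert nfm.column_map[0] == (0, 0)
        assert nfm.column_map[10] == (1, 0)
        assert nfm.column_map[-1] == (2, 90)


class TestEvaluation:
    def test_perfect_predictions_score_one(self, embedding):
        ev = evaluate_predictions(embedding.coords, embedding)
        assert np.allclose(ev["value"], 1.0)
        rec = score_reconstruction(embedding.coords, embedding)
        assert np.allclose(rec["value"], 1.0)

    def test_negated_predictions_score_minus_one(self, embedding):
        ev = evaluate_predictions(-embedding.coords, embedding)
        assert np.allclose(ev["value"], -1.0)

    def test_domain_code_signature(self, embedding):
        """Predictions carrying only each domain's mean coordinates decode
        across domains but not within them (the binary-code signature)."""
        dom = np.asarray(embedding.domains)
        pred = embedding.coords.copy()
        for lab in np.unique(dom):
            pred[dom == lab] = embedding.coords[dom == lab].mean(axis=0)
        ev = evaluate_predictions(pred, embedding)
        all_d1 = ev[(ev.dimension == 1) & (ev.subset == "all")]["value"].iloc[0]
        within = ev[ev.subset != "all"]["value"]
        assert all_d1 > 0.8
        assert within.isna().all() or np.nanmax(np.abs(within)) < 1e-6

    def test_zero_predictions_reported_missing(self, embedding):
        rec = score_reconstruction(np.zeros_like(embedding.coords), embedding)
        assert rec["value"].isna().all()
        ev = evaluate_predictions(np.zeros_like(embedding.coords), embedding)
        assert ev["value"].isna().all()

    def test_reconstruction_grid_is_group_by_scope(self, embedding):
        rec = score_reconstruction(embedding.coords, embedding)
        assert set(rec["group"]) == {"all", "animate", "inanimate"}
        assert set(rec["scope"]) == {"all others", "same domain", "other domain"}
        assert len(rec) == 9


class TestRunStudy:
    def test_planted_band_recovered_in_moving_windows(self, embedding):
        """Three synthetic subjects, moving windows: centered statistics are
        reliably positive only for windows overlapping the planted band."""
        subjects = {}
        for s in range(3):
            eph = make_synthetic_ephys(embedding, n_electrodes=6, n_timepoints=20,
                                       n_signal_columns=16, snr=4.0, seed=100 + s,
                                       signal_window=(200.0, 600.0))
            subjects[f"s{s}"] = NeuralFeatureMatrix(
                eph.X, eph.column_map, eph.item_ids, eph.domains
            )
        spec = WindowSpec.moving(width=200.0, step=200.0)  # 5 windows of 4 bins
        grid = ({"alpha": 1e-3, "lam": 1.0, "omega": 0.3},
                {"alpha": 1e-2, "lam": 1.0, "omega": 0.3})
        out = run_study(
            subjects, embedding, spec, family="growl",
            search=SearchSpec(method="grid", candidates=grid, max_budget=150),
            n_perm=10, n_group=500, seed=0, censor=False,
            retune_permutations=False, tol=1e-5,
        )
        grp = out["group"]
        assert out["failed_subjects"] == []
        d1 = grp[(grp.dimension == 1) & (grp.subset == "all")].set_index("window")
        in_band = ["200-400", "400-600"]
        out_band = ["0-200", "800-1000"]
        assert d1.loc[in_band, "centered"].min() > 0.5
        assert d1.loc[in_band, "p"].max() <= 0.1
        assert d1.loc[out_band, "centered"].max() < 0.4
        assert set(grp.columns) >= {"observed", "sem", "centered", "p", "p_adj"}

    def test_empty_window_list_rejected(self, embedding):
        with pytest.raises(RSLError):
            run_study({}, embedding, WindowSpec("moving", (), ()))
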