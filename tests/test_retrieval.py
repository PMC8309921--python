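"""Tests of weighting, fitting, BIC selection, and end-to-end retrieval."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sifsvd import (
    RetrievalConfig,
    SNRModel,
    build_design_matrix,
    compute_bic,
    compute_rss,
    compute_weights,
    fit_linear_model,
    make_scene_set,
    make_pattern_scenes,
    predict_radiance,
    retrieve_batch,
    retrieve_sif,
    select_num_svs,
)
from sifsvd.forward import DesignMatrix


def _in_span_spectrum(basis, config, nv, fs, rng, v1_amp=300.0):
    """Synthetic windowed spectrum exactly in the model span with known Fs."""
    dm = build_design_matrix(basis, config, nv)
    c = rng.normal(0.0, 1.0, size=dm.n_columns)
    c[0] = v1_amp
    c[dm.hf_index] = fs
    return dm, c, predict_radiance(dm, c)


class TestComputeWeights:
    def test_reciprocal_uncertainty_closed_form(self):
        w = compute_weights(np.full(4, 100.0), SNRModel(offset=300.0))
        np.testing.assert_allclose(w, 3.0)
        w2 = compute_weights(np.full(4, 200.0), SNRModel(offset=300.0))
        np.testing.assert_allclose(w2, 1.5)  # L doubled -> weight halved

    def test_nonpositive_radiance_masked_with_length_preserved(self, caplog):
        radiance = np.full(160, 80.0)
        radiance[7] = -1.0
        with caplog.at_level("WARNING", logger="sifsvd.retrieval"):
            w = compute_weights(radiance, SNRModel())
        assert w.shape == (160,)
        assert w[7] == 0.0
        assert np.count_nonzero(w) == 159
        # masked channel contributes nothing to the RSS
        rss = compute_rss(radiance, np.zeros_like(radiance), w)
        assert rss == pytest.approx(159 * (300.0) ** 2)

    def test_hard_error_mode(self):
        with pytest.raises(ValueError, match="non-positive"):
            compute_weights(np.array([1.0, -1.0]), SNRModel(), on_nonpositive="raise")


class TestFitLinearModel:
    def test_in_span_recovery_with_uniform_weights(self, basis, config, rng):
        dm, c, spectrum = _in_span_spectrum(basis, config, 5, 0.7, rng)
        fitted, cov = fit_linear_model(dm, spectrum)
        np.testing.assert_allclose(fitted, c, rtol=1e-7, atol=1e-9)
        assert cov.shape == (dm.n_columns, dm.n_columns)

    def test_duplicate_column_raises_named_error(self, basis, config):
        dm = build_design_matrix(basis, config, nv=3)
        bad = DesignMatrix(
            matrix=np.column_stack([dm.matrix, dm.matrix[:, 1]]),
            column_labels=dm.column_labels + ("dup",),
            wavelengths=dm.wavelengths,
            window_mask=dm.window_mask,
            poly_order=dm.poly_order,
            nv=dm.nv,
        )
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_linear_model(bad, np.ones(len(dm.wavelengths)))

    def test_matches_normal_equations_oracle(self, basis, config, rng):
        """Independent oracle: solve (A^T W^2 A) c = A^T W^2 y directly."""
        dm = build_design_matrix(basis, config, nv=6)
        y = predict_radiance(dm, rng.normal(1.0, 2.0, dm.n_columns)) + rng.normal(
            0.0, 0.1, len(dm.wavelengths)
        )
        w = rng.uniform(0.5, 4.0, size=len(dm.wavelengths))
        fitted, _ = fit_linear_model(dm, y, w)
        w2 = np.diag(w**2)
        oracle = np.linalg.solve(dm.matrix.T @ w2 @ dm.matrix, dm.matrix.T @ w2 @ y)
        np.testing.assert_allclose(fitted, oracle, rtol=1e-6)

    def test_needs_more_channels_than_coefficients(self, basis, config):
        dm = build_design_matrix(basis, config, nv=5)
        w = np.zeros(len(dm.wavelengths))
        w[: dm.n_columns] = 1.0
        with pytest.raises(ValueError, match="unmasked channels"):
            fit_linear_model(dm, np.ones(len(dm.wavelengths)), w)


class TestRssAndBic:
    def test_rss_conventions(self):
        y = np.array([5.0])
        yhat = np.array([2.0])
        w = np.array([2.0])
        assert compute_rss(y, y, w) == 0.0
        assert compute_rss(y, yhat, w, squared_weights=True) == pytest.approx(36.0)
        assert compute_rss(y, yhat, w, squared_weights=False) == pytest.approx(18.0)

    def test_uniform_weights_reduce_to_plain_sum_of_squares(self, rng):
        y = rng.normal(size=100)
        yhat = rng.normal(size=100)
        assert compute_rss(y, yhat) == pytest.approx(np.sum((y - yhat) ** 2))

    def test_bic_closed_form_and_penalty(self):
        assert compute_bic(160.0, 160, 7) == pytest.approx(7 * np.log(160.0), abs=1e-12)
        assert compute_bic(160.0, 160, 14) - compute_bic(160.0, 160, 7) == pytest.approx(
            7 * np.log(160.0)
        )

    def test_bic_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="rss"):
            compute_bic(0.0, 160, 7)
        with pytest.raises(ValueError, match="k"):
            compute_bic(1.0, 160, 0)


class TestSelectNumSvs:
    def test_single_candidate_is_returned(self, basis, config, rng):
        _, _, spectrum = _in_span_spectrum(basis, config, 5, 0.5, rng)
        nv, bic_map = select_num_svs(basis, config.replace(nv_candidates=(5,)), spectrum)
        assert nv == 5
        assert set(bic_map) == {5}

    def test_selected_candidate_attains_minimum_of_returned_map(self, basis, config, rng):
        scenes = make_pattern_scenes(basis, 5, n_patterns=5, seed=77)
        for row in scenes.spectra:
            w = compute_weights(
                row[basis.grid.window_mask(*config.window)], scenes.snr
            )
            nv, bic_map = select_num_svs(basis, config, row, w)
            assert bic_map[nv] == min(bic_map.values())
            ties = [k for k, v in bic_map.items() if v == bic_map[nv]]
            assert nv == min(ties)

    def test_modal_selection_matches_generating_pattern_count(self, big_basis, config):
        """Scenes built from five spectral patterns: BIC most often keeps five."""
        scenes = make_pattern_scenes(big_basis, 60, n_patterns=5, seed=78)
        picks = [
            retrieve_sif(row, big_basis, config, snr=scenes.snr).nv_selected
            for row in scenes.spectra
        ]
        values, counts = np.unique(picks, return_counts=True)
        assert values[np.argmax(counts)] == 5

    def test_all_candidates_failing_raises_with_diagnostics(self, basis, config, rng):
        _, _, spectrum = _in_span_spectrum(basis, config, 3, 0.5, rng)
        with pytest.raises(RuntimeError, match="candidate"):
            select_num_svs(basis, config.replace(nv_candidates=(99,)), spectrum)


class TestRetrieveSif:
    def test_noiseless_in_span_amplitude_recovered_exactly(self, basis, config, rng):
        _, _, spectrum = _in_span_spectrum(basis, config, 5, 0.8, rng)
        result = retrieve_sif(spectrum, basis, config)
        assert result.fs == pytest.approx(0.8, rel=1e-6)
        assert result.sif_at_ref == pytest.approx(
            0.8 * np.exp(-(35.0**2) / 1800.0), rel=1e-6
        )

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(c=st.floats(-2.0, 4.0))
    def test_adding_fluorescence_shifts_amplitude_by_that_amount(self, basis, c):
        config = RetrievalConfig()
        rng = np.random.default_rng(55)
        dm, _, spectrum = _in_span_spectrum(basis, config, 4, 0.3, rng)
        base = retrieve_sif(spectrum, basis, config, nv=4).fs
        hf_col = dm.matrix[:, dm.hf_index]
        shifted = retrieve_sif(spectrum + c * hf_col, basis, config, nv=4).fs
        assert shifted - base == pytest.approx(c, abs=1e-8)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(scale=st.floats(0.01, 100.0))
    def test_scale_equivariance(self, grid, solar, training_matrix, scale):
        from sifsvd import compute_svs, simulate_toa_radiance, SceneTruth

        basis = compute_svs(training_matrix, grid, 8)
        scaled_basis = compute_svs(scale * training_matrix, grid, 8)
        spectrum, _ = simulate_toa_radiance(grid, solar, SceneTruth(fs_true=0.9))
        cfg = RetrievalConfig()
        fs = retrieve_sif(spectrum, basis, cfg, snr=SNRModel(), nv=5).fs
        fs_scaled = retrieve_sif(
            scale * spectrum, scaled_basis, cfg, snr=SNRModel(), nv=5
        ).fs
        assert fs_scaled == pytest.approx(scale * fs, rel=1e-6)

    def test_bic_selection_invariant_to_radiance_rescaling(self, basis, config, rng):
        scenes = make_pattern_scenes(basis, 3, n_patterns=4, seed=79)
        for row in scenes.spectra:
            nv_a, _ = select_num_svs(basis, config, row)
            nv_b, _ = select_num_svs(basis, config, 7.5 * row)
            assert nv_a == nv_b

    def test_uncertainty_positive_and_calibrated(self, big_basis, config):
        """Empirical scatter agrees with the reported 1-sigma on in-span scenes."""
        scenes = make_pattern_scenes(
            big_basis, 500, n_patterns=5, seed=80, fs_range=(0.8, 0.8)
        )
        results = [
            retrieve_sif(row, big_basis, config, snr=scenes.snr, nv=5)
            for row in scenes.spectra
        ]
        fs = np.array([r.fs for r in results])
        unc = np.array([r.fs_uncertainty for r in results])
        assert np.all(unc > 0)
        assert np.std(fs, ddof=1) == pytest.approx(unc.mean(), rel=0.25)


class TestRetrieveBatch:
    def test_empty_batch_returns_empty_table(self, basis, config):
        table = retrieve_batch(np.empty((0, basis.grid.n_channels)), basis, config)
        assert len(table) == 0
        assert "fs" in table.columns and "flag" in table.columns

    def test_batch_recovery_slope_near_unity(self, grid, solar, big_basis, config):
        scenes = make_scene_set(grid, solar, 300, seed=81, fs_range=(0.0, 2.0))
        table = retrieve_batch(scenes, big_basis, config)
        assert len(table) == 300
        assert (table["flag"] == "ok").all()
        slope = np.polyfit(scenes.fs_true, table["fs"].to_numpy(), 1)[0]
        assert 0.95 <= slope <= 1.05

    def test_corrupt_sounding_is_flagged_and_isolated(self, basis, config):
        scenes = make_pattern_scenes(basis, 10, n_patterns=3, seed=82)
        spectra = scenes.spectra.copy()
        spectra[4] = np.nan
        table = retrieve_batch(spectra, basis, config, snr=scenes.snr)
        assert len(table) == 10
        flags = table["flag"].to_numpy()
        assert (flags[np.arange(10) != 4] == "ok").all()
        assert flags[4].startswith("error")
        assert np.isnan(table["fs"].to_numpy()[4])
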