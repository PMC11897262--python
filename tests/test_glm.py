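"""Design matrix, OLS t maps and block-peak preference maps."""

import numpy as np
import pytest
from scipy import stats

from vasomap.glm import (
    BlockTable,
    block_peak_responses,
    build_design_matrix,
    fit_glm,
    preference_map,
    t_contrast,
)
from vasomap.config import NoiseConfig, tiny_config
from vasomap.pipeline import build_study, simulate_run
from vasomap.preproc import ContrastSeries
from vasomap.stimulus import build_block_timeline


@pytest.fixture(scope="module")
def zero_drift_study():
    """Tiny zero-noise, zero-drift study: block responses are exactly
    periodic, so same-condition amplitudes must agree to float precision."""
    cfg = tiny_config()
    cfg.noise = NoiseConfig(zero_noise=True)
    cfg.vascular.drift_per_run = 0.0
    cfg.n_runs = 1
    study = build_study(cfg)
    return study, simulate_run(study, 0)


@pytest.fixture(scope="module")
def default_design():
    tl = build_block_timeline()
    return build_design_matrix(tl, n_timepoints=738, sampling_interval=2.610 / 2)


@pytest.fixture(scope="module")
def small_design():
    """<=100 timepoints, un-upsampled: 4 + 2*24 = 52 pairs."""
    tl = build_block_timeline(n_initial_rest=4, n_blocks=2)
    return tl, build_design_matrix(tl, n_timepoints=52, sampling_interval=2.610)


class TestDesignMatrix:
    def test_default_shape_and_boxcar_count(self, default_design):
        X = default_design.X
        assert X.shape == (738, 4)
        # 14 blocks of 12 pairs, upsampled x2 -> 24 active rows per block.
        assert (X[:, 2] + X[:, 3]).sum() == 24 * 14 == 336

    def test_dc_ramp_and_disjoint_boxcars(self, default_design):
        X = default_design.X
        assert np.all(X[:, 0] == 1)
        assert X[:, 1].mean() == pytest.approx(0.0, abs=1e-12)
        assert set(np.unique(X[:, 2:])) <= {0.0, 1.0}
        assert np.all(X[:, 2] * X[:, 3] == 0)

    def test_length_mismatch_rejected(self):
        tl = build_block_timeline()
        with pytest.raises(ValueError):
            build_design_matrix(tl, n_timepoints=700, sampling_interval=2.610 / 2)


class TestFitGLM:
    def test_noiseless_recovery_machine_precision(self, small_design):
        _, design = small_design
        beta_true = np.array([100.0, 0.0, 2.0, 1.0])
        y = (design.X @ beta_true).reshape(1, 1, 1, -1)
        res = fit_glm(y, design)
        assert np.allclose(res.beta[0, 0, 0], beta_true, atol=1e-10)
        assert res.df == 52 - 4

    def test_matches_brute_force_normal_equations(self, small_design, rng):
        """Independent oracle: explicit normal equations + t formula."""
        _, design = small_design
        X = design.X
        y = X @ np.array([100.0, 1.0, 2.0, 1.0]) + rng.normal(0, 1.5, X.shape[0])
        res = fit_glm(y.reshape(1, 1, 1, -1), design)
        # Oracle computed from scratch.
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (X.shape[0] - 4)
        for c in ([0, 0, 1, 0], [0, 0, 0, 1], [0, 0, 1, -1]):
            c = np.asarray(c, float)
            t_oracle = (c @ beta) / np.sqrt(sigma2 * c @ xtx_inv @ c)
            assert t_contrast(res, c)[0, 0, 0] == pytest.approx(t_oracle, abs=1e-8)

    def test_symmetric_responses_give_zero_difference(self, small_design, rng):
        """Equal responses to both conditions null the difference contrast."""
        _, design = small_design
        y = (design.X @ np.array([50.0, 0.0, 3.0, 3.0])).reshape(1, 1, 1, -1)
        res = fit_glm(y, design)
        assert res.beta[0, 0, 0, 2] - res.beta[0, 0, 0, 3] == pytest.approx(0.0, abs=1e-10)
        # With symmetric noise added in the boxcar union, t is antisymmetric.
        noisy = y + rng.normal(0, 1.0, y.shape)
        res_n = fit_glm(noisy, design)
        assert t_contrast(res_n, [0, 0, 1, -1])[0, 0, 0] == pytest.approx(
            -t_contrast(res_n, [0, 0, -1, 1])[0, 0, 0]
        )

    def test_rank_deficiency_rejected(self):
        tl = build_block_timeline(n_initial_rest=4, n_blocks=2)
        bad = build_design_matrix(tl, n_timepoints=52, sampling_interval=2.610)
        bad.X[:, 1] = bad.X[:, 0]
        with pytest.raises(ValueError, match="rank"):
            fit_glm(np.zeros((1, 1, 1, 52)), bad)


class TestBlockPeaks:
    def test_noiseless_blocks_have_equal_amplitudes(self, zero_drift_study):
        study, run = zero_drift_study
        series = ContrastSeries(
            data=run.not_nulled, tag="not_nulled", dt=study.timeline.tr_pair
        )
        table = block_peak_responses(series, study.timeline)
        conds = np.array(table.conditions)
        gm = study.geometry.gm_mask
        for cond in ("RF0", "RF4"):
            amps = table.amplitudes[..., conds == cond][gm]
            assert np.allclose(amps, amps[:, :1], atol=1e-9)

    def test_rest_only_series_has_zero_amplitudes(self):
        tl = build_block_timeline(n_initial_rest=4, n_blocks=2)
        series = ContrastSeries(
            data=np.full((2, 2, 2, 52), 100.0), tag="bold", dt=2.610
        )
        table = block_peak_responses(series, tl)
        assert np.all(table.amplitudes == 0)

    def test_preferred_condition_has_larger_amplitude(self, tiny_zero_study):
        study, run = tiny_zero_study["study"], tiny_zero_study["run"]
        series = ContrastSeries(
            data=run.not_nulled, tag="not_nulled", dt=study.timeline.tr_pair
        )
        table = block_peak_responses(series, study.timeline)
        conds = np.array(table.conditions)
        p = study.domains.p
        vox = study.geometry.gm_mask & (p == 1)
        rf0 = table.amplitudes[..., conds == "RF0"][vox].mean()
        rf4 = table.amplitudes[..., conds == "RF4"][vox].mean()
        assert rf0 > rf4

    def test_vaso_sign_inversion(self):
        """A CBV-weighted series that dips during blocks yields positive
        amplitudes after inversion."""
        tl = build_block_timeline(n_initial_rest=4, n_blocks=2)
        dip = 1.0 - 0.02 * np.isin(np.repeat(tl.labels, 1), ["RF0", "RF4"])
        series = ContrastSeries(
            data=np.broadcast_to(dip, (1, 1, 1, 52)).copy(),
            tag="vaso_corrected",
            dt=2.610,
        )
        table = block_peak_responses(series, tl)
        assert np.all(table.amplitudes > 0)

    def test_window_validation(self):
        tl = build_block_timeline()
        series = ContrastSeries(data=np.zeros((1, 1, 1, 369)), tag="bold", dt=2.610)
        with pytest.raises(ValueError):
            block_peak_responses(series, tl, peak_window=(5.22, 40.0))


class TestPreferenceMap:
    def _table(self, amps, conds=("RF0", "RF4", "RF0", "RF4"), tag="bold"):
        return BlockTable(
            amplitudes=np.asarray(amps, float),
            conditions=tuple(conds),
            tag=tag,
            peak_window=(5.22, 31.32),
            baseline_s=10.44,
        )

    def test_identical_amplitudes_give_zero(self):
        table = self._table(np.ones((1, 1, 1, 4)))
        assert preference_map(table).t[0, 0, 0] == 0.0

    def test_label_swap_negates_t(self, rng):
        amps = rng.standard_normal((2, 2, 1, 6))
        a = self._table(amps, conds=("RF0", "RF4") * 3)
        b = self._table(amps, conds=("RF4", "RF0") * 3)
        assert np.allclose(preference_map(a).t, -preference_map(b).t)

    def test_welch_matches_scipy(self, rng):
        """Dual route: vectorised Welch t against scipy.stats.ttest_ind."""
        amps = rng.standard_normal((3, 2, 2, 8))
        conds = ("RF0", "RF4") * 4
        table = self._table(amps, conds=conds)
        ours = preference_map(table, method="welch").t
        mask = np.array(conds) == "RF0"
        ref = stats.ttest_ind(
            amps[..., mask], amps[..., ~mask], axis=-1, equal_var=False
        ).statistic
        assert np.allclose(ours, ref)

    def test_pooled_matches_scipy_and_preserves_sign(self, rng):
        amps = rng.standard_normal((3, 2, 2, 8))
        conds = ("RF0", "RF4") * 4
        table = self._table(amps, conds=conds)
        pooled = preference_map(table, method="pooled").t
        welch = preference_map(table, method="welch").t
        mask = np.array(conds) == "RF0"
        ref = stats.ttest_ind(amps[..., mask], amps[..., ~mask], axis=-1).statistic
        assert np.allclose(pooled, ref)
        assert np.all(np.sign(pooled) == np.sign(welch))

    def test_too_few_blocks_rejected(self):
        table = self._table(np.ones((1, 1, 1, 2)), conds=("RF0", "RF4"))
        with pytest.raises(ValueError):
            preference_map(table)

    def test_zero_noise_sign_matches_ground_truth(self, tiny_zero_study):
        study, run = tiny_zero_study["study"], tiny_zero_study["run"]
        from vasomap.preproc import preprocess_interleaved

        vaso, bold = preprocess_interleaved(run)
        p = study.domains.p
        sel = study.geometry.gm_mask & (p != 0)
        signs = {}
        for name, ser in (("vaso", vaso), ("bold", bold)):
            table = block_peak_responses(ser, study.timeline)
            pref = preference_map(table)
            signs[name] = np.sign(pref.t)
            assert np.all(signs[name][sel] == np.sign(p[sel]))
        # Noiseless VASO and BOLD preference maps agree in sign in GM.
        assert np.all(signs["vaso"][sel] == signs["bold"][sel])
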