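"""Design construction, voxel-wise OLS, and adaptation contrasts."""

import numpy as np
import pandas as pd
import pytest

from adaptune import (
    VolumeSeries,
    adaptation_contrast,
    build_fir_design,
    build_hrf_design,
    default_tuning_grid,
    deviants_vs_identity,
    double_gamma_hrf,
    fit_glm,
    simulate_bold_run,
)
from adaptune.design import events_from_trials, TrialSpec
from adaptune.glm import DesignMatrix
from adaptune.simulate import GRADED, STEP, NoiseParams
from tests.conftest import QUIET, dice


def single_trial_events(length=5, condition="SC", onset=16.0):
    tr = TrialSpec(adaptor_object="a", adaptation_length=length,
                   deviant_condition=condition,
                   deviant_object="a" if condition == "I" else "dev",
                   n_deviant_presentations=2)
    ev = events_from_trials([tr], lead_fix=onset, trail_fix=16.0)
    return ev


class TestFirDesign:
    def test_column_sums_equal_event_counts(self, fmri_events):
        n_vols = int(fmri_events.attrs["run_duration"])
        X = build_fir_design(fmri_events, n_vols)
        df = X.to_frame()
        roles = fmri_events["stimulus_role"]
        for k in range(1, 10):
            assert df[f"adaptor_{k}"].sum() == (roles == f"adaptor_{k}").sum()
        for c in ("SC", "C", "D", "SD", "I"):
            n = ((roles == "deviant") & (fmri_events["condition"] == c)).sum()
            assert df[f"deviant_{c}"].sum() == n

    def test_ninth_position_only_in_longest_trials(self, fmri_events):
        n_vols = int(fmri_events.attrs["run_duration"])
        X = build_fir_design(fmri_events, n_vols)
        vols = np.flatnonzero(X.to_frame()["adaptor_9"].to_numpy())
        lengths = {
            int(fmri_events.loc[fmri_events["onset"] == v, "trial_index"].iloc[0])
            for v in vols
        }
        trial_lengths = fmri_events.groupby("trial_index").apply(
            lambda g: (g["stimulus_role"] != "deviant").sum(), include_groups=False)
        assert all(trial_lengths[t] == 9 for t in lengths)
        assert len(vols) == 10  # 20% of the 50 trials reach a ninth adaptor

    def test_single_trial_impulse_placement(self):
        ev = single_trial_events()
        X = build_fir_design(ev, int(ev.attrs["run_duration"]))
        col = X.to_frame()["adaptor_1"].to_numpy()
        assert col[16] == 1.0 and col.sum() == 1.0

    def test_unexpected_nuisance_count_warns(self, fmri_events):
        n_vols = int(fmri_events.attrs["run_duration"])
        with pytest.warns(UserWarning, match="nuisance"):
            build_fir_design(fmri_events, n_vols, nuisance=np.ones((n_vols, 3)))


class TestHrfDesign:
    def test_isolated_event_regressor_is_shifted_kernel(self):
        from tests.test_simulate import isolated_trial_events

        ev = isolated_trial_events(conditions=("SC", "C", "D", "SD", "I"))
        n_vols = int(ev.attrs["run_duration"])
        X = build_hrf_design(ev, n_vols)
        col = X.to_frame()["SC"].to_numpy()
        kernel = double_gamma_hrf(1.0)
        onset = int(ev.loc[ev["stimulus_role"] == "deviant", "onset"].iloc[0])
        expected = np.zeros(n_vols)
        for o in (onset, onset + 1):  # deviant presented twice
            seg = kernel[: n_vols - o]
            expected[o:o + len(seg)] += seg
        np.testing.assert_allclose(col, expected, atol=1e-12)

    def test_missing_condition_is_error(self):
        ev = single_trial_events(condition="SC")  # no Identity trials
        with pytest.raises(ValueError, match="all-zero"):
            build_hrf_design(ev, int(ev.attrs["run_duration"]))

    def test_linearity_under_amplitude_scaling(self, fmri_events):
        grid = default_tuning_grid((8, 8, 6))
        v1, nu = simulate_bold_run(fmri_events, grid, noise=QUIET, seed=0)
        v2, _ = simulate_bold_run(fmri_events, grid, noise=QUIET, seed=0,
                                  amplitude_scale=2.0)
        X = build_hrf_design(fmri_events, v1.n_vols, nuisance=nu)
        b1 = fit_glm(v1, X)
        b2 = fit_glm(v2, X)
        for name in ("adaptors", "SC", "SD"):
            np.testing.assert_allclose(b2.beta(name), 2 * b1.beta(name), atol=1e-8)


class TestFitGlm:
    def _toy_volume(self, Y):
        data = Y.T.reshape(Y.shape[1], 1, 1, Y.shape[0])
        return VolumeSeries(data=data, tr=1.0, mask=np.ones((Y.shape[1], 1, 1), bool))

    def test_exact_fit_recovers_coefficient(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(40, 3))
        X = DesignMatrix(values=A, names=["a", "b", "c"], tr=1.0, interest=["a"])
        Y = 2.0 * A[:, [1]]
        fit = fit_glm(self._toy_volume(Y), X)
        assert fit.beta("b")[0, 0, 0] == pytest.approx(2.0, abs=1e-12)
        assert fit.resid_var[0, 0, 0] == pytest.approx(0.0, abs=1e-20)
        assert fit.dof == 37

    def test_matches_lstsq_oracle(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(50, 10))
        Y = rng.normal(size=(50, 6))
        X = DesignMatrix(values=A, names=[f"r{j}" for j in range(10)], tr=1.0,
                         interest=["r0"])
        fit = fit_glm(self._toy_volume(Y), X)
        expected = np.linalg.lstsq(A, Y, rcond=None)[0]
        got = np.vstack([[fit.beta(f"r{j}")[v, 0, 0] for v in range(6)]
                         for j in range(10)])
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_constant_shift_moves_only_intercept(self, fmri_events):
        grid = default_tuning_grid((2, 2, 2))
        vol, nu = simulate_bold_run(fmri_events, grid, seed=3)
        X = build_fir_design(fmri_events, vol.n_vols, nuisance=nu)
        f1 = fit_glm(vol, X)
        shifted = VolumeSeries(data=vol.data + 7.5, tr=vol.tr, mask=vol.mask)
        f2 = fit_glm(shifted, X)
        for name in X.interest:
            np.testing.assert_allclose(f2.beta(name), f1.beta(name), atol=1e-8)
        np.testing.assert_allclose(f2.beta("intercept"),
                                   f1.beta("intercept") + 7.5, atol=1e-8)

    def test_rank_deficiency_names_columns(self):
        A = np.ones((20, 2))
        A[:, 0] = np.arange(20)
        A = np.column_stack([A, A[:, 0]])
        X = DesignMatrix(values=A, names=["x", "one", "x_copy"], tr=1.0, interest=["x"])
        with pytest.raises(np.linalg.LinAlgError, match="x_copy"):
            fit_glm(self._toy_volume(np.zeros((20, 1))), X)

    def test_pure_noise_betas_center_on_zero(self):
        rng = np.random.default_rng(2)
        A = np.column_stack([rng.normal(size=(60, 2)), np.ones(60)])
        X = DesignMatrix(values=A, names=["a", "b", "icpt"], tr=1.0, interest=["a"])
        means = []
        for _ in range(100):
            Y = rng.normal(size=(60, 1))
            means.append(fit_glm(self._toy_volume(Y), X).beta("a")[0, 0, 0])
        assert abs(np.mean(means)) < 3 / np.sqrt(60 * 100) * 10


class TestAdaptationContrast:
    def _fir_fits(self, n_subjects, grid, noise, seed0=0, events=None):
        fits = []
        for s in range(n_subjects):
            vol, nu = simulate_bold_run(events, grid, noise=noise, seed=seed0 + s)
            X = build_fir_design(events, vol.n_vols, nuisance=nu)
            fits.append(fit_glm(vol, X))
        return fits

    def test_zero_differences_give_empty_mask(self):
        shape = (3, 3, 3)
        mask = np.ones(shape, bool)
        from adaptune.glm import BetaMaps
        subs = [BetaMaps(betas={"adaptor_4": np.zeros(shape),
                                "adaptor_7": np.zeros(shape)},
                         resid_var=np.zeros(shape), dof=10, mask=mask)
                for _ in range(5)]
        stat, amask = adaptation_contrast(subs)
        assert not amask.any()

    def test_planted_regions_recovered_noise_free(self, fmri_events):
        grid = default_tuning_grid((8, 8, 6))
        fits = self._fir_fits(3, grid, QUIET, events=fmri_events)
        _, amask = adaptation_contrast(fits)
        assert amask[grid.labels > 0].all()
        assert not amask[grid.labels == 0].any()

    def test_too_few_subjects_error(self):
        with pytest.raises(ValueError, match="3 subjects"):
            adaptation_contrast([])


class TestDeviantsVsIdentity:
    def test_contrast_direction_and_overlap(self, fmri_events):
        """Identity below deviants in tuned regions; map overlaps the
        adaptation mask (Dice > 0.5) under the default simulation."""
        from scipy import stats

        grid = default_tuning_grid((8, 8, 6))
        noise = NoiseParams()
        fir_fits, hrf_fits = [], []
        for s in range(8):
            vol, nu = simulate_bold_run(fmri_events, grid, noise=noise, seed=50 + s)
            fir_fits.append(fit_glm(vol, build_fir_design(fmri_events, vol.n_vols,
                                                          nuisance=nu)))
            hrf_fits.append(fit_glm(vol, build_hrf_design(fmri_events, vol.n_vols,
                                                          nuisance=nu)))
        tmap = deviants_vs_identity(hrf_fits)
        assert np.nanmean(tmap.values[grid.labels > 0]) > 3
        _, amask = adaptation_contrast(fir_fits)
        p = stats.t.sf(tmap.values, tmap.dof)
        dvi_mask = np.nan_to_num(p, nan=1.0) < 0.001
        assert dice(amask, dvi_mask) > 0.5

    def test_missing_identity_error(self):
        from adaptune.glm import BetaMaps
        shape = (2, 2, 2)
        b = BetaMaps(betas={"SC": np.zeros(shape)}, resid_var=np.zeros(shape),
                     dof=5, mask=np.ones(shape, bool))
        with pytest.raises(ValueError, match="Identity"):
            deviants_vs_identity([b])


def test_fir_trajectory_peaks_then_declines(quiet_run, fmri_events):
    """Stick-FIR betas trace the peristimulus BOLD course: under planted
    repetition suppression it rises to a peak by the 4th-5th bin and falls
    by the 7th (the adaptation phenomenon the 4>7 contrast detects)."""
    grid, vol, nuis = quiet_run
    X = build_fir_design(fmri_events, vol.n_vols, nuisance=nuis)
    fit = fit_glm(vol, X)
    region = grid.region_mask(GRADED)
    curve = np.array([np.nanmean(fit.beta(f"adaptor_{k}")[region])
                      for k in range(1, 10)])
    peak = int(np.argmax(curve)) + 1
    assert peak in (4, 5, 6)
    assert curve[3] > curve[6]
    assert curve[6] > curve[8] or curve[8] < curve[peak - 1]


def test_convolved_fir_recovers_planted_amplitudes(quiet_run, fmri_events):
    """The HRF-convolved per-position variant inverts the convolution and
    returns the planted neural amplitudes exactly in the noise-free case."""
    grid, vol, nuis = quiet_run
    X = build_fir_design(fmri_events, vol.n_vols, nuisance=nuis, convolve_hrf=True)
    fit = fit_glm(vol, X)
    for label in (GRADED, STEP):
        model = grid.models[label]
        region = grid.region_mask(label)
        est = [np.nanmean(fit.beta(f"adaptor_{k}")[region]) for k in range(1, 10)]
        planted = [model.position_amplitude(k) for k in range(1, 10)]
        np.testing.assert_allclose(est, planted, atol=1e-6)
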