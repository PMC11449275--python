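"""OLS fitting, contrasts, group tests and the synthetic BOLD generator."""

import numpy as np
import pandas as pd
import pytest

from ktcc import design as dg
from ktcc import glm
from ktcc.errors import CollinearityError, ConfigurationError, SampleSizeError


def zero_design(n_frames, tr=0.8):
    frame = pd.DataFrame({"null": np.zeros(n_frames)}, index=np.arange(n_frames) * tr)
    return dg.DesignMatrix(frame=frame, tr_s=tr, column_info={"null": {"kind": "misc"}})


class TestFit:
    def test_noiseless_recovery_is_exact(self, fir_design, rng):
        beta = {c: rng.normal() for c in fir_design.columns}
        tc = glm.simulate_bold(fir_design, beta, sigma=0.0, n_voxels=4, seed=1)
        fit = glm.fit_glm(fir_design, tc)
        err = max(abs(fit.roi_mean_beta[c] - beta[c]) for c in fir_design.columns)
        assert err < 1e-8

    def test_roi_mean_is_mean_of_voxel_betas(self, fir_design):
        tc = glm.simulate_bold(fir_design, np.zeros(len(fir_design.columns)),
                               sigma=1.0, n_voxels=5, seed=2)
        fit = glm.fit_glm(fir_design, tc)
        np.testing.assert_allclose(
            fit.roi_mean_beta.to_numpy(), fit.coef.mean(axis=1).to_numpy()
        )

    def test_rank_deficiency_names_dependent_columns(self, fir_design):
        frame = fir_design.frame.copy()
        frame["dupe"] = frame.iloc[:, 0]
        bad = dg.DesignMatrix(
            frame=frame,
            tr_s=fir_design.tr_s,
            column_info={**fir_design.column_info, "dupe": {"kind": "misc"}},
        )
        tc = glm.simulate_bold(fir_design, np.zeros(len(fir_design.columns)),
                               sigma=1.0, seed=3)
        with pytest.raises(CollinearityError) as exc:
            glm.fit_glm(bad, tc)
        assert "dupe" in exc.value.dependent_columns

    def test_censoring_zero_weight_rows_leaves_beta_unchanged(self, fir_design, rng):
        beta = {c: rng.normal() for c in fir_design.columns}
        tc = glm.simulate_bold(fir_design, beta, sigma=0.0, seed=4)
        # rest frames at the run tail: zero design weight and zero signal
        tail = fir_design.values.sum(axis=1) == 0
        assert tail.any()
        full = glm.fit_glm(fir_design, tc, drift_order=None)
        masked = glm.fit_glm(fir_design, tc, drift_order=None, mask=~tail)
        np.testing.assert_allclose(
            full.roi_mean_beta.to_numpy(), masked.roi_mean_beta.to_numpy(), atol=1e-10
        )

    def test_beta_recovery_bias_small_under_ar1_noise(self, rng):
        # single-run boxcar design, SNR ~ 1, 200 replicates
        trials = [
            dg.TimelineTrial({"tcc": lvl}, onset_s=10.0 + 37.0 * k)
            for k, lvl in enumerate(["high", "low"] * 4)
        ]
        tl = dg.TaskTimeline(trials, run_length_s=10.0 + 37.0 * 8 + 20.0)
        mat = dg.build_boxcar_design(tl, "tcc")
        beta = {c: 1.0 for c in mat.columns}
        target = mat.columns[0]
        est = []
        for rep in range(200):
            tc = glm.simulate_bold(mat, beta, phi=0.3, sigma=1.0, n_voxels=1,
                                   seed=rng)
            fit = glm.fit_glm(mat, tc)
            est.append(fit.roi_mean_beta[target])
        assert abs(np.mean(est) - 1.0) < 0.02


class TestContrast:
    def test_zero_when_levels_share_coefficients(self, fir_design):
        beta = {}
        for name, info in fir_design.column_info.items():
            beta[name] = 0.1 * info["tent"]  # same shape in every condition
        tc = glm.simulate_bold(fir_design, beta, sigma=0.0, seed=5)
        fit = glm.fit_glm(fir_design, tc)
        con = glm.compute_contrast(fit, "tcc")
        np.testing.assert_allclose(con.to_numpy(), 0.0, atol=1e-8)

    def test_additive_effects_have_zero_interaction(self, fir_design):
        beta = {}
        for name, info in fir_design.column_info.items():
            cond, tent = info["condition"], info["tent"]
            beta[name] = (
                0.05 * tent
                + (0.4 if cond["tcc"] == "high" else 0.0)
                + (0.3 if cond["sat"] == "unsat" else 0.0)
            )
        tc = glm.simulate_bold(fir_design, beta, sigma=0.0, seed=6)
        fit = glm.fit_glm(fir_design, tc)
        inter = glm.compute_contrast(fit, "interaction")
        np.testing.assert_allclose(inter.to_numpy(), 0.0, atol=1e-8)
        tcc = glm.compute_contrast(fit, "tcc")
        np.testing.assert_allclose(tcc.to_numpy(), 0.4, atol=1e-8)

    def test_linearity_in_coefficients(self, fir_design, rng):
        beta1 = {c: rng.normal() for c in fir_design.columns}
        beta2 = {c: rng.normal() for c in fir_design.columns}
        both = {c: beta1[c] + beta2[c] for c in fir_design.columns}
        cons = []
        for beta in (beta1, beta2, both):
            tc = glm.simulate_bold(fir_design, beta, sigma=0.0, seed=7)
            cons.append(glm.compute_contrast(glm.fit_glm(fir_design, tc), "sat"))
        np.testing.assert_allclose(
            cons[2].to_numpy(), cons[0].to_numpy() + cons[1].to_numpy(), atol=1e-7
        )

    def test_missing_coefficient_rejected(self, fir_design):
        tc = glm.simulate_bold(fir_design, np.zeros(len(fir_design.columns)),
                               sigma=0.0, seed=8)
        fit = glm.fit_glm(fir_design, tc)
        with pytest.raises(ConfigurationError, match="matches no"):
            glm.compute_contrast(fit, "accuracy")

    def test_unbalanced_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            glm.ContrastSpec("bad", (({"tcc": "high"}, 1.0), ({"tcc": "low"}, -0.5)))


class TestGroupTest:
    def test_requires_two_participants(self):
        with pytest.raises(SampleSizeError):
            glm.group_timepoint_test(np.ones((1, 17)))

    def test_degenerate_variance_handling(self):
        data = np.tile([0.5, 0.0], (6, 1))  # constant across participants
        out = glm.group_timepoint_test(data)
        assert bool(out["significant"].iloc[0]) and bool(out["degenerate"].iloc[0])
        assert not bool(out["significant"].iloc[1])

    def test_power_for_moderate_effect(self):
        rng = np.random.default_rng(9)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            data = rng.normal(0.5, 0.5, size=(20, 1))
            hits += bool(glm.group_timepoint_test(data)["significant"].iloc[0])
        assert hits / n_rep > 0.9


class TestSimulateBold:
    def test_zero_noise_reproduces_signal_exactly(self, fir_design, rng):
        beta = np.asarray([rng.normal() for _ in fir_design.columns])
        tc = glm.simulate_bold(fir_design, beta, sigma=0.0, n_voxels=2, seed=10)
        expected = fir_design.values @ beta
        np.testing.assert_allclose(tc.series.to_numpy()[:, 0], expected)

    def test_same_seed_identical_series(self, fir_design):
        a = glm.simulate_bold(fir_design, np.zeros(len(fir_design.columns)), seed=11)
        b = glm.simulate_bold(fir_design, np.zeros(len(fir_design.columns)), seed=11)
        pd.testing.assert_frame_equal(a.series, b.series)

    def test_noise_lag1_autocorrelation_matches_phi(self):
        mat = zero_design(30_000)
        tc = glm.simulate_bold(mat, [0.0], phi=0.4, sigma=1.0, seed=12)
        x = tc.series.to_numpy()[:, 0]
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1 - 0.4) < 0.02

    def test_invalid_noise_parameters_rejected(self, fir_design):
        z = np.zeros(len(fir_design.columns))
        with pytest.raises(ConfigurationError):
            glm.simulate_bold(fir_design, z, phi=1.0)
        with pytest.raises(ConfigurationError):
            glm.simulate_bold(fir_design, z, sigma=-1.0)

    def test_round_trip_tsv(self, fir_design, tmp_path):
        tc = glm.simulate_bold(fir_design, np.zeros(len(fir_design.columns)),
                               n_voxels=3, seed=13)
        path = tmp_path / "bold.tsv"
        tc.to_tsv(path)
        loaded = glm.ROITimecourse.from_tsv(path, tr_s=tc.tr_s)
        np.testing.assert_allclose(loaded.series.to_numpy(), tc.series.to_numpy())
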