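import numpy as np
import pytest

import secrgrid as sg
from secrgrid.likelihood import _ParamLayout, negloglik
from _oracle import oracle_negloglik

inv_logit = lambda x: 1.0 / (1.0 + np.exp(-x))


def tiny_setting():
    """2 traps, 3 mask points shared by the small-instance oracle tests."""
    traps = sg.TrapArray(("A", "B"), np.array([[0.0, 0.0], [8.0, 0.0]]))
    mask = sg.HabitatMask(
        np.array([[1.0, 2.0], [5.0, -3.0], [10.0, 4.0]]), 0.01, 0.0
    )
    return traps, mask


class TestCaptureHistory:
    def test_duplicate_occasion_rejected(self):
        with pytest.raises(ValueError):
            sg.CaptureHistory((("i1", 1, "A"), ("i1", 1, "B")), 2)

    def test_occasion_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sg.CaptureHistory((("i1", 5, "A"),), 4)

    def test_unknown_trap_caught_at_validation(self):
        traps, _ = tiny_setting()
        ch = sg.CaptureHistory((("i1", 1, "Z"),), 2)
        with pytest.raises(ValueError):
            ch.validate_against(traps)

    def test_spatial_recapture_counting(self):
        ch = sg.CaptureHistory(
            (("i1", 1, "A"), ("i1", 2, "A"), ("i1", 3, "B"), ("i2", 1, "B")), 4
        )
        # i1: repeat at A (not spatial), move to B (spatial); i2: single
        assert ch.n_spatial_recaptures() == 1
        assert ch.n == 2 and ch.n_captures == 4


class TestModelSpec:
    def test_time_behavior_exclusive(self):
        with pytest.raises(ValueError):
            sg.ModelSpec("EX", frozenset({"time", "behavior"}))

    def test_sex_requires_mixture(self):
        with pytest.raises(ValueError):
            sg.ModelSpec("EX", frozenset({"sex"}), mixture=False)

    def test_parameter_counts(self):
        assert _ParamLayout(sg.ModelSpec("EX"), 4).n_params == 3
        assert (
            _ParamLayout(
                sg.ModelSpec("EX", frozenset({"sex"}), frozenset({"sex"})), 4
            ).n_params
            == 6
        )
        assert _ParamLayout(sg.ModelSpec("HR"), 4).n_params == 4
        # time effect on g0: logD + 4 per-occasion g0 + shared sigma
        assert _ParamLayout(sg.ModelSpec("EX", frozenset({"time"})), 4).n_params == 6
        assert _ParamLayout(sg.ModelSpec("EX", frozenset({"behavior"})), 4).n_params == 4


class TestNegloglikOracle:
    """The vectorized likelihood against exhaustive enumeration."""

    def test_sex_mixture_two_individuals(self):
        traps, mask = tiny_setting()
        ch = sg.CaptureHistory(
            (("i1", 1, "A"), ("i1", 2, "B"), ("i2", 2, "B")),
            2,
            {"i1": "F", "i2": "M"},
        )
        spec = sg.ModelSpec("EX", frozenset({"sex"}), frozenset({"sex"}))
        theta = np.array([np.log(25.0), 0.2, -0.4, np.log(6.0), np.log(9.0), 0.3])
        g0 = [inv_logit(0.2), inv_logit(-0.4)]
        sig = [6.0, 9.0]
        piF = inv_logit(0.3)
        ref = oracle_negloglik(
            histories=[(0, 1), (-1, 1)],
            classes=[0, 1],
            pi=[piF, 1 - piF],
            D=25.0,
            mask_points=[tuple(p) for p in mask.points],
            cell_area=0.01,
            trap_coords=[(0.0, 0.0), (8.0, 0.0)],
            params_by_class=[
                [(g0[0], sig[0], "EX", None)] * 2,
                [(g0[1], sig[1], "EX", None)] * 2,
            ],
        )
        assert negloglik(ch, traps, mask, spec, theta) == pytest.approx(
            ref, abs=1e-10
        )

    def test_unknown_sex_marginalizes(self):
        traps, mask = tiny_setting()
        ch = sg.CaptureHistory(
            (("i1", 1, "A"), ("i2", 2, "B")), 2, {"i1": "unknown", "i2": "F"}
        )
        spec = sg.ModelSpec("EX", frozenset({"sex"}), frozenset({"sex"}))
        theta = np.array([np.log(12.0), -0.1, 0.5, np.log(5.0), np.log(11.0), -0.7])
        piF = inv_logit(-0.7)
        ref = oracle_negloglik(
            histories=[(0, -1), (-1, 1)],
            classes=[-1, 0],
            pi=[piF, 1 - piF],
            D=12.0,
            mask_points=[tuple(p) for p in mask.points],
            cell_area=0.01,
            trap_coords=[(0.0, 0.0), (8.0, 0.0)],
            params_by_class=[
                [(inv_logit(-0.1), 5.0, "EX", None)] * 2,
                [(inv_logit(0.5), 11.0, "EX", None)] * 2,
            ],
        )
        assert negloglik(ch, traps, mask, spec, theta) == pytest.approx(
            ref, abs=1e-10
        )

    @pytest.mark.parametrize("detectfn", ["HN", "EX", "HR"])
    def test_null_model_single_individual(self, detectfn):
        traps, mask = tiny_setting()
        ch = sg.CaptureHistory((("i1", 2, "A"),), 2)
        spec = sg.ModelSpec(detectfn)
        if detectfn == "HR":
            theta = np.array([np.log(20.0), 0.0, np.log(7.0), np.log(1.5)])
            params = [(0.5, 7.0, "HR", 2.5)] * 2
        else:
            theta = np.array([np.log(20.0), 0.0, np.log(7.0)])
            params = [(0.5, 7.0, detectfn, None)] * 2
        ref = oracle_negloglik(
            [(-1, 0)], [0], [1.0], 20.0,
            [tuple(p) for p in mask.points], 0.01,
            [(0.0, 0.0), (8.0, 0.0)], [params],
        )
        assert negloglik(ch, traps, mask, spec, theta) == pytest.approx(
            ref, abs=1e-10
        )

    def test_time_effect(self):
        traps, mask = tiny_setting()
        ch = sg.CaptureHistory((("i1", 1, "A"), ("i1", 2, "B"), ("i2", 2, "A")), 2)
        spec = sg.ModelSpec("EX", frozenset({"time"}))
        # theta: logD, logit g0_t1, logit g0_t2, log sigma
        theta = np.array([np.log(18.0), -0.3, 0.6, np.log(6.5)])
        params = [(inv_logit(-0.3), 6.5, "EX", None), (inv_logit(0.6), 6.5, "EX", None)]
        ref = oracle_negloglik(
            [(0, 1), (-1, 0)], [0, 0], [1.0], 18.0,
            [tuple(p) for p in mask.points], 0.01,
            [(0.0, 0.0), (8.0, 0.0)], [params],
        )
        assert negloglik(ch, traps, mask, spec, theta) == pytest.approx(
            ref, abs=1e-10
        )

    def test_behavior_effect_switches_after_first_capture(self):
        traps, mask = tiny_setting()
        ch = sg.CaptureHistory((("i1", 1, "A"), ("i1", 2, "A"), ("i2", 2, "B")), 2)
        spec = sg.ModelSpec("EX", frozenset({"behavior"}))
        # theta: logD, logit g0_naive, logit g0_post, log sigma
        theta = np.array([np.log(22.0), -0.2, 0.9, np.log(7.0)])
        naive = (inv_logit(-0.2), 7.0, "EX", None)
        post = (inv_logit(0.9), 7.0, "EX", None)
        ref = oracle_negloglik(
            [(0, 0), (-1, 1)], [0, 0], [1.0], 22.0,
            [tuple(p) for p in mask.points], 0.01,
            [(0.0, 0.0), (8.0, 0.0)],
            params_by_class=[[naive, naive]],  # exposure uses naive params
            history_params=[
                [[naive, post]],  # i1 caught on occ 1 -> post on occ 2
                [[naive, naive]],  # i2 first caught on occ 2
            ],
        )
        assert negloglik(ch, traps, mask, spec, theta) == pytest.approx(
            ref, abs=1e-10
        )

    def test_empty_history_returns_expected_count(self):
        traps, mask = tiny_setting()
        ch = sg.CaptureHistory((), 2)
        spec = sg.ModelSpec("EX")
        theta = np.array([np.log(20.0), 0.0, np.log(7.0)])
        ref = oracle_negloglik(
            [], [], [1.0], 20.0, [tuple(p) for p in mask.points], 0.01,
            [(0.0, 0.0), (8.0, 0.0)], [[(0.5, 7.0, "EX", None)] * 2],
        )
        value = negloglik(ch, traps, mask, spec, theta)
        assert value == pytest.approx(ref, abs=1e-12)
        assert value > 0  # equals Lambda, the expected number detected

    def test_mask_permutation_invariance(self):
        traps, mask = tiny_setting()
        ch = sg.CaptureHistory((("i1", 1, "A"), ("i1", 2, "B")), 2)
        spec = sg.ModelSpec("EX")
        theta = np.array([np.log(20.0), 0.0, np.log(7.0)])
        v1 = negloglik(ch, traps, mask, spec, theta)
        perm = sg.HabitatMask(mask.points[[2, 0, 1]], 0.01, 0.0)
        v2 = negloglik(ch, traps, perm, spec, theta)
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_nonfinite_theta_rejected(self):
        traps, mask = tiny_setting()
        ch = sg.CaptureHistory((("i1", 1, "A"),), 2)
        with pytest.raises(ValueError):
            negloglik(ch, traps, mask, sg.ModelSpec("EX"),
                      np.array([np.nan, 0.0, 1.0]))


class TestFitSecr:
    def test_recovers_parameters_on_shared_session(self, sim_fit, study_truth):
        # one seeded replicate: loose sanity band, the ensemble-level
        # recovery check lives in the acceptance suite
        assert sim_fit.converged
        assert sim_fit.D_hat == pytest.approx(study_truth.D, rel=0.35)
        assert sim_fit.param("sigma", "F") == pytest.approx(
            study_truth.sigma_F, rel=0.5
        )
        assert sim_fit.SE_D > 0

    def test_aic_identity(self, sim_fit):
        assert sim_fit.AIC == pytest.approx(
            -2 * sim_fit.log_likelihood + 2 * sim_fit.n_parameters, abs=1e-9
        )

    def test_refit_from_perturbed_starts_same_optimum(
        self, sim_session, grid10, mask50, sex_spec, sim_fit
    ):
        rng = np.random.default_rng(9)
        starts = sim_fit.theta + rng.normal(0, 0.3, size=sim_fit.theta.size)
        refit = sg.fit_secr(
            sim_session, grid10, mask50, sex_spec, starts=starts, compute_se=False
        )
        assert refit.D_hat == pytest.approx(sim_fit.D_hat, rel=1e-4)
        assert refit.log_likelihood == pytest.approx(
            sim_fit.log_likelihood, abs=1e-4
        )

    def test_empty_history_rejected(self, grid10, mask50):
        with pytest.raises(ValueError):
            sg.fit_secr(sg.CaptureHistory((), 4), grid10, mask50, sg.ModelSpec())

    def test_sparse_data_flagged(self, grid10, mask50):
        ch = sg.CaptureHistory(
            (("i1", 1, "r1c1"), ("i1", 2, "r1c2"), ("i2", 1, "r5c5")), 4
        )
        fit = sg.fit_secr(ch, grid10, mask50, sg.ModelSpec("EX"), compute_se=False)
        assert "unstable" in fit.flags

    def test_degenerate_low_detection_flagged(self):
        # nearly undetectable animals on a small 4x4 grid: the fit must
        # advertise non-identifiability rather than return a confident D
        traps = sg.build_grid(4, 4, 9.43)
        mask = sg.build_mask(traps, 40.0, 8.0)
        rng = np.random.default_rng(5)
        pop = sg.simulate_population(30.0, mask, 0.5, rng)
        ch = sg.simulate_capthist(
            pop, traps, 4,
            sg.DetectionParams(0.02, 6.0, "EX"),
            seed=rng,
        )
        if ch.n == 0:
            pytest.skip("no captures at all under this seed")
        fit = sg.fit_secr(ch, traps, mask, sg.ModelSpec("EX"))
        cv = fit.SE_D / fit.D_hat if np.isfinite(fit.SE_D) else np.inf
        assert fit.unstable or "boundary" in fit.flags or cv > 1


class TestAicRank:
    def test_single_fit(self, sim_fit):
        table = sg.aic_rank([sim_fit])
        assert table.dAIC.iloc[0] == 0.0
        assert table.weight.iloc[0] == pytest.approx(1.0)

    def test_equal_aic_splits_weight(self, sim_fit):
        import copy

        other = copy.copy(sim_fit)
        other.label = "clone"
        table = sg.aic_rank([sim_fit, other])
        assert np.allclose(table.weight, 0.5)
        assert (table.dAIC >= 0).all()

    def test_mixed_datasets_rejected(self, sim_fit, grid10, mask50):
        ch = sg.CaptureHistory(
            (("x1", 1, "r1c1"), ("x1", 2, "r1c2"), ("x1", 3, "r2c1"),
             ("x2", 1, "r5c5"), ("x2", 2, "r5c6")), 4
        )
        other = sg.fit_secr(ch, grid10, mask50, sg.ModelSpec("EX"), compute_se=False)
        with pytest.raises(ValueError):
            sg.aic_rank([sim_fit, other])

    def test_weights_sum_to_one(self, sim_session, grid10, mask50, sim_fit):
        null = sg.fit_secr(
            sim_session, grid10, mask50, sg.ModelSpec("EX"), compute_se=False
        )
        table = sg.aic_rank([sim_fit, null])
        assert table.weight.sum() == pytest.approx(1.0)
        assert table.AIC.is_monotonic_increasing


class TestSummarizeDensities:
    def test_single_year(self):
        out = sg.summarize_densities({2005: 53.84}, [(2005, 2005)])
        assert out.mean_D.iloc[0] == pytest.approx(53.84)
        assert out.min_year.iloc[0] == 2005

    def test_period_partition(self):
        dens = {2000: 10.0, 2001: 20.0, 2002: 30.0, 2003: 40.0}
        out = sg.summarize_densities(dens, [(2000, 2001), (2002, 2003)])
        assert list(out.mean_D) == [15.0, 35.0]
        assert list(out.max_year) == [2001, 2003]

    def test_empty_period_rejected(self):
        with pytest.raises(ValueError):
            sg.summarize_densities({2000: 10.0}, [(1990, 1995)])
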