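import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from standiff.staging import (
    EventModel,
    StagePosterior,
    age_regress,
    cohort_trajectory,
    ebm_log_likelihood,
    ebm_mcmc,
    prepare_biomarkers,
    select_thresholds,
    sequence_valid,
    stage_posteriors,
    suvr_normalize,
    zscore_vs_controls,
)
from standiff.synthetic import make_ebm_cohort, well_separated_staging_spec, planted_event_model


class TestSuvrNormalize:
    def setup_method(self):
        self.df = pd.DataFrame(
            {"ctx": [1.5, 1.0], "cereb_l": [1.0, 2.0], "cereb_r": [1.0, 2.0]},
            index=["s1", "s2"],
        )

    def test_reference_arithmetic(self):
        out = suvr_normalize(self.df, ("cereb_l", "cereb_r"))
        assert out.loc["s1", "ctx"] == pytest.approx(0.5)
        assert out.loc["s2", "ctx"] == pytest.approx(-0.5)

    def test_regions_equal_to_reference_map_to_zero(self):
        out = suvr_normalize(self.df, ("cereb_l", "cereb_r"))
        assert out.loc["s1", "cereb_l"] == pytest.approx(0.0)

    def test_missing_reference_region(self):
        with pytest.raises(KeyError):
            suvr_normalize(self.df, ("cereb_l", "nope"))

    def test_nonpositive_reference(self):
        bad = self.df.copy()
        bad.loc["s1", ["cereb_l", "cereb_r"]] = 0.0
        with pytest.raises(ValueError, match="reference"):
            suvr_normalize(bad, ("cereb_l", "cereb_r"))


class TestAgeRegress:
    def test_values_linear_in_age_give_zero_residuals(self):
        ages = np.array([60.0, 65, 70, 75])
        df = pd.DataFrame({"v": 2.0 * ages + 3.0})
        res = age_regress(df, ages)
        assert np.allclose(res["v"], 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_age_and_intercept(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(55, 85, 10)
        df = pd.DataFrame({"v": rng.normal(size=10)})
        res = age_regress(df, ages)["v"].to_numpy()
        # normal equations: residual orthogonal to both regressors
        assert abs(res @ ages) < 1e-8
        assert abs(res.sum()) < 1e-8

    def test_constant_ages_rejected(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            age_regress(df, np.array([70.0, 70.0, 70.0]))


class TestZScore:
    def test_hand_computed_standardization(self):
        vals = pd.DataFrame({"b": [1.0, 2, 3, 4, 10, 20, 12, 14]})
        mask = np.array([True] * 4 + [False] * 4)
        z = zscore_vs_controls(vals, mask)
        mu, sd = 2.5, np.std([1, 2, 3, 4], ddof=1)
        assert np.allclose(z["b"], (vals["b"] - mu) / sd)

    def test_control_mean_maps_to_zero_and_one_sd_to_one(self):
        vals = pd.DataFrame({"b": [0.0, 2.0, 1.0, 1.0 + np.std([0, 2], ddof=1)]})
        mask = np.array([True, True, False, False])
        z = zscore_vs_controls(vals, mask)
        assert z["b"].iloc[2] == pytest.approx(0.0)
        assert z["b"].iloc[3] == pytest.approx(1.0)

    def test_degenerate_control_sd(self):
        vals = pd.DataFrame({"b": [1.0, 1.0, 5.0]})
        with pytest.raises(ValueError, match="SD"):
            zscore_vs_controls(vals, np.array([True, True, False]))

    def test_prepare_flips_decreasing_markers(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame({
            "up": rng.normal(size=20), "down": rng.normal(size=20),
        })
        ages = rng.uniform(60, 80, 20)
        mask = np.zeros(20, bool)
        mask[:10] = True
        z = prepare_biomarkers(vals, ages, mask, decreasing=["down"])
        z_raw = prepare_biomarkers(vals, ages, mask)
        assert np.allclose(z["down"], -z_raw["down"])


def _one_event_model():
    return EventModel(thresholds=[[1.0]], sequence=[(0, 0)])


class TestEventModel:
    def test_event_means_interpolate_through_thresholds(self):
        m = EventModel(thresholds=[[1.0, 2.0]], sequence=[(0, 0), (0, 1)])
        M = m.event_means()
        assert np.allclose(M[:, 0], [0.0, 1.0, 2.0])

    def test_means_saturate_after_last_event(self):
        m = EventModel(
            thresholds=[[1.0], [2.0]], sequence=[(1, 0), (0, 0)]
        )
        M = m.event_means()  # biomarker 1 completes at stage 1, holds at 2.0
        assert M[2, 1] == pytest.approx(2.0)
        assert np.all(np.diff(M, axis=0) >= -1e-12)

    def test_invalid_sequences_rejected(self):
        with pytest.raises(ValueError):
            EventModel(thresholds=[[1.0, 2.0]], sequence=[(0, 1), (0, 0)])
        with pytest.raises(ValueError):
            EventModel(thresholds=[[1.0, 2.0]], sequence=[(0, 0), (0, 0)])

    def test_sequence_validity_helper(self):
        assert sequence_valid([(0, 0), (1, 0), (0, 1), (1, 1)])
        assert not sequence_valid([(0, 1), (0, 0)])


class TestEbmLikelihood:
    def test_matches_exhaustive_enumeration(self):
        model = _one_event_model()
        Z = np.array([[0.0], [1.0]])
        # hand sum over the 2 stages with mu = 0 and 1, sigma = 1
        expect = sum(
            np.log(0.5 * (norm.pdf(z, 0, 1) + norm.pdf(z, 1, 1))) for z in (0.0, 1.0)
        )
        assert ebm_log_likelihood(Z, model) == pytest.approx(expect, rel=1e-12)

    def test_subject_permutation_invariance(self):
        model = _one_event_model()
        Z = np.array([[0.3], [1.2], [-0.5]])
        assert ebm_log_likelihood(Z, model) == pytest.approx(
            ebm_log_likelihood(Z[::-1], model)
        )

    def test_outlier_decreases_likelihood(self):
        model = _one_event_model()
        Z = np.array([[0.5], [1.0]])
        Z_out = Z.copy()
        Z_out[0, 0] += 100.0
        assert ebm_log_likelihood(Z_out, model) < ebm_log_likelihood(Z, model)


class TestEbmMcmc:
    def test_two_event_problem_recovers_exhaustive_best(self):
        # 2 biomarkers x 1 threshold: exactly 2 valid orderings
        rng = np.random.default_rng(0)
        truth = EventModel(thresholds=[[2.0], [2.0]], sequence=[(1, 0), (0, 0)])
        M = truth.event_means()
        stages = rng.integers(0, 3, 100)
        Z = M[stages] + rng.standard_normal((100, 2))
        lls = {
            tuple(seq): ebm_log_likelihood(
                Z, EventModel(thresholds=truth.thresholds, sequence=seq)
            )
            for seq in ([(0, 0), (1, 0)], [(1, 0), (0, 0)])
        }
        best_seq = max(lls, key=lls.get)
        fit, _ = ebm_mcmc(Z, truth.thresholds, n_iter=100, rng_seed=1)
        assert tuple(fit.sequence) == best_seq
        assert fit.log_likelihood == pytest.approx(lls[best_seq])

    def test_zero_iterations_returns_initialization(self):
        Z = np.random.default_rng(2).standard_normal((10, 2))
        init = [(0, 0), (1, 0)]
        fit, trace = ebm_mcmc(
            Z, [[1.0], [1.0]], n_iter=0, rng_seed=0, init=init, n_random_inits=0
        )
        assert fit.sequence == init
        assert trace.size == 0

    def test_recovers_planted_sequence_on_separated_cohort(self):
        spec = well_separated_staging_spec()
        model = planted_event_model(spec)
        Z, _ = make_ebm_cohort(model, 200, rng_seed=0)
        fit, _ = ebm_mcmc(Z, model.thresholds, n_iter=20_000, rng_seed=0)
        assert fit.sequence == model.sequence

    def test_deterministic_given_seed(self):
        Z = np.random.default_rng(3).standard_normal((30, 2)) + 1.0
        a, ta = ebm_mcmc(Z, [[1.0], [1.5]], n_iter=500, rng_seed=7)
        b, tb = ebm_mcmc(Z, [[1.0], [1.5]], n_iter=500, rng_seed=7)
        assert a.sequence == b.sequence
        assert np.array_equal(ta, tb)


class TestSelectThresholds:
    def test_single_candidate_returned(self):
        Z = np.random.default_rng(0).standard_normal((20, 2))
        cand = np.array([[1.0], [1.0]])
        model, table = select_thresholds(Z, [cand], n_iter=50, rng_seed=0)
        assert np.allclose(model.thresholds, cand)
        assert len(table) == 1

    def test_planted_thresholds_win_and_order_invariance(self):
        truth = EventModel(
            thresholds=[[2.0], [2.0]], sequence=[(0, 0), (1, 0)]
        )
        Z, _ = make_ebm_cohort(truth, 150, rng_seed=4)
        good = np.array([[2.0], [2.0]])
        bad = np.array([[8.0], [8.0]])
        m1, t1 = select_thresholds(Z, [good, bad], n_iter=300, rng_seed=0)
        m2, t2 = select_thresholds(Z, [bad, good], n_iter=300, rng_seed=0)
        assert np.allclose(m1.thresholds, good)
        assert np.allclose(m2.thresholds, good)

    def test_empty_candidate_list(self):
        with pytest.raises(ValueError, match="empty"):
            select_thresholds(np.zeros((5, 1)), [], n_iter=10)


class TestStagePosteriors:
    def test_rows_sum_to_one_and_zero_profile_maps_to_stage_zero(self):
        model = EventModel(thresholds=[[1.0, 2.0]], sequence=[(0, 0), (0, 1)])
        Z = np.array([[0.0], [2.0], [0.9]])
        post = stage_posteriors(Z, model)
        assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)
        assert post.most_likely_stage[0] == 0
        assert post.most_likely_stage[1] == 2

    def test_matches_product_of_gaussians_enumeration(self):
        model = EventModel(thresholds=[[1.0, 2.0]], sequence=[(0, 0), (0, 1)])
        z = 1.4
        post = stage_posteriors(np.array([[z]]), model)
        dens = np.array([norm.pdf(z, mu, 1.0) for mu in (0.0, 1.0, 2.0)])
        assert np.allclose(post.probs[0], dens / dens.sum(), atol=1e-12)

    def test_argmax_ties_break_to_lower_stage(self):
        model = EventModel(thresholds=[[1.0]], sequence=[(0, 0)])
        post = stage_posteriors(np.array([[0.5]]), model)  # equidistant from 0, 1
        assert post.most_likely_stage[0] == 0


class TestCohortTrajectory:
    def test_uniform_posteriors_give_cohort_mean(self):
        tau = np.array([[1.0, 2, 3], [3.0, 4, 5]])
        post = StagePosterior(
            probs=np.full((2, 4), 0.25), most_likely_stage=np.zeros(2, int)
        )
        traj = cohort_trajectory(post, tau)
        assert np.allclose(traj.tau, np.tile(tau.mean(axis=0), (4, 1)))

    def test_delta_posterior_copies_subject(self):
        tau = np.array([[1.0, 2, 3], [9.0, 9, 9], [4.0, 5, 6]])
        P = np.zeros((3, 4))
        P[0, 0] = P[2, 0] = 1.0
        P[1, 3] = 1.0
        # give tiny mass elsewhere to avoid empty stages
        P[:, 1:3] = 1e-6
        P /= P.sum(axis=1, keepdims=True)
        traj = cohort_trajectory(StagePosterior(P, P.argmax(axis=1)), tau)
        assert np.allclose(traj.tau[3], [9, 9, 9], atol=1e-5)

    def test_mixed_weights_match_hand_computation(self):
        tau = np.array([[1.0], [2.0], [3.0], [4.0]])
        P = np.array([[0.5, 0.5], [0.25, 0.75], [1.0, 0.0], [0.2, 0.8]])
        traj = cohort_trajectory(StagePosterior(P, P.argmax(axis=1)), tau)
        w0 = np.array([0.5, 0.25, 1.0, 0.2])
        expect0 = (w0 @ tau.ravel()) / w0.sum()
        assert traj.tau[0, 0] == pytest.approx(expect0)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(5)
        tau = rng.uniform(size=(6, 4))
        P = rng.dirichlet(np.ones(3), size=6)
        traj = cohort_trajectory(StagePosterior(P, P.argmax(axis=1)), tau)
        for r in range(4):
            assert traj.tau[:, r].min() >= tau[:, r].min() - 1e-12
            assert traj.tau[:, r].max() <= tau[:, r].max() + 1e-12

    def test_empty_stage_rejected_by_name(self):
        tau = np.ones((2, 3))
        P = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match=r"\[1\]"):
            cohort_trajectory(StagePosterior(P, P.argmax(axis=1)), tau)
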