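"""The general-Bayes Gibbs sampler: components, joint correctness, recovery."""

import numpy as np
import pytest

from dpgbcox.coxph import clustered_partial_loglik, fit_cox_mle
from dpgbcox.crp import ConcentrationPrior, PartitionState
from dpgbcox.data import SurvivalDataset
from dpgbcox.exposure import ClusterParams, ExposurePriors
from dpgbcox.sampler import (GlobalParams, PosteriorDraws, SamplerConfig,
                             _ClusterRiskIndex, _EffectiveModel,
                             representative_clustering, run_sampler,
                             summarize_posterior, update_assignments,
                             update_beta)
from dpgbcox.simulate import generate_dataset, scenario_params


def _two_cluster_exposure(rng, n=80, gap=10.0):
    """Exposure clusters separated by `gap` standard deviations."""
    labels = np.repeat([0, 1], n // 2)
    a = rng.normal(labels * gap * 0.5, 0.5)
    return SurvivalDataset(
        time=rng.exponential(1, n) + 1e-3,
        event=(rng.random(n) > 0.2).astype(float),
        exposure=a, z=rng.normal(0, 1, n), v=None), labels


class TestUpdateAssignments:
    def test_well_separated_clusters_recovered(self, rng):
        """Two exposure clusters 10 SDs apart are co-clustered (ARI >= 0.9)
        after a modest number of sweeps."""
        from dpgbcox.metrics import adjusted_rand
        ds, labels = _two_cluster_exposure(rng)
        cfg = SamplerConfig(n_iter=400, n_burn=200, seed=3)
        draws = run_sampler(ds, cfg)
        rep = representative_clustering(draws, "modal_k")
        assert adjusted_rand(rep, labels) >= 0.9

    def test_gamma_zero_limit_keeps_single_cluster(self, rng):
        """With gamma -> 0 and K=1 current, opening a new cluster has
        vanishing probability."""
        ds, _ = _two_cluster_exposure(rng, n=20, gap=0.0)
        cfg = SamplerConfig(seed=0)
        part = PartitionState(np.zeros(20, dtype=int))
        cp = ClusterParams([0.0], np.zeros((1, 0)), [1.0])
        gp = GlobalParams(0.0, np.zeros(1), np.zeros(0), np.zeros(1), 1e-12)
        new_part, _ = update_assignments(ds, part, cp, gp, cfg,
                                         np.random.default_rng(0))
        assert new_part.n_clusters == 1

    @pytest.mark.parametrize("rule", ["exposure_only", "own_factor",
                                      "exact_ratio"])
    def test_rules_preserve_partition_validity(self, rng, rule):
        ds, _ = _two_cluster_exposure(rng, n=30, gap=2.0)
        cfg = SamplerConfig(assignment_rule=rule, seed=1)
        part = PartitionState(np.arange(30) % 3)
        cp = ClusterParams([0.0, 1.0, 2.0], np.zeros((3, 0)), [1.0, 1.0, 1.0])
        gp = GlobalParams(-0.1, np.zeros(1), np.zeros(0), np.zeros(1), 1.0)
        new_part, new_cp = update_assignments(ds, part, cp, gp, cfg,
                                              np.random.default_rng(2))
        assert new_part.sizes.sum() == 30
        assert np.all(new_part.sizes >= 1)
        assert new_cp.n_clusters == new_part.n_clusters
        # labels contiguous
        assert set(new_part.assignments) == set(range(new_part.n_clusters))


class TestExactRatioRule:
    def test_increments_match_brute_force(self, rng):
        """The incremental exact-ratio terms equal brute-force differences of
        the full clustered partial log-likelihood."""
        n = 12
        ds = SurvivalDataset(time=rng.exponential(1, n) + 0.01,
                             event=(rng.random(n) > 0.25).astype(float),
                             exposure=rng.normal(0, 1, n), z=None, v=None)
        s = np.array([0, 1, 2] + list(rng.integers(0, 3, n - 3)))
        beta = np.array([0.4])
        lp = ds.covariates() @ beta
        idxr = _ClusterRiskIndex(ds, s, lp)
        lps = lp - idxr.shift
        w = idxr.w
        for i in range(n):
            cur = s[i]
            t_i, w_i, d_i = ds.time[i], w[i], ds.event[i]
            own_cur = (lps[i] - np.log(idxr.denom(cur, t_i))) if d_i else 0.0
            deltas = np.empty(3)
            for k in range(3):
                if k == cur:
                    deltas[k] = own_cur - idxr.leave_gain(cur, t_i, w_i,
                                                          bool(d_i))
                else:
                    own = ((lps[i] - np.log(idxr.denom(k, t_i) + w_i))
                           if d_i else 0.0)
                    deltas[k] = own - idxr.join_penalty(k, t_i, w_i)
            totals = np.empty(3)
            for k in range(3):
                s2 = s.copy()
                s2[i] = k
                totals[k] = clustered_partial_loglik(beta, ds, s2)[0]
            np.testing.assert_allclose(deltas - deltas[cur],
                                       totals - totals[cur], atol=1e-10)


class TestUpdateBeta:
    def test_zero_proposal_scale_never_moves(self, rng):
        ds, _ = _two_cluster_exposure(rng, n=30, gap=2.0)
        part = PartitionState(np.zeros(30, dtype=int))
        gp = GlobalParams(0.5, np.array([0.1]), np.zeros(0), np.zeros(1), 1.0)
        cfg = SamplerConfig(proposal_scale=0.0, adapt=False)
        ba, bz, bv, _ = update_beta(ds, part, gp, cfg, np.random.default_rng(0))
        assert ba == 0.5 and bz[0] == 0.1

    def test_tight_prior_pins_beta_a(self, rng):
        ds, _ = _two_cluster_exposure(rng, n=30, gap=2.0)
        part = PartitionState(np.zeros(30, dtype=int))
        gp = GlobalParams(0.7, np.zeros(1), np.zeros(0), np.zeros(1), 1.0)
        cfg = SamplerConfig(m_beta_a=0.7, tau2_beta_a=1e-14, n_mh_steps=50,
                            proposal_scale=0.05)
        rngs = np.random.default_rng(4)
        for _ in range(5):
            ba, *_ = update_beta(ds, part, gp, cfg, rngs)
            gp.beta_a = ba
        assert ba == pytest.approx(0.7, abs=1e-3)

    def test_fixed_partition_posterior_matches_stratified_mle(self):
        """With assignments fixed at the truth and flat priors, the posterior
        mean of beta_a agrees with the stratified-Cox MLE within Monte-Carlo
        tolerance (the general posterior concentrates at the optimum)."""
        cfg_dgm = scenario_params("easy", "a")
        ds, truth = generate_dataset(cfg_dgm, 400, 77)
        mle = fit_cox_mle(ds, strata=truth.labels)
        part = PartitionState(truth.labels)
        gp = GlobalParams(0.0, np.zeros(1), np.zeros(1), np.zeros(1), 1.0)
        cfg = SamplerConfig(tau2_beta_a=1e6, tau2_beta_v=1e6, b_shrink=1e6,
                            n_mh_steps=1, proposal_scale=0.08, adapt=False)
        rng = np.random.default_rng(9)
        draws = []
        for it in range(6000):
            ba, bz, bv, _ = update_beta(ds, part, gp, cfg, rng, iteration=it + 1)
            gp.beta_a, gp.beta_z, gp.beta_v = ba, bz, bv
            if it >= 1000:
                draws.append(ba)
        draws = np.array(draws)
        ess_guess = len(draws) / 40  # conservative for a random-walk chain
        mc_se = draws.std(ddof=1) / np.sqrt(ess_guess)
        assert abs(draws.mean() - mle.estimate[0]) < max(3 * mc_se, 0.02)


class TestRunSampler:
    def test_seed_reproducibility(self, rng):
        ds, _ = _two_cluster_exposure(rng, n=40, gap=3.0)
        cfg = SamplerConfig(n_iter=60, n_burn=20, seed=123)
        d1 = run_sampler(ds, cfg)
        d2 = run_sampler(ds, cfg)
        np.testing.assert_array_equal(d1.beta_a, d2.beta_a)
        np.testing.assert_array_equal(d1.assignments, d2.assignments)
        np.testing.assert_array_equal(d1.gamma, d2.gamma)

    def test_retained_count_and_validity(self, rng):
        ds, _ = _two_cluster_exposure(rng, n=30, gap=3.0)
        cfg = SamplerConfig(n_iter=90, n_burn=30, thin=3, seed=5)
        d = run_sampler(ds, cfg)
        assert d.n_retained == 20
        for row, k in zip(d.assignments, d.n_clusters):
            assert row.max() == k - 1
            assert np.all(np.bincount(row, minlength=k) >= 1)

    def test_single_true_cluster_keeps_k_small(self):
        """Data generated with one cluster: posterior mode of K stays <= 2."""
        r = np.random.default_rng(8)
        n = 300
        z = r.normal(0, 1, n)
        a = 0.5 * z + r.normal(0, 0.5, n)
        t = r.exponential(1, n) / np.exp(-0.1 * a)
        ds = SurvivalDataset(time=t, event=np.ones(n), exposure=a, z=z, v=None)
        cfg = SamplerConfig(n_iter=400, n_burn=200, seed=2)
        d = run_sampler(ds, cfg)
        assert np.bincount(d.n_clusters).argmax() <= 2

    def test_intercept_only_clustering_configuration(self, rng):
        """Cluster construction applied only to the exposure intercept (the
        alpha0-only configuration): alpha_v and sigma2 are shared."""
        cfg_dgm = scenario_params("easy", "a")
        ds, _ = generate_dataset(cfg_dgm, 150, 3)
        cfg = SamplerConfig(n_iter=60, n_burn=20, seed=1,
                            cluster_specific=("alpha0",))
        d = run_sampler(ds, cfg)
        # one shared alpha_z block absorbs V: p_z_eff = p_z + p_v
        assert d.alpha_z.shape[1] == 2
        assert np.isfinite(d.beta_a).all()


class TestSummaries:
    def _draws(self, beta_a):
        n_ret = len(beta_a)
        return PosteriorDraws(
            beta_a=np.asarray(beta_a, float),
            beta_z=np.zeros((n_ret, 0)), beta_v=np.zeros((n_ret, 0)),
            alpha_z=np.zeros((n_ret, 0)), gamma=np.ones(n_ret),
            n_clusters=np.full(n_ret, 2, dtype=np.int32),
            assignments=np.zeros((n_ret, 4), dtype=np.int16),
            subject_alpha0=np.tile([0., 0., 5., 5.], (n_ret, 1)),
            log_post=np.zeros(n_ret))

    def test_constant_draws(self):
        s = summarize_posterior(self._draws([0.3, 0.3, 0.3]))
        assert s["beta_a"] == {"mean": pytest.approx(0.3),
                               "ci_low": pytest.approx(0.3),
                               "ci_high": pytest.approx(0.3)}

    def test_mean_of_two_draws(self):
        s = summarize_posterior(self._draws([-0.2, 0.0]))
        assert s["beta_a"]["mean"] == pytest.approx(-0.1)

    def test_hr_is_exp_of_log_scale_summary(self):
        s = summarize_posterior(self._draws([-0.3, -0.1, 0.1]))
        assert s["hazard_ratio"]["mean"] == pytest.approx(
            np.exp(s["beta_a"]["mean"]))

    def test_representative_clustering_splits_at_gap(self):
        d = self._draws([0.0, 0.0])
        lab = representative_clustering(d, 2)
        np.testing.assert_array_equal(lab, [0, 0, 1, 1])
        lab_k = representative_clustering(d, "modal_k")
        np.testing.assert_array_equal(lab_k, [0, 0, 1, 1])

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior(self._draws([0.1]))


class TestGewekeJointCorrectness:
    def test_exposure_only_model_reproduces_prior_moments(self):
        """Successive-conditional simulation (Gibbs sweep, then re-simulate the
        exposure data given the state) must preserve the prior distribution of
        the exposure-model parameters when the Cox factor is switched off
        (learning_rate=0). Compares first and second moments of alpha_z and
        E[sigma2-inverse] against marginal-conditional (pure prior) draws."""
        n = 15
        rng = np.random.default_rng(31)
        pri = ExposurePriors(m_alpha0=0.0, tau2_alpha0=1.0,
                             m_alpha_z=0.0, var_alpha_z=1.0,
                             a_sigma=3.0, b_sigma=2.0)
        conc = ConcentrationPrior(1.0, 1.0)
        cfg = SamplerConfig(n_iter=2, n_burn=1, seed=0, learning_rate=0.0,
                            exposure_priors=pri, concentration_prior=conc,
                            init_clusters=1)
        z = rng.normal(0, 1, n)
        time = rng.exponential(1, n) + 0.01
        event = np.ones(n)

        from dpgbcox.crp import sample_gamma
        from dpgbcox.exposure import update_alpha_z, update_sigma2
        from dpgbcox.sampler import (_cluster_block_draw, _sigma2_sweep)

        n_cycles = 4000
        # successive-conditional: state -> data -> one sweep -> ...
        ds = SurvivalDataset(time=time, event=event,
                             exposure=rng.normal(0, 1, n), z=z, v=None)
        eff = _EffectiveModel(ds, cfg)
        part = PartitionState(np.zeros(n, dtype=int))
        cp = ClusterParams([0.0], np.zeros((1, 0)), [1.0])
        gp = GlobalParams(0.0, np.zeros(1), np.zeros(0), np.zeros(1), 1.0)
        succ_az, succ_prec = [], []
        for _ in range(n_cycles):
            # re-simulate exposures given the current state
            mu = (cp.alpha0[part.assignments]
                  + ds.z[:, 0] * gp.alpha_z[0])
            new_a = rng.normal(mu, np.sqrt(cp.sigma2[part.assignments]))
            ds = SurvivalDataset(time=time, event=event, exposure=new_a,
                                 z=z, v=None)
            eff = _EffectiveModel(ds, cfg)
            exp_ds = eff.exposure_ds
            gp.alpha_z = update_alpha_z(exp_ds, part, cp, eff.priors, rng)
            for k in range(part.n_clusters):
                a0k, _ = _cluster_block_draw(exp_ds, part, gp.alpha_z,
                                             eff.priors, rng, k,
                                             float(cp.sigma2[k]), eff)
                cp.alpha0[k] = a0k
            _sigma2_sweep(exp_ds, part, gp.alpha_z, cp, eff.priors, rng, eff)
            part, cp = update_assignments(ds, part, cp, gp, cfg, rng, eff)
            gp.gamma = sample_gamma(part.n_clusters, n, gp.gamma, conc, rng)
            succ_az.append(gp.alpha_z[0])
            succ_prec.append(1.0 / cp.sigma2[0])
        succ_az = np.array(succ_az)
        succ_prec = np.array(succ_prec)
        # marginal-conditional references: alpha_z ~ N(0,1);
        # 1/sigma2 ~ Gamma(3, rate 2) with mean 1.5, var 0.75
        ess = n_cycles / 20
        assert abs(succ_az.mean()) < 4 * np.sqrt(1.0 / ess)
        assert abs(succ_az.var(ddof=1) - 1.0) < 4 * np.sqrt(2.0 / ess)
        assert abs(succ_prec.mean() - 1.5) < 4 * np.sqrt(0.75 / ess)
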