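"""Generic kernels vs exhaustive-enumeration oracles on tiny models."""

import numpy as np
import pytest
from scipy.special import logsumexp

from hammingball.ball import enumerate_ball
from hammingball.samplers import (
    ImpossibleSliceError,
    SamplerConfig,
    block_gibbs_sweep,
    block_hb_sweep,
    hb_gibbs_iteration,
    hb_marginal_mh_iteration,
    msss_iteration,
    random_radius_iteration,
    restricted_block_weights,
    run_chain,
    update_auxiliary,
)
from util import (
    TableModel,
    brute_joint_posterior,
    brute_posterior,
    empirical_distribution,
    encode,
    random_tables,
    tv,
)

BLOCKS_6 = [np.arange(0, 3), np.arange(3, 6)]


def make_model(seed, blocks=None, scale=1.5):
    blocks = blocks or BLOCKS_6
    rng = np.random.default_rng(seed)
    return TableModel(random_tables(blocks, 2, rng, scale), blocks)


def make_theta_model(seed, blocks=None):
    """Two-level discrete parameter switching the block tables."""
    blocks = blocks or BLOCKS_6
    rng = np.random.default_rng(seed)
    return TableModel(
        random_tables(blocks, 2, rng),
        blocks,
        theta_tables={0: random_tables(blocks, 2, rng), 1: random_tables(blocks, 2, rng)},
        theta_prior={0: np.log(0.4), 1: np.log(0.6)},
    )


class TestUpdateAuxiliary:
    def test_radius_zero_copies_x(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, size=6)
        u = update_auxiliary(x, BLOCKS_6, 0, 2, rng)
        assert np.array_equal(u, x)

    def test_all_blocks_within_ball(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, size=6)
        for _ in range(200):
            u = update_auxiliary(x, BLOCKS_6, 2, 2, rng)
            for blk in BLOCKS_6:
                assert np.count_nonzero(u[blk] != x[blk]) <= 2

    def test_full_radius_uniform_over_block_space(self):
        from scipy.stats import chisquare

        rng = np.random.default_rng(2)
        x = np.zeros(3, dtype=np.int64)
        blocks = [np.arange(3)]
        draws = np.array([update_auxiliary(x, blocks, 3, 2, rng) for _ in range(8000)])
        _, p = chisquare(np.bincount(encode(draws, 2), minlength=8))
        assert p > 0.01


class TestRestrictedBlockWeights:
    def test_constant_model_uniform_over_ball(self):
        model = TableModel([np.zeros(8)], [np.arange(3)])
        x = np.zeros(3, dtype=np.int64)
        cands, probs = restricted_block_weights(model, x, np.arange(3), x, 1, None)
        assert len(cands) == 4
        assert np.allclose(probs, 0.25)

    def test_hand_normalized_two_state(self):
        model = TableModel([np.array([np.log(1.0), np.log(3.0)])], [np.arange(1)])
        x = np.zeros(1, dtype=np.int64)
        _, probs = restricted_block_weights(model, x, np.arange(1), x, 1, None)
        assert np.allclose(probs, [0.25, 0.75])

    def test_full_radius_equals_exact_conditional(self):
        # m=K recovers the unrestricted conditional p(x_i | X_-i) exactly
        model = make_model(3)
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, size=6)
        blk = BLOCKS_6[0]
        cands, probs = restricted_block_weights(model, x, blk, x[blk], 3, None)
        logw = model.tables[0][encode(cands, 2)]
        exact = np.exp(logw - logsumexp(logw))
        assert np.max(np.abs(probs - exact)) < 1e-12

    def test_all_minus_inf_raises(self):
        model = TableModel([np.full(8, -np.inf)], [np.arange(3)])
        x = np.zeros(3, dtype=np.int64)
        with pytest.raises(ImpossibleSliceError):
            restricted_block_weights(model, x, np.arange(3), x, 1, None)


class TestOracleEquivalence:
    """Empirical chain distributions vs exhaustive enumeration."""

    N_ITER = 200_000

    def _run_and_compare(self, kernel, model, tol=0.02, **kw):
        config = SamplerConfig(
            kernel=kernel, iterations=self.N_ITER, burn_in=2000, seed=11,
            partition=BLOCKS_6, **kw,
        )
        trace = run_chain(model, np.zeros(6, dtype=np.int64), None, config)
        _, post = brute_posterior(model, 6)
        emp = empirical_distribution(trace.states)
        assert tv(emp, post) < tol

    def test_block_hb(self):
        self._run_and_compare("block_hb", make_model(20), m=1, K=3)

    def test_block_hb_radius_two(self):
        self._run_and_compare("block_hb", make_model(21), m=2, K=3)

    def test_block_gibbs(self):
        self._run_and_compare("block_gibbs", make_model(22), K=3)

    def test_hb_gibbs_fixed_theta(self):
        self._run_and_compare("hb_gibbs", make_model(23), m=1)

    def test_msss(self):
        self._run_and_compare("msss", make_model(24), m=1)

    def test_random_radius(self):
        model = make_model(25)
        rdist = lambda rng: rng.integers(0, 3, size=2)  # noqa: E731
        config = SamplerConfig(
            kernel="random_radius", iterations=self.N_ITER, burn_in=2000,
            seed=12, partition=BLOCKS_6, rdist=rdist,
        )
        trace = run_chain(model, np.zeros(6, dtype=np.int64), None, config)
        _, post = brute_posterior(model, 6)
        assert tv(empirical_distribution(trace.states), post) < 0.02

    def test_block_hb_random_partitions(self):
        # random re-partitioning each sweep over a non-factorized model
        rng = np.random.default_rng(30)
        full = TableModel([2.0 * rng.normal(size=64)], [np.arange(6)])
        config = SamplerConfig(kernel="block_hb", iterations=150_000, burn_in=2000,
                               seed=13, m=1, K=3)
        trace = run_chain(full, np.zeros(6, dtype=np.int64), None, config)
        _, post = brute_posterior(full, 6)
        assert tv(empirical_distribution(trace.states), post) < 0.02

    def test_hb_gibbs_joint_theta(self):
        # theta resampled from its full conditional between ball updates
        model = make_theta_model(26)
        config = SamplerConfig(kernel="hb_gibbs", iterations=self.N_ITER, burn_in=2000,
                               seed=14, m=1, partition=BLOCKS_6)
        trace = run_chain(model, np.zeros(6, dtype=np.int64), 0, config)
        keys, _, joint = brute_joint_posterior(model, 6)
        emp = np.zeros_like(joint)
        for s, th in zip(trace.states, trace.thetas):
            emp[keys.index(th), int(encode(s, 2)[0])] += 1
        assert tv((emp / emp.sum()).ravel(), joint.ravel()) < 0.02

    def test_marginal_mh_joint_theta(self):
        model = make_theta_model(27)
        config = SamplerConfig(kernel="hb_marginal_mh", iterations=120_000,
                               burn_in=2000, seed=15, m=1, partition=BLOCKS_6)
        trace = run_chain(model, np.zeros(6, dtype=np.int64), 0, config)
        keys, _, joint = brute_joint_posterior(model, 6)
        emp = np.zeros_like(joint)
        for s, th in zip(trace.states, trace.thetas):
            emp[keys.index(th), int(encode(s, 2)[0])] += 1
        assert tv((emp / emp.sum()).ravel(), joint.ravel()) < 0.05


class TestAcceptanceRatioIdentity:
    def test_simplified_equals_four_factor_ratio(self):
        """The collapsed M-H ratio (restricted marginals only) must equal
        the full ratio of joint densities times proposal terms."""
        model = make_theta_model(40)
        rng = np.random.default_rng(41)
        m = 1
        for _ in range(50):
            x = rng.integers(0, 2, size=6)
            u = update_auxiliary(x, BLOCKS_6, m, 2, rng)
            theta, theta_p = 0, 1
            # restricted marginals p~(theta, U, y) via ball sums
            def log_marg(th):
                tot = 0.0
                for blk in BLOCKS_6:
                    cands = enumerate_ball(u[blk], m, 2)
                    logw = model.block_log_weights(x, blk, cands, th)
                    tot += logsumexp(logw)
                return tot

            # draw X' from the restricted conditional under theta'
            x_p = x.copy()
            log_q_xp = 0.0
            log_q_x = 0.0
            for blk in BLOCKS_6:
                cands, probs = restricted_block_weights(model, x_p, blk, u[blk], m, theta_p)
                k = rng.choice(len(cands), p=probs)
                x_p[blk] = cands[k]
                log_q_xp += np.log(probs[k])
            for blk in BLOCKS_6:
                cands, probs = restricted_block_weights(model, x, blk, u[blk], m, theta)
                match = np.flatnonzero((cands == x[blk]).all(axis=1))[0]
                log_q_x += np.log(probs[match])

            simplified = log_marg(theta_p) - log_marg(theta)  # symmetric proposal
            full = (
                model.log_joint(x_p, theta_p)
                - model.log_joint(x, theta)
                + log_q_x
                - log_q_xp
            )
            assert abs(simplified - full) < 1e-10


class TestChangeBounds:
    def test_hb_changes_at_most_2mP(self):
        model = make_model(50)
        rng = np.random.default_rng(51)
        x = rng.integers(0, 2, size=6)
        for m in (1, 2):
            xc = x.copy()
            for _ in range(3000):
                x_new, _, _ = hb_gibbs_iteration(model, xc, None, m, rng, BLOCKS_6)
                assert np.count_nonzero(x_new != xc) <= 2 * m * len(BLOCKS_6)
                for blk in BLOCKS_6:
                    assert np.count_nonzero(x_new[blk] != xc[blk]) <= 2 * m
                xc = x_new

    def test_msss_changes_at_most_mP(self):
        model = make_model(52)
        rng = np.random.default_rng(53)
        x = np.zeros(6, dtype=np.int64)
        for _ in range(3000):
            x_new, _ = msss_iteration(model, x, None, 1, rng, BLOCKS_6)
            assert np.count_nonzero(x_new != x) <= 1 * len(BLOCKS_6)
            x = x_new

    def test_radius_zero_freezes_chain(self):
        model = make_model(54)
        rng = np.random.default_rng(55)
        x = rng.integers(0, 2, size=6)
        x_new, _, _ = hb_gibbs_iteration(model, x, None, 0, rng, BLOCKS_6)
        assert np.array_equal(x_new, x)


class TestSpecialCases:
    def test_block_gibbs_is_hb_with_full_radius(self):
        model_a, model_b = make_model(60), make_model(60)
        rng_a, rng_b = np.random.default_rng(61), np.random.default_rng(61)
        x = np.zeros(6, dtype=np.int64)
        xa = block_gibbs_sweep(model_a, x, None, 3, rng_a, BLOCKS_6)
        xb = block_hb_sweep(model_b, x, None, 3, 3, rng_b, BLOCKS_6)
        assert np.array_equal(xa, xb)

    def test_full_radius_conditional_matches_exact_gibbs(self):
        # the m=K HB per-block conditional equals the exact conditional
        model = make_model(62)
        rng = np.random.default_rng(63)
        for _ in range(20):
            x = rng.integers(0, 2, size=6)
            u = rng.integers(0, 2, size=6)  # any center: ball covers everything
            for i, blk in enumerate(BLOCKS_6):
                cands, probs = restricted_block_weights(model, x, blk, u[blk], 3, None)
                logw = model.tables[i][encode(cands, 2)]
                exact = np.exp(logw - logsumexp(logw))
                assert np.max(np.abs(probs - exact)) < 1e-12

    def test_degenerate_radius_dist_is_single_block_gibbs(self):
        model = make_model(64)
        rng = np.random.default_rng(65)
        x = rng.integers(0, 2, size=6)
        rdist = lambda rng_: np.array([3, 0])  # noqa: E731
        for _ in range(100):
            x_new, _ = random_radius_iteration(model, x, None, rdist, rng, BLOCKS_6)
            assert np.array_equal(x_new[BLOCKS_6[1]], x[BLOCKS_6[1]])
            x = x_new

    def test_all_zero_radii_freeze(self):
        model = make_model(66)
        rng = np.random.default_rng(67)
        x = rng.integers(0, 2, size=6)
        x_new, _ = random_radius_iteration(
            model, x, None, lambda r: np.zeros(2, dtype=int), rng, BLOCKS_6
        )
        assert np.array_equal(x_new, x)

    def test_msss_equal_volumes_always_accept(self):
        model = TableModel([np.zeros(8), np.zeros(8)], BLOCKS_6)
        rng = np.random.default_rng(68)
        x = np.zeros(6, dtype=np.int64)
        accepts = [msss_iteration(model, x, None, 1, rng, BLOCKS_6)[1] for _ in range(200)]
        assert all(accepts)

    def test_mh_identity_proposal_always_accepts(self):
        model = make_theta_model(69)
        model.propose_theta = lambda th, rng: th  # symmetric degenerate proposal
        model.log_proposal_density = lambda a, b: 0.0
        rng = np.random.default_rng(70)
        x = np.zeros(6, dtype=np.int64)
        accepts = [
            hb_marginal_mh_iteration(model, x, 0, 1, rng, BLOCKS_6)[2] for _ in range(200)
        ]
        assert all(accepts)


class TestEvalCounts:
    def test_block_hb_evaluates_M_per_block(self):
        # O(MP) weight evaluations per sweep, M = ball volume
        from hammingball.ball import ball_volume

        model = make_model(80)
        rng = np.random.default_rng(81)
        x = np.zeros(6, dtype=np.int64)
        for _ in range(10):
            x = block_hb_sweep(model, x, None, 3, 1, rng, BLOCKS_6)
        assert model.n_weight_evals == 10 * ball_volume(1, 3) * 2

    def test_block_gibbs_evaluates_full_space_per_block(self):
        model = make_model(82)
        rng = np.random.default_rng(83)
        x = np.zeros(6, dtype=np.int64)
        for _ in range(10):
            x = block_gibbs_sweep(model, x, None, 3, rng, BLOCKS_6)
        assert model.n_weight_evals == 10 * 2**3 * 2


class TestRunChain:
    def test_deterministic_given_seed(self):
        t1 = run_chain(
            make_model(90), np.zeros(6, dtype=np.int64), None,
            SamplerConfig(kernel="block_hb", iterations=200, m=1, K=3, seed=7),
        )
        t2 = run_chain(
            make_model(90), np.zeros(6, dtype=np.int64), None,
            SamplerConfig(kernel="block_hb", iterations=200, m=1, K=3, seed=7),
        )
        assert np.array_equal(t1.states, t2.states)

    def test_trace_length_and_thinning(self):
        trace = run_chain(
            make_model(91), np.zeros(6, dtype=np.int64), None,
            SamplerConfig(kernel="block_hb", iterations=100, burn_in=30, m=1, K=3,
                          seed=8, thin=5),
        )
        assert len(trace) == 20

    def test_invalid_kernel_rejected_before_sampling(self):
        with pytest.raises(ValueError, match="unknown kernel"):
            run_chain(
                make_model(92), np.zeros(6, dtype=np.int64), None,
                SamplerConfig(kernel="nope", iterations=10),
            )

    def test_missing_theta_hooks_raise(self):
        from hammingball.samplers import DiscreteModel

        class Bare(DiscreteModel):
            factorized = True

            def log_joint(self, x, theta=None):
                return 0.0

        with pytest.raises(NotImplementedError, match="sample_theta"):
            run_chain(
                Bare(), np.zeros(6, dtype=np.int64), None,
                SamplerConfig(kernel="hb_gibbs", iterations=5, m=1, partition=BLOCKS_6),
            )

    def test_nonfactorized_multiblock_marginal_mh_rejected(self):
        model = make_theta_model(94)
        model.factorized = False
        with pytest.raises(ValueError, match="factorized"):
            hb_marginal_mh_iteration(
                model, np.zeros(6, dtype=np.int64), 0, 1,
                np.random.default_rng(0), BLOCKS_6,
            )
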