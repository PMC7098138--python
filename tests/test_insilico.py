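"""Bayesian sampler: exact posteriors, schedule, mixing, diagnostics."""

import numpy as np
import pytest

import vaval
from vaval import (ABSENT, MISSING, PRESENT, CauseDictionary, CondProbMatrix,
                   InsilicoConfig, PosteriorDraws, SymptomDictionary,
                   SymptomMatrix, bin_to_levels, convergence_check,
                   extract_prob_raw, individual_posterior, insilico_fit,
                   top_cause)
from vaval.insilico import heidel_stationarity


def _probbase(values):
    values = np.asarray(values, dtype=float)
    return CondProbMatrix(
        values=values,
        cause_dict=CauseDictionary(
            codes=tuple(f"c{i}" for i in range(values.shape[1]))),
        symptom_ids=tuple(f"s{j}" for j in range(values.shape[0])))


def _matrix(values, symptom_ids=None):
    values = np.asarray(values, dtype=np.int8)
    d = SymptomDictionary(
        symptom_ids=symptom_ids
        or tuple(f"s{j}" for j in range(values.shape[1])))
    return SymptomMatrix(values=values, dictionary=d)


TOY_PB = [[0.9, 0.1], [0.2, 0.8]]


class TestIndividualPosterior:
    def test_identical_columns_give_uniform(self):
        pb = _probbase([[0.7, 0.7], [0.3, 0.3]])
        post = individual_posterior([PRESENT, ABSENT], pb, [0.5, 0.5])
        np.testing.assert_allclose(post, [0.5, 0.5])

    def test_all_missing_returns_csmf(self):
        pb = _probbase(TOY_PB)
        csmf = np.array([0.3, 0.7])
        post = individual_posterior([MISSING, MISSING], pb, csmf)
        np.testing.assert_allclose(post, csmf)

    def test_matches_brute_force_bayes_rule(self):
        # independent oracle: enumerate both causes with plain arithmetic
        p = TOY_PB
        lik_c0 = p[0][0] * (1 - p[1][0])   # s0 PRESENT, s1 ABSENT | c0
        lik_c1 = p[0][1] * (1 - p[1][1])
        expected = np.array([0.5 * lik_c0, 0.5 * lik_c1])
        expected /= expected.sum()
        post = individual_posterior([PRESENT, ABSENT], _probbase(p), [0.5, 0.5])
        np.testing.assert_allclose(post, expected, rtol=1e-12)

    def test_permuting_causes_permutes_posterior(self):
        pb = _probbase(TOY_PB)
        perm = _probbase(np.asarray(TOY_PB)[:, ::-1])
        a = individual_posterior([PRESENT, ABSENT], pb, [0.3, 0.7])
        b = individual_posterior([PRESENT, ABSENT], perm, [0.7, 0.3])
        np.testing.assert_allclose(a, b[::-1])

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            individual_posterior([PRESENT], _probbase(TOY_PB), [0.5, 0.5])


class TestTopCause:
    def test_argmax_and_tie_rule(self):
        assert top_cause([0.2, 0.7, 0.1]) == 1
        assert top_cause([0.5, 0.5]) == 0  # tie -> lowest index
        assert top_cause([0.2, 0.7, 0.1], ("a", "b", "c")) == "b"

    def test_equivariant_under_permutation(self):
        v = np.array([0.1, 0.6, 0.3])
        perm = np.array([2, 0, 1])
        assert perm[top_cause(v[perm])] == top_cause(v)


class TestFit:
    def test_default_schedule_retains_500_draws(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.integers(0, 2, (20, 4)))
        pb = _probbase(rng.random((4, 3)) * 0.8 + 0.1)
        draws = insilico_fit(m, pb, InsilicoConfig(seed=1))
        assert draws.n_retained == 500
        assert draws.csmf_draws.shape == (500, 3)
        np.testing.assert_allclose(draws.csmf_draws.sum(axis=1), 1, atol=1e-9)
        np.testing.assert_allclose(draws.individual_probs.sum(axis=1), 1,
                                   atol=1e-9)

    def test_identical_probbase_columns_give_symmetric_csmf(self):
        """Exchangeable causes: posterior CSMF means agree within MC error."""
        rng = np.random.default_rng(2)
        m = _matrix(rng.integers(0, 2, (40, 5)))
        col = rng.random(5) * 0.8 + 0.1
        pb = _probbase(np.stack([col, col], axis=1))
        draws = insilico_fit(m, pb, InsilicoConfig(seed=3, jump_scale=0.3))
        # likelihood is symmetric, so both means are 0.5 up to chain noise
        assert abs(draws.csmf_mean[0] - 0.5) < 0.1

    def test_bit_identical_given_seed(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.integers(-1, 2, (15, 6)))
        pb = _probbase(rng.random((6, 3)) * 0.8 + 0.1)
        cfg = InsilicoConfig(n_iter=800, burn_in=300, thin=5, seed=9)
        a = insilico_fit(m, pb, cfg)
        b = insilico_fit(m, pb, cfg)
        np.testing.assert_array_equal(a.csmf_draws, b.csmf_draws)
        np.testing.assert_array_equal(a.y_draws, b.y_draws)
        assert a.acceptance_rate == b.acceptance_rate

    def test_adaptive_mode_reproducible_and_ordered(self):
        rng = np.random.default_rng(5)
        m = _matrix(rng.integers(-1, 2, (30, 8)))
        train = SymptomMatrix(values=np.abs(m.values), dictionary=m.dictionary,
                              causes=np.array(["c0", "c1"] * 15),
                              cause_dict=CauseDictionary(codes=("c0", "c1")))
        pb = bin_to_levels(extract_prob_raw(train))
        cfg = InsilicoConfig(n_iter=600, burn_in=200, thin=4, seed=6,
                             update_cond_probs=True)
        a = insilico_fit(m, pb, cfg)
        b = insilico_fit(m, pb, cfg)
        np.testing.assert_array_equal(a.level_draws, b.level_draws)
        # strict level ordering preserved in every retained draw
        assert (np.diff(a.level_draws, axis=1) < 0).all()

    def test_dimension_mismatch_errors(self):
        m = _matrix(np.zeros((2, 3)))
        pb = _probbase(np.full((4, 2), 0.5))
        with pytest.raises(ValueError, match="match"):
            insilico_fit(m, pb, InsilicoConfig(n_iter=10, burn_in=5, thin=1))

    def test_impossible_death_identified(self):
        # probbase says s0 certain-present for every cause; a death with
        # s0 ABSENT has zero likelihood everywhere
        pb = _probbase([[1.0, 1.0]])
        m = _matrix([[ABSENT]])
        with pytest.raises(ValueError, match="d0"):
            insilico_fit(m, pb, InsilicoConfig(n_iter=10, burn_in=5, thin=1))

    def test_mean_csmf_recovers_truth_on_model_data(self):
        """Simulation check at C=5, S=30, n=500; tolerance 0.08 frozen from
        a 20-replicate pre-study of the spread of posterior means."""
        spec = vaval.SyntheticSpec(n_causes=5, n_symptoms=30, n_deaths=500,
                                   true_csmf="dirichlet:1",
                                   probbase_gen=(0.3, 0.3),
                                   missing_rate=0.178, n_hce=0, seed=1234)
        m, pb, csmf = vaval.generate(spec)
        draws = insilico_fit(m, pb, InsilicoConfig(jump_scale=0.1, seed=99))
        assert np.abs(draws.csmf_mean - csmf).max() < 0.08


class TestGibbsMatchesExhaustiveBayes:
    def test_y_frequencies_match_individual_posterior(self):
        """With the CSMF held fixed, the sampler's latent-cause draw
        frequencies must reproduce the exhaustive Bayes-rule posterior."""
        pb = _probbase(TOY_PB)
        m = _matrix([[PRESENT, ABSENT],
                     [ABSENT, PRESENT],
                     [PRESENT, MISSING],
                     [MISSING, MISSING]])
        csmf = np.array([0.4, 0.6])
        cfg = InsilicoConfig(n_iter=20_000, burn_in=0, thin=1, seed=7,
                             fix_csmf=csmf)
        draws = insilico_fit(m, pb, cfg)
        freq = (draws.y_draws == 0).mean(axis=0)
        for i in range(m.n_deaths):
            exact = individual_posterior(m.values[i], pb, csmf)[0]
            assert abs(freq[i] - exact) < 0.02  # ~5 binomial SEs at R=20000
        # the Rao-Blackwellized probabilities are exact here
        for i in range(m.n_deaths):
            exact = individual_posterior(m.values[i], pb, csmf)
            np.testing.assert_allclose(draws.individual_probs[i], exact,
                                       atol=1e-9)


class TestAcceptanceRate:
    def _setup(self):
        rng = np.random.default_rng(8)
        m = _matrix(rng.integers(0, 2, (50, 6)))
        pb = _probbase(rng.random((6, 4)) * 0.8 + 0.1)
        return m, pb

    def test_tiny_jump_accepts_nearly_everything(self):
        m, pb = self._setup()
        cfg = InsilicoConfig(n_iter=600, burn_in=200, thin=2, seed=1,
                             jump_scale=1e-4)
        assert vaval.acceptance_rate(insilico_fit(m, pb, cfg)) > 0.9

    def test_huge_jump_rarely_accepts(self):
        m, pb = self._setup()
        cfg = InsilicoConfig(n_iter=600, burn_in=200, thin=2, seed=1,
                             jump_scale=100.0)
        assert vaval.acceptance_rate(insilico_fit(m, pb, cfg)) < 0.1


class TestStatisticalEquivariance:
    def test_cause_permutation_permutes_posterior_means(self):
        """Relabeling causes permutes the posterior within MC error."""
        spec = vaval.SyntheticSpec(n_causes=3, n_symptoms=20, n_deaths=200,
                                   true_csmf=np.array([0.5, 0.3, 0.2]),
                                   probbase_gen=(0.3, 0.3), missing_rate=0.1,
                                   n_hce=0, seed=21)
        m, pb, _ = vaval.generate(spec)
        perm = np.array([2, 0, 1])
        pb_perm = CondProbMatrix(values=pb.values[:, perm],
                                 cause_dict=pb.cause_dict,
                                 symptom_ids=pb.symptom_ids)
        cfg = InsilicoConfig(n_iter=4000, burn_in=1000, thin=5,
                             jump_scale=0.1, seed=13)
        a = insilico_fit(m, pb, cfg)
        b = insilico_fit(m, pb_perm, cfg)
        np.testing.assert_allclose(a.csmf_mean[perm], b.csmf_mean, atol=0.03)
        np.testing.assert_allclose(a.individual_probs[:, perm],
                                   b.individual_probs, atol=0.05)


class TestConvergence:
    def _draws(self, chain):
        R = len(chain)
        csmf = np.column_stack([chain, 1 - chain])
        return PosteriorDraws(csmf_draws=csmf,
                              individual_probs=np.full((1, 2), 0.5),
                              y_draws=np.zeros((R, 1), dtype=np.int32),
                              acceptance_rate=0.3,
                              cause_codes=("c0", "c1"), death_ids=["d0"])

    def test_iid_chain_passes(self):
        rng = np.random.default_rng(10)
        flags, warn = convergence_check(self._draws(rng.beta(5, 5, 500)))
        assert all(flags.values()) and not warn

    def test_trending_chain_fails(self):
        flags, warn = convergence_check(self._draws(np.linspace(0.1, 0.9, 500)))
        assert warn and not all(flags.values())

    def test_too_few_draws_errors(self):
        with pytest.raises(ValueError, match="50"):
            convergence_check(self._draws(np.full(10, 0.5)))

    def test_small_csmf_causes_not_monitored(self):
        # trending but tiny-CSMF chain is ignored at the 0.02 threshold
        chain = np.linspace(0.0, 0.02, 500)
        flags, warn = convergence_check(self._draws(chain))
        assert flags["c0"] and not flags["c1"] and warn

    def test_well_mixed_fit_passes(self):
        rng = np.random.default_rng(30)
        m = _matrix(rng.integers(0, 2, (100, 10)))
        pb = _probbase(rng.random((10, 3)) * 0.8 + 0.1)
        draws = insilico_fit(m, pb, InsilicoConfig(jump_scale=0.1, seed=31))
        flags, warn = convergence_check(draws)
        assert not warn

    def test_stationarity_helper_on_raw_chains(self):
        rng = np.random.default_rng(12)
        assert heidel_stationarity(rng.normal(size=400))
        assert not heidel_stationarity(np.linspace(0, 1, 400))
        assert heidel_stationarity(np.full(400, 0.4))  # constant passes


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"burn_in": 100, "n_iter": 100},
        {"thin": 0},
        {"jump_scale": 0.0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            InsilicoConfig(**kwargs)

    def test_default_retention_count(self):
        assert InsilicoConfig().n_retained == 500
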