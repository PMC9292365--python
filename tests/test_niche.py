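"""Niche-side inference: mirror-image free energy, trace field dynamics,
affordance landscape, type recovery."""

import numpy as np
import pytest

from eai.errors import InvalidDistributionError, UnknownLabelError
from eai.generative_model import Categorical, DirichletCounts, kl_divergence
from eai.inference import free_energy
from eai.niche import (
    AffordanceField,
    NicheBelief,
    NicheModel,
    affordance_field,
    as_generative_model,
    decay_traces,
    deposit_trace,
    niche_exact_posterior,
    niche_free_energy,
    niche_step,
    trace_entropy,
)

from .conftest import assert_bound_contracts, total_variation


def cafe_niche(p_goer=0.9, p_wanderer=0.25, decay=0.01) -> NicheModel:
    """Two agent types, two actions; p(toward_cafe | goer) = 0.9,
    p(toward_cafe | wanderer) = 0.25, uniform type prior."""
    return NicheModel(
        agent_types=("cafe_goer", "wanderer"),
        type_counts=DirichletCounts(np.ones(2)),
        action_likelihood=np.array([[p_goer, p_wanderer], [1 - p_goer, 1 - p_wanderer]]),
        locations=("0,0", "1,0"),
        actions=("toward_cafe", "away"),
        trace=DirichletCounts(np.ones((2, 2))),
        decay_rate=decay,
    )


def random_niche(rng: np.random.Generator) -> NicheModel:
    n_types = int(rng.integers(2, 6))
    n_actions = int(rng.integers(2, 6))
    return NicheModel(
        agent_types=tuple(f"t{i}" for i in range(n_types)),
        type_counts=DirichletCounts(rng.uniform(0.2, 3.0, size=n_types)),
        action_likelihood=rng.dirichlet(np.ones(n_actions), size=n_types).T,
        locations=("0,0",),
        actions=tuple(f"a{i}" for i in range(n_actions)),
        trace=DirichletCounts(rng.uniform(0.5, 5.0, size=(1, n_actions))),
    )


class TestNichePosterior:
    def test_cafe_example_by_hand(self):
        niche = cafe_niche()
        post = niche_exact_posterior(niche, "toward_cafe")
        # Bayes: (0.45, 0.125) / 0.575
        np.testing.assert_allclose(post.probs, [0.45 / 0.575, 0.125 / 0.575], atol=1e-12)
        np.testing.assert_allclose(post.probs, [0.7826, 0.2174], atol=1e-4)

    def test_uninformative_action_returns_prior(self):
        niche = cafe_niche(p_goer=0.5, p_wanderer=0.5)
        post = niche_exact_posterior(niche, "toward_cafe")
        np.testing.assert_allclose(post.probs, niche.type_prior.probs, atol=1e-12)

    def test_type_deterministic_likelihood(self):
        niche = cafe_niche(p_goer=1.0 - 1e-15, p_wanderer=1e-15)
        post = niche_exact_posterior(niche, "toward_cafe")
        assert post.probs[0] > 1 - 1e-9


class TestNicheFreeEnergy:
    def test_cafe_example_decomposition(self):
        niche = cafe_niche()
        rep = niche_free_energy(niche.type_prior_belief(), niche, "toward_cafe")
        assert rep.surprisal == pytest.approx(-np.log(0.575), abs=1e-12)
        hand_div = kl_divergence(
            niche.type_prior, niche_exact_posterior(niche, "toward_cafe").distribution
        )
        assert rep.divergence == pytest.approx(hand_div, abs=1e-9)
        # by hand: 0.5 ln(0.5/0.78261) + 0.5 ln(0.5/0.21739) = 0.19247
        assert rep.divergence == pytest.approx(0.19247, abs=1e-4)
        assert rep.total == pytest.approx(0.55339 + 0.19247, abs=1e-4)

    def test_bound_saturates_at_posterior(self):
        niche = cafe_niche()
        post = niche_exact_posterior(niche, "toward_cafe")
        rep = niche_free_energy(post, niche, "toward_cafe")
        assert rep.divergence == pytest.approx(0.0, abs=1e-12)
        assert rep.total == pytest.approx(-np.log(0.575), abs=1e-9)

    def test_single_type_degenerate_hypothesis_space(self):
        niche = NicheModel(
            agent_types=("only",),
            type_counts=DirichletCounts(np.ones(1)),
            action_likelihood=np.array([[0.7], [0.3]]),
            locations=("0,0",),
            actions=("a", "b"),
            trace=DirichletCounts(np.ones((1, 2))),
        )
        rep = niche_free_energy(niche.type_prior_belief(), niche, "a")
        assert rep.divergence == pytest.approx(0.0, abs=1e-12)
        assert rep.total == pytest.approx(-np.log(0.7), abs=1e-12)

    def test_mirror_symmetry_battery(self):
        # the organism-side bound/equality contracts hold verbatim on the
        # mirrored model with sensations <-> actions, states <-> types
        rng = np.random.default_rng(21)
        for _ in range(200):
            niche = random_niche(rng)
            mirror = as_generative_model(niche)
            a = niche.actions[int(rng.integers(len(niche.actions)))]
            from eai.inference import Belief

            q = Belief(Categorical(niche.agent_types, rng.dirichlet(np.ones(len(niche.agent_types)))))
            assert_bound_contracts(mirror, a, q)
            # and the niche-side wrapper agrees with the organism-side form
            rep_wrap = niche_free_energy(NicheBelief(q.distribution), niche, a)
            rep_mirror = free_energy(q, mirror, a)
            assert rep_wrap.total == pytest.approx(rep_mirror.total, abs=1e-12)


class TestTraceDynamics:
    def make_field_niche(self, concentrations) -> NicheModel:
        arr = np.asarray(concentrations, dtype=float)
        return NicheModel(
            agent_types=("t0",),
            type_counts=DirichletCounts(np.ones(1)),
            action_likelihood=np.full((arr.shape[1], 1), 1.0 / arr.shape[1]),
            locations=tuple(f"{i},0" for i in range(arr.shape[0])),
            actions=tuple(f"a{j}" for j in range(arr.shape[1])),
            trace=DirichletCounts(arr),
        )

    def test_deposit_dirichlet_mean(self):
        niche = self.make_field_niche([[1.0, 1.0, 1.0, 1.0]])
        out = deposit_trace(niche, "0,0", "a0", 4.0)
        np.testing.assert_allclose(out.trace.expected(axis=1)[0], [5 / 8, 1 / 8, 1 / 8, 1 / 8])

    def test_tiny_deposit_leaves_field(self):
        niche = self.make_field_niche([[1.0, 1.0]])
        out = deposit_trace(niche, "0,0", "a0", 1e-9)
        assert total_variation(out.trace.expected(axis=1)[0], [0.5, 0.5]) < 1e-9

    def test_repeated_deposits_approach_certainty(self):
        niche = self.make_field_niche([[1.0, 1.0]])
        prev = 0.5
        for _ in range(50):
            niche = deposit_trace(niche, "0,0", "a0", 5.0)
            p = niche.trace.expected(axis=1)[0, 0]
            assert p > prev
            prev = p
        assert prev > 0.99

    def test_deposit_validation(self):
        niche = self.make_field_niche([[1.0, 1.0]])
        with pytest.raises(ValueError):
            deposit_trace(niche, "0,0", "a0", 0.0)
        with pytest.raises(UnknownLabelError):
            deposit_trace(niche, "9,9", "a0", 1.0)
        with pytest.raises(UnknownLabelError):
            deposit_trace(niche, "0,0", "zzz", 1.0)

    def test_decay_identity_and_mean_invariance(self):
        niche = self.make_field_niche([[8.0, 2.0]])
        same = decay_traces(niche, 0.0)
        np.testing.assert_array_equal(same.trace.concentration, niche.trace.concentration)
        halved = decay_traces(niche, 0.5)
        np.testing.assert_allclose(halved.trace.concentration, [[4.0, 1.0]])
        np.testing.assert_allclose(
            halved.trace.expected(axis=1), niche.trace.expected(axis=1), atol=1e-15
        )

    def test_decay_converges_to_uniform_at_floor(self):
        niche = self.make_field_niche([[80.0, 2.0]])
        for _ in range(2000):
            niche = decay_traces(niche, 0.05)
        np.testing.assert_allclose(niche.trace.expected(axis=1)[0], [0.5, 0.5], atol=1e-6)

    def test_decay_rate_domain(self):
        niche = self.make_field_niche([[1.0, 1.0]])
        with pytest.raises(InvalidDistributionError):
            decay_traces(niche, 1.0)


class TestAffordanceField:
    def test_flat_landscape(self):
        niche = NicheModel(
            agent_types=("t0",),
            type_counts=DirichletCounts(np.ones(1)),
            action_likelihood=np.full((4, 1), 0.25),
            locations=("0,0", "1,0"),
            actions=("a0", "a1", "a2", "a3"),
            trace=DirichletCounts(np.ones((2, 4))),
        )
        aff = affordance_field(niche)
        np.testing.assert_allclose(aff.values, np.log(0.25), atol=1e-12)

    def test_hand_normalization(self):
        niche = NicheModel(
            agent_types=("t0",),
            type_counts=DirichletCounts(np.ones(1)),
            action_likelihood=np.full((4, 1), 0.25),
            locations=("0,0",),
            actions=("a0", "a1", "a2", "a3"),
            trace=DirichletCounts(np.array([[5.0, 1.0, 1.0, 1.0]])),
        )
        aff = affordance_field(niche)
        np.testing.assert_allclose(
            aff.values[0], np.log([0.625, 0.125, 0.125, 0.125]), atol=1e-12
        )
        assert int(np.argmax(aff.values[0])) == 0  # peak = most-deposited action
        assert (aff.values <= 1e-12).all()
        np.testing.assert_allclose(aff.action_surprisal, -aff.values, atol=1e-15)

    def test_normalization_invariant_after_random_deposits(self):
        rng = np.random.default_rng(17)
        niche = cafe_niche()
        for _ in range(100):
            loc = niche.locations[int(rng.integers(2))]
            act = niche.actions[int(rng.integers(2))]
            niche = deposit_trace(niche, loc, act, float(rng.uniform(0.1, 5.0)))
            aff = affordance_field(niche)  # validates rows sum to 1 internally
            assert np.exp(aff.values).sum(axis=1) == pytest.approx(np.ones(2), abs=1e-9)

    def test_field_invariants_enforced(self):
        with pytest.raises(InvalidDistributionError):
            AffordanceField(("0,0",), ("a", "b"), np.array([[0.1, -0.5]]))  # positive log-prob
        with pytest.raises(InvalidDistributionError):
            AffordanceField(("0,0",), ("a", "b"), np.array([[-3.0, -3.0]]))  # not normalized


class TestNicheStep:
    def test_type_recovery_matches_sequential_bayes(self):
        # 500 actions from a pure café-goer: the running type posterior must
        # match the sequential-Bayes oracle and exceed 0.95 on the truth
        niche = cafe_niche()
        rng = np.random.default_rng(42)
        profile = niche.action_likelihood[:, 0]
        log_oracle = np.log(niche.type_prior.probs)
        post = None
        for _ in range(500):
            k = int(rng.choice(2, p=profile))
            log_oracle = log_oracle + np.log(niche.action_likelihood[k])
            niche, post, rep = niche_step(niche, "0,0", niche.actions[k], deposit=0.0)
            assert rep.total >= rep.surprisal - 1e-9
        oracle = np.exp(log_oracle - log_oracle.max())
        oracle /= oracle.sum()
        assert post.probs[0] > 0.95
        # same argmax and close in total variation (the running posterior
        # additionally benefits from the slowly sharpening Dirichlet prior)
        assert total_variation(post.probs, oracle) < 0.05

    def test_zero_deposit_keeps_trace(self):
        niche = cafe_niche()
        out, post, rep = niche_step(niche, "0,0", "toward_cafe", deposit=0.0)
        np.testing.assert_array_equal(out.trace.concentration, niche.trace.concentration)
        assert rep.total > 0

    def test_deposit_recorded(self):
        niche = cafe_niche()
        out, _, _ = niche_step(niche, "1,0", "away", deposit=2.5)
        assert out.trace.concentration[1, 1] == pytest.approx(3.5)

    def test_self_generated_actions_minimize_expected_free_energy(self):
        # actions drawn from the niche's own predictive distribution incur
        # lower average free energy than uniformly random actions
        niche = cafe_niche()
        predictive = niche.action_likelihood @ niche.type_prior.probs
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            f_self = np.mean(
                [
                    niche_free_energy(
                        niche.type_prior_belief(), niche, niche.actions[int(rng.choice(2, p=predictive))]
                    ).total
                    for _ in range(200)
                ]
            )
            f_rand = np.mean(
                [
                    niche_free_energy(
                        niche.type_prior_belief(), niche, niche.actions[int(rng.integers(2))]
                    ).total
                    for _ in range(200)
                ]
            )
            wins += f_self < f_rand
        assert wins >= 15

    def test_dirichlet_increment_reduces_divergence_over_time(self):
        # conjugate counting drives the per-event divergence term down when
        # the action stream is stationary
        niche = cafe_niche()
        rng = np.random.default_rng(5)
        profile = niche.action_likelihood[:, 0]
        early, late = [], []
        for t in range(300):
            k = int(rng.choice(2, p=profile))
            niche, _, rep = niche_step(niche, "0,0", niche.actions[k], deposit=0.0)
            (early if t < 50 else late if t >= 250 else []).append(rep.divergence)
        assert np.mean(late) < np.mean(early)

    def test_consolidation_entropy_non_increasing(self):
        # stationary one-action-per-location stream: expected per-location
        # trace entropy falls monotonically in expectation (20 replicates)
        drops = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            niche = cafe_niche()
            before = trace_entropy(niche, ["0,0"])[0]
            for _ in range(30):
                niche, _, _ = niche_step(niche, "0,0", "toward_cafe", deposit=1.0)
                niche = decay_traces(niche)
            after = trace_entropy(niche, ["0,0"])[0]
            drops += after < before
        assert drops == 20
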