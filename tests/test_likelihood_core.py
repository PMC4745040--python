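import math

import numpy as np
import pytest

from island_assembly import (
    ColonistRecord,
    IslandDataset,
    LikelihoodOptions,
    ParameterSet,
    QStateVector,
    ValidationError,
    dd_rate,
    loglik_colonist,
    loglik_dataset,
)
from island_assembly.likelihood_core import (
    apply_branching,
    apply_colonisation,
    integrate_master,
    state_probabilities,
)

AGE = 4.0
GAMMA_ONLY = ParameterSet(gamma=0.3, lambda_c=0.0, lambda_a=0.0, mu=0.0)
GENERIC = ParameterSet(gamma=0.1, lambda_c=0.5, lambda_a=0.2, mu=0.3, K_prime=5)
GENERIC_INF = ParameterSet(gamma=0.3, lambda_c=0.6, lambda_a=0.4, mu=0.25)


def _rec(status, col=None, bts=(), n_missing=0, max_age=False):
    return ColonistRecord(
        label="r",
        status=status,
        lineage_class="c",
        colonisation_time=col,
        branching_times=bts,
        n_missing=n_missing,
        max_age=max_age,
    )


class TestDDRate:
    def test_no_species_no_feedback(self):
        assert dd_rate(0.7, 0, 5.0) == 0.7

    def test_zero_at_capacity(self):
        assert dd_rate(0.7, 5, 5.0) == 0.0

    def test_clamped_above_capacity(self):
        assert dd_rate(0.7, 9, 5.0) == 0.0

    def test_infinite_capacity_passthrough(self):
        assert dd_rate(0.7, 1000, math.inf) == 0.7

    def test_linear_decline(self):
        assert dd_rate(1.0, 2, 8.0) == pytest.approx(0.75)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            dd_rate(-1.0, 0, 5.0)


class TestParameterSet:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            ParameterSet(gamma=-0.1, lambda_c=0, lambda_a=0, mu=0)

    def test_nonpositive_K_rejected(self):
        with pytest.raises(ValidationError):
            ParameterSet(gamma=0.1, lambda_c=0, lambda_a=0, mu=0, K_prime=0.0)

    def test_round_trip_dict(self):
        p = ParameterSet(gamma=0.1, lambda_c=0.2, lambda_a=0.3, mu=0.4, K_prime=7.0)
        assert ParameterSet.from_dict(p.to_dict()) == p
        p_inf = ParameterSet(gamma=0.1, lambda_c=0.2, lambda_a=0.3, mu=0.4)
        assert ParameterSet.from_dict(p_inf.to_dict()) == p_inf


class TestIntegrateMaster:
    def test_no_events_state_frozen(self):
        p0 = ParameterSet(gamma=0, lambda_c=0, lambda_a=0, mu=0)
        s = QStateVector.initial(10)
        out = integrate_master(s, p0, 0.0, 3.7)
        scale = math.exp(out.log_scale)
        assert out.q_no_mainland[0] * scale == pytest.approx(1.0, abs=1e-12)
        assert np.sum(out.q_with_mainland) * scale == pytest.approx(0.0, abs=1e-12)

    def test_poisson_first_arrival(self):
        s = QStateVector.initial(10)
        out = integrate_master(s, GAMMA_ONLY, 0.0, 2.0)
        scale = math.exp(out.log_scale)
        assert out.q_no_mainland[0] * scale == pytest.approx(math.exp(-0.6), rel=1e-9)
        assert out.q_with_mainland[0] * scale == pytest.approx(
            1.0 - math.exp(-0.6), rel=1e-9
        )

    def test_checkpoint_invariance(self):
        s = QStateVector.initial(30)
        one = integrate_master(s, GENERIC_INF, 0.0, 3.0)
        for t_mid in (0.3, 1.5, 2.9):
            two = integrate_master(
                integrate_master(s, GENERIC_INF, 0.0, t_mid), GENERIC_INF, t_mid, 3.0
            )
            a = one.q_no_mainland * math.exp(one.log_scale)
            b = two.q_no_mainland * math.exp(two.log_scale)
            np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-14)

    def test_backwards_interval_rejected(self):
        s = QStateVector.initial(10)
        with pytest.raises(ValidationError):
            integrate_master(s, GENERIC, 2.0, 1.0)

    def test_expm_matches_ode(self):
        rec = _rec(4, col=3.0, bts=(2.0, 0.7))
        p = ParameterSet(gamma=0.05, lambda_c=0.4, lambda_a=0.3, mu=0.2, K_prime=8)
        ll_expm = loglik_colonist(rec, p, AGE)
        ll_ode = loglik_colonist(rec, p, AGE, LikelihoodOptions(method="ode"))
        assert ll_expm == pytest.approx(ll_ode, abs=5e-8)

    @pytest.mark.parametrize("params", [GENERIC, GENERIC_INF])
    def test_conservation(self, params):
        pa, pm = state_probabilities(params, AGE, 120)
        assert pa.sum() + pm.sum() == pytest.approx(1.0, abs=1e-7)


class TestApplyColonisation:
    def test_direct_substitution_yields_gamma_density(self):
        s = QStateVector.initial(10)
        out = apply_colonisation(s, GAMMA_ONLY)
        assert out.k == 1
        got = out.q_colonist_surviving[0] * math.exp(out.log_scale)
        assert got == pytest.approx(0.3)
        assert np.all(out.q_no_mainland == 0)
        assert np.all(out.q_with_mainland == 0)

    def test_zero_gamma_blocks_colonisation(self):
        p = ParameterSet(gamma=0.0, lambda_c=0.5, lambda_a=0.2, mu=0.3)
        s = QStateVector.initial(10)
        out = apply_colonisation(s, p)
        assert np.all(out.q_colonist_surviving == 0)

    def test_clamped_at_capacity(self):
        p = ParameterSet(gamma=0.4, lambda_c=0.5, lambda_a=0.2, mu=0.3, K_prime=3)
        s = QStateVector.initial(10)
        s.q_no_mainland[:] = 0.0
        s.q_no_mainland[3] = 1.0  # hidden diversity already at K'
        out = apply_colonisation(s, p)
        assert out.q_colonist_surviving[3] == 0.0

    def test_rejected_after_k0(self):
        s = QStateVector.initial(10)
        s1 = apply_colonisation(s, GAMMA_ONLY)
        with pytest.raises(ValidationError):
            apply_colonisation(s1, GAMMA_ONLY)


class TestApplyBranching:
    def test_rejected_at_k0(self):
        s = QStateVector.initial(10)
        with pytest.raises(ValidationError):
            apply_branching(s, GENERIC)

    def test_crown_transfer_literal_equation(self):
        # with the unit-weight (printed-equation) policy the colonist channel
        # passes through unchanged when Q^1 is empty
        opts = LikelihoodOptions(crown_transfer_rate=False)
        s = QStateVector(k=1, t=1.0, n_max=10)
        s.q_colonist_surviving = np.zeros(11)
        s.q_colonist_surviving[0] = 0.37
        out = apply_branching(s, GENERIC_INF, opts)
        assert out.k == 2
        got = out.q_no_mainland[0] * math.exp(out.log_scale)
        assert got == pytest.approx(0.37)

    def test_crown_transfer_rate_weighted(self):
        s = QStateVector(k=1, t=1.0, n_max=10)
        s.q_colonist_surviving = np.zeros(11)
        s.q_colonist_surviving[0] = 0.37
        out = apply_branching(s, GENERIC_INF)
        got = out.q_no_mainland[0] * math.exp(out.log_scale)
        assert got == pytest.approx(0.37 * GENERIC_INF.lambda_c)

    def test_k2_to_k3_rate_factor(self):
        s = QStateVector(k=2, t=1.0, n_max=10)
        s.q_no_mainland[0] = 0.5
        out = apply_branching(s, GENERIC)
        # Q_0^3 = lambda^c_2 * Q_0^2
        expected = 0.5 * dd_rate(GENERIC.lambda_c, 2, GENERIC.K_prime)
        got = out.q_no_mainland[0] * math.exp(out.log_scale)
        assert got == pytest.approx(expected)
        assert out.k == 3


class TestLoglikColonist:
    def test_status1_closed_form(self):
        ll = loglik_colonist(_rec(1), GAMMA_ONLY, AGE)
        assert ll == pytest.approx(-GAMMA_ONLY.gamma * AGE, abs=1e-8)

    def test_status3_closed_form(self):
        a = 1.7
        ll = loglik_colonist(_rec(3, col=a), GAMMA_ONLY, AGE)
        assert ll == pytest.approx(math.log(GAMMA_ONLY.gamma) - GAMMA_ONLY.gamma * a, abs=1e-8)

    def test_status2_closed_form(self):
        bound = 2.5
        ll = loglik_colonist(_rec(2, col=bound, max_age=True), GAMMA_ONLY, AGE)
        expected = math.log(1.0 - math.exp(-GAMMA_ONLY.gamma * bound))
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_status2_bound_at_island_age_is_presence_probability(self):
        ll = loglik_colonist(_rec(2, col=AGE, max_age=True), GAMMA_ONLY, AGE)
        assert ll == pytest.approx(math.log(1.0 - math.exp(-GAMMA_ONLY.gamma * AGE)), abs=1e-8)

    def test_truncation_stability(self):
        rec = _rec(4, col=3.0, bts=(1.5,))
        for params in (GENERIC_INF, GENERIC):
            base = loglik_colonist(rec, params, AGE, LikelihoodOptions(n_max=40))
            double = loglik_colonist(rec, params, AGE, LikelihoodOptions(n_max=80))
            assert abs(base - double) < 1e-6

    def test_continuity_in_K(self):
        rec = _rec(4, col=3.0, bts=(1.5,))
        near_inf = ParameterSet(gamma=0.3, lambda_c=0.6, lambda_a=0.4, mu=0.25, K_prime=1e9)
        ll_near = loglik_colonist(rec, near_inf, AGE)
        ll_inf = loglik_colonist(rec, GENERIC_INF, AGE)
        assert ll_near == pytest.approx(ll_inf, abs=1e-6)

    def test_colonisation_beyond_age_rejected(self):
        with pytest.raises(ValidationError):
            loglik_colonist(_rec(3, col=5.0), GAMMA_ONLY, AGE)

    def test_impossible_observation_is_minus_inf(self):
        # an endemic clade cannot arise without cladogenesis or anagenesis
        p = ParameterSet(gamma=0.3, lambda_c=0.0, lambda_a=0.0, mu=0.0)
        ll = loglik_colonist(_rec(4, col=3.0), p, AGE)
        assert ll == -math.inf


class TestLoglikDataset:
    def test_empty_dataset_zero_gamma(self):
        ds = IslandDataset(island_age=AGE, M=10, class_fractions={"c": 1.0})
        p = ParameterSet(gamma=0.0, lambda_c=0.1, lambda_a=0.1, mu=0.1)
        assert loglik_dataset(ds, {"c": p}) == pytest.approx(0.0, abs=1e-12)

    def test_additivity_over_colonists(self):
        r1 = ColonistRecord(label="a", status=3, lineage_class="c", colonisation_time=1.0)
        r2 = ColonistRecord(
            label="b", status=4, lineage_class="c", colonisation_time=2.5,
            branching_times=(1.2,),
        )
        M = 12
        mk = lambda recs: IslandDataset(
            island_age=AGE, M=M, class_fractions={"c": 1.0}, colonists=recs
        )
        params = {"c": GENERIC_INF}
        ll_both = loglik_dataset(mk((r1, r2)), params)
        ll_1 = loglik_dataset(mk((r1,)), params)
        ll_2 = loglik_dataset(mk((r2,)), params)
        empty = loglik_colonist(
            ColonistRecord(label="e", status=1, lineage_class="c"), GENERIC_INF, AGE
        )
        # each single-colonist dataset carries (M-1) empty terms, the joint
        # one carries (M-2): remove the double-counted empty pool
        assert ll_both == pytest.approx(ll_1 + ll_2 - M * empty, abs=1e-7)

    def test_explicit_status1_equals_pool_accounting(self):
        r1 = ColonistRecord(label="gone", status=1, lineage_class="c")
        with_rec = IslandDataset(
            island_age=AGE, M=10, class_fractions={"c": 1.0}, colonists=(r1,)
        )
        without = IslandDataset(island_age=AGE, M=10, class_fractions={"c": 1.0})
        params = {"c": GENERIC}
        assert loglik_dataset(with_rec, params) == pytest.approx(
            loglik_dataset(without, params), abs=1e-10
        )

    def test_missing_class_parameters_rejected(self):
        ds = IslandDataset(island_age=AGE, M=10, class_fractions={"c": 1.0})
        with pytest.raises(ValidationError):
            loglik_dataset(ds, {"other": GENERIC})

    def test_conditioning_reduces_loglik_of_observed_data(self):
        rec = ColonistRecord(label="a", status=3, lineage_class="c", colonisation_time=1.0)
        ds = IslandDataset(
            island_age=AGE, M=10, class_fractions={"c": 1.0}, colonists=(rec,)
        )
        plain = loglik_dataset(ds, {"c": GENERIC_INF})
        conditioned = loglik_dataset(
            ds, {"c": GENERIC_INF}, LikelihoodOptions(condition_on_colonisation=True)
        )
        assert conditioned > plain  # dividing by P(non-empty) < 1
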