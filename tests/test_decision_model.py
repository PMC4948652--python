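"""The net-benefit model: closed form, outcome accounting, decision summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evppi import (DecisionContext, EconomicConstants, ceac, evpi_curve,
                   incremental_net_benefit, net_benefit_matrix,
                   outcome_accounting_net_benefit, prob_death, prob_ns_saved,
                   switching_threshold)
from evppi.decision_model import (InvalidParameterError, NO_SWITCH,
                                  outcome_probabilities)


def make_draw(**over):
    base = dict(alpha=-1.07, d2M=-0.31, d3M=-2.34, d4M=-0.19, pB=0.10,
                dS=1.88, pL=0.50, qM=19.99, qS=5.38)
    base.update(over)
    return base


class TestProbDeath:
    def test_logit_symmetry(self):
        assert prob_death(0.0, 0.0) == 0.5

    def test_quarter_odds(self):
        # logit(0.25) = -ln 3 : the stated implied median death probability
        assert prob_death(-math.log(3.0)) == pytest.approx(0.25, abs=1e-12)

    def test_matches_direct_expit_evaluation(self):
        # independent arithmetic route: 1 / (1 + e^{1.38})
        assert prob_death(-1.07, -0.31) == pytest.approx(
            1.0 / (1.0 + math.exp(1.38)), abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidParameterError):
            prob_death(np.nan)
        with pytest.raises(InvalidParameterError):
            prob_death(0.0, np.inf)


class TestProbNsSaved:
    def test_half_no_shift(self):
        assert prob_ns_saved(0.5, 0.0) == pytest.approx(1.0 / 3.0, abs=1e-12)

    @given(pB=st.floats(1e-6, 1 - 1e-6))
    @settings(max_examples=50, deadline=None)
    def test_zero_shift_is_odds_of_pb(self, pB):
        assert prob_ns_saved(pB, 0.0) == pytest.approx(pB / (1 + pB),
                                                       rel=1e-12)

    def test_matches_printed_formula(self):
        val = 0.1 * math.exp(1.88) / (1.0 + 0.1 * math.exp(1.88))
        assert prob_ns_saved(0.1, 1.88) == pytest.approx(val, abs=1e-12)

    def test_boundaries(self):
        # the shift composes with ln(pB): pB=0 gives 0, pB=1 gives expit(dS)
        assert prob_ns_saved(0.0, 1.0) == 0.0
        assert prob_ns_saved(1.0, 1.0) == pytest.approx(
            math.exp(1.0) / (1 + math.exp(1.0)), abs=1e-12)
        with pytest.raises(InvalidParameterError):
            prob_ns_saved(-0.1, 0.0)


class TestNetBenefit:
    def test_reference_arm_is_exactly_zero(self, samples_small, econ, ctx):
        nb = net_benefit_matrix(samples_small, econ, ctx)
        assert np.all(nb[:, 0] == 0.0)

    def test_zero_effect_arm_pays_fluid_cost(self, econ, ctx):
        draw = make_draw(d2M=0.0)
        # saline uses d2M; with no mortality effect its net benefit is -cost
        assert incremental_net_benefit(draw, "saline", econ, ctx) == \
            pytest.approx(-econ.fluid_cost["saline"], abs=1e-12)

    def test_unknown_treatment(self, econ, ctx):
        with pytest.raises(KeyError):
            incremental_net_benefit(make_draw(), "dopamine", econ, ctx)

    def test_closed_form_equals_outcome_accounting(self, samples_small, econ,
                                                   ctx):
        draws = samples_small.draws.iloc[:10_000]
        nb = net_benefit_matrix(draws, econ, ctx)
        for j, name in enumerate(ctx.names):
            acc = outcome_accounting_net_benefit(draws, name, econ, ctx)
            assert np.max(np.abs(acc - nb[:, j])) <= 1e-9

    @given(alpha=st.floats(-3, 3), d=st.floats(-3, 3),
           pB=st.floats(0.01, 0.99), dS=st.floats(-3, 3),
           pL=st.floats(0.0, 1.0), qM=st.floats(0, 40), qS=st.floats(0, 15))
    @settings(max_examples=100, deadline=None)
    def test_identity_holds_for_arbitrary_draws(self, alpha, d, pB, dS, pL,
                                                qM, qS):
        econ, ctx = EconomicConstants(), DecisionContext(wtp=250.0)
        draw = make_draw(alpha=alpha, d3M=d, pB=pB, dS=dS, pL=pL, qM=qM, qS=qS)
        a = incremental_net_benefit(draw, "albumin", econ, ctx)
        b = outcome_accounting_net_benefit(draw, "albumin", econ, ctx)
        assert a == pytest.approx(b, abs=1e-9)

    def test_outcome_probabilities_valid(self, samples_small, ctx):
        draws = samples_small.draws.iloc[:5000]
        for t in ctx.treatments:
            probs = outcome_probabilities(draws, t.name, ctx)
            assert probs.shape == (5000, 4)
            assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
            # the with-fluid outcome split is a probability distribution on
            # the draws where the fluid reduces mortality; on harm draws
            # (allowed by the model) the "saved" mass is negative and the
            # split is an accounting identity only
            if t.dm is None:
                beneficial = np.ones(len(draws), dtype=bool)
            else:
                beneficial = (draws[t.dm] <= 0).to_numpy()
            assert np.all(probs[beneficial] >= -1e-12)
            assert np.all(probs[beneficial] <= 1 + 1e-12)

    def test_mean_net_benefit_affine_in_wtp(self, samples_small, econ):
        # three-point collinearity of the mean net benefit in W
        ws = (0.0, 1500.0, 3000.0)
        means = [net_benefit_matrix(samples_small, econ,
                                    DecisionContext(wtp=w)).mean(axis=0)
                 for w in ws]
        midpoint = (means[0] + means[2]) / 2.0
        assert np.allclose(means[1], midpoint, atol=1e-7)


class TestDecisionSummaries:
    def test_ceac_sums_to_one(self, samples_small, econ, ctx):
        probs = ceac(samples_small, econ, ctx)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (probs >= 0).all()

    def test_ceac_degenerate_sample_is_indicator(self, econ, ctx):
        frame = pd.DataFrame([make_draw()] * 5)
        probs = ceac(frame, econ, ctx)
        assert sorted(probs.values) == [0, 0, 0, 1]

    def test_ceac_empty_sample(self, econ, ctx):
        with pytest.raises(ValueError):
            ceac(pd.DataFrame(columns=list(make_draw())), econ, ctx)

    def test_switching_threshold_linear_crossing(self, econ):
        # one deterministic draw: each arm's mean net benefit is an exact
        # line a_j + b_j W, so the top-two crossing is computable in closed
        # form and the bisection must land on it within $1
        draw = make_draw(d2M=-0.1, d3M=-2.0, d4M=-0.5, dS=1.0, pB=0.1,
                         pL=0.5, qM=20.0, qS=5.0)
        frame = pd.DataFrame([draw])

        def line(dm_key, cost):
            p0 = 1 / (1 + math.exp(-draw["alpha"]))
            pj = 1 / (1 + math.exp(-(draw["alpha"] + draw[dm_key])))
            dp = p0 - pj
            h2 = draw["pB"] * math.exp(draw["dS"])
            h2 = h2 / (1 + h2)
            slope = dp * (draw["qM"] - draw["pL"] * h2 * draw["qS"])
            intercept = dp * (-econ.hospital_cost
                              - draw["pL"] * h2 * econ.ns_lifetime_cost) - cost
            return intercept, slope

        lines = {name: line(dm, econ.fluid_cost[name])
                 for name, dm in (("albumin", "d3M"), ("saline", "d2M"),
                                  ("gelofusine", "d4M"))}
        lines["no_fluid"] = (0.0, 0.0)
        grid = np.arange(0.0, 2000.0, 10.0)
        best = [max(lines, key=lambda k: lines[k][0] + lines[k][1] * w)
                for w in grid]
        change = next(i for i in range(1, len(best)) if best[i] != best[i - 1])
        a0, b0 = lines[best[change - 1]]
        a1, b1 = lines[best[change]]
        expected = (a0 - a1) / (b1 - b0)

        found = switching_threshold(frame, econ, grid)
        assert found == pytest.approx(expected, abs=1.0)

    def test_no_switch_sentinel(self, econ):
        frame = pd.DataFrame([make_draw()])
        # far above any crossing the optimum is constant
        assert switching_threshold(frame, econ,
                                   np.array([3000.0, 3500.0, 4000.0])) is NO_SWITCH

    def test_switching_threshold_bad_grid(self, samples_small, econ):
        with pytest.raises(ValueError):
            switching_threshold(samples_small, econ, np.array([100.0]))

    def test_evpi_curve_zero_without_costs_at_zero_wtp(self, samples_small):
        free = EconomicConstants(fluid_cost={t: 0.0 for t in
                                             ("no_fluid", "albumin", "saline",
                                              "gelofusine")},
                                 hospital_cost=0.0, ns_lifetime_cost=0.0)
        curve = evpi_curve(samples_small, free, [0.0])
        assert curve["value"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_evpi_curve_nonnegative(self, samples_small, econ):
        curve = evpi_curve(samples_small, econ, [0.0, 250.0, 1000.0])
        assert (curve["value"] >= 0).all()

    def test_evpi_curve_peaks_near_switching_threshold(self, samples_medium,
                                                       econ):
        # decision uncertainty (hence EVPI) is greatest where the optimal
        # treatment changes
        grid = np.arange(50.0, 1001.0, 50.0)
        curve = evpi_curve(samples_medium, econ, grid)
        peak_w = curve.loc[curve["value"].idxmax(), "W"]
        threshold = switching_threshold(samples_medium, econ,
                                        np.arange(0.0, 4001.0, 50.0))
        assert threshold is not None
        assert abs(peak_w - threshold) <= 50.0  # within one grid step
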