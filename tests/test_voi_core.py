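"""EVPI, single-step EVPPI machinery, plug-in strategies, nested baseline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evppi import (ConditionalNB, evpi,
                   evppi_nested, evppi_single_step, net_benefit_matrix,
                   plugin_mean_conditional_nb, reparam_conditional_nb,
                   select_method)
from evppi.oracles import toy_suite
from evppi.voi import AdmissibilityError, admissibility_registry, normalize_focal


def two_arm_nb(column):
    def nb(frame):
        x = frame[column].to_numpy(dtype=float)
        return np.column_stack([np.zeros_like(x), x])
    return nb


class TestEvpi:
    def test_two_point_difference(self):
        # B2 - B1 = +1 or -1 with equal probability: E[B2]=0, the tie breaks
        # to the reference, and the expected regret is exactly 1/2
        frame = pd.DataFrame({"x": np.tile([1.0, -1.0], 500)})
        est = evpi(frame, None, None, nb=two_arm_nb("x"))
        assert est.value == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_sample_is_zero(self, econ, ctx, samples_small):
        frame = pd.DataFrame([samples_small.draws.iloc[0]] * 10)
        assert evpi(frame, econ, ctx).value == 0.0

    def test_empty_sample_rejected(self, econ, ctx, samples_small):
        with pytest.raises(ValueError):
            evpi(samples_small.draws.iloc[:1], econ, ctx)

    def test_nonnegative_with_se(self, samples_small, econ, ctx):
        est = evpi(samples_small, econ, ctx)
        assert est.value >= 0 and est.mc_se > 0


class TestSingleStep:
    def test_constant_conditional_nb_gives_zero(self, samples_small, econ,
                                                ctx):
        cond = ConditionalNB("const", lambda f: np.tile(
            np.array([0.0, 5.0, 3.0, 1.0]), (len(f), 1)))
        est = evppi_single_step(samples_small, ("qM",), cond, econ, ctx)
        assert est.value == 0.0

    def test_exact_conditional_nb_recovers_evpi(self, samples_small, econ,
                                                ctx):
        # focal = all parameters with the exact net benefit as cond_nb
        cond = ConditionalNB("exact",
                             lambda f: net_benefit_matrix(f, econ, ctx))
        full = ("alpha", "dM", "pB", "dS", "pL", "qM", "qS")
        est = evppi_single_step(samples_small, full, cond, econ, ctx)
        ref = evpi(samples_small, econ, ctx)
        assert est.value == ref.value

    def test_evppi_bounded_by_evpi(self, samples_small, econ, ctx):
        ref = evpi(samples_small, econ, ctx)
        for focal, builder in ((("qM",), reparam_conditional_nb),
                               (("qM", "qS", "pL"), reparam_conditional_nb),
                               (("dM", "alpha", "pB", "dS", "pL"),
                                plugin_mean_conditional_nb)):
            cond = builder(samples_small, focal, econ, ctx)
            est = evppi_single_step(samples_small, focal, cond, econ, ctx)
            assert est.value >= -3 * est.mc_se
            assert est.value <= ref.value + 3 * (est.mc_se + ref.mc_se)


class TestPluginAdmissibility:
    def test_linear_complement_is_m1(self, samples_small, econ, ctx):
        cond = plugin_mean_conditional_nb(
            samples_small, ("dM", "alpha", "pB", "dS", "pL"), econ, ctx)
        assert cond.label == "m1"

    def test_multilinear_complement_is_m2(self, samples_small, econ, ctx):
        cond = plugin_mean_conditional_nb(
            samples_small, ("dM", "alpha", "pB", "dS", "qM"), econ, ctx)
        assert cond.label == "m2"

    def test_nonlinear_complement_rejected(self, samples_small, econ, ctx):
        with pytest.raises(AdmissibilityError, match="alpha"):
            plugin_mean_conditional_nb(samples_small, ("dM", "dS"), econ, ctx)

    def test_registry_mappings(self):
        reg = admissibility_registry()
        assert reg[frozenset({"pL"})] == "m3"
        assert reg[frozenset({"alpha", "pB"})] == "m4-taylor"
        assert reg[frozenset({"dS"})] == "m5-spline"
        assert select_method(("qM", "pB")) == "nested"
        assert select_method(("dM", "dS")) == "m4-taylor"
        assert select_method(("alpha", "dM", "pB", "dS", "pL", "qM",
                              "qS")) == "evpi"

    def test_dM_shorthand(self):
        assert normalize_focal(("dM",)) == frozenset({"d2M", "d3M", "d4M"})


class TestReparam:
    def test_focal_outside_admissible_set(self, samples_small, econ, ctx):
        with pytest.raises(AdmissibilityError):
            reparam_conditional_nb(samples_small, ("alpha",), econ, ctx)

    def test_degenerate_betas_match_direct_plugin(self, econ, ctx,
                                                  samples_small):
        # zero-variance nonfocal block: E[beta] equals the pointwise beta and
        # the reparameterized conditional equals the exact net benefit
        draws = samples_small.draws.iloc[:2000].copy()
        for c in ("alpha", "d2M", "d3M", "d4M", "pB", "dS"):
            draws[c] = draws[c].iloc[0]
        cond = reparam_conditional_nb(draws, ("qM", "qS", "pL"), econ, ctx)
        assert np.allclose(cond(draws), net_benefit_matrix(draws, econ, ctx),
                           atol=1e-9)

    def test_linear_toy_plugin_matches_closed_form(self, rng):
        # method-1 logic on the linear toy model, checked against the exact
        # normal-tail formula  E[max(80 - 100 x1, 0)]
        toy = toy_suite()[0]
        frame = toy.sample(200_000, rng=rng)
        x2_mean = frame["x2"].mean()

        def cond_fn(f):
            x1 = f["x1"].to_numpy(dtype=float)
            return np.column_stack([np.zeros_like(x1),
                                    100.0 * x1 + 50.0 * x2_mean - 120.0])

        est = evppi_single_step(frame, ("x1",), ConditionalNB("m1", cond_fn),
                                None, None, nb=toy.nb_frame)
        mu, sd = -20.0, 50.0  # distribution of 80 - 100 x1, x1 ~ N(1, 0.25)
        exact = sd * stats.norm.pdf(mu / sd) + mu * stats.norm.cdf(mu / sd)
        assert est.value == pytest.approx(exact, abs=4 * est.mc_se)


class TestNested:
    def test_deterministic_complement_equals_plugin(self, econ, ctx,
                                                    samples_small):
        draws = samples_small.draws.iloc[:500].copy()
        for c in draws.columns:
            if c != "qM":
                draws[c] = draws[c].iloc[0]
        nested = evppi_nested(draws, ("qM",), econ, ctx, n_outer=500,
                              n_inner=7, seed=3)
        cond = reparam_conditional_nb(draws, ("qM",), econ, ctx)
        single = evppi_single_step(draws, ("qM",), cond, econ, ctx)
        assert nested.value == pytest.approx(single.value, abs=1e-9)

    def test_marginal_resampling_warns_on_correlated_focal(self, spec, econ,
                                                           ctx,
                                                           samples_small):
        with pytest.warns(UserWarning, match="downward"):
            evppi_nested(samples_small, ("dS",), econ, ctx, n_outer=200,
                         n_inner=50, spec=spec, seed=4)

    def test_small_inner_upward_bias_shrinks(self, rng):
        # on the independent expit toy the nested estimate decreases toward
        # the single-step value as the inner sample grows
        toy = toy_suite()[2]
        frame = toy.sample(60_000, rng=rng)
        estimates = {}
        for n_inner in (2, 20, 2000):
            est = evppi_nested(frame, ("x1",), None, None, n_outer=4000,
                               n_inner=n_inner, seed=5, nb=toy.nb_frame)
            estimates[n_inner] = est
        # gross bias at 2 inner draws is unambiguous even unpaired
        assert estimates[2].value > estimates[2000].value + \
            3 * (estimates[2].mc_se + estimates[2000].mc_se) / 2
        # and the estimate decreases monotonically toward the converged value
        # (outer draws are shared, so the ordering is a paired comparison)
        assert estimates[2].value > estimates[20].value > estimates[2000].value

    def test_n_outer_bounded(self, samples_small, econ, ctx):
        with pytest.raises(ValueError):
            evppi_nested(samples_small.draws.iloc[:100], ("qM",), econ, ctx,
                         n_outer=200, n_inner=10)
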