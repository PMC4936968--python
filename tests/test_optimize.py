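"""Box-constrained optima, generalized distance, Khuri-Conlon intervals."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from fermopt import (
    CodedModel,
    CodingScheme,
    DEFAULT_CODING,
    IndividualOptimum,
    Region,
    distance,
    fit_interaction_model,
    khuri_conlon_interval,
    maximize_individual,
    minimize_distance,
)
from fermopt.datasets import PUBLISHED_INDIVIDUAL_OPTIMA, SIMULTANEOUS_OPTIMUM_SETTINGS

UNIT_CODING = CodingScheme({"a": 1.0, "b": 1.0, "c": 1.0}, {"r": 1.0, "s": 1.0})


def _model(beta, response="r", squared=False, factors=("a", "b", "c")):
    return CodedModel(response, factors, np.asarray(beta, float), squared, UNIT_CODING)


class TestMaximizeIndividual:
    def test_all_negative_linear_optimum_at_lower_corner(self):
        region = Region({"a": (0.0, 2.0), "b": (0.0, 3.0), "c": (0.0, 4.0)})
        m = _model([1.0, -1.0, -2.0, -0.5, 0.0, 0.0, 0.0])
        opt = maximize_individual(m, region)
        assert opt.location == pytest.approx({"a": 0.0, "b": 0.0, "c": 0.0})
        assert opt.value == pytest.approx(1.0)

    def test_published_productivity_surface_maximum_is_on_boundary(
        self, pub_models, full_region
    ):
        # the fitted surfaces are saddles, so the box maximum sits on the
        # boundary and far exceeds the best measured run (0.95 g/L/h)
        opt = maximize_individual(pub_models["productivity"], full_region)
        assert opt.value > 0.93
        on_boundary = [
            abs(opt.location[n] - lo) < 1e-6 or abs(opt.location[n] - hi) < 1e-6
            for n, (lo, hi) in full_region.bounds.items()
        ]
        assert any(on_boundary)

    def test_concave_quadratic_matches_closed_form_stationary_point(self):
        # y = 5 - (a-1)^2 - 2(b-0.5)^2 (interior maximizer (1, 0.5), value 5)
        beta = [5 - 1 - 2 * 0.25, 2.0, 2.0, 0.0, 0.0, 0.0, 0.0, -1.0, -2.0, 0.0]
        m = _model(beta, squared=True)
        region = Region({"a": (0.0, 2.0), "b": (0.0, 2.0), "c": (0.0, 1.0)})
        opt = maximize_individual(m, region)
        assert opt.location["a"] == pytest.approx(1.0, abs=1e-5)
        assert opt.location["b"] == pytest.approx(0.5, abs=1e-5)
        assert opt.value == pytest.approx(5.0, abs=1e-8)

    def test_grid_oracle_optimality(self, table2, full_region):
        # the polished optimum beats a dense random sample of the region
        design, records = table2
        rng = np.random.default_rng(12345)
        names = full_region.names
        lows = np.array([full_region.bounds[n][0] for n in names])
        highs = np.array([full_region.bounds[n][1] for n in names])
        sample = lows + (highs - lows) * rng.random((10_000, 3))
        for response in ("productivity", "concentration", "yield"):
            m = fit_interaction_model(design, records, response)
            opt = maximize_individual(m, full_region)
            opt_coded = m.predict_coded(opt.location)
            sampled = max(
                m.predict_coded(dict(zip(names, row))) for row in sample
            )
            assert opt_coded >= sampled - 1e-9

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            Region({})


class TestDistance:
    def test_zero_at_ideal_point(self):
        y = {"productivity": 0.5, "concentration": 50.0, "yield": 0.4}
        assert distance(y, dict(y), DEFAULT_CODING) == 0.0

    def test_hand_value_from_study_tables(self):
        # sqrt(0.24^2 + 0.002^2 + 0.05^2) with concentration coded /100
        y = {"productivity": 0.81, "concentration": 55.2, "yield": 0.49}
        phi = {"productivity": 0.57, "concentration": 55.0, "yield": 0.54}
        assert distance(y, phi, DEFAULT_CODING) == pytest.approx(0.2452, abs=5e-5)

    def test_single_response(self):
        assert distance({"r": 5.0}, {"r": 2.0}, UNIT_CODING) == pytest.approx(3.0)

    def test_mismatched_names_raise(self):
        with pytest.raises(ValueError, match="same response names"):
            distance({"r": 1.0}, {"s": 1.0}, UNIT_CODING)

    @given(
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=3, max_size=3),
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=3, max_size=3),
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=3, max_size=3),
    )
    def test_metric_axioms(self, xs, ys, zs):
        names = ["productivity", "concentration", "yield"]
        X, Y, Z = (dict(zip(names, v)) for v in (xs, ys, zs))
        dxy = distance(X, Y, DEFAULT_CODING)
        assert dxy >= 0
        assert distance(X, X, DEFAULT_CODING) == 0.0
        assert dxy == pytest.approx(distance(Y, X, DEFAULT_CODING))
        assert distance(X, Z, DEFAULT_CODING) <= dxy + distance(Y, Z, DEFAULT_CODING) + 1e-9


class TestMinimizeDistance:
    def test_single_response_recovers_individual_optimum(self, pub_models, full_region):
        m = pub_models["productivity"]
        opt = maximize_individual(m, full_region)
        sim = minimize_distance({"productivity": m}, {"productivity": opt}, full_region)
        assert sim.distance == pytest.approx(0.0, abs=1e-6)
        assert sim.location == pytest.approx(opt.location, abs=1e-3)

    def test_two_identical_models_behave_as_one(self, full_region):
        beta = [1.0, -0.1, 0.05, -0.2, 0.0, 0.0, 0.0]
        coding = CodingScheme(
            {"pH": 1.0, "agitation": 100.0, "aeration": 1.0}, {"r": 1.0, "s": 1.0}
        )
        m1 = CodedModel("r", ("pH", "agitation", "aeration"), np.array(beta), False, coding)
        m2 = CodedModel("s", ("pH", "agitation", "aeration"), np.array(beta), False, coding)
        o1 = maximize_individual(m1, full_region)
        o2 = maximize_individual(m2, full_region)
        single = minimize_distance({"r": m1}, {"r": o1}, full_region)
        double = minimize_distance({"r": m1, "s": m2}, {"r": o1, "s": o2}, full_region)
        assert double.distance == pytest.approx(0.0, abs=1e-6)
        assert double.location == pytest.approx(single.location, abs=1e-3)

    def test_attainable_targets_recover_common_point(self):
        # Phi chosen as the joint prediction at an off-grid x*: with three
        # responses in three factors the zero of the distance function is
        # isolated, so the minimizer must land on x* itself
        coding = CodingScheme(
            {"a": 1.0, "b": 1.0, "c": 1.0}, {"r": 1.0, "s": 1.0, "t": 1.0}
        )
        region = Region({"a": (0.0, 2.0), "b": (0.0, 2.0), "c": (0.0, 2.0)})
        factors = ("a", "b", "c")
        m_r = CodedModel("r", factors, np.array([0.5, 0.3, -0.2, 0.1, 0.05, -0.04, 0.02]), False, coding)
        m_s = CodedModel("s", factors, np.array([1.0, -0.1, 0.2, -0.3, 0.02, 0.03, -0.01]), False, coding)
        m_t = CodedModel("t", factors, np.array([0.2, 0.15, 0.1, 0.25, -0.03, 0.01, 0.04]), False, coding)
        models = {"r": m_r, "s": m_s, "t": m_t}
        xstar = {"a": 0.731, "b": 1.117, "c": 0.493}
        phi = {n: m.predict_coded(xstar) for n, m in models.items()}
        sim = minimize_distance(models, phi, region)
        assert sim.distance < 1e-6
        assert sim.location == pytest.approx(xstar, abs=1e-3)

    def test_predictions_at_study_operating_point(self, pub_models, full_region):
        # the published operating point's predicted productivity from the
        # published equations
        from fermopt import predict

        value = predict(pub_models["productivity"], SIMULTANEOUS_OPTIMUM_SETTINGS)
        assert round(value, 2) == 0.81
        sim = minimize_distance(pub_models, PUBLISHED_INDIVIDUAL_OPTIMA, full_region)
        # recomputed distance matches its own definition
        assert sim.distance == pytest.approx(
            distance(sim.predicted, PUBLISHED_INDIVIDUAL_OPTIMA, DEFAULT_CODING),
            abs=1e-10,
        )
        # and the found minimum is at least as good as the study's point
        rho_ref = distance(
            {
                n: float(DEFAULT_CODING.decode(n, pub_models[n].predict_coded(SIMULTANEOUS_OPTIMUM_SETTINGS)))
                for n in pub_models
            },
            PUBLISHED_INDIVIDUAL_OPTIMA,
            DEFAULT_CODING,
        )
        assert sim.distance <= rho_ref

    def test_mismatched_response_sets_raise(self, pub_models, full_region):
        with pytest.raises(ValueError, match="same response names"):
            minimize_distance(pub_models, {"productivity": 0.5}, full_region)


class TestKhuriConlon:
    def _toy_model(self, residual_scale=1.0):
        # 4-run straight-line fit with x = (0,1,2,3); MS forced to 1 by
        # injecting residuals (+-1, +-1) with two error degrees of freedom
        coding = CodingScheme({"a": 1.0}, {"r": 1.0})
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        resid = residual_scale * np.array([1.0, -1.0, -1.0, 1.0])
        return CodedModel(
            "r", ("a",), np.array([0.0, 1.0]), False, coding,
            observed=X @ [0.0, 1.0] + resid,
            fitted_values=X @ [0.0, 1.0],
            residuals=resid,
            design_matrix=X,
        )

    def test_half_width_matches_hand_linear_algebra(self):
        # z=(1,1.5), (X'X)^-1 = [[0.7,-0.3],[-0.3,0.2]] -> z'(X'X)^-1 z = 0.25
        # MS = 4/2 = 2; half-width = 0.5*sqrt(2)*t_{0.05,2}
        m = self._toy_model()
        opt = IndividualOptimum("r", {"a": 1.5}, 1.5)
        ci = khuri_conlon_interval(m, opt, alpha=0.10)
        expected = 0.5 * np.sqrt(2.0) * stats.t.ppf(0.95, 2)
        assert ci.gamma2 - opt.value == pytest.approx(expected, abs=1e-12)
        assert opt.value - ci.gamma1 == pytest.approx(expected, abs=1e-12)

    def test_zero_error_mean_square_collapses_interval(self, table2):
        from fermopt import default_surface, generate_design_responses

        design, _ = table2
        records = generate_design_responses(default_surface(0.0), design, seed=0)
        m = fit_interaction_model(design, records, "productivity")
        opt = maximize_individual(m, design.space.region())
        ci = khuri_conlon_interval(m, opt)
        assert ci.gamma1 == pytest.approx(opt.value, abs=1e-6)
        assert ci.gamma2 == pytest.approx(opt.value, abs=1e-6)

    def test_interval_symmetric_about_optimum(self, table2, full_region):
        design, records = table2
        m = fit_interaction_model(design, records, "concentration")
        opt = maximize_individual(m, full_region)
        ci = khuri_conlon_interval(m, opt, alpha=0.10)
        assert ci.gamma2 - opt.value == pytest.approx(opt.value - ci.gamma1)

    def test_width_monotone_in_error_mean_square(self):
        opt = IndividualOptimum("r", {"a": 1.5}, 1.5)
        widths = []
        for scale in (0.5, 1.0, 2.0):
            ci = khuri_conlon_interval(self._toy_model(scale), opt)
            widths.append(ci.gamma2 - ci.gamma1)
        assert widths[0] < widths[1] < widths[2]
        # half-width scales exactly as sqrt(MS), i.e. linearly in the scale
        assert widths[2] / widths[1] == pytest.approx(2.0, abs=1e-10)

    def test_width_monotone_in_leverage(self):
        # g grows as the optimum moves away from the design's x support
        m = self._toy_model()
        widths = [
            khuri_conlon_interval(m, IndividualOptimum("r", {"a": x}, x)).gamma2
            - khuri_conlon_interval(m, IndividualOptimum("r", {"a": x}, x)).gamma1
            for x in (1.5, 3.0, 5.0)
        ]
        assert widths[0] < widths[1] < widths[2]

    def test_saturated_model_rejected(self):
        coding = CodingScheme({"a": 1.0}, {"r": 1.0})
        X = np.column_stack([np.ones(2), np.arange(2.0)])
        m = CodedModel(
            "r", ("a",), np.array([0.0, 1.0]), False, coding,
            observed=np.array([0.0, 1.0]), fitted_values=np.array([0.0, 1.0]),
            residuals=np.zeros(2), design_matrix=X,
        )
        with pytest.raises(ValueError, match="degrees of freedom"):
            khuri_conlon_interval(m, IndividualOptimum("r", {"a": 0.5}, 0.5))
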