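import math

import numpy as np
import pytest

from abskit.binodal import evaluate_binodal
from abskit.tielines import (
    TieLine,
    TieLineError,
    TieLineProblem,
    lever_rule_alpha,
    solve_tieline,
    tieline_metrics,
)


def forward_problem(model, x_il, x_non, alpha):
    """Lever-rule combination of two known binodal points -> mixture."""
    y_il = evaluate_binodal(model, x_il)
    y_non = evaluate_binodal(model, x_non)
    xm = alpha * x_il + (1 - alpha) * x_non
    ym = alpha * y_il + (1 - alpha) * y_non
    return TieLineProblem(model=model, x_m=xm, y_m=ym, alpha=alpha), (x_il, y_il), (x_non, y_non)


class TestSolve:
    def test_forward_construction_recovered(self, merchuck_model):
        problem, il, non = forward_problem(merchuck_model, 1.0, 20.0, alpha=0.6)
        tl = solve_tieline(problem)
        assert tl.il_rich[0] == pytest.approx(il[0], abs=1e-8)
        assert tl.il_rich[1] == pytest.approx(il[1], abs=1e-8)
        assert tl.non_il_rich[0] == pytest.approx(non[0], abs=1e-8)
        assert tl.residual < 1e-8

    def test_random_forward_constructions(self, merchuck_model, rng):
        # oracle equivalence + mass conservation over 100 random cases
        for _ in range(100):
            x_il = rng.uniform(0.05, 3.0)
            x_non = rng.uniform(x_il + 2.0, 24.0)
            alpha = rng.uniform(0.1, 0.9)
            problem, il, non = forward_problem(merchuck_model, x_il, x_non, alpha)
            tl = solve_tieline(problem)
            assert tl.il_rich[0] == pytest.approx(il[0], abs=1e-8)
            assert tl.non_il_rich[0] == pytest.approx(non[0], abs=1e-8)
            # lever-rule mass balance reproduces the mixture on both axes
            xm = alpha * tl.il_rich[0] + (1 - alpha) * tl.non_il_rich[0]
            ym = alpha * tl.il_rich[1] + (1 - alpha) * tl.non_il_rich[1]
            assert xm == pytest.approx(problem.x_m, abs=1e-10)
            assert ym == pytest.approx(problem.y_m, abs=1e-10)

    def test_monophasic_mixture_rejected(self, merchuck_model):
        with pytest.raises(TieLineError, match="biphasic"):
            TieLineProblem(model=merchuck_model, x_m=10.0, y_m=1.0, alpha=0.5)

    def test_mixture_on_binodal_rejected(self, merchuck_model):
        y = evaluate_binodal(merchuck_model, 10.0)
        with pytest.raises(TieLineError):
            TieLineProblem(model=merchuck_model, x_m=10.0, y_m=y, alpha=0.999)

    def test_alpha_outside_unit_interval_rejected(self, merchuck_model):
        with pytest.raises(ValueError, match="alpha"):
            TieLineProblem(model=merchuck_model, x_m=10.0, y_m=60.0, alpha=1.0)

    def test_il_rich_endpoint_has_larger_il_content(self, merchuck_model):
        problem, _, _ = forward_problem(merchuck_model, 0.5, 15.0, alpha=0.4)
        tl = solve_tieline(problem)
        assert tl.il_rich[1] > tl.non_il_rich[1]

    def test_nested_tielines_do_not_cross(self, merchuck_model):
        def ccw(p, q, r):
            return (r[1] - p[1]) * (q[0] - p[0]) > (q[1] - p[1]) * (r[0] - p[0])

        def segments_cross(s1, s2):
            a, b = s1
            c, d = s2
            return ccw(a, c, d) != ccw(b, c, d) and ccw(a, b, c) != ccw(a, b, d)

        tls = []
        for x_il, x_non in [(0.3, 22.0), (0.8, 18.0), (1.5, 14.0), (2.5, 10.0)]:
            problem, _, _ = forward_problem(merchuck_model, x_il, x_non, alpha=0.5)
            tls.append(solve_tieline(problem))
        for i in range(len(tls)):
            for j in range(i + 1, len(tls)):
                assert not segments_cross(
                    (tls[i].il_rich, tls[i].non_il_rich),
                    (tls[j].il_rich, tls[j].non_il_rich),
                )


class TestMetrics:
    def _tl(self, il, non):
        length = math.hypot(il[0] - non[0], il[1] - non[1])
        return TieLine(il_rich=il, non_il_rich=non, length=length, slope=0.0,
                       vertical=False, residual=0.0)

    def test_hand_arithmetic_example(self):
        tll, stl = tieline_metrics(self._tl((10.0, 50.0), (30.0, 5.0)))
        assert tll == pytest.approx(math.sqrt(400 + 2025), rel=1e-12)
        assert tll == pytest.approx(49.2443, abs=1e-4)
        assert stl == pytest.approx(-2.25, rel=1e-12)

    def test_identical_endpoints_zero_length(self):
        tll, _ = tieline_metrics(self._tl((10.0, 50.0), (10.0, 50.0)))
        assert tll == 0.0

    def test_swapping_endpoints_preserves_length_and_slope(self):
        tll1, stl1 = tieline_metrics(self._tl((10.0, 50.0), (30.0, 5.0)))
        tll2, stl2 = tieline_metrics(self._tl((30.0, 5.0), (10.0, 50.0)))
        assert tll1 == pytest.approx(tll2, rel=1e-15)
        assert stl1 == pytest.approx(stl2, rel=1e-15)

    def test_vertical_tieline_flagged_infinite(self):
        tll, stl = tieline_metrics(self._tl((10.0, 50.0), (10.0, 5.0)))
        assert math.isinf(stl)
        assert tll == pytest.approx(45.0)


class TestLeverRule:
    def test_measured_phase_compositions_example(self):
        # mixture at 30 wt% IL between measured phase IL contents
        report = lever_rule_alpha((2.0, 30.0), (0.3349, 54.0350), (6.7525, 4.2344))
        assert report["alpha_y"] == pytest.approx((30.0 - 4.2344) / (54.0350 - 4.2344), rel=1e-12)
        assert report["alpha_y"] == pytest.approx(0.5174, abs=1e-4)

    def test_mixture_at_il_rich_endpoint_gives_one(self):
        report = lever_rule_alpha((1.0, 50.0), (1.0, 50.0), (20.0, 5.0))
        assert report["alpha_y"] == pytest.approx(1.0)
        assert report["alpha_x"] == pytest.approx(1.0)
        assert report["consistency"] == pytest.approx(0.0, abs=1e-12)

    def test_midpoint_gives_half(self):
        report = lever_rule_alpha((10.5, 27.5), (1.0, 50.0), (20.0, 5.0))
        assert report["alpha_y"] == pytest.approx(0.5)
        assert report["alpha_x"] == pytest.approx(0.5)

    def test_axis_with_equal_endpoints_skipped(self):
        report = lever_rule_alpha((5.0, 30.0), (1.0, 40.0), (9.0, 40.0))
        assert report["alpha_y"] is None
        assert report["alpha_x"] == pytest.approx(0.5)
        assert report["consistency"] is None

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(ValueError):
            lever_rule_alpha((5.0, 30.0), (1.0, 40.0), (1.0, 40.0))
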