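"""Pointwise linear regression, location flagging and eye classification."""

from datetime import date, timedelta

import numpy as np
import pytest

from periprog.fields_io import LongitudinalSeries, Visit
from periprog.grid import build_grid
from periprog.plr import (
    CRITERIA,
    PLRResult,
    classify_eye,
    cohort_plr,
    flag_locations,
    pointwise_slopes,
)

from conftest import make_field
from test_grid import brute_force_components, idx_of
from test_normative import constant_model


def result_from_flags(grid, prog=(), imp=()):
    n = grid.n_locations
    flags = np.full(n, "none", dtype=object)
    flags[list(prog)] = "progression"
    flags[list(imp)] = "improvement"
    return PLRResult(
        slopes=np.zeros(n), p_values=np.ones(n), flags=flags
    )


class TestSlopes:
    def test_exact_line(self):
        t = np.arange(5.0)
        y = np.tile((60 - 5 * t)[:, None], (1, 54))
        res = pointwise_slopes(t, y)
        np.testing.assert_allclose(res.slopes, -5.0)
        np.testing.assert_allclose(res.p_values, 0.0)

    def test_constant_series(self):
        res = pointwise_slopes(np.arange(5.0), np.full((5, 54), 80.0))
        np.testing.assert_allclose(res.slopes, 0.0)
        np.testing.assert_allclose(res.p_values, 1.0)

    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(0)
        t = np.array([0.0, 0.9, 2.1, 3.0, 4.2, 5.0])
        y = 70 + rng.normal(0, 5, size=(6, 54))
        res = pointwise_slopes(t, y)
        from scipy.stats import linregress

        for loc in (0, 17, 53):
            ref = linregress(t, y[:, loc])
            assert res.slopes[loc] == pytest.approx(ref.slope)
            assert res.p_values[loc] == pytest.approx(ref.pvalue)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 5"):
            pointwise_slopes(np.arange(4.0), np.zeros((4, 54)))

    def test_non_increasing_times(self):
        with pytest.raises(ValueError, match="increasing"):
            pointwise_slopes(np.array([0.0, 1.0, 1.0, 2.0, 3.0]), np.zeros((5, 54)))

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(123)
        y = 80 + rng.normal(0, 4, size=(5, 4000))
        res = pointwise_slopes(np.arange(5.0), y)
        assert (res.p_values < 0.05).mean() == pytest.approx(0.05, abs=0.012)


class TestFlags:
    @pytest.mark.parametrize(
        "slope, p, edge, expect",
        [
            (-5.0, 0.01, False, "progression"),  # inclusive cut-off
            (-4.9, 0.01, False, "none"),
            (-7.0, 0.001, True, "none"),  # edge needs <= -10
            (-10.0, 0.001, True, "progression"),
            (-20.0, 0.20, False, "none"),  # significance gate
            (5.0, 0.01, False, "improvement"),
            (9.9, 0.01, True, "none"),
        ],
    )
    def test_cutoffs(self, grid_od, slope, p, edge, expect):
        loc = next(
            l.index for l in grid_od.locations
            if l.is_edge == edge and not l.is_blind_spot
        )
        n = grid_od.n_locations
        slopes = np.zeros(n)
        ps = np.ones(n)
        slopes[loc], ps[loc] = slope, p
        res = flag_locations(PLRResult(slopes=slopes, p_values=ps), grid_od)
        assert res.flags[loc] == expect

    def test_blind_spots_never_flagged(self, grid_od):
        n = grid_od.n_locations
        res = flag_locations(
            PLRResult(slopes=np.full(n, -20.0), p_values=np.zeros(n)), grid_od
        )
        for i in grid_od.blind_spot_indices:
            assert res.flags[i] == "none"

    def test_antisymmetry_under_trend_negation(self, grid_od):
        rng = np.random.default_rng(5)
        t = np.arange(6.0)
        slopes = rng.uniform(-15, 15, 54)
        y = 60 + np.outer(t, slopes)  # noise-free trends
        fwd = flag_locations(pointwise_slopes(t, y), grid_od)
        rev = flag_locations(pointwise_slopes(t, 2 * y[0] - y), grid_od)
        swap = {"progression": "improvement", "improvement": "progression", "none": "none"}
        assert [swap[f] for f in fwd.flags] == list(rev.flags)


def oracle_classify(grid, flagged, criterion):
    """Independent re-implementation of the eye criteria from components."""
    flagged = set(flagged)
    nonedge = {i for i in flagged if not grid.locations[i].is_edge}
    if criterion == "liberal":
        return len(flagged) >= 2 and bool(nonedge)
    if criterion == "moderate":
        return len(flagged) >= 3 and bool(nonedge)
    comps = brute_force_components(grid, flagged, same_hemifield=True)
    return any(len(c) >= 3 and (c & nonedge) for c in comps)


class TestClassify:
    def test_adjacent_nonedge_trio_progresses_everywhere(self, grid_od):
        trio = [idx_of(grid_od, x, y) for x, y in [(-3, 9), (3, 9), (3, 15)]]
        assert all(not grid_od.locations[i].is_edge for i in trio)
        cls = classify_eye(result_from_flags(grid_od, prog=trio), grid_od)
        assert all(cls[c] == "progressing" for c in CRITERIA)

    def test_scattered_trio_fails_conservative_only(self, grid_od):
        scattered = [idx_of(grid_od, x, y) for x, y in [(-3, 9), (21, 3), (-9, -21)]]
        assert any(not grid_od.locations[i].is_edge for i in scattered)
        cls = classify_eye(result_from_flags(grid_od, prog=scattered), grid_od)
        assert cls["conservative"] == "stable"
        assert cls["moderate"] == "progressing"
        assert cls["liberal"] == "progressing"

    def test_indeterminate_applied_per_criterion(self, grid_od):
        prog = [idx_of(grid_od, x, y) for x, y in [(-3, 9), (21, 3)]]
        imp = [idx_of(grid_od, x, y) for x, y in [(-3, -9), (3, -9), (3, -15)]]
        cls = classify_eye(result_from_flags(grid_od, prog=prog, imp=imp), grid_od)
        assert cls["liberal"] == "indeterminate"  # both directions met
        assert cls["conservative"] == "improving"  # only the adjacent trio

    def test_matches_oracle_on_random_flag_sets(self, grid_od):
        rng = np.random.default_rng(7)
        analyzed = list(grid_od.analyzed_indices)
        for _ in range(300):
            k = int(rng.integers(0, 10))
            prog = set(rng.choice(analyzed, size=k, replace=False).tolist())
            cls = classify_eye(result_from_flags(grid_od, prog=prog), grid_od)
            for c in CRITERIA:
                expect = "progressing" if oracle_classify(grid_od, prog, c) else "stable"
                assert cls[c] == expect

    def test_criterion_nesting(self, grid_od):
        rng = np.random.default_rng(11)
        analyzed = list(grid_od.analyzed_indices)
        order = {"stable": 0, "progressing": 1}
        for _ in range(300):
            k = int(rng.integers(0, 12))
            prog = set(rng.choice(analyzed, size=k, replace=False).tolist())
            cls = classify_eye(result_from_flags(grid_od, prog=prog), grid_od)
            assert (
                order[cls["conservative"]]
                <= order[cls["moderate"]]
                <= order[cls["liberal"]]
            )


class TestCohort:
    def test_noise_free_stable_eye_stable_everywhere(self):
        model = constant_model(normal_db=34.0, slope=-0.06)
        visits = []
        for k in range(6):
            age = 60.0 + k
            f = make_field(
                np.full(54, model.predict_normal("SAP", age, location=0)),
                age=age,
                test_date=date(2015, 1, 1) + timedelta(days=int(365.25 * k)),
            )
            visits.append(Visit(fields={"SAP": f, "SWAP": f, "FDT": f}))
        # constant model only has SAP; reuse it for all three modalities
        model.fits["SWAP"] = model.fits["SAP"]
        model.fits["FDT"] = model.fits["SAP"]
        series = LongitudinalSeries(subject_id="T000", eye="OD", visits=visits)
        table, counts = cohort_plr([series], model.grid, model)
        assert (table[list(CRITERIA)] == "stable").all().all()
        assert all(c.sum() == 0 for c in counts.values())

    def test_injected_defect_detected(self, normative_model):
        """A noise-free adjacent nonedge cluster declining 8%/yr is flagged
        as progressing under every criterion."""
        grid = normative_model.grid
        trio = [idx_of(grid, x, y) for x, y in [(-3, 9), (3, 9), (3, 15)]]
        visits = []
        for k in range(6):
            age = 60.0 + k
            sens = normative_model.predict_normal("SAP", age).copy()
            # 8% of normal per year, expressed in dB: 10*log10(1-0.08*k)
            sens[trio] += 10 * np.log10(max(1 - 0.08 * k, 0.1))
            f = make_field(sens, age=age,
                           test_date=date(2015, 1, 1) + timedelta(days=int(365.25 * k)))
            visits.append(Visit(fields={"SAP": f, "SWAP": f, "FDT": f}))
        series = LongitudinalSeries(subject_id="T000", eye="OD", visits=visits)
        from periprog.plr import percent_series, pointwise_slopes as ps

        t, v = percent_series(series, "SAP", normative_model)
        res = flag_locations(ps(t, v), grid)
        assert all(res.flags[i] == "progression" for i in trio)
        cls = classify_eye(res, grid)
        assert cls["conservative"] == "progressing"
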