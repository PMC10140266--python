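import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bar_grid_root
from nesfe.constants import KB_KCAL_PER_MOL_K
from nesfe.exceptions import InsufficientOverlapError, ParseError
from nesfe.neswork import (
    DhdlTrace,
    FreeEnergyEstimate,
    WorkSet,
    bar_estimate,
    bootstrap_se,
    combine_replicas,
    edge_ddg,
    frame_schedule,
    integrate_work,
    jarzynski_estimate,
    read_dhdl_trace,
    read_work_file,
)
from nesfe.synthgen import gen_cft_gaussian_works

KBT298 = KB_KCAL_PER_MOL_K * 298.0


def workset(w_f, w_r):
    return WorkSet("e", "complex", 1, np.asarray(w_f, float), np.asarray(w_r, float))


class TestFrameSchedule:
    def test_production_protocol_80_frames_over_last_4ns(self):
        times = frame_schedule(6000.0, 2000.0, 80)
        assert len(times) == 80
        assert times[-1] == pytest.approx(6000.0)
        assert np.allclose(np.diff(times), 50.0)
        assert times[0] == pytest.approx(2050.0)  # discard boundary excluded

    def test_closed_form_small_case(self):
        np.testing.assert_allclose(frame_schedule(4.0, 0.0, 4), [1, 2, 3, 4])

    def test_single_frame_lands_at_end(self):
        np.testing.assert_allclose(frame_schedule(100.0, 50.0, 1), [100.0])

    @pytest.mark.parametrize("args", [(100.0, 100.0, 5), (100.0, -1.0, 5), (100.0, 0.0, 0)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            frame_schedule(*args)


class TestIntegrateWork:
    def test_constant_integrand_gives_the_constant(self):
        lam = np.linspace(0, 1, 11)
        assert integrate_work(DhdlTrace(lam, np.full(11, 3.7))) == pytest.approx(3.7)

    def test_zero_integrand(self):
        lam = np.linspace(0, 1, 5)
        assert integrate_work(DhdlTrace(lam, np.zeros(5))) == 0.0

    def test_linear_integrand_exact_for_trapezoid(self):
        lam = np.linspace(0, 1, 21)
        assert integrate_work(DhdlTrace(lam, 2 * lam)) == pytest.approx(1.0, abs=1e-12)

    def test_reverse_traversal_negates_the_integral(self):
        lam = np.linspace(0, 1, 21)
        fwd = integrate_work(DhdlTrace(lam, 2 * lam))
        rev = integrate_work(DhdlTrace(lam[::-1], 2 * lam[::-1]))
        assert rev == pytest.approx(-fwd)

    def test_non_monotone_lambda_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            DhdlTrace(np.array([0.0, 0.5, 0.4, 1.0]), np.zeros(4))


class TestBarEstimate:
    def test_symmetric_zero_works_give_zero(self):
        assert bar_estimate(workset([0, 0, 0], [0, 0, 0])).value == pytest.approx(0.0, abs=1e-9)

    def test_delta_function_works_give_exact_crossing(self):
        est = bar_estimate(workset([5.0] * 3, [-5.0] * 3))
        assert est.value == pytest.approx(5.0, abs=1e-9)

    def test_gaussian_cft_works_recover_truth(self):
        ws = gen_cft_gaussian_works(2.0, 1.0, 1000, 1000, temperature=298.0, seed=11)
        est = bar_estimate(ws, 298.0)
        se = bootstrap_se(ws, 298.0, n_boot=100, seed=12)
        assert abs(est.value - 2.0) < 3 * se

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_grid_scan_root_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ws = workset(rng.normal(1.0, 2.0, 60), rng.normal(-0.4, 2.0, 45))
        est = bar_estimate(ws, 298.0)
        oracle = bar_grid_root(ws.w_forward, ws.w_reverse, 298.0)
        assert est.value == pytest.approx(oracle, abs=1e-6)

    def test_non_overlapping_distributions_raise(self):
        with pytest.raises(InsufficientOverlapError, match="bracket"):
            bar_estimate(workset([1000.0] * 5, [500.0] * 5))

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(-3, 3), min_size=2, max_size=20),
        st.lists(st.floats(-3, 3), min_size=2, max_size=20),
        st.floats(-5, 5),
    )
    def test_shift_covariance(self, w_f, w_r, c):
        base = bar_estimate(workset(w_f, w_r)).value
        shifted = bar_estimate(workset(np.array(w_f) + c, np.array(w_r) - c)).value
        assert shifted == pytest.approx(base + c, abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(-3, 3), min_size=2, max_size=20),
        st.lists(st.floats(-3, 3), min_size=2, max_size=20),
    )
    def test_antisymmetric_under_direction_swap(self, w_f, w_r):
        # reversing the perturbation makes the B→A works the forward set
        forward = bar_estimate(workset(w_f, w_r)).value
        backward = bar_estimate(workset(w_r, w_f)).value
        assert backward == pytest.approx(-forward, abs=1e-9)


class TestJarzynski:
    def test_delta_function_returns_the_work(self):
        assert jarzynski_estimate(np.full(10, 3.3)) == pytest.approx(3.3)

    def test_zero_works_return_zero(self):
        assert jarzynski_estimate(np.zeros(5)) == 0.0

    def test_reverse_direction_sign(self):
        assert jarzynski_estimate(np.full(10, -5.0), direction="r") == pytest.approx(5.0)

    def test_gaussian_closed_form(self):
        # ΔG = μ − βσ²/2 for Gaussian works
        rng = np.random.default_rng(5)
        mu, sigma = 1.5, 0.6
        w = rng.normal(mu, sigma, 10000)
        expected = mu - sigma**2 / (2 * KBT298)
        assert jarzynski_estimate(w, 298.0) == pytest.approx(expected, abs=0.05)

    def test_agrees_with_bar_on_gaussian_cft_works(self):
        ws = gen_cft_gaussian_works(1.0, 0.8, 10000, 10000, seed=21)
        jarz = jarzynski_estimate(ws.w_forward, 298.0, "f")
        bar = bar_estimate(ws, 298.0).value
        assert jarz == pytest.approx(bar, abs=0.1)
        assert jarz == pytest.approx(1.0, abs=0.1)


class TestBootstrap:
    def test_zero_variance_works_give_zero_se(self):
        assert bootstrap_se(workset([2.0] * 20, [-2.0] * 20), n_boot=50, seed=0) == 0.0

    def test_deterministic_for_fixed_seed(self):
        ws = gen_cft_gaussian_works(1.0, 1.0, 100, 100, seed=3)
        a = bootstrap_se(ws, n_boot=50, seed=9)
        b = bootstrap_se(ws, n_boot=50, seed=9)
        assert a == b

    def test_tracks_true_sampling_error(self):
        # bootstrap SE within 30% of the empirical SD over independent
        # regenerations of the same Gaussian process
        estimates = [
            bar_estimate(gen_cft_gaussian_works(1.0, 1.0, 100, 100, seed=k)).value
            for k in range(100)
        ]
        empirical = np.std(estimates, ddof=1)
        ws = gen_cft_gaussian_works(1.0, 1.0, 100, 100, seed=1000)
        se = bootstrap_se(ws, n_boot=200, seed=5)
        assert abs(se - empirical) / empirical < 0.3


class TestCombineAndAssemble:
    def _est(self, value, se):
        return FreeEnergyEstimate(value, se, "bar", 10, 10, 298.0)

    def test_identical_replicas_have_zero_spread(self):
        assert combine_replicas([self._est(2.0, 0.0)] * 3) == (2.0, 0.0)

    def test_between_replica_scatter_closed_form(self):
        vals = [self._est(v, 0.0) for v in (1.0, 2.0, 3.0)]
        value, se = combine_replicas(vals)
        assert value == pytest.approx(2.0)
        assert se == pytest.approx(1.0 / np.sqrt(3))

    def test_bootstrap_term_enters_in_quadrature(self):
        vals = [self._est(v, 0.3) for v in (1.0, 2.0, 3.0)]
        _, se = combine_replicas(vals)
        assert se == pytest.approx(np.sqrt(1 / 3 + 0.27 / 9))

    def test_single_replica_passes_bootstrap_se_through(self):
        assert combine_replicas([self._est(1.5, 0.4)]) == (1.5, 0.4)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combine_replicas([])

    def test_edge_ddg_difference_and_quadrature(self):
        r = edge_ddg("a→b", (5.0, 0.0), (3.0, 0.0))
        assert r.ddg == pytest.approx(2.0) and r.se == 0.0
        r = edge_ddg("a→b", (-1.2, 0.3), (0.8, 0.4))
        assert r.ddg == pytest.approx(-2.0) and r.se == pytest.approx(0.5)

    def test_equal_legs_cancel_with_quadrature_error(self):
        r = edge_ddg("a→b", (4.0, 0.2), (4.0, 0.2))
        assert r.ddg == 0.0 and r.se == pytest.approx(0.2 * np.sqrt(2))


class TestWorkFileIO:
    def test_unit_conversion_from_kj(self, tmp_path):
        p = tmp_path / "w.dat"
        p.write_text("1 4.184\n")
        np.testing.assert_allclose(read_work_file(p), [1.0])

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "w.dat"
        p.write_text("# only a comment\n")
        with pytest.raises(ParseError, match="no work values"):
            read_work_file(p)

    def test_80_rows_in_file_order(self, tmp_path):
        p = tmp_path / "w.dat"
        p.write_text("".join(f"{i} {i * 4.184}\n" for i in range(1, 81)))
        works = read_work_file(p)
        np.testing.assert_allclose(works, np.arange(1, 81))

    def test_non_numeric_row_names_the_line(self, tmp_path):
        p = tmp_path / "w.dat"
        p.write_text("1 4.184\n2 oops\n")
        with pytest.raises(ParseError, match=":2"):
            read_work_file(p)

    def test_dhdl_trace_two_and_three_column(self, tmp_path):
        p2 = tmp_path / "t2.xvg"
        p2.write_text("0.0 4.184\n0.5 4.184\n1.0 4.184\n")
        t = read_dhdl_trace(p2)
        np.testing.assert_allclose(t.dhdl, [1.0, 1.0, 1.0])
        p3 = tmp_path / "t3.xvg"
        p3.write_text("0 0.0 4.184\n1 0.5 4.184\n2 1.0 4.184\n")
        np.testing.assert_allclose(read_dhdl_trace(p3).lam, [0.0, 0.5, 1.0])
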