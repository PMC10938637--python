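import math

import numpy as np
import pytest

from enmix.constants import kt
from enmix.errors import (
    CoverageError,
    EmptyInputError,
    InsufficientDataError,
    ParameterError,
)
from enmix.free_energy import (
    FreeEnergyEstimate,
    IntervalEstimate,
    WindowWorkData,
    acf,
    bar_asymptotic_error,
    bar_chain,
    bar_interval,
    block_error,
    chain_intervals,
    convergence_profile,
    cycle_absolute,
    ddg,
    read_work_data,
    ti_estimate,
)
from enmix.perturbation import paper_lambda_schedule, uniform_lambda_schedule
from enmix.toysim import gaussian_work_pair

T = 310.0


def window(fwd, rev, lo=0.0, hi=1.0, temperature=T):
    fwd = np.asarray(fwd, dtype=float)
    rev = np.asarray(rev, dtype=float)
    return WindowWorkData(
        lo, hi,
        np.arange(len(fwd)) * 50.0, fwd,
        np.arange(len(rev)) * 50.0, rev,
        temperature=temperature,
    )


class TestBarInterval:
    def test_constant_work_exact(self):
        c = 3.7
        iv = bar_interval(window([c] * 20, [-c] * 20))
        assert iv.dG == pytest.approx(c, abs=1e-9)

    def test_all_zero_work(self):
        iv = bar_interval(window([0.0] * 20, [0.0] * 20))
        assert iv.dG == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("mu,sigma", [(1.0, 1.0), (5.0, 2.0), (-3.0, 4.0)])
    def test_gaussian_crooks_oracle(self, mu, sigma):
        w = gaussian_work_pair(mu, sigma, 100_000, seed=17, temperature=T)
        iv = bar_interval(w)
        se = max(iv.err, bar_asymptotic_error(w))
        assert abs(iv.dG - w.true_dG) < 3 * se

    def test_swap_antisymmetry(self):
        # works are direction-local (each set is the ΔU toward the other
        # state), so exchanging the two sets negates ΔG exactly
        rng = np.random.default_rng(5)
        fwd = rng.normal(2.0, 1.5, 500)
        rev = rng.normal(-1.0, 1.5, 500)
        a = bar_interval(window(fwd, rev)).dG
        b = bar_interval(window(rev, fwd)).dG
        assert a == pytest.approx(-b, abs=1e-9)

    def test_empty_forward_rejected(self):
        with pytest.raises(EmptyInputError):
            bar_interval(window([], [1.0]))

    def test_empty_reverse_falls_back_with_warning(self):
        w = window([1.0] * 50, [])
        with pytest.warns(UserWarning):
            iv = bar_interval(w)
        assert iv.fallback_exp_avg
        assert iv.dG == pytest.approx(1.0)  # zero-variance exp averaging

    def test_unequal_sample_counts(self):
        w = gaussian_work_pair(2.0, 1.0, 4000, seed=2, temperature=T)
        uneven = window(w.forward_work, w.reverse_work[:1000])
        iv = bar_interval(uneven)
        assert abs(iv.dG - w.true_dG) < 0.2


class TestBlockError:
    def test_tiled_blocks_zero_error(self):
        base_f = np.array([1.0, 2.0, 3.0])
        base_r = np.array([-1.0, -2.0, -3.0])
        w = window(np.tile(base_f, 5), np.tile(base_r, 5))
        assert block_error(w, n_blocks=5) == pytest.approx(0.0, abs=1e-9)

    def test_hand_arithmetic_oracle(self):
        # per-block constant work c_b gives block BAR estimate exactly c_b;
        # block estimates {1..5} -> std = sqrt(2.5), err = sqrt(2.5)/sqrt(5)
        fwd = np.repeat([1.0, 2.0, 3.0, 4.0, 5.0], 10)
        rev = -fwd
        err = block_error(window(fwd, rev), n_blocks=5)
        assert err == pytest.approx(math.sqrt(2.5) / math.sqrt(5), rel=1e-9)
        assert err == pytest.approx(0.7071, abs=1e-4)

    def test_stability_across_block_counts(self):
        w = gaussian_work_pair(2.0, 1.5, 20_000, seed=23, temperature=T)
        errs = [block_error(w, n_blocks=n) for n in range(2, 11)]
        rel_range = (max(errs) - min(errs)) / np.mean(errs)
        assert rel_range < 0.5

    def test_too_few_blocks(self):
        with pytest.raises(ParameterError):
            block_error(window([1.0] * 10, [1.0] * 10), n_blocks=1)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            block_error(window([1.0] * 3, [1.0] * 3), n_blocks=5)


class TestChainIntervals:
    def test_single_interval(self):
        est = chain_intervals([(1.5, 0.2)])
        assert (est.dG, est.err) == (1.5, 0.2)

    def test_linear_error_summation(self):
        est = chain_intervals([(1.0, 0.1), (2.0, 0.2)])
        assert est.dG == pytest.approx(3.0)
        assert est.err == pytest.approx(0.3)

    def test_quadrature_option(self):
        est = chain_intervals([(1.0, 0.3), (2.0, 0.4)], error_combination="quadrature")
        assert est.err == pytest.approx(0.5)

    def test_paper_schedule_of_zeros(self):
        sched = paper_lambda_schedule()
        ivs = [IntervalEstimate(lo, hi, 0.0, 0.0) for lo, hi in sched.intervals()]
        assert len(ivs) == 28
        est = chain_intervals(ivs)
        assert (est.dG, est.err) == (0.0, 0.0)

    def test_gap_detected(self):
        ivs = [IntervalEstimate(0.0, 0.4, 1.0, 0.0), IntervalEstimate(0.6, 1.0, 1.0, 0.0)]
        with pytest.raises(CoverageError):
            chain_intervals(ivs)

    def test_overlap_detected(self):
        ivs = [IntervalEstimate(0.0, 0.6, 1.0, 0.0), IntervalEstimate(0.4, 1.0, 1.0, 0.0)]
        with pytest.raises(CoverageError):
            chain_intervals(ivs)

    def test_partition_invariance_on_exact_data(self):
        # deterministic (zero-variance) energies: any partition of [0,1]
        # chains to the same total
        total = 4.0
        for n in (2, 5, 11):
            sched = uniform_lambda_schedule(n)
            ivs = []
            for lo, hi in sched.intervals():
                c = total * (hi - lo)
                ivs.append(bar_interval(window([c] * 10, [-c] * 10, lo, hi)))
            est = chain_intervals(ivs)
            assert est.dG == pytest.approx(total, abs=1e-8)


class TestTI:
    def test_zero_means(self):
        sched = uniform_lambda_schedule(5)
        est = ti_estimate([np.zeros(50)] * 5, sched)
        assert est.dG == 0.0

    def test_constant_mean(self):
        c = 2.5
        sched = uniform_lambda_schedule(11)
        est = ti_estimate([np.full(50, c)] * 11, sched)
        assert est.dG == pytest.approx(c)

    def test_linear_dhdl_integrates_exactly(self):
        # dH/dλ = a + bλ integrates to a + b/2 regardless of grid
        a, b = 1.0, 3.0
        sched = paper_lambda_schedule()
        series = [np.full(20, a + b * lam) for lam in sched]
        est = ti_estimate(series, sched)
        assert est.dG == pytest.approx(a + b / 2, rel=1e-12)

    def test_interval_sum_invariant(self):
        rng = np.random.default_rng(8)
        sched = uniform_lambda_schedule(6)
        series = [rng.normal(size=100) for _ in sched]
        est = ti_estimate(series, sched)
        assert est.dG == pytest.approx(sum(iv.dG for iv in est.per_interval), abs=1e-12)

    def test_missing_series(self):
        with pytest.raises(ParameterError):
            ti_estimate([np.zeros(10)] * 3, uniform_lambda_schedule(5))


class TestACF:
    def test_lag_zero_is_one(self, rng):
        res = acf(rng.normal(size=500), max_lag=10)
        assert res.values[0] == pytest.approx(1.0)

    def test_white_noise_bound(self):
        x = np.random.default_rng(11).normal(size=100_000)
        res = acf(x, max_lag=20)
        assert np.all(np.abs(res.values[1:]) < 0.02)

    def test_ar1_closed_form(self):
        phi = 0.8
        rng = np.random.default_rng(12)
        n = 100_000
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t]
        res = acf(x, max_lag=10)
        for k in range(1, 11):
            assert abs(res.values[k] - phi**k) < 0.02

    def test_integrated_time_white_noise_near_one(self):
        x = np.random.default_rng(13).normal(size=50_000)
        res = acf(x, max_lag=50)
        assert res.integrated_time == pytest.approx(1.0, abs=0.2)

    def test_constant_series_rejected(self):
        with pytest.raises(ParameterError):
            acf(np.ones(100), max_lag=5)

    def test_max_lag_bound(self):
        with pytest.raises(ParameterError):
            acf(np.arange(5.0), max_lag=10)


class TestConvergence:
    def _stationary_windows(self):
        return [
            gaussian_work_pair(1.0, 1.0, 2000, seed=s, temperature=T,
                               lambda_low=lo, lambda_high=hi)
            for s, (lo, hi) in enumerate(uniform_lambda_schedule(4).intervals())
        ]

    def test_single_fraction_equals_full_estimate(self):
        windows = self._stationary_windows()
        prof = convergence_profile(windows, fractions=[1.0])
        full = bar_chain(windows)
        assert prof.points == [(1.0, full.dG)]
        assert prof.converged

    def test_stationary_data_converged(self):
        prof = convergence_profile(self._stationary_windows())
        assert prof.converged
        dgs = [p[1] for p in prof.points]
        assert max(dgs) - min(dgs) < 0.5

    def test_injected_drift_flags_false(self):
        w = gaussian_work_pair(1.0, 0.5, 4000, seed=1, temperature=T)
        drift = window(
            np.concatenate([w.forward_work[:2000] + 8.0, w.forward_work[2000:]]),
            w.reverse_work,
        )
        prof = convergence_profile([drift], fractions=[0.5, 1.0], tolerance=0.5)
        assert not prof.converged

    def test_insufficient_samples(self):
        w = window([1.0] * 20, [-1.0] * 20)
        with pytest.raises(InsufficientDataError):
            convergence_profile([w], fractions=[0.1, 1.0])


class TestDdgAndCycle:
    def _est(self, dg, err, prov="toy"):
        return FreeEnergyEstimate(dg, err, [], "BAR", 5, provenance=prov)

    def test_identical_estimates_zero(self):
        res = ddg(self._est(-3.0, 0.1), self._est(-3.0, 0.1))
        assert res.ddG == 0.0
        assert res.err == pytest.approx(0.2)

    def test_antisymmetry(self):
        x, y = self._est(-1.0, 0.1), self._est(-7.65, 0.2)
        assert ddg(x, y).ddG == pytest.approx(-ddg(y, x).ddG)

    def test_arithmetic(self):
        res = ddg(self._est(-1.0, 0.1), self._est(-7.65, 0.2))
        assert res.ddG == pytest.approx(-6.65)
        assert res.err == pytest.approx(0.3)

    def test_provenance_mismatch_warns_in_result(self):
        res = ddg(self._est(0.0, 0.0, "sysA"), self._est(0.0, 0.0, "sysB"))
        assert res.warnings

    def test_cycle_all_zero(self):
        res = cycle_absolute(0.0, 0.0, 0.0)
        assert res.ddG == 0.0

    def test_cycle_equal_condition_legs(self):
        res = cycle_absolute(-2.0, 1.3, 1.3)
        assert res.ddG == pytest.approx(0.0)

    def test_cycle_closure_residual(self):
        # ΔG_AB(Y) = ΔG_AB(X) − ΔG_A(XY) + ΔG_B(XY)
        res = cycle_absolute(-2.0, 0.5, 1.5, dG_AB_Y=-1.0)
        assert res.closure_residual == pytest.approx(0.0)
        res2 = cycle_absolute(-2.0, 0.5, 1.5, dG_AB_Y=-1.4)
        assert res2.closure_residual == pytest.approx(0.4)


class TestReadWorkData:
    def _write_files(self, tmp_path, fmt="tsv"):
        from enmix.perturbation import LambdaSchedule

        tmp_path.mkdir(parents=True, exist_ok=True)
        sched = LambdaSchedule((0.0, 0.4, 1.0))
        rng = np.random.default_rng(3)
        data = {
            0: rng.normal(1.0, 0.5, 30),        # dU to 0.4
            1: (rng.normal(-1.0, 0.5, 30), rng.normal(0.5, 0.5, 30)),  # to 0.0, to 1.0
            2: rng.normal(-0.5, 0.5, 30),       # dU to 0.4
        }
        paths = []
        for idx in range(3):
            p = tmp_path / f"window_{idx:03d}.{fmt}"
            comment = "@" if fmt == "xvg" else "#"
            lines = [f"{comment} header line"]
            for row in range(30):
                t = row * 50.0
                if idx == 1:
                    lines.append(f"{t}\t{data[1][0][row]}\t{data[1][1][row]}")
                else:
                    lines.append(f"{t}\t{data[idx][row]}")
            p.write_text("\n".join(lines) + "\n")
            paths.append(p)
        return sched, paths, data

    def test_three_lambda_fixture_counts(self, tmp_path):
        sched, paths, data = self._write_files(tmp_path)
        windows = read_work_data(paths, sched, temperature=T)
        assert len(windows) == 2
        w0, w1 = windows
        assert (w0.lambda_low, w0.lambda_high) == (0.0, 0.4)
        np.testing.assert_allclose(w0.forward_work, data[0])
        np.testing.assert_allclose(w0.reverse_work, data[1][0])
        np.testing.assert_allclose(w1.forward_work, data[1][1])
        np.testing.assert_allclose(w1.reverse_work, data[2])

    def test_comment_only_file_rejected(self, tmp_path):
        from enmix.perturbation import LambdaSchedule

        sched = LambdaSchedule((0.0, 1.0))
        a = tmp_path / "a.tsv"
        b = tmp_path / "b.tsv"
        a.write_text("# nothing\n@ still nothing\n")
        b.write_text("0.0\t1.0\n")
        with pytest.raises(EmptyInputError):
            read_work_data([a, b], sched)

    def test_xvg_and_tsv_identical_estimates(self, tmp_path):
        sched_t, paths_t, _ = self._write_files(tmp_path / "t", fmt="tsv")
        sched_x, paths_x, _ = self._write_files(tmp_path / "x", fmt="xvg")
        est_t = bar_chain(read_work_data(paths_t, sched_t, temperature=T))
        est_x = bar_chain(read_work_data(paths_x, sched_x, temperature=T))
        assert est_t.dG == est_x.dG
        assert est_t.err == est_x.err

    def test_wrong_column_count(self, tmp_path):
        from enmix.perturbation import LambdaSchedule

        sched = LambdaSchedule((0.0, 1.0))
        a = tmp_path / "a.tsv"
        b = tmp_path / "b.tsv"
        a.write_text("0.0\t1.0\t2.0\n")  # endpoint file must have 2 columns
        b.write_text("0.0\t1.0\n")
        with pytest.raises(Exception):
            read_work_data([a, b], sched)
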