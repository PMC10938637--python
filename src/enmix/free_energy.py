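"""Free-energy estimation from per-window work data.

Per λ interval the Bennett acceptance ratio (BAR) equation

    Σ_F f(ln(n_F/n_R) + β(w_F − ΔG)) = Σ_R f(ln(n_R/n_F) + β(w_R + ΔG)),
    f(x) = 1 / (1 + exp(x)),

is solved with a bracketing root-finder; thermodynamic integration (TI) is
provided as the trapezoidal quadrature of per-λ mean ∂H/∂λ. Errors follow
the block convention: each window's time series is cut into ``n_blocks``
contiguous blocks (default 5), the estimator is re-run per block, and the
standard error of the block estimates is reported. Interval errors (and
errors across conditions in ΔΔG) combine by plain summation; quadrature
combination is available behind ``error_combination="quadrature"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .constants import DEFAULT_N_BLOCKS, DEFAULT_TEMPERATURE, kt
from .errors import (
    CoverageError,
    EmptyInputError,
    EnmixError,
    InsufficientDataError,
    NonOverlapError,
    ParameterError,
    ParseError,
    ValidationError,
)
from .perturbation import LambdaSchedule


@dataclass
class WindowWorkData:
    """Forward/reverse energy-difference samples for one λ interval.

    ``forward_work[t]`` is U(λ_high) − U(λ_low) evaluated on λ_low-ensemble
    configurations; ``reverse_work`` the mirror image on the λ_high ensemble.
    All energies kJ/mol, times ps.
    """

    lambda_low: float
    lambda_high: float
    forward_time: np.ndarray
    forward_work: np.ndarray
    reverse_time: np.ndarray
    reverse_work: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    #: analytic ΔG when the data come from a synthetic generator, else None
    true_dG: float | None = None

    def __post_init__(self):
        if self.lambda_low >= self.lambda_high:
            raise ValidationError("lambda_low must be < lambda_high")
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")
        for name in ("forward_time", "forward_work", "reverse_time", "reverse_work"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def reversed(self) -> "WindowWorkData":
        """The same interval traversed high→low.

        Stored works are direction-local (each series is the ΔU toward the
        other endpoint), so reversing the path is a plain swap of the two
        sets; the implied ΔG changes sign.
        """
        return WindowWorkData(
            lambda_low=self.lambda_low,
            lambda_high=self.lambda_high,
            forward_time=self.reverse_time.copy(),
            forward_work=self.reverse_work.copy(),
            reverse_time=self.forward_time.copy(),
            reverse_work=self.forward_work.copy(),
            temperature=self.temperature,
            true_dG=None if self.true_dG is None else -self.true_dG,
        )


@dataclass
class IntervalEstimate:
    """Point estimate and block error for one λ interval."""

    lambda_low: float
    lambda_high: float
    dG: float
    err: float
    #: set when BAR fell back to one-sided exponential averaging
    fallback_exp_avg: bool = False

    def __iter__(self):
        return iter((self.dG, self.err))


@dataclass
class FreeEnergyEstimate:
    """Total ΔG over [0, 1] with per-interval contributions."""

    dG: float
    err: float
    per_interval: list[IntervalEstimate]
    method: str
    n_blocks: int
    temperature: float = DEFAULT_TEMPERATURE
    provenance: str = ""

    def __post_init__(self):
        if self.per_interval:
            total = sum(iv.dG for iv in self.per_interval)
            if abs(total - self.dG) > 1e-9 * max(1.0, abs(self.dG)):
                raise ValidationError("dG does not equal the sum of interval dG values")

    def to_dict(self) -> dict:
        return {
            "dG": self.dG,
            "err": self.err,
            "method": self.method,
            "n_blocks": self.n_blocks,
            "temperature": self.temperature,
            "provenance": self.provenance,
            "per_interval": [
                {
                    "lambda_low": iv.lambda_low,
                    "lambda_high": iv.lambda_high,
                    "dG": iv.dG,
                    "err": iv.err,
                }
                for iv in self.per_interval
            ],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "FreeEnergyEstimate":
        d = json.loads(Path(path).read_text())
        return cls(
            dG=d["dG"],
            err=d["err"],
            per_interval=[
                IntervalEstimate(iv["lambda_low"], iv["lambda_high"], iv["dG"], iv["err"])
                for iv in d["per_interval"]
            ],
            method=d["method"],
            n_blocks=d["n_blocks"],
            temperature=d.get("temperature", DEFAULT_TEMPERATURE),
            provenance=d.get("provenance", ""),
        )


@dataclass
class CycleResult:
    """ΔΔG between two condition sets, optionally with absolute cycle legs."""

    ddG: float
    err: float
    dG_A_XY: float | None = None
    dG_B_XY: float | None = None
    closure_residual: float | None = None
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# BAR
# ---------------------------------------------------------------------------

def _fermi(x: np.ndarray) -> np.ndarray:
    # numerically safe 1/(1+exp(x))
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return out


def _bar_solve(
    w_f: np.ndarray, w_r: np.ndarray, temperature: float
) -> float:
    """Solve the self-consistent BAR equation for ΔG (kJ/mol)."""
    beta = 1.0 / kt(temperature)
    n_f, n_r = len(w_f), len(w_r)
    log_ratio = math.log(n_f / n_r)

    def residual(dg: float) -> float:
        lhs = _fermi(log_ratio + beta * (w_f - dg)).sum()
        rhs = _fermi(-log_ratio + beta * (w_r + dg)).sum()
        return lhs - rhs

    # residual is monotone increasing in dg; expand a bracket around the
    # crude two-sided guess by doubling until the sign changes
    guess = 0.5 * (w_f.mean() - w_r.mean())
    bound = max(np.abs(w_f).max(), np.abs(w_r).max()) + 50.0 / beta
    half = max(1.0 / beta, 1e-6)
    lo, hi = guess - half, guess + half
    while residual(lo) > 0 or residual(hi) < 0:
        half *= 2.0
        lo, hi = guess - half, guess + half
        if half > 2 * bound + abs(guess):
            raise NonOverlapError(
                "BAR equation has no root within the search bound; forward and "
                "reverse work distributions do not overlap — add λ points"
            )
    if residual(lo) == 0:
        return float(lo)
    dg = brentq(residual, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    tol = 1e-10 * (n_f + n_r)
    if abs(residual(dg)) > tol:
        # polish with bisection on the monotone residual
        a, b = dg - 1e-8, dg + 1e-8
        while residual(a) > 0:
            a -= 1e-8
        while residual(b) < 0:
            b += 1e-8
        for _ in range(200):
            mid = 0.5 * (a + b)
            if residual(mid) > 0:
                b = mid
            else:
                a = mid
            if abs(residual(mid)) <= tol:
                return float(mid)
        dg = 0.5 * (a + b)
    return float(dg)


def _exp_avg(w_f: np.ndarray, temperature: float) -> float:
    beta = 1.0 / kt(temperature)
    # -kT ln <exp(-beta w)> with a max-shift for stability
    m = (-beta * w_f).max()
    return float(-(m + math.log(np.mean(np.exp(-beta * w_f - m)))) / beta)


def bar_interval(
    w: WindowWorkData, n_blocks: int = DEFAULT_N_BLOCKS
) -> IntervalEstimate:
    """BAR estimate of ΔG for one λ interval, with block error.

    An empty reverse set triggers a one-sided exponential-averaging fallback
    flagged on the result. If either series is shorter than ``n_blocks`` the
    error is reported as NaN.
    """
    if len(w.forward_work) == 0:
        raise EmptyInputError("forward work series is empty")
    if len(w.reverse_work) == 0:
        import warnings

        warnings.warn(
            "reverse work series empty: falling back to exponential averaging",
            UserWarning,
            stacklevel=2,
        )
        dg = _exp_avg(w.forward_work, w.temperature)
        if len(w.forward_work) >= n_blocks:
            err = _block_std(
                [w.forward_work],
                lambda parts: _exp_avg(parts[0], w.temperature),
                n_blocks,
            )
        else:
            err = float("nan")
        return IntervalEstimate(w.lambda_low, w.lambda_high, dg, err, fallback_exp_avg=True)

    dg = _bar_solve(w.forward_work, w.reverse_work, w.temperature)
    if min(len(w.forward_work), len(w.reverse_work)) >= n_blocks and n_blocks >= 2:
        err = block_error(w, n_blocks=n_blocks)
    else:
        err = float("nan")
    return IntervalEstimate(w.lambda_low, w.lambda_high, dg, err)


def bar_asymptotic_error(w: WindowWorkData) -> float:
    """Bennett's large-sample variance formula — cross-check only."""
    beta = 1.0 / kt(w.temperature)
    dg = _bar_solve(w.forward_work, w.reverse_work, w.temperature)
    n_f, n_r = len(w.forward_work), len(w.reverse_work)
    log_ratio = math.log(n_f / n_r)
    x = np.concatenate(
        [
            log_ratio + beta * (w.forward_work - dg),
            -log_ratio - beta * (w.reverse_work + dg),
        ]
    )
    f = _fermi(x)
    n = n_f + n_r
    var = (np.mean(f * f) / np.mean(f) ** 2 - 1.0) / n * (n / n_f + n / n_r)
    return float(np.sqrt(max(var, 0.0)) / beta)


# ---------------------------------------------------------------------------
# block error
# ---------------------------------------------------------------------------

def _split_blocks(series: np.ndarray, n_blocks: int) -> list[np.ndarray]:
    size = len(series) // n_blocks
    return [series[b * size : (b + 1) * size] for b in range(n_blocks)]


def _block_std(
    series_list: list[np.ndarray],
    estimate: Callable[[list[np.ndarray]], float],
    n_blocks: int,
) -> float:
    per_block = []
    splits = [_split_blocks(s, n_blocks) for s in series_list]
    for b in range(n_blocks):
        per_block.append(estimate([sp[b] for sp in splits]))
    return float(np.std(per_block, ddof=1) / math.sqrt(n_blocks))


def block_error(
    w: WindowWorkData,
    n_blocks: int = DEFAULT_N_BLOCKS,
    estimator: str = "BAR",
) -> float:
    """Block-averaged standard error of the per-interval estimate.

    Both time series are cut into ``n_blocks`` contiguous equal-length
    blocks (a trailing remainder is dropped), the estimator is re-run on
    each block pair, and std(block estimates)/sqrt(n_blocks) is returned.
    """
    if n_blocks < 2:
        raise ParameterError(f"n_blocks must be >= 2, got {n_blocks}")
    if min(len(w.forward_work), len(w.reverse_work)) < n_blocks:
        raise InsufficientDataError(
            f"need at least {n_blocks} samples per series for {n_blocks} blocks"
        )
    if estimator == "BAR":
        fn = lambda parts: _bar_solve(parts[0], parts[1], w.temperature)
    elif estimator == "EXP":
        fn = lambda parts: _exp_avg(parts[0], w.temperature)
    else:
        raise ParameterError(f"unknown estimator {estimator!r}")
    return _block_std([w.forward_work, w.reverse_work], fn, n_blocks)


# ---------------------------------------------------------------------------
# chaining and TI
# ---------------------------------------------------------------------------

def _check_coverage(bounds: Sequence[tuple[float, float]]) -> None:
    bounds = sorted(bounds)
    if not bounds:
        raise CoverageError("no intervals supplied")
    if abs(bounds[0][0]) > 1e-9 or abs(bounds[-1][1] - 1.0) > 1e-9:
        raise CoverageError("intervals must span [0, 1]")
    for (lo1, hi1), (lo2, hi2) in zip(bounds, bounds[1:]):
        if abs(hi1 - lo2) > 1e-9:
            kind = "gap" if lo2 > hi1 else "overlap"
            raise CoverageError(f"{kind} in λ coverage between {hi1} and {lo2}")


def chain_intervals(
    intervals: Sequence,
    method: str = "BAR",
    n_blocks: int = DEFAULT_N_BLOCKS,
    temperature: float = DEFAULT_TEMPERATURE,
    provenance: str = "",
    error_combination: str = "linear",
    check_coverage: bool = True,
) -> FreeEnergyEstimate:
    """Sum per-interval estimates over the λ path.

    ``intervals`` may be :class:`IntervalEstimate` objects or bare
    ``(dG, err)`` pairs (coverage checking then requires λ bounds and is
    skipped). Errors add linearly by default (the reference convention);
    pass ``error_combination="quadrature"`` for root-sum-square.
    """
    ivs: list[IntervalEstimate] = []
    have_bounds = True
    for item in intervals:
        if isinstance(item, IntervalEstimate):
            ivs.append(item)
        else:
            item = tuple(item)
            if len(item) == 2:
                have_bounds = False
                ivs.append(IntervalEstimate(0.0, 1.0, float(item[0]), float(item[1])))
            elif len(item) == 4:
                ivs.append(IntervalEstimate(item[0], item[1], float(item[2]), float(item[3])))
            else:
                raise ParameterError("interval items must be (dG, err) or (lo, hi, dG, err)")
    if not ivs:
        raise CoverageError("no intervals supplied")
    if check_coverage and have_bounds and len(ivs) > 1:
        _check_coverage([(iv.lambda_low, iv.lambda_high) for iv in ivs])
    dg = float(sum(iv.dG for iv in ivs))
    errs = [iv.err for iv in ivs]
    if error_combination == "linear":
        err = float(sum(errs))
    elif error_combination == "quadrature":
        err = float(np.sqrt(np.sum(np.square(errs))))
    else:
        raise ParameterError(f"unknown error_combination {error_combination!r}")
    return FreeEnergyEstimate(
        dG=dg, err=err, per_interval=ivs, method=method, n_blocks=n_blocks,
        temperature=temperature, provenance=provenance,
    )


def bar_chain(
    windows: Sequence[WindowWorkData],
    n_blocks: int = DEFAULT_N_BLOCKS,
    provenance: str = "",
    error_combination: str = "linear",
) -> FreeEnergyEstimate:
    """BAR over every window, chained into the total ΔG over [0, 1]."""
    if not windows:
        raise EmptyInputError("no windows supplied")
    ivs = [bar_interval(w, n_blocks=n_blocks) for w in windows]
    return chain_intervals(
        ivs,
        method="BAR",
        n_blocks=n_blocks,
        temperature=windows[0].temperature,
        provenance=provenance,
        error_combination=error_combination,
    )


def ti_estimate(
    dhdl: Sequence[np.ndarray],
    schedule: LambdaSchedule,
    n_blocks: int = DEFAULT_N_BLOCKS,
    temperature: float = DEFAULT_TEMPERATURE,
    provenance: str = "",
    error_combination: str = "linear",
) -> FreeEnergyEstimate:
    """Thermodynamic integration: trapezoidal quadrature of per-λ mean ∂H/∂λ."""
    if len(dhdl) != len(schedule):
        raise ParameterError(
            f"need one ∂H/∂λ series per schedule point: {len(dhdl)} vs {len(schedule)}"
        )
    series = [np.asarray(s, dtype=float) for s in dhdl]
    for idx, s in enumerate(series):
        if len(s) == 0:
            raise EmptyInputError(f"∂H/∂λ series at λ={schedule[idx]} is empty")
    means = [float(s.mean()) for s in series]
    can_block = all(len(s) >= n_blocks for s in series) and n_blocks >= 2
    block_means = (
        [[float(b.mean()) for b in _split_blocks(s, n_blocks)] for s in series]
        if can_block
        else None
    )
    ivs = []
    for idx, (lo, hi) in enumerate(schedule.intervals()):
        width = hi - lo
        dg = 0.5 * width * (means[idx] + means[idx + 1])
        if block_means is not None:
            per_block = [
                0.5 * width * (block_means[idx][b] + block_means[idx + 1][b])
                for b in range(n_blocks)
            ]
            err = float(np.std(per_block, ddof=1) / math.sqrt(n_blocks))
        else:
            err = float("nan")
        ivs.append(IntervalEstimate(lo, hi, dg, err))
    return chain_intervals(
        ivs, method="TI", n_blocks=n_blocks, temperature=temperature,
        provenance=provenance, error_combination=error_combination,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ACFResult:
    """Normalized autocorrelation values and the integrated time (in lags)."""

    values: np.ndarray
    integrated_time: float


def acf(series: Sequence[float], max_lag: int) -> ACFResult:
    """Normalized autocovariance up to ``max_lag``; values[0] == 1.

    The integrated autocorrelation time is 1 + 2·Σ acf[k], truncated at the
    first nonpositive value.
    """
    x = np.asarray(series, dtype=float)
    if len(x) <= max_lag:
        raise ParameterError(f"series length {len(x)} must exceed max_lag {max_lag}")
    x = x - x.mean()
    var = float(np.dot(x, x)) / len(x)
    if var == 0.0:
        raise ParameterError("series is constant; ACF normalization undefined")
    vals = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        vals[lag] = float(np.dot(x[: len(x) - lag], x[lag:])) / len(x) / var
    tau = 1.0
    for lag in range(1, max_lag + 1):
        if vals[lag] <= 0:
            break
        tau += 2.0 * vals[lag]
    return ACFResult(values=vals, integrated_time=tau)


@dataclass
class ConvergenceProfile:
    points: list[tuple[float, float]]  # (fraction, dG)
    converged: bool
    tolerance: float


def convergence_profile(
    windows: Sequence[WindowWorkData],
    fractions: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
    n_blocks: int = DEFAULT_N_BLOCKS,
    tolerance: float | None = None,
) -> ConvergenceProfile:
    """Re-estimate the total ΔG on growing prefixes of every window.

    The run is flagged converged when the last two prefix estimates differ
    by less than ``tolerance`` (default: 2x the full-data block error).
    """
    fractions = list(fractions)
    if any(b <= a for a, b in zip(fractions, fractions[1:])):
        raise ParameterError("fractions must be increasing")
    if not fractions or abs(fractions[-1] - 1.0) > 1e-12:
        raise ParameterError("last fraction must be 1.0")
    if any(f <= 0 for f in fractions):
        raise ParameterError("fractions must be in (0, 1]")

    points = []
    full_est = None
    for frac in fractions:
        truncated = []
        for w in windows:
            nf = int(len(w.forward_work) * frac)
            nr = int(len(w.reverse_work) * frac)
            if min(nf, nr) < 10:
                raise InsufficientDataError(
                    f"fraction {frac} leaves fewer than 10 samples in window "
                    f"[{w.lambda_low}, {w.lambda_high}]"
                )
            truncated.append(
                WindowWorkData(
                    w.lambda_low, w.lambda_high,
                    w.forward_time[:nf], w.forward_work[:nf],
                    w.reverse_time[:nr], w.reverse_work[:nr],
                    temperature=w.temperature,
                )
            )
        est = bar_chain(truncated, n_blocks=n_blocks)
        points.append((frac, est.dG))
        if frac == fractions[-1]:
            full_est = est
    tol = tolerance if tolerance is not None else 2.0 * full_est.err
    converged = len(points) < 2 or abs(points[-1][1] - points[-2][1]) < tol
    return ConvergenceProfile(points=points, converged=converged, tolerance=tol)


# ---------------------------------------------------------------------------
# ΔΔG and thermodynamic cycles
# ---------------------------------------------------------------------------

def ddg(
    est_X: FreeEnergyEstimate,
    est_Y: FreeEnergyEstimate,
    error_combination: str = "linear",
) -> CycleResult:
    """ΔΔG_AB(XY) = ΔG_AB(Y) − ΔG_AB(X); errors add (linear by default)."""
    warnings = []
    if est_X.provenance and est_Y.provenance and est_X.provenance != est_Y.provenance:
        warnings.append(
            f"provenance mismatch: {est_X.provenance!r} vs {est_Y.provenance!r}; "
            f"the two estimates may not share the same A/B definition"
        )
    value = est_Y.dG - est_X.dG
    if error_combination == "linear":
        err = est_X.err + est_Y.err
    elif error_combination == "quadrature":
        err = math.hypot(est_X.err, est_Y.err)
    else:
        raise ParameterError(f"unknown error_combination {error_combination!r}")
    return CycleResult(ddG=float(value), err=float(err), warnings=warnings)


def cycle_absolute(
    dG_AB_X: float,
    dG_A_XY: float,
    dG_B_XY: float,
    dG_AB_Y: float | None = None,
) -> CycleResult:
    """Close the thermodynamic cycle: ΔG_AB(Y) = ΔG_AB(X) − ΔG_A(XY) + ΔG_B(XY).

    When an independently computed ΔG_AB(Y) is supplied, the closure
    residual |ΔG_AB(X) + ΔG_B(XY) − ΔG_AB(Y) − ΔG_A(XY)| is reported.
    """
    predicted = dG_AB_X - dG_A_XY + dG_B_XY
    residual = None if dG_AB_Y is None else abs(predicted - dG_AB_Y)
    return CycleResult(
        ddG=float(predicted - dG_AB_X),
        err=float("nan"),
        dG_A_XY=dG_A_XY,
        dG_B_XY=dG_B_XY,
        closure_residual=residual,
    )


# ---------------------------------------------------------------------------
# work-data files
# ---------------------------------------------------------------------------

def _read_table(path) -> np.ndarray:
    """Read an xvg-like or TSV table, skipping '#'/'@' comment lines."""
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "@", ";")):
                continue
            fields = s.split()
            try:
                row = [float(f) for f in fields]
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", path, lineno) from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ParseError(
                    f"inconsistent column count ({len(row)} vs {width})", path, lineno
                )
            rows.append(row)
    if not rows:
        raise EmptyInputError(f"{path}: no data rows found")
    return np.asarray(rows, dtype=float)


def read_work_data(
    paths: Sequence,
    schedule: LambdaSchedule,
    temperature: float = DEFAULT_TEMPERATURE,
) -> list[WindowWorkData]:
    """Assemble per-interval work data from per-λ tabular files.

    One file per schedule point, columns: time, then the energy difference
    to each neighbouring λ in ascending-λ order (interior points have two
    neighbour columns, the endpoints one).
    """
    if len(paths) != len(schedule):
        raise ParameterError(
            f"need one file per λ point: {len(paths)} files for {len(schedule)} points"
        )
    n = len(schedule)
    tables = [_read_table(p) for p in paths]
    for idx, tab in enumerate(tables):
        expected = 2 if idx in (0, n - 1) else 3
        if tab.shape[1] != expected:
            raise ParseError(
                f"expected {expected} columns (time + neighbour ΔU) for "
                f"λ={schedule[idx]}, found {tab.shape[1]}",
                paths[idx],
            )
    windows = []
    for idx in range(n - 1):
        fwd_col = 1 if idx == 0 else 2  # ΔU to the next (higher) λ
        low = tables[idx]
        high = tables[idx + 1]
        windows.append(
            WindowWorkData(
                lambda_low=schedule[idx],
                lambda_high=schedule[idx + 1],
                forward_time=low[:, 0],
                forward_work=low[:, fwd_col],
                reverse_time=high[:, 0],
                reverse_work=high[:, 1],  # ΔU to the previous λ is always col 1
                temperature=temperature,
            )
        )
    return windows
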