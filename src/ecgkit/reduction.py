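"""Minimax (Chebyshev) order reduction of IIR transfer functions.

A high-order digital prototype H(z) is condensed to a low-order rational
function whose magnitude response tracks the prototype's as closely as
possible in the worst-case (minimax) sense:

    minimise over coefficients x   maximise over grid frequencies f
        | |H_red(x, f)| - |H_proto(f)| |

The outer minimisation runs over the reduced filter's coefficient vector,
constrained to a nonnegative box; the inner maximisation is exact — a scan
over the frequency grid. Coefficients are optimised sequentially: the
search builds the numerator up one degree at a time, warm-starting each
order from the best lower-order solution (zero-padded), then polishing with
projected Nelder–Mead from several seeded starts. Because every candidate
ever evaluated is tracked and the best kept, the achieved deviation is
non-increasing in the target order and never worse than the initial
candidate.

The nonnegativity constraint is structural: the reduced filter is intended
as a smoothing stage whose output preserves the sign of a nonnegative
input, which holds exactly when the filter is FIR (constant denominator)
with nonnegative taps. For reduced filters with a nontrivial denominator no
such guarantee exists and none is claimed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .filters import TransferFunction, evaluate_response

__all__ = [
    "ReductionProblem",
    "ReductionResult",
    "response_deviation",
    "minimax_reduce",
]

_STABILITY_PENALTY = 1e9


def default_grid(tf: TransferFunction, n_points: int = 256) -> np.ndarray:
    """Log-spaced evaluation grid from 0.1 Hz up to just below Nyquist."""
    if tf.domain == "z":
        assert tf.fs is not None
        high = 0.499 * tf.fs
    else:
        high = 200.0
    return np.geomspace(0.1, high, n_points)


def response_deviation(
    a: TransferFunction, b: TransferFunction, grid: np.ndarray
) -> float:
    """Worst-case magnitude-response difference max_f ||H_a| - |H_b|| over
    the grid. Symmetric in its two arguments."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("frequency grid must be nonempty")
    ha = np.abs(evaluate_response(a, grid))
    hb = np.abs(evaluate_response(b, grid))
    return float(np.max(np.abs(ha - hb)))


@dataclass
class ReductionProblem:
    """Specification of one order-reduction run.

    ``num_order`` and ``den_order`` are the target polynomial degrees; the
    default (1, 0) yields a two-coefficient numerator over a positive
    constant, i.e. a reported filter order of 2 (coefficient count of the
    longest polynomial). ``bound`` is the upper edge of the coefficient box
    [0, bound].
    """

    prototype: TransferFunction
    num_order: int = 1
    den_order: int = 0
    grid: np.ndarray | None = None
    bound: float = 50.0
    seed: int = 0
    max_iter: int = 400
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.num_order < 0 or self.den_order < 0:
            raise ValueError("target orders must be >= 0")
        proto_order = self.prototype.order
        if max(self.num_order, self.den_order) > proto_order:
            raise ValueError(
                f"target order {max(self.num_order, self.den_order)} must not "
                f"exceed the prototype order {proto_order}"
            )
        if self.grid is None:
            self.grid = default_grid(self.prototype)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.size == 0:
            raise ValueError("frequency grid must be nonempty")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.prototype.domain == "z":
            assert self.prototype.fs is not None
            if self.grid[-1] >= self.prototype.fs / 2:
                raise ValueError("grid must stay below Nyquist")
        if self.bound <= 0:
            raise ValueError("coefficient bound must be positive")


@dataclass
class ReductionResult:
    """Outcome of a minimax reduction."""

    reduced: TransferFunction
    deviation: float
    iterations: int
    converged: bool

    @property
    def order(self) -> int:
        """Reported order: coefficient count of the longest polynomial."""
        return max(self.reduced.num.size, self.reduced.den.size)


def _target_magnitude(problem: ReductionProblem) -> np.ndarray:
    return np.abs(evaluate_response(problem.prototype, problem.grid))


def _eval_basis(problem: ReductionProblem) -> np.ndarray:
    """Evaluation points for the reduced filter (same domain as prototype)."""
    proto = problem.prototype
    if proto.domain == "z":
        return np.exp(1j * 2 * np.pi * problem.grid / proto.fs)
    return 1j * 2 * np.pi * problem.grid


def _objective_factory(problem: ReductionProblem, target: np.ndarray):
    x = _eval_basis(problem)
    n_num = problem.num_order + 1
    n_den = problem.den_order + 1
    vander_num = np.vander(x, n_num)  # columns x^(n-1) ... x^0
    vander_den = np.vander(x, n_den)

    def split(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        theta = np.clip(theta, 0.0, problem.bound)
        num = theta[:n_num]
        den = theta[n_num:]
        return num, den

    def objective(theta: np.ndarray) -> float:
        num, den = split(theta)
        den_val = vander_den @ den
        if np.any(np.abs(den_val) < 1e-12) or den[0] < 1e-9:
            return _STABILITY_PENALTY
        if n_den > 1:
            poles = np.roots(den)
            unstable = (
                np.any(np.abs(poles) >= 1.0)
                if problem.prototype.domain == "z"
                else np.any(poles.real >= 0)
            )
            if unstable:
                return _STABILITY_PENALTY
        h = (vander_num @ num) / den_val
        # exact inner maximisation: scan the whole grid
        return float(np.max(np.abs(np.abs(h) - target)))

    return objective, split, n_num, n_den


def _least_squares_start(
    problem: ReductionProblem, target: np.ndarray, n_num: int
) -> np.ndarray:
    """Seed the numerator from a least-squares magnitude fit with unit
    denominator, folded into the nonnegative box."""
    x = _eval_basis(problem)
    basis = np.abs(np.vander(x, n_num))
    coeffs, *_ = np.linalg.lstsq(basis, target, rcond=None)
    return np.clip(np.abs(coeffs), 0.0, problem.bound)


def minimax_reduce(problem: ReductionProblem) -> ReductionResult:
    """Reduce ``problem.prototype`` to the requested target order.

    Returns the best transfer function found; ``converged`` is False when
    the iteration budget ran out before the improvement between polishing
    rounds fell below ``problem.tol``.
    """
    target = _target_magnitude(problem)
    rng = np.random.default_rng(problem.seed)

    best_theta: np.ndarray | None = None
    best_val = np.inf
    total_iters = 0
    converged = False

    # Sequential build-up over numerator degree: each stage warm-starts from
    # the previous stage's best solution (zero-padded on the high-degree
    # side), so the achieved deviation is monotone in the target order.
    prev_best: np.ndarray | None = None
    for stage_order in range(problem.num_order + 1):
        sub = ReductionProblem(
            prototype=problem.prototype,
            num_order=stage_order,
            den_order=problem.den_order,
            grid=problem.grid,
            bound=problem.bound,
            seed=problem.seed,
            max_iter=problem.max_iter,
            tol=problem.tol,
        )
        objective, split, n_num, n_den = _objective_factory(sub, target)

        starts = []
        ls = _least_squares_start(sub, target, n_num)
        starts.append(np.concatenate([ls, np.ones(n_den)]))
        if prev_best is not None:
            # zero-pad the lower-order numerator up to this stage's degree
            pad_num = np.concatenate([[0.0], prev_best[: n_num - 1]])
            starts.append(np.concatenate([pad_num, prev_best[n_num - 1:]]))
        mid = problem.bound / 2
        starts.append(np.full(n_num + n_den, mid) * rng.uniform(0.5, 1.5, n_num + n_den))

        stage_best: np.ndarray | None = None
        stage_val = np.inf
        for theta0 in starts:
            theta0 = np.clip(theta0, 1e-6, problem.bound)
            v0 = objective(theta0)
            if v0 < stage_val:
                stage_val, stage_best = v0, theta0.copy()
            res = optimize.minimize(
                objective,
                theta0,
                method="Nelder-Mead",
                options={
                    "maxiter": problem.max_iter,
                    "xatol": 1e-10,
                    "fatol": problem.tol,
                    "disp": False,
                },
            )
            total_iters += int(res.nit)
            v = objective(res.x)
            if v < stage_val:
                stage_val = v
                stage_best = np.clip(res.x, 0.0, problem.bound)
            if res.status == 0:
                converged = True
        prev_best = stage_best
        if stage_order == problem.num_order:
            best_theta, best_val = stage_best, stage_val

    assert best_theta is not None
    num, den = np.split(np.clip(best_theta, 0.0, problem.bound),
                        [problem.num_order + 1])
    reduced = TransferFunction(
        num, den, problem.prototype.domain, problem.prototype.fs
    )
    if not converged:
        warnings.warn(
            "minimax reduction did not converge within the iteration budget",
            RuntimeWarning,
        )
    return ReductionResult(
        reduced=reduced,
        deviation=float(best_val),
        iterations=total_iters,
        converged=converged,
    )
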