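"""Quasi-Newton optimization of element phases.

Starting phases are drawn uniformly on [0, 2*pi) from a seeded generator;
the aggregate infidelity is minimized by full-memory BFGS (SciPy's
implementation with a Wolfe line search), using the exact analytic
gradients.  Phases are unconstrained reals during optimization and are
wrapped into [0, 2*pi) only at export time.

Stopping: iteration cap, gradient-norm tolerance, or the relative change
of the best-so-far infidelity staying below a tolerance over a sliding
window of iterations.

The "horserace" mode launches several seeds for a short checkpoint and
carries only the most promising trajectory to completion.  Because BFGS
accumulates curvature, a restarted continuation would not reproduce a
plain run; the winner is therefore re-run from its seed with the full
budget, which reproduces its checkpoint trajectory exactly and then
continues it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._engine import aggregate_cost_grad
from .model import Pulse, PulseSpec, validate_spec

__all__ = [
    "OptimizerOptions",
    "HorseraceOptions",
    "OptimizationResult",
    "init_phases",
    "optimize",
    "horserace",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HorseraceOptions:
    """Multi-seed mode: n_seeds short runs, best-at-checkpoint continues."""

    n_seeds: int = 50
    checkpoint_iterations: int = 100


@dataclass(frozen=True)
class OptimizerOptions:
    seed: int = 0
    max_iterations: int = 2000
    rel_tolerance: float = 1e-9  # relative best-so-far change over the window
    rel_window: int = 10
    grad_tolerance: float = 1e-10
    horserace: HorseraceOptions | None = None


@dataclass
class OptimizationResult:
    pulse: Pulse
    infidelity: float
    trace: list[tuple[int, float]]  # (iteration, best-so-far infidelity)
    seed: int
    converged: bool
    n_iterations: int = 0
    message: str = ""
    horserace_seeds: list[int] = field(default_factory=list)


def init_phases(n: int, seed: int) -> np.ndarray:
    """n starting phases drawn uniformly on [0, 2*pi), deterministically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.random.default_rng(seed).uniform(0.0, 2.0 * np.pi, size=n)


class _CostRecorder:
    """Wraps the aggregate cost, tracking the best phases ever evaluated."""

    def __init__(self, spec: PulseSpec):
        self.spec = spec
        self.best_value = np.inf
        self.best_phases: np.ndarray | None = None
        self.n_evals = 0

    def __call__(self, phases: np.ndarray):
        value, grad = aggregate_cost_grad(phases, self.spec)
        if not np.isfinite(value):
            raise FloatingPointError(
                f"infidelity evaluation failed after {self.n_evals} evaluations"
            )
        self.n_evals += 1
        if value < self.best_value:
            self.best_value = value
            self.best_phases = phases.copy()
        return value, grad


def optimize(spec: PulseSpec, opts: OptimizerOptions | None = None) -> OptimizationResult:
    """Minimize the aggregate infidelity over element phases.

    Deterministic: identical (spec, opts) give identical results up to the
    floating-point reproducibility of the line search.
    """
    opts = opts or OptimizerOptions()
    spec, warnings = validate_spec(spec)
    for w in warnings:
        logger.warning("%s", w)
    recorder = _CostRecorder(spec)
    x0 = init_phases(spec.n_elements, opts.seed)

    trace: list[tuple[int, float]] = []
    best_so_far = [np.inf]
    stop_reason = [""]

    def callback(intermediate_result):
        it = len(trace)
        best_so_far[0] = min(best_so_far[0], float(intermediate_result.fun))
        trace.append((it, best_so_far[0]))
        logger.debug("iter %d infidelity %.3e", it, best_so_far[0])
        w = opts.rel_window
        if len(trace) > w:
            old = trace[-1 - w][1]
            new = trace[-1][1]
            denom = max(abs(old), 1e-300)
            if (old - new) / denom < opts.rel_tolerance:
                stop_reason[0] = "relative-change tolerance reached"
                raise StopIteration

    try:
        res = minimize(
            recorder,
            x0,
            jac=True,
            method="BFGS",
            callback=callback,
            options={"maxiter": opts.max_iterations, "gtol": opts.grad_tolerance},
        )
        message = stop_reason[0] or str(res.message)
        converged = bool(res.success) or bool(stop_reason[0])
    except FloatingPointError as err:
        raise RuntimeError(f"cost evaluation failure during optimization: {err}") from err

    final_phases = recorder.best_phases if recorder.best_phases is not None else x0
    final_value = recorder.best_value
    best_so_far[0] = min(best_so_far[0], final_value)
    trace.append((len(trace), best_so_far[0]))
    return OptimizationResult(
        pulse=Pulse(spec=spec, phases=final_phases),
        infidelity=float(final_value),
        trace=trace,
        seed=opts.seed,
        converged=converged,
        n_iterations=len(trace) - 1,
        message=message,
    )


def horserace(spec: PulseSpec, opts: OptimizerOptions) -> OptimizationResult:
    """Run n_seeds short optimizations (seeds seed, seed+1, ...), then carry
    the best-at-checkpoint seed to completion.  Ties break to the lowest
    seed.  With n_seeds=1 this is bitwise identical to :func:`optimize`."""
    if opts.horserace is None:
        raise ValueError("OptimizerOptions.horserace must be set")
    hr = opts.horserace
    if hr.n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    seeds = [opts.seed + k for k in range(hr.n_seeds)]
    if hr.n_seeds == 1:
        result = optimize(spec, _with(opts, seed=seeds[0], horserace=None))
        result.horserace_seeds = seeds
        return result

    checkpoint_scores: list[float] = []
    for s in seeds:
        short = optimize(
            spec,
            _with(opts, seed=s, max_iterations=hr.checkpoint_iterations, horserace=None),
        )
        checkpoint_scores.append(short.infidelity)
        logger.info("horserace seed %d checkpoint infidelity %.3e", s, short.infidelity)
    winner = seeds[int(np.argmin(checkpoint_scores))]  # argmin takes first == lowest seed
    result = optimize(spec, _with(opts, seed=winner, horserace=None))
    result.horserace_seeds = seeds
    result.message = (
        f"horserace winner seed {winner} "
        f"(checkpoint infidelity {min(checkpoint_scores):.3e}); " + result.message
    )
    return result


def _with(opts: OptimizerOptions, **kw) -> OptimizerOptions:
    d = {
        "seed": opts.seed,
        "max_iterations": opts.max_iterations,
        "rel_tolerance": opts.rel_tolerance,
        "rel_window": opts.rel_window,
        "grad_tolerance": opts.grad_tolerance,
        "horserace": opts.horserace,
    }
    d.update(kw)
    return OptimizerOptions(**d)
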