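"""Continuous Jellyfish Search Optimizer (JSO).

A swarm metaheuristic for box-constrained minimisation. Each member of the
population ("jellyfish") is a point in the search box. At every iteration a
time-control value

    c(t) = (1 - t / Maxt) * (2*rand - 1)

is drawn per member. When c(t) exceeds a threshold (0.5 by default) the
member drifts with the ocean current toward the best-known solution,

    x <- x + r1 * (x* - beta * r2 * mu),

where ``x*`` is the best position seen so far, ``mu`` the population mean and
``beta`` (default 3) the current-strength coefficient. Otherwise the member
performs a group move: either a passive local step scaled by ``gamma``
(default 0.1) times the box width, or an active step toward a random partner
with a lower cost (and away from a partner with a higher one). The envelope
of c(t) shrinks to zero as t approaches Maxt, so ocean-current drift and
passive exploration both fade out and the swarm contracts around good
solutions.

The best-so-far candidate is tracked with global elitism, and by default a
member only adopts a proposed move that improves its own cost (greedy
replacement; see :class:`JSOParams`), so the reported optimum can only
improve and the swarm contracts as exploration fades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Objective = Callable[[np.ndarray], float]

BOUNDARY_MODES = ("clip", "reflect", "wrap")
INIT_MODES = ("uniform", "chaotic")
REPLACEMENT_MODES = ("greedy", "always")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box of decision variables.

    ``lower`` and ``upper`` are vectors of equal length; a dimension may be
    degenerate (lower == upper), in which case every sample collapses onto
    that point.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lower and upper must be 1-d vectors of equal length")
        if lo.size < 1:
            raise ValueError("search space needs at least one dimension")
        if np.any(lo > hi):
            raise ValueError("lower bound exceeds upper bound in some dimension")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


@dataclass(frozen=True)
class JSOParams:
    """Run parameters for the optimizer.

    beta is the ocean-current strength (usually 3), gamma the passive-motion
    coefficient (usually 0.1). ``switch_threshold`` is compared with c(t) to
    choose between ocean-current and group moves. ``abs_time_control``
    selects |c(t)| instead of the signed value. ``boundary_mode`` decides how
    out-of-box proposals are repaired; ``init_mode`` chooses uniform random
    or logistic-chaotic-map initialisation.

    ``replacement`` controls whether a proposed move overwrites the member
    only when it improves its cost ("greedy", the default) or always
    ("always"). Greedy replacement lets the swarm contract onto good
    solutions and is what makes the optimizer converge to fine tolerances;
    with unconditional updates the away-from-worse active moves keep
    re-inflating the swarm and progress stalls once the ocean-current phase
    ends. Global-best elitism is tracked separately in either mode.
    """

    pop_size: int = 30
    max_iter: int = 100
    beta: float = 3.0
    gamma: float = 0.1
    switch_threshold: float = 0.5
    abs_time_control: bool = False
    boundary_mode: str = "clip"
    init_mode: str = "uniform"
    replacement: str = "greedy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be at least 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0.0 < self.switch_threshold < 1.0:
            raise ValueError("switch_threshold must lie in (0, 1)")
        if self.boundary_mode not in BOUNDARY_MODES:
            raise ValueError(f"boundary_mode must be one of {BOUNDARY_MODES}")
        if self.init_mode not in INIT_MODES:
            raise ValueError(f"init_mode must be one of {INIT_MODES}")
        if self.replacement not in REPLACEMENT_MODES:
            raise ValueError(f"replacement must be one of {REPLACEMENT_MODES}")


@dataclass
class Candidate:
    """A position in the search box with its (optionally evaluated) cost."""

    position: np.ndarray
    cost: float | None = None

    def copy(self) -> "Candidate":
        return Candidate(self.position.copy(), self.cost)


@dataclass
class Swarm:
    """Population of candidates plus the elitist best-so-far solution."""

    members: list[Candidate]
    best: Candidate

    @property
    def mean_position(self) -> np.ndarray:
        return np.mean([m.position for m in self.members], axis=0)

    @property
    def mean_cost(self) -> float:
        return float(np.mean([m.cost for m in self.members]))


@dataclass(frozen=True)
class TraceRecord:
    iteration: int
    best_cost: float
    mean_cost: float


# ---------------------------------------------------------------------------
# Elementary moves
# ---------------------------------------------------------------------------

def ocean_current_step(
    x: np.ndarray,
    best: np.ndarray,
    mean: np.ndarray,
    beta: float,
    draws: tuple[float, float],
) -> np.ndarray:
    """Drift with the ocean current: ``x + r1*(best - beta*r2*mean)``.

    The two scalar uniform draws are applied to the whole vector. No
    boundary handling happens here.
    """
    r1, r2 = draws
    return x + r1 * (best - beta * r2 * mean)


def passive_step(
    x: np.ndarray, space: SearchSpace, gamma: float, draw: float
) -> np.ndarray:
    """Local exploration around the member's own position.

    ``x + gamma * r * (upper - lower)`` elementwise; the step is a fraction
    of the box width, so degenerate dimensions never move.
    """
    return x + gamma * draw * space.width


def active_step(
    xi: np.ndarray, cost_i: float, xj: np.ndarray, cost_j: float, draw: float
) -> np.ndarray:
    """Move relative to a random partner based on relative solution quality.

    Toward the partner when the partner is strictly better (lower cost),
    away from it otherwise — the food-seeking semantics of the swarm.
    """
    if cost_j < cost_i:
        return xi + draw * (xj - xi)
    return xi + draw * (xi - xj)


def time_control(t: int, max_iter: int, draw: float, abs_mode: bool = False) -> float:
    """Time-control value c(t) = (1 - t/Maxt) * (2*rand - 1).

    Its envelope shrinks linearly to zero at t = Maxt. With ``abs_mode`` the
    absolute value is returned. The caller compares the result against the
    switch threshold: above -> ocean-current move, otherwise group move.
    """
    if max_iter == 0:
        raise ValueError("max_iter must be positive in time_control")
    ct = (1.0 - t / max_iter) * (2.0 * draw - 1.0)
    return abs(ct) if abs_mode else ct


def apply_boundary(x: np.ndarray, space: SearchSpace, mode: str) -> np.ndarray:
    """Repair an out-of-box proposal so the result lies inside the box.

    clip: coordinate-wise clamp; reflect: fold the overshoot back into the
    box (triangular fold, period twice the width); wrap: toroidal re-entry.
    """
    lo, hi, w = space.lower, space.upper, space.width
    if mode == "clip":
        return np.clip(x, lo, hi)
    if mode == "reflect":
        out = np.where(w > 0, x, lo)
        with np.errstate(invalid="ignore", divide="ignore"):
            y = np.mod(out - lo, np.where(w > 0, 2 * w, 1.0))
            folded = np.where(y > w, 2 * w - y, y)
        return np.where(w > 0, lo + folded, lo)
    if mode == "wrap":
        with np.errstate(invalid="ignore", divide="ignore"):
            wrapped = lo + np.mod(x - lo, np.where(w > 0, w, 1.0))
        return np.where(w > 0, wrapped, lo)
    raise ValueError(f"unknown boundary mode {mode!r}; expected one of {BOUNDARY_MODES}")


# ---------------------------------------------------------------------------
# Population machinery
# ---------------------------------------------------------------------------

def _evaluate(objective: Objective, x: np.ndarray, context: str) -> float:
    c = float(objective(x))
    if not np.isfinite(c):
        raise ValueError(f"non-finite objective value {c!r} at {x!r} ({context})")
    return c


def init_swarm(
    space: SearchSpace,
    params: JSOParams,
    objective: Objective,
    rng: np.random.Generator | None = None,
    seed_positions: Sequence[np.ndarray] | None = None,
) -> Swarm:
    """Draw the initial population and evaluate it.

    Positions are independent uniform draws within the box (or a logistic
    chaotic map stretched onto the box when ``init_mode == 'chaotic'``).
    ``seed_positions`` optionally replaces the first members with given
    points (clamped to the box), guaranteeing they are evaluated.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n, d = params.pop_size, space.dim
    if params.init_mode == "chaotic":
        # logistic map x_{k+1} = 4 x (1 - x), seeded away from fixed points
        u = np.empty((n, d))
        state = rng.uniform(0.05, 0.95, size=d)
        for i in range(n):
            state = 4.0 * state * (1.0 - state)
            u[i] = state
    else:
        u = rng.random((n, d))
    positions = space.lower + u * space.width
    if seed_positions is not None:
        for i, p in enumerate(seed_positions):
            if i >= n:
                break
            positions[i] = np.clip(np.asarray(p, dtype=float), space.lower, space.upper)
    members = [
        Candidate(positions[i], _evaluate(objective, positions[i], "initialisation"))
        for i in range(n)
    ]
    best = min(members, key=lambda m: m.cost).copy()
    return Swarm(members=members, best=best)


def optimize(
    objective: Objective,
    space: SearchSpace,
    params: JSOParams,
    seed_positions: Sequence[np.ndarray] | None = None,
) -> tuple[Candidate, list[TraceRecord]]:
    """Run the Jellyfish Search Optimizer.

    Per member and iteration the scalar draws are consumed in a fixed,
    documented order — c(t) draw, then (for a group move) the
    passive-vs-active branch draw, then the step draws — so a run is fully
    reproducible from ``params.seed``.

    The passive/active branch inside a group move is tied to the same
    time-control quantity: with u ~ U(0,1), the passive step is taken when
    u > 1 - c(t), so passive local search decays as c(t) shrinks.

    Returns the elitist best candidate and one trace record per iteration;
    the traced best cost is non-increasing.
    """
    rng = np.random.default_rng(params.seed)
    swarm = init_swarm(space, params, objective, rng=rng,
                       seed_positions=seed_positions)
    best = swarm.best
    trace: list[TraceRecord] = []
    n = params.pop_size

    for t in range(1, params.max_iter + 1):
        mu = swarm.mean_position
        for i, member in enumerate(swarm.members):
            ct = time_control(t, params.max_iter, rng.random(),
                              params.abs_time_control)
            if ct > params.switch_threshold:
                proposal = ocean_current_step(
                    member.position, best.position, mu, params.beta,
                    (rng.random(), rng.random()),
                )
            else:
                u = rng.random()
                if u > 1.0 - ct:
                    proposal = passive_step(member.position, space,
                                            params.gamma, rng.random())
                else:
                    j = int(rng.integers(n - 1))
                    if j >= i:
                        j += 1
                    partner = swarm.members[j]
                    proposal = active_step(member.position, member.cost,
                                           partner.position, partner.cost,
                                           rng.random())
            proposal = apply_boundary(proposal, space, params.boundary_mode)
            cost = _evaluate(objective, proposal, f"iteration {t}")
            if params.replacement == "always" or cost < member.cost:
                member.position, member.cost = proposal, cost
            if cost < best.cost:
                best = Candidate(proposal.copy(), cost)
        trace.append(TraceRecord(iteration=t, best_cost=best.cost,
                                 mean_cost=swarm.mean_cost))
    logger.debug("optimize finished: best cost %.6g after %d iterations",
                 best.cost, params.max_iter)
    return best, trace


def trace_frame(trace: Sequence[TraceRecord]):
    """Iteration trace as a DataFrame with columns iteration,best_cost,mean_cost."""
    import pandas as pd

    return pd.DataFrame(
        {
            "iteration": [r.iteration for r in trace],
            "best_cost": [r.best_cost for r in trace],
            "mean_cost": [r.mean_cost for r in trace],
        }
    )
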