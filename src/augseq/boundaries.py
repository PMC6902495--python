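"""Error-spending group-sequential boundaries on the canonical joint
distribution of sequential z-statistics.

Sequential statistics S_1..S_W computed at information levels I_1..I_W are
multivariate normal with Cov(S_v, S_w) = sqrt(I_v / I_w) and drift
E[S_w] = theta * sqrt(I_w).  Boundaries are found by a stagewise recursion
that propagates the sub-density of the non-stopped statistic on a z-grid
(Simpson quadrature) and solves each stage's stopping probability for the
boundary by root bracketing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .model import ModelError

Z_SPAN = 7.5  # half-width of the quadrature grid around the stage mean
DEFAULT_NODES = 601  # Simpson nodes per stage (odd)
ROOT_TOL = 1e-10


class SpendingError(ModelError):
    """Invalid error-spending specification."""


class BoundaryError(RuntimeError):
    """Numerical failure while solving stopping boundaries."""


@dataclass(frozen=True)
class SpendingPlan:
    """Cumulative lower (futility) and upper (efficacy) error spending over
    W analyses, for a one-sided test at overall level ``alpha``."""

    alphaL_cum: np.ndarray
    alphaU_cum: np.ndarray
    alpha: float = 0.025

    def __post_init__(self) -> None:
        aL = np.asarray(self.alphaL_cum, dtype=float)
        aU = np.asarray(self.alphaU_cum, dtype=float)
        if aL.ndim != 1 or aU.shape != aL.shape or aL.size < 1:
            raise SpendingError("spending vectors must be 1-D and of equal length W >= 1")
        if not 0 < self.alpha < 1:
            raise SpendingError("alpha must lie in (0, 1)")
        for name, a in (("lower", aL), ("upper", aU)):
            if np.any(a < 0) or np.any(a > 1):
                bad = int(np.argmax((a < 0) | (a > 1)))
                raise SpendingError(f"{name} spending entry {bad} outside [0, 1]: {a[bad]}")
            if np.any(np.diff(a) < -1e-12):
                bad = int(np.argmax(np.diff(a) < -1e-12)) + 1
                raise SpendingError(f"{name} spending decreases at analysis {bad}")
        if abs(aU[-1] - self.alpha) > 1e-9:
            raise SpendingError(f"upper spending must end at alpha={self.alpha}, got {aU[-1]}")
        if abs(aL[-1] - (1.0 - self.alpha)) > 1e-9:
            raise SpendingError(f"lower spending must end at 1-alpha={1 - self.alpha}, got {aL[-1]}")
        if np.any(aL[:-1] + aU[:-1] >= 1.0):
            bad = int(np.argmax(aL[:-1] + aU[:-1] >= 1.0))
            raise SpendingError(f"lower + upper spending reach 1 before the final analysis (analysis {bad})")
        object.__setattr__(self, "alphaL_cum", aL)
        object.__setattr__(self, "alphaU_cum", aU)

    @property
    def W(self) -> int:
        return self.alphaL_cum.size

    @property
    def lower_increments(self) -> np.ndarray:
        return np.diff(np.concatenate(([0.0], self.alphaL_cum)))

    @property
    def upper_increments(self) -> np.ndarray:
        return np.diff(np.concatenate(([0.0], self.alphaU_cum)))

    @classmethod
    def from_increments(cls, lower, upper, alpha: float = 0.025) -> "SpendingPlan":
        lo = np.cumsum(np.asarray(lower, dtype=float))
        up = np.cumsum(np.asarray(upper, dtype=float))
        return cls(alphaL_cum=lo, alphaU_cum=up, alpha=alpha)


def validate_spending(lower, upper, alpha: float = 0.025, cumulative: bool = True) -> SpendingPlan:
    """Normalize a spending specification to a cumulative SpendingPlan.

    With ``cumulative=False`` the vectors are per-look increments; increments
    summing above their endpoint (alpha / 1 - alpha) are rejected.
    """
    if cumulative:
        return SpendingPlan(alphaL_cum=np.asarray(lower, float), alphaU_cum=np.asarray(upper, float), alpha=alpha)
    lo = np.asarray(lower, dtype=float)
    up = np.asarray(upper, dtype=float)
    if np.any(lo < 0) or np.any(up < 0):
        raise SpendingError("spending increments must be non-negative")
    if lo.sum() > 1.0 - alpha + 1e-9:
        raise SpendingError(f"lower increments sum to {lo.sum():.6g} > 1 - alpha")
    if up.sum() > alpha + 1e-9:
        raise SpendingError(f"upper increments sum to {up.sum():.6g} > alpha")
    return SpendingPlan.from_increments(lo, up, alpha=alpha)


@dataclass(frozen=True)
class InformationSchedule:
    """Planned information levels (1/variance units) at each analysis."""

    info: np.ndarray

    def __post_init__(self) -> None:
        info = np.asarray(self.info, dtype=float)
        if info.ndim != 1 or info.size < 1:
            raise ModelError("information schedule must be a non-empty vector")
        if np.any(info <= 0):
            raise ModelError("information levels must be > 0")
        if np.any(np.diff(info) <= 0):
            raise ModelError("information levels must be strictly increasing")
        object.__setattr__(self, "info", info)

    @property
    def W(self) -> int:
        return self.info.size

    def fractions(self) -> np.ndarray:
        return self.info / self.info[-1]


@dataclass(frozen=True)
class BoundarySet:
    """Lower/upper z-scale stopping boundaries per analysis.  Infinite
    sentinels mark analyses where no stopping of that kind can occur; the
    final analysis has a single critical value (lower == upper)."""

    lower: np.ndarray
    upper: np.ndarray
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        up = np.asarray(self.upper, dtype=float)
        if lo.shape != up.shape or lo.ndim != 1 or lo.size < 1:
            raise ModelError("lower/upper boundaries must be equal-length vectors")
        if np.any(lo[:-1] >= up[:-1]):
            raise ModelError("lower boundary must be below upper boundary before the final analysis")
        if not (lo[-1] == up[-1] or abs(lo[-1] - up[-1]) < 1e-9):
            raise ModelError("final analysis must have a single critical value (lower == upper)")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @property
    def W(self) -> int:
        return self.lower.size


@dataclass(frozen=True)
class CrossingProbabilities:
    """Per-analysis stopping probabilities for a given drift."""

    lower: np.ndarray  # P(stop below the lower boundary at analysis w)
    upper: np.ndarray  # P(stop at/above the upper boundary at analysis w)

    @property
    def total(self) -> float:
        return float(self.lower.sum() + self.upper.sum())


def _simpson_weights(grid: np.ndarray) -> np.ndarray:
    n = grid.size
    if n < 3 or n % 2 == 0:
        raise ValueError("Simpson grid needs an odd number of nodes >= 3")
    h = (grid[-1] - grid[0]) / (n - 1)
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * h / 3.0


class _Stage:
    """Sub-density of the non-stopped z-statistic after a given analysis."""

    def __init__(self, grid: np.ndarray, dens: np.ndarray, info: float):
        self.grid = grid
        self.dens = dens
        self.info = info
        self.weights = _simpson_weights(grid)

    @property
    def mass(self) -> float:
        return float(self.weights @ self.dens)


def _first_stage(lower: float, upper: float, info: float, theta: float, nodes: int) -> _Stage:
    mean = theta * np.sqrt(info)
    lo = max(lower, mean - Z_SPAN)
    hi = min(upper, mean + Z_SPAN)
    if hi <= lo:  # continuation region carries (numerically) no mass
        grid = np.linspace(lo, lo + 1e-9, nodes)
        return _Stage(grid, np.zeros(nodes), info)
    grid = np.linspace(lo, hi, nodes if nodes % 2 else nodes + 1)
    return _Stage(grid, norm.pdf(grid - mean), info)


def _transition(stage: _Stage, info_next: float, theta: float):
    """Return (p_lower, p_upper, propagate) callables for the next stage."""
    sq_prev = np.sqrt(stage.info)
    sq = np.sqrt(info_next)
    delta = info_next - stage.info
    sd = np.sqrt(delta)
    base = stage.grid * sq_prev + theta * delta
    wdens = stage.weights * stage.dens

    def p_lower(l: float) -> float:
        return float(wdens @ norm.cdf((l * sq - base) / sd))

    def p_upper(u: float) -> float:
        return float(wdens @ norm.sf((u * sq - base) / sd))

    def propagate(lower: float, upper: float, nodes: int) -> _Stage:
        mean = theta * sq
        lo = max(lower, mean - Z_SPAN)
        hi = min(upper, mean + Z_SPAN)
        if hi <= lo:
            grid = np.linspace(lo, lo + 1e-9, nodes)
            return _Stage(grid, np.zeros(grid.size), info_next)
        grid = np.linspace(lo, hi, nodes if nodes % 2 else nodes + 1)
        dens = (wdens[None, :] * norm.pdf((grid[:, None] * sq - base[None, :]) / sd)).sum(axis=1) * sq / sd
        return _Stage(grid, dens, info_next)

    return p_lower, p_upper, propagate


def _solve_root(fun, target: float, decreasing: bool, what: str) -> float:
    """Solve fun(z) = target for z in [-12, 12]; fun monotone."""
    lo, hi = -12.0, 12.0
    flo, fhi = fun(lo) - target, fun(hi) - target
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        if flo > 0 and fhi > 0:
            # the target is below even the extreme tail probability at |z| = 12;
            # the boundary is effectively unreachable
            return math.inf if decreasing else -math.inf
        raise BoundaryError(
            f"cannot bracket {what} boundary: f(-12)={flo + target:.3g}, f(12)={fhi + target:.3g}, "
            f"target={target:.3g} (spending exceeds the remaining probability mass)"
        )
    return float(brentq(lambda z: fun(z) - target, lo, hi, xtol=ROOT_TOL))


def compute_boundaries(
    plan: SpendingPlan,
    schedule: InformationSchedule,
    binding: bool = True,
    nodes: int = DEFAULT_NODES,
) -> BoundarySet:
    """Solve stopping boundaries so that the cumulative probabilities of
    crossing under the null match the spending plan.

    With ``binding=True`` upper boundaries account for prior futility
    stopping; with ``binding=False`` they are computed ignoring the lower
    boundaries (and the lower boundaries are then solved given the fixed
    upper ones).  The final analysis takes its critical value from the
    remaining upper spending and sets lower == upper; a diagnostic records
    how far the implied lower spending is from 1 - alpha.
    """
    if plan.W != schedule.W:
        raise ModelError(f"spending plan has {plan.W} analyses but schedule has {schedule.W}")
    if binding:
        lower, upper, diag = _solve_sequence(plan, schedule, nodes, lower_mode="solve", upper_mode="solve")
    else:
        # pass 1: upper boundaries ignoring futility stopping
        _, upper, _ = _solve_sequence(plan, schedule, nodes, lower_mode="open", upper_mode="solve")
        # pass 2: lower boundaries given the fixed upper boundaries
        lower, upper, diag = _solve_sequence(
            plan, schedule, nodes, lower_mode="solve", upper_mode="fixed", fixed_upper=upper
        )
    if abs(diag["final_lower_spend_error"]) > 1e-4:
        warnings.warn(
            "implied lower spending at the final analysis misses 1 - alpha by "
            f"{diag['final_lower_spend_error']:.2e}",
            RuntimeWarning,
        )
    return BoundarySet(lower=lower, upper=upper, diagnostics=diag)


def _solve_sequence(
    plan: SpendingPlan,
    schedule: InformationSchedule,
    nodes: int,
    lower_mode: str,
    upper_mode: str,
    fixed_upper: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    W = plan.W
    info = schedule.info
    aL = plan.lower_increments
    aU = plan.upper_increments
    lower = np.full(W, -np.inf)
    upper = np.full(W, np.inf)
    diag: dict = {"achieved_lower": np.zeros(W), "achieved_upper": np.zeros(W)}

    stage: _Stage | None = None
    for w in range(W):
        final = w == W - 1
        if w == 0:
            p_lower = lambda l: float(norm.cdf(l))  # noqa: E731 - closed forms at the first analysis
            p_upper = lambda u: float(norm.sf(u))  # noqa: E731
            propagate = lambda lo, up, nn: _first_stage(lo, up, info[0], 0.0, nn)  # noqa: E731
        else:
            p_lower, p_upper, propagate = _transition(stage, info[w], 0.0)

        if upper_mode == "fixed":
            u = float(fixed_upper[w])
        elif aU[w] <= 0:
            u = np.inf
        elif w == 0:
            u = float(norm.isf(aU[0]))  # closed form at the first analysis
        else:
            u = _solve_root(p_upper, aU[w], decreasing=True, what=f"upper (analysis {w + 1})")
        if final:
            l = u
        elif lower_mode == "open" or aL[w] <= 0:
            l = -np.inf
        elif w == 0:
            l = float(norm.ppf(aL[0]))
        else:
            l = _solve_root(p_lower, aL[w], decreasing=False, what=f"lower (analysis {w + 1})")
        if not final and l >= u:
            raise BoundaryError(f"boundaries cross at analysis {w + 1}: lower {l:.4f} >= upper {u:.4f}")
        lower[w], upper[w] = l, u
        diag["achieved_lower"][w] = p_lower(l) if np.isfinite(l) else 0.0
        diag["achieved_upper"][w] = p_upper(u) if np.isfinite(u) else 0.0
        if not final:
            stage = propagate(l, u, nodes)
    diag["final_lower_spend_error"] = float(diag["achieved_lower"][-1] - aL[-1])
    return lower, upper, diag


def crossing_probabilities(
    bounds: BoundarySet,
    schedule: InformationSchedule,
    drift: float = 0.0,
    nodes: int = DEFAULT_NODES,
) -> CrossingProbabilities:
    """Per-analysis stopping probabilities under drift ``theta``
    (E[S_w] = theta * sqrt(I_w)), by the same stagewise recursion used to
    construct boundaries.  At the final analysis the single critical value
    partitions all remaining probability, so the totals sum to one."""
    if bounds.W != schedule.W:
        raise ModelError("boundary set and schedule have different numbers of analyses")
    W = bounds.W
    info = schedule.info
    p_lo = np.zeros(W)
    p_up = np.zeros(W)
    mean0 = drift * np.sqrt(info[0])
    p_lo[0] = float(norm.cdf(bounds.lower[0] - mean0)) if np.isfinite(bounds.lower[0]) else 0.0
    p_up[0] = float(norm.sf(bounds.upper[0] - mean0)) if np.isfinite(bounds.upper[0]) else 0.0
    if W == 1:
        # single analysis: lower == upper partitions everything
        p_lo[0] = float(norm.cdf(bounds.lower[0] - mean0))
        p_up[0] = float(norm.sf(bounds.upper[0] - mean0))
        return CrossingProbabilities(lower=p_lo, upper=p_up)
    stage = _first_stage(bounds.lower[0], bounds.upper[0], info[0], drift, nodes)
    for w in range(1, W):
        p_lower, p_upper, propagate = _transition(stage, info[w], drift)
        if w == W - 1:
            p_lo[w] = p_lower(bounds.lower[w])
            p_up[w] = p_upper(bounds.upper[w])
        else:
            p_lo[w] = p_lower(bounds.lower[w]) if np.isfinite(bounds.lower[w]) else 0.0
            p_up[w] = p_upper(bounds.upper[w]) if np.isfinite(bounds.upper[w]) else 0.0
            stage = propagate(bounds.lower[w], bounds.upper[w], nodes)
    return CrossingProbabilities(lower=p_lo, upper=p_up)
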