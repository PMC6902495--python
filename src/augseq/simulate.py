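"""Virtual-trial simulation: recruitment, outcome generation, sequential
monitoring and decisions, and operating characteristics over replicates."""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .boundaries import BoundarySet, InformationSchedule, SpendingPlan, compute_boundaries
from .data import DEFAULT_LAGS, TrialDataset
from .effect import expected_information, final_information, get_nuisance_estimator, summarize
from .engine import CONTINUE, STOP_EFFICACY, STOP_FUTILITY, decide, information_events
from .model import EndpointModel, LookCounts, ModelError


@dataclass(frozen=True)
class RecruitmentSchedule:
    """Multicentre Poisson recruitment with a staged centre-opening ramp.

    ``centres[m]`` is the number of open centres in month ``m + 1``; the last
    entry persists until the cap is reached (or ``max_months`` passes).
    """

    centres: tuple
    rate: float
    cap: int | None = None
    max_months: int = 240

    def __post_init__(self) -> None:
        c = tuple(int(x) for x in self.centres)
        if not c or any(x < 0 for x in c) or any(b < a for a, b in zip(c, c[1:])):
            raise ModelError("centre counts must be non-negative and non-decreasing to the plateau")
        if self.rate < 0:
            raise ModelError("recruitment rate must be >= 0")
        object.__setattr__(self, "centres", c)

    def centres_at(self, month: int) -> int:
        """Open centres during calendar month ``month`` (1-based)."""
        return self.centres[min(month, len(self.centres)) - 1]

    def exposure(self, months: int) -> int:
        """Total centre-months of recruitment over the first ``months``."""
        return sum(self.centres_at(m) for m in range(1, months + 1))


def start_recruitment(target: int = 170, months: int = 24) -> RecruitmentSchedule:
    """The START:REACTS recruitment model: ramp 1,2,3,6,9,12 centres over the
    first six months, then 15 centres, with a constant per-centre rate chosen
    so the target accrues over the planned months (303 centre-months)."""
    schedule = RecruitmentSchedule(centres=(1, 2, 3, 6, 9, 12, 15), rate=0.0, cap=target)
    rate = target / schedule.exposure(months)
    return replace(schedule, rate=rate)


def simulate_recruitment(schedule: RecruitmentSchedule, rng: np.random.Generator) -> np.ndarray:
    """Sorted entry times (months).  Monthly counts are independent Poisson
    with mean rate x open centres; entries fall uniformly within their month;
    recruitment stops once the cap is reached."""
    entries: list[np.ndarray] = []
    total = 0
    cap = schedule.cap if schedule.cap is not None else np.inf
    for month in range(1, schedule.max_months + 1):
        if total >= cap:
            break
        n = int(rng.poisson(schedule.rate * schedule.centres_at(month)))
        if n:
            entries.append(month - 1 + rng.random(n))
            total += n
    if not entries:
        return np.empty(0)
    out = np.sort(np.concatenate(entries))
    if np.isfinite(cap):
        out = out[: int(cap)]
    return out


def permuted_block_arms(n: int, rng: np.random.Generator) -> np.ndarray:
    """1:1 allocation in permuted blocks of two, in entry order."""
    n_blocks = (n + 1) // 2
    blocks = np.tile([0, 1], (n_blocks, 1))
    flip = rng.random(n_blocks) < 0.5
    blocks[flip] = blocks[flip][:, ::-1]
    return blocks.reshape(-1)[:n]


@dataclass(frozen=True)
class ScenarioTruth:
    """True generative model for a simulation scenario (the design may assume
    a different model for scheduling)."""

    model: EndpointModel
    dropout: float = 0.0  # per-follow-up probability of dropping out (default off)

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ModelError("dropout probability must lie in [0, 1)")


def simulate_outcomes(
    truth: ScenarioTruth,
    entries: np.ndarray,
    arms: np.ndarray,
    rng: np.random.Generator,
    lags: tuple = DEFAULT_LAGS,
) -> TrialDataset:
    """One multivariate-normal outcome draw per participant, observable at
    entry + lag per endpoint."""
    model = truth.model
    n = entries.size
    cov = model.covariance()
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(model.K))
    values = rng.standard_normal((n, model.K)) @ chol.T
    values[arms == 0] += model.means_control
    values[arms == 1] += model.means_active
    if truth.dropout > 0:
        drop = rng.random((n, model.K)) < truth.dropout
        gone = np.cumsum(drop, axis=1) > 0  # once dropped, later outcomes missing too
        values[gone] = np.nan
    return TrialDataset(values=values, arms=arms, entries=entries, lags=lags)


@dataclass(frozen=True)
class DesignConfig:
    """A complete sequential design: spending, planned per-arm counts at the
    early looks, final size, assumed nuisance model and policies."""

    plan: SpendingPlan
    look_counts: tuple  # per early look: per-arm (N_1, ..., N_K)
    final_n_per_arm: int
    assumed_model: EndpointModel
    recruitment: RecruitmentSchedule | None = None
    lags: tuple = DEFAULT_LAGS
    binding: bool = True
    looks_after_recruitment: bool = True
    monitor_start: float = 18.0
    recalc_boundaries: bool = False
    nuisance_method: str = "regression"

    def __post_init__(self) -> None:
        lc = tuple(tuple(int(x) for x in row) for row in self.look_counts)
        if self.plan.W != len(lc) + 1:
            raise ModelError(
                f"spending plan has {self.plan.W} analyses but {len(lc)} early looks are configured"
            )
        for a, b in zip(lc, lc[1:]):
            if any(y < x for x, y in zip(a, b)):
                raise ModelError("per-look counts must be non-decreasing across looks")
        for row in lc:
            LookCounts.equal_arms(row)  # validates nesting
        if self.final_n_per_arm < max((row[-1] for row in lc), default=1):
            raise ModelError("final per-arm N must be at least the last look's long-term count")
        object.__setattr__(self, "look_counts", lc)

    @property
    def n_early_looks(self) -> int:
        return len(self.look_counts)


def design_schedule(design: DesignConfig) -> InformationSchedule:
    """Planned information at each analysis: the early looks via the
    augmented-estimator variance with assumed nuisance values, the final
    analysis at N/(2 sigma_K^2)."""
    infos = [
        expected_information(LookCounts.equal_arms(row), design.assumed_model)
        for row in design.look_counts
    ]
    infos.append(final_information(design.final_n_per_arm, float(design.assumed_model.sigmas[-1])))
    return InformationSchedule(np.asarray(infos))


def design_boundaries(design: DesignConfig, nodes: int | None = None) -> tuple[InformationSchedule, BoundarySet]:
    schedule = design_schedule(design)
    kwargs = {} if nodes is None else {"nodes": nodes}
    bounds = compute_boundaries(design.plan, schedule, binding=design.binding, **kwargs)
    return schedule, bounds


@dataclass(frozen=True)
class LookRecord:
    look: int
    time: float
    counts: LookCounts
    info_observed: float
    info_planned: float
    S: float
    lower: float
    upper: float
    verdict: str


@dataclass(frozen=True)
class TrialTrace:
    """One simulated trial: per-look records and the overall outcome."""

    looks: tuple
    stopped_at: int | None  # 0-based early-look index, None if no early stop
    stop_reason: str | None
    randomised_at_stop: int
    total_randomised: int
    final_S: float | None
    rejected: bool
    recruitment_end: float
    abandoned_looks: tuple

    @property
    def sample_size(self) -> int:
        return self.randomised_at_stop if self.stopped_at is not None else self.total_randomised


def run_simulated_trial(
    design: DesignConfig,
    truth: ScenarioTruth,
    rng: np.random.Generator,
    schedule: InformationSchedule | None = None,
    bounds: BoundarySet | None = None,
) -> TrialTrace:
    """Simulate one trial end to end: recruit, draw outcomes, monitor
    information, trigger looks, decide, and (if never stopped) run the final
    analysis on the complete data."""
    if bounds is None or schedule is None:
        schedule, bounds = design_boundaries(design)
    recruitment = design.recruitment if design.recruitment is not None else start_recruitment(2 * design.final_n_per_arm)
    entries = simulate_recruitment(recruitment, rng)
    arms = permuted_block_arms(entries.size, rng)
    data = simulate_outcomes(truth, entries, arms, rng, lags=design.lags)
    recruitment_end = float(entries[-1]) if entries.size else 0.0

    estimator = get_nuisance_estimator(design.nuisance_method)
    looks: list[LookRecord] = []
    abandoned: list[int] = []
    stopped_at: int | None = None
    stop_reason: str | None = None
    stop_time = math.inf

    w = 0
    n_looks = design.n_early_looks
    events = information_events(data, design.assumed_model, start_time=design.monitor_start)
    for trigger, info in events:
        if trigger < design.monitor_start:
            continue
        while w < n_looks and info >= schedule.info[w] and stopped_at is None:
            target = schedule.info[w]
            if not design.looks_after_recruitment and trigger > recruitment_end:
                abandoned.append(w)
                w += 1
                continue
            snapshot = data.at(trigger)
            nuisance = estimator(snapshot, design.assumed_model)
            summary = summarize(snapshot, nuisance)
            lower, upper = float(bounds.lower[w]), float(bounds.upper[w])
            verdict = decide(summary.S, lower, upper)
            looks.append(
                LookRecord(
                    look=w, time=trigger, counts=snapshot.counts(), info_observed=summary.info,
                    info_planned=float(target), S=summary.S, lower=lower, upper=upper, verdict=verdict,
                )
            )
            if verdict != CONTINUE:
                stopped_at = w
                stop_reason = verdict
                stop_time = trigger
            w += 1
        if stopped_at is not None or w >= n_looks:
            events.close()
            break
    abandoned.extend(range(w, n_looks) if stopped_at is None and w < n_looks else [])

    final_S = None
    rejected = stop_reason == STOP_EFFICACY
    if stopped_at is None:
        nuisance = estimator(data, design.assumed_model)
        summary = summarize(data, nuisance)
        final_S = summary.S
        rejected = final_S >= float(bounds.upper[-1])

    randomised_at_stop = int(np.searchsorted(entries, stop_time, side="right")) if stopped_at is not None else entries.size
    return TrialTrace(
        looks=tuple(looks),
        stopped_at=stopped_at,
        stop_reason=stop_reason,
        randomised_at_stop=randomised_at_stop,
        total_randomised=int(entries.size),
        final_S=final_S,
        rejected=rejected,
        recruitment_end=recruitment_end,
        abandoned_looks=tuple(abandoned),
    )


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Stopping probabilities, power and expected sample size over replicated
    simulated trials, with Monte Carlo standard errors."""

    p_futility_cum: np.ndarray  # cumulative P(stop for futility by look w)
    p_efficacy: float  # P(early efficacy stop)
    p_final: float  # P(rejection at the final analysis)
    power: float  # p_efficacy + p_final
    ess: float
    ess_formula: float
    replicates: int
    se_futility_cum: np.ndarray
    se_power: float
    frac_recruited_before_last_look: float
    mean_n_final_at_looks: np.ndarray  # mean per-arm long-term count at each look trigger
    seed: int | None = None

    def as_dict(self) -> dict:
        return {
            "p_futility_cum": self.p_futility_cum.tolist(),
            "p_efficacy": self.p_efficacy,
            "p_final": self.p_final,
            "power": self.power,
            "ess": self.ess,
            "ess_formula": self.ess_formula,
            "replicates": self.replicates,
            "se_futility_cum": self.se_futility_cum.tolist(),
            "se_power": self.se_power,
            "frac_recruited_before_last_look": self.frac_recruited_before_last_look,
            "mean_n_final_at_looks": self.mean_n_final_at_looks.tolist(),
            "seed": self.seed,
        }


def expected_sample_size(stop_probs: np.ndarray, mean_randomised: np.ndarray, full_size: float) -> float:
    """ESS from per-look stop probabilities and the mean number randomised at
    each look trigger: sum_w P(stop at w) E[randomised at w] + P(no stop) full."""
    stop_probs = np.asarray(stop_probs, dtype=float)
    mean_randomised = np.asarray(mean_randomised, dtype=float)
    p_none = 1.0 - stop_probs.sum()
    return float((stop_probs * mean_randomised).sum() + p_none * full_size)


def operating_characteristics(
    design: DesignConfig,
    truth: ScenarioTruth,
    n_reps: int,
    seed: int | None = None,
    return_traces: bool = False,
):
    """Estimate stopping probabilities, power and ESS over ``n_reps``
    independent simulated trials (one spawned RNG substream per replicate)."""
    if n_reps < 1:
        raise ModelError("n_reps must be >= 1")
    schedule, bounds = design_boundaries(design)
    W_early = design.n_early_looks
    master = np.random.SeedSequence(seed)
    streams = master.spawn(n_reps)

    fut_by_look = np.zeros(W_early)
    n_eff = 0
    n_final_reject = 0
    sizes = np.zeros(n_reps)
    randomised_at_look = np.zeros(W_early)
    stop_count_at_look = np.zeros(W_early)
    stopped_any = np.zeros(n_reps, dtype=bool)
    recruited_before_last = 0
    n_last_look = 0
    n_final_sums = np.zeros(W_early)
    n_final_obs = np.zeros(W_early)
    traces = [] if return_traces else None

    full_size = 2 * design.final_n_per_arm
    for r in range(n_reps):
        rng = np.random.default_rng(streams[r])
        trace = run_simulated_trial(design, truth, rng, schedule=schedule, bounds=bounds)
        if trace.stopped_at is not None:
            if trace.stop_reason == STOP_FUTILITY:
                fut_by_look[trace.stopped_at] += 1
            else:
                n_eff += 1
            stop_count_at_look[trace.stopped_at] += 1
            randomised_at_look[trace.stopped_at] += trace.randomised_at_stop
            stopped_any[r] = True
        elif trace.rejected:
            n_final_reject += 1
        sizes[r] = trace.sample_size
        for rec in trace.looks:
            n_final_sums[rec.look] += 0.5 * (rec.counts.n(rec.counts.K - 1, 0) + rec.counts.n(rec.counts.K - 1, 1))
            n_final_obs[rec.look] += 1
        if trace.looks and trace.looks[-1].look == W_early - 1:
            n_last_look += 1
            if trace.recruitment_end <= trace.looks[-1].time:
                recruited_before_last += 1
        if return_traces:
            traces.append(trace)

    p_fut = fut_by_look / n_reps
    p_fut_cum = np.cumsum(p_fut)
    p_eff = n_eff / n_reps
    p_final = n_final_reject / n_reps
    power = p_eff + p_final
    ess = float(sizes.mean())
    with np.errstate(invalid="ignore"):
        mean_rand = np.where(stop_count_at_look > 0, randomised_at_look / np.maximum(stop_count_at_look, 1), full_size)
    ess_formula = expected_sample_size(stop_count_at_look / n_reps, mean_rand, full_size)
    se = lambda p: math.sqrt(max(p * (1 - p), 1e-12) / n_reps)  # noqa: E731
    oc = OperatingCharacteristics(
        p_futility_cum=p_fut_cum,
        p_efficacy=p_eff,
        p_final=p_final,
        power=power,
        ess=ess,
        ess_formula=ess_formula,
        replicates=n_reps,
        se_futility_cum=np.array([se(p) for p in p_fut_cum]),
        se_power=se(power),
        frac_recruited_before_last_look=recruited_before_last / n_last_look if n_last_look else math.nan,
        mean_n_final_at_looks=np.where(n_final_obs > 0, n_final_sums / np.maximum(n_final_obs, 1), np.nan),
        seed=seed,
    )
    if return_traces:
        return oc, traces
    return oc
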