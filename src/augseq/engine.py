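"""Interim decision making on a trial dataset: information monitoring, look
triggering, boundary comparison and the overrunning (final) analysis.

The decision rule is: stop for futility iff S_w < l_w, stop for efficacy iff
S_w >= u_w, otherwise continue.  Crossing is inclusive at the upper boundary
and exclusive at the lower one, so the three verdicts partition the line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .boundaries import BoundarySet, InformationSchedule
from .data import TrialDataset
from .effect import get_nuisance_estimator, summarize
from .model import EffectSummary, EndpointModel, NuisanceEstimate

logger = logging.getLogger(__name__)

STOP_FUTILITY = "stop_futility"
STOP_EFFICACY = "stop_efficacy"
CONTINUE = "continue"

# monitoring-time guards: with fewer data than this, fall back on the
# design-assumed nuisance values rather than trusting wild early estimates
_MIN_VAR_DOF = 4
_CLAMP = 0.99


@dataclass(frozen=True)
class InterimDecision:
    look: int
    summary: EffectSummary
    lower: float
    upper: float
    verdict: str


@dataclass(frozen=True)
class OverrunResult:
    B: float
    varB: float
    p_value: float
    n_per_arm: tuple


def decide(S: float, lower: float, upper: float) -> str:
    if S >= upper:
        return STOP_EFFICACY
    if S < lower:
        return STOP_FUTILITY
    return CONTINUE


def run_interim_analysis(
    data: TrialDataset,
    look: int,
    bounds: BoundarySet,
    fallback: EndpointModel | None = None,
    time: float | None = None,
    nuisance: NuisanceEstimate | None = None,
    method: str = "regression",
) -> InterimDecision:
    """Compute S_w from the data observable at ``time`` and compare it to the
    pre-defined boundaries for ``look`` (0-based).

    Nuisance parameters are estimated from the snapshot unless supplied
    explicitly; ``method`` selects the estimator ("regression" or "moments").
    """
    if not 0 <= look < bounds.W:
        raise ValueError(f"no boundaries defined for look {look} (design has {bounds.W} analyses)")
    snapshot = data.at(time) if time is not None else data
    if nuisance is None:
        nuisance = get_nuisance_estimator(method)(snapshot, fallback)
    summary = summarize(snapshot, nuisance)
    lower, upper = float(bounds.lower[look]), float(bounds.upper[look])
    verdict = decide(summary.S, lower, upper)
    logger.info(
        "look=%d n=%s info=%.4f S=%.4f bounds=(%.4g, %.4g) verdict=%s",
        look + 1, snapshot.counts().counts.tolist(), summary.info, summary.S, lower, upper, verdict,
    )
    return InterimDecision(look=look, summary=summary, lower=lower, upper=upper, verdict=verdict)


def information_events(data: TrialDataset, fallback: EndpointModel, start_time: float = -math.inf):
    """Lazily yield ``(time, info)`` for each observed outcome value in
    calendar order, where ``info`` is 1/var(B) recomputed after the event
    from incrementally updated nuisance estimates.

    Estimation mirrors ``estimate_nuisance_regression``: the covariance
    matrix is built by stagewise arm-adjusted regressions over the nested
    complete subsets, with design-assumed conditional parameters substituted
    while a stage is data-poor; correlations are clamped to +/-0.99 before
    entering the variance formula.  Events before ``start_time`` update the
    accumulators but skip the estimate (their info is reported as 0.0), and
    abandoning the iterator abandons the remaining work.
    """
    K = data.K
    avail = data.available_times()
    arms = data.arms
    values = data.values

    events = []  # (time, participant, endpoint)
    n_rows = data.n
    for i in range(n_rows):
        for k in range(K):
            t = avail[i, k]
            if math.isfinite(t):
                events.append((t, i, k))
    events.sort()

    # assumed conditional (stagewise) parameters for fallback
    cov0 = fallback.covariance()
    stage0 = []  # (b_coefs, resid_var) per stage
    for k in range(K):
        if k == 0:
            stage0.append(((), float(cov0[0, 0])))
        else:
            b = np.linalg.solve(cov0[:k, :k], cov0[:k, k])
            stage0.append((tuple(float(x) for x in b), float(cov0[k, k] - b @ cov0[:k, k])))

    # accumulators --------------------------------------------------------
    counts = [[0] * K, [0] * K]  # raw observed counts [arm][endpoint]
    # nested-subset cross moments: per arm, per stage k, sums over rows with
    # endpoints 0..k all observed: count, sums (k+1), products (upper triangle)
    n_sub = [[0] * K, [0] * K]
    s_sub = [[[0.0] * (k + 1) for k in range(K)] for _ in range(2)]
    q_sub = [[[[0.0] * (k + 1) for _ in range(k + 1)] for k in range(K)] for _ in range(2)]
    prefix = [0] * n_rows
    observed = [[False] * K for _ in range(n_rows)]

    sqrt = math.sqrt
    sig_mat = [[0.0] * K for _ in range(K)]
    for t, i, k in events:
        j = int(arms[i])
        observed[i][k] = True
        counts[j][k] += 1
        p = prefix[i]
        row_obs = observed[i]
        while p < K and row_obs[p]:
            # row joins stage p: accumulate its first p+1 endpoints
            row = values[i]
            n_sub[j][p] += 1
            s = s_sub[j][p]
            q = q_sub[j][p]
            for a in range(p + 1):
                xa = float(row[a])
                s[a] += xa
                qa = q[a]
                for b in range(a, p + 1):
                    qa[b] += xa * float(row[b])
            p += 1
        prefix[i] = p
        if t < start_time:
            yield t, 0.0
            continue

        # stagewise covariance estimate from pooled arm-centred moments
        for k_st in range(K):
            n_tot = n_sub[0][k_st] + n_sub[1][k_st]
            arms_present = (n_sub[0][k_st] > 0) + (n_sub[1][k_st] > 0)
            dof = n_tot - k_st - arms_present
            use_fallback = dof < _MIN_VAR_DOF
            if not use_fallback:
                c = [[0.0] * (k_st + 1) for _ in range(k_st + 1)]
                for arm in (0, 1):
                    n_a = n_sub[arm][k_st]
                    if n_a == 0:
                        continue
                    s = s_sub[arm][k_st]
                    q = q_sub[arm][k_st]
                    for a in range(k_st + 1):
                        for b in range(a, k_st + 1):
                            c[a][b] += q[a][b] - s[a] * s[b] / n_a
                if k_st == 0:
                    coefs = ()
                    resid = c[0][0] / dof
                    if resid <= 0:
                        use_fallback = True
                elif k_st == 1:
                    if c[0][0] <= 0:
                        use_fallback = True
                    else:
                        b1 = c[0][1] / c[0][0]
                        coefs = (b1,)
                        resid = (c[1][1] - b1 * c[0][1]) / dof
                        if resid <= 0:
                            use_fallback = True
                else:
                    # general small solve via numpy (k_st >= 2)
                    A = np.empty((k_st, k_st))
                    for a in range(k_st):
                        for b in range(k_st):
                            A[a, b] = c[a][b] if a <= b else c[b][a]
                    rhs = np.array([c[a][k_st] for a in range(k_st)])
                    try:
                        bv = np.linalg.solve(A, rhs)
                        coefs = tuple(float(x) for x in bv)
                        resid = (c[k_st][k_st] - float(bv @ rhs)) / dof
                        if resid <= 0:
                            use_fallback = True
                    except np.linalg.LinAlgError:
                        use_fallback = True
            if use_fallback:
                coefs, resid = stage0[k_st]
            if k_st == 0:
                sig_mat[0][0] = resid
            else:
                acc = resid
                for a in range(k_st):
                    cov_ak = 0.0
                    for b in range(k_st):
                        cov_ak += sig_mat[a][b] * coefs[b]
                    sig_mat[a][k_st] = cov_ak
                    sig_mat[k_st][a] = cov_ak
                    acc += coefs[a] * cov_ak
                sig_mat[k_st][k_st] = acc

        sigK = sqrt(sig_mat[K - 1][K - 1])
        rho = {}
        for a in range(K):
            for b in range(a + 1, K):
                r = sig_mat[a][b] / sqrt(sig_mat[a][a] * sig_mat[b][b])
                if r > _CLAMP:
                    r = _CLAMP
                elif r < -_CLAMP:
                    r = -_CLAMP
                rho[(a, b)] = r

        yield t, _monitored_information(counts, sigK, rho, K)


def information_path(data: TrialDataset, fallback: EndpointModel):
    """Full observed-information trajectory: ``(times, infos)`` lists with
    one entry per observed outcome value."""
    times: list[float] = []
    infos: list[float] = []
    for t, info in information_events(data, fallback):
        times.append(t)
        infos.append(info)
    return times, infos


def _monitored_information(counts, sigK: float, rho, K: int) -> float:
    """1/var(B) from per-arm counts, a final-endpoint SD and clamped pairwise
    correlations (only sigma_K and the correlations enter the variance)."""
    var = 0.0
    s2 = sigK * sigK
    for j in (0, 1):
        c = counts[j]
        nK = c[K - 1]
        if nK == 0:
            return 0.0
        v = s2 / nK
        # cross/diagonal correction terms; sigma_k cancels throughout
        for k in range(K - 1):
            mk = c[k] - nK
            if mk <= 0:
                continue
            rk = rho[(k, K - 1)]
            wk = rk * mk / c[k]  # w_k * sigma_k / sigma_K
            v -= 2.0 * s2 * wk * rk / nK
            for l in range(K - 1):
                ml = c[l] - nK
                if ml <= 0:
                    continue
                rl = rho[(l, K - 1)]
                wl = rl * ml / c[l]
                rkl = 1.0 if k == l else rho[(k, l) if k < l else (l, k)]
                overlap = (mk if mk < ml else ml) / (mk * ml)
                v += s2 * wk * wl * rkl * (overlap + 1.0 / nK)
        if v <= 0:  # clamping pathology; treat as (numerically) no information
            v = 1e-8 * 2.0 * s2 / nK
        var += v
    return 1.0 / var


def monitor_information(
    data: TrialDataset,
    schedule: InformationSchedule,
    fallback: EndpointModel,
    start_time: float = 0.0,
) -> list:
    """First calendar event time at which observed information reaches each
    planned level, or None for looks never reached.

    Looks trigger in order: a later look cannot trigger before an earlier
    one.  The final entry of ``schedule`` is the final analysis and is not a
    monitored look; pass only the early-look levels if that is the intent.
    """
    targets = list(schedule.info)
    triggers: list = [None] * len(targets)
    w = 0
    for t, info in information_events(data, fallback, start_time=start_time):
        while w < len(targets) and t >= start_time and info >= targets[w]:
            triggers[w] = t
            w += 1
        if w >= len(targets):
            break
    return triggers


def overrun_analysis(
    data: TrialDataset, fallback: EndpointModel | None = None, method: str = "regression"
) -> OverrunResult:
    """Definitive analysis on all recruited participants after a stop.

    Computes B and var(B) on the full data (reducing to the plain difference
    of arm means when everyone has the final endpoint) and a two-sided
    normal p-value 2 * Phi(-|S|).
    """
    incomplete = (data.available_times()[:, -1] == math.inf).sum()
    if incomplete:
        logger.warning("overrunning analysis with %d participants missing the final endpoint", incomplete)
    nuisance = get_nuisance_estimator(method)(data, fallback)
    summary = summarize(data, nuisance)
    p = 2.0 * float(norm.sf(abs(summary.S)))
    counts = data.counts()
    return OverrunResult(
        B=summary.B,
        varB=summary.varB,
        p_value=p,
        n_per_arm=(counts.n(data.K - 1, 0), counts.n(data.K - 1, 1)),
    )
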