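"""Augmented treatment-effect estimator for a long-term endpoint supported
by short-term measurements of the same score.

The estimator combines the plain difference of arm means on the final
endpoint with mean-centred corrections from participants who have an early
endpoint observed but not yet the final one, weighted by the
correlation-scaled ratio rho_kK * sigma_K / sigma_k.  Because the
corrections are centred, the estimator is unbiased for the final-endpoint
difference regardless of any treatment effect on the early endpoints.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
from scipy import stats

from .data import TrialDataset
from .model import (
    EffectSummary,
    EndpointModel,
    InsufficientDataError,
    LookCounts,
    ModelError,
    NuisanceEstimate,
    check_correlation_matrix,
    nearest_psd_corr,
)

logger = logging.getLogger(__name__)

CORR_CLAMP = 0.99
MIN_PAIRS = 3
VAR_FLOOR_FACTOR = 1e-8


def _params(model) -> tuple[np.ndarray, np.ndarray]:
    """Accept either an assumed EndpointModel or a NuisanceEstimate."""
    return np.asarray(model.sigmas, dtype=float), np.asarray(model.corr, dtype=float)


def treatment_effect(data: TrialDataset, nuisance) -> float:
    """Augmented estimate of the treatment difference on the final endpoint.

    Each arm contributes its final-endpoint mean over participants with the
    final outcome observed, plus, for every early endpoint k, the scaled sum
    of centred residuals of participants with endpoint k observed but the
    final endpoint still pending (centred by the arm mean over everyone with
    endpoint k observed, divided by the arm's completer count).
    """
    sig, corr = _params(nuisance)
    K = data.K
    if sig.size != K:
        raise ModelError("nuisance dimension does not match dataset endpoints")
    effect = 0.0
    for arm, sign in ((1, 1.0), (0, -1.0)):
        in_arm = data.arms == arm
        vals = data.values[in_arm]
        final_obs = ~np.isnan(vals[:, K - 1])
        n_final = int(final_obs.sum())
        if n_final == 0:
            raise InsufficientDataError(f"arm {arm} has no observed final-endpoint data")
        contribution = float(vals[final_obs, K - 1].mean())
        for k in range(K - 1):
            k_obs = ~np.isnan(vals[:, k])
            pending = k_obs & ~final_obs
            if not pending.any():
                continue
            centred = vals[pending, k] - vals[k_obs, k].mean()
            contribution += corr[k, K - 1] * sig[K - 1] / sig[k] * centred.sum() / n_final
        effect += sign * contribution
    return effect


def _arm_variance_k3(n1: int, n2: int, n3: int, sigma3: float, r13: float, r23: float, r12: float) -> float:
    """Single-arm variance contribution for two early endpoints (the printed
    closed form, halved and with this arm's counts)."""
    if n3 <= 0:
        raise InsufficientDataError("no long-term outcome data: information is zero")
    bracket = (
        1.0
        - r13 * r13 * (n1 - n3) / n1
        - r23 * r23 * (n2 - n3) / n2
        + 2.0 * r13 * r23 * r12 * (1.0 - n3 / n2)
    )
    return sigma3 * sigma3 / n3 * bracket


def treatment_effect_variance(counts: LookCounts, model) -> float:
    """Variance of the augmented effect estimate for K = 3 endpoints.

    Uses the closed-form bracket per arm and sums the two independent arm
    contributions; for equal arm sizes this is exactly
    ``(2 sigma3^2 / N3) * bracket``.
    """
    sig, corr = _params(model)
    if counts.K != 3 or sig.size != 3:
        raise ModelError("treatment_effect_variance is the K=3 closed form; use generalized_variance")
    check_correlation_matrix(corr, tol=1e-6)
    var = 0.0
    for arm in (0, 1):
        var += _arm_variance_k3(
            counts.n(0, arm), counts.n(1, arm), counts.n(2, arm),
            sig[2], corr[0, 2], corr[1, 2], corr[0, 1],
        )
    return _apply_variance_floor(var, sig[-1], counts)


def _apply_variance_floor(var: float, sigma_final: float, counts: LookCounts) -> float:
    n3 = counts.n(counts.K - 1, 0) + counts.n(counts.K - 1, 1)
    floor = VAR_FLOOR_FACTOR * 2.0 * sigma_final**2 / max(n3, 1)
    if var <= floor:
        warnings.warn(
            "variance bracket collapsed to <= 0 after clamping; flooring", RuntimeWarning, stacklevel=3
        )
        return floor
    return var


def _arm_variance_general(n_arm: np.ndarray, sig: np.ndarray, corr: np.ndarray) -> float:
    """Single-arm variance of the augmented estimator for any K, from exact
    covariance algebra over the multivariate normal model with nested counts."""
    K = sig.size
    nK = int(n_arm[K - 1])
    if nK <= 0:
        raise InsufficientDataError("no long-term outcome data: information is zero")
    sK = sig[K - 1]
    var = sK * sK / nK
    m = np.array([int(n_arm[k]) - nK for k in range(K - 1)], dtype=float)
    w = np.zeros(K - 1)
    for k in range(K - 1):
        if m[k] > 0:
            w[k] = corr[k, K - 1] * sK / sig[k] * m[k] / float(n_arm[k])
    for k in range(K - 1):
        if m[k] <= 0:
            continue
        var -= 2.0 * w[k] * sK * sig[k] * corr[k, K - 1] / nK
        for l in range(K - 1):
            if m[l] <= 0:
                continue
            overlap = min(m[k], m[l]) / (m[k] * m[l])
            var += w[k] * w[l] * sig[k] * sig[l] * corr[k, l] * (overlap + 1.0 / nK)
    return var


def generalized_variance(counts: LookCounts, model) -> float:
    """Variance of the augmented estimator for K - 1 early endpoints."""
    sig, corr = _params(model)
    if counts.K != sig.size:
        raise ModelError("counts dimension does not match model endpoints")
    if sig.size < 2:
        raise ModelError("need at least one early endpoint and a final endpoint (K >= 2)")
    check_correlation_matrix(corr, tol=1e-6)
    var = sum(_arm_variance_general(counts.arm(arm), sig, corr) for arm in (0, 1))
    return _apply_variance_floor(var, sig[-1], counts)


def generalized_effect(data: TrialDataset, nuisance) -> EffectSummary:
    """Full effect summary (B, var, standardized statistic, information) for
    any number of early endpoints."""
    if data.K < 2:
        raise ModelError("need at least one early endpoint and a final endpoint (K >= 2)")
    B = treatment_effect(data, nuisance)
    varB = generalized_variance(data.counts(), nuisance)
    return EffectSummary.from_effect(B, varB)


def summarize(data: TrialDataset, nuisance) -> EffectSummary:
    """Effect summary using the K=3 closed-form variance when applicable."""
    B = treatment_effect(data, nuisance)
    counts = data.counts()
    if data.K == 3:
        varB = treatment_effect_variance(counts, nuisance)
    else:
        varB = generalized_variance(counts, nuisance)
    return EffectSummary.from_effect(B, varB)


def expected_information(counts: LookCounts, model) -> float:
    """Expected information 1/var(B) at a planned look, from assumed
    (not estimated) nuisance values."""
    if counts.K == 3:
        return 1.0 / treatment_effect_variance(counts, model)
    return 1.0 / generalized_variance(counts, model)


def final_information(n_per_arm: int, sigma_final: float) -> float:
    """Information at the final analysis with everyone complete: N/(2 sigma^2)."""
    if n_per_arm <= 0 or sigma_final <= 0:
        raise ModelError("final information requires n_per_arm > 0 and sigma > 0")
    return n_per_arm / (2.0 * sigma_final**2)


def information_fraction(look_info: float, final_info: float, as_percent: bool = False) -> float:
    if final_info <= 0:
        raise ModelError("final information must be > 0")
    if look_info > final_info:
        warnings.warn("look information exceeds final information", RuntimeWarning, stacklevel=2)
    frac = look_info / final_info
    return 100.0 * frac if as_percent else frac


def estimate_nuisance(data: TrialDataset, fallback: EndpointModel | None = None) -> NuisanceEstimate:
    """Estimate per-endpoint SDs and between-endpoint correlations.

    SDs pool arm-mean-centred residuals over both arms (denominator
    ``n - #arms``, i.e. n-2 when both arms contribute).  Correlations use
    pairwise-complete arm-centred residuals pooled across arms; estimates are
    clamped to +/-0.99 and the matrix is repaired to positive semi-definite.
    A correlation with fewer than three complete pairs falls back to the
    design-assumed value (zero if no fallback model is given) with a warning.
    """
    K = data.K
    values, arms = data.values, data.arms
    sigma_hats = np.empty(K)
    for k in range(K):
        ss = 0.0
        n_tot = 0
        arms_present = 0
        for arm in (0, 1):
            x = data.observed(k, arm)
            if x.size:
                arms_present += 1
                n_tot += x.size
                ss += float(((x - x.mean()) ** 2).sum())
        dof = n_tot - arms_present
        if n_tot < 2 or dof < 1 or ss <= 0:
            raise InsufficientDataError(f"cannot estimate SD of endpoint {k}: insufficient data")
        sigma_hats[k] = math.sqrt(ss / dof)

    corr_hat = np.eye(K)
    n_pairs = np.zeros((K, K), dtype=int)
    np.fill_diagonal(n_pairs, (~np.isnan(values)).sum(axis=0))
    for k in range(K):
        for l in range(k + 1, K):
            sxy = sxx = syy = 0.0
            n_pair = 0
            for arm in (0, 1):
                both = (arms == arm) & ~np.isnan(values[:, k]) & ~np.isnan(values[:, l])
                if both.sum() < 2:
                    n_pair += int(both.sum())
                    continue
                x = values[both, k] - values[both, k].mean()
                y = values[both, l] - values[both, l].mean()
                sxy += float((x * y).sum())
                sxx += float((x * x).sum())
                syy += float((y * y).sum())
                n_pair += int(both.sum())
            if n_pair < MIN_PAIRS or sxx * syy <= 0:
                r = float(fallback.corr[k, l]) if fallback is not None else 0.0
                logger.warning(
                    "correlation (%d,%d) inestimable (%d pairs); using fallback %.3f", k, l, n_pair, r
                )
            else:
                r = sxy / math.sqrt(sxx * syy)
            r = min(max(r, -CORR_CLAMP), CORR_CLAMP)
            corr_hat[k, l] = corr_hat[l, k] = r
            n_pairs[k, l] = n_pairs[l, k] = n_pair
    corr_hat = nearest_psd_corr(corr_hat)
    return NuisanceEstimate(sigma_hats=sigma_hats, corr_hat=corr_hat, n_pairs=n_pairs)


def estimate_nuisance_regression(data: TrialDataset, fallback: EndpointModel | None = None) -> NuisanceEstimate:
    """Nuisance estimation by sequential (factored) regression.

    Builds the covariance matrix stage by stage: the marginal variance of the
    earliest endpoint from everyone observed on it, then each later endpoint
    from its arm-adjusted regression on all earlier endpoints over the nested
    complete subset.  This uses the partially observed early data to sharpen
    the long-term variance and correlation estimates, which keeps
    information-triggered looks close to their planned counts.  Falls back to
    the design-assumed conditional parameters for any stage with too little
    data (with a warning); the result is positive semi-definite by
    construction.
    """
    K = data.K
    values, arms = data.values, data.arms
    assumed = None
    if fallback is not None:
        assumed = fallback.covariance()
    sig_mat = np.zeros((K, K))
    n_stage = np.zeros(K, dtype=int)

    def _assumed_stage(k: int) -> tuple[np.ndarray, float]:
        if assumed is None:
            raise InsufficientDataError(
                f"cannot estimate stage {k} of the covariance factorization and no fallback model given"
            )
        if k == 0:
            return np.empty(0), float(assumed[0, 0])
        b = np.linalg.solve(assumed[:k, :k], assumed[:k, k])
        resid = float(assumed[k, k] - b @ assumed[:k, k])
        return b, resid

    for k in range(K):
        subset = ~np.isnan(values[:, : k + 1]).any(axis=1)
        n_sub = int(subset.sum())
        n_stage[k] = n_sub
        dof = n_sub - k - 2  # k regressors plus two arm means
        centred = values[subset, : k + 1].copy()
        sub_arms = arms[subset]
        for arm in (0, 1):
            sel = sub_arms == arm
            if sel.any():
                centred[sel] -= centred[sel].mean(axis=0)
        use_fallback = dof < 1
        if not use_fallback:
            cross = centred.T @ centred
            if k == 0:
                b = np.empty(0)
                resid = cross[0, 0] / dof
            else:
                try:
                    b = np.linalg.solve(cross[:k, :k], cross[:k, k])
                except np.linalg.LinAlgError:
                    use_fallback = True
                if not use_fallback:
                    resid = float(cross[k, k] - b @ cross[:k, k]) / dof
                    if resid <= 0:
                        use_fallback = True
        if use_fallback:
            logger.warning("covariance stage %d inestimable (%d rows); using fallback", k, n_sub)
            b, resid = _assumed_stage(k)
        if k == 0:
            sig_mat[0, 0] = resid
        else:
            sig_mat[k, :k] = sig_mat[:k, :k] @ b
            sig_mat[:k, k] = sig_mat[k, :k]
            sig_mat[k, k] = resid + float(b @ sig_mat[:k, :k] @ b)
    sd = np.sqrt(np.diag(sig_mat))
    if np.any(sd <= 0):
        raise InsufficientDataError("degenerate variance estimate in covariance factorization")
    corr = sig_mat / np.outer(sd, sd)
    corr = np.clip(corr, -CORR_CLAMP, CORR_CLAMP)
    np.fill_diagonal(corr, 1.0)
    corr = nearest_psd_corr(corr)
    n_pairs = np.minimum.outer(n_stage, n_stage)
    return NuisanceEstimate(sigma_hats=sd, corr_hat=corr, n_pairs=n_pairs)


NUISANCE_ESTIMATORS = {
    "moments": estimate_nuisance,
    "regression": estimate_nuisance_regression,
}


def get_nuisance_estimator(method: str):
    try:
        return NUISANCE_ESTIMATORS[method]
    except KeyError:
        raise ModelError(f"unknown nuisance estimation method {method!r}") from None


def fixed_design_sample_size(
    delta: float, sigma: float, power: float = 0.9, alpha_two_sided: float = 0.05
) -> tuple[int, int]:
    """Normal-approximation two-sample size: per-group n and total."""
    if delta == 0:
        raise ModelError("cannot size a design for a zero treatment difference")
    if sigma <= 0 or not 0 < power < 1 or not 0 < alpha_two_sided < 1:
        raise ModelError("require sigma > 0, 0 < power < 1 and 0 < alpha < 1")
    z_a = stats.norm.ppf(1.0 - alpha_two_sided / 2.0)
    z_b = stats.norm.ppf(power)
    n = 2.0 * sigma**2 * (z_a + z_b) ** 2 / delta**2
    per_group = int(math.ceil(n - 1e-12))
    return per_group, 2 * per_group
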