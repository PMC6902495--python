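"""Shared domain types: endpoint distribution models, interim-look counts and
effect summaries.

The outcome model is a K-variate normal for the repeated measurements of a
single score, with arm-specific means and a covariance shared between arms.
Endpoint ``K-1`` (0-based) is the definitive long-term outcome; earlier
indices are the short-term measurements of the same score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ModelError(ValueError):
    """Invalid endpoint model or correlation structure."""


class InsufficientDataError(ValueError):
    """Not enough observed data to carry out a computation."""


def check_correlation_matrix(corr: np.ndarray, *, tol: float = 1e-8) -> None:
    """Validate that ``corr`` is a correlation matrix (symmetric, unit
    diagonal, entries in [-1, 1], positive semi-definite up to ``tol``)."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ModelError(f"correlation matrix must be square, got shape {corr.shape}")
    if not np.allclose(corr, corr.T, atol=tol):
        raise ModelError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=tol):
        raise ModelError("correlation matrix must have unit diagonal")
    if np.any(np.abs(corr) > 1.0 + tol):
        raise ModelError("correlation entries must lie in [-1, 1]")
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -tol:
        raise ModelError(f"correlation matrix is not positive semi-definite (min eigenvalue {eigmin:.3g})")


def nearest_psd_corr(corr: np.ndarray, *, eig_floor: float = 1e-6) -> np.ndarray:
    """Repair a near-correlation matrix by clipping eigenvalues at
    ``eig_floor`` and rescaling to unit diagonal."""
    corr = np.asarray(corr, dtype=float)
    corr = 0.5 * (corr + corr.T)
    w, q = np.linalg.eigh(corr)
    if w.min() >= eig_floor:
        return corr
    w = np.clip(w, eig_floor, None)
    repaired = (q * w) @ q.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


@dataclass(frozen=True)
class EndpointModel:
    """Distributional assumptions for the K repeated outcomes.

    Parameters
    ----------
    sigmas : per-endpoint standard deviations (length K, score units).
    corr : K x K correlation matrix between endpoints.
    means_control, means_active : per-endpoint arm means (length K).
    """

    sigmas: np.ndarray
    corr: np.ndarray
    means_control: np.ndarray
    means_active: np.ndarray

    def __post_init__(self) -> None:
        sig = np.asarray(self.sigmas, dtype=float)
        corr = np.asarray(self.corr, dtype=float)
        mc = np.asarray(self.means_control, dtype=float)
        ma = np.asarray(self.means_active, dtype=float)
        if sig.ndim != 1 or sig.size < 2:
            raise ModelError("sigmas must be a vector of length K >= 2")
        if np.any(sig <= 0):
            raise ModelError("all endpoint standard deviations must be > 0")
        check_correlation_matrix(corr)
        if corr.shape[0] != sig.size:
            raise ModelError("corr shape does not match number of endpoints")
        if mc.shape != sig.shape or ma.shape != sig.shape:
            raise ModelError("arm mean vectors must have length K")
        object.__setattr__(self, "sigmas", sig)
        object.__setattr__(self, "corr", corr)
        object.__setattr__(self, "means_control", mc)
        object.__setattr__(self, "means_active", ma)

    @property
    def K(self) -> int:
        return self.sigmas.size

    @property
    def delta_final(self) -> float:
        """True treatment difference on the long-term endpoint."""
        return float(self.means_active[-1] - self.means_control[-1])

    def covariance(self) -> np.ndarray:
        return self.corr * np.outer(self.sigmas, self.sigmas)

    def means(self, arm: int) -> np.ndarray:
        return self.means_active if arm == 1 else self.means_control

    @classmethod
    def uniform(
        cls,
        K: int = 3,
        sigma: float = 20.0,
        rho: float = 0.5,
        delta: float | np.ndarray = 0.0,
        base_mean: float = 0.0,
    ) -> "EndpointModel":
        """Equal-SD, exchangeable-correlation model.

        ``delta`` may be a scalar (applied to the final endpoint only) or a
        length-K vector of per-endpoint treatment differences.
        """
        corr = np.full((K, K), float(rho))
        np.fill_diagonal(corr, 1.0)
        mc = np.full(K, float(base_mean))
        d = np.zeros(K)
        if np.ndim(delta) == 0:
            d[-1] = float(delta)
        else:
            d = np.asarray(delta, dtype=float)
            if d.shape != (K,):
                raise ModelError("delta vector must have length K")
        return cls(sigmas=np.full(K, float(sigma)), corr=corr, means_control=mc, means_active=mc + d)

    def with_correlation(self, corr: np.ndarray) -> "EndpointModel":
        return EndpointModel(self.sigmas, corr, self.means_control, self.means_active)


@dataclass(frozen=True)
class LookCounts:
    """Per-arm numbers of participants with each endpoint observed.

    ``counts[k, j]`` is the number in arm ``j`` with endpoint ``k`` observed;
    earlier endpoints must be observed on at least as many participants.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ModelError("counts must have shape (K, 2)")
        if np.any(c < 0):
            raise ModelError("counts must be non-negative")
        if np.any(np.diff(c.astype(float), axis=0) > 0):
            raise ModelError("counts must be non-increasing from earliest to final endpoint")
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def K(self) -> int:
        return self.counts.shape[0]

    def n(self, k: int, arm: int) -> int:
        return int(self.counts[k, arm])

    def arm(self, arm: int) -> np.ndarray:
        return self.counts[:, arm]

    @classmethod
    def equal_arms(cls, per_arm) -> "LookCounts":
        """Counts from a per-arm vector (N_1, ..., N_K) shared by both arms."""
        per_arm = np.asarray(per_arm, dtype=int)
        return cls(np.column_stack([per_arm, per_arm]))


@dataclass(frozen=True)
class EffectSummary:
    """Augmented treatment-effect estimate with its variance, standardized
    statistic and observed information."""

    B: float
    varB: float
    S: float
    info: float

    @classmethod
    def from_effect(cls, B: float, varB: float) -> "EffectSummary":
        if not varB > 0:
            raise ModelError(f"variance of effect estimate must be > 0, got {varB}")
        sd = float(np.sqrt(varB))
        return cls(B=float(B), varB=float(varB), S=float(B) / sd, info=1.0 / float(varB))


@dataclass(frozen=True)
class NuisanceEstimate:
    """Estimated nuisance parameters: per-endpoint SDs and a repaired
    correlation matrix, plus the pair counts each correlation used."""

    sigma_hats: np.ndarray
    corr_hat: np.ndarray
    n_pairs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        sig = np.asarray(self.sigma_hats, dtype=float)
        corr = np.asarray(self.corr_hat, dtype=float)
        if np.any(sig <= 0):
            raise ModelError("estimated standard deviations must be > 0")
        check_correlation_matrix(corr, tol=1e-6)
        object.__setattr__(self, "sigma_hats", sig)
        object.__setattr__(self, "corr_hat", corr)
        if self.n_pairs is None:
            object.__setattr__(self, "n_pairs", np.zeros_like(corr, dtype=int))

    # aliases so estimators and assumed models are interchangeable downstream
    @property
    def sigmas(self) -> np.ndarray:
        return self.sigma_hats

    @property
    def corr(self) -> np.ndarray:
        return self.corr_hat

    @property
    def K(self) -> int:
        return self.sigma_hats.size
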