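"""File formats and configuration: CSV datasets, YAML/JSON design and
scenario configs, JSON reports, and the synthetic fixture generator."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .boundaries import BoundarySet, InformationSchedule, validate_spending
from .data import DEFAULT_LAGS, TrialDataset
from .model import EndpointModel, ModelError
from .simulate import DesignConfig, RecruitmentSchedule, ScenarioTruth

DATASET_COLUMNS = ("participant_id", "arm", "entry_month")


class ConfigError(ValueError):
    """Malformed configuration or data file."""


# ---------------------------------------------------------------------------
# datasets

def read_dataset(path, lags: tuple = DEFAULT_LAGS) -> TrialDataset:
    """Read a long-format CSV dataset.  Empty outcome cells are missing
    values; malformed rows are reported with their (1-based data) row
    number."""
    df = pd.read_csv(path, float_precision="round_trip")
    outcome_cols = [f"outcome_{int(lag)}m" for lag in lags]
    required = list(DATASET_COLUMNS) + outcome_cols
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing required columns {missing}")
    arm = pd.to_numeric(df["arm"], errors="coerce")
    bad = df.index[~arm.isin([0, 1])]
    if len(bad):
        raise ConfigError(f"{path}: row {bad[0] + 2}: arm must be 0 or 1, got {df.loc[bad[0], 'arm']!r}")
    entry = pd.to_numeric(df["entry_month"], errors="coerce")
    bad = df.index[entry.isna() | (entry < 0)]
    if len(bad):
        raise ConfigError(f"{path}: row {bad[0] + 2}: entry_month must be a non-negative number")
    for col in outcome_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")]
        if len(bad):
            raise ConfigError(f"{path}: row {bad[0] + 2}: non-numeric value in {col}")
        df[col] = vals
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ConfigError(f"{path}: duplicate participant_id {dup!r}")
    df["arm"] = arm.astype(int)
    df["entry_month"] = entry.astype(float)
    return TrialDataset.from_frame(df, lags=lags)


def write_dataset(data: TrialDataset, path) -> None:
    data.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fixture generation

def generate_fixture(
    model: EndpointModel,
    counts_per_arm,
    seed: int,
    reference_time: float = 18.0,
    lags: tuple = DEFAULT_LAGS,
    censor: bool = True,
) -> TrialDataset:
    """Synthetic interim dataset with exact per-arm observed counts.

    ``counts_per_arm`` gives (N_1, ..., N_K) for each arm (earliest to final
    endpoint); entry times are staggered so that at ``reference_time``
    exactly N_k participants per arm have endpoint k observable.  With
    ``censor=True`` values not observable at the reference time are written
    as missing; otherwise the complete outcomes are kept (useful for
    replaying later looks from the same file).
    """
    counts = np.atleast_2d(np.asarray(counts_per_arm, dtype=int))
    if counts.shape[0] == 1:
        counts = np.vstack([counts, counts])
    K = len(lags)
    if counts.shape[1] != K:
        raise ModelError(f"counts must list {K} endpoints per arm")
    if np.any(np.diff(counts, axis=1) > 0):
        raise ModelError("counts must satisfy N_1 >= N_2 >= ... >= N_K in each arm")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(model.covariance() + 1e-12 * np.eye(K))
    frames = []
    next_pid = 0
    for arm in (0, 1):
        n_arm = int(counts[arm, 0])
        values = rng.standard_normal((n_arm, K)) @ chol.T + model.means(arm)
        entries = np.empty(n_arm)
        # stagger entries: the first N_K participants are past the final lag
        # at the reference time, the next N_{K-1} - N_K past lag K-1, etc.
        lo_idx = 0
        bands = list(range(K - 1, -1, -1))  # final endpoint band first
        for b, k in enumerate(bands):
            n_band = int(counts[arm, k]) - (int(counts[arm, k + 1]) if k + 1 < K else 0)
            if n_band == 0:
                continue
            upper_lag = lags[k]
            lower_lag = lags[k + 1] if k + 1 < K else None
            hi = reference_time - upper_lag
            lo = 0.0 if lower_lag is None else max(reference_time - lower_lag, 0.0) + 1e-9
            if hi < lo:
                raise ModelError("reference_time too small for the requested counts and lags")
            entries[lo_idx : lo_idx + n_band] = np.sort(lo + (hi - lo) * rng.random(n_band))
            lo_idx += n_band
        frames.append((values, np.full(n_arm, arm), entries, np.arange(next_pid, next_pid + n_arm)))
        next_pid += n_arm
    values = np.vstack([f[0] for f in frames])
    arms = np.concatenate([f[1] for f in frames])
    entries = np.concatenate([f[2] for f in frames])
    pids = np.concatenate([f[3] for f in frames])
    data = TrialDataset(values=values, arms=arms, entries=entries, lags=lags, pids=pids)
    return data.at(reference_time) if censor else data


# ---------------------------------------------------------------------------
# configuration parsing

def _load_structured(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        obj = json.loads(text)
    else:
        obj = yaml.safe_load(text)
    if not isinstance(obj, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return obj


def _check_keys(d: dict, allowed: set, required: set, ctx: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{ctx}: unknown keys {sorted(unknown)}")
    missing = required - set(d)
    if missing:
        raise ConfigError(f"{ctx}: missing required keys {sorted(missing)}")


def _parse_model(d: dict, ctx: str, K: int = 3) -> EndpointModel:
    _check_keys(d, {"sigmas", "sigma", "corr", "rho", "delta", "means_control", "means_active"}, set(), ctx)
    if "sigmas" in d:
        sigmas = np.asarray(d["sigmas"], dtype=float)
    elif "sigma" in d:
        sigmas = np.full(K, float(d["sigma"]))
    else:
        raise ConfigError(f"{ctx}: provide 'sigmas' or 'sigma'")
    K = sigmas.size
    if "corr" in d:
        corr = np.asarray(d["corr"], dtype=float)
    elif "rho" in d:
        rho = d["rho"]
        if np.ndim(rho) == 0:
            corr = np.full((K, K), float(rho))
            np.fill_diagonal(corr, 1.0)
        else:
            if K != 3 or len(rho) != 3:
                raise ConfigError(f"{ctx}: 'rho' as a list means [rho12, rho13, rho23] with K=3")
            r12, r13, r23 = (float(x) for x in rho)
            corr = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    else:
        raise ConfigError(f"{ctx}: provide 'corr' or 'rho'")
    if "means_control" in d or "means_active" in d:
        if not ("means_control" in d and "means_active" in d):
            raise ConfigError(f"{ctx}: provide both means_control and means_active, or neither")
        mc = np.asarray(d["means_control"], dtype=float)
        ma = np.asarray(d["means_active"], dtype=float)
    else:
        mc = np.zeros(K)
        delta = d.get("delta", 0.0)
        dv = np.zeros(K)
        if np.ndim(delta) == 0:
            dv[-1] = float(delta)
        else:
            dv = np.asarray(delta, dtype=float)
        ma = mc + dv
    try:
        return EndpointModel(sigmas=sigmas, corr=corr, means_control=mc, means_active=ma)
    except ModelError as exc:
        raise ConfigError(f"{ctx}: {exc}") from exc


def _parse_recruitment(d: dict, ctx: str) -> RecruitmentSchedule:
    _check_keys(d, {"centres", "rate", "cap", "max_months"}, {"centres", "rate"}, ctx)
    try:
        return RecruitmentSchedule(
            centres=tuple(d["centres"]),
            rate=float(d["rate"]),
            cap=int(d["cap"]) if d.get("cap") is not None else None,
            max_months=int(d.get("max_months", 240)),
        )
    except ModelError as exc:
        raise ConfigError(f"{ctx}: {exc}") from exc


def parse_design(d: dict, ctx: str = "design") -> DesignConfig:
    allowed = {
        "alpha", "spending", "looks", "final_n_per_arm", "assumed_model",
        "lags_months", "recruitment", "policy",
    }
    _check_keys(d, allowed, {"spending", "looks", "final_n_per_arm", "assumed_model"}, ctx)
    sp = d["spending"]
    _check_keys(sp, {"lower", "upper", "cumulative"}, {"lower", "upper"}, f"{ctx}.spending")
    alpha = float(d.get("alpha", 0.025))
    try:
        plan = validate_spending(sp["lower"], sp["upper"], alpha=alpha, cumulative=bool(sp.get("cumulative", True)))
    except ModelError as exc:
        raise ConfigError(f"{ctx}.spending: {exc}") from exc
    lk = d["looks"]
    _check_keys(lk, {"counts_per_arm"}, {"counts_per_arm"}, f"{ctx}.looks")
    lags = tuple(float(x) for x in d.get("lags_months", DEFAULT_LAGS))
    model = _parse_model(d["assumed_model"], f"{ctx}.assumed_model", K=len(lags))
    policy = d.get("policy", {})
    _check_keys(
        policy,
        {"binding", "looks_after_recruitment", "monitor_start_month", "recalc_boundaries"},
        set(),
        f"{ctx}.policy",
    )
    recruitment = _parse_recruitment(d["recruitment"], f"{ctx}.recruitment") if "recruitment" in d else None
    try:
        return DesignConfig(
            plan=plan,
            look_counts=tuple(tuple(row) for row in lk["counts_per_arm"]),
            final_n_per_arm=int(d["final_n_per_arm"]),
            assumed_model=model,
            recruitment=recruitment,
            lags=lags,
            binding=bool(policy.get("binding", True)),
            looks_after_recruitment=bool(policy.get("looks_after_recruitment", True)),
            monitor_start=float(policy.get("monitor_start_month", 18.0)),
            recalc_boundaries=bool(policy.get("recalc_boundaries", False)),
        )
    except ModelError as exc:
        raise ConfigError(f"{ctx}: {exc}") from exc


def load_design(path) -> DesignConfig:
    return parse_design(_load_structured(path), ctx=str(path))


@dataclass(frozen=True)
class Scenario:
    design: DesignConfig
    truth: ScenarioTruth
    reps: int
    seed: int | None


def parse_scenario(d: dict, ctx: str = "scenario") -> Scenario:
    _check_keys(d, {"design", "truth", "reps", "seed"}, {"design", "truth"}, ctx)
    design = parse_design(d["design"], f"{ctx}.design")
    td = dict(d["truth"])
    dropout = float(td.pop("dropout", 0.0))
    model = _parse_model(td, f"{ctx}.truth", K=len(design.lags))
    try:
        truth = ScenarioTruth(model=model, dropout=dropout)
    except ModelError as exc:
        raise ConfigError(f"{ctx}.truth: {exc}") from exc
    reps = int(d.get("reps", 1000))
    if reps < 1:
        raise ConfigError(f"{ctx}: reps must be >= 1")
    seed = d.get("seed")
    return Scenario(design=design, truth=truth, reps=reps, seed=None if seed is None else int(seed))


def load_scenario(path) -> Scenario:
    return parse_scenario(_load_structured(path), ctx=str(path))


def parse_fixture_config(d: dict, ctx: str = "fixture") -> dict:
    _check_keys(d, {"model", "counts_per_arm", "reference_time", "lags_months", "censor"}, {"model", "counts_per_arm"}, ctx)
    lags = tuple(float(x) for x in d.get("lags_months", DEFAULT_LAGS))
    model = _parse_model(d["model"], f"{ctx}.model", K=len(lags))
    return {
        "model": model,
        "counts_per_arm": d["counts_per_arm"],
        "reference_time": float(d.get("reference_time", 18.0)),
        "lags": lags,
        "censor": bool(d.get("censor", True)),
    }


# ---------------------------------------------------------------------------
# reports

def _jsonable(x):
    if isinstance(x, (np.floating, float)):
        f = float(x)
        if math.isinf(f):
            return "inf" if f > 0 else "-inf"
        return f
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    return x


def boundary_report(design: DesignConfig, schedule: InformationSchedule, bounds: BoundarySet) -> dict:
    return {
        "alpha_one_sided": design.plan.alpha,
        "spending_lower_cum": _jsonable(design.plan.alphaL_cum),
        "spending_upper_cum": _jsonable(design.plan.alphaU_cum),
        "spending_lower_increments": _jsonable(design.plan.lower_increments),
        "spending_upper_increments": _jsonable(design.plan.upper_increments),
        "information": _jsonable(schedule.info),
        "information_fractions": _jsonable(schedule.fractions()),
        "lower": _jsonable(bounds.lower),
        "upper": _jsonable(bounds.upper),
        "binding": design.binding,
        "diagnostics": _jsonable(bounds.diagnostics),
    }


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")
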