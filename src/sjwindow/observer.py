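"""Synthetic SJ observers: a two-sided psychometric generative model.

Each observer x condition is parameterized by the magnitudes of its two 50%
crossings (``c_av_ms`` on the audio-leading side, ``c_va_ms`` on the
visual-leading side), one logistic slope per side, and optional guess/lapse
floors. The probability of a "synchronous" response at a signed SOA is

    p(soa) = guess + (1 - guess - lapse) * core(soa)
    core(soa) = logistic(slope_av * (soa + c_av))   for soa < 0
    core(soa) = logistic(-slope_va * (soa - c_va))  for soa >= 0

With guess = lapse = 0 (the default) the generative 50% crossings are
exactly (-c_av, +c_va), so the estimation pipeline's 50% criterion targets
the generative truth directly.

Population-level simulation draws per-participant crossings from truncated
normal distributions whose *truncated* mean and SD match the requested
population values (the underlying normal parameters are moment-matched), with
a configurable Gaussian-copula correlation between the two conditions so that
paired contrasts have realistic within-subject coupling. Default population
values are group statistics from a talk-vs-listen SJ study with 17
participants: active AV 240.76 (SD 100.71), VA 119.53 (91.45); passive AV
259.00 (79.13), VA 222.41 (82.97) ms. Trial rejection emulates microphone
failures: in the active condition a subset of participants (default 7) loses
a uniform 1-26 trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, ndtr

from .design import DesignSpec, DeviceCalibration, build_design, effective_onsets
from .exceptions import ValidationError

__all__ = [
    "ObserverParams",
    "ConditionCrossings",
    "PopulationSpec",
    "p_synchronous",
    "sample_population",
    "simulate_session",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ObserverParams:
    """Generative psychometric parameters for one participant x condition."""

    c_av_ms: float
    c_va_ms: float
    slope_av: float
    slope_va: float
    lapse: float = 0.0
    guess: float = 0.0

    def __post_init__(self):
        if self.c_av_ms <= 0 or self.c_va_ms <= 0:
            raise ValidationError("crossing magnitudes must be positive")
        if self.slope_av <= 0 or self.slope_va <= 0:
            raise ValidationError("slopes must be positive")
        for name in ("lapse", "guess"):
            v = getattr(self, name)
            if not 0 <= v < 0.5:
                raise ValidationError(f"{name} must lie in [0, 0.5)")
        if 1.0 - self.guess - self.lapse <= 0:
            raise ValidationError("guess + lapse must leave positive dynamic range")


def p_synchronous(soa_ms, params: ObserverParams):
    """Probability of a synchronous report at signed SOA(s) in ms.

    Vectorized over ``soa_ms``; returns a float for scalar input. Unimodal:
    nondecreasing for soa < 0 and nonincreasing for soa >= 0.
    """
    soa = np.asarray(soa_ms, dtype=float)
    core = np.where(
        soa < 0,
        expit(params.slope_av * (soa + params.c_av_ms)),
        expit(-params.slope_va * (soa - params.c_va_ms)),
    )
    p = params.guess + (1.0 - params.guess - params.lapse) * core
    return float(p) if np.isscalar(soa_ms) else p


@dataclass(frozen=True)
class ConditionCrossings:
    """Population mean/SD of the two crossing magnitudes for one condition."""

    av_mean: float
    av_sd: float
    va_mean: float
    va_sd: float

    def __post_init__(self):
        if min(self.av_sd, self.va_sd) < 0:
            raise ValidationError("SDs must be nonnegative")
        if min(self.av_mean, self.va_mean) <= 0:
            raise ValidationError("mean crossings must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """Generative population for a paired (two-condition) SJ cohort.

    ``crossings`` maps condition label -> :class:`ConditionCrossings`; the
    defaults are the active/passive group statistics quoted in the module
    docstring. ``correlation`` is the Gaussian-copula correlation of each
    crossing between the two conditions within a participant (0.5 by
    default). Slopes are lognormal with the given median and log-SD, drawn
    once per participant per side and shared across conditions.
    """

    crossings: dict[str, ConditionCrossings] = field(
        default_factory=lambda: {
            "active": ConditionCrossings(240.76, 100.71, 119.53, 91.45),
            "passive": ConditionCrossings(259.00, 79.13, 222.41, 82.97),
        }
    )
    slope_median: float = 0.02
    slope_log_sd: float = 0.25
    lapse: float = 0.0
    guess: float = 0.0
    n_participants: int = 17
    correlation: float = 0.5
    rejected_trials_range: tuple[int, int] = (1, 26)
    n_rejection_participants: int = 7
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValidationError("need at least one participant")
        if not -1.0 < self.correlation < 1.0:
            raise ValidationError("correlation must lie in (-1, 1)")
        lo, hi = self.rejected_trials_range
        if lo < 0 or hi < lo:
            raise ValidationError("rejected_trials_range must be a valid interval")
        if not 0 <= self.n_rejection_participants <= self.n_participants:
            raise ValidationError("n_rejection_participants out of range")
        if self.slope_median <= 0 or self.slope_log_sd < 0:
            raise ValidationError("slope distribution parameters invalid")


@lru_cache(maxsize=256)
def _matched_truncnorm(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Underlying (mu, sigma) whose truncation at zero has the target moments.

    Solved so that the population of crossings is positive while its mean/SD
    equal the requested values exactly. Raises for infeasible targets (a
    zero-truncated normal always has SD < mean, since its left tail is cut
    at a finite point while the right tail is Gaussian).
    """
    if target_mean <= 0:
        raise ValidationError("target mean of a positive crossing must be > 0")
    if target_sd >= target_mean:
        raise ValidationError(
            f"truncated-at-zero normal cannot have SD {target_sd} >= mean {target_mean}"
        )

    def moments(x):
        mu, log_sigma = x
        sigma = math.exp(log_sigma)
        a = -mu / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - target_mean, math.sqrt(v) - target_sd]

    sol, info, ier, msg = optimize.fsolve(
        moments, x0=[target_mean, math.log(target_sd)], full_output=True
    )
    if ier != 1 or max(abs(np.asarray(moments(sol)))) > 1e-6:
        raise ValidationError(
            f"could not moment-match truncated normal for mean={target_mean}, "
            f"sd={target_sd}: {msg}"
        )
    return float(sol[0]), float(math.exp(sol[1]))


def _truncnorm_from_copula(z: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Map standard-normal copula draws to matched truncated-normal margins."""
    if sd == 0:
        return np.full(z.shape, mean)
    mu, sigma = _matched_truncnorm(mean, sd)
    a = -mu / sigma
    return stats.truncnorm.ppf(ndtr(z), a, np.inf, loc=mu, scale=sigma)


def sample_population(
    spec: PopulationSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw per-participant generative parameters for every condition.

    Returns a DataFrame with one row per participant x condition and columns
    ``participant, condition, c_av_ms, c_va_ms, slope_av, slope_va, lapse,
    guess``. Crossings have exactly the spec's mean/SD in the (truncated)
    population; with all SDs zero every participant receives the population
    means. Reproducible from ``spec.rng_seed``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    conditions = list(spec.crossings)
    n = spec.n_participants
    k = len(conditions)

    # One copula draw per side: k-variate standard normal, equicorrelated.
    cov = np.full((k, k), spec.correlation)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov) if k > 1 else np.ones((1, 1))
    z_av = rng.standard_normal((n, k)) @ chol.T
    z_va = rng.standard_normal((n, k)) @ chol.T

    slope_av = spec.slope_median * np.exp(spec.slope_log_sd * rng.standard_normal(n))
    slope_va = spec.slope_median * np.exp(spec.slope_log_sd * rng.standard_normal(n))

    ids = [f"p{i + 1:02d}" for i in range(n)]
    frames = []
    for j, cond in enumerate(conditions):
        cc = spec.crossings[cond]
        frames.append(
            pd.DataFrame(
                {
                    "participant": ids,
                    "condition": cond,
                    "c_av_ms": _truncnorm_from_copula(z_av[:, j], cc.av_mean, cc.av_sd),
                    "c_va_ms": _truncnorm_from_copula(z_va[:, j], cc.va_mean, cc.va_sd),
                    "slope_av": slope_av,
                    "slope_va": slope_va,
                    "lapse": spec.lapse,
                    "guess": spec.guess,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _params_from_row(row) -> ObserverParams:
    return ObserverParams(
        c_av_ms=float(row.c_av_ms),
        c_va_ms=float(row.c_va_ms),
        slope_av=float(row.slope_av),
        slope_va=float(row.slope_va),
        lapse=float(row.lapse),
        guess=float(row.guess),
    )


def simulate_session(
    design: pd.DataFrame,
    params: ObserverParams,
    rejection_count: int = 0,
    rng: np.random.Generator | None = None,
    calibration: DeviceCalibration | None = None,
) -> pd.DataFrame:
    """Fill one session's responses by Bernoulli draws from the observer model.

    ``rejection_count`` trials are flagged rejected, chosen uniformly without
    replacement (microphone failures carry no SOA dependence); their responses
    are retained but excluded by the analysis. If ``calibration`` is given,
    response probabilities are evaluated at effective SOAs (constants + jitter)
    instead of nominal levels.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(design)
    if design["response"].notna().any():
        raise ValidationError("design already carries responses")
    if rejection_count >= n:
        raise ValidationError(
            f"rejection_count {rejection_count} must be < number of trials {n}"
        )
    out = design.copy()
    if calibration is not None:
        audio, video = effective_onsets(out, calibration, rng)
        soa = audio - video
    else:
        soa = out["soa_ms"].to_numpy(dtype=float)
    p = p_synchronous(soa, params)
    out["response"] = pd.array((rng.random(n) < p).astype(int), dtype="Int64")
    out["rejected"] = False
    if rejection_count > 0:
        idx = rng.choice(n, size=rejection_count, replace=False)
        out.iloc[idx, out.columns.get_loc("rejected")] = True
    return out


def simulate_cohort(
    population: PopulationSpec,
    design: DesignSpec | None = None,
    seed: int | None = None,
    calibration: DeviceCalibration | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort: trial log plus the generative truth table.

    Every participant receives an independently randomized session per
    condition. Rejection hits ``n_rejection_participants`` randomly chosen
    participants in the active (first) condition with a uniform count on
    ``rejected_trials_range``. Returns ``(trials, truth)`` where ``truth`` is
    the :func:`sample_population` table (the sidecar for recovery tests).
    """
    if design is None:
        design = DesignSpec()
    seed = population.rng_seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    pop_ss, rej_ss, sess_ss = root.spawn(3)
    truth = sample_population(population, np.random.default_rng(pop_ss))

    rej_rng = np.random.default_rng(rej_ss)
    ids = sorted(truth["participant"].unique())
    rejected_ids = set(
        rej_rng.choice(ids, size=population.n_rejection_participants, replace=False)
    )
    lo, hi = population.rejected_trials_range
    rejection_condition = design.conditions[0] if design.conditions else None

    frames = []
    child_seeds = sess_ss.spawn(len(truth))
    for (_, row), child in zip(truth.iterrows(), child_seeds):
        rng = np.random.default_rng(child)
        spec_p = replace(design, conditions=(row.condition,))
        sess = build_design(spec_p, participant=row.participant, rng=rng)
        count = 0
        if row.condition == rejection_condition and row.participant in rejected_ids:
            count = int(rej_rng.integers(lo, hi + 1))
        frames.append(
            simulate_session(
                sess, _params_from_row(row), count, rng, calibration=calibration
            )
        )
    trials = pd.concat(frames, ignore_index=True)
    return trials, truth
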