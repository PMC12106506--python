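"""Temporal-binding-window estimation from simultaneity-judgment trials.

The estimator follows the side-split sigmoid method: per-SOA rates of
perceived simultaneity are computed over non-rejected trials; a binomial
regression with logit link (probit available by option) is fitted separately
to the audio-leading trials (AV side, SOA < 0) and the visual-leading trials
(VA side, SOA > 0); each side's 50% crossing is the SOA where the fitted
curve equals probability 0.5, in closed form ``-b0/b1``. The TBW width is
the sum of the two crossing magnitudes, the asymmetry their difference
(positive = auditory shift), and the peak amplitude the maximum of the two
fitted curves at SOA 0 (each side's fitted supremum over its own domain).

The public surface is a statsmodels-style pair: :class:`SimultaneityJudgment`
is the model for one observer session and its :meth:`~SimultaneityJudgment.fit`
returns :class:`TBWResults` with estimates, diagnostics and ``summary()``.
Cohort-level helpers (:func:`fit_cohort`, :func:`group_tbw`) build the
per-participant table and its group summary.

Complete or quasi-complete separation (a side answered all-synchronous, say)
leaves the ML fit unbounded; such sides are refitted with a Jeffreys-prior
(Firth) penalty, which is deterministic and always yields finite
coefficients, and the fit is flagged ``penalized``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from .exceptions import (
    FitFailureError,
    InsufficientDataError,
    NoCrossingError,
    ValidationError,
)

__all__ = [
    "RateTable",
    "SigmoidFit",
    "TBWResults",
    "SimultaneityJudgment",
    "compute_rates",
    "fit_side",
    "crossing_ms",
    "estimate_tbw",
    "fit_cohort",
    "group_tbw",
]

#: Minimum |slope| (per ms) for a usable 50% crossing; shallower fits are
#: flagged unusable rather than extrapolated to a wild crossing.
MIN_SLOPE = 1e-4

#: |linear predictor| beyond which a fitted side is treated as separated.
_SEPARATION_ETA = 15.0


def compute_rates(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-SOA simultaneity rates over valid (non-rejected) trials.

    Returns a DataFrame indexed by ``soa_ms`` with columns ``n_valid``,
    ``n_synchronous`` and ``rate``. SOA levels whose trials were all rejected
    are dropped with a warning; an empty or fully rejected input raises.
    """
    if len(trials) == 0:
        raise InsufficientDataError("no trials supplied")
    valid = trials.loc[~trials["rejected"].astype(bool)]
    if valid["response"].isna().any():
        raise ValidationError("trials carry missing responses; simulate or ingest first")
    designed = set(trials["soa_ms"].unique())
    grouped = valid.groupby("soa_ms")["response"]
    table = pd.DataFrame(
        {"n_valid": grouped.size(), "n_synchronous": grouped.sum().astype(int)}
    )
    dropped = sorted(designed - set(table.index))
    if dropped:
        warnings.warn(
            f"SOA levels {dropped} had no valid trials and were dropped",
            stacklevel=2,
        )
    if len(table) == 0:
        raise InsufficientDataError("all trials rejected")
    table["rate"] = table["n_synchronous"] / table["n_valid"]
    return table.sort_index()


@dataclass(frozen=True)
class SigmoidFit:
    """One side's fitted binomial regression on signed SOA.

    ``b0`` and ``b1`` are intercept and slope (per ms) on the linear-predictor
    scale. For the AV side the rate rises toward SOA 0, so b1 > 0 is
    expected; on the VA side b1 < 0.
    """

    side: str  # "AV" or "VA"
    b0: float
    b1: float
    n_trials: int
    n_levels: int
    converged: bool
    penalized: bool
    link: str = "logit"

    def predict(self, soa_ms) -> np.ndarray:
        """Fitted probability of a synchronous report at signed SOA(s)."""
        eta = self.b0 + self.b1 * np.asarray(soa_ms, dtype=float)
        return norm.cdf(eta) if self.link == "probit" else expit(eta)


def _firth_logit(soa: np.ndarray, successes: np.ndarray, totals: np.ndarray):
    """Jeffreys-penalized (Firth) binomial logit fit on aggregated data.

    Maximizes l(beta) + 0.5 log|I(beta)| by Newton steps on the modified
    score U*(beta) = X'(y - m p + h (1/2 - p)), h the hat diagonals under
    weights m p (1 - p). Deterministic; always finite.
    """
    X = np.column_stack([np.ones_like(soa, dtype=float), soa.astype(float)])
    beta = np.zeros(2)
    for _ in range(500):
        p = expit(X @ beta)
        w = totals * p * (1.0 - p)
        info = (X.T * w) @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.inv(info + 1e-8 * np.eye(2))
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (successes - totals * p + h * (0.5 - p))
        step = info_inv @ score
        # Dampen absurd steps; Newton near the optimum is unaffected.
        norm_step = np.max(np.abs(step))
        if norm_step > 5.0:
            step *= 5.0 / norm_step
        beta = beta + step
        if np.max(np.abs(score)) < 1e-8 and norm_step < 1e-8:
            return beta, True
    return beta, bool(np.all(np.isfinite(beta)))


def _aggregate_side(trials: pd.DataFrame, side: str) -> pd.DataFrame:
    if side not in ("AV", "VA"):
        raise ValidationError(f"side must be 'AV' or 'VA', got {side!r}")
    soa = trials["soa_ms"]
    mask = (soa <= 0) if side == "AV" else (soa >= 0)  # 0 belongs to both
    sub = trials.loc[mask]
    if len(sub) == 0:
        raise InsufficientDataError(f"no trials on the {side} side")
    return compute_rates(sub)


def fit_side(trials: pd.DataFrame, side: str, link: str = "logit") -> SigmoidFit:
    """Fit one side's sigmoid: binomial ML regression of response on SOA.

    ``side`` selects trials by SOA sign (AV: soa < 0, VA: soa > 0; a zero
    level, if present, joins both sides). Aggregation to per-SOA counts is
    exact for a binomial likelihood, so this equals the trial-level fit. At
    least two distinct SOA levels with valid trials are required. Separated
    or non-converged fits are refitted with the Jeffreys penalty and flagged.
    """
    rates = _aggregate_side(trials, side)
    if len(rates) < 2:
        raise InsufficientDataError(
            f"{side} side has {len(rates)} usable SOA level(s); need >= 2"
        )
    soa = rates.index.to_numpy(dtype=float)
    succ = rates["n_synchronous"].to_numpy(dtype=float)
    tot = rates["n_valid"].to_numpy(dtype=float)
    n_trials = int(tot.sum())

    if link == "logit":
        family = sm.families.Binomial()
    elif link == "probit":
        family = sm.families.Binomial(link=sm.families.links.Probit())
    else:
        raise ValidationError(f"unknown link {link!r}")

    exog = np.column_stack([np.ones_like(soa), soa])
    beta = None
    converged = False
    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(np.column_stack([succ, tot - succ]), exog, family=family).fit(
                maxiter=200, tol=1e-10
            )
            beta = np.asarray(res.params, dtype=float)
            converged = bool(res.converged)
        except Exception:
            beta = None

    separated = (
        beta is None
        or not np.all(np.isfinite(beta))
        or not converged
        or np.max(np.abs(exog @ beta)) > _SEPARATION_ETA
    )
    if separated:
        if link != "logit":
            raise FitFailureError(
                f"{side} side: separation under {link} link; penalized refit "
                "supports logit only",
                diagnostics={"side": side, "link": link, "beta": beta},
            )
        beta, converged = _firth_logit(soa, succ, tot)
        penalized = True
        if not (converged and np.all(np.isfinite(beta))):
            raise FitFailureError(
                f"{side} side: penalized fit failed to converge",
                diagnostics={"side": side, "beta": list(map(float, beta))},
            )
    return SigmoidFit(
        side=side,
        b0=float(beta[0]),
        b1=float(beta[1]),
        n_trials=n_trials,
        n_levels=len(rates),
        converged=bool(converged),
        penalized=penalized,
        link=link,
    )


def crossing_ms(fit: SigmoidFit, min_slope: float = MIN_SLOPE) -> float:
    """Magnitude in ms of the SOA where the fitted curve equals 0.5.

    Closed form |-b0/b1| (the linear predictor's root; for both logit and
    probit links the curve passes 0.5 exactly where the predictor is zero).
    Slopes shallower than ``min_slope`` give no usable crossing and raise
    :class:`NoCrossingError`; extrapolation beyond the measured SOA range is
    the caller's concern (see :func:`estimate_tbw` flags).
    """
    if abs(fit.b1) < min_slope:
        raise NoCrossingError(
            f"{fit.side} side slope {fit.b1:.2e}/ms below usable minimum {min_slope:.0e}"
        )
    return abs(-fit.b0 / fit.b1)


@dataclass
class TBWResults:
    """Fitted temporal binding window for one participant x condition.

    Attributes
    ----------
    av_side_ms, va_side_ms
        50% crossing magnitudes of the audio-leading and visual-leading side.
    width_ms
        ``av_side_ms + va_side_ms`` (exact).
    asymmetry_ms
        ``av_side_ms - va_side_ms``; positive values are an auditory shift.
    peak_amplitude
        Maximum fitted synchrony probability (both sides evaluated at SOA 0).
    flags
        Diagnostic markers: ``{av,va}_penalized``, ``{av,va}_extrapolated``.
    """

    av_fit: SigmoidFit
    va_fit: SigmoidFit
    av_side_ms: float
    va_side_ms: float
    peak_amplitude: float
    flags: frozenset[str] = frozenset()
    participant: str | None = None
    condition: str | None = None

    @property
    def width_ms(self) -> float:
        return self.av_side_ms + self.va_side_ms

    @property
    def asymmetry_ms(self) -> float:
        return self.av_side_ms - self.va_side_ms

    def predict(self, soa_ms) -> np.ndarray:
        """Fitted synchrony probability, spliced at SOA 0 by side."""
        soa = np.asarray(soa_ms, dtype=float)
        return np.where(soa < 0, self.av_fit.predict(soa), self.va_fit.predict(soa))

    def summary(self) -> str:
        who = " x ".join(s for s in (self.participant, self.condition) if s)
        lines = [
            f"Temporal binding window{f' [{who}]' if who else ''}",
            "=" * 46,
            f"{'AV side (audio leads)':30s} {self.av_side_ms:10.2f} ms",
            f"{'VA side (visual leads)':30s} {self.va_side_ms:10.2f} ms",
            f"{'Total width':30s} {self.width_ms:10.2f} ms",
            f"{'Asymmetry (AV - VA)':30s} {self.asymmetry_ms:10.2f} ms",
            f"{'Peak amplitude':30s} {self.peak_amplitude:10.3f}",
            "-" * 46,
            f"AV fit: b0={self.av_fit.b0:+.4f}, b1={self.av_fit.b1:+.6f}/ms, "
            f"n={self.av_fit.n_trials}"
            + (" [penalized]" if self.av_fit.penalized else ""),
            f"VA fit: b0={self.va_fit.b0:+.4f}, b1={self.va_fit.b1:+.6f}/ms, "
            f"n={self.va_fit.n_trials}"
            + (" [penalized]" if self.va_fit.penalized else ""),
        ]
        if self.flags:
            lines.append(f"flags: {', '.join(sorted(self.flags))}")
        return "\n".join(lines)


class SimultaneityJudgment:
    """Side-split psychometric model of one observer's SJ session.

    Parameters
    ----------
    trials
        Long-format trial table for a single participant x condition
        (columns ``soa_ms``, ``response``, ``rejected``; other columns are
        carried through untouched).
    link
        ``"logit"`` (default, the tested path) or ``"probit"``.
    min_slope
        Usable-crossing slope threshold, per ms.
    peak_definition
        ``"fitted"`` (max of the two fitted curves at SOA 0, default) or
        ``"observed"`` (max empirical per-SOA rate) for sensitivity analyses.

    Examples
    --------
    >>> model = SimultaneityJudgment.from_dataframe(trials, "p01", "active")
    >>> res = model.fit()
    >>> res.width_ms  # doctest: +SKIP
    361.4
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        link: str = "logit",
        min_slope: float = MIN_SLOPE,
        peak_definition: str = "fitted",
    ):
        if peak_definition not in ("fitted", "observed"):
            raise ValidationError(f"unknown peak_definition {peak_definition!r}")
        self.trials = trials
        self.link = link
        self.min_slope = min_slope
        self.peak_definition = peak_definition
        ids = trials["participant"].unique() if "participant" in trials else []
        conds = trials["condition"].unique() if "condition" in trials else []
        if len(ids) > 1 or len(conds) > 1:
            raise ValidationError(
                "model expects one participant x condition; use fit_cohort for tables"
            )
        self.participant = str(ids[0]) if len(ids) else None
        self.condition = str(conds[0]) if len(conds) else None

    @classmethod
    def from_dataframe(
        cls, trials: pd.DataFrame, participant=None, condition=None, **kwargs
    ) -> "SimultaneityJudgment":
        """Select one participant x condition out of a cohort-level table."""
        sub = trials
        if participant is not None:
            sub = sub.loc[sub["participant"] == participant]
        if condition is not None:
            sub = sub.loc[sub["condition"] == condition]
        if len(sub) == 0:
            raise InsufficientDataError(
                f"no trials for participant={participant!r}, condition={condition!r}"
            )
        return cls(sub, **kwargs)

    def fit(self) -> TBWResults:
        """Fit both sides and derive the window estimate.

        Raises
        ------
        InsufficientDataError, FitFailureError, NoCrossingError
            When either side cannot produce a usable 50% crossing; the
            participant x condition is then unusable for group analysis.
        """
        av = fit_side(self.trials, "AV", link=self.link)
        va = fit_side(self.trials, "VA", link=self.link)
        av_ms = crossing_ms(av, self.min_slope)
        va_ms = crossing_ms(va, self.min_slope)

        flags = set()
        for fit, value, tag in ((av, av_ms, "av"), (va, va_ms, "va")):
            if fit.penalized:
                flags.add(f"{tag}_penalized")
            mags = np.abs(self.trials["soa_ms"].to_numpy(dtype=float))
            mags = mags[mags > 0]
            if value < mags.min() or value > mags.max():
                flags.add(f"{tag}_extrapolated")

        if self.peak_definition == "observed":
            peak = float(compute_rates(self.trials)["rate"].max())
        else:
            peak = float(max(av.predict(0.0), va.predict(0.0)))
        return TBWResults(
            av_fit=av,
            va_fit=va,
            av_side_ms=float(av_ms),
            va_side_ms=float(va_ms),
            peak_amplitude=peak,
            flags=frozenset(flags),
            participant=self.participant,
            condition=self.condition,
        )


def estimate_tbw(trials: pd.DataFrame, **options) -> TBWResults:
    """Functional shorthand for ``SimultaneityJudgment(trials, **options).fit()``."""
    return SimultaneityJudgment(trials, **options).fit()


def fit_cohort(
    trials: pd.DataFrame, **options
) -> tuple[pd.DataFrame, list[dict]]:
    """Estimate every participant x condition window in a cohort table.

    Returns ``(estimates, failures)``: one row per successful fit with
    columns ``participant, condition, av_ms, va_ms, width_ms, asymmetry_ms,
    peak, flags`` (flags ';'-joined, sorted); failures list the units whose
    window was unavailable with the reason, mirroring how unusable fits
    propagate to the group stage as missing.
    """
    rows, failures = [], []
    for (pid, cond), sub in trials.groupby(["participant", "condition"], sort=True):
        try:
            res = estimate_tbw(sub, **options)
        except (InsufficientDataError, FitFailureError, NoCrossingError) as exc:
            failures.append(
                {"participant": pid, "condition": cond, "reason": str(exc)}
            )
            continue
        rows.append(
            {
                "participant": pid,
                "condition": cond,
                "av_ms": res.av_side_ms,
                "va_ms": res.va_side_ms,
                "width_ms": res.width_ms,
                "asymmetry_ms": res.asymmetry_ms,
                "peak": res.peak_amplitude,
                "flags": ";".join(sorted(res.flags)),
            }
        )
    return pd.DataFrame(rows), failures


def group_tbw(estimates: pd.DataFrame) -> pd.DataFrame:
    """Group summary: per condition, mean and sample SD of each window field.

    The group window is the arithmetic mean of the per-participant AV and VA
    sides; SDs use the n-1 denominator. Requires >= 2 estimates per
    condition.
    """
    if len(estimates) == 0:
        raise InsufficientDataError("no estimates to summarize")
    out = []
    for cond, sub in estimates.groupby("condition", sort=True):
        if len(sub) < 2:
            raise InsufficientDataError(
                f"condition {cond!r} has {len(sub)} estimate(s); need >= 2"
            )
        row = {"condition": cond, "n": len(sub)}
        for col in ("av_ms", "va_ms", "width_ms", "peak"):
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sd"] = float(sub[col].std(ddof=1))
        out.append(row)
    return pd.DataFrame(out)
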