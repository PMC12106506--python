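"""Group-level inference for paired psychophysics designs.

Covers the inferential toolkit a within-subject SJ study needs:

* paired-samples t-tests with the paired-design Cohen's d (d_z = mean of
  within-subject differences / their SD, so that d = t / sqrt(n) exactly);
* the fully within-subject 2x2 ANOVA (condition x stimulus order) with each
  effect tested against its own subject-by-effect interaction error term and
  partial eta squared = F * df1 / (F * df1 + df2);
* exact a-priori power for paired t-tests from the noncentral t distribution
  (noncentrality d * sqrt(n), df n - 1) and the minimal-n solver.

Sample-size power defaults to one tailed; with 2-level factors sphericity is
trivially satisfied, so no correction machinery is included. No
multiple-testing correction is applied by default (Holm available via
``holm_adjust``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import (
    DegenerateDifferencesError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "PairedTResult",
    "RmAnovaResult",
    "PowerSpec",
    "paired_t",
    "cohens_d_from_t",
    "rm_anova_2x2",
    "partial_eta_sq",
    "power_paired_t",
    "required_n",
    "holm_adjust",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedTResult:
    """Paired t-test with the d_z effect size; df = n - 1 and t = d*sqrt(n)."""

    t: float
    df: int
    p_two_tailed: float
    d: float
    n: int
    mean_diff: float
    sd_diff: float

    def summary(self) -> str:
        return (
            f"t({self.df}) = {self.t:.3f}, p = {self.p_two_tailed:.4g}, "
            f"Cohen's d = {self.d:.3f} (n = {self.n}, "
            f"mean diff = {self.mean_diff:.2f}, SD diff = {self.sd_diff:.2f})"
        )


def paired_t(x, y) -> PairedTResult:
    """Classical paired t-test of ``x - y`` with two-tailed p and d_z.

    Pairs with a missing value on either side are dropped (and counted via
    the returned n). Zero-variance differences with a nonzero mean raise
    :class:`DegenerateDifferencesError` (t would be infinite); identical
    samples return t = d = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("paired_t: dropped %d incomplete pair(s)", dropped)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"need >= 2 complete pairs, got {n}")
    diff = x - y
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    if sd_diff == 0.0:
        if mean_diff == 0.0:
            return PairedTResult(0.0, n - 1, 1.0, 0.0, n, 0.0, 0.0)
        raise DegenerateDifferencesError(
            f"differences are constant ({mean_diff:.4g}) with zero variance; "
            "t is infinite"
        )
    res = sps.ttest_rel(x, y)
    d = mean_diff / sd_diff
    return PairedTResult(
        t=float(res.statistic),
        df=n - 1,
        p_two_tailed=float(res.pvalue),
        d=d,
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
    )


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired-design Cohen's d (d_z) recovered from a t statistic: t / sqrt(n)."""
    if n < 2:
        raise ValidationError("n must be >= 2")
    return float(t) / np.sqrt(n)


def partial_eta_sq(F: float, df_effect: int, df_error: int) -> float:
    """Partial eta squared from an F ratio: F*df1 / (F*df1 + df2)."""
    if F < 0 or df_effect <= 0 or df_error <= 0:
        raise ValidationError("need F >= 0 and positive dfs")
    return (F * df_effect) / (F * df_effect + df_error)


@dataclass(frozen=True)
class RmAnovaResult:
    """2x2 fully-within ANOVA: one row per effect, each with df = (1, n-1)."""

    effects: dict  # name -> {"F", "df_effect", "df_error", "p", "partial_eta_sq", "ss_effect", "ss_error"}
    n: int
    factor_a: str
    factor_b: str

    def __getitem__(self, effect: str) -> dict:
        return self.effects[effect]

    def summary(self) -> str:
        lines = [
            f"Repeated-measures ANOVA ({self.factor_a} x {self.factor_b}, "
            f"n = {self.n})",
            f"{'effect':<24}{'F':>10}{'df':>10}{'p':>12}{'eta_p^2':>10}",
        ]
        for name, e in self.effects.items():
            lines.append(
                f"{name:<24}{e['F']:>10.3f}"
                f"{f'({e_df(e)})':>10}{e['p']:>12.4g}{e['partial_eta_sq']:>10.3f}"
            )
        return "\n".join(lines)


def e_df(e: dict) -> str:
    return f"{e['df_effect']}, {e['df_error']}"


def rm_anova_2x2(
    cells: np.ndarray,
    factor_a: str = "condition",
    factor_b: str = "order",
    a_levels: tuple[str, str] = ("active", "passive"),
    b_levels: tuple[str, str] = ("AV", "VA"),
) -> RmAnovaResult:
    """Fully within-subject 2x2 ANOVA by sums-of-squares decomposition.

    ``cells`` is an (n, 2, 2) array: subjects x factor A levels x factor B
    levels; subjects with any non-finite cell are dropped with a warning.
    Each effect is tested against its own subject x effect interaction
    (error) term; with 1 df effects, F equals the square of the matching
    paired contrast t and partial eta squared is F / (F + n - 1).
    """
    y = np.asarray(cells, dtype=float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise ValidationError("cells must have shape (n_subjects, 2, 2)")
    complete = np.isfinite(y).all(axis=(1, 2))
    if (~complete).any():
        logger.warning(
            "rm_anova_2x2: dropped %d subject(s) with incomplete cells",
            int((~complete).sum()),
        )
    y = y[complete]
    n = y.shape[0]
    if n < 2:
        raise InsufficientDataError(f"need >= 2 complete subjects, got {n}")

    gm = y.mean()
    subj = y.mean(axis=(1, 2))           # (n,)
    m_a = y.mean(axis=(0, 2))            # (2,)
    m_b = y.mean(axis=(0, 1))            # (2,)
    m_ab = y.mean(axis=0)                # (2, 2)
    m_as = y.mean(axis=2)                # (n, 2)
    m_bs = y.mean(axis=1)                # (n, 2)

    ss_a = 2 * n * np.sum((m_a - gm) ** 2)
    ss_b = 2 * n * np.sum((m_b - gm) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_as = 2 * np.sum((m_as - m_a[None, :] - subj[:, None] + gm) ** 2)
    ss_bs = 2 * np.sum((m_bs - m_b[None, :] - subj[:, None] + gm) ** 2)
    resid = (
        y
        - m_ab[None, :, :]
        - m_as[:, :, None]
        - m_bs[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + subj[:, None, None]
        - gm
    )
    ss_abs = np.sum(resid**2)

    df_err = n - 1
    # sums of squares below float cancellation noise are exact zeros
    tiny = np.finfo(float).eps ** 0.5 * max(1.0, float(np.sum((y - gm) ** 2)))
    effects = {}
    for name, ss_eff, ss_err in (
        (factor_a, ss_a, ss_as),
        (factor_b, ss_b, ss_bs),
        (f"{factor_a} x {factor_b}", ss_ab, ss_abs),
    ):
        ms_eff = (0.0 if ss_eff < tiny else ss_eff) / 1
        ms_err = (0.0 if ss_err < tiny else ss_err) / df_err
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
        p = float(sps.f.sf(F, 1, df_err)) if np.isfinite(F) else 0.0
        effects[name] = {
            "F": float(F),
            "df_effect": 1,
            "df_error": df_err,
            "p": p,
            "partial_eta_sq": partial_eta_sq(F, 1, df_err) if np.isfinite(F) else 1.0,
            "ss_effect": float(ss_eff),
            "ss_error": float(ss_err),
        }
    del a_levels, b_levels  # labels documented in reports; levels fixed at 2
    return RmAnovaResult(effects=effects, n=n, factor_a=factor_a, factor_b=factor_b)


@dataclass(frozen=True)
class PowerSpec:
    """A-priori power-analysis request for a paired-samples t-test."""

    effect_size_d: float
    alpha: float = 0.05
    target_power: float = 0.95
    tails: str = "one"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValidationError("target power must lie in (0, 1)")
        if self.effect_size_d <= 0:
            raise ValidationError("effect size must be positive")
        if self.tails not in ("one", "two"):
            raise ValidationError("tails must be 'one' or 'two'")


def power_paired_t(d: float, n: int, alpha: float = 0.05, tails: str = "one") -> float:
    """Exact power of a paired t-test at effect size d (d_z) and n pairs.

    Uses the noncentral t distribution with noncentrality d*sqrt(n) and
    df = n - 1; the rejection region comes from the central t at ``alpha``
    (split across both tails for two-tailed tests). At d = 0 the one-tailed
    power equals alpha.
    """
    if n < 2:
        raise ValidationError("n must be >= 2")
    if tails not in ("one", "two"):
        raise ValidationError("tails must be 'one' or 'two'")
    df = n - 1
    nc = d * np.sqrt(n)
    if tails == "one":
        crit = sps.t.ppf(1 - alpha, df)
        return float(sps.nct.sf(crit, df, nc))
    crit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(crit, df, nc) + sps.nct.cdf(-crit, df, nc))


def required_n(spec: PowerSpec, n_max: int = 100_000) -> int:
    """Smallest n with paired-t power >= the target, by doubling + bisection.

    Deterministic and exact (the power function is strictly increasing in
    n). One-tailed by default; the choice of tails is logged so reports are
    always explicit about it.
    """
    logger.info(
        "required_n: %s-tailed paired t, d = %g, alpha = %g, power = %g",
        spec.tails,
        spec.effect_size_d,
        spec.alpha,
        spec.target_power,
    )

    def ok(n: int) -> bool:
        return power_paired_t(spec.effect_size_d, n, spec.alpha, spec.tails) >= spec.target_power

    lo, hi = 2, 2
    if ok(lo):
        return lo
    while not ok(hi):
        hi *= 2
        if hi > n_max:
            raise ValidationError(
                f"target power unreachable below n = {n_max} for d = {spec.effect_size_d}"
            )
    while hi - lo > 1:  # invariant: not ok(lo), ok(hi)
        mid = (lo + hi) // 2
        lo, hi = (lo, mid) if ok(mid) else (mid, hi)
    return hi


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default in reports)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
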