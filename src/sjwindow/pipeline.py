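"""End-to-end orchestration: simulate (or ingest) -> fit -> group statistics.

``run_pipeline`` executes the whole analysis for one configuration and seed:
per-participant window estimation, group summaries, the three paired
active-vs-passive tests (AV side, VA side, total width), the peak-amplitude
comparison, the within-condition auditory-shift tests (AV vs VA), the 2x2
within-subject ANOVA, the reversed-order subgroup tests, and — when a
variant-passive condition is present in the data — its paired set against
the active condition. All tables are TSV, carry the config hash, and the
whole bundle is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import psychometric, stats
from .exceptions import InsufficientDataError, SJWindowError
from .io import RunConfig, write_trials
from .observer import simulate_cohort

__all__ = ["ReportBundle", "run_pipeline", "group_stats"]

logger = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run (files mirror these tables)."""

    config: RunConfig
    trials: pd.DataFrame
    truth: pd.DataFrame | None
    estimates: pd.DataFrame
    failures: list[dict]
    group: pd.DataFrame | None
    tests: pd.DataFrame | None
    anova: stats.RmAnovaResult | None
    notes: list[str] = field(default_factory=list)
    out_dir: Path | None = None


def _paired_row(name, a, b, n_label=None):
    res = stats.paired_t(a, b)
    return {
        "comparison": name,
        "n": res.n,
        "t": res.t,
        "df": res.df,
        "p": res.p_two_tailed,
        "cohens_d": res.d,
        "mean_diff": res.mean_diff,
        "sd_diff": res.sd_diff,
        "subset": n_label or "all",
    }


def _wide(estimates: pd.DataFrame, value: str) -> pd.DataFrame:
    return estimates.pivot(index="participant", columns="condition", values=value)


def group_stats(
    estimates: pd.DataFrame,
    active: str = "active",
    passive: str = "passive",
    reverse_order_ids: list[str] | None = None,
    variant_passive: str | None = None,
    holm: bool = False,
) -> tuple[pd.DataFrame, stats.RmAnovaResult | None, list[str]]:
    """The full inferential block on a per-participant estimates table.

    Returns ``(tests, anova, notes)``. Participants lacking either condition
    are dropped listwise per comparison; drops and skipped analyses are
    listed in ``notes``.
    """
    notes: list[str] = []
    rows: list[dict] = []
    have = set(estimates["condition"].unique())
    if not {active, passive} <= have:
        raise InsufficientDataError(
            f"need both {active!r} and {passive!r} conditions, have {sorted(have)}"
        )

    av = _wide(estimates, "av_ms")
    va = _wide(estimates, "va_ms")
    width = _wide(estimates, "width_ms")
    peak = _wide(estimates, "peak")
    complete = av[[active, passive]].dropna().index
    n_drop = av.shape[0] - len(complete)
    if n_drop:
        notes.append(f"dropped {n_drop} participant(s) without both conditions")

    for name, tbl in (
        ("AV side: active vs passive", av),
        ("VA side: active vs passive", va),
        ("total TBW: active vs passive", width),
        ("peak amplitude: active vs passive", peak),
    ):
        sub = tbl.loc[complete]
        rows.append(_paired_row(name, sub[active], sub[passive]))

    # Auditory shift: AV vs VA side within each condition.
    for cond in (active, passive):
        sub = estimates.loc[estimates["condition"] == cond]
        rows.append(
            _paired_row(f"AV vs VA side within {cond}", sub["av_ms"], sub["va_ms"])
        )

    # 2x2 within ANOVA on (condition x side) crossings.
    anova = None
    try:
        cells = np.stack(
            [
                np.stack(
                    [av.loc[complete, c].to_numpy(), va.loc[complete, c].to_numpy()],
                    axis=1,
                )
                for c in (active, passive)
            ],
            axis=1,
        )
        anova = stats.rm_anova_2x2(cells, factor_a="condition", factor_b="order")
    except SJWindowError as exc:
        notes.append(f"ANOVA skipped: {exc}")

    if reverse_order_ids:
        ids = [p for p in reverse_order_ids if p in complete]
        if len(ids) >= 2:
            for name, tbl in (
                ("AV side (reverse order)", av),
                ("VA side (reverse order)", va),
                ("total TBW (reverse order)", width),
            ):
                sub = tbl.loc[ids]
                rows.append(
                    _paired_row(
                        f"{name}: active vs passive",
                        sub[active],
                        sub[passive],
                        n_label="reverse-order",
                    )
                )
        else:
            notes.append("reverse-order subgroup too small; subgroup tests skipped")

    if variant_passive and variant_passive in have:
        pair = av[[active, variant_passive]].dropna().index
        if len(pair) >= 2:
            for name, tbl in (("AV side", av), ("VA side", va), ("total TBW", width)):
                sub = tbl.loc[pair]
                rows.append(
                    _paired_row(
                        f"{name}: active vs {variant_passive}",
                        sub[active],
                        sub[variant_passive],
                        n_label="variant-passive",
                    )
                )
        else:
            notes.append("variant-passive subgroup too small; tests skipped")
    elif variant_passive:
        notes.append(
            f"condition {variant_passive!r} absent from data; variant-passive "
            "tests skipped"
        )

    tests = pd.DataFrame(rows)
    if holm and len(tests):
        tests["p_holm"] = stats.holm_adjust(tests["p"].to_numpy())
    return tests, anova, notes


def run_pipeline(
    config: RunConfig, trials: pd.DataFrame | None = None
) -> ReportBundle:
    """Run the pipeline; simulate a cohort unless ``trials`` are supplied.

    Writes (under ``config.out_dir``): ``trials.csv``, ``truth.tsv`` (the
    generative sidecar, simulation only), ``estimates.tsv``,
    ``group_summary.tsv``, ``tests.tsv``, ``anova.tsv``, ``report.txt``,
    ``run_log.json`` and optionally ``tbw_curves.png``. Partial outputs are
    preserved if a later stage fails.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stamp = f"# config_hash: {chash}\n"
    log: dict = {"config_hash": chash, "seed": config.seed}

    (out / "config.yaml").write_text(config.to_yaml(), encoding="utf-8")

    truth = None
    if trials is None:
        trials, truth = simulate_cohort(
            config.population, config.design, seed=config.seed
        )
        write_trials(trials, out / "trials.csv")
        with open(out / "truth.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write(stamp)
            truth.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    log["n_trials"] = int(len(trials))
    log["n_rejected"] = int(trials["rejected"].astype(bool).sum())

    estimates, failures = psychometric.fit_cohort(
        trials,
        link=config.link,
        min_slope=config.min_slope,
        peak_definition=config.peak_definition,
    )
    log["n_fits"] = int(len(estimates))
    log["n_fit_failures"] = len(failures)
    with open(out / "estimates.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(stamp)
        estimates.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    bundle = ReportBundle(
        config=config,
        trials=trials,
        truth=truth,
        estimates=estimates,
        failures=failures,
        group=None,
        tests=None,
        anova=None,
        out_dir=out,
    )
    try:
        group = psychometric.group_tbw(estimates)
        participants = sorted(estimates["participant"].unique())
        reverse_ids = participants[-config.reverse_order_n :] if config.reverse_order_n else []
        tests, anova, notes = group_stats(
            estimates,
            reverse_order_ids=reverse_ids,
            variant_passive=config.variant_passive_condition,
            holm=config.holm,
        )
    except SJWindowError as exc:
        log["group_stage_error"] = str(exc)
        (out / "run_log.json").write_text(json.dumps(log, indent=2), encoding="utf-8")
        raise

    bundle.group, bundle.tests, bundle.anova, bundle.notes = group, tests, anova, notes
    with open(out / "group_summary.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(stamp)
        group.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    with open(out / "tests.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(stamp)
        tests.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    if anova is not None:
        anova_df = pd.DataFrame(
            [{"effect": k, **v} for k, v in anova.effects.items()]
        )
        with open(out / "anova.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write(stamp)
            anova_df.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    (out / "report.txt").write_text(_render_report(bundle), encoding="utf-8")
    (out / "run_log.json").write_text(json.dumps(log, indent=2), encoding="utf-8")

    if config.make_plots:
        try:
            from .plotting import plot_group_curves

            plot_group_curves(trials, estimates, out / "tbw_curves.png")
        except Exception as exc:  # plots are optional artifacts
            logger.warning("plotting failed: %s", exc)
    return bundle


def _render_report(b: ReportBundle) -> str:
    lines = [
        "Simultaneity-judgment window analysis",
        f"config_hash: {b.config.config_hash()}   seed: {b.config.seed}",
        "",
        f"trials: {len(b.trials)} ({int(b.trials['rejected'].astype(bool).sum())} rejected)",
        f"fitted units: {len(b.estimates)}; failures: {len(b.failures)}",
        "",
        "Group summary (mean +/- SD over participants):",
    ]
    for _, r in b.group.iterrows():
        lines.append(
            f"  {r['condition']:<10} n={int(r['n']):<3d} "
            f"AV {r['av_ms_mean']:7.2f} +/- {r['av_ms_sd']:6.2f}  "
            f"VA {r['va_ms_mean']:7.2f} +/- {r['va_ms_sd']:6.2f}  "
            f"width {r['width_ms_mean']:7.2f} +/- {r['width_ms_sd']:6.2f}  "
            f"peak {r['peak_mean']:.3f}"
        )
    lines += ["", "Paired comparisons (two-tailed):"]
    for _, r in b.tests.iterrows():
        lines.append(
            f"  {r['comparison']:<42} t({int(r['df'])}) = {r['t']:7.3f}, "
            f"p = {r['p']:.4g}, d = {r['cohens_d']:6.3f}"
        )
    if b.anova is not None:
        lines += ["", b.anova.summary()]
    if b.notes:
        lines += ["", "Notes:"] + [f"  - {n}" for n in b.notes]
    lines.append("")
    return "\n".join(lines)
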