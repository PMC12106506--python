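"""Trial-log and configuration I/O.

The canonical on-disk trial format is a long-format UTF-8 CSV with header

    participant,condition,block,trial,soa_ms,audio_delay_ms,video_delay_ms,response,rejected

one row per trial, LF line endings, empty ``response`` for design-only files
(allowed only when the reader is told to expect them). ``RunConfig`` bundles
every knob of the pipeline, round-trips through YAML, and hashes canonically
so outputs can carry their provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import TRIAL_COLUMNS, DesignSpec, DeviceCalibration
from .exceptions import InsufficientDataError, ValidationError
from .observer import ConditionCrossings, PopulationSpec

__all__ = ["read_trials", "write_trials", "RunConfig"]

logger = logging.getLogger(__name__)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table in the canonical CSV dialect (LF, UTF-8)."""
    df = trials.loc[:, list(TRIAL_COLUMNS)].copy()
    df["rejected"] = df["rejected"].astype(bool).astype(int)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, index=False, lineterminator="\n")


def read_trials(
    path,
    allow_missing_responses: bool = False,
    permissive: bool = False,
    soa_levels: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    Malformed rows (non-integer fields, responses outside {0, 1}, SOAs not
    in ``soa_levels`` when given, delay/SOA mismatch) raise with their line
    numbers, or are dropped with a warning under ``permissive=True``. Empty
    ``response`` fields are only legal with ``allow_missing_responses``.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(raw.columns) != list(TRIAL_COLUMNS):
        unknown = set(raw.columns) - set(TRIAL_COLUMNS)
        missing = set(TRIAL_COLUMNS) - set(raw.columns)
        raise ValidationError(
            f"{path}: header mismatch (unknown columns {sorted(unknown)}, "
            f"missing {sorted(missing)})"
        )
    if len(raw) == 0:
        raise InsufficientDataError(f"{path}: no trial rows")

    bad: list[tuple[int, str]] = []  # (1-based data line number, reason)
    records = []
    for i, row in enumerate(raw.itertuples(index=False), start=2):  # line 1 = header
        try:
            soa = int(row.soa_ms)
            audio = int(row.audio_delay_ms)
            video = int(row.video_delay_ms)
            block = int(row.block)
            trial = int(row.trial)
            rejected = row.rejected.strip()
            if rejected not in {"0", "1", "True", "False"}:
                raise ValueError(f"bad rejected flag {row.rejected!r}")
            resp_txt = row.response.strip()
            if resp_txt == "":
                if not allow_missing_responses:
                    raise ValueError("missing response")
                resp = None
            elif resp_txt in {"0", "1"}:
                resp = int(resp_txt)
            else:
                raise ValueError(f"response {row.response!r} not in {{0, 1}}")
            if soa_levels is not None and soa not in soa_levels:
                raise ValueError(f"SOA {soa} not a design level")
            if audio - video != soa:
                raise ValueError(
                    f"audio - video = {audio - video} inconsistent with SOA {soa}"
                )
        except ValueError as exc:
            bad.append((i, str(exc)))
            continue
        records.append(
            (
                row.participant,
                row.condition,
                block,
                trial,
                soa,
                audio,
                video,
                resp,
                rejected in {"1", "True"},
            )
        )
    if bad and not permissive:
        head = "; ".join(f"line {ln}: {why}" for ln, why in bad[:5])
        raise ValidationError(f"{path}: {len(bad)} malformed row(s): {head}")
    for ln, why in bad:
        logger.warning("%s: dropped line %d (%s)", path, ln, why)
    if not records:
        raise InsufficientDataError(f"{path}: no valid trial rows")
    df = pd.DataFrame(records, columns=list(TRIAL_COLUMNS))
    df["response"] = pd.array(df["response"], dtype="Int64")
    return df


@dataclass(frozen=True)
class RunConfig:
    """Every pipeline knob, with defaults reproducing the reference setup.

    Fitting options: ``link`` (logit/probit), ``min_slope`` (usable-crossing
    threshold per ms), ``peak_definition`` (fitted/observed). Stats options:
    ``power_tails`` and ``holm`` (off by default). ``reverse_order_n`` marks
    the last-n participants as the reversed-presentation subgroup for the
    subgroup t-tests; ``variant_passive_condition`` names the optional third
    condition (analysed only if present in the data).
    """

    design: DesignSpec = field(default_factory=DesignSpec)
    calibration: DeviceCalibration = field(default_factory=DeviceCalibration)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    link: str = "logit"
    min_slope: float = 1e-4
    peak_definition: str = "fitted"
    power_tails: str = "one"
    holm: bool = False
    reverse_order_n: int = 6
    variant_passive_condition: str = "passive_variant"
    seed: int = 0
    out_dir: str = "sjwindow_run"
    make_plots: bool = True
    verbosity: str = "info"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "design" in data and isinstance(data["design"], dict):
            d = dict(data["design"])
            if "soa_levels_ms" in d:
                d["soa_levels_ms"] = tuple(d["soa_levels_ms"])
            if "conditions" in d:
                d["conditions"] = tuple(d["conditions"])
            data["design"] = DesignSpec(**d)
        if "calibration" in data and isinstance(data["calibration"], dict):
            data["calibration"] = DeviceCalibration(**data["calibration"])
        if "population" in data and isinstance(data["population"], dict):
            p = dict(data["population"])
            if "crossings" in p:
                p["crossings"] = {
                    k: ConditionCrossings(**v) if isinstance(v, dict) else v
                    for k, v in p["crossings"].items()
                }
            if "rejected_trials_range" in p:
                p["rejected_trials_range"] = tuple(p["rejected_trials_range"])
            data["population"] = PopulationSpec(**p)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Short stable hash of the analysis-relevant configuration.

        Presentation-only fields (output directory, plotting, verbosity) are
        excluded so identical analyses hash identically wherever they run.
        """
        d = self.to_dict()
        for key in ("out_dir", "make_plots", "verbosity"):
            d.pop(key, None)
        text = yaml.safe_dump(_plain(d), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _plain(obj):
    """Recursively convert tuples/numpy scalars so YAML stays canonical."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
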