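"""Simultaneity-judgment experiment design.

An SJ session presents audiovisual stimulus pairs at a fixed schedule of
stimulus onset asynchronies (SOAs). Each trial commands an audio delay and a
video delay (both measured from the action onset); their difference realizes
the trial's SOA. The sign convention used throughout the package is

    soa_ms = audio_delay_ms - video_delay_ms,

so negative SOAs mean the auditory stimulus leads (AV trials) and positive
SOAs mean the visual stimulus leads (VA trials).

The default schedule is 14 signed levels (+/-67, 100, 167, 200, 267, 334,
400 ms), 4 blocks per condition with 4 trials per SOA per block (16 per SOA,
224 per condition), delays drawn on [200, 600] ms, and two conditions
("active": self-generated speech with echo playback; "passive": prerecorded
playback of the same stimuli).

Apparatus calibration (constant device delays plus jitter) is carried by
:class:`DeviceCalibration` and only enters through :func:`effective_onsets`,
which the simulator may use to perturb effective SOAs; the analysis operates
on nominal SOA levels because constant delays are compensated at design time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DelayRangeError, InfeasibleSOAError, ValidationError

__all__ = [
    "DEFAULT_SOA_MAGNITUDES",
    "DEFAULT_SOA_LEVELS",
    "DesignSpec",
    "DeviceCalibration",
    "TRIAL_COLUMNS",
    "delays_for_soa",
    "build_design",
    "effective_onsets",
]

DEFAULT_SOA_MAGNITUDES: tuple[int, ...] = (67, 100, 167, 200, 267, 334, 400)
DEFAULT_SOA_LEVELS: tuple[int, ...] = tuple(
    sorted([-m for m in DEFAULT_SOA_MAGNITUDES] + list(DEFAULT_SOA_MAGNITUDES))
)

#: Column order of the canonical long-format trial table.
TRIAL_COLUMNS = (
    "participant",
    "condition",
    "block",
    "trial",
    "soa_ms",
    "audio_delay_ms",
    "video_delay_ms",
    "response",
    "rejected",
)


@dataclass(frozen=True)
class DesignSpec:
    """Parameters defining one SJ session design.

    Parameters
    ----------
    soa_levels_ms
        Signed SOA levels in milliseconds; negative = auditory leads.
    blocks_per_condition, trials_per_soa_per_block
        Block structure; each block is balanced over the SOA levels.
    delay_min_ms, delay_max_ms
        Range of commanded stimulus delays from action onset.
    conditions
        Ordered condition labels.
    rng_seed
        Seed for trial-order randomization and delay draws.
    """

    soa_levels_ms: tuple[int, ...] = DEFAULT_SOA_LEVELS
    blocks_per_condition: int = 4
    trials_per_soa_per_block: int = 4
    delay_min_ms: int = 200
    delay_max_ms: int = 600
    conditions: tuple[str, ...] = ("active", "passive")
    rng_seed: int = 0

    def __post_init__(self):
        levels = tuple(int(s) for s in self.soa_levels_ms)
        object.__setattr__(self, "soa_levels_ms", levels)
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if len(set(levels)) != len(levels):
            raise ValidationError("SOA levels must be distinct")
        if not levels:
            raise ValidationError("at least one SOA level is required")
        if self.blocks_per_condition <= 0 or self.trials_per_soa_per_block <= 0:
            raise ValidationError("block and trial counts must be positive")
        if self.delay_min_ms < 0 or self.delay_max_ms <= self.delay_min_ms:
            raise ValidationError(
                f"need 0 <= delay_min < delay_max, got [{self.delay_min_ms}, {self.delay_max_ms}]"
            )
        span = self.delay_max_ms - self.delay_min_ms
        too_big = [s for s in levels if abs(s) > span]
        if too_big:
            raise InfeasibleSOAError(
                f"SOA levels {too_big} exceed the delay span {span} ms "
                f"([{self.delay_min_ms}, {self.delay_max_ms}])"
            )
        if not self.conditions:
            raise ValidationError("at least one condition label is required")

    @property
    def trials_per_soa(self) -> int:
        return self.blocks_per_condition * self.trials_per_soa_per_block

    @property
    def trials_per_condition(self) -> int:
        return self.trials_per_soa * len(self.soa_levels_ms)

    @property
    def trials_total(self) -> int:
        """Trials in the whole session, all conditions combined."""
        return self.trials_per_condition * len(self.conditions)


@dataclass(frozen=True)
class DeviceCalibration:
    """Constant reproduction delays and jitter of the stimulation apparatus.

    The constants are compensated when commanded delays are computed, so the
    nominal SOA schedule is realized on average; jitter perturbs individual
    effective onsets. Defaults are the measured audio 170 +/- 5 ms and video
    150 +/- 8 ms.
    """

    audio_const_ms: float = 170.0
    audio_jitter_ms: float = 5.0
    video_const_ms: float = 150.0
    video_jitter_ms: float = 8.0

    def __post_init__(self):
        if min(self.audio_const_ms, self.video_const_ms) < 0:
            raise ValidationError("calibration constants must be nonnegative")
        if min(self.audio_jitter_ms, self.video_jitter_ms) < 0:
            raise ValidationError("jitters must be nonnegative")


def delays_for_soa(
    target_soa_ms: int, leading_delay_ms: int, spec: DesignSpec | None = None
) -> tuple[int, int]:
    """Commanded (audio, video) delays realizing ``target_soa_ms``.

    The leading modality (audio for negative SOAs, video for positive)
    receives ``leading_delay_ms``; the lagging modality receives
    ``leading_delay_ms + |soa|``. For example, a -200 ms SOA with a 200 ms
    leading delay commands audio at 200 ms and video at 400 ms.

    Raises
    ------
    InfeasibleSOAError
        If ``|soa|`` exceeds the delay span of the design.
    DelayRangeError
        If the leading delay leaves no room for the lagging stimulus.
    """
    spec = spec if spec is not None else DesignSpec()
    soa = int(target_soa_ms)
    lead = int(leading_delay_ms)
    span = spec.delay_max_ms - spec.delay_min_ms
    if abs(soa) > span:
        raise InfeasibleSOAError(
            f"|SOA| = {abs(soa)} ms exceeds the feasible span {span} ms of "
            f"delays [{spec.delay_min_ms}, {spec.delay_max_ms}]"
        )
    hi = spec.delay_max_ms - abs(soa)
    if not (spec.delay_min_ms <= lead <= hi):
        raise DelayRangeError(
            f"leading delay {lead} ms outside feasible interval "
            f"[{spec.delay_min_ms}, {hi}] for SOA {soa} ms"
        )
    if soa < 0:  # auditory leads
        audio, video = lead, lead + abs(soa)
    elif soa > 0:  # visual leads
        audio, video = lead + soa, lead
    else:
        audio = video = lead
    assert audio - video == soa
    return audio, video


def build_design(
    spec: DesignSpec,
    calibration: DeviceCalibration | None = None,
    participant: str = "p01",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate the unanswered trial table for one participant.

    Per condition, every block contains ``trials_per_soa_per_block`` trials
    at each SOA level in random order; leading delays are drawn uniformly on
    the feasible integer interval. The result is reproducible from
    ``spec.rng_seed`` (or an explicit ``rng``).

    ``calibration`` is accepted for interface symmetry but does not alter
    commanded delays: constants are compensated at design time and only act
    through :func:`effective_onsets`.
    """
    del calibration  # constants compensated at design time; see effective_onsets
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    frames = []
    per_block = len(spec.soa_levels_ms) * spec.trials_per_soa_per_block
    for condition in spec.conditions:
        for block in range(spec.blocks_per_condition):
            soas = np.repeat(spec.soa_levels_ms, spec.trials_per_soa_per_block)
            soas = soas[rng.permutation(soas.size)]
            hi = spec.delay_max_ms - np.abs(soas)
            lead = rng.integers(spec.delay_min_ms, hi + 1)
            audio = np.where(soas < 0, lead, lead + soas)
            video = np.where(soas < 0, lead - soas, lead)
            frames.append(
                pd.DataFrame(
                    {
                        "participant": participant,
                        "condition": condition,
                        "block": block,
                        "trial": block * per_block + np.arange(per_block),
                        "soa_ms": soas,
                        "audio_delay_ms": audio,
                        "video_delay_ms": video,
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    df["response"] = pd.array([pd.NA] * len(df), dtype="Int64")
    df["rejected"] = False
    return df


def effective_onsets(
    trials: pd.DataFrame,
    calibration: DeviceCalibration,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Physical stimulus onsets: commanded delay + device constant + jitter.

    Jitter is uniform on [-j, +j] per stimulus, rounded to 0.1 ms. Returns
    ``(audio_onset_ms, video_onset_ms)`` aligned with ``trials``. With equal
    constants and zero jitter the effective SOA equals the nominal SOA; with
    the default calibration and zero jitter it is nominal + 20 ms (the
    170 - 150 ms constant offset). Only the simulator's effective-onset path
    uses this; the analysis works on nominal SOA levels.
    """
    n = len(trials)
    aj = calibration.audio_jitter_ms
    vj = calibration.video_jitter_ms
    audio = (
        trials["audio_delay_ms"].to_numpy(dtype=float)
        + calibration.audio_const_ms
        + (rng.uniform(-aj, aj, size=n) if aj > 0 else 0.0)
    )
    video = (
        trials["video_delay_ms"].to_numpy(dtype=float)
        + calibration.video_const_ms
        + (rng.uniform(-vj, vj, size=n) if vj > 0 else 0.0)
    )
    return np.round(audio, 1), np.round(video, 1)
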