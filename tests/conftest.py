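import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sjwindow as sj

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec() -> sj.DesignSpec:
    return sj.DesignSpec()


@pytest.fixture(scope="session")
def default_design(default_spec) -> pd.DataFrame:
    return sj.build_design(default_spec)


@pytest.fixture()
def observer() -> sj.ObserverParams:
    """A plausible mid-cohort observer (crossings near the group means)."""
    return sj.ObserverParams(
        c_av_ms=240.0, c_va_ms=120.0, slope_av=0.02, slope_va=0.02
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_trials(soa_levels, successes, totals, participant="p01", condition="active"):
    """Expand per-SOA counts into a minimal long-format trial table."""
    rows = []
    t = 0
    for soa, k, n in zip(soa_levels, successes, totals):
        for j in range(n):
            rows.append((participant, condition, 0, t, int(soa), 1 if j < k else 0))
            t += 1
    df = pd.DataFrame(
        rows,
        columns=["participant", "condition", "block", "trial", "soa_ms", "response"],
    )
    df["audio_delay_ms"] = 300 + df["soa_ms"].clip(lower=0)
    df["video_delay_ms"] = 300 - df["soa_ms"].clip(upper=0)
    df["response"] = pd.array(df["response"], dtype="Int64")
    df["rejected"] = False
    return df


@pytest.fixture(scope="session")
def simulated_session(default_spec) -> tuple[pd.DataFrame, sj.ObserverParams]:
    params = sj.ObserverParams(240.0, 120.0, 0.02, 0.02)
    design = sj.build_design(
        sj.DesignSpec(conditions=("active",)), participant="p01"
    )
    trials = sj.simulate_session(design, params, 0, np.random.default_rng(7))
    return trials, params
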