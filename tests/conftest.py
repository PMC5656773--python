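import numpy as np
import pytest

from fallstack.features import features_dataframe
from fallstack.preprocess import WindowingConfig, extract_activity_clips, \
    extract_fall_clips, magnitude_filter
from fallstack.simulate import SimConfig, simulate_lab_session
from fallstack.types import CLIP_SAMPLES, Clip


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Compact protocol: 2 carry locations, short activity intervals."""
    return SimConfig(
        seed=42,
        n_subjects={"control": 3, "amputee": 2},
        carry_locations=("waist", "pocket"),
        activity_duration_s=40.0,
    )


@pytest.fixture(scope="session")
def wcfg() -> WindowingConfig:
    return WindowingConfig(rng_seed=7)


@pytest.fixture(scope="session")
def lab_session(small_config):
    """One simulated control subject: (stream, events)."""
    return simulate_lab_session(small_config, "C01", "control")


@pytest.fixture(scope="session")
def lab_clips(lab_session, wcfg):
    """All clips of the session: fall clips plus 2 g-filtered activity clips."""
    stream, events = lab_session
    rng = np.random.default_rng(123)
    clips = []
    for event in events:
        if event.is_fall:
            clips.extend(extract_fall_clips(stream, event, wcfg, rng=rng))
    activity = extract_activity_clips(
        stream, [e for e in events if not e.is_fall], wcfg
    )
    clips.extend(magnitude_filter(activity, wcfg.filter_threshold_g))
    return clips


@pytest.fixture(scope="session")
def lab_features(lab_clips):
    return features_dataframe(lab_clips)


def random_clip(rng: np.random.Generator, scale: float = 1.0) -> Clip:
    """An unstructured random clip for oracle comparisons."""
    return Clip(
        subject="X",
        population="control",
        location="waist",
        is_fall=False,
        accel=rng.normal(0, scale, (3, CLIP_SAMPLES)),
        gyro=rng.normal(0, 50 * scale, (3, CLIP_SAMPLES)),
    )


@pytest.fixture(scope="session")
def synthetic_feature_table():
    """Directly constructed feature table with a separable class structure.

    Bypasses the simulator: 8 subjects x 30 clips with Gaussian features
    where the two classes differ in mean on a handful of columns. Useful
    for fast detector tests.
    """
    from fallstack.features import FEATURE_NAMES, META_COLUMNS
    import pandas as pd

    rng = np.random.default_rng(2024)
    rows = []
    values = []
    clip_id = 0
    for s in range(8):
        for k in range(30):
            is_fall = k < 15
            x = rng.normal(0, 1, 40)
            if is_fall:
                x[:6] += 2.5
            values.append(x)
            rows.append(
                {
                    "clip_id": clip_id,
                    "subject": f"S{s:02d}",
                    "population": "control",
                    "location": "waist",
                    "is_fall": is_fall,
                }
            )
            clip_id += 1
    df = pd.DataFrame(rows, columns=META_COLUMNS)
    feats = pd.DataFrame(np.array(values), columns=list(FEATURE_NAMES))
    # keep the threshold feature positive and class-separated
    feats["accel.resultant.max"] = np.abs(feats["accel.resultant.max"]) + 1.0
    return pd.concat([df, feats], axis=1)
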