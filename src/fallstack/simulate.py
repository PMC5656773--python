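"""Seeded synthetic IMU generator for fall-detection experiments.

Real fall/activity recordings from phone sensors are rarely shareable, so
this module synthesizes streams with the statistical structure the analysis
pipeline assumes:

* falls are short events with a sub-1 g free-fall dip, a sharp impact peak
  whose magnitude is heavy-tailed (lognormal, truncated below 2 g) and
  carry-location dependent, a body rotation captured by the gyroscope, and
  a post-impact rest phase;
* activities of daily living stay below 2 g except for sporadic
  phone-handling and phone-set-down transients (Poisson-timed), which are
  the confounders a peak-acceleration threshold cannot reject;
* the two populations ("control", "amputee") differ only in gait
  parameters (cadence and step asymmetry), never in fall morphology — the
  structural assumption behind training on one population and testing on
  the other;
* timestamps carry uniform jitter around the nominal 50 Hz grid, so
  downstream resampling is always exercised.

Signals are synthesized as a magnitude profile times a unit direction
vector, so the resultant acceleration is controlled exactly and is
invariant under the carry-orientation rotation applied afterwards.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .types import AnnotationEvent, SensorStream, VALID_LOCATIONS

FALL_TYPES = ("trip", "slip", "lateral_left", "lateral_right")
ACTIVITIES = ("sitting", "standing", "walking", "stairs", "lying")

#: Body-frame rotation axis of each fall type (phone pitches forward in a
#: trip, backward in a slip, rolls sideways in lateral falls).
_FALL_AXES = {
    "trip": np.array([1.0, 0.0, 0.0]),
    "slip": np.array([-1.0, 0.0, 0.0]),
    "lateral_left": np.array([0.0, 1.0, 0.0]),
    "lateral_right": np.array([0.0, -1.0, 0.0]),
}

_GRAVITY_BODY = np.array([0.0, 0.0, 1.0])


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    ``fall_peak_g`` maps carry location to (median_g, sigma_log) of a
    lognormal impact-peak distribution, truncated below at 2 g by
    rejection; medians sit in [3, 8] g so the 2 g pre-filter retains
    essentially all falls. ``adl_supra2g_rate`` is the expected number of
    supra-2 g transients per hour of free living. ``gait_asymmetry`` maps
    population to a step-asymmetry scalar in [0, 1] (0 = symmetric gait);
    it is the only population-dependent parameter.
    """

    seed: int = 0
    sampling_rate_hz: float = 50.0
    timestamp_jitter: float = 0.1  # fraction of the nominal interval
    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"control": 10, "amputee": 6}
    )
    fall_peak_g: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "waist": (5.0, 0.25),
            "pocket": (6.0, 0.25),
            "hand": (4.0, 0.25),
        }
    )
    adl_supra2g_rate: float = 9.0  # per hour, free-living
    lab_handling_rate: float = 120.0  # per hour, during the activity protocol
    gait_asymmetry: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0, "amputee": 0.4}
    )
    carry_locations: tuple[str, ...] = ("waist", "pocket", "hand")
    home_days: float = 2.0
    falls_per_type: int = 3
    activity_duration_s: float = 60.0

    def validate(self) -> None:
        if len(self.carry_locations) == 0:
            raise ValueError("carry_locations must not be empty")
        for loc in self.carry_locations:
            if loc not in VALID_LOCATIONS:
                raise ValueError(f"unknown carry location {loc!r}")
            if loc not in self.fall_peak_g:
                raise ValueError(f"no fall_peak_g entry for location {loc!r}")
            median, sigma = self.fall_peak_g[loc]
            if median <= 2.0 or sigma <= 0:
                raise ValueError(
                    f"fall_peak_g[{loc!r}] = ({median}, {sigma}) is not a "
                    "valid truncated-lognormal spec (median must exceed 2 g)"
                )
        if self.adl_supra2g_rate < 0 or self.lab_handling_rate < 0:
            raise ValueError("transient rates must be non-negative")
        if not 0 <= self.timestamp_jitter < 0.5:
            raise ValueError("timestamp_jitter must lie in [0, 0.5)")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")


@dataclass
class FallKernel:
    """Parametric description of one fall waveform.

    The rendered resultant acceleration is ~1 g in quiet segments, dips to
    ``pre_fall_dip_g`` (< 1 g, the free-fall phase), rises to a single
    global maximum of exactly ``impact_peak_g``, rings down over a short
    settle phase and rests at 1 g for ``post_rest_s``.
    """

    fall_type: str
    impact_peak_g: float
    pre_fall_dip_g: float
    pre_fall_s: float = 0.4
    impact_width_s: float = 0.12
    post_rest_s: float = 3.0

    def __post_init__(self) -> None:
        if self.fall_type not in FALL_TYPES:
            raise ValueError(f"unknown fall type {self.fall_type!r}")
        if not 0 < self.pre_fall_dip_g < 1:
            raise ValueError("pre_fall_dip_g must lie in (0, 1) g")
        if self.impact_peak_g <= 1:
            raise ValueError("impact_peak_g must exceed 1 g")


def subject_rng(seed: int, subject: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for one (seed, subject) pair."""
    return np.random.default_rng([seed, zlib.crc32(subject.encode())])


def sample_fall_peak(
    rng: np.random.Generator, median_g: float, sigma_log: float, size: int = 1
) -> np.ndarray:
    """Draw impact peaks from a lognormal truncated below at 2 g."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(np.log(median_g), sigma_log, size=size - filled)
        keep = draw[draw > 2.0]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def sample_fall_kernel(
    rng: np.random.Generator, fall_type: str, median_g: float, sigma_log: float
) -> FallKernel:
    peak = float(sample_fall_peak(rng, median_g, sigma_log, 1)[0])
    # free-fall dip deepens with impact energy; weak falls barely dip,
    # which is what makes the low-peak regime genuinely hard
    dip = float(np.clip(1.0 - 0.16 * (peak - 1.0) + rng.normal(0, 0.03), 0.25, 0.92))
    return FallKernel(
        fall_type=fall_type,
        impact_peak_g=peak,
        pre_fall_dip_g=dip,
        pre_fall_s=float(rng.uniform(0.3, 0.5)),
        impact_width_s=float(rng.uniform(0.10, 0.16)),
        post_rest_s=3.0,
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (carry orientation)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _plateau_bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine pulse clipped to a flat top.

    The flat top spans ~24% of ``width``, wider than the worst-case jittered
    sample spacing at 50 Hz, so at least one raw sample attains the exact
    peak value regardless of grid phase.
    """
    tau = (t - center) / width + 0.5
    bump = np.where(
        (tau >= 0) & (tau <= 1), 1.15 * 0.5 * (1 - np.cos(2 * np.pi * tau)), 0.0
    )
    return np.minimum(bump, 1.0)


def _smoothstep(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    x = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return x * x * (3 - 2 * x)


def _smooth_noise(rng: np.random.Generator, n: int, scale: float, corr: int = 8
                  ) -> np.ndarray:
    """Band-limited noise: white noise smoothed with a short boxcar."""
    if n == 0:
        return np.zeros(0)
    w = rng.normal(0, scale, n + corr)
    kernel = np.ones(corr) / corr
    return np.convolve(w, kernel, mode="valid")[:n]


def render_fall(
    kernel: FallKernel,
    orientation: np.ndarray,
    rate_hz: float,
    rng: np.random.Generator | None = None,
    lead_s: float = 5.0,
    trail_s: float = 2.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Render one fall as a 6-channel segment on a uniform grid.

    Returns ``(t, accel, gyro, onset_s, peak_s)`` with accel (N, 3) in g and
    gyro (N, 3) in deg/s; ``onset_s`` is the start of the free-fall dip and
    ``peak_s`` the impact time, both in segment-local seconds. The resultant
    acceleration is independent of ``orientation``.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    orientation = np.asarray(orientation, dtype=float)
    if orientation.shape != (3, 3) or not np.allclose(
        orientation @ orientation.T, np.eye(3), atol=1e-8
    ):
        raise ValueError("orientation must be a 3x3 rotation matrix")
    if rng is None:
        rng = np.random.default_rng(0)

    settle_s = 0.8
    total = lead_s + kernel.pre_fall_s + kernel.impact_width_s + settle_s + \
        kernel.post_rest_s + trail_s
    n = int(round(total * rate_hz))
    t = np.arange(n) / rate_hz

    onset = lead_s
    impact_start = onset + kernel.pre_fall_s
    peak_t = impact_start + kernel.impact_width_s / 2.0
    settle_start = impact_start + kernel.impact_width_s

    # --- resultant magnitude profile ---
    m = 1.0 + _smooth_noise(rng, n, 0.015)
    dip_phase = (t >= onset) & (t < impact_start)
    tau = (t[dip_phase] - onset) / kernel.pre_fall_s
    m[dip_phase] = kernel.pre_fall_dip_g + (1 - kernel.pre_fall_dip_g) * 0.5 * (
        1 + np.cos(np.pi * tau)
    )
    bump = _plateau_bump(t, peak_t, kernel.impact_width_s)
    in_impact = bump > 0
    base_impact = kernel.pre_fall_dip_g
    m[in_impact] = base_impact + (kernel.impact_peak_g - base_impact) * bump[in_impact]
    # post-impact ring-down around 1 g
    ring = (t >= settle_start) & (t < settle_start + settle_s)
    tau_r = t[ring] - settle_start
    amp = min(0.5, 0.15 * (kernel.impact_peak_g - 1.0))
    m[ring] = 1.0 + amp * np.exp(-tau_r / 0.25) * np.cos(2 * np.pi * 6 * tau_r) \
        + _smooth_noise(rng, int(ring.sum()), 0.01)
    m = np.maximum(m, 0.02)

    # --- body rotation: gravity direction tips about the fall axis ---
    axis = _FALL_AXES[kernel.fall_type]
    theta_end = np.deg2rad(
        np.clip(18.0 * kernel.impact_peak_g, 30.0, 95.0) + rng.normal(0, 5)
    )
    theta = theta_end * _smoothstep(t, onset, settle_start + 0.2)
    k_cross_g = np.cross(axis, _GRAVITY_BODY)
    u = (
        np.outer(np.cos(theta), _GRAVITY_BODY)
        + np.outer(np.sin(theta), k_cross_g)
    )
    accel_body = m[:, None] * u

    # --- gyroscope: rotation rate about the fall axis + impact jolt ---
    dtheta = np.gradient(theta, t)
    gyro_body = np.outer(np.rad2deg(dtheta), axis)
    jolt = 25.0 * kernel.impact_peak_g * bump
    jolt_axis = rng.normal(size=3)
    jolt_axis /= np.linalg.norm(jolt_axis)
    gyro_body = gyro_body + np.outer(jolt, jolt_axis)
    gyro_body += np.column_stack(
        [_smooth_noise(rng, n, 1.5) for _ in range(3)]
    )

    accel = accel_body @ orientation.T
    gyro = gyro_body @ orientation.T
    return t, accel, gyro, onset, peak_t


def _add_transients(
    m: np.ndarray,
    gyro: np.ndarray,
    t: np.ndarray,
    rng: np.random.Generator,
    rate_hz: float,
    n_events: int,
    margin_s: float = 3.0,
) -> None:
    """Inject supra-2 g phone transients in place.

    Two morphologies, equally likely: "handling" (a spike with ongoing
    motion afterwards — phone pulled out of a pocket) and "set-down" (a
    spike followed by ~1 s of stillness — phone dropped onto a table),
    the latter being the classic fall confounder.
    """
    duration = t[-1]
    if n_events <= 0 or duration <= 2 * margin_s:
        return
    times = np.sort(rng.uniform(margin_s, duration - margin_s, n_events))
    for t_ev in times:
        peak = float(
            np.clip(rng.lognormal(np.log(2.8), 0.30), 2.05, None)
        )
        width = float(rng.uniform(0.10, 0.20))
        # operate on a local slice: streams can be millions of samples long
        j0 = int(np.searchsorted(t, t_ev - width))
        j1 = int(np.searchsorted(t, t_ev + width))
        bump = _plateau_bump(t[j0:j1], t_ev, width)
        sel = np.nonzero(bump > 0)[0] + j0
        bump = bump[bump > 0]
        m[sel] = m[sel] * (1 - bump) + peak * bump
        is_setdown = rng.random() < 0.5
        g_amp = rng.uniform(30, 80) if is_setdown else rng.uniform(60, 160)
        g_axis = rng.normal(size=3)
        g_axis /= np.linalg.norm(g_axis)
        gyro[sel] += np.outer(bump * g_amp, g_axis)
        if is_setdown:
            i0 = int(np.searchsorted(t, t_ev + width))
            i1 = min(int(np.searchsorted(t, t_ev + width + 1.0)), len(m))
            m[i0:i1] = 1.0 + _smooth_noise(rng, i1 - i0, 0.004)
            gyro[i0:i1] = _smooth_noise(rng, i1 - i0, 0.5)[:, None]


def _gait_magnitude(
    t: np.ndarray, rng: np.random.Generator, label: str, asymmetry: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vertical-bounce magnitude modulation and sway rate for locomotion."""
    step_hz = (1.8 if label == "walking" else 1.4) * (1 - 0.15 * asymmetry)
    amp = 0.25 if label == "walking" else 0.35
    phase = 2 * np.pi * step_hz * t + rng.uniform(0, 2 * np.pi)
    # alternate steps differ in amplitude by the asymmetry factor
    envelope = 1.0 + 0.5 * asymmetry * np.sign(np.sin(phase / 2.0))
    mag = amp * envelope * np.abs(np.sin(phase)) ** 1.5
    sway = 25.0 * np.sin(phase / 2.0)
    return mag, sway


def _activity_segment(
    label: str,
    duration_s: float,
    rng: np.random.Generator,
    rate_hz: float,
    asymmetry: float,
    transient_rate_per_h: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one activity interval; returns (t, accel, gyro) in body frame."""
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    m = 1.0 + _smooth_noise(rng, n, 0.012)
    gyro = np.column_stack([_smooth_noise(rng, n, 2.0) for _ in range(3)])

    if label in ("walking", "stairs"):
        mag, sway = _gait_magnitude(t, rng, label, asymmetry)
        m = m + mag
        gyro[:, 2] += sway
    elif label in ("sitting", "standing") and duration_s > 5.0:
        # occasional postural shifts, sub-2 g
        for _ in range(rng.poisson(duration_s / 30.0)):
            c = rng.uniform(2.0, duration_s - 2.0)
            b = _plateau_bump(t, c, rng.uniform(0.4, 0.8))
            m = m + rng.uniform(0.2, 0.7) * b
            gyro[:, rng.integers(3)] += 20.0 * b

    n_transients = rng.poisson(transient_rate_per_h * duration_s / 3600.0)
    _add_transients(m, gyro, t, rng, rate_hz, n_transients, margin_s=2.5)

    # slowly wandering gravity direction
    tilt = _smooth_noise(rng, n, 0.3, corr=int(rate_hz * 2))
    u = np.column_stack([np.sin(tilt), np.zeros(n), np.cos(tilt)])
    accel = np.maximum(m, 0.02)[:, None] * u
    return t, accel, gyro


def _jittered_timestamps(
    n: int, rate_hz: float, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    dt = 1.0 / rate_hz
    return (np.arange(n) + jitter * rng.uniform(-1, 1, n)) * dt


def simulate_lab_session(
    config: SimConfig, subject: str, population: str
) -> tuple[SensorStream, list[AnnotationEvent]]:
    """Simulate one subject's full lab protocol.

    For each carry location the subject performs every fall type
    ``falls_per_type`` times (4 types x 3 repetitions x |locations| fall
    annotations in total) followed by one interval per activity. Fall
    impact peaks are drawn from the location's truncated lognormal;
    activity intervals carry supra-2 g phone transients at the configured
    lab rate.
    """
    config.validate()
    if population not in config.gait_asymmetry:
        raise ValueError(f"no gait_asymmetry entry for population {population!r}")
    rng = subject_rng(config.seed, subject)
    rate = config.sampling_rate_hz
    asym = config.gait_asymmetry[population]

    chunks_a: list[np.ndarray] = []
    chunks_g: list[np.ndarray] = []
    events: list[AnnotationEvent] = []
    t_cursor = 0.0
    n_total = 0

    def _append(accel: np.ndarray, gyro: np.ndarray, seconds: float) -> float:
        nonlocal t_cursor, n_total
        start = t_cursor
        chunks_a.append(accel)
        chunks_g.append(gyro)
        n_total += len(accel)
        t_cursor += seconds
        return start

    def _gap(seconds: float = 2.0) -> None:
        n = int(round(seconds * rate))
        quiet = 1.0 + _smooth_noise(rng, n, 0.01)
        u = np.tile(_GRAVITY_BODY, (n, 1))
        g = np.column_stack([_smooth_noise(rng, n, 1.0) for _ in range(3)])
        _append(quiet[:, None] * u, g, n / rate)

    for location in config.carry_locations:
        orientation = random_rotation(rng)
        median_g, sigma_log = config.fall_peak_g[location]
        for fall_type in FALL_TYPES:
            for _ in range(config.falls_per_type):
                kernel = sample_fall_kernel(rng, fall_type, median_g, sigma_log)
                t_seg, accel, gyro, onset, peak_t = render_fall(
                    kernel, orientation, rate, rng
                )
                seg_len = len(t_seg) / rate
                start = _append(accel, gyro, seg_len)
                rest_end = onset + kernel.pre_fall_s + kernel.impact_width_s \
                    + 0.8 + kernel.post_rest_s
                events.append(
                    AnnotationEvent(
                        subject=subject,
                        population=population,
                        label=fall_type,
                        is_fall=True,
                        location=location,
                        t_start=start + onset,
                        t_end=start + rest_end,
                    )
                )
                _gap()
        for activity in ACTIVITIES:
            t_seg, accel_b, gyro_b = _activity_segment(
                activity,
                config.activity_duration_s,
                rng,
                rate,
                asym,
                config.lab_handling_rate,
            )
            accel = accel_b @ orientation.T
            gyro = gyro_b @ orientation.T
            start = _append(accel, gyro, len(t_seg) / rate)
            events.append(
                AnnotationEvent(
                    subject=subject,
                    population=population,
                    label=activity,
                    is_fall=False,
                    location=location,
                    t_start=start,
                    t_end=start + len(t_seg) / rate,
                )
            )
            _gap()

    accel = np.vstack(chunks_a)
    gyro = np.vstack(chunks_g)
    timestamps = _jittered_timestamps(
        len(accel), rate, config.timestamp_jitter, rng
    )
    stream = SensorStream(
        subject=subject,
        population=population,
        timestamps=timestamps,
        accel=accel,
        gyro=gyro,
    )
    return stream, events


def simulate_home_stream(config: SimConfig, subject: str,
                         population: str = "amputee") -> SensorStream:
    """Simulate a free-living ("home") recording with no falls.

    The stream spans ``home_days`` x 24 h of gap-free samples: a quiet
    baseline with hourly walking bouts and Poisson-timed supra-2 g phone
    transients at ``adl_supra2g_rate`` per hour. The expected number of
    5 s windows exceeding 2 g is therefore ~rate x 24 x home_days.
    """
    config.validate()
    if config.home_days <= 0:
        raise ValueError("home_days must be positive")
    rng = subject_rng(config.seed, subject + "/home")
    rate = config.sampling_rate_hz
    asym = config.gait_asymmetry.get(population, 0.0)

    n = int(round(config.home_days * 24 * 3600 * rate))
    t = np.arange(n) / rate
    m = 1.0 + _smooth_noise(rng, n, 0.012)
    gyro = np.column_stack([_smooth_noise(rng, n, 2.0) for _ in range(3)])

    # one ~10 min walking bout per simulated hour
    n_hours = int(config.home_days * 24)
    for h in range(n_hours):
        bout_len = rng.uniform(420, 780)
        start = h * 3600 + rng.uniform(0, 3600 - bout_len)
        i0, i1 = int(start * rate), int((start + bout_len) * rate)
        tb = t[i0:i1] - t[i0]
        mag, sway = _gait_magnitude(tb, rng, "walking", asym)
        m[i0:i1] += mag
        gyro[i0:i1, 2] += sway

    n_transients = rng.poisson(config.adl_supra2g_rate * config.home_days * 24)
    _add_transients(m, gyro, t, rng, rate, n_transients, margin_s=3.0)

    tilt = _smooth_noise(rng, n, 0.3, corr=int(rate * 2))
    u = np.column_stack([np.sin(tilt), np.zeros(n), np.cos(tilt)])
    accel_body = np.maximum(m, 0.02)[:, None] * u
    orientation = random_rotation(rng)
    accel = accel_body @ orientation.T
    gyro = gyro @ orientation.T
    timestamps = _jittered_timestamps(n, rate, config.timestamp_jitter, rng)
    return SensorStream(
        subject=subject,
        population=population,
        timestamps=timestamps,
        accel=accel,
        gyro=gyro,
    )


def subject_ids(config: SimConfig, population: str) -> list[str]:
    """Canonical subject identifiers for one population of the cohort."""
    n = config.n_subjects[population]
    prefix = {"control": "C", "amputee": "A"}[population]
    return [f"{prefix}{i + 1:02d}" for i in range(n)]
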