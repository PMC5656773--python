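"""Windowing of annotated streams into labeled 5 s clips.

Falls are windowed around the impact (the resultant-acceleration peak
inside the annotated event): a 10 s clip centered on the peak is cut and
ten 5 s windows are drawn from it such that the annotated fall onset sits
at a Uniform(0 s, 3 s) offset from each window start. Activities are tiled
with non-overlapping 5 s windows, and only activity windows whose peak
resultant acceleration exceeds 2 g — the transients a threshold detector
would confuse with falls — are kept. All clips are resampled to a uniform
50 Hz grid (250 samples) with a cubic spline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .types import CLIP_LEN_S, CLIP_RATE_HZ, CLIP_SAMPLES, AnnotationEvent, Clip, \
    SensorStream


@dataclass
class WindowingConfig:
    clip_len_s: float = 5.0
    event_window_s: float = 10.0
    windows_per_fall: int = 10
    onset_range_s: tuple[float, float] = (0.0, 3.0)
    filter_threshold_g: float = 2.0
    target_rate_hz: float = 50.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.event_window_s < self.clip_len_s:
            raise ValueError("event_window_s must be >= clip_len_s")
        lo, hi = self.onset_range_s
        if not (0 <= lo < hi <= self.clip_len_s):
            raise ValueError("onset_range_s must lie within [0, clip_len_s)")
        if self.filter_threshold_g <= 0:
            raise ValueError("filter_threshold_g must be positive")
        if self.windows_per_fall < 1:
            raise ValueError("windows_per_fall must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.clip_len_s * self.target_rate_hz))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


def resample_channels(
    t: np.ndarray, values: np.ndarray, t0: float, n_samples: int, rate_hz: float
) -> np.ndarray:
    """Cubic-spline resample (N, C) samples onto a uniform grid.

    The spline uses not-a-knot boundary conditions, so it reproduces cubic
    polynomials exactly and passes through every input sample. Returns a
    (C, n_samples) matrix evaluated at ``t0 + i / rate_hz``.
    """
    t = np.asarray(t, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == t.shape[0]:
        values = values.T  # accept (N, C) or (C, N)
    if t.shape[0] < 4:
        raise ValueError(f"need >= 4 samples for cubic resampling, got {t.shape[0]}")
    grid = t0 + np.arange(n_samples) / rate_hz
    span_needed = (n_samples - 1) / rate_hz
    # tolerate sub-sample jitter at the edges; anything more is a real gap
    edge_tol = 1.5 / rate_hz
    if t[0] > t0 + edge_tol or t[-1] < t0 + span_needed - edge_tol:
        raise ValueError(
            f"raw segment [{t[0]:.3f}, {t[-1]:.3f}] does not span the "
            f"requested window [{t0:.3f}, {t0 + span_needed:.3f}]"
        )
    spline = CubicSpline(t, values.T, bc_type="not-a-knot", extrapolate=True)
    return spline(grid).T


def resample_clip(
    t: np.ndarray,
    accel: np.ndarray,
    gyro: np.ndarray,
    cfg: WindowingConfig,
    *,
    t0: float | None = None,
    subject: str = "",
    population: str = "control",
    location: str = "waist",
    is_fall: bool = False,
    source_label: str = "",
    onset_offset_s: float | None = None,
) -> Clip:
    """Resample one timestamped 6-channel segment to a 250-sample Clip."""
    t = np.asarray(t, dtype=float)
    if t0 is None:
        t0 = float(t[0])
    if t[-1] - t[0] < cfg.clip_len_s - 2.0 / cfg.target_rate_hz:
        raise ValueError(
            f"segment spans {t[-1] - t[0]:.3f} s < clip length {cfg.clip_len_s} s"
        )
    a = resample_channels(t, accel, t0, cfg.n_samples, cfg.target_rate_hz)
    g = resample_channels(t, gyro, t0, cfg.n_samples, cfg.target_rate_hz)
    return Clip(
        subject=subject,
        population=population,
        location=location,
        is_fall=is_fall,
        accel=a,
        gyro=g,
        source_label=source_label,
        window_start_s=t0,
        onset_offset_s=onset_offset_s,
    )


def _slice(stream: SensorStream, t_lo: float, t_hi: float) -> np.ndarray:
    i0 = int(np.searchsorted(stream.timestamps, t_lo, side="left"))
    i1 = int(np.searchsorted(stream.timestamps, t_hi, side="right"))
    return np.arange(i0, i1)


def find_impact_peak(stream: SensorStream, event: AnnotationEvent) -> float:
    """Time of the maximum resultant acceleration within the event.

    Ties are broken toward the earliest sample; the search uses the
    accelerometer only.
    """
    idx = _slice(stream, event.t_start, event.t_end)
    if idx.size == 0:
        raise ValueError(
            f"no samples inside event {event.label!r} "
            f"[{event.t_start}, {event.t_end}] of subject {event.subject}"
        )
    norm = np.linalg.norm(stream.accel[idx], axis=1)
    return float(stream.timestamps[idx[int(np.argmax(norm))]])


def extract_fall_clips(
    stream: SensorStream,
    event: AnnotationEvent,
    cfg: WindowingConfig,
    rng: np.random.Generator | None = None,
) -> list[Clip]:
    """Cut ``windows_per_fall`` randomized 5 s clips around one fall impact."""
    if not event.is_fall:
        raise ValueError(f"event {event.label!r} is not a fall")
    if rng is None:
        rng = cfg.rng()
    peak_t = find_impact_peak(stream, event)
    half = cfg.event_window_s / 2.0
    pad = 3.0 / cfg.target_rate_hz
    if stream.timestamps[0] > peak_t - half + pad or \
            stream.timestamps[-1] < peak_t + half - pad:
        raise ValueError(
            f"stream does not cover the {cfg.event_window_s:.0f} s window "
            f"around the impact of event {event.label!r} at t={peak_t:.2f} s "
            f"(subject {event.subject})"
        )
    clips = []
    for _ in range(cfg.windows_per_fall):
        offset = rng.uniform(*cfg.onset_range_s)
        w0 = event.t_start - offset
        if w0 < peak_t - half - 1e-9 or w0 + cfg.clip_len_s > peak_t + half + 1e-9:
            raise ValueError(
                f"window [{w0:.2f}, {w0 + cfg.clip_len_s:.2f}] falls outside "
                f"the event clip of {event.label!r} at t={peak_t:.2f} s"
            )
        idx = _slice(stream, w0 - 0.2, w0 + cfg.clip_len_s + 0.2)
        clips.append(
            resample_clip(
                stream.timestamps[idx],
                stream.accel[idx],
                stream.gyro[idx],
                cfg,
                t0=w0,
                subject=event.subject,
                population=event.population,
                location=event.location,
                is_fall=True,
                source_label=event.label,
                onset_offset_s=offset,
            )
        )
    return clips


def extract_activity_clips(
    stream: SensorStream,
    events: list[AnnotationEvent],
    cfg: WindowingConfig,
) -> list[Clip]:
    """Tile each non-fall interval with non-overlapping 5 s windows.

    Windows are half-open ``[start, start + 5 s)``; a trailing remainder
    shorter than 5 s is dropped. Fall events in ``events`` are ignored.
    """
    clips = []
    for event in events:
        if event.is_fall:
            continue
        n_windows = int(np.floor(event.duration / cfg.clip_len_s))
        for k in range(n_windows):
            w0 = event.t_start + k * cfg.clip_len_s
            idx = _slice(stream, w0 - 0.2, w0 + cfg.clip_len_s + 0.2)
            clips.append(
                resample_clip(
                    stream.timestamps[idx],
                    stream.accel[idx],
                    stream.gyro[idx],
                    cfg,
                    t0=w0,
                    subject=event.subject,
                    population=event.population,
                    location=event.location,
                    is_fall=False,
                    source_label=event.label,
                )
            )
    return clips


def magnitude_filter(clips: list[Clip], threshold_g: float = 2.0) -> list[Clip]:
    """Keep clips whose peak resultant acceleration strictly exceeds the
    threshold. Intended for activity/home clips; fall clips are retained by
    construction (the threshold is calibrated as the falls' 1st percentile)
    and should not be passed through this filter."""
    if threshold_g < 0:
        raise ValueError("threshold_g must be non-negative")
    return [c for c in clips if c.max_resultant_accel() > threshold_g]


def extract_home_clips(stream: SensorStream, cfg: WindowingConfig,
                       location: str = "pocket") -> list[Clip]:
    """Window a free-living stream and keep only supra-threshold clips.

    The whole stream is tiled with non-overlapping 5 s windows. Windows are
    pre-screened on the raw resultant (cheap, vectorized) and only
    candidates near the threshold are resampled, after which the magnitude
    filter is applied to the resampled clips — the retained set is the same
    as filtering every resampled window, at a fraction of the cost.
    """
    t = stream.timestamps
    norm = np.linalg.norm(stream.accel, axis=1)
    n_windows = int(np.floor((t[-1] - t[0]) / cfg.clip_len_s))
    edges = t[0] + cfg.clip_len_s * np.arange(n_windows + 1)
    bounds = np.searchsorted(t, edges[:-1], side="left")
    w_max = np.maximum.reduceat(norm, bounds)
    w_max[np.diff(np.append(bounds, len(t))) == 0] = 0.0
    # raw peak within 5% of threshold -> resample and decide exactly
    candidates = np.nonzero(w_max > 0.95 * cfg.filter_threshold_g)[0]
    clips = []
    for k in candidates:
        w0 = t[0] + k * cfg.clip_len_s
        idx = _slice(stream, w0 - 0.2, w0 + cfg.clip_len_s + 0.2)
        clips.append(
            resample_clip(
                t[idx],
                stream.accel[idx],
                stream.gyro[idx],
                cfg,
                t0=w0,
                subject=stream.subject,
                population=stream.population,
                location=location,
                is_fall=False,
                source_label="home",
            )
        )
    return magnitude_filter(clips, cfg.filter_threshold_g)
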