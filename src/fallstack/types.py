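"""Canonical in-memory records shared by every stage of the pipeline.

Units are fixed across the package: accelerometer channels in g (gravity
included, so a resting phone reads a resultant of ~1 g), gyroscope channels
in deg/s, and time in seconds from the start of each recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Number of samples per channel in a resampled clip (5 s at 50 Hz).
CLIP_SAMPLES = 250
#: Uniform sampling rate of resampled clips, Hz.
CLIP_RATE_HZ = 50.0
#: Clip duration, seconds.
CLIP_LEN_S = 5.0

VALID_LOCATIONS = ("waist", "pocket", "hand")
VALID_POPULATIONS = ("control", "amputee")


@dataclass
class SensorStream:
    """One subject's continuous 6-channel IMU recording.

    Attributes
    ----------
    subject : str
        Subject identifier.
    population : str
        ``"control"`` or ``"amputee"``.
    timestamps : ndarray, shape (N,)
        Seconds from stream start, strictly increasing.
    accel : ndarray, shape (N, 3)
        Accelerometer x/y/z in g.
    gyro : ndarray, shape (N, 3)
        Gyroscope x/y/z in deg/s.
    """

    subject: str
    population: str
    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.timestamps.shape[0]
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError(
                f"accel/gyro must be (N, 3) matching {n} timestamps; "
                f"got accel {self.accel.shape}, gyro {self.gyro.shape}"
            )
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if (
            not np.all(np.isfinite(self.timestamps))
            or not np.all(np.isfinite(self.accel))
            or not np.all(np.isfinite(self.gyro))
        ):
            raise ValueError("stream contains non-finite values")
        if self.population not in VALID_POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")

    @property
    def duration_s(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def resultant_accel(self) -> np.ndarray:
        """Euclidean norm of the three accelerometer axes, in g."""
        return np.linalg.norm(self.accel, axis=1)


@dataclass
class AnnotationEvent:
    """A labeled interval of one subject's stream (a fall trial or activity)."""

    subject: str
    population: str
    label: str
    is_fall: bool
    location: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.location not in VALID_LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.population not in VALID_POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        if not self.t_end > self.t_start:
            raise ValueError(
                f"event {self.label!r}: t_end ({self.t_end}) must exceed "
                f"t_start ({self.t_start})"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class Clip:
    """A 5 s, 50 Hz window of resampled IMU data — the classification unit.

    ``accel`` and ``gyro`` are (3, 250) matrices (channels x samples) on a
    uniform 1/50 s grid. ``onset_offset_s`` is, for fall clips, the offset of
    the annotated fall onset from the window start (the quantity that is
    uniform on (0 s, 3 s) by construction of the windowing).
    """

    subject: str
    population: str
    location: str
    is_fall: bool
    accel: np.ndarray
    gyro: np.ndarray
    source_label: str = ""
    window_start_s: float = 0.0
    onset_offset_s: float | None = None

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        expected = (3, CLIP_SAMPLES)
        if self.accel.shape != expected or self.gyro.shape != expected:
            raise ValueError(
                f"clip matrices must be {expected}; got accel "
                f"{self.accel.shape}, gyro {self.gyro.shape}"
            )

    def resultant_accel(self) -> np.ndarray:
        return np.linalg.norm(self.accel, axis=0)

    def resultant_gyro(self) -> np.ndarray:
        return np.linalg.norm(self.gyro, axis=0)

    def max_resultant_accel(self) -> float:
        return float(self.resultant_accel().max())


def check_no_overlap(events: list[AnnotationEvent]) -> None:
    """Raise if any two events of the same subject overlap in time."""
    by_subject: dict[str, list[AnnotationEvent]] = {}
    for ev in events:
        by_subject.setdefault(ev.subject, []).append(ev)
    for subject, evs in by_subject.items():
        ordered = sorted(evs, key=lambda e: e.t_start)
        for a, b in zip(ordered, ordered[1:]):
            if b.t_start < a.t_end:
                raise ValueError(
                    f"overlapping events for subject {subject}: "
                    f"{a.label!r} [{a.t_start}, {a.t_end}) and "
                    f"{b.label!r} [{b.t_start}, {b.t_end})"
                )
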