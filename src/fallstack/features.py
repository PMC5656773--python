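"""The 40-dimensional clip descriptor (20 features per sensor).

For each sensor (accelerometer, gyroscope) the descriptor contains, on the
resultant signal sqrt(x^2 + y^2 + z^2): mean, median, standard deviation,
skewness, excess kurtosis, IQR, minimum, maximum, plus the IQR / minimum /
maximum of the resultant's first-difference derivative (11 features); and
per axis x, y, z: maximum, minimum, IQR (9 features).

Conventions (fixed so the descriptor is exactly reproducible):

* standard deviation is the population standard deviation (ddof = 0);
* skewness and kurtosis are standardized central moments, kurtosis as
  excess (Gaussian -> 0); a zero-variance signal maps both to 0;
* IQR is the 75th minus 25th percentile with linear-interpolation
  quantiles;
* the derivative is the first difference scaled by the sampling rate
  (units per second), 249 samples long;
* feature order and names are frozen in :data:`FEATURE_NAMES` and stamped
  by :data:`MANIFEST_HASH` into fitted models.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .types import CLIP_RATE_HZ, CLIP_SAMPLES, Clip

_RESULTANT_STATS = (
    "mean",
    "median",
    "std",
    "skewness",
    "kurtosis",
    "iqr",
    "min",
    "max",
)
_DERIV_STATS = ("iqr", "min", "max")
_AXIS_STATS = ("max", "min", "iqr")
_AXES = ("x", "y", "z")


def _names_for_sensor(sensor: str) -> list[str]:
    names = [f"{sensor}.resultant.{s}" for s in _RESULTANT_STATS]
    names += [f"{sensor}.resultant_deriv.{s}" for s in _DERIV_STATS]
    names += [f"{sensor}.{ax}.{s}" for ax in _AXES for s in _AXIS_STATS]
    return names


#: Frozen 40-entry feature manifest: accelerometer block then gyroscope block.
FEATURE_NAMES: tuple[str, ...] = tuple(
    _names_for_sensor("accel") + _names_for_sensor("gyro")
)
assert len(FEATURE_NAMES) == 40

#: Version stamp of the manifest; models refuse feature tables built under
#: a different manifest.
MANIFEST_HASH: str = hashlib.sha256(",".join(FEATURE_NAMES).encode()).hexdigest()[:16]

#: The single feature used by the threshold baseline.
MAX_ACCEL_FEATURE = "accel.resultant.max"

#: Metadata columns preceding the 40 features in a feature table.
META_COLUMNS = ["clip_id", "subject", "population", "location", "is_fall"]


def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75.0, 25.0])
    return float(q75 - q25)


def _moments(x: np.ndarray) -> tuple[float, float, float]:
    """(std, skewness, excess kurtosis) with the degenerate-signal map."""
    mu = x.mean()
    centered = x - mu
    var = np.mean(centered**2)
    std = float(np.sqrt(var))
    # a constant signal accumulates O(ulp) variance; snap it to zero so the
    # degenerate-clip convention (std = skew = kurt = 0) holds exactly
    if std <= 1e-12 * max(1.0, abs(mu)):
        return 0.0, 0.0, 0.0
    skew = float(np.mean(centered**3) / std**3)
    kurt = float(np.mean(centered**4) / var**2 - 3.0)
    return std, skew, kurt


def _sensor_block(channels: np.ndarray, rate_hz: float) -> np.ndarray:
    resultant = np.linalg.norm(channels, axis=0)
    deriv = np.diff(resultant) * rate_hz
    std, skew, kurt = _moments(resultant)
    block = [
        float(resultant.mean()),
        float(np.median(resultant)),
        std,
        skew,
        kurt,
        _iqr(resultant),
        float(resultant.min()),
        float(resultant.max()),
        _iqr(deriv),
        float(deriv.min()),
        float(deriv.max()),
    ]
    for ax in range(3):
        sig = channels[ax]
        block += [float(sig.max()), float(sig.min()), _iqr(sig)]
    return np.array(block)


def compute_features(clip: Clip) -> np.ndarray:
    """Compute the 40-vector for one clip (accel block, then gyro block).

    A pure function: the same clip always yields the bit-identical vector.
    """
    if clip.accel.shape != (3, CLIP_SAMPLES):
        raise ValueError(f"clip has shape {clip.accel.shape}, expected (3, 250)")
    if not (np.all(np.isfinite(clip.accel)) and np.all(np.isfinite(clip.gyro))):
        raise ValueError("clip contains non-finite samples")
    vec = np.concatenate(
        [
            _sensor_block(clip.accel, CLIP_RATE_HZ),
            _sensor_block(clip.gyro, CLIP_RATE_HZ),
        ]
    )
    return vec


def max_resultant_acceleration(clip: Clip) -> float:
    """Peak resultant acceleration of a clip in g (the threshold feature).

    Identical to the ``accel.resultant.max`` entry of
    :func:`compute_features`.
    """
    return clip.max_resultant_accel()


def features_dataframe(clips: list[Clip]) -> pd.DataFrame:
    """Feature table: one row per clip, metadata columns then 40 features."""
    rows = np.empty((len(clips), 40))
    meta = []
    for i, clip in enumerate(clips):
        rows[i] = compute_features(clip)
        meta.append(
            {
                "clip_id": i,
                "subject": clip.subject,
                "population": clip.population,
                "location": clip.location,
                "is_fall": clip.is_fall,
            }
        )
    df = pd.DataFrame(meta, columns=META_COLUMNS)
    return pd.concat([df, pd.DataFrame(rows, columns=list(FEATURE_NAMES))], axis=1)


def write_features(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = META_COLUMNS + list(FEATURE_NAMES)
    if list(df.columns) != expected:
        raise ValueError(f"{path}: feature table header does not match the manifest")
    return df
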