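"""Reconstruction error metrics.

Errors are computed per discrete time point k and channel:

    e[k] = |U[k] - U_hat[k]|                      (absolute, mV)
    r[k] = |U[k] - U_hat[k]| / |U[k]| * 100       (relative, %)

and summarised as pooled mean +/- population standard deviation over all
channel-sample pairs.  Samples where the reference potential is effectively
zero (|U[k]| below a tolerance) are excluded from the relative error and the
exclusion count is reported.  A normalised variant rescales every channel of
each recording by its own max-abs level first, measuring waveform-shape
fidelity independent of scale — the convention used when comparing against
methods with unreliable absolute scaling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .geometry import PotentialRecording

__all__ = [
    "ErrorReport",
    "DEFAULT_ZERO_TOLERANCE_MV",
    "absolute_errors",
    "mean_absolute_error",
    "mean_relative_error",
    "per_channel_profile",
    "normalize_recordings",
    "evaluate_reconstruction",
]

# |U| below this (mV) counts as "effectively zero" for relative errors.
DEFAULT_ZERO_TOLERANCE_MV = 1e-9


@dataclass(frozen=True)
class ErrorReport:
    """Summary of reconstruction accuracy against a reference recording."""

    mean_abs_error: float  # mV
    abs_error_sd: float  # mV
    mean_rel_error: float  # percent
    rel_error_sd: float  # percent
    per_channel_mean_abs: tuple  # mV, one entry per channel
    excluded_samples: int
    normalized: bool

    def __post_init__(self) -> None:
        if self.mean_abs_error < 0 or self.mean_rel_error < 0:
            raise ValueError("error summaries must be non-negative")
        object.__setattr__(
            self, "per_channel_mean_abs", tuple(float(x) for x in self.per_channel_mean_abs)
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, data: dict) -> "ErrorReport":
        return cls(**data)

    @classmethod
    def from_json(cls, text: str) -> "ErrorReport":
        return cls.from_dict(json.loads(text))


def _pair(u, u_hat):
    a = u.values if isinstance(u, PotentialRecording) else np.asarray(u, dtype=float)
    b = u_hat.values if isinstance(u_hat, PotentialRecording) else np.asarray(u_hat, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def absolute_errors(u, u_hat) -> np.ndarray:
    """Element-wise absolute differences e[k] = |U[k] - U_hat[k]| (mV)."""
    a, b = _pair(u, u_hat)
    return np.abs(a - b)


def mean_absolute_error(u, u_hat):
    """Pooled mean and population standard deviation of e[k] (both mV)."""
    e = absolute_errors(u, u_hat)
    if e.size == 0:
        raise ValueError("cannot average an empty error set")
    return float(e.mean()), float(e.std())


def mean_relative_error(u, u_hat, zero_tolerance: float = DEFAULT_ZERO_TOLERANCE_MV):
    """Pooled relative error (%) over samples with |U| above ``zero_tolerance``.

    Returns ``(mean, sd, excluded)`` where ``excluded`` counts the reference
    samples treated as effectively zero and left out of the average.  Raises
    if every sample is excluded.
    """
    a, b = _pair(u, u_hat)
    keep = np.abs(a) > zero_tolerance
    excluded = int(a.size - keep.sum())
    if not np.any(keep):
        raise ValueError(
            f"all {a.size} samples are below the zero tolerance "
            f"{zero_tolerance} mV; relative error undefined"
        )
    r = np.abs(a[keep] - b[keep]) / np.abs(a[keep]) * 100.0
    return float(r.mean()), float(r.std()), excluded


def per_channel_profile(u, u_hat):
    """Per-channel time-averaged error and signal level (both mV).

    Returns ``(mean_abs_error_per_channel, mean_abs_level_per_channel)`` —
    the spatial-bias check: reconstruction error per electrode viewed against
    how much signal that electrode carries.
    """
    a, _ = _pair(u, u_hat)
    e = absolute_errors(u, u_hat)
    return e.mean(axis=1), np.abs(a).mean(axis=1)


def _channel_scales(values: np.ndarray, method: str) -> np.ndarray:
    if method == "maxabs":
        return np.max(np.abs(values), axis=1)
    if method == "rms":
        return np.sqrt(np.mean(values**2, axis=1))
    raise ValueError(f"unknown normalization method {method!r}")


def normalize_recordings(u, u_hat, method: str = "maxabs"):
    """Rescale every channel of each recording by its own level.

    ``method='maxabs'`` divides by the channel max-abs (default), ``'rms'``
    by the channel RMS.  Channels whose reference level is identically zero
    in either recording are dropped from both, with a warning naming them.
    Returns the two normalised recordings (or plain arrays, matching input).
    """
    a, b = _pair(u, u_hat)
    scale_a = _channel_scales(a, method)
    scale_b = _channel_scales(b, method)
    keep = (scale_a > 0) & (scale_b > 0)
    if not np.all(keep):
        dropped = np.flatnonzero(~keep)
        if isinstance(u, PotentialRecording):
            names = [u.labels[i] for i in dropped]
        else:
            names = dropped.tolist()
        warnings.warn(
            f"dropping identically-zero channel(s) {names} from normalization",
            UserWarning,
            stacklevel=2,
        )
        if not np.any(keep):
            raise ValueError("every channel is identically zero; cannot normalize")
    norm_a = a[keep] / scale_a[keep, None]
    norm_b = b[keep] / scale_b[keep, None]
    if isinstance(u, PotentialRecording) and isinstance(u_hat, PotentialRecording):
        labels = tuple(np.asarray(u.labels, dtype=object)[keep])
        return (
            PotentialRecording(norm_a, u.sampling_rate, labels),
            PotentialRecording(norm_b, u_hat.sampling_rate, labels),
        )
    return norm_a, norm_b


def evaluate_reconstruction(
    u,
    u_hat,
    zero_tolerance: float = DEFAULT_ZERO_TOLERANCE_MV,
    normalized: bool = False,
    norm_method: str = "maxabs",
) -> ErrorReport:
    """Full accuracy report for a reconstruction against its reference."""
    if normalized:
        u, u_hat = normalize_recordings(u, u_hat, method=norm_method)
    mae, mae_sd = mean_absolute_error(u, u_hat)
    rel, rel_sd, excluded = mean_relative_error(u, u_hat, zero_tolerance)
    per_channel, _ = per_channel_profile(u, u_hat)
    return ErrorReport(
        mean_abs_error=mae,
        abs_error_sd=mae_sd,
        mean_rel_error=rel,
        rel_error_sd=rel_sd,
        per_channel_mean_abs=tuple(per_channel),
        excluded_samples=excluded,
        normalized=normalized,
    )
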