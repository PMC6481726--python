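"""Synthetic torso–heart geometry and paired body-surface / endocardial recordings.

This module stands in for a clinical data-collection setup: a multi-lead ECG
vest sampling potentials on the torso surface while a basket catheter records
endocardial potentials inside the atria, both referenced to a common-mode
(Wilson-Central-Terminal-style) average and digitised at a fixed rate.

The geometry is deliberately idealised — two concentric ellipsoid surfaces at
anatomical scale with electrodes placed by a deterministic quasi-uniform
lattice — and the volume conductor is an infinite homogeneous medium, so that
the forward map from heart to torso is a closed-form quasi-static point-source
kernel F[i, j] = 1 / (4 pi sigma r_ij).  That keeps the forward problem linear
with the characteristic distance decay of the real operator while remaining
fully testable.  A controllable element-wise saturation applied to the torso
potentials introduces the forward-model mismatch that motivates a nonlinear
inverse; at gain zero the system is exactly linear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import trimesh

__all__ = [
    "SurfaceMesh",
    "LeadSet",
    "PotentialRecording",
    "ForwardOperator",
    "SimConfig",
    "make_torso_heart_geometry",
    "build_forward_operator",
    "simulate_endocardial_sources",
    "generate_paired_dataset",
    "saturate",
    "subtract_common_mode",
    "TORSO_SEMI_AXES_MM",
    "HEART_SEMI_AXES_MM",
    "MIN_SOURCE_SENSOR_DISTANCE_MM",
]

# Anatomy-scale semi-axes (mm) of the two concentric ellipsoid surfaces.
TORSO_SEMI_AXES_MM = (200.0, 150.0, 300.0)
HEART_SEMI_AXES_MM = (50.0, 50.0, 60.0)

# Sources closer to a sensor than this are rejected: the 1/r kernel diverges.
MIN_SOURCE_SENSOR_DISTANCE_MM = 1e-3

_MM_PER_M = 1000.0

# Frequency (Hz) of the slow baseline-wander term added to each source channel.
_DRIFT_FREQ_HZ = 0.15


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated surface: ``vertices`` (V, 3) in mm, ``faces`` (F, 3) indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=int)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (V, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError(f"faces must be (F, 3), got {f.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("mesh vertices contain non-finite coordinates")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face index out of range")
        degenerate = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        if np.any(degenerate):
            raise ValueError(f"{int(degenerate.sum())} degenerate face(s) with repeated vertices")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class LeadSet:
    """Electrode positions (mm) with unique labels on one surface."""

    positions: np.ndarray
    labels: tuple
    surface: str  # "torso" or "endocardium"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        labels = tuple(str(s) for s in self.labels)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError(f"positions must be (L, 3), got {pos.shape}")
        if len(labels) != len(pos):
            raise ValueError(
                f"{len(labels)} labels for {len(pos)} positions"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("lead labels must be unique within a lead set")
        if self.surface not in ("torso", "endocardium"):
            raise ValueError(f"unknown surface {self.surface!r}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("lead positions contain non-finite coordinates")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class PotentialRecording:
    """Multichannel potential recording: ``values`` (channels, samples) in mV."""

    values: np.ndarray
    sampling_rate: float
    labels: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        labels = tuple(str(s) for s in self.labels)
        if v.ndim != 2:
            raise ValueError(f"values must be 2-D (channels, samples), got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("recording contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if len(labels) != v.shape[0]:
            raise ValueError(f"{len(labels)} labels for {v.shape[0]} channels")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", labels)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.sampling_rate

    def with_values(self, values: np.ndarray) -> "PotentialRecording":
        return PotentialRecording(values, self.sampling_rate, self.labels)


@dataclass(frozen=True)
class ForwardOperator:
    """Linear map from endocardial (source) to torso (sensor) potentials.

    ``matrix`` has shape (n_sensors, n_sources); entry (i, j) is the transfer
    gain from source lead j to sensor lead i.
    """

    matrix: np.ndarray
    source_leads: LeadSet | None = None
    sensor_leads: LeadSet | None = None
    conductivity: float = 0.2  # S/m

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("forward matrix must be 2-D")
        if not np.all(np.isfinite(m)):
            raise ValueError("forward matrix contains non-finite entries")
        if self.source_leads is not None and m.shape[1] != len(self.source_leads):
            raise ValueError("matrix columns do not match source lead count")
        if self.sensor_leads is not None and m.shape[0] != len(self.sensor_leads):
            raise ValueError("matrix rows do not match sensor lead count")
        if self.conductivity <= 0:
            raise ValueError("conductivity must be > 0")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic acquisition.

    Defaults mirror a clinical AF mapping session: 54 torso ECG leads, a
    64-pole basket catheter, 7.4 s of simultaneous data at 2035.5 Hz, a ~5 Hz
    dominant atrial rate with decaying harmonics, measurement noise on the
    torso, and a mild saturating forward nonlinearity.
    """

    n_torso_leads: int = 54
    n_endo_leads: int = 64
    duration: float = 7.4  # s
    sampling_rate: float = 2035.5  # Hz
    dominant_freq: float = 5.0  # Hz; typical AF dominant rate
    n_harmonics: int = 3
    noise_sd: float = 0.05  # mV, additive Gaussian on the torso channels
    nonlinearity_gain: float = 0.3  # 0 => exactly linear forward model
    drift_amplitude: float = 0.2  # mV, slow baseline wander of the sources
    saturation_mv: float = 10.0  # mV scale at which the forward map saturates
    conductivity: float = 0.2  # S/m, homogeneous medium
    subtract_reference: bool = True  # common-mode (WCT-style) referencing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_torso_leads < 1 or self.n_endo_leads < 1:
            raise ValueError("lead counts must be >= 1")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be > 0")
        if self.n_harmonics < 0:
            raise ValueError("n_harmonics must be >= 0")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise_sd and drift_amplitude must be >= 0")
        if not 0 <= self.nonlinearity_gain <= 1:
            raise ValueError("nonlinearity_gain must lie in [0, 1]")
        if self.saturation_mv <= 0:
            raise ValueError("saturation_mv must be > 0")
        if self.conductivity <= 0:
            raise ValueError("conductivity must be > 0")

    @property
    def n_samples(self) -> int:
        return int(math.floor(self.duration * self.sampling_rate))

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _fibonacci_directions(count: int) -> np.ndarray:
    """Quasi-uniform unit directions from the Fibonacci sphere lattice."""
    i = np.arange(count, dtype=float)
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / golden
    z = 1.0 - (2.0 * i + 1.0) / count
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _ellipsoid_mesh(semi_axes, subdivisions: int = 3) -> SurfaceMesh:
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    vertices = np.asarray(sphere.vertices) * np.asarray(semi_axes, dtype=float)
    return SurfaceMesh(vertices=vertices, faces=np.asarray(sphere.faces))


def make_torso_heart_geometry(config: SimConfig):
    """Build concentric torso and heart surfaces with surface electrodes.

    Returns ``(torso_mesh, heart_mesh, torso_leads, endo_leads)``.  Electrodes
    are placed by mapping a Fibonacci lattice onto each ellipsoid, so the
    layout is quasi-uniform and fully deterministic.
    """
    torso_mesh = _ellipsoid_mesh(TORSO_SEMI_AXES_MM)
    heart_mesh = _ellipsoid_mesh(HEART_SEMI_AXES_MM, subdivisions=2)

    torso_dirs = _fibonacci_directions(config.n_torso_leads)
    endo_dirs = _fibonacci_directions(config.n_endo_leads)
    width_t = max(2, len(str(config.n_torso_leads)))
    width_e = max(2, len(str(config.n_endo_leads)))
    torso_leads = LeadSet(
        positions=torso_dirs * np.asarray(TORSO_SEMI_AXES_MM),
        labels=tuple(f"T{i + 1:0{width_t}d}" for i in range(config.n_torso_leads)),
        surface="torso",
    )
    endo_leads = LeadSet(
        positions=endo_dirs * np.asarray(HEART_SEMI_AXES_MM),
        labels=tuple(f"E{i + 1:0{width_e}d}" for i in range(config.n_endo_leads)),
        surface="endocardium",
    )
    return torso_mesh, heart_mesh, torso_leads, endo_leads


def build_forward_operator(
    endo_leads: LeadSet,
    torso_leads: LeadSet,
    conductivity: float = 0.2,
) -> ForwardOperator:
    """Quasi-static point-source forward operator F[i, j] = 1/(4 pi sigma r_ij).

    ``r_ij`` is the distance (converted to metres) between torso sensor ``i``
    and endocardial source ``j`` in an infinite homogeneous medium of
    conductivity ``sigma`` (S/m).  Entries are positive and decrease
    monotonically with distance.  Raises if any source/sensor pair is closer
    than ``MIN_SOURCE_SENSOR_DISTANCE_MM``.
    """
    if len(endo_leads) == 0 or len(torso_leads) == 0:
        raise ValueError("lead sets must be nonempty")
    if conductivity <= 0:
        raise ValueError("conductivity must be > 0")
    diff = torso_leads.positions[:, None, :] - endo_leads.positions[None, :, :]
    r_mm = np.sqrt(np.sum(diff * diff, axis=2))
    if np.any(r_mm < MIN_SOURCE_SENSOR_DISTANCE_MM):
        raise ValueError(
            "source and sensor leads closer than "
            f"{MIN_SOURCE_SENSOR_DISTANCE_MM} mm; 1/r kernel undefined"
        )
    matrix = 1.0 / (4.0 * np.pi * conductivity * (r_mm / _MM_PER_M))
    return ForwardOperator(
        matrix=matrix,
        source_leads=endo_leads,
        sensor_leads=torso_leads,
        conductivity=conductivity,
    )


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------


def _source_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 0])


def _noise_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 1])


def _synthesize_sources(config: SimConfig, endo_leads: LeadSet) -> np.ndarray:
    """AF-like endocardial channels: dominant sinusoid + decaying harmonics.

    Each channel carries a per-channel phase derived from its position (a
    travelling-wave surrogate for activation spread), a seeded amplitude
    jitter, and a slow baseline drift.  Amplitudes sit on the mV scale.
    """
    rng = _source_rng(config)
    t = np.arange(config.n_samples) / config.sampling_rate
    m = len(endo_leads)

    # Travelling-wave phase: projection of each electrode onto a seeded
    # propagation direction, scaled so phases span a few radians across the
    # heart surface.
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    proj = endo_leads.positions @ direction / max(HEART_SEMI_AXES_MM)
    base_phase = np.pi * proj  # (m,)

    amplitude = 1.0 * (0.75 + 0.5 * rng.random(m))  # 0.75–1.25 mV
    harmonic_phase = 2.0 * np.pi * rng.random(config.n_harmonics + 1)

    values = np.zeros((m, config.n_samples))
    for h in range(config.n_harmonics + 1):
        f_h = config.dominant_freq * (h + 1)
        a_h = amplitude / (h + 1) ** 2
        phase = (h + 1) * base_phase + harmonic_phase[h]
        values += a_h[:, None] * np.sin(
            2.0 * np.pi * f_h * t[None, :] + phase[:, None]
        )
    if config.drift_amplitude > 0:
        values += config.drift_amplitude * np.sin(
            2.0 * np.pi * _DRIFT_FREQ_HZ * t[None, :] + 0.5 * base_phase[:, None]
        )
    return values


def simulate_endocardial_sources(config: SimConfig) -> PotentialRecording:
    """Simulate clean endocardial source potentials for the configured catheter."""
    _, _, _, endo_leads = make_torso_heart_geometry(config)
    values = _synthesize_sources(config, endo_leads)
    return PotentialRecording(
        values=values, sampling_rate=config.sampling_rate, labels=endo_leads.labels
    )


def saturate(x: np.ndarray, gain: float, scale_mv: float) -> np.ndarray:
    """Element-wise saturation blended with identity.

    ``(1 - gain) * x + gain * scale * tanh(x / scale)`` — slope 1 at the
    origin for every gain, identity at gain 0, and bounded excursions of the
    saturating component at gain 1.
    """
    if gain == 0:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    return (1.0 - gain) * x + gain * scale_mv * np.tanh(x / scale_mv)


def subtract_common_mode(values: np.ndarray) -> np.ndarray:
    """Remove the channel mean at every time sample (WCT-style referencing)."""
    values = np.asarray(values, dtype=float)
    return values - values.mean(axis=0, keepdims=True)


def generate_paired_dataset(config: SimConfig):
    """Generate a paired (torso, endocardial) dataset and the true operator.

    Returns ``(u_torso, u_endo, forward)`` where
    ``u_torso = ref(saturate(F @ u_endo) + noise)``: the clean sources are
    pushed through the linear kernel, distorted by the configured element-wise
    saturation, corrupted with Gaussian sensor noise, and finally re-referenced
    by common-mode subtraction when ``subtract_reference`` is set.
    """
    _, _, torso_leads, endo_leads = make_torso_heart_geometry(config)
    forward = build_forward_operator(endo_leads, torso_leads, config.conductivity)

    source_values = _synthesize_sources(config, endo_leads)
    u_endo = PotentialRecording(
        values=source_values, sampling_rate=config.sampling_rate, labels=endo_leads.labels
    )

    torso_values = forward.matrix @ source_values
    torso_values = saturate(torso_values, config.nonlinearity_gain, config.saturation_mv)
    if config.noise_sd > 0:
        torso_values = torso_values + _noise_rng(config).normal(
            scale=config.noise_sd, size=torso_values.shape
        )
    if config.subtract_reference:
        torso_values = subtract_common_mode(torso_values)

    u_torso = PotentialRecording(
        values=torso_values, sampling_rate=config.sampling_rate, labels=torso_leads.labels
    )
    return u_torso, u_endo, forward
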