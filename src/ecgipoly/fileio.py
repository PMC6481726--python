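"""Text-first file formats for recordings, models, operators and geometry.

All artifacts are plain text so they remain inspectable and diff-able:
recordings and forward operators as headered whitespace-delimited matrices
(17 significant digits, so numeric round-trips are exact in double
precision), polynomial-network models as versioned JSON, lead sets as CSV,
meshes as ASCII OFF, run configuration as strict YAML (unknown keys are
fatal), and training histories as CSV tables.
"""

from __future__ import annotations

import csv
import json
from dataclasses import fields
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .geometry import (
    ForwardOperator,
    LeadSet,
    PotentialRecording,
    SimConfig,
    SurfaceMesh,
)
from .linear import TikhonovConfig
from .polynet import PolyNet
from .training import TrainConfig, TrainHistory

__all__ = [
    "FormatError",
    "read_recording",
    "write_recording",
    "read_model",
    "write_model",
    "read_forward_operator",
    "write_forward_operator",
    "read_lead_set",
    "write_lead_set",
    "read_mesh",
    "write_mesh",
    "load_run_config",
    "write_history",
]

RECORDING_MAGIC = "ecgipoly-recording"
OPERATOR_MAGIC = "ecgipoly-forward-operator"
MODEL_FORMAT = "ecgipoly-model"
FORMAT_VERSION = 1
_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """A file failed structural validation."""


# ---------------------------------------------------------------------------
# Headered matrix files (recordings, forward operators)
# ---------------------------------------------------------------------------


def _write_matrix_file(path, magic: str, header: dict, matrix: np.ndarray) -> None:
    path = Path(path)
    lines = [f"# {magic} v{FORMAT_VERSION}"]
    for key, value in header.items():
        lines.append(f"# {key} = {value}")
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, matrix, fmt=_FLOAT_FMT)


def _read_matrix_file(path, magic: str):
    path = Path(path)
    header: dict = {}
    rows: list = []
    with path.open() as fh:
        first = fh.readline().strip()
        if first != f"# {magic} v{FORMAT_VERSION}":
            raise FormatError(
                f"{path}: expected header '# {magic} v{FORMAT_VERSION}', got {first!r}"
            )
        width = None
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise FormatError(f"{path}:{lineno}: malformed header line {line!r}")
                key, _, value = body.partition("=")
                header[key.strip()] = value.strip()
                continue
            try:
                row = [float(tok) for tok in line.split()]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric payload: {exc}") from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise FormatError(
                    f"{path}:{lineno}: row has {len(row)} values, expected {width}"
                )
            rows.append(row)
    if not rows or width == 0:
        raise FormatError(f"{path}: no samples in payload")
    matrix = np.array(rows, dtype=float)
    bad = np.argwhere(~np.isfinite(matrix))
    if len(bad):
        r, c = bad[0]
        raise FormatError(f"{path}: non-finite value at row {r}, column {c}")
    return header, matrix


def write_recording(recording: PotentialRecording, path) -> None:
    """Write a recording as a headered text matrix (channels as rows)."""
    labels = ",".join(recording.labels)
    if any("," in lab or "\n" in lab for lab in recording.labels):
        raise FormatError("channel labels may not contain commas or newlines")
    _write_matrix_file(
        path,
        RECORDING_MAGIC,
        {"sampling_rate_hz": repr(recording.sampling_rate), "labels": labels},
        recording.values,
    )


def read_recording(path) -> PotentialRecording:
    """Read a recording written by :func:`write_recording`."""
    header, matrix = _read_matrix_file(path, RECORDING_MAGIC)
    try:
        rate = float(header["sampling_rate_hz"])
        labels = tuple(header["labels"].split(","))
    except KeyError as exc:
        raise FormatError(f"{path}: missing header field {exc}") from exc
    if len(labels) != matrix.shape[0]:
        raise FormatError(
            f"{path}: {len(labels)} labels for {matrix.shape[0]} payload rows"
        )
    if rate <= 0:
        raise FormatError(f"{path}: sampling rate must be > 0, got {rate}")
    return PotentialRecording(values=matrix, sampling_rate=rate, labels=labels)


def write_forward_operator(forward: ForwardOperator, path) -> None:
    _write_matrix_file(
        path,
        OPERATOR_MAGIC,
        {"conductivity_s_per_m": repr(forward.conductivity)},
        forward.matrix,
    )


def read_forward_operator(path) -> ForwardOperator:
    header, matrix = _read_matrix_file(path, OPERATOR_MAGIC)
    conductivity = float(header.get("conductivity_s_per_m", "0.2"))
    return ForwardOperator(matrix=matrix, conductivity=conductivity)


# ---------------------------------------------------------------------------
# Model files (JSON)
# ---------------------------------------------------------------------------


def write_model(net: PolyNet, path) -> None:
    """Serialise a polynomial network as versioned JSON."""
    payload = {
        "format": MODEL_FORMAT,
        "version": FORMAT_VERSION,
        "degree": net.degree,
        "m": net.n_outputs,
        "n": net.n_inputs,
        "matrix": net.matrix.tolist(),
        "weights": net.weights.tolist(),
        "output_labels": list(net.output_labels) if net.output_labels else None,
    }
    Path(path).write_text(json.dumps(payload))


def read_model(path) -> PolyNet:
    """Read a model file, validating declared shapes against the payload."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid model JSON ({exc})") from exc
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise FormatError(f"{path}: missing '{MODEL_FORMAT}' format marker")
    if payload.get("version") != FORMAT_VERSION:
        raise FormatError(f"{path}: unsupported model version {payload.get('version')}")
    try:
        matrix = np.array(payload["matrix"], dtype=float)
        weights = np.array(payload["weights"], dtype=float)
        degree, m, n = payload["degree"], payload["m"], payload["n"]
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed model payload ({exc})") from exc
    if matrix.ndim != 2 or matrix.shape != (m, n):
        raise FormatError(
            f"{path}: declared matrix shape ({m}, {n}) does not match payload "
            f"{matrix.shape}"
        )
    if weights.ndim != 2 or weights.shape != (degree + 1, m):
        raise FormatError(
            f"{path}: declared degree {degree} / m {m} do not match weight "
            f"payload {weights.shape}"
        )
    labels = payload.get("output_labels")
    return PolyNet(
        matrix=matrix,
        weights=weights,
        output_labels=tuple(labels) if labels else None,
    )


# ---------------------------------------------------------------------------
# Geometry files
# ---------------------------------------------------------------------------


def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Write a triangle mesh as ASCII OFF."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    exported = tm.export(file_type="off")
    if isinstance(exported, bytes):
        exported = exported.decode()
    Path(path).write_text(exported)


def read_mesh(path) -> SurfaceMesh:
    tm = trimesh.load_mesh(str(path), file_type="off", process=False)
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


def write_lead_set(leads: LeadSet, path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "x_mm", "y_mm", "z_mm", "surface"])
        for label, pos in zip(leads.labels, leads.positions):
            writer.writerow(
                [label, _FLOAT_FMT % pos[0], _FLOAT_FMT % pos[1], _FLOAT_FMT % pos[2], leads.surface]
            )


def read_lead_set(path) -> LeadSet:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["label", "x_mm", "y_mm", "z_mm", "surface"]:
            raise FormatError(f"{path}: unexpected lead-set header {header}")
        labels, positions, surfaces = [], [], set()
        for row in reader:
            if len(row) != 5:
                raise FormatError(f"{path}: malformed lead row {row}")
            labels.append(row[0])
            positions.append([float(row[1]), float(row[2]), float(row[3])])
            surfaces.add(row[4])
    if not labels:
        raise FormatError(f"{path}: empty lead set")
    if len(surfaces) != 1:
        raise FormatError(f"{path}: mixed surfaces {sorted(surfaces)} in one lead set")
    return LeadSet(positions=np.array(positions), labels=tuple(labels), surface=surfaces.pop())


# ---------------------------------------------------------------------------
# Run configuration (strict YAML) and history tables
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "simulation": SimConfig,
    "tikhonov": TikhonovConfig,
    "training": TrainConfig,
}
_TOP_LEVEL_KEYS = set(_SECTION_TYPES) | {"metrics", "log_level"}
_METRIC_KEYS = {"zero_tolerance", "normalized", "norm_method"}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(
            f"unknown key(s) {sorted(unknown)} in config section '{section}'"
        )
    if cls is TrainConfig and "trial_steps" in data:
        data = dict(data, trial_steps=tuple(data["trial_steps"]))
    return cls(**data)


def load_run_config(path) -> dict:
    """Load a strict YAML run config into per-stage config objects.

    Returns a dict with keys ``simulation`` (:class:`SimConfig`),
    ``tikhonov`` (:class:`TikhonovConfig`), ``training``
    (:class:`TrainConfig`), ``metrics`` (dict) and ``log_level``; sections
    that are absent get defaults.  Unknown keys anywhere are fatal.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config root must be a mapping")
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise FormatError(f"{path}: unknown top-level config key(s) {sorted(unknown)}")
    out: dict = {}
    for section, cls in _SECTION_TYPES.items():
        data = raw.get(section, {}) or {}
        if not isinstance(data, dict):
            raise FormatError(f"{path}: section '{section}' must be a mapping")
        try:
            out[section] = _build_section(cls, data, section)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: invalid '{section}' section: {exc}") from exc
    metric_data = raw.get("metrics", {}) or {}
    unknown = set(metric_data) - _METRIC_KEYS
    if unknown:
        raise FormatError(f"{path}: unknown metric option(s) {sorted(unknown)}")
    out["metrics"] = metric_data
    out["log_level"] = raw.get("log_level", "INFO")
    return out


def write_history(history: TrainHistory, path) -> None:
    """Write the objective/step trace of a training run as CSV."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "objective", "step"])
        writer.writerow([0, repr(history.objectives[0]), ""])
        for i, (obj, step) in enumerate(
            zip(history.objectives[1:], history.steps), start=1
        ):
            writer.writerow([i, repr(obj), repr(step)])
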