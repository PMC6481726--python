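"""Element-wise polynomial inverse network.

The reconstruction model is a degree-p polynomial applied element-wise to a
linearly transformed input: for a torso sample u (length n),

    z = M u,        u_hat = sum_{k=0}^{p} w_k  ⊙  z^{⊙k},

where M is a trainable m x n matrix, w_0 ... w_p are per-output weight
vectors, ⊙ is the Schur (element-wise) product and z^{⊙k} the element-wise
k-th power (z^{⊙0} = 1, so w_0 acts as a per-channel bias).  The model is
applied independently to every time sample, making it time invariant by
construction.  With w_1 = 1 and every other w_k = 0 the network is exactly
the linear map M — the natural initialisation from a Tikhonov or
pseudo-inverse solution.

This is the trainable generalisation of the truncated Cayley–Hamilton series
inverse: the series' scalar coefficients and determinant prefactor are
absorbed into free per-channel weights, which also lets M be non-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import PotentialRecording

__all__ = ["PolyNet", "predict", "init_linear", "input_jacobian"]

DEFAULT_DEGREE = 3


@dataclass(frozen=True)
class PolyNet:
    """Polynomial inverse model: ``matrix`` (m, n) and ``weights`` (p + 1, m)."""

    matrix: np.ndarray
    weights: np.ndarray
    output_labels: tuple | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D (m, n)")
        if w.ndim != 2 or w.shape[0] < 1:
            raise ValueError("weights must be 2-D (p + 1, m) with p >= 0")
        if w.shape[1] != m.shape[0]:
            raise ValueError(
                f"weight vectors have length {w.shape[1]} but matrix has {m.shape[0]} rows"
            )
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(w))):
            raise ValueError("model parameters must be finite")
        if self.output_labels is not None and len(self.output_labels) != m.shape[0]:
            raise ValueError("output_labels length must equal matrix rows")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "weights", w)
        if self.output_labels is not None:
            object.__setattr__(self, "output_labels", tuple(self.output_labels))

    @property
    def degree(self) -> int:
        return self.weights.shape[0] - 1

    @property
    def n_outputs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.matrix.shape[1]

    def labels(self) -> tuple:
        if self.output_labels is not None:
            return self.output_labels
        width = max(2, len(str(self.n_outputs)))
        return tuple(f"A{i + 1:0{width}d}" for i in range(self.n_outputs))


def init_linear(m0: np.ndarray, degree: int = DEFAULT_DEGREE, output_labels=None) -> PolyNet:
    """Network that initially reproduces the linear map ``m0`` exactly.

    ``w_1`` is set to all-ones and every other weight vector to zero, so
    ``predict`` returns ``m0 @ u`` until training moves the weights.  Degree 0
    cannot express a linear map and is rejected.
    """
    m0 = np.asarray(m0, dtype=float)
    if m0.ndim != 2:
        raise ValueError("initial matrix must be 2-D")
    if degree < 1:
        raise ValueError("degree must be >= 1 to express the linear map")
    weights = np.zeros((degree + 1, m0.shape[0]))
    weights[1] = 1.0
    return PolyNet(matrix=m0, weights=weights, output_labels=output_labels)


def _evaluate(net: PolyNet, values: np.ndarray) -> np.ndarray:
    """Apply the polynomial map column-wise to a (n, T) array."""
    z = net.matrix @ values
    out = np.zeros((net.n_outputs, values.shape[1]))
    # Element-wise powers by iterated multiplication: sign-correct for
    # negative potentials and exact for the small degrees used here.
    zk = np.ones_like(z)
    for k in range(net.degree + 1):
        out += net.weights[k][:, None] * zk
        if k < net.degree:
            zk = zk * z
    return out


def predict(net: PolyNet, u_torso: PotentialRecording) -> PotentialRecording:
    """Reconstruct source potentials sample-by-sample from a torso recording."""
    if u_torso.n_channels != net.n_inputs:
        raise ValueError(
            f"recording has {u_torso.n_channels} channels but the model "
            f"expects {net.n_inputs}"
        )
    return PotentialRecording(
        values=_evaluate(net, u_torso.values),
        sampling_rate=u_torso.sampling_rate,
        labels=net.labels(),
    )


def input_jacobian(net: PolyNet, u_sample: np.ndarray) -> np.ndarray:
    """Jacobian of the reconstruction with respect to one torso sample.

    With z = M u the derivative is diag(g) M where
    g_i = sum_{k>=1} k w_k[i] z_i^{k-1}; it quantifies the roughness of the
    inverse map with respect to its input and feeds the Sobolev penalty used
    during training.  For a linear-initialised network it equals M for every
    input.
    """
    u = np.asarray(u_sample, dtype=float).reshape(-1)
    if len(u) != net.n_inputs:
        raise ValueError(f"sample has length {len(u)}, expected {net.n_inputs}")
    z = net.matrix @ u
    g = np.zeros(net.n_outputs)
    zk = np.ones_like(z)  # z^{k-1}
    for k in range(1, net.degree + 1):
        g += k * net.weights[k] * zk
        zk = zk * z
    return g[:, None] * net.matrix
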