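"""Classical linear inversion baselines.

Zero-order Tikhonov regularisation of the ill-posed torso-to-heart problem:

    U_A = (F^T F + lambda I)^{-1} F^T U_T,

solved per time sample through a Cholesky factorisation of the regularised
normal matrix.  ``lambda = 0`` falls back to the minimum-norm least-squares
(pseudo-inverse) solution.  These serve both as initialisation for the
trainable polynomial inverse and as the comparison baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .geometry import ForwardOperator, PotentialRecording

__all__ = ["TikhonovConfig", "RankDeficiencyWarning", "tikhonov_inverse"]


class RankDeficiencyWarning(UserWarning):
    """Least-squares solve (lambda = 0) hit a rank-deficient operator."""


@dataclass(frozen=True)
class TikhonovConfig:
    """Zero-order Tikhonov settings; ``lam`` is the regularisation weight."""

    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")


def _forward_matrix(forward) -> np.ndarray:
    if isinstance(forward, ForwardOperator):
        return forward.matrix
    m = np.asarray(forward, dtype=float)
    if m.ndim != 2:
        raise ValueError("forward operator must be a 2-D matrix")
    return m


def _source_labels(forward, n_sources: int) -> tuple:
    if isinstance(forward, ForwardOperator) and forward.source_leads is not None:
        return forward.source_leads.labels
    width = max(2, len(str(n_sources)))
    return tuple(f"A{i + 1:0{width}d}" for i in range(n_sources))


def tikhonov_inverse(
    forward,
    u_torso: PotentialRecording,
    config: TikhonovConfig = TikhonovConfig(),
) -> PotentialRecording:
    """Reconstruct source potentials by zero-order Tikhonov inversion.

    All time samples share one factorisation of ``F^T F + lambda I``; at
    ``lambda = 0`` the minimum-norm least-squares solution is returned and a
    :class:`RankDeficiencyWarning` is emitted if ``F`` is rank-deficient.
    """
    f = _forward_matrix(forward)
    if u_torso.n_channels != f.shape[0]:
        raise ValueError(
            f"torso recording has {u_torso.n_channels} channels but the "
            f"forward operator has {f.shape[0]} rows"
        )
    n_sources = f.shape[1]
    if config.lam > 0:
        normal = f.T @ f + config.lam * np.eye(n_sources)
        rhs = f.T @ u_torso.values
        cho = scipy.linalg.cho_factor(normal)
        solution = scipy.linalg.cho_solve(cho, rhs)
    else:
        solution, _, rank, _ = np.linalg.lstsq(f, u_torso.values, rcond=None)
        if rank < n_sources:
            warnings.warn(
                f"forward operator rank {rank} < {n_sources} source channels; "
                "returning the minimum-norm pseudo-inverse solution",
                RankDeficiencyWarning,
                stacklevel=2,
            )
    return PotentialRecording(
        values=solution,
        sampling_rate=u_torso.sampling_rate,
        labels=_source_labels(forward, n_sources),
    )
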