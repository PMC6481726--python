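"""Sobolev-regularised training of the polynomial inverse network.

The parameters (M and the weight vectors w_k) are fitted to simultaneously
recorded torso/endocardial pairs by minimising

    E = mean_t || u_hat(t) - u_endo(t) ||_2^2
        + lambda * mean_t sum_ij | J(t)_ij |^s,

where J(t) is the Jacobian of the reconstruction with respect to the torso
sample (see :func:`ecgipoly.polynet.input_jacobian`).  The Sobolev penalty
bounds the roughness of the learned inverse map with respect to its *input*,
a surrogate for output-side Tikhonov/TV regularisation; it is applied only
during training, never at reconstruction time.

Optimisation is plain gradient descent with a discrete line search: the
analytic gradient is normalised to unit max-abs and candidate updates
``theta + gamma * scale * direction`` are evaluated for gamma in a fixed
trial set containing 0, keeping the best.  Because gamma = 0 is always a
candidate, the objective sequence is non-increasing by construction.  Train
and test data are disjoint random subsets of the time samples, which makes
the fitted model time invariant by protocol as well as by structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import PotentialRecording
from .polynet import PolyNet

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "Gradients",
    "split_time_samples",
    "objective",
    "parameter_gradient",
    "line_search_update",
    "train",
]

_TINY = 1e-300


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    ``lambda_sobolev`` is interpreted relative to the data term when
    ``lambda_relative`` is set (the default): :func:`train` rescales it once
    so the penalty contributes ``lambda_sobolev`` times the initial data term
    at the starting point, then keeps the resolved absolute weight fixed.
    :func:`objective` always treats the configured value as absolute.
    """

    lambda_sobolev: float = 1e-3
    sobolev_exponent: float = 2.0
    n_iterations: int = 200
    trial_steps: tuple = (-1.0, -0.5, -0.1, 0.0, 0.1, 0.5, 1.0)
    train_fraction: float = 0.7
    seed: int = 0
    optimize_weights: bool = True
    sobolev_reduce: str = "mean"  # "mean" or "sum" over time samples
    lambda_relative: bool = True
    early_stop_zero_wins: int = 10

    def __post_init__(self) -> None:
        steps = tuple(float(g) for g in self.trial_steps)
        if 0.0 not in steps:
            raise ValueError("trial_steps must contain 0 (the no-move safeguard)")
        if any(abs(g) > 1.0 for g in steps):
            raise ValueError("trial steps must lie in [-1, 1]")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.lambda_sobolev < 0:
            raise ValueError("lambda_sobolev must be >= 0")
        if self.sobolev_exponent < 1:
            raise ValueError("sobolev_exponent must be >= 1")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.sobolev_reduce not in ("mean", "sum"):
            raise ValueError("sobolev_reduce must be 'mean' or 'sum'")
        object.__setattr__(self, "trial_steps", steps)


@dataclass
class TrainHistory:
    """Per-iteration record of a training run."""

    objectives: list = field(default_factory=list)
    steps: list = field(default_factory=list)
    train_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    test_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    lambda_resolved: float = 0.0
    stopped_early: bool = False


@dataclass(frozen=True)
class Gradients:
    """Raw objective gradients; ``weights`` is None when weights are frozen."""

    matrix: np.ndarray
    weights: np.ndarray | None

    @property
    def max_abs(self) -> float:
        m = float(np.max(np.abs(self.matrix))) if self.matrix.size else 0.0
        if self.weights is not None and self.weights.size:
            m = max(m, float(np.max(np.abs(self.weights))))
        return m

    @property
    def is_null(self) -> bool:
        return self.max_abs == 0.0

    def normalized(self) -> "Gradients":
        """Unit max-abs descent direction; raises on a null gradient."""
        scale = self.max_abs
        if scale == 0.0:
            raise ValueError("gradient is identically zero; no descent direction")
        return Gradients(
            matrix=self.matrix / scale,
            weights=None if self.weights is None else self.weights / scale,
        )


def split_time_samples(n_samples: int, train_fraction: float, seed: int):
    """Random disjoint, exhaustive train/test split of sample indices.

    The train set has ``round(train_fraction * n_samples)`` elements.  Raises
    if either side would be empty.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 time samples to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = int(round(train_fraction * n_samples))
    if n_train == 0 or n_train == n_samples:
        raise ValueError(
            f"train_fraction {train_fraction} leaves an empty split for "
            f"{n_samples} samples"
        )
    perm = np.random.default_rng(seed).permutation(n_samples)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _values(rec) -> np.ndarray:
    if isinstance(rec, PotentialRecording):
        return rec.values
    return np.asarray(rec, dtype=float)


def _check_shapes(net: PolyNet, ut: np.ndarray, ua: np.ndarray) -> None:
    if ut.shape[0] != net.n_inputs:
        raise ValueError(
            f"torso data has {ut.shape[0]} channels, model expects {net.n_inputs}"
        )
    if ua.shape[0] != net.n_outputs:
        raise ValueError(
            f"endocardial data has {ua.shape[0]} channels, model has {net.n_outputs}"
        )
    if ut.shape[1] != ua.shape[1]:
        raise ValueError("torso and endocardial recordings differ in sample count")


def _forward_pieces(net: PolyNet, ut: np.ndarray):
    """z = M u, element-wise powers, prediction, g = d(u_hat)/dz, h = dg/dz."""
    p = net.degree
    z = net.matrix @ ut  # (m, T)
    zpow = [np.ones_like(z)]
    for _ in range(max(p, 2) - 1 + 1):
        zpow.append(zpow[-1] * z)
    pred = np.zeros_like(z)
    for k in range(p + 1):
        pred += net.weights[k][:, None] * zpow[k]
    g = np.zeros_like(z)
    for k in range(1, p + 1):
        g += k * net.weights[k][:, None] * zpow[k - 1]
    h = np.zeros_like(z)
    for k in range(2, p + 1):
        h += k * (k - 1) * net.weights[k][:, None] * zpow[k - 2]
    return z, zpow, pred, g, h


def _row_power(net: PolyNet, s: float) -> np.ndarray:
    """rho_i = sum_j |M_ij|^s — the per-row Sobolev mass of M."""
    return np.sum(np.abs(net.matrix) ** s, axis=1)


def objective(net: PolyNet, u_torso, u_endo, config: TrainConfig, indices) -> float:
    """Regularised training objective on the selected time samples.

    Data term: mean over samples of the squared reconstruction error summed
    over channels.  Sobolev term: ``lambda`` times the (mean or summed, per
    ``sobolev_reduce``) entry-wise ``|J|^s`` of the input Jacobian, which for
    this model factorises as ``sum_i |g_i(t)|^s * sum_j |M_ij|^s``.
    """
    ut = _values(u_torso)
    ua = _values(u_endo)
    _check_shapes(net, ut, ua)
    idx = np.asarray(indices, dtype=int)
    ut = ut[:, idx]
    ua = ua[:, idx]
    n_t = ut.shape[1]
    _, _, pred, g, _ = _forward_pieces(net, ut)
    resid = pred - ua
    value = float(np.sum(resid * resid)) / n_t
    if config.lambda_sobolev > 0:
        s = config.sobolev_exponent
        rho = _row_power(net, s)
        sob = float(np.sum((np.abs(g) ** s) * rho[:, None]))
        if config.sobolev_reduce == "mean":
            sob /= n_t
        value += config.lambda_sobolev * sob
    if np.isnan(value):
        raise ArithmeticError("objective evaluated to NaN; parameters diverged")
    return value


def parameter_gradient(net: PolyNet, u_torso, u_endo, config: TrainConfig, indices) -> Gradients:
    """Analytic gradient of the full objective with respect to M (and w_k).

    Returned unnormalised; call :meth:`Gradients.normalized` for the unit
    max-abs descent direction used by the line search.  A zero gradient is
    reported via :attr:`Gradients.is_null` so the caller can stop.
    """
    ut = _values(u_torso)
    ua = _values(u_endo)
    _check_shapes(net, ut, ua)
    idx = np.asarray(indices, dtype=int)
    ut = ut[:, idx]
    ua = ua[:, idx]
    n_t = ut.shape[1]
    p = net.degree
    z, zpow, pred, g, h = _forward_pieces(net, ut)
    resid = pred - ua

    # Data term: d/dM = (2/T) (resid ⊙ g) U^T, d/dw_k = (2/T) row-sum(resid ⊙ z^k).
    d_matrix = (2.0 / n_t) * (resid * g) @ ut.T
    d_weights = None
    if config.optimize_weights:
        d_weights = np.empty_like(net.weights)
        for k in range(p + 1):
            d_weights[k] = (2.0 / n_t) * np.sum(resid * zpow[k], axis=1)

    if config.lambda_sobolev > 0:
        s = config.sobolev_exponent
        lam = config.lambda_sobolev
        reduce_factor = 1.0 / n_t if config.sobolev_reduce == "mean" else 1.0
        rho = _row_power(net, s)
        abs_g = np.abs(g)
        # |g|^{s-1} sign(g); finite for s >= 1 (0 at g = 0).
        g_pow = np.where(abs_g > 0, abs_g ** (s - 1.0), 0.0) * np.sign(g)
        gs_sum = np.sum(abs_g**s, axis=1)  # (m,)
        abs_m = np.abs(net.matrix)
        m_pow = np.where(abs_m > 0, abs_m ** (s - 1.0), 0.0) * np.sign(net.matrix)
        # Through rho: sum_t |g_it|^s * s |M_ij|^{s-1} sign(M_ij).
        d_matrix += lam * reduce_factor * s * gs_sum[:, None] * m_pow
        # Through g (z depends on M): h is dg/dz.
        d_matrix += lam * reduce_factor * s * ((g_pow * rho[:, None] * h) @ ut.T)
        if d_weights is not None:
            for k in range(1, p + 1):
                d_weights[k] += (
                    lam
                    * reduce_factor
                    * s
                    * np.sum(g_pow * rho[:, None] * k * zpow[k - 1], axis=1)
                )
    return Gradients(matrix=d_matrix, weights=d_weights)


def _apply_step(net: PolyNet, direction: Gradients, step: float) -> PolyNet:
    if step == 0.0:
        return net
    weights = net.weights
    if direction.weights is not None:
        weights = weights + step * direction.weights
    return replace(net, matrix=net.matrix + step * direction.matrix, weights=weights)


def line_search_update(
    net: PolyNet,
    direction: Gradients,
    config: TrainConfig,
    u_torso,
    u_endo,
    indices,
    scale: float = 1.0,
):
    """Evaluate every trial step gamma * scale along ``direction``; keep the best.

    Returns ``(updated_net, chosen_gamma, new_objective)``.  Ties prefer the
    smallest |gamma|, so when no move improves the objective the network is
    returned unchanged with gamma = 0, making descent monotone by
    construction.
    """
    best = None
    for gamma in sorted(config.trial_steps, key=abs):
        candidate = _apply_step(net, direction, gamma * scale)
        value = objective(candidate, u_torso, u_endo, config, indices)
        if best is None or value < best[2]:
            best = (candidate, gamma, value)
    return best


def _resolve_lambda(net, ut, ua, config: TrainConfig, idx) -> TrainConfig:
    if not config.lambda_relative or config.lambda_sobolev == 0:
        return replace(config, lambda_relative=False)
    data_term = objective(net, ut, ua, replace(config, lambda_sobolev=0.0), idx)
    sob_cfg = replace(config, lambda_sobolev=1.0, lambda_relative=False)
    sob_raw = objective(net, ut, ua, sob_cfg, idx) - data_term
    lam_abs = config.lambda_sobolev * data_term / max(sob_raw, _TINY)
    return replace(config, lambda_sobolev=lam_abs, lambda_relative=False)


def train(net: PolyNet, u_torso, u_endo, config: TrainConfig = TrainConfig()):
    """Fit the network on a random train split of the time samples.

    Runs ``n_iterations`` of normalised-gradient line search on the train
    indices; the per-iteration step scale starts at 1, is halved whenever
    gamma = 0 wins twice in a row and doubled whenever the largest trial
    magnitude wins (so a badly scaled start recovers quickly in both
    directions), and training stops early after ``early_stop_zero_wins``
    consecutive zero wins or on a null gradient.
    Returns ``(fitted_net, TrainHistory)``; the history holds the objective
    trace (non-increasing by construction), the chosen steps and the split.
    """
    ut = _values(u_torso)
    ua = _values(u_endo)
    _check_shapes(net, ut, ua)
    train_idx, test_idx = split_time_samples(
        ut.shape[1], config.train_fraction, config.seed
    )
    cfg = _resolve_lambda(net, ut, ua, config, train_idx)
    history = TrainHistory(
        train_indices=train_idx,
        test_indices=test_idx,
        lambda_resolved=cfg.lambda_sobolev,
    )
    history.objectives.append(objective(net, ut, ua, cfg, train_idx))
    scale = 1.0
    zero_run = 0
    max_trial = max(abs(g) for g in cfg.trial_steps)
    for _ in range(cfg.n_iterations):
        grads = parameter_gradient(net, ut, ua, cfg, train_idx)
        if grads.is_null:
            history.stopped_early = True
            break
        direction = grads.normalized()
        net, gamma, value = line_search_update(
            net, direction, cfg, ut, ua, train_idx, scale
        )
        history.objectives.append(value)
        history.steps.append(gamma)
        if gamma == 0.0:
            zero_run += 1
            if zero_run % 2 == 0:
                scale *= 0.5
            if zero_run >= cfg.early_stop_zero_wins:
                history.stopped_early = True
                break
        else:
            zero_run = 0
            if abs(gamma) == max_trial:
                scale *= 2.0
    return net, history
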