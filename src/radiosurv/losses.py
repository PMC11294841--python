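"""Loss terms and latent-variable primitives of the survival framework.

Each loss exists in two forms: a numpy-facing function with full input
validation (the public contract) and a ``*_t`` tensor form used inside
training graphs. Both share the same arithmetic.

The Cox term is the negative log partial likelihood

    -sum_{i: delta_i=1} [ pi_i - log sum_{j: t_j >= t_i} exp(pi_j) ]

with Breslow handling of tied event times and log-sum-exp
stabilization; the prognostic index pi is the Cox head's linear output.
The beta-VAE regularizer follows the capacity-annealing form
``kld_weight * gamma * |KL - C(step)|`` where the target capacity
C(step) ramps linearly from 0 to ``max_capacity`` over
``capacity_max_iter`` steps; a plain ``beta * KL`` mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp as _np_logsumexp

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .datatypes import SurvivalLabels


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

def risk_set_matrix(time: np.ndarray) -> np.ndarray:
    """R[i, j] = 1 iff sample j is at risk at time t_i (t_j >= t_i)."""
    t = np.asarray(time, dtype=float)
    return (t[None, :] >= t[:, None]).astype(float)


def cox_neg_log_partial_likelihood(pi, labels: SurvivalLabels) -> float:
    """Negative log Cox partial likelihood of scores ``pi`` (Breslow ties)."""
    pi = np.asarray(pi, dtype=float)
    if not np.all(np.isfinite(pi)):
        raise ValueError("prognostic scores must be finite")
    if pi.shape != labels.time.shape:
        raise ValueError("pi and labels must have equal length")
    events = labels.event == 1
    if not events.any():
        raise ValueError("Cox partial likelihood requires >= 1 event")
    total = 0.0
    for i in np.nonzero(events)[0]:
        at_risk = labels.time >= labels.time[i]
        total += pi[i] - _np_logsumexp(pi[at_risk])
    return -float(total)


def cox_loss_t(pi: Tensor, labels: SurvivalLabels) -> Tensor:
    """Tensor form of the Cox loss for training graphs.

    ``pi`` is an (n,)-shaped tensor; risk sets are batch-local.
    """
    events = labels.event == 1
    if not events.any():
        raise ValueError("Cox partial likelihood requires >= 1 event")
    R = risk_set_matrix(labels.time)           # (n, n) constant
    shift = Tensor(pi.data.max())
    e = (pi - shift).exp()                     # (n,)
    denom = (Tensor(R) @ e).log() + shift      # (n,) log-sum-exp over risk sets
    idx = np.nonzero(events)[0]
    terms = pi[idx] - denom[idx]
    return -terms.sum()


def cox_loss_mean_t(pi: Tensor, labels: SurvivalLabels) -> Tensor:
    """Cox loss averaged over observed events (training reduction).

    A constant rescaling of :func:`cox_loss_t` that keeps the Cox term
    on a comparable scale to per-feature mean reconstruction losses,
    independent of batch size.
    """
    n_events = int((labels.event == 1).sum())
    return cox_loss_t(pi, labels) * (1.0 / n_events)


# ---------------------------------------------------------------------------
# reconstruction and penalty terms
# ---------------------------------------------------------------------------

def mse_loss(x, x_hat) -> float:
    """Mean squared error, averaged over samples and features/pixels."""
    x, x_hat = np.asarray(x, dtype=float), np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2))


def mse_loss_t(x: Tensor, x_hat: Tensor) -> Tensor:
    x, x_hat = as_tensor(x), as_tensor(x_hat)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    return ((x - x_hat) ** 2).mean()


def l2_penalty(weights, lam: float) -> float:
    """lambda * sum of squared weights over a flat collection."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return float(lam * sum(float(np.sum(np.square(w))) for w in
                           (np.asarray(w, dtype=float) for w in weights)))


def l2_penalty_t(params, lam: float) -> Tensor:
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    total = Tensor(0.0)
    for p in params:
        total = total + (p ** 2.0).sum()
    return total * lam


# ---------------------------------------------------------------------------
# variational primitives
# ---------------------------------------------------------------------------

def reparameterize(mu, sigma, noise) -> np.ndarray:
    """Reparameterization trick z = mu + sigma * eps (element-wise)."""
    mu, sigma, noise = (np.asarray(a, dtype=float) for a in (mu, sigma, noise))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    return mu + sigma * noise


def reparameterize_t(mu: Tensor, sigma: Tensor, noise: np.ndarray) -> Tensor:
    return mu + sigma * Tensor(noise)


def kl_gaussian(mu, sigma) -> np.ndarray:
    """Per-sample KL(N(mu, sigma^2) || N(0, I)); >= 0, zero iff (0, 1)."""
    mu, sigma = np.asarray(mu, dtype=float), np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    per_dim = -0.5 * (1.0 + np.log(sigma ** 2) - mu ** 2 - sigma ** 2)
    return per_dim.sum(axis=-1) if per_dim.ndim > 1 else float(per_dim.sum())


def kl_gaussian_t(mu: Tensor, log_var: Tensor) -> Tensor:
    """Mean over the batch of per-sample KL, from mu and log-variance."""
    per_dim = (mu ** 2 + log_var.exp() - log_var - 1.0) * 0.5
    return per_dim.sum(axis=-1).mean()


@dataclass
class CapacitySchedule:
    """Capacity-annealed beta-VAE regularization constants."""

    capacity_max_iter: float = 1e5
    gamma: float = 1000.0
    max_capacity: float = 25.0
    kld_weight: float = 0.005
    mode: str = "capacity"   # or "beta": plain beta * KL with beta = gamma

    def __post_init__(self):
        if min(self.capacity_max_iter, self.gamma, self.max_capacity,
               self.kld_weight) <= 0:
            raise ValueError("all schedule constants must be positive")

    def capacity(self, step: int) -> float:
        return self.max_capacity * min(1.0, step / self.capacity_max_iter)


def capacity_regularizer(kl: float, step: int,
                         sched: CapacitySchedule) -> float:
    """kld_weight * gamma * |KL - C(step)| (or beta*KL in plain mode)."""
    if step < 0:
        raise ValueError("step must be >= 0")
    if sched.mode == "beta":
        return sched.kld_weight * sched.gamma * float(kl)
    return sched.kld_weight * sched.gamma * abs(float(kl) - sched.capacity(step))


def capacity_regularizer_t(kl: Tensor, step: int,
                           sched: CapacitySchedule) -> Tensor:
    if sched.mode == "beta":
        return kl * (sched.kld_weight * sched.gamma)
    return (kl - sched.capacity(step)).abs() * (sched.kld_weight * sched.gamma)


# ---------------------------------------------------------------------------
# numpy-facing sparse pathway forward (contract-level op)
# ---------------------------------------------------------------------------

def sparse_pathway_forward(g0, W0, b0, W, A, b) -> np.ndarray:
    """relu((W * A)^T relu(W0^T g0 + b0) + b) for a single sample or batch.

    ``g0`` may be (m,) or (n, m); weights follow the m x m gene layer and
    m x q pathway layer shapes.
    """
    g0, W0, b0, W, A, b = (np.asarray(a, dtype=float)
                           for a in (g0, W0, b0, W, A, b))
    if W.shape != A.shape:
        raise ValueError("pathway weight and mask shapes differ")
    m = W0.shape[0]
    if g0.shape[-1] != m or W0.shape != (m, m) or W.shape[0] != m:
        raise ValueError("dimension mismatch in sparse pathway forward")
    hidden = np.maximum(g0 @ W0 + b0, 0.0)
    return np.maximum(hidden @ (W * A) + b, 0.0)
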