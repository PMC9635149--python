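"""Batch-effect objectives on the latent space.

Three estimators of dependence between the latent representation ``z`` and
the categorical batch label ``s``:

* **MINE** — a neural lower bound on the mutual information
  ``I(z; s)``: ``mean_i f_ψ(z_i, s_i) − log mean_i exp f_ψ(z_i, s'_i)`` where
  ``s'`` is a shuffled copy of the labels that breaks the coupling.  The
  statistics network ``f_ψ`` is maximized adversarially; the resulting value
  is the trainable batch-effect objective.
* **MMD** — the biased V-statistic estimator of the maximum mean discrepancy
  between per-batch latent samples under a mixture of 5 Gaussian kernels,
  square-rooted (clamped at zero first).  With more than two batches the
  value is the mean over unordered batch pairs.
* **kNN MI** — the digamma-form Ross estimator of mutual information between
  continuous ``z`` and discrete ``s``; evaluation-only (not differentiable).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.special import digamma
from sklearn.neighbors import KDTree, NearestNeighbors

from .nn import MLP, Tensor, concat, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "MmdConfig",
    "MineNetwork",
    "shuffle_batch_labels",
    "mine_value",
    "mine_value_graph",
    "mine_fit",
    "mmd_kernel",
    "mmd_value",
    "mmd_value_graph",
    "standardize_latent",
    "nn_mutual_information",
]


# ---------------------------------------------------------------------------
# MINE


def shuffle_batch_labels(s: np.ndarray, seed: int) -> np.ndarray:
    """Uniform random permutation of the labels (multiset preserved)."""
    s = np.asarray(s)
    if s.shape[0] < 2:
        raise ValueError("need at least 2 labels to shuffle")
    rng = np.random.default_rng(seed)
    return s[rng.permutation(s.shape[0])]


def _one_hot(s: np.ndarray, n_levels: int) -> np.ndarray:
    s = np.asarray(s, dtype=np.int64)
    out = np.zeros((s.shape[0], n_levels))
    out[np.arange(s.shape[0]), s] = 1.0
    return out


class MineNetwork:
    """Statistics network f_ψ : R^{d_z} × one-hot(B) → R.

    Default architecture: 10 fully connected hidden layers of 128 units with
    ELU activations, weights initialized N(0, 0.02); configurable down for
    small problems.
    """

    def __init__(self, d_z: int, n_batches: int, hidden: int = 128,
                 n_layers: int = 10, seed: int = 0):
        rng = np.random.default_rng(seed)
        sizes = [d_z + n_batches] + [hidden] * n_layers + [1]
        self.net = MLP(sizes, rng, activation="elu", weight_std=0.02)
        self.d_z, self.n_batches = d_z, n_batches

    def __call__(self, z: Tensor, s_onehot: np.ndarray) -> Tensor:
        if s_onehot.shape[1] != self.n_batches:
            raise ValueError("one-hot width does not match the MINE input")
        return self.net(concat([z, Tensor(s_onehot)], axis=1))

    def parameters(self) -> list[Tensor]:
        return self.net.parameters()


def mine_value_graph(net: MineNetwork, z: Tensor | np.ndarray, s: np.ndarray,
                     s_shuffled: np.ndarray) -> Tensor:
    """Differentiable MINE objective on a minibatch (log-sum-exp stabilized)."""
    z = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=np.float64))
    m = z.data.shape[0]
    joint = net(z, _one_hot(s, net.n_batches))
    marginal = net(z, _one_hot(s_shuffled, net.n_batches))
    value = joint.mean() - (logsumexp(marginal, axis=None) - np.log(m))
    if not np.all(np.isfinite(value.data)):
        raise FloatingPointError("overflow in the MINE exponential term")
    return value


def mine_value(net: MineNetwork, z: np.ndarray, s: np.ndarray,
               s_shuffled: np.ndarray) -> float:
    return mine_value_graph(net, z, s, s_shuffled).item()


def mine_fit(z: np.ndarray, s: np.ndarray, *, epochs: int = 50,
             lr: float = 5e-4, batch_size: int = 128, hidden: int = 128,
             n_layers: int = 10, seed: int = 0, adam_eps: float = 1e-8,
             net: MineNetwork | None = None) -> tuple[MineNetwork, list[float]]:
    """Fit a statistics network by minibatch gradient ascent on the MINE bound.

    A fresh label shuffle is drawn for every minibatch.  Returns the fitted
    network and the per-epoch trace of the full-sample bound.
    """
    from .nn import Adam

    z = np.asarray(z, dtype=np.float64)
    s = np.asarray(s, dtype=np.int64)
    n, d_z = z.shape
    n_batches = int(s.max()) + 1
    if net is None:
        net = MineNetwork(d_z, n_batches, hidden=hidden, n_layers=n_layers,
                          seed=seed)
    opt = Adam(net.parameters(), lr=lr, eps=adam_eps)
    rng = np.random.default_rng(seed + 1)
    trace: list[float] = []
    step = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            if idx.size < 2:
                continue
            sp = shuffle_batch_labels(s[idx], seed=seed + 7919 * step + 13)
            value = mine_value_graph(net, z[idx], s[idx], sp)
            loss = -value
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    "MINE training diverged; try a lower learning rate"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            step += 1
        sp = shuffle_batch_labels(s, seed=seed + 104729 + epoch)
        trace.append(mine_value(net, z, s, sp))
        if not np.isfinite(trace[-1]):
            raise FloatingPointError(
                "MINE training diverged; try a lower learning rate"
            )
    return net, trace


# ---------------------------------------------------------------------------
# MMD


@dataclasses.dataclass
class MmdConfig:
    """Mixture-of-Gaussians kernel configuration."""

    bandwidths: tuple[float, ...] = (1.0, 2.0, 5.0, 8.0, 10.0)
    d_z: int = 10

    def __post_init__(self):
        if any(b <= 0 for b in self.bandwidths):
            raise ValueError("bandwidths must be positive")
        if self.d_z < 1:
            raise ValueError("d_z must be >= 1")


def mmd_kernel(z1: np.ndarray, z2: np.ndarray, cfg: MmdConfig) -> float:
    """Mixture kernel between two single latent vectors."""
    sq = float(np.sum((np.asarray(z1, float) - np.asarray(z2, float)) ** 2))
    bws = np.asarray(cfg.bandwidths)
    return float(np.mean(np.exp(-sq * np.sqrt(cfg.d_z) / (2.0 * bws**2))))


def _gram_graph(a: Tensor, b: Tensor, cfg: MmdConfig) -> Tensor:
    """Kernel Gram matrix between rows of a and rows of b (differentiable)."""
    # ||a_i - b_j||^2 = ||a_i||^2 + ||b_j||^2 - 2 a_i.b_j
    aa = (a * a).sum(axis=1, keepdims=True)                      # (n,1)
    bb = (b * b).sum(axis=1, keepdims=True).reshape(1, b.shape[0])  # (1,m)
    bt = _transpose(b)
    sq = aa + bb - 2.0 * (a @ bt)
    sq = sq * Tensor((sq.data > 0).astype(np.float64))  # clip fp negatives
    out = None
    scale = np.sqrt(cfg.d_z)
    for bw in cfg.bandwidths:
        term = (sq * (-scale / (2.0 * bw**2))).exp()
        out = term if out is None else out + term
    return out * (1.0 / len(cfg.bandwidths))


def _transpose(t: Tensor) -> Tensor:
    def backward(g):
        t._accum(g.T)

    return Tensor._node(t.data.T, (t,), backward)


def _mmd_pair_graph(z0: Tensor, z1: Tensor, cfg: MmdConfig) -> Tensor:
    n0, n1 = z0.shape[0], z1.shape[0]
    k00 = _gram_graph(z0, z0, cfg).mean()
    k11 = _gram_graph(z1, z1, cfg).mean()
    k01 = _gram_graph(z0, z1, cfg).mean()
    mmd2 = k00 + k11 - 2.0 * k01
    # clamp at 0 before the square root; the gradient is guarded near 0
    m2 = float(mmd2.data)
    val = np.sqrt(max(m2, 0.0))

    def backward(g):
        mmd2._accum(g * (0.5 / max(val, 1e-8)) * float(m2 > 0))

    return Tensor._node(val, (mmd2,), backward)


def mmd_value_graph(z: Tensor | np.ndarray, s: np.ndarray,
                    cfg: MmdConfig) -> Tensor:
    """Differentiable MMD batch-effect objective.

    Two batches: square-rooted biased V-statistic.  More than two: mean over
    unordered batch pairs.
    """
    z = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=np.float64))
    s = np.asarray(s, dtype=np.int64)
    levels = np.unique(s)
    if levels.size < 2:
        raise ValueError("MMD needs at least 2 non-empty batch groups")
    groups = {}
    for b in levels:
        idx = np.flatnonzero(s == b)
        if idx.size == 0:
            raise ValueError(f"batch {b} has no cells")
        groups[b] = _row_select(z, idx)
    total = None
    n_pairs = 0
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            term = _mmd_pair_graph(groups[a], groups[b], cfg)
            total = term if total is None else total + term
            n_pairs += 1
    return total * (1.0 / n_pairs)


def _row_select(t: Tensor, idx: np.ndarray) -> Tensor:
    def backward(g):
        acc = np.zeros_like(t.data)
        np.add.at(acc, idx, g)
        t._accum(acc)

    return Tensor._node(t.data[idx], (t,), backward)


def mmd_value(z: np.ndarray, s: np.ndarray, cfg: MmdConfig) -> float:
    return mmd_value_graph(np.asarray(z, dtype=np.float64), s, cfg).item()


def standardize_latent(z: np.ndarray) -> np.ndarray:
    """Center each latent dimension and scale it to unit standard deviation.

    A degenerate (constant) dimension is left centered only, with a warning.
    """
    z = np.asarray(z, dtype=np.float64)
    if z.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    centered = z - z.mean(axis=0, keepdims=True)
    sd = z.std(axis=0, ddof=0)
    degenerate = sd == 0
    if np.any(degenerate):
        logger.warning(
            "latent dimensions %s are constant; left centered only",
            np.flatnonzero(degenerate).tolist(),
        )
    safe = np.where(degenerate, 1.0, sd)
    return centered / safe


# ---------------------------------------------------------------------------
# kNN mutual information (Ross estimator; evaluation only)


def nn_mutual_information(z: np.ndarray, s: np.ndarray, k: int = 3) -> float:
    """Digamma-form kNN estimate of I(z; s), clamped at zero.

    For each point, the distance to its k-th nearest neighbor *within its own
    label class* defines a radius; counting all points (any label) inside
    that radius yields the digamma correction.  Ties broken by index through
    the deterministic KD-tree ordering.
    """
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    if z.shape[0] != np.asarray(s).shape[0]:
        z = z.T
    s = np.asarray(s)
    n = z.shape[0]
    levels, counts = np.unique(s, return_counts=True)
    if levels.size == 1:
        return 0.0
    if np.any(counts <= k):
        bad = levels[counts <= k][0]
        raise ValueError(f"label level {bad!r} has <= k={k} members")
    radius = np.empty(n)
    label_counts = np.empty(n)
    nn = NearestNeighbors(n_neighbors=k)
    for lev, cnt in zip(levels, counts):
        mask = s == lev
        nn.fit(z[mask])
        dist, _ = nn.kneighbors()          # excludes self
        radius[mask] = np.nextafter(dist[:, -1], 0)
        label_counts[mask] = cnt
    tree = KDTree(z)
    m_all = tree.query_radius(z, radius, count_only=True)
    mi = (
        digamma(n)
        + digamma(k)
        - np.mean(digamma(label_counts))
        - np.mean(digamma(np.maximum(m_all, 1)))
    )
    return max(0.0, float(mi))
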