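"""Synthetic data with the statistical structure the method assumes.

Three generators:

* :func:`simulate_zinb_dataset` — counts from the Gamma–Poisson–Bernoulli
  hierarchy: cell types define gene loadings, a batch effect shifts the
  log-mean of a gene subset, per-batch log-normal library sizes, and
  mean-dependent (or constant) dropout.  The full latent truth is returned.
* :func:`simulate_mi_pairs` — Gaussian class-conditional latents with a
  controlled mean separation and the true mutual information computed by
  quadrature (collinear means) or high-n Monte Carlo.
* :func:`toy_front` — analytic quarter-circle fronts (convex or non-convex)
  with dominated noise points and ground-truth flags.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.integrate import quad
from scipy.stats import multivariate_normal

from .data import ExpressionDataset

__all__ = ["SimSpec", "simulate_zinb_dataset", "simulate_mi_pairs", "toy_front"]


@dataclasses.dataclass
class SimSpec:
    """Study conditions for the count simulator.

    Defaults give a two-batch, three-type dataset with a moderate batch
    shift — the confound the method is designed to remove — and realistic
    single-cell scale: ~2000-count libraries, strong per-type signatures,
    mean-linked dropout.
    """

    n: int = 2000
    G: int = 60
    B: int = 2
    T: int = 3
    type_proportions: tuple[float, ...] | None = None
    batch_proportions: tuple[float, ...] | None = None
    type_batch_confounding: float = 0.0   # in [0,1): composition shift across batches
    type_loading_scale: float = 1.0
    batch_effect_strength: float = 1.0
    batch_gene_fraction: float = 0.3
    inv_dispersion_log_mean: float = np.log(5.0)
    inv_dispersion_log_sd: float = 0.7
    library_log_mean: tuple[float, ...] | None = None   # per batch
    library_log_sd: tuple[float, ...] | None = None
    dropout_mode: str = "logistic"   # or "constant"
    dropout_base_rate: float = 0.1
    dropout_slope: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.T > self.n or self.B > self.n:
            raise ValueError("more cell types or batches than cells")
        if self.n < 1 or self.G < 1 or self.B < 1 or self.T < 1:
            raise ValueError("all counts must be >= 1")
        if self.batch_effect_strength < 0:
            raise ValueError("batch effect strength must be >= 0")
        if self.type_proportions is None:
            self.type_proportions = tuple([1.0 / self.T] * self.T)
        if abs(sum(self.type_proportions) - 1.0) > 1e-8:
            raise ValueError("type proportions must sum to 1")
        if self.batch_proportions is None:
            self.batch_proportions = tuple([1.0 / self.B] * self.B)
        if abs(sum(self.batch_proportions) - 1.0) > 1e-8:
            raise ValueError("batch proportions must sum to 1")
        if not 0.0 <= self.type_batch_confounding < 1.0:
            raise ValueError("type_batch_confounding must lie in [0, 1)")
        if self.library_log_mean is None:
            self.library_log_mean = tuple([np.log(2000.0)] * self.B)
        if self.library_log_sd is None:
            self.library_log_sd = tuple([0.3] * self.B)
        if len(self.library_log_mean) != self.B or len(self.library_log_sd) != self.B:
            raise ValueError("library parameters need one entry per batch")
        if self.dropout_mode not in ("logistic", "constant"):
            raise ValueError("dropout_mode must be 'logistic' or 'constant'")


def simulate_zinb_dataset(spec: SimSpec) -> tuple[ExpressionDataset, dict]:
    """Draw counts from the ZINB hierarchy with known ground truth.

    Per cell i and gene g: ``ε_i = softmax(loading[type_i] + shift[batch_i])``,
    ``w ~ Gamma(shape c_g, scale ε_i^g / c_g)`` (so E w = ε and the marginal
    count is NB with mean ``l_i ε_i^g`` and inverse dispersion ``c_g``),
    ``y ~ Poisson(l_i w)``, and dropout zeroes y with probability π.  The
    truth record carries ε, c, π, library sizes and the batch-shift mask.
    """
    rng = np.random.default_rng(spec.seed)
    n, G, B, T = spec.n, spec.G, spec.B, spec.T

    batch = rng.choice(B, size=n, p=np.asarray(spec.batch_proportions))
    # compositional confounding: cell-type proportions tilt linearly across
    # batches, so type identity itself carries batch information (as when
    # differently sampled protocols are integrated)
    base = np.asarray(spec.type_proportions)
    tilt = np.linspace(-1.0, 1.0, T)
    if B > 1:
        bpos = np.linspace(-1.0, 1.0, B)
    else:
        bpos = np.zeros(1)
    cell_type = np.empty(n, dtype=np.int64)
    for b in range(B):
        p = base * (1.0 + spec.type_batch_confounding * bpos[b] * tilt)
        p = np.maximum(p, 1e-12)
        p /= p.sum()
        mask = batch == b
        cell_type[mask] = rng.choice(T, size=int(mask.sum()), p=p)

    loadings = rng.normal(0.0, spec.type_loading_scale, size=(T, G))
    n_shift = int(round(spec.batch_gene_fraction * G))
    shifted_genes = rng.choice(G, size=n_shift, replace=False)
    shift = np.zeros((B, G))
    for b in range(1, B):
        signs = rng.choice([-1.0, 1.0], size=n_shift)
        shift[b, shifted_genes] = spec.batch_effect_strength * signs

    logits = loadings[cell_type] + shift[batch]
    logits -= logits.max(axis=1, keepdims=True)
    eps = np.exp(logits)
    eps /= eps.sum(axis=1, keepdims=True)

    c = np.exp(rng.normal(spec.inv_dispersion_log_mean,
                          spec.inv_dispersion_log_sd, size=G))
    log_lib = rng.normal(np.asarray(spec.library_log_mean)[batch],
                         np.asarray(spec.library_log_sd)[batch])
    library = np.exp(log_lib)

    w = rng.gamma(shape=c[None, :], scale=eps / c[None, :])
    y = rng.poisson(library[:, None] * w)

    nb_mean = library[:, None] * eps
    if spec.dropout_mode == "constant":
        pi = np.full((n, G), spec.dropout_base_rate)
    else:
        base_logit = np.log(spec.dropout_base_rate / (1 - spec.dropout_base_rate))
        pi = 1.0 / (1.0 + np.exp(-(base_logit
                                   - spec.dropout_slope * np.log1p(nb_mean))))
    h = rng.random((n, G)) < pi
    counts = np.where(h, 0, y).astype(np.int64)

    # guard against all-zero cells (breaks the log-library prior)
    dead = counts.sum(axis=1) == 0
    if np.any(dead):
        top = np.argmax(eps[dead], axis=1)
        counts[np.flatnonzero(dead), top] = 1

    ds = ExpressionDataset(
        counts=counts,
        batch=batch,
        gene_names=np.asarray([f"gene_{g}" for g in range(G)], dtype=object),
        cell_type=cell_type,
    )
    truth = {
        "mean_prop": eps,
        "inv_dispersion": c,
        "dropout_prob": pi,
        "library": library,
        "shifted_genes": np.sort(shifted_genes),
        "loadings": loadings,
        "batch_shift": shift,
    }
    return ds, truth


# ---------------------------------------------------------------------------
# Gaussian mixtures with known mutual information


def _collinear_mixture_mi(offsets: np.ndarray, weights: np.ndarray) -> float:
    """Exact MI by 1-D quadrature when the class means are collinear.

    ``offsets`` are the signed positions of the class means along the common
    direction; conditional distributions are unit-variance Gaussians.
    """
    sd = 1.0

    def cond(t, mu):
        return np.exp(-((t - mu) ** 2) / (2 * sd**2)) / np.sqrt(2 * np.pi * sd**2)

    def integrand(t):
        ps = np.array([cond(t, mu) for mu in offsets])
        mix = float(weights @ ps)
        out = 0.0
        for wgt, p in zip(weights, ps):
            if p > 0 and mix > 0:
                out += wgt * p * np.log(p / mix)
        return out

    lo = float(offsets.min() - 12)
    hi = float(offsets.max() + 12)
    val, _ = quad(integrand, lo, hi, limit=400)
    return max(0.0, float(val))


def _mc_mixture_mi(means: np.ndarray, weights: np.ndarray, n_mc: int,
                   seed: int) -> tuple[float, float]:
    """Monte-Carlo MI for arbitrary unit-variance Gaussian class means."""
    rng = np.random.default_rng(seed)
    B, d = means.shape
    labels = rng.choice(B, size=n_mc, p=weights)
    x = means[labels] + rng.standard_normal((n_mc, d))
    log_cond = np.empty(n_mc)
    log_comp = np.empty((n_mc, B))
    for b in range(B):
        log_comp[:, b] = multivariate_normal.logpdf(x, mean=means[b])
    log_cond = log_comp[np.arange(n_mc), labels]
    log_mix = np.logaddexp.reduce(log_comp + np.log(weights)[None, :], axis=1)
    vals = log_cond - log_mix
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_mc))


def simulate_mi_pairs(B: int, mu: float, d_z: int, n: int, seed: int = 0):
    """Labeled Gaussian latents with known mutual information.

    ``s`` is uniform over B classes; ``z | s = b ~ N(m_b, I)`` with the class
    means spaced ``mu`` apart along the first axis.  Returns
    ``(z, s, true_mi, mi_err)`` where the truth comes from 1-D quadrature
    (error ~1e-10) since the means are collinear by construction.
    """
    if B < 2:
        raise ValueError("need at least 2 classes")
    if n < 100 * B:
        raise ValueError("need at least 100 draws per class")
    rng = np.random.default_rng(seed)
    offsets = (np.arange(B) - (B - 1) / 2.0) * mu
    means = np.zeros((B, d_z))
    means[:, 0] = offsets
    s = rng.integers(0, B, size=n)
    z = means[s] + rng.standard_normal((n, d_z))
    weights = np.full(B, 1.0 / B)
    true_mi = _collinear_mixture_mi(offsets, weights)
    return z, s, true_mi, 1e-10


def mixture_mi_mc(B: int, mu: float, d_z: int, n_mc: int = 10**6,
                  seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo cross-check of the quadrature truth (value, std. error)."""
    offsets = (np.arange(B) - (B - 1) / 2.0) * mu
    means = np.zeros((B, d_z))
    means[:, 0] = offsets
    return _mc_mixture_mi(means, np.full(B, 1.0 / B), n_mc, seed)


# ---------------------------------------------------------------------------
# analytic fronts


def toy_front(shape: str, n: int, seed: int = 0):
    """Points on an analytic quarter-circle front plus dominated noise.

    ``convex``: the front is ``(1−cos t, 1−sin t)`` (bulges toward the
    origin — every point is a minimizer of some scalarization).
    ``nonconvex``: the front is ``(cos t, sin t)`` (bulges away from the
    origin — interior points minimize no scalarization).  Returns
    ``(points, is_front)`` with exactly the first ``ceil(n/2)`` rows on the
    front.
    """
    if n < 3:
        raise ValueError("need at least 3 points")
    if shape not in ("convex", "nonconvex"):
        raise ValueError("shape must be 'convex' or 'nonconvex'")
    rng = np.random.default_rng(seed)
    n_front = (n + 1) // 2
    t = np.linspace(0.0, np.pi / 2.0, n_front)
    if shape == "convex":
        front = np.column_stack([1.0 - np.cos(t), 1.0 - np.sin(t)])
    else:
        front = np.column_stack([np.cos(t), np.sin(t)])
    n_noise = n - n_front
    base = front[rng.integers(0, n_front, size=n_noise)]
    noise = base + rng.uniform(0.05, 0.6, size=(n_noise, 2))
    points = np.vstack([front, noise])
    flags = np.zeros(n, dtype=bool)
    flags[:n_front] = True
    return points, flags
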