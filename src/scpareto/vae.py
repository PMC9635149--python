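"""Zero-inflated negative binomial variational autoencoder.

The generative model, following the scVI family: a low-dimensional biological
latent ``z ~ N(0, I)`` and a scalar log-library latent
``l ~ N(l_mu[batch], l_var[batch])`` decode, together with the one-hot batch
label ``s``, into per-cell ZINB parameters:

* ``mean_prop`` (ε): per-cell expression proportions over genes (simplex rows,
  softmax decoder head),
* ``inv_dispersion`` (c): gene-wise inverse dispersion, a free parameter
  ``exp(log_c)`` shared across cells,
* ``dropout_prob`` (π): zero-inflation probability, sigmoid decoder head.

The Gamma–Poisson–Bernoulli hierarchy marginalizes analytically to the ZINB
pmf with NB mean ``μ = exp(l)·ε`` and inverse dispersion ``c``, where the NB
pmf is ``NB(x; μ, c) = Γ(x+c)/(Γ(c) x!) (c/(c+μ))^c (μ/(c+μ))^x`` (variance
``μ + μ²/c``).

The training objective is the negative evidence lower bound (one Monte Carlo
sample for the reconstruction expectation, analytic Gaussian KL terms); we
call it the generative loss ``U_n`` throughout.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import gammaln

from .data import ExpressionDataset
from .nn import MLP, Linear, Tensor, concat, logaddexp

__all__ = [
    "LibraryPrior",
    "LatentPosterior",
    "ZINBParams",
    "compute_library_prior",
    "kl_diag_normal",
    "zinb_log_pmf",
    "ZinbVae",
]


@dataclasses.dataclass
class LibraryPrior:
    """Per-batch empirical mean and variance of log total counts."""

    l_mu: np.ndarray   # (B,)
    l_var: np.ndarray  # (B,)

    def __post_init__(self):
        self.l_mu = np.asarray(self.l_mu, dtype=np.float64)
        self.l_var = np.asarray(self.l_var, dtype=np.float64)
        if self.l_mu.shape != self.l_var.shape or self.l_mu.ndim != 1:
            raise ValueError("l_mu and l_var must be 1-D with one entry per batch")
        if np.any(self.l_var <= 0):
            raise ValueError("library variance must be strictly positive per batch")


@dataclasses.dataclass
class LatentPosterior:
    """Diagonal-Gaussian variational posterior parameters per cell."""

    z_mean: np.ndarray
    z_var: np.ndarray
    l_mean: np.ndarray
    l_var: np.ndarray


@dataclasses.dataclass
class ZINBParams:
    """Decoded per-cell ZINB parameters."""

    mean_prop: np.ndarray       # (n, G) simplex rows (ε)
    inv_dispersion: np.ndarray  # (G,) positive (c)
    dropout_prob: np.ndarray    # (n, G) in (0, 1)
    library: np.ndarray         # (n,) positive (exp l)


def compute_library_prior(ds: ExpressionDataset) -> LibraryPrior:
    """Empirical per-batch mean/variance (unbiased, n−1) of log library size."""
    totals = ds.counts.sum(axis=1)
    if np.any(totals <= 0):
        bad = int(np.flatnonzero(totals <= 0)[0])
        raise ValueError(f"cell {bad} has zero total count; cannot take log")
    log_tot = np.log(totals.astype(np.float64))
    B = ds.n_batches
    l_mu = np.empty(B)
    l_var = np.empty(B)
    for b in range(B):
        vals = log_tot[ds.batch == b]
        if vals.size < 2:
            raise ValueError(f"batch {b} has fewer than 2 cells; variance undefined")
        l_mu[b] = vals.mean()
        l_var[b] = vals.var(ddof=1)
        if l_var[b] <= 0:
            raise ValueError(f"batch {b} has zero log-library variance")
    return LibraryPrior(l_mu=l_mu, l_var=l_var)


def kl_diag_normal(mu0, var0, mu1, var1):
    """Closed-form KL( N(mu0, diag var0) || N(mu1, diag var1) ), summed over dims.

    Accepts numpy arrays (returns float) or graph tensors (returns a Tensor);
    the last axis is the dimension axis, leading axes are batch axes that are
    summed into the scalar result only for the numpy path.
    """
    if isinstance(mu0, Tensor) or isinstance(var0, Tensor):
        mu0, var0 = Tensor._lift(mu0), Tensor._lift(var0)
        mu1, var1 = Tensor._lift(mu1), Tensor._lift(var1)
        if np.any(var0.data <= 0) or np.any(var1.data <= 0):
            raise ValueError("variances must be strictly positive")
        term = (var1.log() - var0.log() + (var0 + (mu0 - mu1) ** 2) / var1 - 1.0) * 0.5
        return term.sum(axis=-1) if term.data.ndim > 1 else term.sum()
    mu0, var0 = np.asarray(mu0, float), np.asarray(var0, float)
    mu1, var1 = np.asarray(mu1, float), np.asarray(var1, float)
    if np.any(var0 <= 0) or np.any(var1 <= 0):
        raise ValueError("variances must be strictly positive")
    term = 0.5 * (np.log(var1 / var0) + (var0 + (mu0 - mu1) ** 2) / var1 - 1.0)
    return float(term.sum())


def zinb_log_pmf(x, mu, c, pi):
    """Log pmf of the zero-inflated negative binomial.

    ``log[ π·1{x=0} + (1−π)·NB(x; mean μ, inverse dispersion c) ]``, evaluated
    in log space (log-sum-exp at x = 0).  Vectorized over broadcastable inputs.
    """
    x = np.asarray(x)
    if np.any(x < 0) or not np.all(x == np.round(x)):
        raise ValueError("x must be a non-negative integer count")
    x = x.astype(np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    pi = np.asarray(pi, dtype=np.float64)
    if np.any(mu <= 0) or np.any(c <= 0):
        raise ValueError("mu and c must be strictly positive")
    if np.any(pi <= 0) or np.any(pi >= 1):
        raise ValueError("pi must lie strictly inside (0, 1)")
    log_nb = (
        gammaln(x + c)
        - gammaln(c)
        - gammaln(x + 1.0)
        + c * (np.log(c) - np.log(c + mu))
        + x * (np.log(mu) - np.log(c + mu))
    )
    case_pos = np.log1p(-pi) + log_nb
    case_zero = np.logaddexp(np.log(pi), np.log1p(-pi) + c * (np.log(c) - np.log(c + mu)))
    out = np.where(x == 0, case_zero, case_pos)
    return out if out.ndim else float(out)


def _zinb_log_pmf_graph(x_const: np.ndarray, mu: Tensor, c: Tensor,
                        dropout_logits: Tensor) -> Tensor:
    """Graph version on the dropout logit scale (α = logit π) for stability.

    log π = −softplus(−α), log(1−π) = −softplus(α).
    """
    x = Tensor(x_const.astype(np.float64))
    log_c_ratio = c * (c.log() - (c + mu).log())        # log NB(0)
    log_pi = -(-dropout_logits).softplus()
    log_1mpi = -dropout_logits.softplus()
    case_zero = logaddexp(log_pi, log_1mpi + log_c_ratio)
    log_nb = (
        (x + c).lgamma()
        - c.lgamma()
        - Tensor(gammaln(x_const + 1.0))
        + log_c_ratio
        + x * (mu.log() - (c + mu).log())
    )
    case_pos = log_1mpi + log_nb
    mask0 = Tensor((x_const == 0).astype(np.float64))
    return mask0 * case_zero + (1.0 - mask0) * case_pos


class ZinbVae:
    """Encoder/decoder pair with the negative-ELBO objective.

    Parameters
    ----------
    n_genes, n_batches : data dimensions.
    d_z : latent dimension (default 10).
    hidden : width of the single hidden layer in encoder and decoder
        (default 128, the scVI convention).
    library_log_mean : optional initial bias for the library-mean head, so the
        decoded library starts near the data scale.
    seed : seed for weight initialization.
    """

    def __init__(self, n_genes: int, n_batches: int, d_z: int = 10,
                 hidden: int = 128, library_log_mean: float = 0.0,
                 seed: int = 0):
        if d_z < 1:
            raise ValueError("d_z must be >= 1")
        rng = np.random.default_rng(seed)
        self.n_genes, self.n_batches, self.d_z = n_genes, n_batches, d_z
        # encoder trunk on log1p(counts), four heads
        self.enc_trunk = Linear(n_genes, hidden, rng)
        self.enc_z_mean = Linear(hidden, d_z, rng, weight_std=0.01)
        self.enc_z_logvar = Linear(hidden, d_z, rng, weight_std=0.01)
        self.enc_l_mean = Linear(hidden, 1, rng, weight_std=0.01)
        self.enc_l_logvar = Linear(hidden, 1, rng, weight_std=0.01)
        self.enc_l_mean.b.data = self.enc_l_mean.b.data + library_log_mean
        # decoder trunk on (z, one-hot s), two heads + free dispersion
        self.dec_trunk = Linear(d_z + n_batches, hidden, rng)
        self.dec_eps = Linear(hidden, n_genes, rng, weight_std=0.01)
        self.dec_dropout = Linear(hidden, n_genes, rng, weight_std=0.01)
        self.log_c = Tensor(np.zeros(n_genes), requires_grad=True)

    # -- parameter groups -------------------------------------------------
    def encoder_parameters(self) -> list[Tensor]:
        return (
            self.enc_trunk.parameters()
            + self.enc_z_mean.parameters()
            + self.enc_z_logvar.parameters()
            + self.enc_l_mean.parameters()
            + self.enc_l_logvar.parameters()
        )

    def decoder_parameters(self) -> list[Tensor]:
        return (
            self.dec_trunk.parameters()
            + self.dec_eps.parameters()
            + self.dec_dropout.parameters()
            + [self.log_c]
        )

    def parameters(self) -> list[Tensor]:
        return self.encoder_parameters() + self.decoder_parameters()

    # -- encoder -----------------------------------------------------------
    def _encode_graph(self, counts: np.ndarray):
        x = np.asarray(counts, dtype=np.float64)
        if np.any(x < 0) or not np.all(np.isfinite(x)):
            raise ValueError("counts must be finite and non-negative")
        h = self.enc_trunk(Tensor(np.log1p(x)))
        if not np.all(np.isfinite(h.data)):
            raise FloatingPointError("non-finite activation in encoder layer 0")
        h = h * Tensor((h.data > 0).astype(np.float64))  # ReLU
        z_mean = self.enc_z_mean(h)
        z_var = self.enc_z_logvar(h).exp()
        l_mean = self.enc_l_mean(h)
        l_var = self.enc_l_logvar(h).exp()
        for name, t in [("z_mean", z_mean), ("z_var", z_var),
                        ("l_mean", l_mean), ("l_var", l_var)]:
            if not np.all(np.isfinite(t.data)):
                raise FloatingPointError(f"non-finite activation in encoder head {name}")
        return z_mean, z_var, l_mean, l_var

    def encode(self, counts: np.ndarray) -> LatentPosterior:
        """Posterior parameters for a minibatch of count rows (deterministic)."""
        z_mean, z_var, l_mean, l_var = self._encode_graph(counts)
        return LatentPosterior(
            z_mean=z_mean.data.copy(),
            z_var=z_var.data.copy(),
            l_mean=l_mean.data[:, 0].copy(),
            l_var=l_var.data[:, 0].copy(),
        )

    @staticmethod
    def sample_latent(post: LatentPosterior, seed: int):
        """One reparameterized draw (z, l) per cell from the posterior."""
        if np.any(post.z_var < 0) or np.any(post.l_var < 0):
            raise ValueError("posterior variances must be non-negative")
        rng = np.random.default_rng(seed)
        z = post.z_mean + np.sqrt(post.z_var) * rng.standard_normal(post.z_mean.shape)
        l = post.l_mean + np.sqrt(post.l_var) * rng.standard_normal(post.l_mean.shape)
        return z, l

    # -- decoder -----------------------------------------------------------
    def _decode_graph(self, z: Tensor, s_onehot: np.ndarray):
        if s_onehot.shape[1] != self.n_batches:
            raise ValueError("one-hot batch width does not match n_batches")
        h = self.dec_trunk(concat([z, Tensor(s_onehot)], axis=1))
        h = h * Tensor((h.data > 0).astype(np.float64))
        # tiny floor keeps extreme logits from underflowing a proportion to
        # exactly zero (log μ appears in the likelihood); rows still sum to 1
        G = self.n_genes
        eps = (self.dec_eps(h).softmax(axis=1) + 1e-10) * (1.0 / (1.0 + G * 1e-10))
        dropout_logits = self.dec_dropout(h)
        return eps, dropout_logits

    def decode(self, z: np.ndarray, s_onehot: np.ndarray,
               library_log: np.ndarray | None = None) -> ZINBParams:
        """Decode latent draws into ZINB parameters (numpy, detached)."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        if not np.all(np.isfinite(z)):
            raise ValueError("z must be finite")
        eps, dropout_logits = self._decode_graph(Tensor(z), np.asarray(s_onehot))
        pi = 0.5 * (1.0 + np.tanh(0.5 * dropout_logits.data))
        lib = np.exp(library_log) if library_log is not None else np.ones(z.shape[0])
        return ZINBParams(
            mean_prop=eps.data.copy(),
            inv_dispersion=np.exp(self.log_c.data),
            dropout_prob=pi,
            library=np.asarray(lib, dtype=np.float64),
        )

    def one_hot(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=np.int64)
        out = np.zeros((s.shape[0], self.n_batches))
        out[np.arange(s.shape[0]), s] = 1.0
        return out

    # -- objective -----------------------------------------------------------
    def negative_elbo_graph(self, counts: np.ndarray, s: np.ndarray,
                            prior: LibraryPrior, seed: int,
                            kl_weight: float = 1.0) -> Tensor:
        """Minibatch-mean negative ELBO as a graph scalar (differentiable).

        One reparameterized latent sample estimates the reconstruction
        expectation; both KL terms use the analytic Gaussian closed form.
        ``kl_weight`` exists as a test hook (0 isolates the reconstruction
        term); training always uses 1.
        """
        counts = np.asarray(counts)
        s = np.asarray(s, dtype=np.int64)
        z_mean, z_var, l_mean, l_var = self._encode_graph(counts)
        rng = np.random.default_rng(seed)
        eps_z = rng.standard_normal(z_mean.data.shape)
        eps_l = rng.standard_normal(l_mean.data.shape)
        z = z_mean + z_var.sqrt() * Tensor(eps_z)
        l = l_mean + l_var.sqrt() * Tensor(eps_l)
        # keep exp(l) in a sane band around the empirical library prior
        l = l.clip(float(prior.l_mu.min()) - 10.0, float(prior.l_mu.max()) + 10.0)

        s_onehot = self.one_hot(s)
        eps_prop, dropout_logits = self._decode_graph(z, s_onehot)
        mu = l.exp() * eps_prop                     # (n,1) broadcast to (n,G)
        c = self.log_c.exp()
        log_pmf = _zinb_log_pmf_graph(counts, mu, c, dropout_logits)
        recon = log_pmf.sum(axis=1)

        kl_z = kl_diag_normal(z_mean, z_var, Tensor(0.0), Tensor(1.0))
        prior_mu = prior.l_mu[s][:, None]
        prior_var = prior.l_var[s][:, None]
        kl_l = kl_diag_normal(l_mean, l_var, Tensor(prior_mu), Tensor(prior_var))

        for name, t in [("reconstruction", recon), ("kl_z", kl_z), ("kl_l", kl_l)]:
            if not np.all(np.isfinite(t.data)):
                raise FloatingPointError(f"non-finite {name} term in negative ELBO")
        return (-recon + kl_weight * (kl_z + kl_l)).mean()

    def negative_elbo(self, counts: np.ndarray, s: np.ndarray,
                      prior: LibraryPrior, seed: int,
                      kl_weight: float = 1.0) -> float:
        """Scalar U_n for a minibatch (see :meth:`negative_elbo_graph`)."""
        return self.negative_elbo_graph(counts, s, prior, seed, kl_weight).item()

    def latent_mean(self, counts: np.ndarray) -> np.ndarray:
        """Posterior mean of z — the latent coordinates used for evaluation."""
        return self.encode(counts).z_mean
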