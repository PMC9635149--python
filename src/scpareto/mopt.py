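"""Multi-objective training: Pareto MTL and scalarization.

The bi-objective problem is ``min (U̅_n, V̅_n)`` over encoder/decoder weights,
where both objectives are standardized by min/max bounds recorded during
single-objective pretraining.  Pareto MTL decomposes the first quadrant with
unit preference vectors ``c_k`` and solves one constrained subproblem per
sector: constraint values ``g_j = (c_j − c_k)ᵀ L̅`` define an ε-active set,
and each update direction is the min-norm convex combination of the active
objective/constraint gradients (initialization phase: constraint gradients
only; main phase: objective gradients included).  Scalarization minimizes
``λ U̅ + (1−λ) V̅`` over a fixed λ grid.  With MINE as the batch-effect
measure, the statistics network is re-maximized adversarially before every
minimization step.

The min-norm subproblem ``min ‖Σ a_i v_i‖²`` over the simplex is solved
analytically for one or two vectors and by Frank–Wolfe with exact line
search otherwise.
"""

from __future__ import annotations

import copy
import dataclasses
from typing import Callable, Literal

import numpy as np

from .data import ExpressionDataset
from .measures import (
    MineNetwork,
    MmdConfig,
    mine_fit,
    mine_value,
    mine_value_graph,
    mmd_value,
    mmd_value_graph,
    shuffle_batch_labels,
    standardize_latent,
)
from .nn import Adam, SGD, Tensor, assign_flat_grads, flatten_grads
from .vae import LibraryPrior, ZinbVae, compute_library_prior

__all__ = [
    "StandardizationBounds",
    "MinNormSolution",
    "TrainConfig",
    "ParetoCandidate",
    "preference_vectors",
    "standardize",
    "constraint_values",
    "active_set",
    "min_norm_point",
    "min_norm_init",
    "min_norm_main",
    "apply_update",
    "scalarized_loss",
    "record_bounds",
    "train_candidate",
    "train_extremes",
    "evaluate_candidate",
    "pareto_mtl_minimize",
    "scalarization_minimize",
]


# ---------------------------------------------------------------------------
# small pure pieces


@dataclasses.dataclass
class StandardizationBounds:
    U_min: float
    U_max: float
    V_min: float
    V_max: float

    def __post_init__(self):
        if not self.U_max > self.U_min:
            raise ValueError("U_max must exceed U_min")
        if not self.V_max > self.V_min:
            raise ValueError("V_max must exceed V_min")


def preference_vectors(K: int) -> np.ndarray:
    """K unit vectors spanning the first quadrant: c_k = (cos a_k, sin a_k),
    a_k = (k−1)π / (2(K−1))."""
    if K < 2:
        raise ValueError("K must be >= 2")
    angles = np.arange(K) * np.pi / (2.0 * (K - 1))
    return np.column_stack([np.cos(angles), np.sin(angles)])


def standardize(value: float, lo: float, hi: float) -> float:
    """(value − lo)/(hi − lo); values outside [0, 1] are not clamped."""
    if not hi > lo:
        raise ValueError("upper bound must exceed lower bound")
    return (value - lo) / (hi - lo)


def constraint_values(L: np.ndarray, k: int, prefs: np.ndarray) -> np.ndarray:
    """g_j = (c_j − c_k)ᵀ L̅ for every preference vector j."""
    L = np.asarray(L, dtype=np.float64)
    return (prefs - prefs[k]) @ L


def active_set(g: np.ndarray, eps: float) -> np.ndarray:
    """Indices with g_j ≥ −ε (the subproblem's own index is always in)."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    return np.flatnonzero(np.asarray(g) >= -eps)


@dataclasses.dataclass
class MinNormSolution:
    coeffs: np.ndarray          # simplex weights over the supplied vectors
    d: np.ndarray               # composite direction Σ coeffs_i v_i
    converged: bool = True

    @property
    def norm_sq(self) -> float:
        return float(self.d @ self.d)


def min_norm_point(vectors: list[np.ndarray], max_iter: int = 200,
                   tol: float = 1e-7) -> MinNormSolution:
    """Minimize ‖Σ a_i v_i‖² over the probability simplex.

    Analytic for one or two vectors; Frank–Wolfe with exact line search on
    the Gram matrix otherwise (stops at duality gap ≤ tol).
    """
    if len(vectors) == 0:
        raise ValueError("min-norm needs at least one vector")
    V = np.asarray(vectors, dtype=np.float64)
    if V.ndim == 1:
        V = V[:, None]
    m = V.shape[0]
    if m == 1:
        return MinNormSolution(coeffs=np.array([1.0]), d=V[0].copy())
    if m == 2:
        diff = V[0] - V[1]
        denom = float(diff @ diff)
        if denom == 0.0:
            a = 0.5
        else:
            a = float(np.clip((V[1] @ V[1] - V[1] @ V[0]) / denom, 0.0, 1.0))
        coeffs = np.array([a, 1.0 - a])
        return MinNormSolution(coeffs=coeffs, d=coeffs @ V)
    G = V @ V.T
    if m <= 16:
        return _min_norm_exact(V, G)
    a = np.full(m, 1.0 / m)
    converged = False
    for _ in range(max_iter):
        grad = G @ a  # ∝ gradient of ½ aᵀGa
        s = int(np.argmin(grad))
        fw_gap = float(a @ grad - grad[s])
        if fw_gap <= tol:
            converged = True
            break
        support = np.flatnonzero(a > 0)
        v = int(support[np.argmax(grad[support])])
        # away-step variant: pick the steeper of the toward/away directions
        if fw_gap >= float(grad[v] - a @ grad):
            dvec = -a.copy()
            dvec[s] += 1.0
            max_step = 1.0
        else:
            dvec = a.copy()
            dvec[v] -= 1.0
            max_step = a[v] / (1.0 - a[v]) if a[v] < 1.0 else 0.0
        denom = float(dvec @ G @ dvec)
        if denom <= 0:
            converged = True
            break
        step = float(np.clip(-(a @ G @ dvec) / denom, 0.0, max_step))
        if step == 0.0:
            converged = True
            break
        a = a + step * dvec
        a = np.maximum(a, 0.0)
        a /= a.sum()
    return MinNormSolution(coeffs=a, d=a @ V, converged=converged)


def _min_norm_exact(V: np.ndarray, G: np.ndarray) -> MinNormSolution:
    """Exact simplex-constrained min-norm by KKT support enumeration.

    For every candidate support S solve the equality-constrained system
    ``[G_S, 1; 1ᵀ, 0][a; ν] = [0; 1]`` and keep the best feasible solution.
    Exponential in the number of vectors, exact and deterministic; used for
    the small systems (≲ a dozen gradients) this package produces.
    """
    m = G.shape[0]
    best: tuple[float, np.ndarray] | None = None
    for mask in range(1, 1 << m):
        idx = [i for i in range(m) if mask >> i & 1]
        ms = len(idx)
        A = np.zeros((ms + 1, ms + 1))
        A[:ms, :ms] = G[np.ix_(idx, idx)]
        A[:ms, ms] = 1.0
        A[ms, :ms] = 1.0
        rhs = np.zeros(ms + 1)
        rhs[ms] = 1.0
        try:
            sub = np.linalg.lstsq(A, rhs, rcond=None)[0][:ms]
        except np.linalg.LinAlgError:
            continue
        if np.any(sub < -1e-10):
            continue
        a = np.zeros(m)
        a[idx] = np.maximum(sub, 0.0)
        total = a.sum()
        if total <= 0:
            continue
        a /= total
        val = float(a @ G @ a)
        if best is None or val < best[0] - 1e-15:
            best = (val, a)
    assert best is not None
    a = best[1]
    return MinNormSolution(coeffs=a, d=a @ V, converged=True)


_ZERO_NORM = 1e-12


def min_norm_init(gradients: list[np.ndarray]) -> MinNormSolution:
    """Initialization-phase solve over active constraint gradients only.

    Zero gradients (the subproblem's own constraint has ∇g_k = 0 identically)
    carry no direction and are excluded from the solve; if nothing remains
    the current point already satisfies the sector and d = 0 is returned.
    """
    if len(gradients) == 0:
        raise ValueError("empty active set")
    norms = [float(np.linalg.norm(g)) for g in gradients]
    keep = [i for i, nm in enumerate(norms) if nm > _ZERO_NORM]
    if not keep:
        dim = np.asarray(gradients[0]).shape
        return MinNormSolution(coeffs=np.zeros(len(gradients)),
                               d=np.zeros(dim), converged=True)
    sol = min_norm_point([gradients[i] for i in keep])
    coeffs = np.zeros(len(gradients))
    coeffs[keep] = sol.coeffs
    return MinNormSolution(coeffs=coeffs, d=sol.d, converged=sol.converged)


def min_norm_main(grad_u: np.ndarray, grad_v: np.ndarray,
                  constraint_grads: list[np.ndarray]) -> MinNormSolution:
    """Main-phase solve over (∇U̅, ∇V̅) plus active constraint gradients.

    Returns coefficients ordered (λ1, λ2, β_1..); zero constraint gradients
    are excluded from the solve (they carry no direction).  If every supplied
    gradient is zero, d = 0 is returned with the converged flag (stationary
    point).
    """
    vectors = [np.asarray(grad_u, float), np.asarray(grad_v, float)]
    keep_c = [i for i, g in enumerate(constraint_grads)
              if float(np.linalg.norm(g)) > _ZERO_NORM]
    all_vecs = vectors + [np.asarray(constraint_grads[i], float) for i in keep_c]
    if all(float(np.linalg.norm(v)) <= _ZERO_NORM for v in all_vecs):
        coeffs = np.zeros(2 + len(constraint_grads))
        return MinNormSolution(coeffs=coeffs, d=np.zeros_like(vectors[0]),
                               converged=True)
    sol = min_norm_point(all_vecs)
    coeffs = np.zeros(2 + len(constraint_grads))
    coeffs[0], coeffs[1] = sol.coeffs[0], sol.coeffs[1]
    for j, i in enumerate(keep_c):
        coeffs[2 + i] = sol.coeffs[2 + j]
    return MinNormSolution(coeffs=coeffs, d=sol.d, converged=sol.converged)


def apply_update(params: list[Tensor], d: np.ndarray, optimizer) -> None:
    """Step the parameters using the composite direction d as the gradient."""
    d = np.asarray(d, dtype=np.float64)
    if not np.all(np.isfinite(d)):
        raise FloatingPointError("non-finite update direction")
    assign_flat_grads(params, d)
    optimizer.step()
    optimizer.zero_grad()


def scalarized_loss(u: float, v: float, lam: float) -> float:
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return lam * u + (1.0 - lam) * v


# ---------------------------------------------------------------------------
# configuration and candidate record


@dataclasses.dataclass
class TrainConfig:
    """Hyperparameters for one Pareto-front estimation run.

    Defaults follow the published training recipe (single hidden layer of
    128 units, d_z = 10, Adam with denominator ε = 0.01, minibatch 128,
    pre-training 200 epochs at 1e−3, adversarial pre-training 400 epochs at
    5e−5, main phase 150 epochs at 1e−3 with one adversarial pass per step);
    every field scales down for small problems.
    """

    K: int = 10
    d_z: int = 10
    hidden: int = 128
    measure: Literal["mine", "mmd"] = "mine"
    batch_size: int = 128
    pre_epochs: int = 200
    pre_lr: float = 1e-3
    pre_adv_epochs: int = 400
    pre_adv_lr: float = 5e-5
    epochs: int = 150
    lr: float = 1e-3
    init_epochs: int = 2
    adv_epochs: int = 1
    adv_lr: float = 5e-5
    mine_warmup_epochs: int = 20
    mine_hidden: int = 128
    mine_layers: int = 10
    eval_mine_epochs: int = 80
    eval_mine_lr: float = 1e-3
    eval_shuffles: int = 25
    eps_active: float = 0.01
    adam_eps: float = 0.01
    mmd_bandwidths: tuple[float, ...] = (1.0, 2.0, 5.0, 8.0, 10.0)
    seed: int = 0
    optimizer: Literal["adam", "sgd"] = "adam"

    def mmd_config(self) -> MmdConfig:
        return MmdConfig(bandwidths=self.mmd_bandwidths, d_z=self.d_z)


@dataclasses.dataclass
class ParetoCandidate:
    """One trained encoder/decoder with its evaluated objective pairs."""

    tag: str                       # "k=3", "lambda=0.27", "U_extreme", ...
    vae: ZinbVae
    mine: MineNetwork | None
    raw: dict = dataclasses.field(default_factory=dict)          # split -> (U, V)
    standardized: dict = dataclasses.field(default_factory=dict) # split -> (U̅, V̅)
    trace: list = dataclasses.field(default_factory=list)


# ---------------------------------------------------------------------------
# minibatch plumbing


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for lo in range(0, n, batch_size):
        idx = order[lo : lo + batch_size]
        if idx.size >= 2:
            yield idx


def _make_optimizer(params: list[Tensor], lr: float, cfg: TrainConfig):
    if cfg.optimizer == "sgd":
        return SGD(params, lr=lr)
    return Adam(params, lr=lr, eps=cfg.adam_eps)


def _new_vae(ds: ExpressionDataset, cfg: TrainConfig, seed: int) -> ZinbVae:
    log_lib = float(np.log(np.maximum(ds.counts.sum(axis=1), 1)).mean())
    return ZinbVae(ds.n_genes, ds.n_batches, d_z=cfg.d_z, hidden=cfg.hidden,
                   library_log_mean=log_lib, seed=seed)


def _sample_z_graph(vae: ZinbVae, counts: np.ndarray, seed: int) -> Tensor:
    """Reparameterized posterior z sample as a graph node (grads reach φ)."""
    z_mean, z_var, _, _ = vae._encode_graph(counts)
    rng = np.random.default_rng(seed)
    return z_mean + z_var.sqrt() * Tensor(rng.standard_normal(z_mean.data.shape))


def _mine_adversarial_pass(vae: ZinbVae, net: MineNetwork, opt,
                           counts: np.ndarray, s: np.ndarray,
                           cfg: TrainConfig, rng: np.random.Generator,
                           seed: int) -> None:
    """One full pass of MINE maximization over ψ with the encoder frozen.

    The latent is standardized before entering the statistics network:
    mutual information is invariant under affine maps, and bounded inputs
    keep the adversarial game numerically stable.
    """
    for idx in _minibatches(counts.shape[0], cfg.batch_size, rng):
        post = vae.encode(counts[idx])
        z, _ = vae.sample_latent(post, seed=seed + int(idx[0]))
        sp = shuffle_batch_labels(s[idx], seed=seed + 31 + int(idx[0]))
        loss = -mine_value_graph(net, standardize_latent(z), s[idx], sp)
        opt.zero_grad()
        loss.backward()
        opt.step()


def _v_objective_graph(vae: ZinbVae, net: MineNetwork | None,
                       counts: np.ndarray, s: np.ndarray, cfg: TrainConfig,
                       seed: int) -> Tensor:
    """Differentiable batch-effect objective V_n on a minibatch."""
    z = _sample_z_graph(vae, counts, seed)
    zd = z.data
    mean = zd.mean(axis=0, keepdims=True)
    sd = zd.std(axis=0, ddof=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    z_std = (z - Tensor(mean)) * Tensor(1.0 / sd)  # standardized latent
    if cfg.measure == "mine":
        sp = shuffle_batch_labels(s, seed=seed + 17)
        return mine_value_graph(net, z_std, s, sp)
    return mmd_value_graph(z_std, s, cfg.mmd_config())


def _grad_of(value: Tensor, params: list[Tensor]) -> np.ndarray:
    for p in params:
        p.grad = None
    value.backward()
    g = flatten_grads(params)
    for p in params:
        p.grad = None
    return g


# ---------------------------------------------------------------------------
# bounds recording (single-objective pretraining)


def record_bounds(ds_train: ExpressionDataset, cfg: TrainConfig,
                  prior: LibraryPrior | None = None):
    """Run both single-objective pretraining phases and record the min/max of
    each per-minibatch objective across all epochs.

    Returns ``(bounds, u_model, (v_model, v_mine))``: the U run is a plain
    generative fit (this is also the U-extreme candidate); the V run
    minimizes the batch-effect measure alone over the encoder (with
    adversarial MINE updates when the measure is MINE) and is the encoder of
    the V-extreme.
    """
    if prior is None:
        prior = compute_library_prior(ds_train)
    counts, s = ds_train.counts, ds_train.batch
    n = counts.shape[0]

    # -- U phase: minimize U_n alone -----------------------------------
    u_vae = _new_vae(ds_train, cfg, seed=cfg.seed)
    opt = _make_optimizer(u_vae.parameters(), cfg.pre_lr, cfg)
    rng = np.random.default_rng(cfg.seed + 1000)
    u_vals: list[float] = []
    step = 0
    for _ in range(cfg.pre_epochs):
        for idx in _minibatches(n, cfg.batch_size, rng):
            loss = u_vae.negative_elbo_graph(counts[idx], s[idx], prior,
                                             seed=cfg.seed + step)
            val = loss.item()
            if not np.isfinite(val):
                raise FloatingPointError("non-finite U_n during pretraining")
            u_vals.append(val)
            opt.zero_grad()
            loss.backward()
            opt.step()
            step += 1

    # -- V phase: minimize V_n alone over the encoder ------------------
    # warm-started from the U-pretrained model so the recorded V trace spans
    # the full range from the generative fit's batch dependence down to the
    # collapsed encoder
    v_vae = copy.deepcopy(u_vae)
    v_mine = None
    v_opt = _make_optimizer(v_vae.encoder_parameters(), cfg.pre_lr, cfg)
    if cfg.measure == "mine":
        v_mine = MineNetwork(cfg.d_z, ds_train.n_batches, hidden=cfg.mine_hidden,
                             n_layers=cfg.mine_layers, seed=cfg.seed + 2)
        mine_opt = Adam(v_mine.parameters(), lr=cfg.pre_adv_lr, eps=1e-8)
    rng = np.random.default_rng(cfg.seed + 2000)
    v_vals: list[float] = []
    step = 0
    if cfg.measure == "mine":
        # warm up the statistics network with the encoder frozen so the
        # recorded V trace starts at the dependence present at init
        for epoch in range(cfg.mine_warmup_epochs):
            _mine_adversarial_pass(v_vae, v_mine, mine_opt, counts, s, cfg,
                                   rng, seed=cfg.seed + 4000 + 37 * epoch)
        for idx in _minibatches(n, cfg.batch_size, rng):
            loss = _v_objective_graph(v_vae, v_mine, counts[idx], s[idx], cfg,
                                      seed=cfg.seed + 8500 + int(idx[0]))
            v_vals.append(loss.item())
    for epoch in range(cfg.pre_adv_epochs if cfg.measure == "mine"
                       else cfg.pre_epochs):
        for idx in _minibatches(n, cfg.batch_size, rng):
            if cfg.measure == "mine":
                # re-maximize the statistics network before every encoder
                # step; a stale network makes the lower bound a poor target
                _mine_adversarial_pass(v_vae, v_mine, mine_opt, counts, s,
                                       cfg, rng, seed=cfg.seed + 5000 + 37 * step)
            loss = _v_objective_graph(v_vae, v_mine, counts[idx], s[idx], cfg,
                                      seed=cfg.seed + 9000 + step)
            val = loss.item()
            if not np.isfinite(val):
                raise FloatingPointError("non-finite V_n during pretraining")
            v_vals.append(val)
            v_opt.zero_grad()
            loss.backward()
            # only encoder parameters step; MINE grads from this pass dropped
            if v_mine is not None:
                for p in v_mine.parameters():
                    p.grad = None
            v_opt.step()
            step += 1

    bounds = StandardizationBounds(
        U_min=float(np.min(u_vals)), U_max=float(np.max(u_vals)),
        V_min=float(np.min(v_vals)), V_max=float(np.max(v_vals)),
    )
    return bounds, u_vae, (v_vae, v_mine)


# ---------------------------------------------------------------------------
# candidate training


def train_candidate(ds_train: ExpressionDataset, cfg: TrainConfig,
                    bounds: StandardizationBounds, *,
                    method: Literal["pareto_mtl", "scalarization"],
                    k: int | None = None, lam: float | None = None,
                    prior: LibraryPrior | None = None) -> ParetoCandidate:
    """Train one Pareto candidate (subproblem k, or scalarization weight λ).

    Per outer step: (MINE only) ``adv_epochs`` full passes of statistics-
    network maximization, then one minimization step on the shared minibatch
    using either the Pareto MTL composite direction or the scalarized
    gradient.  Per-candidate base seed is ``cfg.seed + k`` (or the λ index).
    """
    if prior is None:
        prior = compute_library_prior(ds_train)
    if method == "pareto_mtl":
        if k is None:
            raise ValueError("pareto_mtl requires k")
        base_seed = cfg.seed + k
        tag = f"k={k + 1}"
        prefs = preference_vectors(cfg.K)
    else:
        if lam is None:
            raise ValueError("scalarization requires lam")
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        base_seed = cfg.seed + int(round(lam * (cfg.K + 1)))
        tag = f"lambda={lam:.4f}"

    counts, s = ds_train.counts, ds_train.batch
    n = counts.shape[0]
    vae = _new_vae(ds_train, cfg, seed=base_seed)
    params = vae.parameters()
    opt = _make_optimizer(params, cfg.lr, cfg)
    mine_net = None
    if cfg.measure == "mine":
        mine_net = MineNetwork(cfg.d_z, ds_train.n_batches,
                               hidden=cfg.mine_hidden, n_layers=cfg.mine_layers,
                               seed=base_seed + 101)
        mine_opt = Adam(mine_net.parameters(), lr=cfg.adv_lr, eps=1e-8)
    rng = np.random.default_rng(base_seed + 3000)
    if cfg.measure == "mine":
        for epoch in range(cfg.mine_warmup_epochs):
            _mine_adversarial_pass(vae, mine_net, mine_opt, counts, s, cfg,
                                   rng, seed=base_seed + 20000 + 37 * epoch)
    u_range = bounds.U_max - bounds.U_min
    v_range = bounds.V_max - bounds.V_min
    cand = ParetoCandidate(tag=tag, vae=vae, mine=mine_net)
    step = 0
    for epoch in range(cfg.epochs):
        init_phase = method == "pareto_mtl" and epoch < cfg.init_epochs
        for idx in _minibatches(n, cfg.batch_size, rng):
            if cfg.measure == "mine":
                for a in range(cfg.adv_epochs):
                    _mine_adversarial_pass(
                        vae, mine_net, mine_opt, counts, s, cfg, rng,
                        seed=base_seed + 40000 + 97 * step + a)
            u_graph = vae.negative_elbo_graph(counts[idx], s[idx], prior,
                                              seed=base_seed + step)
            v_graph = _v_objective_graph(vae, mine_net, counts[idx], s[idx],
                                         cfg, seed=base_seed + 70000 + step)
            u_raw, v_raw = u_graph.item(), v_graph.item()
            if not (np.isfinite(u_raw) and np.isfinite(v_raw)):
                raise FloatingPointError(
                    f"non-finite objective at step {step}; trace: "
                    f"{cand.trace[-5:]}"
                )
            u_bar = standardize(u_raw, bounds.U_min, bounds.U_max)
            v_bar = standardize(v_raw, bounds.V_min, bounds.V_max)
            grad_u = _grad_of(u_graph, params) / u_range
            grad_v = _grad_of(v_graph, params) / v_range
            if method == "scalarization":
                d = lam * grad_u + (1.0 - lam) * grad_v
            else:
                L = np.array([u_bar, v_bar])
                g = constraint_values(L, k, prefs)
                act = active_set(g, cfg.eps_active)
                c_grads = [
                    (prefs[j] - prefs[k])[0] * grad_u
                    + (prefs[j] - prefs[k])[1] * grad_v
                    for j in act
                ]
                if init_phase:
                    sol = min_norm_init(c_grads)
                else:
                    sol = min_norm_main(grad_u, grad_v, c_grads)
                d = sol.d
            apply_update(params, d, opt)
            cand.trace.append((step, u_raw, v_raw, u_bar, v_bar))
            step += 1
    return cand


def train_extremes(ds_train: ExpressionDataset, cfg: TrainConfig, *,
                   prior: LibraryPrior | None = None,
                   pretrained: tuple | None = None
                   ) -> tuple[ParetoCandidate, ParetoCandidate]:
    """The two extreme candidates: each raw objective minimized alone.

    The U-extreme is a plain generative fit.  The V-extreme minimizes V_n
    over the encoder (adversarially for MINE); its decoder is then fitted by
    minimizing U_n over θ with the encoder frozen.  No standardization is
    involved.  ``pretrained`` may supply the single-objective models from
    :func:`record_bounds` to avoid repeating those runs.
    """
    if prior is None:
        prior = compute_library_prior(ds_train)
    if pretrained is not None:
        u_vae, (v_vae, v_mine) = pretrained
    else:
        _, u_vae, (v_vae, v_mine) = record_bounds(ds_train, cfg, prior=prior)

    # fit the V-extreme decoder with the encoder frozen
    counts, s = ds_train.counts, ds_train.batch
    opt = _make_optimizer(v_vae.decoder_parameters(), cfg.pre_lr, cfg)
    rng = np.random.default_rng(cfg.seed + 6000)
    step = 0
    for _ in range(cfg.pre_epochs):
        for idx in _minibatches(counts.shape[0], cfg.batch_size, rng):
            loss = v_vae.negative_elbo_graph(counts[idx], s[idx], prior,
                                             seed=cfg.seed + 80000 + step)
            opt.zero_grad()
            loss.backward()
            for p in v_vae.encoder_parameters():
                p.grad = None
            opt.step()
            step += 1
    u_cand = ParetoCandidate(tag="U_extreme", vae=u_vae, mine=None,
                             trace=[("pretrain", None, None, None, None)])
    v_cand = ParetoCandidate(tag="V_extreme", vae=v_vae, mine=v_mine,
                             trace=[("pretrain", None, None, None, None)])
    return u_cand, v_cand


# ---------------------------------------------------------------------------
# evaluation


def evaluate_candidate(cand: ParetoCandidate, ds: ExpressionDataset,
                       cfg: TrainConfig, bounds: StandardizationBounds,
                       prior: LibraryPrior, *, split: str = "train",
                       seed: int = 0) -> tuple[float, float, float, float]:
    """Evaluate (U_n, V_n, U̅_n, V̅_n) for one candidate on one data split.

    U_n is the full-split mean negative ELBO.  With MMD the batch measure is
    computed directly on the standardized posterior latent sample; with MINE
    a de-novo statistics network is trained to its optimum with the encoder
    frozen, and the bound evaluated with a fresh shuffle.  Candidate weights
    are never mutated.
    """
    if bounds is None:
        raise ValueError("standardization bounds missing")
    counts, s = ds.counts, ds.batch
    n = counts.shape[0]
    vae = cand.vae
    u_terms = []
    for lo in range(0, n, 512):
        idx = np.arange(lo, min(lo + 512, n))
        u_terms.append(
            vae.negative_elbo(counts[idx], s[idx], prior, seed=seed + lo)
            * idx.size
        )
    u_raw = float(np.sum(u_terms) / n)

    post = vae.encode(counts)
    z, _ = vae.sample_latent(post, seed=seed + 999)
    z = standardize_latent(z)
    if cfg.measure == "mmd":
        v_raw = mmd_value(z, s, cfg.mmd_config())
    else:
        net, trace = mine_fit(
            z, s, epochs=cfg.eval_mine_epochs, lr=cfg.eval_mine_lr,
            batch_size=cfg.batch_size, hidden=cfg.mine_hidden,
            n_layers=cfg.mine_layers, seed=seed + 555,
        )
        vals = []
        for r in range(cfg.eval_shuffles):
            sp = shuffle_batch_labels(s, seed=seed + 777 + r)
            vals.append(mine_value(net, z, s, sp))
        v_raw = float(np.mean(vals))
    u_bar = standardize(u_raw, bounds.U_min, bounds.U_max)
    v_bar = standardize(v_raw, bounds.V_min, bounds.V_max)
    cand.raw[split] = (u_raw, v_raw)
    cand.standardized[split] = (u_bar, v_bar)
    return u_raw, v_raw, u_bar, v_bar


# ---------------------------------------------------------------------------
# analytic toy problems (no neural networks) — the same stepping logic on a
# plain parameter vector, used to validate sector convergence


def pareto_mtl_minimize(fun: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
                        omega0: np.ndarray, k: int, K: int, *,
                        steps: int = 200, lr: float = 0.05,
                        init_steps: int = 20, eps_active: float = 0.01
                        ) -> np.ndarray:
    """Pareto MTL on an analytic bi-objective.

    ``fun(ω)`` returns ``(L, J)`` with L the objective pair and J the 2×d
    Jacobian.  Plain gradient steps (no optimizer state) make the dynamics
    exactly the published update rule.
    """
    prefs = preference_vectors(K)
    omega = np.asarray(omega0, dtype=np.float64).copy()
    for t in range(steps):
        L, J = fun(omega)
        g = constraint_values(L, k, prefs)
        act = active_set(g, eps_active)
        c_grads = [(prefs[j] - prefs[k]) @ J for j in act]
        if t < init_steps:
            sol = min_norm_init(c_grads)
            if float(np.linalg.norm(sol.d)) <= _ZERO_NORM:
                sol = min_norm_main(J[0], J[1], c_grads)
        else:
            sol = min_norm_main(J[0], J[1], c_grads)
        omega = omega - lr * sol.d
    return omega


def scalarization_minimize(fun: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
                           omega0: np.ndarray, lam: float, *,
                           steps: int = 500, lr: float = 0.05) -> np.ndarray:
    """Gradient descent on λL₁ + (1−λ)L₂ for an analytic bi-objective."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    omega = np.asarray(omega0, dtype=np.float64).copy()
    for _ in range(steps):
        _, J = fun(omega)
        omega = omega - lr * (lam * J[0] + (1.0 - lam) * J[1])
    return omega
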