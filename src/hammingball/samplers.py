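"""Generic Hamming ball MCMC kernels over discrete latent states.

The latent object is a flat integer vector ``x`` (a matrix is handled by
flattening or by treating its columns as blocks) partitioned into P
disjoint blocks.  An auxiliary state ``u`` of the same shape is drawn
uniformly (or center-weighted) from the per-block Hamming balls around
``x``; the next ``x`` is then drawn from the model posterior restricted
to the balls around ``u``.  Because the ball volume does not depend on
the center, the construction is a valid Gibbs scheme on the augmented
target p(y, x, theta) p(u | x), and marginally the chain targets
p(x, theta | y).

Kernels provided:

- ``block_hb_sweep``       sequential per-block update (random blocks),
- ``block_gibbs_sweep``    the m = K special case (standard block Gibbs),
- ``hb_gibbs_iteration``   U -> theta -> X Gibbs cycle,
- ``hb_marginal_mh_iteration``  joint (theta, X) Metropolis-Hastings with
  the restricted marginal computed by ball sums,
- ``msss_iteration``       Metropolized Shotgun Stochastic Search
  comparator (pure M-H from the sliced posterior),
- ``random_radius_iteration``   per-block random radii drawn from p(m).

All weight arithmetic is in log space; categorical draws use inverse-CDF
on max-stabilized normalized weights.  A state with log weight -inf is a
legal candidate with probability zero; if every candidate in a slice is
-inf the kernel raises ``ImpossibleSliceError``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

from .ball import BallSpec, enumerate_ball, sample_ball

__all__ = [
    "DiscreteModel",
    "ChainTrace",
    "SamplerConfig",
    "ImpossibleSliceError",
    "random_partition",
    "update_auxiliary",
    "restricted_block_weights",
    "block_hb_sweep",
    "block_gibbs_sweep",
    "hb_gibbs_iteration",
    "hb_marginal_mh_iteration",
    "msss_iteration",
    "random_radius_iteration",
    "run_chain",
]

KERNELS = (
    "hb_gibbs",
    "hb_marginal_mh",
    "block_hb",
    "block_gibbs",
    "msss",
    "random_radius",
)


class ImpossibleSliceError(RuntimeError):
    """Every candidate in a Hamming ball slice has zero probability."""


class DiscreteModel:
    """Plug-in contract a model exposes to the generic kernels.

    Subclasses must implement ``log_joint``; models used with the block
    kernels should override ``block_log_weights`` with a vectorized
    version.  ``factorized = True`` declares that the joint factorizes
    over the blocks of the partition in use, which the marginal M-H,
    plain HB-Gibbs and M-SSS kernels require when P > 1.
    """

    S: int = 2
    factorized: bool = False

    def __init__(self) -> None:
        self.n_weight_evals = 0

    def log_joint(self, x: np.ndarray, theta) -> float:
        raise NotImplementedError

    def block_log_weights(
        self, x: np.ndarray, block: np.ndarray, candidates: np.ndarray, theta
    ) -> np.ndarray:
        """log p(y, x with block:=candidate, theta) for each candidate row.

        Default: loops over candidates calling ``log_joint``.  An
        additive constant per block is irrelevant.
        """
        out = np.empty(len(candidates))
        xc = x.copy()
        for t, cand in enumerate(candidates):
            xc[block] = cand
            out[t] = self.log_joint(xc, theta)
        return out

    # Optional hooks -------------------------------------------------
    def sample_theta(self, x: np.ndarray, theta, rng: np.random.Generator):
        raise NotImplementedError(
            f"{type(self).__name__} does not provide sample_theta; "
            "the hb_gibbs kernel requires it"
        )

    def propose_theta(self, theta, rng: np.random.Generator):
        raise NotImplementedError(
            f"{type(self).__name__} does not provide propose_theta; "
            "the hb_marginal_mh kernel requires it"
        )

    def log_proposal_density(self, theta_to, theta_from) -> float:
        raise NotImplementedError


@dataclass
class SamplerConfig:
    """Settings for ``run_chain``; validated before any sampling."""

    kernel: str
    iterations: int
    m: int = 1
    K: int | None = None
    lam: float = 0.0
    burn_in: int = 0
    seed: int = 0
    thin: int = 1
    partition: Sequence[np.ndarray] | None = None  # fixed partition; else random chunks of K
    rdist: Callable[[np.random.Generator], np.ndarray] | None = None

    def validate(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; choose from {KERNELS}")
        if self.iterations < 1 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("iterations >= 1, burn_in >= 0, thin >= 1 required")
        if self.kernel == "random_radius" and self.rdist is None:
            raise ValueError("random_radius kernel requires a radius distribution rdist")
        if self.kernel != "random_radius" and self.m < 0:
            raise ValueError("radius m must be >= 0")


@dataclass
class ChainTrace:
    """Ordered record of sampled states/parameters with provenance."""

    states: np.ndarray
    thetas: list
    accepts: np.ndarray
    config: SamplerConfig
    seed: int
    n_weight_evals: int = 0
    extras: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.states)


def random_partition(D: int, K: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Uniform random permutation chopped into chunks of size K.

    The final block may be shorter when K does not divide D.
    """
    perm = rng.permutation(D)
    return [perm[i : i + K] for i in range(0, D, K)]


def fixed_partition(D: int, K: int) -> list[np.ndarray]:
    """Contiguous chunks of size K in index order (no shuffling)."""
    idx = np.arange(D)
    return [idx[i : i + K] for i in range(0, D, K)]


def _block_spec(m: int, block_len: int, S: int, lam: float) -> BallSpec:
    return BallSpec(min(m, block_len), block_len, S, lam)


def update_auxiliary(
    x: np.ndarray,
    partition: Sequence[np.ndarray],
    m: int | np.ndarray,
    S: int,
    rng: np.random.Generator,
    lam: float = 0.0,
) -> np.ndarray:
    """Draw u ~ p(U | X): independent per-block ball draws around x.

    ``m`` may be a scalar or a per-block vector of radii.
    """
    u = x.copy()
    m_vec = np.broadcast_to(np.asarray(m), (len(partition),))
    for i, block in enumerate(partition):
        mi = int(m_vec[i])
        if mi == 0:
            continue
        u[block] = sample_ball(x[block], _block_spec(mi, len(block), S, lam), rng)
    return u


def _eval_weights(model, x, block, candidates, theta) -> np.ndarray:
    model.n_weight_evals += len(candidates)
    return np.asarray(model.block_log_weights(x, block, candidates, theta), dtype=float)


def _normalize_log(logw: np.ndarray) -> np.ndarray:
    mx = logw.max()
    if not np.isfinite(mx):
        raise ImpossibleSliceError(
            "all candidates in the Hamming ball slice have log weight -inf"
        )
    w = np.exp(logw - mx)
    return w / w.sum()


def restricted_block_weights(
    model: DiscreteModel,
    x: np.ndarray,
    block: np.ndarray,
    u_block: np.ndarray,
    m: int,
    theta,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized weights over the ball around u_block for one block.

    Returns ``(candidates, probs)`` with probs summing to one; computed
    in log space with max-subtraction before exponentiation.
    """
    candidates = enumerate_ball(u_block, m, model.S)
    logw = _eval_weights(model, x, block, candidates, theta)
    return candidates, _normalize_log(logw)


def _categorical(probs: np.ndarray, rng: np.random.Generator) -> int:
    c = np.cumsum(probs)
    c[-1] = 1.0  # guard roundoff
    return int(np.searchsorted(c, rng.random(), side="right"))


def block_hb_sweep(
    model: DiscreteModel,
    x: np.ndarray,
    theta,
    K: int,
    m: int,
    rng: np.random.Generator,
    partition: Sequence[np.ndarray] | None = None,
    lam: float = 0.0,
) -> np.ndarray:
    """One sweep of the block Hamming ball sampler (Gibbs within slices).

    Entries are re-partitioned into random blocks of size K (unless a
    fixed partition is supplied); each block i is updated by
    u_i ~ uniform on the ball around x_i, then x_i ~ restricted
    conditional on the ball around u_i.
    """
    x = x.copy()
    if partition is None:
        partition = random_partition(x.shape[0], K, rng)
    for block in partition:
        mi = min(m, len(block))
        u_b = sample_ball(x[block], _block_spec(mi, len(block), model.S, lam), rng)
        cands, probs = restricted_block_weights(model, x, block, u_b, mi, theta)
        x[block] = cands[_categorical(probs, rng)]
    return x


def block_gibbs_sweep(
    model: DiscreteModel,
    x: np.ndarray,
    theta,
    K: int,
    rng: np.random.Generator,
    partition: Sequence[np.ndarray] | None = None,
) -> np.ndarray:
    """Standard block Gibbs: the m = K special case of the HB sweep."""
    return block_hb_sweep(model, x, theta, K=K, m=K, rng=rng, partition=partition)


def _require_tractable(model: DiscreteModel, partition, kernel: str) -> None:
    if len(partition) > 1 and not model.factorized:
        raise ValueError(
            f"{kernel} with P > 1 blocks requires a per-block factorized model "
            "(set factorized = True and make block_log_weights independent of "
            "the other blocks)"
        )


def hb_gibbs_iteration(
    model: DiscreteModel,
    x: np.ndarray,
    theta,
    m: int,
    rng: np.random.Generator,
    partition: Sequence[np.ndarray] | None = None,
    lam: float = 0.0,
) -> tuple[np.ndarray, object, np.ndarray]:
    """One U -> theta -> X cycle of the plain Hamming ball sampler.

    Requires ``model.sample_theta`` and a tractable restricted
    conditional p(X | theta, U, y): either a single block or a model
    that factorizes over the partition.  The new X lies inside the ball
    around U, hence differs from the previous X in at most 2 m P entries.
    """
    if partition is None:
        partition = [np.arange(x.shape[0])]
    _require_tractable(model, partition, "hb_gibbs")
    u = update_auxiliary(x, partition, m, model.S, rng, lam)
    theta = model.sample_theta(x, theta, rng)
    x_new = x.copy()
    for block in partition:
        mi = min(m, len(block))
        cands, probs = restricted_block_weights(model, x_new, block, u[block], mi, theta)
        x_new[block] = cands[_categorical(probs, rng)]
    return x_new, theta, u


def _restricted_log_marginal(model, x, partition, u, m, theta) -> float:
    """log p~(theta, U, y) = sum_i log sum_{x_i in ball(u_i)} w_i(x_i)."""
    total = 0.0
    for block in partition:
        mi = min(m, len(block))
        cands = enumerate_ball(u[block], mi, model.S)
        logw = _eval_weights(model, x, block, cands, theta)
        total += logsumexp(logw)
    return float(total)


def hb_marginal_mh_iteration(
    model: DiscreteModel,
    x: np.ndarray,
    theta,
    m: int,
    rng: np.random.Generator,
    partition: Sequence[np.ndarray] | None = None,
    lam: float = 0.0,
) -> tuple[np.ndarray, object, bool]:
    """Joint (theta, X) update via the restricted marginal M-H step.

    Proposes theta' ~ q(.|theta), accepts with probability
    min{1, p~(theta', U, y) q(theta|theta') / (p~(theta, U, y)
    q(theta'|theta))} where p~ sums model weights over the per-block
    balls around U; on acceptance X is redrawn blockwise from the
    restricted conditionals under theta'.
    """
    if partition is None:
        partition = [np.arange(x.shape[0])]
    _require_tractable(model, partition, "hb_marginal_mh")
    u = update_auxiliary(x, partition, m, model.S, rng, lam)
    theta_p = model.propose_theta(theta, rng)
    log_marg_cur = _restricted_log_marginal(model, x, partition, u, m, theta)
    log_marg_prop = _restricted_log_marginal(model, x, partition, u, m, theta_p)
    if not np.isfinite(log_marg_cur) and not np.isfinite(log_marg_prop):
        raise ImpossibleSliceError("restricted marginal is -inf under both states")
    log_alpha = (
        log_marg_prop
        - log_marg_cur
        + model.log_proposal_density(theta, theta_p)
        - model.log_proposal_density(theta_p, theta)
    )
    if np.log(rng.random()) < log_alpha:
        x_new = x.copy()
        for block in partition:
            mi = min(m, len(block))
            cands, probs = restricted_block_weights(model, x_new, block, u[block], mi, theta_p)
            x_new[block] = cands[_categorical(probs, rng)]
        return x_new, theta_p, True
    return x, theta, False


def msss_iteration(
    model: DiscreteModel,
    x: np.ndarray,
    theta,
    m: int,
    rng: np.random.Generator,
    partition: Sequence[np.ndarray] | None = None,
) -> tuple[np.ndarray, bool]:
    """Metropolized Shotgun Stochastic Search comparator.

    Proposes X' from the model sliced to the ball around X,
    Q(X'|X) = p(y, X', theta) I(X' in H_m(X)) / Z_m(X), and accepts with
    probability min{1, Z_m(X) / Z_m(X')}.  The accepted X' differs from
    X in at most m P entries — half the HB sampler's reach per
    iteration at the same cost.
    """
    if partition is None:
        partition = [np.arange(x.shape[0])]
    _require_tractable(model, partition, "msss")
    x_prop = x.copy()
    log_z_cur = 0.0
    log_z_prop = 0.0
    for block in partition:
        mi = min(m, len(block))
        cands = enumerate_ball(x[block], mi, model.S)
        logw = _eval_weights(model, x, block, cands, theta)
        log_z_cur += logsumexp(logw)
        x_prop[block] = cands[_categorical(_normalize_log(logw), rng)]
    for block in partition:
        mi = min(m, len(block))
        cands = enumerate_ball(x_prop[block], mi, model.S)
        logw = _eval_weights(model, x_prop, block, cands, theta)
        log_z_prop += logsumexp(logw)
    if np.log(rng.random()) < log_z_cur - log_z_prop:
        return x_prop, True
    return x, False


def random_radius_iteration(
    model: DiscreteModel,
    x: np.ndarray,
    theta,
    rdist: Callable[[np.random.Generator], np.ndarray],
    rng: np.random.Generator,
    partition: Sequence[np.ndarray] | None = None,
    lam: float = 0.0,
) -> tuple[np.ndarray, object]:
    """One sweep with per-block radii m = (m_1..m_P) drawn from p(m).

    With the degenerate p(m) that picks one block i and sets
    m_i = len(block_i), all others zero, this reduces to single-block
    Gibbs sampling.  Blocks with m_i = 0 are left untouched.
    """
    if partition is None:
        partition = [np.arange(x.shape[0])]
    x = x.copy()
    m_vec = np.asarray(rdist(rng), dtype=int)
    if m_vec.shape != (len(partition),):
        raise ValueError(
            f"rdist returned shape {m_vec.shape}, expected ({len(partition)},)"
        )
    for mi, block in zip(m_vec, partition):
        mi = int(min(mi, len(block)))
        if mi < 0:
            raise ValueError("per-block radius must be >= 0")
        if mi == 0:
            continue
        u_b = sample_ball(x[block], _block_spec(mi, len(block), model.S, lam), rng)
        cands, probs = restricted_block_weights(model, x, block, u_b, mi, theta)
        x[block] = cands[_categorical(probs, rng)]
    return x, theta


def run_chain(
    model: DiscreteModel,
    x0: np.ndarray,
    theta0,
    config: SamplerConfig,
) -> ChainTrace:
    """Run burn-in plus sampling with one kernel; deterministic in seed.

    Records the post-burn-in states (thinned by ``config.thin``), the
    parameter values alongside, and acceptance indicators for M-H
    kernels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    x = np.asarray(x0).copy()
    theta = theta0
    D = x.shape[0]
    K = config.K if config.K is not None else D
    states, thetas, accepts = [], [], []

    total = config.burn_in + config.iterations
    for it in range(total):
        accepted = np.nan
        if config.kernel == "block_hb":
            x = block_hb_sweep(model, x, theta, K, config.m, rng, config.partition, config.lam)
        elif config.kernel == "block_gibbs":
            x = block_gibbs_sweep(model, x, theta, K, rng, config.partition)
        elif config.kernel == "hb_gibbs":
            x, theta, _ = hb_gibbs_iteration(
                model, x, theta, config.m, rng, config.partition, config.lam
            )
        elif config.kernel == "hb_marginal_mh":
            x, theta, acc = hb_marginal_mh_iteration(
                model, x, theta, config.m, rng, config.partition, config.lam
            )
            accepted = float(acc)
        elif config.kernel == "msss":
            x, acc = msss_iteration(model, x, theta, config.m, rng, config.partition)
            accepted = float(acc)
        elif config.kernel == "random_radius":
            x, theta = random_radius_iteration(
                model, x, theta, config.rdist, rng, config.partition, config.lam
            )
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            states.append(x.copy())
            thetas.append(theta)
            accepts.append(accepted)

    return ChainTrace(
        states=np.array(states),
        thetas=thetas,
        accepts=np.array(accepts, dtype=float),
        config=config,
        seed=config.seed,
        n_weight_evals=model.n_weight_evals,
    )
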