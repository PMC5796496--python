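"""Tumor subclonal deconvolution by a binomial read-count mixture.

A tumor sample is a mixture of K cell subpopulations with weights theta
(a point on the K-simplex) and binary genotypes in a K x N matrix X
(rows = subclones, columns = variants).  A heterozygous variant carried
by a fraction p_i = (1/2) sum_k theta_k X_ki of cells is observed at
variant allele frequency phi_i = (1-e) p_i + e (1-p_i), where e is the
sequencing error rate, and the variant read count is
r_i ~ Binomial(d_i, phi_i).

Priors: theta is Dirichlet(alpha/K, ..., alpha/K) represented through
independent gamma variables gamma_k (worked with on the log scale,
v_k = log gamma_k), which for alpha <= 1 shrinks unused components to
zero and so selects the number of subclones automatically; the
genotype entries are Bernoulli(f_i) with per-variant frequencies f_i
given a Beta(f_alpha, f_beta) prior.

Inference is the marginal Hamming ball Metropolis-Hastings scheme: the
columns of X are the blocks; the auxiliary matrix U is resampled
column-wise from uniform Hamming balls around X; a proposal v' (an
epsilon-mixture of a random walk and an independent prior draw) is
accepted using the marginal

    p~(v, U, y) = [prod_i sum_{x_i in H_m(u_i)} p(y_i|x_i, theta(v))
                   p(x_i|f_i)] prod_k g(v_k | alpha/K, 1),

whose per-column ball sums have only M = sum_j C(K, j) terms instead of
2^K; on acceptance all columns of X are redrawn from the restricted
conditionals.  A multi-sample extension shares X across samples, each
with its own weights theta_s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp, xlogy

from .ball import BallSpec, _flip_patterns, sample_ball_many


@dataclass
class DeconvHyper:
    """Model and sampler hyperparameters for the deconvolution model."""

    K: int = 8
    alpha: float = 1.0
    f_a: float = 0.5
    f_b: float = 0.5
    e: float = 0.01
    m: int = 4
    eps: float = 0.01  # prior-proposal mixture weight

    def __post_init__(self) -> None:
        if not (0 <= self.e < 0.5):
            raise ValueError("error rate e must be in [0, 0.5)")
        if not (0 <= self.m <= self.K):
            raise ValueError("ball radius m must be in [0, K]")
        if not (0 < self.eps < 1):
            raise ValueError("mixture weight eps must be in (0, 1)")
        if min(self.alpha, self.f_a, self.f_b) <= 0 or self.K < 1:
            raise ValueError("alpha, f_a, f_b must be positive and K >= 1")


def vaf(theta: np.ndarray, X: np.ndarray, e: float) -> np.ndarray:
    """Variant allele frequencies phi from weights and genotypes.

    phi_i = (1-e) p_i + e (1-p_i) with p_i = (1/2) sum_k theta_k X_ki.
    """
    theta = np.asarray(theta, dtype=float)
    X = np.asarray(X)
    p = 0.5 * theta @ X
    return (1.0 - e) * p + e * (1.0 - p)


def log_lik(r: np.ndarray, d: np.ndarray, phi: np.ndarray) -> float:
    """Sum of binomial log-densities, -inf for impossible phi in {0,1}."""
    r = np.asarray(r)
    d = np.asarray(d)
    phi = np.asarray(phi, dtype=float)
    lchoose = gammaln(d + 1) - gammaln(r + 1) - gammaln(d - r + 1)
    return float(np.sum(lchoose + xlogy(r, phi) + xlogy(d - r, 1.0 - phi)))


def log_prior_v(v: np.ndarray, alpha: float, K: int) -> float:
    """Density of v = log(gamma) with gamma ~ Gamma(alpha/K, 1) i.i.d."""
    a = alpha / K
    v = np.asarray(v, dtype=float)
    return float(np.sum(a * v - np.exp(v) - gammaln(a)))


def _log_lgamma_pdf(v: np.ndarray, a: float) -> np.ndarray:
    return a * v - np.exp(v) - gammaln(a)


def theta_from_v(v: np.ndarray) -> np.ndarray:
    """Simplex weights theta_k = gamma_k / sum_j gamma_j from v = log gamma."""
    g = np.exp(v - np.max(v, axis=-1, keepdims=True))
    return g / g.sum(axis=-1, keepdims=True)


def _ball_masks(K: int, m: int) -> np.ndarray:
    """(M, K) boolean flip masks enumerating a binary Hamming ball."""
    return _flip_patterns(K, m, 2)[0]


def _column_logweights(
    v: np.ndarray, U: np.ndarray, r: np.ndarray, d: np.ndarray, f: np.ndarray, hyper: DeconvHyper
) -> np.ndarray:
    """(N, M) log weights of every ball candidate for every column.

    v is (S, K) (S samples sharing X), r and d are (N, S); the
    likelihood term of a candidate column is the product over samples.
    """
    masks = _ball_masks(hyper.K, hyper.m)  # (M, K)
    cands = U.T[:, None, :] ^ masks[None, :, :]  # (N, M, K)
    thetas = theta_from_v(v)  # (S, K)
    p = 0.5 * np.einsum("nmk,sk->nms", cands, thetas)
    phi = (1.0 - hyper.e) * p + hyper.e * (1.0 - p)
    ll = xlogy(r[:, None, :], phi) + xlogy((d - r)[:, None, :], 1.0 - phi)
    s = cands.sum(axis=2)  # mutations per candidate column
    fc = np.clip(f, 1e-12, 1.0 - 1e-12)  # guard 0 * log(0) at extreme Beta draws
    log_px = s * np.log(fc)[:, None] + (hyper.K - s) * np.log1p(-fc)[:, None]
    return ll.sum(axis=2) + log_px


def restricted_log_marginal(
    v: np.ndarray, U: np.ndarray, r: np.ndarray, d: np.ndarray, f: np.ndarray, hyper: DeconvHyper
) -> float:
    """log p~(v, U, y): per-column ball sums plus the log-gamma prior.

    With m = K the ball is the whole column space and this is the fully
    marginalized log p(v, y | f); with m = 0 it collapses to the single
    term at X = U.  Binomial coefficients are omitted (constant in v, X).
    """
    v2 = np.atleast_2d(v)
    logw = _column_logweights(v2, U, r, d, f, hyper)
    return float(logsumexp(logw, axis=1).sum() + log_prior_v(v2, hyper.alpha, hyper.K))


def draw_X_columns(
    v: np.ndarray,
    U: np.ndarray,
    r: np.ndarray,
    d: np.ndarray,
    f: np.ndarray,
    hyper: DeconvHyper,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample every column of X from its restricted ball conditional."""
    v2 = np.atleast_2d(v)
    logw = _column_logweights(v2, U, r, d, f, hyper)  # (N, M)
    gumbel = rng.gumbel(size=logw.shape)
    picks = np.argmax(logw + gumbel, axis=1)  # Gumbel-max categorical draw
    masks = _ball_masks(hyper.K, hyper.m)
    return (U.T ^ masks[picks]).T


def update_U(X: np.ndarray, hyper: DeconvHyper, rng: np.random.Generator) -> np.ndarray:
    """Resample U column-wise, uniform on the ball around each column of X."""
    spec = BallSpec(hyper.m, hyper.K)
    return sample_ball_many(X.T, spec, rng).T


def gibbs_f_update(X: np.ndarray, hyper: DeconvHyper, rng: np.random.Generator) -> np.ndarray:
    """Conjugate Beta draw of the per-variant mutation frequencies."""
    counts = X.sum(axis=0)
    return rng.beta(hyper.f_a + counts, hyper.f_b + hyper.K - counts)


def _propose_v(
    v: np.ndarray, sigma_v2: float, hyper: DeconvHyper, rng: np.random.Generator
) -> np.ndarray:
    from_prior = rng.random(v.shape) < hyper.eps
    walk = rng.normal(v, np.sqrt(sigma_v2))
    prior = np.log(rng.gamma(hyper.alpha / hyper.K, 1.0, size=v.shape))
    return np.where(from_prior, prior, walk)


def _log_q_v(v_to: np.ndarray, v_from: np.ndarray, sigma_v2: float, hyper: DeconvHyper) -> float:
    """Mixture proposal density with the component indicator marginalized."""
    log_norm = -0.5 * np.log(2 * np.pi * sigma_v2) - 0.5 * (v_to - v_from) ** 2 / sigma_v2
    log_prior = _log_lgamma_pdf(v_to, hyper.alpha / hyper.K)
    return float(
        np.sum(np.logaddexp(np.log1p(-hyper.eps) + log_norm, np.log(hyper.eps) + log_prior))
    )


def multi_sample_update(
    v: np.ndarray,
    X: np.ndarray,
    U: np.ndarray,
    r: np.ndarray,
    d: np.ndarray,
    f: np.ndarray,
    hyper: DeconvHyper,
    sigma_v2: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Joint M-H update of all per-sample weights and the shared X.

    v is (S, K); r, d are (N, S).  Proposes v' componentwise from the
    eps-mixture, accepts via the ratio of restricted marginals (whose
    per-column likelihood multiplies over samples) with the Hastings
    correction, and on acceptance redraws every column of X under the
    proposed weights.  S = 1 is exactly the single-sample update.
    """
    v = np.atleast_2d(v)
    v_prop = _propose_v(v, sigma_v2, hyper, rng)
    lm_cur = restricted_log_marginal(v, U, r, d, f, hyper)
    lm_prop = restricted_log_marginal(v_prop, U, r, d, f, hyper)
    log_alpha = (
        lm_prop
        - lm_cur
        + _log_q_v(v, v_prop, sigma_v2, hyper)
        - _log_q_v(v_prop, v, sigma_v2, hyper)
    )
    if np.log(rng.random()) < log_alpha:
        X_new = draw_X_columns(v_prop, U, r, d, f, hyper, rng)
        return v_prop, X_new, True
    return v, X, False


def mh_theta_X_update(
    v: np.ndarray,
    X: np.ndarray,
    U: np.ndarray,
    r: np.ndarray,
    d: np.ndarray,
    f: np.ndarray,
    hyper: DeconvHyper,
    sigma_v2: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Single-sample joint (v, X) M-H step (S = 1 case of the above)."""
    v2 = np.atleast_2d(np.asarray(v, dtype=float))
    r2 = np.asarray(r).reshape(-1, 1)
    d2 = np.asarray(d).reshape(-1, 1)
    v_new, X_new, acc = multi_sample_update(v2, X, U, r2, d2, f, hyper, sigma_v2, rng)
    return v_new[0] if np.asarray(v).ndim == 1 else v_new, X_new, acc


def tune_proposal(
    sigma_v2: float,
    acceptance_rate: float,
    low: float = 0.10,
    high: float = 0.40,
    factor: float = 2.0,
    bounds: tuple[float, float] = (0.01, 10.0),
) -> float:
    """Multiplicative adjustment of the random-walk variance toward the band.

    Acceptance below ``low`` shrinks the variance, above ``high`` grows
    it; the result is hard-clipped to ``bounds``.  Call only during the
    tuning phase — the variance must be frozen afterwards to preserve
    the stationary distribution.
    """
    if acceptance_rate < low:
        sigma_v2 /= factor
    elif acceptance_rate > high:
        sigma_v2 *= factor
    return float(np.clip(sigma_v2, *bounds))


@dataclass
class DeconvTrace:
    """Post-burn-in record of the deconvolution chain."""

    thetas: np.ndarray  # (T, S, K)
    max_theta: np.ndarray  # (T, S)
    phi_mean: np.ndarray  # (N, S) posterior mean VAF
    acceptance_rate: float
    sigma_v2: float
    seed: int
    settings: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.thetas)


def run_deconv(
    r: np.ndarray,
    d: np.ndarray,
    hyper: DeconvHyper | None = None,
    iterations: int = 100_000,
    burn_in: int = 10_000,
    seed: int = 0,
    tuning_iters: int = 1000,
    tune_interval: int = 100,
    sigma_v2: float = 1.0,
    thin: int = 1,
) -> DeconvTrace:
    """Run the marginal Hamming ball sampler on read counts.

    ``r`` and ``d`` may be 1-D (single sample) or (N, S) for S samples
    sharing a genotype matrix.  One iteration is: column-wise U update,
    joint (v, X) M-H step, conjugate f update.  The proposal variance is
    tuned every ``tune_interval`` iterations during the first
    ``tuning_iters`` iterations of burn-in, then frozen.  Defaults match
    the long benchmark runs; desk-scale analyses typically use a few
    thousand burn-in and tens of thousands of samples.
    """
    hyper = hyper or DeconvHyper()
    r2 = np.asarray(r)
    d2 = np.asarray(d)
    if r2.ndim == 1:
        r2 = r2.reshape(-1, 1)
        d2 = d2.reshape(-1, 1)
    if r2.shape != d2.shape:
        raise ValueError("r and d shapes differ")
    if np.any(r2 < 0) or np.any(r2 > d2) or np.any(d2 <= 0):
        raise ValueError("need 0 <= r <= d and d > 0")
    if tuning_iters > burn_in:
        raise ValueError("tuning phase must fit inside burn-in")
    N, S = r2.shape
    K = hyper.K
    rng = np.random.default_rng(seed)

    v = np.log(rng.gamma(hyper.alpha / K, 1.0, size=(S, K)))
    X = rng.integers(0, 2, size=(K, N))
    f = rng.beta(hyper.f_a, hyper.f_b, size=N)

    thetas, max_theta = [], []
    phi_sum = np.zeros((N, S))
    n_acc_main = 0
    n_main = 0
    window_acc: list[bool] = []

    total = burn_in + iterations
    for it in range(total):
        U = update_U(X, hyper, rng)
        v, X, acc = multi_sample_update(v, X, U, r2, d2, f, hyper, sigma_v2, rng)
        f = gibbs_f_update(X, hyper, rng)

        if it < tuning_iters:
            window_acc.append(acc)
            if (it + 1) % tune_interval == 0:
                sigma_v2 = tune_proposal(sigma_v2, float(np.mean(window_acc)))
                window_acc = []
        if it >= burn_in:
            n_main += 1
            n_acc_main += int(acc)
            theta = theta_from_v(v)
            phi_sum += np.stack([vaf(theta[s], X, hyper.e) for s in range(S)], axis=1)
            if (it - burn_in) % thin == 0:
                thetas.append(theta.copy())
                max_theta.append(theta.max(axis=1))

    return DeconvTrace(
        thetas=np.array(thetas),
        max_theta=np.array(max_theta),
        phi_mean=phi_sum / max(n_main, 1),
        acceptance_rate=n_acc_main / max(n_main, 1),
        sigma_v2=sigma_v2,
        seed=seed,
        settings={
            "K": K,
            "m": hyper.m,
            "iterations": iterations,
            "burn_in": burn_in,
            "tuning_iters": tuning_iters,
        },
    )
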