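"""Sparse Bayesian linear regression with a Zellner g-prior.

The inclusion vector X in {0,1}^D selects columns of the design Z.
With the conjugate normal-inverse-gamma/g-prior structure and a
Beta-Bernoulli prior on inclusion, the coefficients, noise variance and
inclusion probability all integrate out analytically:

    p(y, X | .) ∝ C(X) [2 b_sigma + S(X)]^{-(2 a_sigma + N - 1)/2},
    C(X)  = (1+g)^{-D_X/2} Gamma(D_X + a_pi0) Gamma(D - D_X + b_pi0),
    S(X)  = y'y - g/(1+g) y'Z_X (Z_X'Z_X)^{-1} Z_X'y,

where D_X is the number of included covariates and y is centered.  The
sampler explores the 2^D model space with the block Hamming ball sweep:
each iteration re-partitions the covariates into random blocks of size
K and updates each block within a radius-m ball.

A rank-deficient Z_X'Z_X (e.g. both members of a duplicated column pair
included, or D_X > N) leaves the g-prior undefined; such X get zero
posterior mass (log weight -inf).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .ball import BallSpec, enumerate_ball, sample_ball
from .samplers import DiscreteModel, ImpossibleSliceError, random_partition

# Relative Schur-complement pivot below which an added column is treated
# as linearly dependent on the current support (condition ~ 1e10).
_SINGULAR_TOL = 1e-10


@dataclass
class RegressionData:
    """Centered response and design matrix.

    ``center=True`` removes the response mean and the column means of
    the design: the marginal likelihood below carries no intercept, so
    the intercept is handled implicitly by centering (its flat-prior
    integral is what makes the exponent (N-1)/2 rather than N/2).
    ``scale=True`` additionally scales y to unit variance, the
    convention used for expression phenotypes.
    """

    y: np.ndarray
    Z: np.ndarray
    center: bool = True
    scale: bool = False

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float).copy()
        Z = np.asarray(self.Z, dtype=float)
        if Z.shape[0] != y.shape[0]:
            raise ValueError("y and Z row counts differ")
        if np.allclose(y, 0):
            raise ValueError("response is identically zero")
        if self.center:
            y -= y.mean()
            Z = Z - Z.mean(axis=0)
        self.Z = Z
        if self.scale:
            sd = y.std()
            if sd == 0:
                raise ValueError("response has zero variance")
            y /= sd
        self.y = y

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def d(self) -> int:
        return self.Z.shape[1]


@dataclass
class RegressionHyper:
    """g-prior and Beta-Bernoulli hyperparameters.

    ``g=None`` resolves to N (unit-information prior).  The default
    Beta(0.001, 1) inclusion prior strongly favors sparse models.
    """

    g: float | None = None
    a_sigma: float = 0.1
    b_sigma: float = 0.1
    a_pi0: float = 0.001
    b_pi0: float = 1.0

    def resolve_g(self, n: int) -> float:
        g = float(self.g) if self.g is not None else float(n)
        if g <= 0 or self.a_sigma <= 0 or self.b_sigma <= 0 or self.a_pi0 <= 0 or self.b_pi0 <= 0:
            raise ValueError("all hyperparameters must be positive")
        return g


class SupportSolver:
    """Incrementally maintained inverse Gram of the included columns.

    Supports O(D_X^2) add/remove of single columns via block-inverse
    (Schur complement) up/down-dates, so a candidate model differing
    from the current one by a few flips costs a few rank-one updates
    rather than a fresh factorization.  A singular addition (pivot below
    ``_SINGULAR_TOL`` relative to the column norm) marks the solver
    singular.
    """

    def __init__(self, gram: np.ndarray, zty: np.ndarray):
        self.gram = gram
        self.zty = zty
        self.idx: list[int] = []
        self.ainv = np.zeros((0, 0))
        self.singular = False

    @classmethod
    def build(cls, gram: np.ndarray, zty: np.ndarray, support) -> "SupportSolver":
        s = cls(gram, zty)
        for j in support:
            s.add(int(j))
        return s

    def copy(self) -> "SupportSolver":
        s = SupportSolver(self.gram, self.zty)
        s.idx = list(self.idx)
        s.ainv = self.ainv.copy()
        s.singular = self.singular
        return s

    def add(self, j: int) -> None:
        if self.singular:
            return
        d = float(self.gram[j, j])
        if not self.idx:
            if d <= 0:
                self.singular = True
                return
            self.idx = [j]
            self.ainv = np.array([[1.0 / d]])
            return
        c = self.gram[self.idx, j]
        w = self.ainv @ c
        s = d - float(c @ w)
        if s <= _SINGULAR_TOL * d:
            self.singular = True
            return
        n = len(self.idx)
        new = np.empty((n + 1, n + 1))
        new[:n, :n] = self.ainv + np.outer(w, w) / s
        new[:n, n] = -w / s
        new[n, :n] = -w / s
        new[n, n] = 1.0 / s
        self.ainv = new
        self.idx.append(j)

    def remove(self, j: int) -> None:
        if self.singular:
            raise ValueError("cannot downdate a singular solver")
        p = self.idx.index(j)
        keep = [t for t in range(len(self.idx)) if t != p]
        f = self.ainv[keep, p]
        gpp = self.ainv[p, p]
        self.ainv = self.ainv[np.ix_(keep, keep)] - np.outer(f, f) / gpp
        del self.idx[p]

    def quad(self) -> float:
        """y'Z_X (Z_X'Z_X)^{-1} Z_X'y for the current support."""
        if self.singular:
            raise ValueError("quad undefined for singular support")
        if not self.idx:
            return 0.0
        b = self.zty[self.idx]
        return float(b @ self.ainv @ b)


def _log_marginal_from_quad(
    quad: float, dx: int, n: int, d: int, yty: float, g: float, hyper: RegressionHyper
) -> float:
    s = yty - g / (1.0 + g) * quad
    s = max(s, yty / (1.0 + g) * 1e-12)  # guard roundoff; S(X) >= y'y/(1+g) > 0
    log_c = (
        -0.5 * dx * np.log1p(g)
        + gammaln(dx + hyper.a_pi0)
        + gammaln(d - dx + hyper.b_pi0)
    )
    return float(log_c - 0.5 * (2 * hyper.a_sigma + n - 1) * np.log(2 * hyper.b_sigma + s))


def log_marginal(x, data: RegressionData, hyper: RegressionHyper | None = None) -> float:
    """log p(y, X | .) up to an additive constant shared across X.

    ``x`` may be a binary vector of length D or an iterable of included
    indices.  Returns -inf when the included columns are linearly
    dependent (rank rule) or D_X > N.
    """
    hyper = hyper or RegressionHyper()
    x = np.asarray(x)
    support = np.flatnonzero(x) if x.size == data.d and x.ndim == 1 else x.astype(int)
    n, d = data.n, data.d
    if len(support) > n:
        return -np.inf
    g = hyper.resolve_g(n)
    zx = data.Z[:, support]
    solver = SupportSolver.build(zx.T @ zx, zx.T @ data.y, range(len(support)))
    if solver.singular:
        return -np.inf
    yty = float(data.y @ data.y)
    return _log_marginal_from_quad(solver.quad(), len(support), n, d, yty, g, hyper)


class RegressionModel(DiscreteModel):
    """ModelContract wrapper so the generic kernels can drive this model."""

    S = 2

    def __init__(self, data: RegressionData, hyper: RegressionHyper | None = None):
        super().__init__()
        self.data = data
        self.hyper = hyper or RegressionHyper()
        self.gram = data.Z.T @ data.Z
        self.zty = data.Z.T @ data.y
        self.yty = float(data.y @ data.y)
        self.g = self.hyper.resolve_g(data.n)

    def _lm_support(self, support) -> float:
        if len(support) > self.data.n:
            return -np.inf
        solver = SupportSolver.build(self.gram, self.zty, support)
        if solver.singular:
            return -np.inf
        return _log_marginal_from_quad(
            solver.quad(), len(support), self.data.n, self.data.d, self.yty, self.g, self.hyper
        )

    def log_joint(self, x: np.ndarray, theta=None) -> float:
        return self._lm_support(np.flatnonzero(x))

    def block_log_weights(self, x, block, candidates, theta=None) -> np.ndarray:
        outside = np.setdiff1d(np.flatnonzero(x), block)
        base = SupportSolver.build(self.gram, self.zty, outside)
        out = np.empty(len(candidates))
        for t, cand in enumerate(candidates):
            s = base.copy()
            for j in np.asarray(block)[np.asarray(cand, dtype=bool)]:
                s.add(int(j))
            dx = len(outside) + int(cand.sum())
            if s.singular or dx > self.data.n:
                out[t] = -np.inf
            else:
                out[t] = _log_marginal_from_quad(
                    s.quad(), dx, self.data.n, self.data.d, self.yty, self.g, self.hyper
                )
        return out


def regression_block_hb(
    data: RegressionData,
    hyper: RegressionHyper | None = None,
    K: int = 10,
    m: int = 1,
    iterations: int = 5000,
    burn_in: int = 100,
    seed: int = 0,
    _force_general: bool = False,
) -> "RegressionTrace":
    """Block Hamming ball sampler over inclusion vectors.

    Per iteration: a fresh uniform random partition of the D covariates
    into P = ceil(D/K) blocks; for each block, an auxiliary block u_i
    uniform on the radius-m ball around the current x_i, then x_i drawn
    from the ball around u_i with weights proportional to the
    marginalized joint.  m = K gives the BG-K block Gibbs sampler.

    The trace stores the sparse support set per iteration.  The chain
    starts from the empty model (the all-zero vector has positive mass
    and avoids rank-deficient starts when D > N).
    """
    hyper = hyper or RegressionHyper()
    rng = np.random.default_rng(seed)
    n, d = data.n, data.d
    g = hyper.resolve_g(n)
    gram = data.Z.T @ data.Z
    gram_diag = np.diag(gram).copy()
    zty = data.Z.T @ data.y
    yty = float(data.y @ data.y)
    exp_coef = 0.5 * (2 * hyper.a_sigma + n - 1)
    log1pg = np.log1p(g)
    shrink = g / (1.0 + g)
    gam_a = gammaln(np.arange(n + 2) + hyper.a_pi0)
    gam_b = gammaln(np.maximum(d - np.arange(n + 2), 0) + hyper.b_pi0)
    spec_cache: dict[int, BallSpec] = {}

    def logw_from_quads(quads: np.ndarray, dxs: np.ndarray) -> np.ndarray:
        s = np.maximum(yty - shrink * quads, yty / (1.0 + g) * 1e-12)
        return (
            -0.5 * dxs * log1pg
            + gam_a[dxs]
            + gam_b[dxs]
            - exp_coef * np.log(2 * hyper.b_sigma + s)
        )

    x = np.zeros(d, dtype=np.int64)
    support: set[int] = set()
    supports: list[tuple[int, ...]] = []
    log_marg_trace: list[float] = []
    n_evals = 0

    def slow_block(base, block, outside_ct, cands):
        logw = np.empty(len(cands))
        cand_solvers = []
        for t, cand in enumerate(cands):
            s2 = base.copy()
            for j in block[np.asarray(cand, dtype=bool)]:
                s2.add(int(j))
            dx = outside_ct + int(cand.sum())
            if s2.singular or dx > n:
                logw[t] = -np.inf
            else:
                logw[t] = _log_marginal_from_quad(s2.quad(), dx, n, d, yty, g, hyper)
            cand_solvers.append(s2)
        return logw, cand_solvers

    tiny_diag = np.maximum(gram_diag, 1e-300)

    class _Cur:
        """Current-support state with all single-add weights precomputed.

        Because the chain is sparse and the support changes only a few
        times per sweep (usually less), the expensive parts — the
        inverse Gram of the support and the Schur pivots / numerators of
        adding any single column — are computed once per support and
        reused by every block until the support moves.
        """

        __slots__ = ("idx", "ainv", "ainv_b", "quad", "logw_cur", "s_all", "num_all",
                     "sing_all", "logw_add", "Ct", "W")

        def __init__(self, sup: list[int]):
            t = len(sup)
            self.idx = list(sup)
            if t == 0:
                self.ainv = np.zeros((0, 0))
                self.ainv_b = np.zeros(0)
                self.quad = 0.0
                self.s_all = gram_diag.copy()
                self.num_all = zty.copy()
                self.Ct = np.zeros((0, d))
                self.W = np.zeros((0, d))
            else:
                G = gram[np.ix_(sup, sup)]
                L = np.linalg.cholesky(G)  # support always nonsingular by construction
                if L.diagonal().min() ** 2 <= _SINGULAR_TOL * gram_diag[sup].max():
                    raise np.linalg.LinAlgError("singular support")
                self.ainv = np.linalg.inv(G)
                b = zty[sup]
                self.ainv_b = self.ainv @ b
                self.quad = float(b @ self.ainv_b)
                Ct = gram[sup, :]
                W = self.ainv @ Ct
                self.s_all = gram_diag - np.einsum("ij,ij->j", Ct, W)
                self.num_all = zty - self.ainv_b @ Ct
                self.Ct = Ct
                self.W = W
            self.sing_all = self.s_all <= _SINGULAR_TOL * tiny_diag
            self.logw_cur = float(
                logw_from_quads(np.array([self.quad]), np.array([t]))[0]
            )
            q_add = self.quad + np.where(
                self.sing_all, 0.0, self.num_all**2 / np.where(self.sing_all, 1.0, self.s_all)
            )
            self.logw_add = logw_from_quads(q_add, np.full(d, t + 1, dtype=np.int64))
            self.logw_add[self.sing_all] = -np.inf
            if t + 1 > n:
                self.logw_add[:] = -np.inf

    def draw_pick(logw: np.ndarray) -> int:
        mx = logw.max()
        if not np.isfinite(mx):
            raise ImpossibleSliceError("all block candidates have zero mass")
        w = np.exp(logw - mx)
        c = np.cumsum(w)
        return int(np.searchsorted(c, rng.random() * c[-1], side="right"))

    def pair_add_logw(j0: int, J: np.ndarray) -> np.ndarray:
        """log weights of the supports T + {j0, j}, j in J, via one extra
        Schur correction on the precomputed single-add pivots."""
        s0 = cur.s_all[j0]
        num0 = cur.num_all[j0]
        t = len(cur.idx)
        if t:
            cross = gram[j0, J] - cur.Ct[:, j0] @ cur.W[:, J]
        else:
            cross = gram[j0, J]
        s2 = cur.s_all[J] - cross**2 / s0
        num2 = cur.num_all[J] - cross * (num0 / s0)
        bad2 = cur.sing_all[J] | (s2 <= _SINGULAR_TOL * tiny_diag[J]) | (t + 2 > n)
        q2 = (cur.quad + num0**2 / s0) + np.where(bad2, 0.0, num2**2 / np.where(bad2, 1.0, s2))
        lw2 = logw_from_quads(q2, np.full(len(J), t + 2, dtype=np.int64))
        lw2[bad2] = -np.inf
        return lw2

    old_err = np.seterr(divide="ignore", invalid="ignore")
    cur = _Cur([])
    cur_minus: dict[int, _Cur] = {}

    def move_to(new_support: set[int]) -> None:
        nonlocal support, cur
        support = new_support
        cur = _Cur(sorted(support))
        cur_minus.clear()
        for jb in support:
            cur_minus[jb] = _Cur(sorted(support - {jb}))

    for it in range(burn_in + iterations):
        for block in random_partition(d, K, rng):
            kb = len(block)
            mi = min(m, kb)
            xb = x[block]
            sup_pos = np.flatnonzero(xb)

            if mi == 1 and sup_pos.size <= 1 and not _force_general:
                # u is uniform on {x_b} + single flips: encode as f = -1
                # (u = x_b) or the flipped position f
                f = int(rng.integers(-1, kb))
                n_evals += 1 + kb
                logw = np.empty(1 + kb)
                if sup_pos.size == 0:
                    if f < 0:  # u = x: stay, or add any single block column
                        logw[0] = cur.logw_cur
                        logw[1:] = cur.logw_add[block]
                    else:  # u adds j0: keep it, drop it, or add a second
                        j0 = int(block[f])
                        logw[0] = cur.logw_add[j0]
                        logw[1 + f] = cur.logw_cur
                        others = np.flatnonzero(np.arange(kb) != f)
                        if cur.sing_all[j0]:
                            logw[0] = -np.inf
                            logw[1 + others] = -np.inf
                        else:
                            logw[1 + others] = pair_add_logw(j0, block[others])
                else:  # exactly one support column jb in the block
                    bpos = int(sup_pos[0])
                    jb = int(block[bpos])
                    cm = cur_minus[jb]
                    if f < 0:  # u = x
                        logw[0] = cur.logw_cur
                        logw[1:] = cur.logw_add[block]
                        logw[1 + bpos] = cm.logw_cur  # flipping jb drops it
                    elif f == bpos:  # u dropped jb: swaps are single adds to T - jb
                        logw[0] = cm.logw_cur
                        logw[1:] = cm.logw_add[block]
                        logw[1 + bpos] = cur.logw_cur  # re-adding jb restores T
                    else:  # u added j0 while jb stays
                        j0 = int(block[f])
                        logw[0] = cur.logw_add[j0]
                        logw[1 + f] = cur.logw_cur
                        logw[1 + bpos] = cm.logw_add[j0]  # drop jb, keep j0
                        others = np.flatnonzero((np.arange(kb) != f) & (np.arange(kb) != bpos))
                        if cur.sing_all[j0]:
                            logw[0] = -np.inf
                            logw[1 + others] = -np.inf
                        else:
                            logw[1 + others] = pair_add_logw(j0, block[others])
                pick = draw_pick(logw)
                unchanged = pick == 0 if f < 0 else pick == 1 + f
                if not unchanged:
                    chosen = xb.copy()
                    if f >= 0:
                        chosen[f] ^= 1
                    if pick > 0:
                        chosen[pick - 1] ^= 1
                    x[block] = chosen
                    block_set = set(int(j) for j in block)
                    move_to(
                        (support - block_set)
                        | set(int(j) for j in block[chosen.astype(bool)])
                    )
            else:
                # General path: m > 1, or several support columns in one block
                spec = spec_cache.setdefault(kb, BallSpec(min(m, kb), kb))
                u_b = sample_ball(xb, spec, rng)
                block_set = set(int(j) for j in block)
                sup_out = sorted(support - block_set)
                base = SupportSolver.build(gram, zty, sup_out)
                cands = enumerate_ball(u_b, mi)
                n_evals += len(cands)
                logw, _ = slow_block(base, block, len(sup_out), cands)
                pick = draw_pick(logw)
                chosen = cands[pick]
                x[block] = chosen
                new_support = set(sup_out) | set(
                    int(j) for j in block[np.asarray(chosen, dtype=bool)]
                )
                if new_support != support:
                    move_to(new_support)
        if it >= burn_in:
            supports.append(tuple(sorted(support)))
            log_marg_trace.append(cur.logw_cur)
    np.seterr(**old_err)

    return RegressionTrace(
        supports=supports,
        d=d,
        log_marginal=np.array(log_marg_trace),
        n_weight_evals=n_evals,
        seed=seed,
        settings={"K": K, "m": m, "iterations": iterations, "burn_in": burn_in},
    )


@dataclass
class RegressionTrace:
    """Post-burn-in support sets plus provenance."""

    supports: list[tuple[int, ...]]
    d: int
    log_marginal: np.ndarray
    n_weight_evals: int
    seed: int
    settings: dict

    def __len__(self) -> int:
        return len(self.supports)

    def indicator_matrix(self) -> np.ndarray:
        out = np.zeros((len(self.supports), self.d), dtype=np.int8)
        for t, sup in enumerate(self.supports):
            out[t, list(sup)] = 1
        return out


def inclusion_probabilities(trace: RegressionTrace) -> np.ndarray:
    """Per-covariate marginal posterior inclusion probability."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    counts = np.zeros(trace.d)
    for sup in trace.supports:
        counts[list(sup)] += 1
    return counts / len(trace)


def running_inclusion(trace: RegressionTrace, j: int) -> np.ndarray:
    """Cumulative inclusion probability of covariate j along the chain."""
    ind = np.fromiter((j in sup for sup in trace.supports), dtype=float, count=len(trace))
    return np.cumsum(ind) / np.arange(1, len(trace) + 1)


def screen_covariates(y: np.ndarray, Z: np.ndarray, threshold: float = 0.3) -> np.ndarray:
    """Indices of covariates whose |Pearson r| with y is below threshold.

    Data-preparation utility mirroring the common pre-screening step in
    eQTL-style analyses (keep a large background of uncorrelated SNPs,
    spike in the correlated ones of interest).
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    yc = y - y.mean()
    Zc = Z - Z.mean(axis=0)
    denom = np.sqrt((Zc**2).sum(axis=0) * (yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Zc.T @ yc / denom, 0.0)
    return np.flatnonzero(np.abs(r) < threshold)
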