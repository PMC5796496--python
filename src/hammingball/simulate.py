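"""Seeded generators for the three benchmark simulation designs.

Each generator is a pure function of its arguments and seed, and
returns the data together with a ground-truth sidecar so that
parameter-recovery tests are self-contained.

The three designs share one idea: the data are constructed so that two
(or more) latent configurations explain them equally well, creating
exactly symmetric posterior modes that a well-mixing sampler must visit
and switch between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Printed ground truth of the tumor simulation: three subclones with
# weights theta0 and nested (linear-phylogeny) genotypes over nine
# variants; the read counts are a single frozen binomial draw at depth
# 800 from phi = (0.5, 0.5, 0.5, 0.3, 0.3, 0.3, 0.15, 0.15, 0.15).
TUMOR_THETA0 = np.array([0.3, 0.3, 0.4])
TUMOR_X0 = np.array(
    [
        [1, 1, 1, 1, 1, 1, 1, 1, 1],
        [1, 1, 1, 1, 1, 1, 0, 0, 0],
        [1, 1, 1, 0, 0, 0, 0, 0, 0],
    ]
)
TUMOR_DEPTH = 800
TUMOR_R_FROZEN = np.array([405, 397, 393, 239, 245, 247, 123, 121, 123])

# A branched-phylogeny alternative reproducing the same phi vector:
# theta = (0.1, 0.6, 0.3) with the trunk variants shared and the two
# later variant groups on different branches.  Derived algebraically
# (0.5*[1,1,1]=.5 etc.), used in tests as the second posterior mode.
TUMOR_THETA_BRANCHED = np.array([0.1, 0.6, 0.3])
TUMOR_X_BRANCHED = np.array(
    [
        [1, 1, 1, 0, 0, 0, 0, 0, 0],
        [1, 1, 1, 1, 1, 1, 0, 0, 0],
        [1, 1, 1, 0, 0, 0, 1, 1, 1],
    ]
)


@dataclass
class SimRecipe:
    """Which experiment, at what size and noise, under what seed."""

    experiment: str  # toy | regression | tumor | multisample_tumor
    seed: int
    params: dict = field(default_factory=dict)


def gen_toy(sigma2: float = 0.5, seed: int = 0, n: int = 200, d_half: int = 10):
    """Toy regression with duplicated covariates and known coefficients.

    Covariates ``z_{i,d} ~ U(0,1)`` for d = 1..d_half, the remaining
    columns exact replicas (``z_{i,d_half+d} = z_{i,d}``); responses
    ``y_i = z_{i,6} + N(0, sigma2)``.  Truth: only covariate 6 active —
    but its replica (covariate 16 at default size) explains the data
    identically, so the posterior over inclusion vectors has two
    symmetric modes.

    Returns ``(y, Z, x_true)`` with ``x_true`` the binary truth vector.
    """
    rng = np.random.default_rng(seed)
    Zh = rng.uniform(0.0, 1.0, size=(n, d_half))
    Z = np.hstack([Zh, Zh])
    active = 5  # 0-based index of covariate 6
    y = Z[:, active] + rng.normal(0.0, np.sqrt(sigma2), size=n)
    x_true = np.zeros(2 * d_half, dtype=np.int64)
    x_true[active] = 1
    return y, Z, x_true


def gen_regression(seed: int = 0, n: int = 100, d_half: int = 600, sigma: float = 0.1):
    """Sparse-regression benchmark with a duplicated design.

    An n x d_half design with entries uniform on {0, 1, 2} (SNP-style
    coding), responses ``y_i = z_{i,11} + N(0, sigma^2)``, then the
    design is duplicated columnwise to n x (2 d_half) so covariates 11
    and d_half+11 are exact replicas and give equally good explanations.

    Returns ``(y, Z, x_true)``; y is raw (centering is the model's
    preprocessing step).
    """
    rng = np.random.default_rng(seed)
    Zh = rng.integers(0, 3, size=(n, d_half)).astype(float)
    active = 10  # 0-based index of covariate 11
    y = Zh[:, active] + rng.normal(0.0, sigma, size=n)
    Z = np.hstack([Zh, Zh])
    x_true = np.zeros(2 * d_half, dtype=np.int64)
    x_true[active] = 1
    return y, Z, x_true


def gen_tumor(seed: int = 0, fresh: bool = False):
    """Single-sample tumor read counts at depth 800 from the 3-clone truth.

    ``fresh=False`` returns the frozen printed draw (a single stochastic
    realization; it cannot be regenerated from any seed, so it is
    shipped as a constant).  ``fresh=True`` draws new binomial counts at
    the same phi.

    Returns ``(r, d, truth)`` with truth = dict(theta0, X0, p0).
    """
    from .deconv import vaf  # local import to avoid a cycle

    p0 = vaf(TUMOR_THETA0, TUMOR_X0, e=0.0)
    d = np.full(9, TUMOR_DEPTH, dtype=np.int64)
    if fresh:
        rng = np.random.default_rng(seed)
        r = rng.binomial(d, p0)
    else:
        r = TUMOR_R_FROZEN.copy()
    truth = {"theta0": TUMOR_THETA0.copy(), "X0": TUMOR_X0.copy(), "p0": p0}
    return r, d, truth


def gen_multisample_tumor(
    S: int = 13,
    seed: int = 0,
    n_variants: int = 17,
    n_clones: int = 4,
    depth: int = 800,
    e: float = 0.01,
):
    """Multi-sample tumor counts: one shared genotype matrix, per-sample weights.

    Emulates a multi-region design (default 17 variants x 13 samples,
    the last sample a normal-tissue control).  Clone 1 carries no
    mutations (normal cells); the remaining clones form a nested
    (linear) phylogeny over random variant groups.  Tumor samples get
    Dirichlet mixture weights over all clones; the normal sample puts
    all weight on the mutation-free clone, so its expected VAF is just
    the error rate e.

    Returns ``(r, d, truth)`` where r, d are (n_variants, S) arrays and
    truth = dict(X, thetas, phi).
    """
    if S < 2:
        raise ValueError("need at least 2 samples (one tumor, one normal)")
    from .deconv import vaf

    rng = np.random.default_rng(seed)
    # nested genotypes: clone k carries the union of groups 1..k-1
    X = np.zeros((n_clones, n_variants), dtype=np.int64)
    groups = np.array_split(rng.permutation(n_variants), n_clones - 1)
    for k in range(1, n_clones):
        for g in groups[: n_clones - k]:
            X[k, g] = 1
    thetas = np.empty((S, n_clones))
    thetas[: S - 1] = rng.dirichlet(np.ones(n_clones), size=S - 1)
    thetas[S - 1] = np.eye(n_clones)[0]  # normal sample: mutation-free clone only
    phi = np.stack([vaf(thetas[s], X, e=e) for s in range(S)], axis=1)
    d = np.full((n_variants, S), depth, dtype=np.int64)
    r = rng.binomial(d, phi)
    truth = {"X": X, "thetas": thetas, "phi": phi}
    return r, d, truth
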