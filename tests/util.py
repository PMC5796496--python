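"""Shared test scaffolding: tiny table models and brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np

from hammingball.samplers import DiscreteModel


def encode(states: np.ndarray, S: int) -> np.ndarray:
    """Map rows of categorical states to integer indices (base-S)."""
    states = np.atleast_2d(states)
    powers = S ** np.arange(states.shape[1])
    return states @ powers


class TableModel(DiscreteModel):
    """Log-joint factorized over fixed blocks as per-block lookup tables.

    ``tables[i]`` has S^{K_i} entries, indexed by the base-S encoding of
    the block pattern; the optional ``theta_tables`` dict switches the
    tables with a discrete parameter theta.
    """

    factorized = True

    def __init__(self, tables, blocks, S=2, theta_tables=None, theta_prior=None):
        super().__init__()
        self.S = S
        self.blocks = [np.asarray(b) for b in blocks]
        self.tables = [np.asarray(t, dtype=float) for t in tables]
        self.theta_tables = theta_tables  # {theta: list of tables}
        self.theta_prior = theta_prior  # {theta: log prior}

    def _tabs(self, theta):
        if self.theta_tables is not None and theta is not None:
            return self.theta_tables[theta]
        return self.tables

    def log_joint(self, x, theta=None) -> float:
        tabs = self._tabs(theta)
        total = 0.0 if self.theta_prior is None or theta is None else self.theta_prior[theta]
        for blk, tab in zip(self.blocks, tabs):
            total += tab[int(encode(x[blk], self.S)[0])]
        return float(total)

    def block_log_weights(self, x, block, candidates, theta=None) -> np.ndarray:
        tabs = self._tabs(theta)
        for i, blk in enumerate(self.blocks):
            if np.array_equal(blk, block):
                base = 0.0
                # theta prior belongs to exactly one factor so that the
                # product of block ball-sums equals the joint ball-sum
                if i == 0 and self.theta_prior is not None and theta is not None:
                    base = self.theta_prior[theta]
                return tabs[i][encode(candidates, self.S)] + base
        # fall back to the generic (slow) evaluation for exotic blocks
        return super().block_log_weights(x, block, candidates, theta)

    # theta machinery for the hb_gibbs / marginal MH kernels ----------
    def sample_theta(self, x, theta, rng):
        if self.theta_tables is None:
            return theta
        keys = sorted(self.theta_tables)
        logw = np.array([self.log_joint(x, k) for k in keys])
        w = np.exp(logw - logw.max())
        return keys[rng.choice(len(keys), p=w / w.sum())]

    def propose_theta(self, theta, rng):
        keys = sorted(self.theta_tables)
        return keys[int(rng.integers(len(keys)))]  # independent uniform proposal

    def log_proposal_density(self, theta_to, theta_from) -> float:
        return -np.log(len(self.theta_tables))


def all_states(D: int, S: int = 2) -> np.ndarray:
    return np.array(list(itertools.product(range(S), repeat=D)), dtype=np.int64)


def brute_posterior(model: DiscreteModel, D: int, theta=None, S: int = 2):
    """Exhaustive posterior over all S^D states, indexed by ``encode``."""
    states = all_states(D, S)
    logp = np.array([model.log_joint(s, theta) for s in states])
    w = np.exp(logp - logp.max())
    probs = np.zeros(S**D)
    probs[encode(states, S)] = w / w.sum()
    return states, probs


def brute_joint_posterior(model: TableModel, D: int, S: int = 2):
    """Joint posterior over (theta, state), states indexed by ``encode``."""
    keys = sorted(model.theta_tables)
    states = all_states(D, S)
    logp = np.array([[model.log_joint(s, k) for s in states] for k in keys])
    w = np.exp(logp - logp.max())
    w /= w.sum()
    probs = np.zeros_like(w)
    probs[:, encode(states, S)] = w
    return keys, states, probs


def empirical_distribution(chain_states: np.ndarray, S: int = 2) -> np.ndarray:
    D = chain_states.shape[1]
    counts = np.bincount(encode(chain_states, S), minlength=S**D)
    return counts / counts.sum()


def tv(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(p - q).sum())


def random_tables(blocks, S, rng, scale=1.5):
    """Moderately concentrated random per-block log-weight tables."""
    return [scale * rng.normal(size=S ** len(b)) for b in blocks]
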