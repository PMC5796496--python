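"""Combinatorics of Hamming balls over categorical sequences.

A Hamming ball of radius ``m`` around a length-``K`` block ``x`` with
alphabet size ``S`` is the set ``H_m(x) = {u : d(u, x) <= m}`` where
``d`` is the Hamming distance.  Its cardinality,

    M = sum_{j=0}^{m} (S-1)^j C(K, j),

does not depend on the center — the property that makes the ball usable
as the support of an auxiliary distribution in a Gibbs sampler.  The
optional weight ``lam`` tilts the distribution toward the center,
``p(u | x) ∝ exp(-lam * d(u, x))`` on the ball, with weighted volume
``M_lam = sum_j exp(-lam j) (S-1)^j C(K, j)``.

Symbols are represented internally as integers ``0 .. S-1``; callers
that use external codings (e.g. genotype codes {0,1,2}) map labels at
the boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import comb


@dataclass(frozen=True)
class BallSpec:
    """Radius, block size, alphabet size and center-weight of a ball.

    ``lam = 0`` gives the uniform auxiliary distribution (the default
    scheme); ``lam > 0`` concentrates mass toward the center.
    """

    m: int
    K: int
    S: int = 2
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError(f"alphabet size S must be >= 2, got {self.S}")
        if self.K < 1:
            raise ValueError(f"block size K must be >= 1, got {self.K}")
        if not 0 <= self.m <= self.K:
            raise ValueError(f"radius m must satisfy 0 <= m <= K, got m={self.m}, K={self.K}")
        if self.lam < 0:
            raise ValueError(f"weight lam must be >= 0, got {self.lam}")


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"block length mismatch: {a.shape} vs {b.shape}")
    return a, b


def hamming_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Number of positions at which two equal-length blocks differ."""
    a, b = _check_pair(a, b)
    return int(np.count_nonzero(a != b))


def ball_volume(m: int, K: int, S: int = 2, lam: float = 0.0) -> float:
    """Cardinality (lam=0) or weighted volume (lam>0) of a radius-m ball.

    Independent of the center.  For ``lam == 0`` the result is an exact
    integer; for ``lam > 0`` it is the weighted sum
    ``sum_j exp(-lam j) (S-1)^j C(K, j)``.
    """
    BallSpec(m, K, S, lam)  # validate
    j = np.arange(m + 1)
    terms = comb(K, j, exact=False) * float(S - 1) ** j
    if lam == 0.0:
        return int(round(terms.sum()))
    return float(np.sum(np.exp(-lam * j) * terms))


@lru_cache(maxsize=256)
def _flip_patterns(K: int, m: int, S: int) -> tuple[np.ndarray, np.ndarray]:
    """All substitution patterns for states within distance m of a center.

    Returns ``(positions, offsets)`` where row t of ``positions`` is a
    boolean mask of substituted positions and row t of ``offsets`` holds,
    for each substituted position, a value in ``1..S-1`` to be added
    (mod S) to the center symbol.  Enumeration order: distance
    j = 0..m, position subsets lexicographic, substitute symbols in
    symbol order.
    """
    masks = []
    offs = []
    for j in range(m + 1):
        for pos in itertools.combinations(range(K), j):
            for sub in itertools.product(range(1, S), repeat=j):
                mask = np.zeros(K, dtype=bool)
                off = np.zeros(K, dtype=np.int64)
                mask[list(pos)] = True
                off[list(pos)] = sub
                masks.append(mask)
                offs.append(off)
    return np.array(masks, dtype=bool), np.array(offs, dtype=np.int64)


def enumerate_ball(center: np.ndarray, m: int, S: int = 2) -> np.ndarray:
    """Every state at Hamming distance <= m from ``center``, each once.

    Returns an ``(M, K)`` integer array whose first row is the center.
    Rows are ordered by distance, then lexicographic position subsets,
    then symbol order, so the enumeration is deterministic.
    """
    center = np.asarray(center, dtype=np.int64)
    K = center.shape[0]
    if not 0 <= m <= K:
        raise ValueError(f"radius m={m} outside [0, {K}]")
    _, offs = _flip_patterns(K, m, S)
    return (center[None, :] + offs) % S


def in_ball(u: np.ndarray, center: np.ndarray, m: int) -> bool:
    """True iff ``d(u, center) <= m``; symmetric in (u, center)."""
    return hamming_distance(u, center) <= m


def _distance_class_logweights(m: int, K: int, S: int, lam: float) -> np.ndarray:
    j = np.arange(m + 1)
    with np.errstate(divide="ignore"):
        logw = (
            -lam * j
            + j * np.log(S - 1.0)
            + np.log(comb(K, j, exact=False))
        )
    return logw


@lru_cache(maxsize=256)
def _distance_class_cumprobs(m: int, K: int, S: int, lam: float) -> np.ndarray:
    logw = _distance_class_logweights(m, K, S, lam)
    w = np.exp(logw - logw.max())
    c = np.cumsum(w / w.sum())
    c[-1] = 1.0
    return c


def sample_ball(
    center: np.ndarray,
    spec: BallSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one state from the (possibly lam-weighted) ball around center.

    Draws the distance class j with probability proportional to
    ``exp(-lam j) (S-1)^j C(K, j)``, then a uniform position subset of
    size j, then independent uniform alternative symbols — exact
    sampling without materializing the ball.
    """
    center = np.asarray(center, dtype=np.int64)
    K = center.shape[0]
    if spec.K != K:
        raise ValueError(f"spec.K={spec.K} does not match center length {K}")
    cum = _distance_class_cumprobs(spec.m, K, spec.S, spec.lam)
    j = int(np.searchsorted(cum, rng.random(), side="right"))
    out = center.copy()
    if j == 1:  # common case: one cheap draw instead of rng.choice
        p = int(rng.integers(K))
        out[p] = (out[p] + int(rng.integers(1, spec.S))) % spec.S
    elif j > 1:
        pos = rng.choice(K, size=j, replace=False)
        out[pos] = (out[pos] + rng.integers(1, spec.S, size=j)) % spec.S
    return out


def sample_ball_many(
    centers: np.ndarray,
    spec: BallSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized ``sample_ball`` over the rows of a 2-D center array."""
    centers = np.asarray(centers, dtype=np.int64)
    n, K = centers.shape
    cum = _distance_class_cumprobs(spec.m, K, spec.S, spec.lam)
    js = np.searchsorted(cum, rng.random(n), side="right")
    out = centers.copy()
    for i in range(n):
        j = int(js[i])
        if j > 0:
            pos = rng.choice(K, size=j, replace=False)
            out[i, pos] = (out[i, pos] + rng.integers(1, spec.S, size=j)) % spec.S
    return out
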