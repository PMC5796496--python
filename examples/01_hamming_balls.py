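"""Hamming ball geometry: volumes, enumeration, and sampling.

A Hamming ball of radius m around a length-K categorical block is the
set of states differing from the center in at most m positions.  Its
size is independent of the center — the property that lets a sampler
use it as the support of an auxiliary slice.
"""

import numpy as np

from hammingball import BallSpec, ball_volume, enumerate_ball, sample_ball

# The per-block summation counts that make restricted sampling cheap:
# a binary block of size 10 has 2^10 = 1024 states, but only 11 lie
# within radius 1 and 176 within radius 3.
for m in (1, 2, 3, 10):
    print(f"binary K=10, radius {m:2d}: ball volume = {ball_volume(m, 10):4d}")

# Enumeration is deterministic: distance class, then position, then symbol.
center = np.array([0, 1, 0])
print("\nball of radius 1 around (0,1,0), S=2:")
print(enumerate_ball(center, 1, S=2))

# Center-weighted sampling: probability decays as exp(-lam * distance).
rng = np.random.default_rng(0)
spec = BallSpec(m=3, K=3, S=2, lam=1.0)
draws = [sample_ball(center, spec, rng) for _ in range(20000)]
dists = np.array([(d != center).sum() for d in draws])
print("\nweighted draws (lam=1): fraction at each distance (expect geometric decay")
print("per state, i.e. class mass proportional to C(3,j) exp(-j)):")
print(np.bincount(dists, minlength=4) / len(dists))
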