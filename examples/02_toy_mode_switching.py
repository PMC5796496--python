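"""Mode switching on a toy regression with duplicated covariates.

Covariates 6 and 16 are exact copies, so the inclusion-vector posterior
has two symmetric modes ({x6=1} and {x16=1}).  Jumping between them
requires flipping two bits at once: a Hamming ball sampler with one
block and radius 1 can, single-site Gibbs cannot (at low noise).
"""

from hammingball import ToyData, gen_toy, mode_occupancy, mode_switches, run_toy_chain

for sigma2 in (0.5, 2.0, 5.0):
    y, Z, _ = gen_toy(sigma2=sigma2, seed=0)
    data = ToyData(y, Z, sigma2)
    hb = run_toy_chain(data, "block_hb", m=1, iterations=1000, burn_in=100, seed=1)
    gibbs = run_toy_chain(data, "block_gibbs", K=1, iterations=1000, burn_in=100, seed=1)
    s_hb = mode_switches(mode_occupancy(hb.states, 5, 15))
    s_g = mode_switches(mode_occupancy(gibbs.states, 5, 15))
    print(f"sigma^2 = {sigma2}: mode switches in 1000 sweeps — "
          f"Hamming ball {s_hb:3d}, single-site Gibbs {s_g:3d}")

print("\nAt low noise the Gibbs chain records zero switches (stuck in one mode);")
print("the ball sampler hops freely because it proposes joint two-bit flips.")
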