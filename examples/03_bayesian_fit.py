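"""Bayesian two-parameter von Bertalanffy fit via Metropolis-Hastings.

Simulates a blue mask ray sample (n = 34, generated at w_inf = 42 cm,
k = 0.38 yr^-1) and fits it under the informative priors: lognormal w_inf
(natural-scale mean 77 cm, log-sd 0.5), Beta(21.9, 162.3) for k,
inverse-Gamma(0.01, 0.01) for the variance.  At field sample sizes the
tight k prior (centred near 0.12) visibly shrinks the estimate for this
fast-growing species; with a few hundred records the data dominate and
the posterior median lands on the generating value.
"""

from raygrowth import MCMC_PRESETS, PriorSet, SPECIES_PRESETS, generate_sample, sample_posterior, summarize_posterior

preset = SPECIES_PRESETS["N_kuhlii"]
data = generate_sample(preset, seed=7)
chain = sample_posterior(data, PriorSet(), MCMC_PRESETS["desk"], w0=preset.w0)
summary = summarize_posterior(chain)

print(f"n = {len(data)} records, {len(chain)} retained draws, "
      f"acceptance {chain.acceptance_rate:.0%}")
for par, unit in (("w_inf", "cm"), ("k", "yr^-1"), ("sigma2", "cm^2")):
    s = summary[par]
    print(f"  {par:>6}: median {s['median']:7.3f} {unit:<5} "
          f"95% CI ({s['ci_lower']:.3f}, {s['ci_upper']:.3f})  "
          f"Geweke z {chain.geweke_z[par]:+.2f}")
print("\nThe medians with 95% credibility intervals summarise the posterior;")
print("|Geweke z| <= 1.96 is consistent with a converged chain.  The k")
print("median sits between the generating 0.38 and the prior's 0.12 —")
print("informative-prior shrinkage at small n.")
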