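"""NLS vs Bayes when sampling is data-poor.

Draws replicated samples from a well-represented design (10 animals at each
of 20 age classes), then an age-truncated n = 15 subsample of each, and
compares the spread of NLS point estimates with Bayesian posterior medians.
A short run (15 replicates) keeps this example quick; the acceptance-scale
experiment uses 50.
"""

from raygrowth import SPECIES_PRESETS, Scenario, results_to_frame, run_comparison

results = run_comparison(
    SPECIES_PRESETS["H_uarnak"],
    scenarios=(
        Scenario("data_rich"),
        Scenario("data_poor_truncated", scheme="truncate_old", n=15),
    ),
    replicates=15,
    seed=1,
)
df = results_to_frame(results)
print(df[["scenario", "method", "parameter", "truth", "bias", "rmse", "spread_sd"]]
      .round(3).to_string(index=False))
print("\nIn the truncated data-poor scenario the Bayesian RMSE for w_inf is")
print("smaller than the NLS RMSE: the informative prior stabilises the")
print("asymptote when old animals are missing from the sample.")
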