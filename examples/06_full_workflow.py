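"""End-to-end three-step workflow on a synthetic four-species bundle.

Generates size-at-age data for all four species presets plus a reader
matrix, writes them as CSV, and runs the full pipeline: readability
filtering, Ford-Walford starts, NLS + AICc ranking, Bayesian 2VBGF fit,
and the precision report.  Outputs land in scratch/example_run/.
"""

from pathlib import Path

from raygrowth import (
    RunConfig,
    SPECIES_PRESETS,
    generate_reader_matrix,
    generate_sample,
    run_full_workflow,
)
from raygrowth.io import write_reader_matrix, write_size_at_age

out = Path("scratch/example_run")
out.mkdir(parents=True, exist_ok=True)

records = []
for i, name in enumerate(sorted(SPECIES_PRESETS)):
    records.extend(generate_sample(SPECIES_PRESETS[name], seed=20 + i))
write_size_at_age(out / "sizes.csv", records)
matrix = generate_reader_matrix([r.age for r in records], epsilon=0.12, seed=20)
write_reader_matrix(out / "reads.csv", matrix)

manifest = run_full_workflow(
    RunConfig(
        size_at_age=str(out / "sizes.csv"),
        reader_matrix=str(out / "reads.csv"),
        mcmc_preset="desk",
        seed=0,
        out_dir=str(out / "results"),
    )
)

print("Bayesian growth-parameter summary (per species):")
print(
    manifest["tables"]["bayes_summary"][
        ["species", "w_inf_median", "w_inf_lo", "w_inf_hi", "k_median", "k_lo", "k_hi"]
    ].to_string(index=False)
)
print(f"\nfiles written: {manifest['outputs']} in {out / 'results'}")
print("Each species row gives the posterior median and 95% credibility")
print("interval for asymptotic disc width (cm) and growth coefficient (yr^-1).")
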