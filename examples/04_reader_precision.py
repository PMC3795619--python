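"""Multi-reader ageing precision: consensus, readability filter, IAPE, CV.

Simulates three blind readers over 120 animals with a 15% chance of a
plus-or-minus one band miscount per read, then computes consensus ages
(two readers must agree), drops unreadable (score 3) animals, and reports
the Beamish-Fournier IAPE and Chang CV precision indices.
"""

import numpy as np

from raygrowth import consensus_age, cv_index, generate_reader_matrix, iape

rng = np.random.default_rng(3)
true_ages = rng.integers(1, 20, size=120).astype(float)
matrix = generate_reader_matrix(true_ages, epsilon=0.15, seed=3)

consensus = [consensus_age(row) for row in matrix.reads]
resolved = sum(1 for c in consensus if c != "unresolved")
readable = matrix.readability != 3

overall_iape, per_iape = iape(matrix, per_reader=True)
overall_cv, per_cv = cv_index(matrix, per_reader=True)

print(f"animals: {len(true_ages)}  consensus reached: {resolved}  "
      f"readability<=2: {int(readable.sum())}")
print(f"IAPE {overall_iape:.2f}%   per reader: "
      + "  ".join(f"{v:.2f}%" for v in per_iape))
print(f"CV   {overall_cv:.2f}%   per reader: "
      + "  ".join(f"{v:.2f}%" for v in per_cv))
print("\nLow IAPE/CV (a few percent) indicates readers rarely disagree by")
print("more than a band; CV is roughly sqrt(2) x IAPE for near-symmetric errors.")
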