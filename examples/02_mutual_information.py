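"""Estimate mutual information between STAT3 expression and phosphorylation.

First validates the KDE + quadrature estimator against the closed form for a
correlated Gaussian pair, then computes MI on synthetic populations: low MI
in unstimulated wildtype cells (phosphorylation decoupled from expression =
robust activation), higher MI at a saturating dose and in the SHP2 mutant.
"""

import numpy as np

from siginfo import (
    SyntheticConfig,
    estimate_mi,
    gaussian_mi_oracle,
    generate_condition,
    log_transform,
)

# estimator vs closed form
rng = np.random.default_rng(1)
rho = 0.718
xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=10_000)
res = estimate_mi(xy[:, 0], xy[:, 1])
print(f"Gaussian pair, rho={rho}: estimated {res.mi_bits:.3f} bits, "
      f"closed form {gaussian_mi_oracle(rho):.3f} bits")

# MI on synthetic populations (log10 intensities)
config = SyntheticConfig(seed=1)
for genotype, dose in (("wt", 0.0), ("wt", 150.0), ("dEx3", 0.0)):
    events = generate_condition(config, genotype, dose, "early", replicate=1)
    logged, _ = log_transform(events)
    mi = estimate_mi(logged["stat3"].to_numpy(), logged["pstat3"].to_numpy())
    print(f"{genotype:>5} at {dose:>5.0f} ng/ml: MI = {mi.mi_bits:.3f} bits")

print("\nLow MI = phosphorylation independent of a cell's STAT3 content "
      "(robust); stimulation and SHP2 loss both couple the two channels.")
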