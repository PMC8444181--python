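# siginfo

Information-theoretic analysis of cytokine signalling in heterogeneous
single-cell populations.

Cells of an isogenic population differ strongly in how much of a signalling
protein they express, and this heterogeneity shapes what a population can
"say" with a pathway. `siginfo` quantifies two complementary properties of
IL-6-type JAK/STAT signalling from multiplexed flow-cytometry event tables
(total STAT3 and phospho-STAT3-Y705 per cell, across cytokine doses,
stimulation times, genotypes and replicates):

* **Robustness** — the mutual information between a cell's STAT3 expression
  *S* and its STAT3-Y705 phosphorylation *R*,

      MI(S;R) = ∬ p(S,R) log₂ [ p(S,R) / (p(S)p(R)) ] dR dS

  estimated by Gaussian kernel density estimation plus numerical quadrature.
  Low MI means the strength of activation does not depend on how much STAT3
  an individual cell happens to contain — activation is *robust* to
  expression heterogeneity.

* **Information transfer** — the channel capacity between the discrete
  cytokine dose ladder S and the continuous phospho-response R,

      CC(S;R) = max_{p(S)} MI(S;R)

  with 2^CC the number of stimulation levels a cell can distinguish. Two
  estimators are provided: Blahut–Arimoto on KDE conditionals, and a
  classifier-based (multinomial-logit) estimator with out-of-fold posteriors
  and Monte-Carlo MI.

* **Statistics** — the replicate-level comparison scheme: per-group
  centring/scaling, Kolmogorov–Smirnov normality check, N-way and 1-way
  ANOVA, and the unbiased Cohen's d

      d_unb = (m_A − m_B) / s_AB,   s_AB = √((SS_A + SS_B)/(df_A + df_B))

  with the two-stage decision rule: a comparison is starred only when
  p ≤ 0.05 **and** |d_unb| > 0.2 (effects graded small/medium/large at
  0.2/0.5/0.8).

Because raw flow data of this kind are rarely public, the package ships a
phenomenological single-cell generator (`siginfo.synthetic`) that emulates
the relevant population structure — dose-independent log-normal STAT3
expression, a Hill-type dose response with a genotype-specific basal floor,
additive background fluorescence and multiplicative measurement noise — so
the entire analysis runs end-to-end without any download. Genotype presets
cover wildtype, a SHP2 loss-of-function mutant (raised basal
phosphorylation), its reconstitution, and MEK-inhibited wildtype.

## Worked example

```python
import pandas as pd
from siginfo import (SyntheticConfig, generate_condition, generate_study,
                     log_transform, estimate_mi,
                     ChannelSamples, capacity_blahut_arimoto)

config = SyntheticConfig(seed=1)

# robustness: MI between log10 expression and log10 phosphorylation
for genotype, dose in (("wt", 0.0), ("wt", 150.0), ("dEx3", 0.0)):
    events = generate_condition(config, genotype, dose, "early", replicate=1)
    logged, _ = log_transform(events)
    mi = estimate_mi(logged["stat3"].to_numpy(), logged["pstat3"].to_numpy())
    print(f"{genotype:>5} at {dose:>5.0f} ng/ml: MI = {mi.mi_bits:.3f} bits")

# information transfer: capacity over the 7-dose ladder, one replicate
study = generate_study(config, presets=["wt"], times=["early"], n_replicates=1)
events = pd.concat(study.values(), ignore_index=True)
cc = capacity_blahut_arimoto(ChannelSamples.from_events(events))
print(f"wt early capacity: {cc.cc_bits:.3f} bits = {cc.n_states:.2f} states")
```

prints

```
   wt at     0 ng/ml: MI = 0.133 bits
   wt at   150 ng/ml: MI = 0.523 bits
 dEx3 at     0 ng/ml: MI = 0.439 bits
wt early capacity: 0.951 bits = 1.93 states
```

Unstimulated wildtype cells show low MI: basal phosphorylation is decoupled
from expression (robust). A saturating dose couples the two channels
(MI 0.52 bits), and losing SHP2 couples them already at dose zero (0.44
bits) — the mutant has lost robustness of basal activation. The capacity of
just under one bit says a single cell can essentially distinguish cytokine
presence from absence; in the SHP2 mutant the raised basal floor narrows the
usable response range and capacity drops (run
`examples/03_channel_capacity.py` and the acceptance script for the
genotype contrast).

The `examples/` directory holds one short script per capability
(simulation, MI, capacity, statistics, full pipeline); each prints the
numbers it computes with a line on what they mean. A thin CLI mirrors the
pipeline stages: `siginfo simulate | mi | capacity | stats | run | convert`.

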