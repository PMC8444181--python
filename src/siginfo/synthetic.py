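"""Phenomenological generator of heterogeneous (STAT3, pSTAT3) cell populations.

The generator emulates the statistical structure of IL-6 trans-signalling
flow-cytometry data in murine fibroblasts:

* STAT3 expression is strongly heterogeneous and *independent of dose*:
  ``E_i = 10**Z_i`` with ``Z_i ~ Normal(mu_E, sigma_E)``, drawn from a
  substream that does not depend on dose, so the same cells are "measured"
  at every concentration of one replicate.
* Phosphorylated STAT3 combines a cytokine-driven component proportional to
  a cell's expression with an additive cytokine-independent background:
  ``P_i = gain * E_i * f(dose) * eps_i + B_i`` where ``eps_i`` is log-normal
  measurement noise and ``B_i = 10**Normal(mu_B, sigma_B)``.
* The phosphorylated fraction follows a Hill dose response with a basal
  floor ``beta`` (cytokine-independent activity) and a late-phase
  attenuation ``delta_late``::

      f(dose) = beta + delta * (1 - beta) * dose**h / (dose**h + K**h)

  with ``delta = 1`` at the early time point (15 min) and ``delta_late`` at
  the late time point (90 min).

Genotypes differ only in the basal floor ``beta``: SHP2 loss-of-function
(``dEx3``) raises basal phosphorylation, reconstitution with wildtype SHP2
(``dEx3_SHP2``) largely restores it, and MEK inhibition (``wt_U0126``) leaves
the wildtype parameters untouched.  Low-dose robustness (low mutual
information between the channels) is emergent: at small ``f`` the additive
background dominates ``pstat3`` and decouples it from ``stat3``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Default Hy-IL-6 dose ladder (ng/ml), log-spaced across the study's range.
DEFAULT_DOSES = (0.0, 1.0, 5.0, 10.0, 25.0, 75.0, 150.0)

#: A dose at the saturated end of the ladder.
SATURATING_DOSE = 150.0

#: Stimulation time in minutes for each named phase.
TIME_MINUTES = {"early": 15, "late": 90}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative-model parameters for one genotype/time population.

    Parameters
    ----------
    mu_E, sigma_E
        Mean and sd of log10 STAT3 expression (a.u. on the log10 scale).
    gain
        Scale linking expression to the phosphorylation signal (a.u.).
    K, h
        Half-maximal Hy-IL-6 dose (ng/ml) and Hill coefficient.
    beta
        Basal (cytokine-independent) phosphorylated fraction, in [0, 1).
    delta_late
        Late-phase attenuation of the induced component, in (0, 1].
    mu_B, sigma_B
        log10 parameters of the additive background fluorescence.
    sigma_eps
        sd (log10 scale) of multiplicative log-normal measurement noise.
    n_cells
        Events per condition-replicate.
    seed
        Master random seed; all condition substreams derive from it.
    """

    mu_E: float = 2.0
    sigma_E: float = 0.3
    gain: float = 1.0
    K: float = 15.0
    h: float = 1.0
    beta: float = 0.02
    delta_late: float = 0.25
    mu_B: float = 0.8
    sigma_B: float = 0.2
    sigma_eps: float = 0.19
    n_cells: int = 6700
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        problems = []
        if not 0 <= self.beta < 1:
            problems.append(f"beta must be in [0, 1), got {self.beta}")
        if not 0 < self.delta_late <= 1:
            problems.append(f"delta_late must be in (0, 1], got {self.delta_late}")
        for name in ("sigma_E", "sigma_B", "sigma_eps"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.K > 0:
            problems.append(f"K must be > 0, got {self.K}")
        if not self.h > 0:
            problems.append(f"h must be > 0, got {self.h}")
        if self.n_cells < 0:
            problems.append(f"n_cells must be >= 0, got {self.n_cells}")
        if problems:
            raise ValidationError("; ".join(problems))
        return self


@dataclass(frozen=True)
class GenotypePreset:
    """A named genotype with parameter overrides (at minimum ``beta``)."""

    name: str
    overrides: Mapping[str, float] = field(default_factory=dict)

    def apply(self, config: SyntheticConfig) -> SyntheticConfig:
        return dataclasses.replace(config, **dict(self.overrides)).validate()


#: Default presets.  Only the basal fraction differs: SHP2 loss raises it,
#: reconstitution largely restores it, MEK inhibition changes nothing.
GENOTYPE_PRESETS: dict[str, GenotypePreset] = {
    "wt": GenotypePreset("wt", {"beta": 0.02}),
    "dEx3": GenotypePreset("dEx3", {"beta": 0.12}),
    "dEx3_SHP2": GenotypePreset("dEx3_SHP2", {"beta": 0.03}),
    "wt_U0126": GenotypePreset("wt_U0126", {"beta": 0.02}),
}

_GENOTYPE_INDEX = {name: i for i, name in enumerate(GENOTYPE_PRESETS)}
_TIME_INDEX = {"early": 0, "late": 1}


def _genotype_key(name: str) -> int:
    """Stable integer stream key for a genotype (custom presets included)."""
    if name in _GENOTYPE_INDEX:
        return _GENOTYPE_INDEX[name]
    import hashlib

    digest = hashlib.sha256(name.encode()).digest()
    return 16 + int.from_bytes(digest[:4], "big") % (2**30)


def _substream(config: SyntheticConfig, *keys: int) -> np.random.Generator:
    """Deterministic per-condition random substream derived from the master seed."""
    ss = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, *[int(k) for k in keys]])
    return np.random.default_rng(ss)


def _expression_stream(config, genotype: str, time: str, replicate: int):
    # No dose key: expression draws are identical across doses by construction.
    return _substream(config, 0, _genotype_key(genotype), _TIME_INDEX[time], replicate)


def _response_stream(config, genotype: str, time: str, replicate: int, dose: float):
    return _substream(
        config, 1, _genotype_key(genotype), _TIME_INDEX[time], replicate,
        int(round(dose * 1_000_000)),
    )


def sample_expression(
    config: SyntheticConfig, n: int, stream: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` per-cell STAT3 expression values ``10**Normal(mu_E, sigma_E)``."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return 10.0 ** stream.normal(config.mu_E, config.sigma_E, size=n)


def response_fraction(dose: float, config: SyntheticConfig, time: str = "early") -> float:
    """Phosphorylated fraction at ``dose``: Hill response on a basal floor.

    Nondecreasing in dose, equal to ``beta`` at dose 0, approaching
    ``beta + delta*(1 - beta)`` at saturation.
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    if time not in TIME_MINUTES:
        raise ValueError(f"time must be one of {sorted(TIME_MINUTES)}, got {time!r}")
    delta = 1.0 if time == "early" else config.delta_late
    hill = 0.0 if dose == 0 else dose**config.h / (dose**config.h + config.K**config.h)
    return config.beta + delta * (1.0 - config.beta) * hill


def generate_condition(
    config: SyntheticConfig,
    genotype: str | GenotypePreset,
    dose: float,
    time: str,
    replicate: int,
) -> pd.DataFrame:
    """Generate one condition-replicate event table.

    Deterministic given ``(config.seed, genotype, dose, time, replicate)``.
    The measured ``stat3`` channel is the latent expression times its own
    log-normal noise draw; ``pstat3`` is the induced component plus additive
    background.
    """
    preset = GENOTYPE_PRESETS[genotype] if isinstance(genotype, str) else genotype
    cfg = preset.apply(config)
    n = cfg.n_cells

    expr = _expression_stream(cfg, preset.name, time, replicate)
    E = sample_expression(cfg, n, expr)
    stat3_noise = 10.0 ** expr.normal(0.0, cfg.sigma_eps, size=n)

    resp = _response_stream(cfg, preset.name, time, replicate, dose)
    eps = 10.0 ** resp.normal(0.0, cfg.sigma_eps, size=n)
    background = 10.0 ** resp.normal(cfg.mu_B, cfg.sigma_B, size=n)

    f = response_fraction(dose, cfg, time)
    pstat3 = cfg.gain * E * f * eps + background

    return pd.DataFrame(
        {
            "cell_index": np.arange(n),
            "stat3": E * stat3_noise,
            "pstat3": pstat3,
            "genotype": preset.name,
            "dose_ng_ml": float(dose),
            "time_min": TIME_MINUTES[time],
            "replicate": int(replicate),
        }
    )


def generate_study(
    config: SyntheticConfig,
    presets: Sequence[str | GenotypePreset] | None = None,
    doses: Sequence[float] = DEFAULT_DOSES,
    times: Sequence[str] = ("early", "late"),
    n_replicates: int = 3,
) -> dict[tuple, pd.DataFrame]:
    """Full factorial study: one event table per (genotype, dose, time, replicate).

    Returns a dict keyed by ``(genotype, dose, time_min, replicate)``.  Each
    condition derives its own substream from the master seed, so any single
    condition can be regenerated in isolation with `generate_condition`.
    """
    if not doses or not times or (presets is not None and not presets):
        raise ValueError("doses, times and presets must be nonempty")
    if presets is None:
        presets = list(GENOTYPE_PRESETS.values())
    presets = [GENOTYPE_PRESETS[p] if isinstance(p, str) else p for p in presets]

    study: dict[tuple, pd.DataFrame] = {}
    for preset in presets:
        for time in times:
            for rep in range(1, n_replicates + 1):
                for dose in doses:
                    key = (preset.name, float(dose), TIME_MINUTES[time], rep)
                    if key in study:
                        raise ValueError(f"duplicate condition key {key}")
                    study[key] = generate_condition(config, preset, dose, time, rep)
    return study


def concat_study(study: Mapping[tuple, pd.DataFrame]) -> pd.DataFrame:
    """Stack a study dict into one long event table."""
    return pd.concat(study.values(), ignore_index=True)
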