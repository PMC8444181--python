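"""Channel capacity between the Hy-IL-6 dose ladder and the pSTAT3 response.

The signalling pathway is treated as a noisy channel: the input S is the
(discrete) stimulation dose, the output R the single-cell log10 pSTAT3
intensity.  Capacity is the maximum of the mutual information over all input
distributions p(S)::

    CC(S; R) = max_{p(S)} MI(S; R)

and ``2**CC`` is the number of input states distinguishable from the
response.  Two estimators are provided:

* `blahut_arimoto` — the classical alternating maximisation on KDE
  conditionals discretised on a shared response grid; its capacity sequence
  is nondecreasing by construction (checked every run).
* `capacity_classifier` — a statistical-learning estimator: a regularised
  multinomial logistic model for P(S | R) fitted with out-of-fold
  posteriors, a Monte-Carlo estimate of MI for given input weights, and the
  same alternating reweighting to maximise over p(S).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .exceptions import DegenerateDataError
from .io_flow import log_transform
from .mi import fit_kde

LOG2 = np.log(2.0)


@dataclass
class ChannelSamples:
    """Per-dose response samples for one (genotype, time, replicate)."""

    input_levels: np.ndarray  # ordered doses, ng/ml
    responses: list  # one array of log10 pSTAT3 values per level
    condition: tuple | None = None

    def __post_init__(self):
        self.input_levels = np.asarray(self.input_levels, dtype=float)
        if len(self.input_levels) < 2:
            raise ValueError("need >= 2 input levels")
        if len(np.unique(self.input_levels)) != len(self.input_levels):
            raise ValueError("input levels must be unique")
        if len(self.responses) != len(self.input_levels):
            raise ValueError("one response sample per input level required")
        if any(len(r) == 0 for r in self.responses):
            raise ValueError("every level needs at least one response")

    @classmethod
    def from_events(cls, events: pd.DataFrame, floor: float = 1.0, condition=None):
        """Build from one replicate's event table (log10-transforms pstat3)."""
        logged, _ = log_transform(events, floor=floor, channels=("pstat3",))
        levels, samples = [], []
        for dose, grp in logged.groupby("dose_ng_ml", sort=True):
            levels.append(dose)
            samples.append(grp["pstat3"].to_numpy())
        return cls(np.asarray(levels), samples, condition=condition)


@dataclass(frozen=True)
class CCResult:
    """A channel-capacity estimate in bits, with the optimising input law."""

    cc_bits: float
    optimal_input: np.ndarray
    method: str
    iterations: int
    converged: bool
    input_levels: np.ndarray | None = None
    condition: tuple | None = None
    n: int = 0

    @property
    def n_states(self) -> float:
        return 2.0 ** self.cc_bits


def n_distinguishable_states(result: CCResult) -> float:
    """``2**CC``: the number of input states distinguishable from the response."""
    return 2.0 ** result.cc_bits


def conditional_densities(
    channel: ChannelSamples, grid_size: int = 512, min_samples: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Per-level 1-D Gaussian KDEs evaluated on one shared response grid.

    The grid spans the pooled response range ± 3 maximal bandwidths.  Each
    conditional is renormalised to integrate to one on the grid (trapezoid),
    so truncation cannot bias the capacity estimators.
    """
    kdes = []
    for dose, r in zip(channel.input_levels, channel.responses):
        if len(r) < min_samples:
            raise DegenerateDataError(
                f"dose {dose} ng/ml has {len(r)} < {min_samples} responses"
            )
        kdes.append(fit_kde(r))
    pooled_lo = min(r.min() for r in channel.responses)
    pooled_hi = max(r.max() for r in channel.responses)
    bws = [float(k.bandwidth[0]) for k in kdes]
    pad = 3.0 * max(bws)
    # The grid must resolve the narrowest kernel, else a sharply peaked
    # conditional can be missed entirely between grid points.
    span = (pooled_hi + pad) - (pooled_lo - pad)
    needed = int(np.ceil(span / (min(bws) / 2.0))) + 1
    grid = np.linspace(pooled_lo - pad, pooled_hi + pad, max(grid_size, needed))
    P = np.vstack([k.evaluate(grid) for k in kdes])
    P /= np.trapezoid(P, grid, axis=1)[:, None]
    return grid, P


def mi_for_input(
    weights: np.ndarray, conditionals: np.ndarray, grid: np.ndarray
) -> tuple[float, np.ndarray]:
    """MI in bits for a fixed input distribution, plus per-level divergences.

    Returns ``(MI, D)`` with ``D[s] = KL(p(r|s) || q(r))`` in bits, where
    ``q(r)`` is the output density induced by ``weights``; ``MI = w · D``.
    """
    w = np.asarray(weights, dtype=float)
    q = w @ conditionals
    ratio = np.ones_like(conditionals)
    # densities below ~1e-200 contribute nothing to the KL integral but can
    # underflow q to zero; clamp them out of the integrand
    ok = (conditionals > 1e-200) & (np.broadcast_to(q, conditionals.shape) > 0)
    ratio[ok] = conditionals[ok] / np.broadcast_to(q, conditionals.shape)[ok]
    integrand = np.where(ok, conditionals * np.log2(ratio), 0.0)
    D = np.trapezoid(integrand, grid, axis=1)
    return float(w @ D), D


def blahut_arimoto(
    conditionals: np.ndarray,
    grid: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 10_000,
    condition: tuple | None = None,
    input_levels: np.ndarray | None = None,
    n: int = 0,
) -> CCResult:
    """Capacity of a discrete-input channel by Blahut–Arimoto iteration.

    ``conditionals`` is a ``(k, m)`` array of per-level densities on ``grid``.
    The input law is updated as ``w ∝ w · 2**D`` where ``D`` holds the
    per-level divergences from the induced output; the capacity sequence is
    nondecreasing and iteration stops when it changes by less than ``tol``
    bits.
    """
    P = np.asarray(conditionals, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need a (k >= 2, m) conditional-density array")
    if not np.isfinite(P).all() or (P < 0).any():
        raise ValueError("conditional densities must be finite and nonnegative")
    k = P.shape[0]
    w = np.full(k, 1.0 / k)
    capacity = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_capacity, D = mi_for_input(w, P, grid)
        if new_capacity < capacity - 1e-9:
            raise RuntimeError(
                f"capacity sequence decreased ({capacity:.9f} -> {new_capacity:.9f}); "
                "conditionals are likely ill-conditioned"
            )
        delta = new_capacity - capacity
        capacity = new_capacity
        if delta < tol:
            converged = True
            break
        w = w * np.exp2(D)
        w /= w.sum()
    return CCResult(
        cc_bits=max(capacity, 0.0),
        optimal_input=w,
        method="blahut_arimoto",
        iterations=it,
        converged=converged,
        input_levels=input_levels,
        condition=condition,
        n=n,
    )


def capacity_blahut_arimoto(channel: ChannelSamples, grid_size: int = 512,
                            min_samples: int = 100, **ba_options) -> CCResult:
    """KDE conditionals + Blahut–Arimoto, from raw per-dose samples."""
    grid, P = conditional_densities(channel, grid_size=grid_size, min_samples=min_samples)
    return blahut_arimoto(
        P, grid,
        condition=channel.condition,
        input_levels=channel.input_levels,
        n=sum(len(r) for r in channel.responses),
        **ba_options,
    )


def capacity_classifier(
    channel: ChannelSamples,
    n_folds: int = 10,
    C: float = 1.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_samples: int = 100,
) -> CCResult:
    """Classifier-based capacity estimate from per-dose response samples.

    A multinomial logistic model with quadratic response features estimates
    the posterior P(S | R) out-of-fold (stratified K-fold).  For candidate
    input weights ``w`` the posterior is reweighted from the empirical class
    proportions, MI is the Monte-Carlo average of
    ``log2[P(s_i | r_i) / w(s_i)]`` within each class, and the weights are
    maximised by the same alternating update as Blahut–Arimoto.
    """
    k = len(channel.input_levels)
    counts = np.array([len(r) for r in channel.responses])
    if (counts < max(min_samples, n_folds)).any():
        bad = channel.input_levels[counts < max(min_samples, n_folds)]
        raise DegenerateDataError(
            f"input level(s) {bad} have too few responses for {n_folds}-fold estimation"
        )
    r = np.concatenate(channel.responses)
    y = np.repeat(np.arange(k), counts)
    X = np.column_stack([r, r**2])

    model = make_pipeline(
        StandardScaler(),
        LogisticRegression(C=C, max_iter=2000),
    )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    Q = cross_val_predict(model, X, y, cv=cv, method="predict_proba")
    Q = np.clip(Q, 1e-12, None)
    p_emp = counts / counts.sum()

    class_masks = [y == s for s in range(k)]
    w = np.full(k, 1.0 / k)
    capacity = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        qw = Q * (w / p_emp)[None, :]
        qw /= qw.sum(axis=1, keepdims=True)
        D = np.array(
            [np.mean(np.log2(qw[mask, s] / w[s])) for s, mask in enumerate(class_masks)]
        )
        new_capacity = float(w @ D)
        delta = new_capacity - capacity
        capacity = new_capacity
        if abs(delta) < tol:
            converged = True
            break
        w = w * np.exp2(D)
        w /= w.sum()
    return CCResult(
        cc_bits=max(capacity, 0.0),
        optimal_input=w,
        method="classifier",
        iterations=it,
        converged=converged,
        input_levels=channel.input_levels,
        condition=channel.condition,
        n=int(counts.sum()),
    )


def cc_per_condition(
    study: Mapping[tuple, pd.DataFrame] | pd.DataFrame,
    time: str | int = "early",
    method: str = "ba",
    floor: float = 1.0,
    **options,
) -> pd.DataFrame:
    """One capacity estimate per (genotype, time, replicate).

    Every replicate must contain the study's full dose ladder; a missing dose
    raises an error naming the condition.  ``method`` is ``"ba"`` or
    ``"classifier"``.
    """
    from .synthetic import TIME_MINUTES

    time_min = TIME_MINUTES.get(time, time)
    if isinstance(study, pd.DataFrame):
        events = study
    else:
        events = pd.concat(study.values(), ignore_index=True)
    events = events[events["time_min"] == time_min]
    if len(events) == 0:
        raise ValueError(f"study has no events at time {time!r}")
    ladder = set(events["dose_ng_ml"].unique())

    rows = []
    for (genotype, replicate), grp in events.groupby(["genotype", "replicate"], sort=True):
        cond = (genotype, time_min, replicate)
        missing = ladder - set(grp["dose_ng_ml"].unique())
        if missing:
            raise ValueError(f"condition {cond} is missing dose level(s) {sorted(missing)}")
        channel = ChannelSamples.from_events(grp, floor=floor, condition=cond)
        if method == "ba":
            res = capacity_blahut_arimoto(channel, **options)
        elif method == "classifier":
            res = capacity_classifier(channel, **options)
        else:
            raise ValueError(f"unknown method {method!r}; use 'ba' or 'classifier'")
        rows.append(
            {
                "genotype": genotype,
                "time_min": time_min,
                "replicate": replicate,
                "method": res.method,
                "cc_bits": res.cc_bits,
                "n_states": res.n_states,
                "converged": res.converged,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)
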