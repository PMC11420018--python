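"""Expected symptom activity (ESA) under conditioning of strategy nodes.

The fitted mixed graphical model supplies one linear-Gaussian conditional
per node (symmetric edge weights as coefficients on standardized values,
per-node residual scale).  Strategy nodes are clamped at raw sum-scores and
standardized with the training statistics; the remaining nodes are updated
by single-site Gibbs sampling.  An ordinal symptom's state is kept on its
0-3 code grid: the Gaussian draw is mapped back to the raw scale, rounded
and clipped, and re-standardized before it is used by other conditionals.

ESA is the sum over the 16 symptom nodes of their conditional means on the
0-3 code scale; baseline symptom activity is the same sum either observed in
the sample (primary definition) or simulated from the unclamped model.
Because the unclamped nodes of a fully conditioned network live on a finite
grid, the systematic-scan Gibbs chain is a finite Markov chain, and small
networks admit an exact stationary-distribution computation
(:func:`exact_symptom_means`) used as an oracle for the sampler.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .items import STRATEGIES, strategy_score_range
from .network import WeightedNetwork

#: background sum-scores of the non-swept strategies under each scenario.
SCENARIOS: dict[str, dict[str, int]] = {
    "minimum": {s: strategy_score_range(s)[0] for s in STRATEGIES},
    "median": {
        "suppression": 24,
        "engagement": 24,
        "reappraisal": 24,
        "rumination": 18,
        "arousal_control": 12,
        "distraction": 12,
    },
    "maximum": {s: strategy_score_range(s)[1] for s in STRATEGIES},
}

ORDINAL_MAX = 3


@dataclass
class GibbsSettings:
    """Sampler budget: total retained draws, total burn-in scans (split
    across ``n_chains`` parallel chains) and thinning interval."""

    n_samples: int = 20_000
    burn_in: int = 2_000
    thin: int = 1
    n_chains: int = 20

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.burn_in < 0 or self.thin < 1 or self.n_chains < 1:
            raise ValueError("invalid sampler settings")


def validate_clamp(net: WeightedNetwork, clamp: dict[str, float]) -> None:
    kinds = net.kinds or ["continuous_strategy"] * net.p
    for node, value in clamp.items():
        i = net.index_of(node)
        if kinds[i] == "ordinal_symptom":
            raise ValueError(f"symptom node {node!r} cannot be clamped")
        if node in STRATEGIES:
            lo, hi = strategy_score_range(node)
            if not lo <= value <= hi:
                raise ValueError(f"clamp {node}={value} outside [{lo}, {hi}]")


def _model_arrays(net: WeightedNetwork):
    if net.means is None or net.sds is None or net.residual_sd is None:
        raise ValueError("network lacks training statistics; fit it with estimate_mgm")
    kinds = net.kinds or ["ordinal_symptom"] * net.p
    ordinal = np.array([k == "ordinal_symptom" for k in kinds])
    return net.means, net.sds, net.residual_sd, ordinal


def gibbs_sample_conditional(
    net: WeightedNetwork,
    clamp: dict[str, float],
    settings: GibbsSettings | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Samples of every unclamped node on its raw scale.

    Systematic-scan single-site Gibbs in standardized space over all
    unclamped nodes; clamped nodes stay fixed at their standardized values.
    Ordinal symptom columns come back as 0-3 codes, continuous columns as
    real values.  Deterministic given ``seed``.
    """
    settings = settings or GibbsSettings()
    validate_clamp(net, clamp)
    means, sds, resid_sd, ordinal = _model_arrays(net)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = net.p
    C = settings.n_chains
    W = net.weights

    clamped = np.zeros(p, dtype=bool)
    z0 = np.zeros(p)
    for node, value in clamp.items():
        i = net.index_of(node)
        clamped[i] = True
        z0[i] = (value - means[i]) / sds[i]
    # start unclamped ordinal nodes on the code grid nearest their mean
    for i in range(p):
        if not clamped[i] and ordinal[i]:
            code = float(np.clip(np.rint(means[i]), 0, ORDINAL_MAX))
            z0[i] = (code - means[i]) / sds[i]

    Z = np.tile(z0[:, None], (1, C))
    update_order = [i for i in range(p) if not clamped[i]]

    burn_scans = int(np.ceil(settings.burn_in / C))
    keep_scans = int(np.ceil(settings.n_samples / C)) * settings.thin
    collected = []
    for scan in range(burn_scans + keep_scans):
        for i in update_order:
            mu = W[i] @ Z
            z = mu + resid_sd[i] * rng.standard_normal(C)
            if ordinal[i]:
                y = means[i] + sds[i] * z
                code = np.clip(np.rint(y), 0, ORDINAL_MAX)
                z = (code - means[i]) / sds[i]
            Z[i] = z
        if scan >= burn_scans and (scan - burn_scans) % settings.thin == 0:
            raw = means[update_order, None] + sds[update_order, None] * Z[update_order]
            collected.append(raw.T.copy())

    draws = np.concatenate(collected, axis=0)[: settings.n_samples]
    return pd.DataFrame(draws, columns=[net.node_ids[i] for i in update_order])


def expected_symptom_activity(
    net: WeightedNetwork,
    clamp: dict[str, float],
    settings: GibbsSettings | None = None,
    seed: int | np.random.Generator = 0,
) -> float:
    """Sum over symptom nodes of their conditional mean on the 0-3 scale."""
    samples = gibbs_sample_conditional(net, clamp, settings, seed)
    kinds = net.kinds or ["ordinal_symptom"] * net.p
    symptom_cols = [
        net.node_ids[i]
        for i in range(net.p)
        if kinds[i] == "ordinal_symptom" and net.node_ids[i] in samples.columns
    ]
    return float(samples[symptom_cols].mean(axis=0).sum())


def _ordinal_bin_probs(mean_y: float, sd_y: float) -> np.ndarray:
    """P(code = 0..3) for a rounded, clipped N(mean_y, sd_y) raw draw."""
    bounds = np.array([0.5, 1.5, 2.5])
    cdf = stats.norm.cdf((bounds - mean_y) / sd_y)
    return np.diff(np.concatenate([[0.0], cdf, [1.0]]))


def exact_symptom_means(net: WeightedNetwork, clamp: dict[str, float]) -> pd.Series:
    """Exact stationary symptom means of the discretized Gibbs chain.

    Requires every unclamped node to be ordinal (all strategies clamped) and
    a small state space: the systematic-scan kernel is assembled as a
    product of single-site transition matrices over the joint code grid and
    its stationary distribution solved exactly.  Independent check for
    :func:`gibbs_sample_conditional`.
    """
    validate_clamp(net, clamp)
    means, sds, resid_sd, ordinal = _model_arrays(net)
    p = net.p
    clamped = np.zeros(p, dtype=bool)
    z_clamp = np.zeros(p)
    for node, value in clamp.items():
        i = net.index_of(node)
        clamped[i] = True
        z_clamp[i] = (value - means[i]) / sds[i]
    free = [i for i in range(p) if not clamped[i]]
    if any(not ordinal[i] for i in free):
        raise ValueError("exact enumeration requires all unclamped nodes ordinal")
    if len(free) > 4:
        raise ValueError("state space too large for exact enumeration")

    codes = list(itertools.product(range(ORDINAL_MAX + 1), repeat=len(free)))
    n_states = len(codes)
    z_of_code = {
        (i, c): (c - means[i]) / sds[i] for i in free for c in range(ORDINAL_MAX + 1)
    }

    def state_z(state: tuple[int, ...]) -> np.ndarray:
        z = z_clamp.copy()
        for k, i in enumerate(free):
            z[i] = z_of_code[(i, state[k])]
        return z

    kernel = np.eye(n_states)
    state_index = {s: k for k, s in enumerate(codes)}
    for k_node, i in enumerate(free):
        T = np.zeros((n_states, n_states))
        for s_idx, state in enumerate(codes):
            z = state_z(state)
            mu = float(net.weights[i] @ z - net.weights[i, i] * z[i])
            mean_y = means[i] + sds[i] * mu
            sd_y = sds[i] * resid_sd[i]
            probs = _ordinal_bin_probs(mean_y, sd_y)
            for c in range(ORDINAL_MAX + 1):
                new_state = list(state)
                new_state[k_node] = c
                T[s_idx, state_index[tuple(new_state)]] += probs[c]
        kernel = kernel @ T

    # stationary distribution: solve pi (K - I) = 0 with sum(pi) = 1
    A = np.vstack([kernel.T - np.eye(n_states), np.ones(n_states)])
    b = np.concatenate([np.zeros(n_states), [1.0]])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()

    grid = np.array(codes, dtype=float)
    node_means = grid.T @ pi
    return pd.Series(node_means, index=[net.node_ids[i] for i in free])


@dataclass
class BaselineESA:
    """Baseline symptom activity: observed sum of symptom means (primary)
    and the model-implied value from an unclamped simulation."""

    observed: float
    model_implied: float

    @property
    def discrepancy(self) -> float:
        return self.model_implied - self.observed


def baseline_esa(
    symptom_data: pd.DataFrame,
    net: WeightedNetwork,
    settings: GibbsSettings | None = None,
    seed: int | np.random.Generator = 0,
) -> BaselineESA:
    """Observed and model-implied baseline symptom activity.

    ``symptom_data`` holds the 16 observed symptom columns (0-3 codes); the
    model-implied value reruns the sampler with no node clamped.
    """
    observed = float(symptom_data.mean(axis=0).sum())
    model = expected_symptom_activity(net, {}, settings, seed)
    return BaselineESA(observed=observed, model_implied=model)


@dataclass
class ESAProfile:
    """ESA of one strategy swept over its full sum-score range under one
    background scenario for the other five strategies."""

    strategy: str
    scenario: str
    grid: np.ndarray
    esa_values: np.ndarray
    baseline_esa: float
    background: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.esa_values = np.asarray(self.esa_values, dtype=float)
        if len(self.grid) != len(self.esa_values):
            raise ValueError("grid and esa_values must align")

    @property
    def crossing_point(self) -> int | None:
        return crossing_point(self)

    def to_frame(self) -> pd.DataFrame:
        cross = self.crossing_point
        return pd.DataFrame(
            {
                "strategy": self.strategy,
                "scenario": self.scenario,
                "sum_score": self.grid,
                "esa": self.esa_values,
                "baseline_esa": self.baseline_esa,
                "crossing_point": np.nan if cross is None else cross,
            }
        )


def crossing_point(profile: ESAProfile) -> int | None:
    """Smallest swept sum-score whose ESA strictly exceeds baseline."""
    above = profile.esa_values > profile.baseline_esa
    if not above.any():
        return None
    return int(profile.grid[int(np.argmax(above))])


def esa_scenario_sweep(
    net: WeightedNetwork,
    strategy: str,
    scenario: str,
    baseline: float,
    settings: GibbsSettings | None = None,
    seed: int = 0,
) -> ESAProfile:
    """Sweep one strategy over its range with the others held at the
    scenario's background sum-scores, computing ESA at each grid value."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    background = {
        s: v
        for s, v in SCENARIOS[scenario].items()
        if s != strategy and s in net.node_ids
    }
    lo, hi = strategy_score_range(strategy)
    grid = np.arange(lo, hi + 1)
    children = np.random.SeedSequence(seed).spawn(len(grid))
    esa_values = np.empty(len(grid), dtype=float)
    for g, value in enumerate(grid):
        clamp = {strategy: float(value), **background}
        rng = np.random.default_rng(children[g])
        esa_values[g] = expected_symptom_activity(net, clamp, settings, rng)
    return ESAProfile(
        strategy=strategy,
        scenario=scenario,
        grid=grid,
        esa_values=esa_values,
        baseline_esa=baseline,
        background=background,
    )
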