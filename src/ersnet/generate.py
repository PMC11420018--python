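"""Synthetic item-level data with the structure the network analysis assumes.

The study's participant data are not publicly deposited, so analyses are run
on synthetic samples that emulate their documented structure:

* 38 strategy items loading on six correlated latent strategy factors
  (pairwise factor correlation +0.3), discretized to 1-5 Likert codes;
* 16 symptom items generated from a latent Gaussian whose precision matrix
  carries positive within-instrument partial associations plus a fixed set of
  signed strategy-symptom cross-links (e.g. rumination-uncontrollable worry
  positive, reappraisal-hopelessness negative), discretized to 0-3 codes with
  right-skewed marginals typical of a community sample.

Symptom thresholds are calibrated so the expected per-item severity is about
0.92 on the 0-3 scale, putting the sum of the 16 symptom means near 14.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .items import (
    GAD7_ITEMS,
    PHQ9_ITEMS,
    STRATEGIES,
    STRATEGY_LAYOUT,
    SYMPTOMS,
    ItemResponseMatrix,
    default_items,
)

#: (strategy, symptom, sign) cross-links planted in the latent precision.
DEFAULT_CROSS_LINKS: tuple[tuple[str, str, int], ...] = (
    ("rumination", "uncontrollable_worry", +1),
    ("suppression", "low_self_esteem", +1),
    ("arousal_control", "fatigue", +1),
    ("arousal_control", "restlessness", +1),
    ("arousal_control", "excessive_worry", +1),
    ("reappraisal", "hopelessness", -1),
    ("reappraisal", "fatigue", -1),
    ("reappraisal", "low_self_esteem", -1),
    ("reappraisal", "uncontrollable_worry", -1),
    ("reappraisal", "irritability", -1),
    ("engagement", "fatigue", -1),
    ("distraction", "low_self_esteem", -1),
    ("distraction", "suicidal_ideation", -1),
    ("rumination", "restlessness", -1),
)

DEFAULT_CROSS_MAGNITUDE = 0.25

#: cumulative probabilities defining the Likert thresholds.  Strategy items
#: are roughly bell-shaped on 1-5; symptom items are right-skewed on 0-3 with
#: mean 0.92 (0.42/0.33/0.16/0.09 across codes 0..3).
RESS_CUM_PROBS = (0.10, 0.35, 0.70, 0.90)
SYMPTOM_CUM_PROBS = (0.42, 0.75, 0.91)


def default_cross_edges(
    magnitude: float = DEFAULT_CROSS_MAGNITUDE,
) -> list[tuple[str, str, int, float]]:
    return [(s, y, sign, magnitude) for s, y, sign in DEFAULT_CROSS_LINKS]


@dataclass
class GeneratorConfig:
    """Tunable structure of the synthetic sample.

    Parameters
    ----------
    n
        Number of participants (study sample size 376).
    loading
        Standardized loading of every strategy item on its factor, in (0, 1).
    strategy_intercorrelation
        Target pairwise correlation among the six latent strategy factors.
    planted_cross_edges
        (strategy, symptom, sign, magnitude) tuples; each becomes a latent
        partial correlation of ``sign * magnitude``.
    within_symptom_edge
        Latent partial correlation between any two symptoms of the same
        instrument.
    seed
        Single integer source of all randomness.
    """

    n: int = 376
    loading: float = 0.7
    strategy_intercorrelation: float = 0.3
    planted_cross_edges: list[tuple[str, str, int, float]] = field(
        default_factory=default_cross_edges
    )
    within_symptom_edge: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"n must be positive, got {self.n}")
        if not 0.0 < self.loading < 1.0:
            raise ValueError(f"loading must be in (0, 1), got {self.loading}")
        for s, y, sign, mag in self.planted_cross_edges:
            if sign not in (-1, +1):
                raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}")
            if y not in SYMPTOMS:
                raise ValueError(f"unknown symptom {y!r}")
            if mag < 0:
                raise ValueError("edge magnitude must be non-negative")


def latent_precision(config: GeneratorConfig) -> tuple[np.ndarray, list[str]]:
    """Precision matrix of the 22 latent variables (6 factors + 16 symptoms).

    The strategy block uses the off-diagonal precision value whose inverse
    yields the requested equicorrelation r among the six factors in
    isolation, p = r / (1 + 4 r).  Cross-links and within-instrument blocks
    enter directly as partial correlations (precision entry -rho).
    """
    order = list(STRATEGIES) + list(SYMPTOMS)
    idx = {name: i for i, name in enumerate(order)}
    K = np.eye(22)

    r = config.strategy_intercorrelation
    p = r / (1.0 + 4.0 * r)
    for a in range(6):
        for b in range(a + 1, 6):
            K[a, b] = K[b, a] = -p

    w = config.within_symptom_edge
    for block in (PHQ9_ITEMS, GAD7_ITEMS):
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                a, b = idx[block[i]], idx[block[j]]
                K[a, b] = K[b, a] = -w

    for strategy, symptom, sign, mag in config.planted_cross_edges:
        a, b = idx[strategy], idx[symptom]
        K[a, b] = K[b, a] = -sign * mag

    eigmin = float(np.linalg.eigvalsh(K).min())
    if eigmin <= 1e-8:
        raise ValueError(
            f"latent precision not positive definite (min eigenvalue {eigmin:.3g});"
            " reduce edge magnitudes"
        )
    return K, order


def _discretize(z: np.ndarray, cum_probs: tuple[float, ...], offset: int) -> np.ndarray:
    """Threshold standard-normal latents into integer codes offset..offset+k."""
    thresholds = stats.norm.ppf(cum_probs)
    return offset + np.searchsorted(thresholds, z, side="left").astype(np.int64)


def generate_dataset(config: GeneratorConfig) -> ItemResponseMatrix:
    """Draw one synthetic participants x 54 item response matrix.

    Latents are sampled from N(0, K^-1) with K from :func:`latent_precision`
    and rescaled to unit marginal variance; strategy items add independent
    measurement noise before thresholding.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    K, order = latent_precision(config)
    cov = np.linalg.inv(K)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    chol = np.linalg.cholesky(corr)
    latent = rng.standard_normal((config.n, 22)) @ chol.T

    lam = config.loading
    noise_sd = np.sqrt(1.0 - lam**2)
    columns: list[np.ndarray] = []
    for k, (strategy, (_, n_items)) in enumerate(STRATEGY_LAYOUT.items()):
        factor = latent[:, k]
        for _ in range(n_items):
            raw = lam * factor + noise_sd * rng.standard_normal(config.n)
            columns.append(_discretize(raw, RESS_CUM_PROBS, offset=1))
    for j in range(16):
        columns.append(_discretize(latent[:, 6 + j], SYMPTOM_CUM_PROBS, offset=0))

    values = np.column_stack(columns)
    return ItemResponseMatrix(values=values, items=default_items())
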