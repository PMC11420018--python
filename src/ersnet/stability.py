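"""Case-dropping bootstrap and the correlation-stability (CS) coefficient.

For each drop proportion q, subsamples of ceil((1-q) n) rows are drawn
without replacement, the network statistic (node strength or vectorized edge
weights) is re-estimated from scratch, and correlated with the full-sample
statistic.  CS is the largest q at which at least 95% of replicates reach
correlation 0.7 with the full-sample value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

DEFAULT_DROP_PROPORTIONS = tuple(
    float(q) for q in np.round(np.arange(0.10, 0.751, 0.05), 2)
)


@dataclass
class StabilitySettings:
    drop_proportions: Sequence[float] = DEFAULT_DROP_PROPORTIONS
    replicates: int = 500
    cor_threshold: float = 0.7
    prob: float = 0.95
    min_rows: int = 23  # smallest subsample the estimator can be refit on


@dataclass
class BootstrapResult:
    statistic: str
    settings: StabilitySettings
    correlations: dict[float, np.ndarray]  # drop proportion -> replicate corr
    cs_coefficient: float
    skipped_proportions: list[float] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        """Mean and 2.5/97.5% quantile correlation per drop proportion."""
        rows = []
        for q, corr in sorted(self.correlations.items()):
            rows.append(
                {
                    "drop_proportion": q,
                    "mean_cor": float(np.mean(corr)),
                    "q025": float(np.quantile(corr, 0.025)),
                    "q975": float(np.quantile(corr, 0.975)),
                    "prop_above_threshold": float(
                        np.mean(corr >= self.settings.cor_threshold)
                    ),
                }
            )
        return pd.DataFrame(rows)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cs_coefficient(
    correlations: dict[float, np.ndarray],
    threshold: float = 0.7,
    prob: float = 0.95,
) -> float:
    """Largest drop proportion with >= ``prob`` of replicates >= ``threshold``.

    Returns 0.0 when no evaluated proportion qualifies.
    """
    if not correlations:
        raise ValueError("no drop proportions evaluated")
    qualifying = [
        q
        for q, corr in correlations.items()
        if np.mean(np.asarray(corr) >= threshold) >= prob
    ]
    return max(qualifying) if qualifying else 0.0


def case_dropping_bootstrap(
    data: pd.DataFrame,
    estimator: Callable[[pd.DataFrame], np.ndarray],
    settings: StabilitySettings | None = None,
    seed: int = 0,
    statistic: str = "strength",
) -> BootstrapResult:
    """Case-dropping bootstrap of a deterministic ``data -> vector`` estimator.

    Proportions whose subsample would fall below ``settings.min_rows`` are
    skipped and recorded in ``skipped_proportions``.  Deterministic given
    ``seed``.
    """
    settings = settings or StabilitySettings()
    rng = np.random.default_rng(seed)
    n = len(data)
    full = np.asarray(estimator(data), dtype=float)

    correlations: dict[float, np.ndarray] = {}
    skipped: list[float] = []
    for q in settings.drop_proportions:
        size = int(np.ceil((1.0 - q) * n))
        if size < settings.min_rows:
            skipped.append(float(q))
            continue
        corr = np.empty(settings.replicates)
        for r in range(settings.replicates):
            rows = rng.choice(n, size=size, replace=False)
            sub = np.asarray(estimator(data.iloc[rows].reset_index(drop=True)), dtype=float)
            corr[r] = _safe_corr(full, sub)
        correlations[float(q)] = corr

    cs = cs_coefficient(correlations, settings.cor_threshold, settings.prob)
    return BootstrapResult(
        statistic=statistic,
        settings=settings,
        correlations=correlations,
        cs_coefficient=cs,
        skipped_proportions=skipped,
    )
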