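"""Item and node metadata for the strategy/symptom battery.

The battery has 54 items: 38 emotion-regulation items (six subscales, coded
1-5), nine depression items (coded 0-3) and seven anxiety items (coded 0-3).
Strategy sum-scores and symptom items together form the 22-node network
(6 continuous strategy nodes + 16 ordinal symptom nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESS = "RESS"
PHQ9 = "PHQ9"
GAD7 = "GAD7"

#: subscale -> (prefix, number of items); sum-score ranges follow from the
#: 1-5 item coding: 8 items -> 8..40, 6 -> 6..30, 4 -> 4..20.
STRATEGY_LAYOUT: dict[str, tuple[str, int]] = {
    "suppression": ("sup", 8),
    "engagement": ("eng", 8),
    "reappraisal": ("rea", 8),
    "rumination": ("rum", 6),
    "arousal_control": ("aro", 4),
    "distraction": ("dis", 4),
}

STRATEGIES = tuple(STRATEGY_LAYOUT)

PHQ9_ITEMS = (
    "interest_loss",
    "hopelessness",
    "sleep",
    "fatigue",
    "appetite",
    "low_self_esteem",
    "concentration",
    "psychomotor",
    "suicidal_ideation",
)

GAD7_ITEMS = (
    "nervousness",
    "uncontrollable_worry",
    "excessive_worry",
    "trouble_relaxing",
    "restlessness",
    "irritability",
    "fear_awful",
)

SYMPTOMS = PHQ9_ITEMS + GAD7_ITEMS


@dataclass(frozen=True)
class ItemMeta:
    """One questionnaire item: identity, instrument, subscale and legal range."""

    item_id: str
    instrument: str  # RESS | PHQ9 | GAD7
    subscale: str  # strategy name for RESS items, else the instrument name
    min_code: int
    max_code: int

    def __post_init__(self) -> None:
        if self.instrument == RESS and (self.min_code, self.max_code) != (1, 5):
            raise ValueError(f"RESS item {self.item_id} must be coded 1-5")
        if self.instrument in (PHQ9, GAD7) and (self.min_code, self.max_code) != (0, 3):
            raise ValueError(f"symptom item {self.item_id} must be coded 0-3")


def default_items() -> list[ItemMeta]:
    """The 54-item default layout: 38 strategy items then 16 symptom items."""
    items: list[ItemMeta] = []
    for strategy, (prefix, k) in STRATEGY_LAYOUT.items():
        for i in range(1, k + 1):
            items.append(ItemMeta(f"{prefix}{i}", RESS, strategy, 1, 5))
    for name in PHQ9_ITEMS:
        items.append(ItemMeta(name, PHQ9, PHQ9, 0, 3))
    for name in GAD7_ITEMS:
        items.append(ItemMeta(name, GAD7, GAD7, 0, 3))
    return items


@dataclass
class ItemResponseMatrix:
    """Complete participants x items integer response grid.

    Every cell must lie inside its item's legal range; missing responses are
    not representable (complete-data contract).
    """

    values: np.ndarray  # (n, n_items) integer
    items: list[ItemMeta] = field(default_factory=default_items)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.items):
            raise ValueError(
                f"values has shape {self.values.shape}, expected (n, {len(self.items)})"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(self.values == np.round(self.values)):
                raise ValueError("responses must be integers")
            self.values = self.values.astype(np.int64)
        self.validate()

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def item_ids(self) -> list[str]:
        return [m.item_id for m in self.items]

    def validate(self) -> None:
        for j, meta in enumerate(self.items):
            col = self.values[:, j]
            bad = (col < meta.min_code) | (col > meta.max_code)
            if bad.any():
                row = int(np.argmax(bad))
                raise ValueError(
                    f"item {meta.item_id!r}, participant row {row}: code "
                    f"{int(col[row])} outside [{meta.min_code}, {meta.max_code}]"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.item_ids)

    def subset(self, item_ids: list[str]) -> np.ndarray:
        index = {m.item_id: j for j, m in enumerate(self.items)}
        missing = [i for i in item_ids if i not in index]
        if missing:
            raise KeyError(f"items not present: {missing}")
        return self.values[:, [index[i] for i in item_ids]]

    def ress_matrix(self) -> pd.DataFrame:
        ids = [m.item_id for m in self.items if m.instrument == RESS]
        return pd.DataFrame(self.subset(ids), columns=ids)

    def symptom_matrix(self) -> pd.DataFrame:
        ids = [m.item_id for m in self.items if m.instrument in (PHQ9, GAD7)]
        return pd.DataFrame(self.subset(ids), columns=ids)


def strategy_score_range(strategy: str) -> tuple[int, int]:
    """Sum-score range of a strategy subscale (e.g. suppression -> (8, 40))."""
    _, k = STRATEGY_LAYOUT[strategy]
    return k, 5 * k


def score_subscales(data: ItemResponseMatrix) -> pd.DataFrame:
    """Sum each strategy's items into a participants x 6 sum-score table."""
    scores = {}
    for strategy, (prefix, k) in STRATEGY_LAYOUT.items():
        ids = [f"{prefix}{i}" for i in range(1, k + 1)]
        scores[strategy] = data.subset(ids).sum(axis=1)
    return pd.DataFrame(scores)


@dataclass(frozen=True)
class NodeMeta:
    """One node of the 22-node strategy/symptom network."""

    node_id: str
    kind: str  # continuous_strategy | ordinal_symptom
    group: str  # ER | depression | anxiety
    value_range: tuple[float, float]


def default_nodes() -> list[NodeMeta]:
    """6 strategy + 9 depression + 7 anxiety nodes, in network order."""
    nodes = [
        NodeMeta(s, "continuous_strategy", "ER", strategy_score_range(s))
        for s in STRATEGIES
    ]
    nodes += [NodeMeta(s, "ordinal_symptom", "depression", (0, 3)) for s in PHQ9_ITEMS]
    nodes += [NodeMeta(s, "ordinal_symptom", "anxiety", (0, 3)) for s in GAD7_ITEMS]
    return nodes


def network_table(data: ItemResponseMatrix) -> pd.DataFrame:
    """Participants x 22 table: strategy sum-scores then symptom codes."""
    scores = score_subscales(data)
    symptoms = data.symptom_matrix()
    return pd.concat([scores, symptoms], axis=1)
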