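"""Readers and writers: item CSVs with strict validation, network edge
lists, GraphML, and the tidy report tables.

All floating-point outputs use six decimals so repeated runs with the same
configuration and seed produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .items import ItemMeta, ItemResponseMatrix, default_items
from .network import CommunityPartition, WeightedNetwork

FLOAT_FORMAT = "%.6f"


def write_item_csv(data: ItemResponseMatrix, path) -> None:
    data.to_frame().to_csv(path, index=False)


def read_item_csv(path, items: list[ItemMeta] | None = None) -> ItemResponseMatrix:
    """Read a participants x items CSV against the expected item layout.

    Raises on missing/extra columns, missing cells and out-of-range codes
    (the analysis assumes complete data), naming the offending row/column.
    """
    items = items or default_items()
    frame = pd.read_csv(path)
    expected = [m.item_id for m in items]
    missing = [c for c in expected if c not in frame.columns]
    extra = [c for c in frame.columns if c not in expected]
    if missing or extra:
        raise ValueError(
            f"item schema mismatch: missing columns {missing}, unexpected columns {extra}"
        )
    frame = frame[expected]
    if frame.isna().any().any():
        col = frame.columns[frame.isna().any().to_numpy().argmax()]
        row = int(frame[col].isna().to_numpy().argmax())
        raise ValueError(f"missing cell at row {row}, item {col!r}; data must be complete")
    return ItemResponseMatrix(values=frame.to_numpy(), items=items)


def write_item_meta(items: list[ItemMeta], path) -> None:
    payload = [
        {
            "item_id": m.item_id,
            "instrument": m.instrument,
            "subscale": m.subscale,
            "min_code": m.min_code,
            "max_code": m.max_code,
        }
        for m in items
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_item_meta(path) -> list[ItemMeta]:
    payload = json.loads(Path(path).read_text())
    return [ItemMeta(**entry) for entry in payload]


def write_edges_csv(net: WeightedNetwork, path) -> None:
    net.edge_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def network_to_graphml(net: WeightedNetwork, path) -> None:
    g = nx.Graph()
    for i, node in enumerate(net.node_ids):
        attrs = {}
        if net.kinds is not None:
            attrs["kind"] = net.kinds[i]
        if net.groups is not None:
            attrs["group"] = net.groups[node]
        g.add_node(node, **attrs)
    for _, row in net.edge_frame().iterrows():
        g.add_edge(row["node_a"], row["node_b"], weight=float(row["weight"]))
    nx.write_graphml(g, path)


def write_partition_csv(partition: CommunityPartition, path) -> None:
    frame = pd.DataFrame(
        sorted(partition.assignment.items()), columns=["node_id", "community"]
    )
    frame.to_csv(path, index=False)


def round_floats(obj, decimals: int = 6):
    """Recursively round floats in a JSON-like structure."""
    if isinstance(obj, float):
        return round(obj, decimals)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), decimals)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, dict):
        return {k: round_floats(v, decimals) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, decimals) for v in obj]
    return obj


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(round_floats(payload), indent=1, sort_keys=True) + "\n")
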