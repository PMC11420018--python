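"""Mixed graphical model over strategies and symptoms.

Fits the 22-node network (6 continuous strategy sum-scores + 16 ordinal
symptom items) by nodewise cross-validated lasso regressions and reports
edge counts, density and the recovered strategy-symptom links.

Reads results/item_responses.csv; writes results/mgm_edges.csv,
results/mgm_network.graphml and results/global_properties.json.
"""

from pathlib import Path

import ersnet as e
from ersnet.io import network_to_graphml, read_item_csv, write_edges_csv, write_json

OUT = Path(__file__).resolve().parents[1] / "results"
CV_SEED = 20260927

def main() -> None:
    data = read_item_csv(OUT / "item_responses.csv")
    table = e.network_table(data)
    net = e.estimate_mgm(table, e.default_nodes(), e.EstimationSettings(cv_seed=CV_SEED))

    write_edges_csv(net, OUT / "mgm_edges.csv")
    network_to_graphml(net, OUT / "mgm_network.graphml")
    props = e.global_properties(net)
    write_json(props.to_dict(), OUT / "global_properties.json")

    print(f"mixed graphical model: {props.n_edges} edges "
          f"({props.n_negative_edges} negative), density {props.density:.3f}")
    print(f"average path length {props.average_path_length:.3f}, "
          f"transitivity {props.transitivity:.3f}, "
          f"clustering coefficient {props.clustering_coefficient:.3f}")
    edges = net.edge_frame()
    cross = edges[
        edges.apply(
            lambda r: (r.node_a in e.STRATEGIES) != (r.node_b in e.STRATEGIES), axis=1
        )
    ]
    print(f"strategy-symptom links ({len(cross)}):")
    for _, r in cross.sort_values("weight").iterrows():
        print(f"  {r.node_a:>16s} -- {r.node_b:<20s} {r.weight:+.3f}")

if __name__ == "__main__":
    main()
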