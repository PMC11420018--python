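"""Exploratory graph analysis of the 38 strategy items.

Estimates the EBIC-glasso partial-correlation network of the raw item
scores and reads the strategy structure off its walktrap communities; with
six well-separated subscales the expected result is six communities that
coincide with the generating subscales.

Reads results/item_responses.csv; writes results/ega_edges.csv and
results/ega_communities.csv.
"""

from pathlib import Path

import ersnet as e
from ersnet.io import read_item_csv, write_edges_csv, write_partition_csv

OUT = Path(__file__).resolve().parents[1] / "results"

def main() -> None:
    data = read_item_csv(OUT / "item_responses.csv")
    corr = e.correlation_matrix(data.ress_matrix(), method="pearson")
    net = e.ebic_glasso(corr, n=data.n)
    partition = e.walktrap_communities(net)

    write_edges_csv(net, OUT / "ega_edges.csv")
    write_partition_csv(partition, OUT / "ega_communities.csv")

    print(f"item network: {net.n_edges} edges over {net.p} items")
    print(f"walktrap communities: {partition.n_communities}")
    by_community: dict[int, list[str]] = {}
    for item, c in partition.assignment.items():
        by_community.setdefault(c, []).append(item)
    for c, items in sorted(by_community.items()):
        print(f"  community {c}: {', '.join(sorted(items))}")

if __name__ == "__main__":
    main()
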