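"""Node-level influence measures on the estimated network: one-step
expected influence (EI) for central symptoms and bridge expected influence
(BEI) for symptoms connecting the PTS and PTG clusters.  Writes the node
metrics table and prints the rankings."""

from pathlib import Path

import pandas as pd

from symptomnet.centrality import centrality_table, rank_nodes
from symptomnet.pipeline import write_node_metrics

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    adj = pd.read_csv(ROOT / "network" / "adjacency.tsv", sep="\t",
                      index_col=0)
    communities = ["PTS" if lb.startswith("PTS") else "PTG"
                   for lb in adj.index]
    table = centrality_table(adj.values, list(adj.index), communities)
    out = ROOT / "network"
    write_node_metrics(table, out / "node_metrics.tsv")

    ei_order, ei_ties = rank_nodes(table, "ei")
    print("expected influence (descending):")
    for lb in ei_order[:5]:
        print(f"  {lb:6s} EI {table.loc[lb, 'ei']:+.2f}")
    if ei_ties:
        print("  (ties broken lexicographically)")

    bei = table["bei"]
    print(f"strongest positive bridge: {bei.idxmax()} "
          f"(BEI {bei.max():+.2f})")
    print(f"strongest negative bridge: {bei.idxmin()} "
          f"(BEI {bei.min():+.2f})")
    print(f"wrote {out / 'node_metrics.tsv'}")


if __name__ == "__main__":
    main()
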