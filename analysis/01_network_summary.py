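#!/usr/bin/env python
"""Load the packaged B-cell network and summarize its structure.

Writes the signed interaction list and network exports (SIF, GraphML,
DOT, SBML-qual, BoolNet text) under results/network/.
"""

from pathlib import Path

import pandas as pd

from bcellfate import extract_interactions, load_bcell_network
from bcellfate.io import write_dot, write_graphml, write_network, write_sbml_qual, write_sif

OUT = Path(__file__).resolve().parent.parent / "results" / "network"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    net = load_bcell_network()
    edges = extract_interactions(net)
    inputs = set(net.input_names)
    core = [n.name for n in net.nodes if n.category.value == "core"]

    print(f"nodes: {net.n_nodes} ({len(net.rules)} ruled + {len(inputs)} environment inputs)")
    print(f"core module: {', '.join(core)}")
    print(f"signed interactions: {len(edges)} "
          f"({sum(e.sign.value == 'positive' for e in edges)} positive, "
          f"{sum(e.sign.value == 'negative' for e in edges)} negative)")
    preds = [("Pax5", "Bcl6"), ("Irf4", "Pax5"), ("Bcl6", "Bcl6"), ("Pax5", "Pax5")]
    present = [(s, t) for s, t in preds if any(e.source == s and e.target == t for e in edges)]
    print(f"model-predicted interactions present: {present}")

    pd.DataFrame(
        [{"source": e.source, "target": e.target, "sign": e.sign.value} for e in edges]
    ).to_csv(OUT / "interactions.csv", index=False)
    write_sif(net, OUT / "bcell.sif")
    write_graphml(net, OUT / "bcell.graphml")
    write_dot(net, OUT / "bcell.dot")
    write_sbml_qual(net, OUT / "bcell.sbml")
    write_network(net, OUT / "bcell.bnet")
    print(f"wrote exports to {OUT}")


if __name__ == "__main__":
    main()
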