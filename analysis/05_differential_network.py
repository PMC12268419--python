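#!/usr/bin/env python
"""Differential network analysis: delta centrality, toxicant nexus, and
proximity-ranked enrichment.

Compares the two condition networks node by node (absent nodes contribute
centrality zero), flags |delta| > 0.1 features, selects nexus chemicals by
the three-criteria rule (toxicant-annotated, more abundant in cases at
p < 0.05, delta centrality > 0.1), and runs preranked GSEA on transcript
delta centralities and on signed proximity weights to the nexus chemicals.
"""

from pathlib import Path

import pandas as pd

from isletnet.diffnet import (
    centrality_ranked_enrichment,
    delta_centrality,
    proximity_weights,
    toxicant_nexus,
)
from isletnet.gsea import parse_gmt
from isletnet.network import AssociationNetwork
import igraph as ig

STUDY = Path("results/study")
NET = Path("results/networks")
OUT = Path("results/diffnet")
SEED = 1


def load_network(condition: str) -> AssociationNetwork:
    g = ig.Graph.Read_GraphML(str(NET / f"network_{condition}.graphml"))
    return AssociationNetwork(graph=g, condition=condition)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    nets = {c: load_network(c) for c in ("case", "control")}
    tables = {c: n.nodes_table() for c, n in nets.items()}
    layers = pd.concat([t["layer"] for t in tables.values()])
    layers = layers[~layers.index.duplicated()]
    delta = delta_centrality(tables["case"]["centrality"], tables["control"]["centrality"],
                             layers=layers)
    delta.to_csv(OUT / "delta_centrality.tsv", sep="\t")
    changed = delta[delta["changed"]]
    print(f"{len(changed)} / {len(delta)} nodes with |delta centrality| > 0.1 "
          f"({changed.groupby('layer').size().to_dict()})")

    diff = pd.read_csv("results/differential/differential_metabolite.tsv", sep="\t", index_col=0)
    tox = pd.read_csv("results/pathways/annotations_toxicant.tsv", sep="\t")
    nexus = toxicant_nexus(delta, diff, tox)
    nexus.to_csv(OUT / "toxicant_nexus.tsv", sep="\t")
    truth = pd.read_csv(STUDY / "truth_toxicants.tsv", sep="\t")["feature_id"]
    print(f"nexus chemicals: {nexus.index.tolist()} (planted: {truth.tolist()})")

    sets = parse_gmt(STUDY / "gene_sets.gmt")
    gsea_delta = centrality_ranked_enrichment(delta, sets, layer="rna", n_perm=1000, seed=SEED)
    gsea_delta.to_csv(OUT / "gsea_delta_centrality_rna.tsv", sep="\t")
    top = gsea_delta.sort_values("p_adj").head(3)
    print("top delta-centrality transcript sets:")
    print(top[["size", "es", "p_adj"]].to_string())

    prox = proximity_weights(nets["case"], nexus.index)
    prox.to_frame().to_csv(OUT / "proximity_weights.tsv", sep="\t")
    prox_table = pd.DataFrame({"delta": prox, "layer": layers.reindex(prox.index)})
    gsea_prox = centrality_ranked_enrichment(prox_table, sets, layer="rna",
                                             n_perm=1000, seed=SEED)
    gsea_prox.to_csv(OUT / "gsea_proximity_rna.tsv", sep="\t")
    print("top toxicant-proximity transcript sets:")
    print(gsea_prox.sort_values("p_adj").head(3)[["size", "es", "p_adj"]].to_string())


if __name__ == "__main__":
    main()
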