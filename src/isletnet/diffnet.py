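"""Differential network analysis: delta centrality, centrality-ranked
enrichment, and the hazardous-chemical (toxicant) nexus procedure.

Condition networks generally have different node sets; a node absent from
one network contributes centrality zero there.  Nodes with |delta| > 0.1 are
flagged as changed.  Nexus chemicals are metabolomic features that are (i)
annotated against the toxicant mass table, (ii) more abundant in cases (raw
p < 0.05 with case mean above control), and (iii) more central in the case
network (delta centrality > 0.1).  Per-node proximity weights are the signed
sum of direct case-network edge weights to nexus chemicals; ranked
enrichment on those weights reads out the processes linked to the chemicals
(negative weights preserving inverse associations).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ValidationError
from .gsea import preranked_gsea
from .network import AssociationNetwork

__all__ = [
    "delta_centrality",
    "centrality_ranked_enrichment",
    "toxicant_nexus",
    "proximity_weights",
    "DELTA_THRESHOLD",
    "NEXUS_ALPHA",
]

logger = logging.getLogger(__name__)

DELTA_THRESHOLD = 0.1
NEXUS_ALPHA = 0.05


def delta_centrality(
    case: pd.Series,
    control: pd.Series,
    layers: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-node case-minus-control eigenvector centrality.

    Takes node -> centrality Series for each condition; the union of node
    ids is used, absent nodes contributing 0.  Returns a table with
    ``c_case``, ``c_control``, ``delta`` and ``changed`` (|delta| > 0.1),
    plus ``layer`` when provided.
    """
    if case.empty and control.empty:
        raise ValidationError("both centrality tables are empty")
    nodes = sorted(set(case.index) | set(control.index))
    c1 = case.reindex(nodes).fillna(0.0)
    c0 = control.reindex(nodes).fillna(0.0)
    out = pd.DataFrame({"c_case": c1, "c_control": c0})
    out["delta"] = out["c_case"] - out["c_control"]
    out["changed"] = out["delta"].abs() > DELTA_THRESHOLD
    if layers is not None:
        out.insert(0, "layer", layers.reindex(nodes))
    out.index.name = "node"
    return out


def centrality_ranked_enrichment(
    delta_table: pd.DataFrame,
    sets: dict[str, tuple[str, list[str]]],
    layer: str | None = None,
    score_column: str = "delta",
    min_size: int = 6,
    max_size: int = 500,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA on delta centralities (or proximity weights).

    ``delta_table`` rows are restricted to ``layer`` when given (enrichment
    is run within the transcript or protein layer); the ranking scores come
    from ``score_column``.
    """
    table = delta_table
    if layer is not None:
        if "layer" not in table.columns:
            raise ValidationError("delta table has no 'layer' column to restrict on")
        table = table[table["layer"] == layer]
    if len(table) < min_size:
        logger.warning("centrality_ranked_enrichment: only %d features; empty result", len(table))
        return pd.DataFrame(
            columns=["size", "es", "p", "p_adj", "leading_edge"]
        ).rename_axis("set_id")
    scores = table[score_column].astype(float)
    return preranked_gsea(
        scores, sets, min_size=min_size, max_size=max_size, n_perm=n_perm, seed=seed
    )


def toxicant_nexus(
    delta_table: pd.DataFrame,
    differential: pd.DataFrame,
    toxicant_annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Features satisfying all three nexus criteria.

    (1) toxicant-annotated; (2) more abundant in cases: raw p < 0.05 and
    mean_case > mean_control; (3) more central in the case network: delta
    centrality > 0.1.  Returns the qualifying rows of the delta table with
    the supporting statistics attached; empty result allowed.
    """
    annotated = (
        set(toxicant_annotations["feature_id"]) if not toxicant_annotations.empty else set()
    )
    rows = []
    for fid in sorted(annotated):
        if fid not in delta_table.index or fid not in differential.index:
            continue
        delta = float(delta_table.loc[fid, "delta"])
        p = float(differential.loc[fid, "p"])
        up = float(differential.loc[fid, "mean_case"]) > float(differential.loc[fid, "mean_control"])
        if delta > DELTA_THRESHOLD and p < NEXUS_ALPHA and up:
            compounds = ";".join(
                sorted(
                    set(
                        toxicant_annotations.loc[
                            toxicant_annotations["feature_id"] == fid, "compound_id"
                        ]
                    )
                )
            )
            rows.append(
                {"feature_id": fid, "delta": delta, "p": p, "compounds": compounds}
            )
    return pd.DataFrame(rows, columns=["feature_id", "delta", "p", "compounds"]).set_index(
        "feature_id"
    )


def proximity_weights(net_case: AssociationNetwork, nexus_features) -> pd.Series:
    """Signed sum of direct case-network edge weights to nexus chemicals.

    Non-neighbors get 0; nexus chemicals absent from the network are skipped
    with a warning; an empty nexus yields all-zero weights with a warning.
    """
    g = net_case.graph
    names = list(g.vs["name"]) if g.vcount() else []
    weights = pd.Series(0.0, index=pd.Index(names, name="node"), name="proximity")
    nexus = sorted(set(nexus_features))
    if not nexus:
        logger.warning("proximity_weights: empty nexus; all weights zero")
        return weights
    index = {n: i for i, n in enumerate(names)}
    for chem in nexus:
        if chem not in index:
            logger.warning("proximity_weights: nexus chemical %s not in case network", chem)
            continue
        vi = index[chem]
        for e in g.es[g.incident(vi)]:
            other = e.target if e.source == vi else e.source
            weights.iloc[other] += float(e["weight"])
    return weights
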