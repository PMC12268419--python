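#!/usr/bin/env python
"""m/z annotation and metabolite pathway enrichment.

Matches metabolomic feature m/z values against the metabolite reference
(primary M+H ion required) and the toxicant table at 5 ppm, then runs the
permutation-calibrated pathway overrepresentation test on the differentially
abundant features and classifies retained pathways as up/down/mixed.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from isletnet.annotate import annotate_toxicants, match_features, read_mass_table
from isletnet.pathways import pathway_directions, permutation_pathways
from isletnet.pipeline import load_study_tsv
from isletnet.preprocess import impute_below_detection, prevalence_filter, summarize_triplicate_medians

STUDY = Path("results/study")
DIFF = Path("results/differential")
OUT = Path("results/pathways")
SEED = 1


def main() -> None:
    matrices, meta = load_study_tsv(STUDY)
    mass_table = read_mass_table(STUDY / "mass_table.tsv")
    OUT.mkdir(parents=True, exist_ok=True)

    met = impute_below_detection(
        prevalence_filter(summarize_triplicate_medians(matrices["metabolite"], meta), meta, 0.8)
    )
    annotations = match_features(met.feature_meta, mass_table.restrict("metabolite"),
                                 ppm=5.0, require_primary=True)
    tox = annotate_toxicants(met, mass_table, ppm=5.0)
    annotations.to_csv(OUT / "annotations_metabolite.tsv", sep="\t", index=False)
    tox.to_csv(OUT / "annotations_toxicant.tsv", sep="\t", index=False)
    print(f"annotated {annotations['feature_id'].nunique()} / {met.n_features} features "
          f"(metabolite table, M+H required); {tox['feature_id'].nunique()} toxicant matches")

    diff = pd.read_csv(DIFF / "differential_metabolite.tsv", sep="\t", index_col=0)
    da = [f for f in diff.index[diff["p"] < 0.05] if f in set(annotations["feature_id"])]
    pathways = {pid: (pid, members) for pid, members in mass_table.pathway_members().items()}
    res = permutation_pathways(annotations, da, pathways, n_perm=1000, seed=SEED)
    res["direction"] = pathway_directions(
        annotations, da, np.sign(diff["log2fc"]), pathways
    ).reindex(res.index)
    res.to_csv(OUT / "pathway_enrichment.tsv", sep="\t")
    retained = res[res["retained"]]
    print(f"{len(da)} differentially abundant annotated features; "
          f"{len(retained)} / {len(res)} pathways retained "
          f"(BH p<0.05, >=3 DA metabolites): {retained.index.tolist()}")
    if len(retained):
        print(retained[["n_da", "n_total", "p_adj", "direction"]].to_string())


if __name__ == "__main__":
    main()
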