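#!/usr/bin/env python
"""Generate the synthetic tri-omics islet study analyzed by the later steps.

Writes the three layer tables (RNA counts, protein heavy/light ratios,
triplicate LC-MS metabolite intensities), sample metadata, the compound mass
tables, transcript gene sets, and the planted ground truth under
results/study/.
"""

from pathlib import Path

from isletnet.annotate import write_mass_table
from isletnet.gsea import write_gmt
from isletnet.synthetic import SimConfig, simulate_study, truth_gene_sets, write_fixtures

OUT = Path("results/study")
SEED = 1


def main() -> None:
    config = SimConfig(seed=SEED)
    study, mass_table = simulate_study(config)
    paths = write_fixtures(study, OUT)
    write_mass_table(mass_table, OUT / "mass_table.tsv")
    write_gmt(truth_gene_sets(study, layer="rna"), OUT / "gene_sets.gmt")

    met = study.matrices["metabolite"]
    print(f"simulated study (seed {SEED}): "
          f"{study.matrices['rna'].n_features} transcripts x {study.matrices['rna'].n_samples} samples, "
          f"{study.matrices['protein'].n_features} proteins x {study.matrices['protein'].n_samples}, "
          f"{met.n_features} metabolite features x {met.n_samples} injections")
    print(f"planted: {study.config.n_factors} cross-layer factors, "
          f"{len(study.truth_differential)} differential features, "
          f"{len(study.truth_toxicants)} case-only toxicants {study.truth_toxicants}")
    print(f"wrote {len(paths) + 2} files under {OUT}")


if __name__ == "__main__":
    main()
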