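#!/usr/bin/env python
"""Per-layer preprocessing and two-group differential statistics.

Applies the layer-specific pipelines (triplicate medians, group-wise
prevalence filters at 80% / two-thirds, half-minimum imputation, log10) and
Welch tests with BH adjustment, then reports the differential (raw p < 0.05)
and significant (BH p < 0.1) feature counts per layer.
"""

from pathlib import Path

from isletnet.diff import differential_table
from isletnet.pipeline import _preprocess_layers, load_study_tsv
from isletnet.preprocess import PREVALENCE_DEFAULTS

STUDY = Path("results/study")
OUT = Path("results/differential")


def main() -> None:
    matrices, meta = load_study_tsv(STUDY)
    OUT.mkdir(parents=True, exist_ok=True)
    net_in, diff_in, counts = _preprocess_layers(matrices, meta, PREVALENCE_DEFAULTS)
    for layer, (m, log_scale) in diff_in.items():
        table = differential_table(m, meta, log_scale=log_scale)
        table.to_csv(OUT / f"differential_{layer}.tsv", sep="\t")
        kept = counts[layer]["prevalence"]
        print(f"{layer}: {counts[layer]['input']} features, {kept} past prevalence filter, "
              f"{int(table['differential'].sum())} differential (p<0.05), "
              f"{int(table['significant'].sum())} significant (BH p<0.1)")
        # the network stage consumes the non-normalized / imputed versions
        net_in[layer].values.to_csv(OUT / f"network_input_{layer}.tsv", sep="\t")


if __name__ == "__main__":
    main()
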