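"""End-to-end orchestration of the tri-omics differential network analysis.

Stage order: simulate (or load) -> per-layer preprocessing -> differential
statistics -> transcript GSEA -> m/z annotation -> metabolite pathway
enrichment -> per-condition networks -> delta centrality -> toxicant nexus
and proximity enrichment.  Every stage output is written under the run's
output directory together with a machine-readable summary and a manifest
recording the seed, configuration echo and output checksums.

Network inputs follow the integration design: non-normalized transcript
counts, imputed (non-normalized) protein ratios, and missing-value-imputed
log10 metabolite intensities.  Count normalization (median-of-ratios) is
used only for the transcript differential stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffnet, gsea, network, pathways, preprocess
from .annotate import MassTable, annotate_toxicants, match_features, read_mass_table
from .containers import OmicsMatrix, SampleMetadata, ValidationError
from .diff import ALPHA_RAW, differential_table
from .synthetic import SimConfig, simulate_study, truth_gene_sets, write_fixtures

__all__ = ["RunConfig", "RunSummary", "run_pipeline", "write_manifest", "load_study_tsv"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulate`` (a SimConfig) or ``input_dir`` (a fixture
    directory as written by :func:`isletnet.synthetic.write_fixtures`) must
    be set.  ``exclude_samples`` supports sensitivity reruns that drop
    individual donors.
    """

    simulate: SimConfig | None = None
    input_dir: str | None = None
    exclude_samples: list[str] = field(default_factory=list)
    outdir: str = "results/run"
    seed: int = 0
    ppm: float = 5.0
    ppm_noise: float = 2.0
    prevalence: dict = field(default_factory=lambda: dict(preprocess.PREVALENCE_DEFAULTS))
    network_cap: float = network.RSD_CAP
    network_threshold: float = network.EDGE_THRESHOLD
    network_alpha: float = network.EDGE_ALPHA
    max_components: int = network.MAX_COMPONENTS
    gsea_n_perm: int = 1000
    pathway_n_perm: int = 1000

    def validate(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise ValidationError("exactly one of simulate/input_dir must be set")
        if self.simulate is not None:
            self.simulate.validate()
        for layer, thr in self.prevalence.items():
            if not (0 < thr <= 1):
                raise ValidationError(f"prevalence[{layer!r}] out of range: {thr}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunSummary:
    """Machine-readable run outcome: stage feature counts and key results."""

    seed: int
    feature_counts: dict
    n_differential: dict
    retained_pathways: list[str]
    nexus_features: list[str]
    network_sizes: dict
    excluded_samples: list[str]
    outputs: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)


def load_study_tsv(input_dir) -> tuple[dict[str, OmicsMatrix], SampleMetadata]:
    """Read the three layer TSVs and sample metadata from a fixture directory."""
    input_dir = Path(input_dir)
    meta = SampleMetadata(pd.read_csv(input_dir / "samples.tsv", sep="\t"))
    matrices: dict[str, OmicsMatrix] = {}
    for layer in ("rna", "protein"):
        df = pd.read_csv(input_dir / f"{layer}.tsv", sep="\t").set_index("feature_id")
        matrices[layer] = OmicsMatrix(layer, df)
    met = pd.read_csv(input_dir / "metabolite.tsv", sep="\t").set_index("feature_id")
    fmeta = met[["mz", "time"]].rename(columns={"time": "rt"})
    matrices["metabolite"] = OmicsMatrix("metabolite", met.drop(columns=["mz", "time"]), fmeta)
    return matrices, meta


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(config: RunConfig, outdir: Path, outputs: dict[str, str]) -> Path:
    """JSON manifest: config echo, seed, and per-output checksums."""
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "checksums": {
            name: _checksum(Path(p)) for name, p in sorted(outputs.items()) if Path(p).is_file()
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


def _preprocess_layers(matrices, meta, prevalence):
    """Per-layer preprocessing; returns network inputs, differential inputs,
    and stage feature counts."""
    counts: dict[str, dict[str, int]] = {}
    net_in: dict[str, OmicsMatrix] = {}
    diff_in: dict[str, tuple[OmicsMatrix, bool]] = {}  # matrix, log_scale flag

    # metabolite: medians -> prevalence -> impute -> log10 (network input);
    # autoscaling ahead of the t test leaves Welch statistics unchanged but
    # is applied for the exported differential matrix to match the stated
    # metabolomics workflow.
    met = matrices["metabolite"]
    counts["metabolite"] = {"input": met.n_features}
    med = preprocess.summarize_triplicate_medians(met, meta)
    kept = preprocess.prevalence_filter(med, meta, prevalence["metabolite"])
    counts["metabolite"]["prevalence"] = kept.n_features
    if kept.n_features:
        imputed = preprocess.impute_below_detection(kept)
        logged = preprocess.log10_transform(imputed)
        net_in["metabolite"] = logged
        diff_in["metabolite"] = (logged, True)

    prot = matrices["protein"]
    counts["protein"] = {"input": prot.n_features}
    kept = preprocess.prevalence_filter(prot, meta, prevalence["protein"])
    counts["protein"]["prevalence"] = kept.n_features
    if kept.n_features:
        imputed = preprocess.impute_below_detection(kept)
        net_in["protein"] = imputed  # non-normalized ratios
        diff_in["protein"] = (preprocess.log10_transform(imputed), True)

    rna = matrices["rna"]
    counts["rna"] = {"input": rna.n_features}
    kept = preprocess.prevalence_filter(rna, meta, prevalence["rna"])
    counts["rna"]["prevalence"] = kept.n_features
    if kept.n_features:
        net_in["rna"] = kept  # non-normalized counts
        sf = preprocess.size_factors(kept)
        log_counts = np.log10(kept.values.div(sf, axis=1) + 1.0)
        diff_in["rna"] = (log_counts, True)
    return net_in, diff_in, counts


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the full analysis; returns the run summary (also written to
    ``<outdir>/summary.json``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str, index=True):
        path = outdir / name
        df.to_csv(path, sep="\t", index=index)
        outputs[name] = str(path)

    stage = "simulate"
    try:
        gene_sets: dict[str, tuple[str, list[str]]]
        if config.simulate is not None:
            study, mass_table = simulate_study(config.simulate, ppm_noise=config.ppm_noise)
            matrices, meta = study.matrices, study.metadata
            gene_sets = truth_gene_sets(study, layer="rna")
            fixture_dir = outdir / "fixtures"
            write_fixtures(study, fixture_dir)
            outputs["fixtures"] = str(fixture_dir)
        else:
            matrices, meta = load_study_tsv(config.input_dir)
            mass_table = read_mass_table(Path(config.input_dir) / "mass_table.tsv")
            gmt = Path(config.input_dir) / "gene_sets.gmt"
            gene_sets = gsea.parse_gmt(gmt) if gmt.exists() else {}

        if config.exclude_samples:
            drop = set(config.exclude_samples)
            rep = meta.replicate_map()
            expanded = set(drop)
            for bio in drop:
                expanded.update(rep.get(bio, []))
            keep = [s for s in meta.sample_ids if s not in expanded]
            meta = meta.subset(keep)
            matrices = {
                layer: m.subset_samples([s for s in m.sample_ids if s not in expanded])
                for layer, m in matrices.items()
            }

        stage = "preprocess"
        net_in, diff_in, feature_counts = _preprocess_layers(matrices, meta, config.prevalence)

        stage = "differential"
        diff_tables: dict[str, pd.DataFrame] = {}
        for layer, (m, log_scale) in diff_in.items():
            tbl = differential_table(m, meta, log_scale=log_scale)
            diff_tables[layer] = tbl
            save(tbl, f"differential_{layer}.tsv")
        n_differential = {
            layer: int(tbl["differential"].sum()) for layer, tbl in diff_tables.items()
        }

        stage = "gsea"
        if "rna" in diff_tables and gene_sets:
            res = gsea.preranked_gsea(
                diff_tables["rna"]["rank_metric"],
                gene_sets,
                n_perm=config.gsea_n_perm,
                seed=config.seed,
            )
            save(res, "gsea_rna.tsv")

        stage = "annotation"
        met_meta = net_in["metabolite"].feature_meta if "metabolite" in net_in else None
        annotations = pd.DataFrame(columns=["feature_id", "compound_id", "adduct",
                                            "theoretical_mz", "ppm_error"])
        tox_annotations = annotations.copy()
        if met_meta is not None and met_meta["mz"].notna().any():
            annotations = match_features(
                met_meta, mass_table.restrict("metabolite"), ppm=config.ppm, require_primary=True
            )
            tox_annotations = annotate_toxicants(met_meta, mass_table, ppm=config.ppm)
            save(annotations, "annotations_metabolite.tsv", index=False)
            save(tox_annotations, "annotations_toxicant.tsv", index=False)

        stage = "pathways"
        pathway_results = pd.DataFrame()
        if not annotations.empty and "metabolite" in diff_tables:
            met_diff = diff_tables["metabolite"]
            da = [
                f for f in met_diff.index[met_diff["p"] < ALPHA_RAW]
                if f in set(annotations["feature_id"])
            ]
            pw = {
                pid: (pid, members) for pid, members in mass_table.pathway_members().items()
            }
            if da and pw:
                pathway_results = pathways.permutation_pathways(
                    annotations, da, pw, n_perm=config.pathway_n_perm, seed=config.seed
                )
                signs = np.sign(met_diff["log2fc"])
                directions = pathways.pathway_directions(annotations, da, signs, pw)
                pathway_results["direction"] = directions.reindex(pathway_results.index)
                save(pathway_results, "pathway_enrichment.tsv")
        retained = (
            sorted(pathway_results.index[pathway_results["retained"]])
            if "retained" in pathway_results
            else []
        )

        stage = "networks"
        nets: dict[str, network.AssociationNetwork] = {}
        for condition, group in (("case", "case"), ("control", "control")):
            cond_samples = set(meta.samples_in_group(group))
            cond_matrices = {}
            for layer, m in net_in.items():
                cols = [s for s in m.sample_ids if s in cond_samples]
                if len(cols) >= 3:
                    cond_matrices[layer] = m.subset_samples(cols)
            net = network.build_condition_network(
                cond_matrices,
                condition=condition,
                cap_fraction=config.network_cap,
                threshold=config.network_threshold,
                alpha=config.network_alpha,
                max_components=config.max_components,
                seed=config.seed,
            )
            nets[condition] = net
            net.write_edges_tsv(outdir / f"network_{condition}_edges.tsv")
            outputs[f"network_{condition}_edges.tsv"] = str(outdir / f"network_{condition}_edges.tsv")
            if net.graph.vcount():
                net.write_graphml(outdir / f"network_{condition}.graphml")
                outputs[f"network_{condition}.graphml"] = str(outdir / f"network_{condition}.graphml")
                save(net.nodes_table(), f"network_{condition}_nodes.tsv")
        network_sizes = {
            c: {"nodes": n.graph.vcount(), "edges": n.graph.ecount()} for c, n in nets.items()
        }

        stage = "differential_network"
        layer_map = pd.concat(
            [n.nodes_table()["layer"] for n in nets.values()]
        )
        layer_map = layer_map[~layer_map.index.duplicated()]
        cent_case = nets["case"].nodes_table().get("centrality", pd.Series(dtype=float))
        cent_control = nets["control"].nodes_table().get("centrality", pd.Series(dtype=float))
        delta = pd.DataFrame()
        if len(cent_case) or len(cent_control):
            delta = diffnet.delta_centrality(cent_case, cent_control, layers=layer_map)
            save(delta, "delta_centrality.tsv")
            if gene_sets:
                rna_delta = delta[delta["layer"] == "rna"]
                if len(rna_delta) >= gsea.GSEA_MIN_SIZE:
                    res = diffnet.centrality_ranked_enrichment(
                        delta, gene_sets, layer="rna",
                        n_perm=config.gsea_n_perm, seed=config.seed,
                    )
                    save(res, "gsea_delta_centrality_rna.tsv")

        stage = "nexus"
        nexus = pd.DataFrame(columns=["delta", "p", "compounds"])
        if not delta.empty and "metabolite" in diff_tables and not tox_annotations.empty:
            nexus = diffnet.toxicant_nexus(delta, diff_tables["metabolite"], tox_annotations)
            save(nexus, "toxicant_nexus.tsv")
            prox = diffnet.proximity_weights(nets["case"], nexus.index)
            save(prox.to_frame(), "proximity_weights.tsv")
            if gene_sets and len(prox):
                prox_table = pd.DataFrame({"delta": prox, "layer": layer_map.reindex(prox.index)})
                rna_prox = prox_table[prox_table["layer"] == "rna"]
                if len(rna_prox) >= gsea.GSEA_MIN_SIZE:
                    res = diffnet.centrality_ranked_enrichment(
                        prox_table, gene_sets, layer="rna",
                        n_perm=config.gsea_n_perm, seed=config.seed,
                    )
                    save(res, "gsea_proximity_rna.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = RunSummary(
        seed=config.seed,
        feature_counts=feature_counts,
        n_differential=n_differential,
        retained_pathways=retained,
        nexus_features=sorted(nexus.index.tolist()),
        network_sizes=network_sizes,
        excluded_samples=sorted(config.exclude_samples),
        outputs=outputs,
    )
    (outdir / "summary.json").write_text(summary.to_json())
    outputs["summary.json"] = str(outdir / "summary.json")
    write_manifest(config, outdir, outputs)
    return summary
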