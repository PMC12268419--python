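"""Generator determinism, planted structure, censoring, and m/z identities."""

import numpy as np
import pandas as pd
import pytest

from isletnet.annotate import match_features
from isletnet.chem import PROTON_MASS
from isletnet.containers import ValidationError
from isletnet.synthetic import (
    SimConfig,
    assign_mz_identities,
    build_mass_table,
    generate_multiomics,
    simulate_study,
    truth_gene_sets,
    write_fixtures,
)

SMALL = dict(n_features_per_layer={"rna": 60, "protein": 30, "metabolite": 50})


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(n_case=0), "n_case"),
            (dict(n_toxicants=-1), "n_toxicants"),
            (dict(lod_quantile=1.0), "lod_quantile"),
            (dict(loading_density=0.0), "loading_density"),
            (dict(n_features_per_layer={"rna": 10}), "n_features_per_layer"),
            (dict(protein_n_per_group=9), "protein_n_per_group"),
        ],
    )
    def test_invalid_configs_name_the_field(self, kwargs, field):
        with pytest.raises(ValidationError, match=field):
            SimConfig(**kwargs).validate()


class TestGenerate:
    def test_shapes_follow_config(self):
        cfg = SimConfig(n_case=5, n_control=5, triplicates=3, **SMALL)
        study = generate_multiomics(cfg)
        assert study.matrices["metabolite"].values.shape == (50, 30)
        assert study.matrices["rna"].values.shape == (60, 10)
        assert study.matrices["protein"].values.shape == (30, 6)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=42, **SMALL)
        a, b = generate_multiomics(cfg), generate_multiomics(cfg)
        for layer in a.matrices:
            pd.testing.assert_frame_equal(a.matrices[layer].values, b.matrices[layer].values)
        assert a.truth_communities == b.truth_communities
        assert a.truth_differential == b.truth_differential
        assert a.truth_toxicants == b.truth_toxicants

    def test_censoring_fraction_near_quantile(self):
        fracs = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, lod_quantile=0.2, n_toxicants=0,
                            n_features_per_layer={"rna": 10, "protein": 10, "metabolite": 300})
            met = generate_multiomics(cfg).matrices["metabolite"].values
            fracs.append(np.isnan(met.to_numpy()).mean())
        assert np.mean(fracs) == pytest.approx(0.2, abs=0.03)

    def test_censoring_monotone_in_quantile(self):
        counts = []
        for q in (0.0, 0.1, 0.2, 0.4):
            cfg = SimConfig(seed=3, lod_quantile=q, **SMALL)
            met = generate_multiomics(cfg).matrices["metabolite"].values
            counts.append(int(np.isnan(met.to_numpy()).sum()))
        assert counts == sorted(counts)

    def test_toxicants_absent_in_controls_present_in_cases(self):
        study = generate_multiomics(SimConfig(seed=1, **SMALL))
        met = study.matrices["metabolite"].values
        ctrl_cols = [c for c in met.columns if c.startswith("CTRL")]
        case_cols = [c for c in met.columns if c.startswith("CASE")]
        for tox in study.truth_toxicants:
            assert met.loc[tox, ctrl_cols].isna().all()
            assert met.loc[tox, case_cols].notna().all()
            assert study.truth_communities[tox] == 0

    def test_noiseless_limit_recovers_block_correlations(self):
        # eps -> 0, no group effect: same community -> |r| ~ 1, across -> ~0
        cfg = SimConfig(
            n_case=25, n_control=25, noise_sd=1e-3, secondary_noise_sd=1e-3,
            control_hub_noise_sd=1e-3, group_effect_size=0.0, differential_fraction=0.0,
            lod_quantile=0.0, n_toxicants=0, triplicates=1, seed=7,
            n_features_per_layer={"rna": 30, "protein": 30, "metabolite": 30},
        )
        study = generate_multiomics(cfg)
        # metabolite intensities observed for all samples; log10 is linear in
        # the latent (the 3+3 protein subset is too small for this check)
        met = np.log10(study.matrices["metabolite"].values)
        comm = study.truth_communities
        corr = met.T.corr()
        ids = met.index.tolist()
        same, cross = [], []
        for i, fi in enumerate(ids):
            for fj in ids[i + 1:]:
                (same if comm[fi] == comm[fj] else cross).append(abs(corr.loc[fi, fj]))
        assert np.min(same) > 0.99
        assert np.max(cross) < 0.2


class TestMzIdentities:
    def test_exact_mass_arithmetic_at_zero_noise(self):
        table = build_mass_table(seed=0)
        study = generate_multiomics(SimConfig(seed=0, **SMALL))
        study = assign_mz_identities(study, table, ppm_noise=0.0)
        met = study.matrices["metabolite"]
        glc_feats = [f for f, c in study.truth_compounds.items() if c == "MET_GLC"]
        for f in glc_feats:
            assert met.feature_meta.loc[f, "mz"] == pytest.approx(181.070664, abs=1e-6)
        # generic: observed m/z = mass + proton exactly
        masses = table.table.set_index("compound_id")["monoisotopic_mass"]
        for f, c in study.truth_compounds.items():
            assert met.feature_meta.loc[f, "mz"] == pytest.approx(masses[c] + PROTON_MASS, abs=1e-9)

    def test_zero_noise_roundtrip_recovers_all_compounds(self):
        study, table = simulate_study(SimConfig(seed=2, **SMALL), ppm_noise=0.0)
        met = study.matrices["metabolite"]
        ann = match_features(met.feature_meta, table, ppm=5.0)
        pairs = set(map(tuple, ann[["feature_id", "compound_id"]].to_numpy()))
        for f, c in study.truth_compounds.items():
            assert (f, c) in pairs

    def test_large_noise_breaks_some_matches(self):
        misses = 0
        for seed in range(5):
            study, table = simulate_study(SimConfig(seed=seed, **SMALL), ppm_noise=20.0)
            met = study.matrices["metabolite"]
            ann = match_features(met.feature_meta, table, ppm=5.0)
            pairs = set(map(tuple, ann[["feature_id", "compound_id"]].to_numpy()))
            misses += sum((f, c) not in pairs for f, c in study.truth_compounds.items())
        assert misses > 0

    def test_more_features_than_compounds_rejected(self):
        table = build_mass_table(n_metabolite_compounds=52, seed=0)
        study = generate_multiomics(
            SimConfig(seed=0, n_features_per_layer={"rna": 10, "protein": 10, "metabolite": 60})
        )
        with pytest.raises(ValidationError):
            assign_mz_identities(study, table)


class TestFixtures:
    def test_roundtrip_and_manifest(self, tmp_path, default_study):
        study, _ = default_study
        paths = write_fixtures(study, tmp_path)
        import json

        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seed"] == study.config.seed
        rna = pd.read_csv(paths["rna"], sep="\t").set_index("feature_id")
        pd.testing.assert_frame_equal(rna, study.matrices["rna"].values, check_names=False)
        met = pd.read_csv(paths["metabolite"], sep="\t").set_index("feature_id")
        got = met.drop(columns=["mz", "time"])
        pd.testing.assert_frame_equal(got, study.matrices["metabolite"].values,
                                      check_names=False, check_exact=False)
        comm = pd.read_csv(paths["truth_communities"], sep="\t")
        assert len(comm) == len(study.truth_communities)

    def test_truth_gene_sets_cover_factors(self, default_study):
        study, _ = default_study
        sets = truth_gene_sets(study, layer="rna")
        factor_sets = [s for s in sets if s.startswith("FACTOR")]
        assert len(factor_sets) == study.config.n_factors
        for sid in factor_sets:
            _, members = sets[sid]
            k = int(sid[len("FACTOR")])
            assert all(study.truth_communities[m] == k for m in members)
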