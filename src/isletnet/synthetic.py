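"""Seeded tri-omics study generator with known ground truth.

The generator emulates the statistical structure of a two-group (case vs
control) donor-islet multiomics study: a small number of latent biological
factors induce cross-layer co-regulation blocks; a subset of features carries
a group effect; metabolite intensities are left-censored below a detection
limit and measured as triplicate injections; a handful of "toxicant" features
are planted that are detected only in case samples and load on one designated
hub factor.  Ground truth (community labels, differential effects, toxicant
identities, compound assignments) is carried alongside so every downstream
stage has a truth-bearing input.

Study-design defaults mirror a pilot donor study: 5 case + 5 control samples
for transcriptomics and metabolomics, with proteomics available for a 3+3
subset, and 3 LC-MS injections per metabolomics sample.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import MassTable, write_mass_table
from .chem import PROTON_MASS, formula_mass
from .containers import LAYERS, OmicsMatrix, SampleMetadata, ValidationError

__all__ = [
    "SimConfig",
    "SyntheticStudy",
    "generate_multiomics",
    "assign_mz_identities",
    "write_fixtures",
    "build_mass_table",
    "truth_gene_sets",
    "simulate_study",
]

# Curated small-molecule reference: (compound_id, name, formula, pathway ids).
# Masses are derived from the formulas; pathway groupings follow common
# metabolic-map conventions.  This is a synthetic stand-in reference table,
# not an export of any real database.
CURATED_METABOLITES = [
    ("MET_GLC", "D-glucose", "C6H12O6", "PWY_GLYCOLYSIS"),
    ("MET_G6P", "glucose 6-phosphate", "C6H13O9P", "PWY_GLYCOLYSIS"),
    ("MET_F16BP", "fructose 1,6-bisphosphate", "C6H14O12P2", "PWY_GLYCOLYSIS"),
    ("MET_PYR", "pyruvate", "C3H4O3", "PWY_GLYCOLYSIS;PWY_TCA"),
    ("MET_LAC", "lactate", "C3H6O3", "PWY_GLYCOLYSIS"),
    ("MET_CIT", "citrate", "C6H8O7", "PWY_TCA"),
    ("MET_AKG", "2-oxoglutarate", "C5H6O5", "PWY_TCA;PWY_AA"),
    ("MET_SUC", "succinate", "C4H6O4", "PWY_TCA"),
    ("MET_FUM", "fumarate", "C4H4O4", "PWY_TCA"),
    ("MET_MAL", "malate", "C4H6O5", "PWY_TCA"),
    ("MET_HYP", "hypoxanthine", "C5H4N4O", "PWY_PURINE"),
    ("MET_XAN", "xanthine", "C5H4N4O2", "PWY_PURINE"),
    ("MET_URATE", "urate", "C5H4N4O3", "PWY_PURINE"),
    ("MET_INO", "inosine", "C10H12N4O5", "PWY_PURINE"),
    ("MET_ADO", "adenosine", "C10H13N5O4", "PWY_PURINE"),
    ("MET_GUO", "guanosine", "C10H13N5O5", "PWY_PURINE"),
    ("MET_AMP", "AMP", "C10H14N5O7P", "PWY_PURINE"),
    ("MET_URA", "uracil", "C4H4N2O2", "PWY_PYRIMIDINE"),
    ("MET_URD", "uridine", "C9H12N2O6", "PWY_PYRIMIDINE"),
    ("MET_CYT", "cytidine", "C9H13N3O5", "PWY_PYRIMIDINE"),
    ("MET_THY", "thymidine", "C10H14N2O5", "PWY_PYRIMIDINE"),
    ("MET_OROT", "orotate", "C5H4N2O4", "PWY_PYRIMIDINE"),
    ("MET_LEU", "leucine", "C6H13NO2", "PWY_BCAA"),
    ("MET_ILE", "isoleucine", "C6H13NO2", "PWY_BCAA"),  # leucine isomer, same mass
    ("MET_VAL", "valine", "C5H11NO2", "PWY_BCAA"),
    ("MET_KIC", "ketoleucine", "C6H10O3", "PWY_BCAA"),
    ("MET_HIS", "histidine", "C6H9N3O2", "PWY_HISTIDINE"),
    ("MET_URO", "urocanate", "C6H6N2O2", "PWY_HISTIDINE"),
    ("MET_IMP5", "imidazolone propanoate", "C6H8N2O3", "PWY_HISTIDINE"),
    ("MET_CARN", "carnosine", "C9H14N4O3", "PWY_HISTIDINE"),
    ("MET_PALM", "palmitate", "C16H32O2", "PWY_FA"),
    ("MET_OLE", "oleate", "C18H34O2", "PWY_FA"),
    ("MET_CARN16", "palmitoylcarnitine", "C23H45NO4", "PWY_FA"),
    ("MET_ACCARN", "acetylcarnitine", "C9H17NO4", "PWY_FA"),
    ("MET_GLU", "glutamate", "C5H9NO4", "PWY_AA"),
    ("MET_GLN", "glutamine", "C5H10N2O3", "PWY_AA"),
    ("MET_ALA", "alanine", "C3H7NO2", "PWY_AA"),
    ("MET_SER", "serine", "C3H7NO3", "PWY_AA"),
    ("MET_GLY", "glycine", "C2H5NO2", "PWY_AA"),
    ("MET_ARG", "arginine", "C6H14N4O2", "PWY_UREA"),
    ("MET_ORN", "ornithine", "C5H12N2O2", "PWY_UREA"),
    ("MET_CITR", "citrulline", "C6H13N3O3", "PWY_UREA"),
    ("MET_GSH", "glutathione", "C10H17N3O6S", "PWY_GSH"),
    ("MET_GSSG", "glutathione disulfide", "C20H32N6O12S2", "PWY_GSH"),
    ("MET_CYS", "cysteine", "C3H7NO2S", "PWY_GSH"),
    ("MET_TRP", "tryptophan", "C11H12N2O2", "PWY_TRP"),
    ("MET_KYN", "kynurenine", "C10H12N2O3", "PWY_TRP"),
    ("MET_5HT", "serotonin", "C10H12N2O", "PWY_TRP"),
]

# Industrial/environmental chemicals of the kind catalogued by toxicant
# databases; masses from formulas (synthetic stand-in table).
CURATED_TOXICANTS = [
    ("TOX_PCB153", "2,2',4,4',5,5'-hexachlorobiphenyl", "C12H4Cl6"),
    ("TOX_PCB77", "3,3',4,4'-tetrachlorobiphenyl", "C12H6Cl4"),
    ("TOX_PBB", "octabromobiphenyl", "C12H2Br8"),
    ("TOX_BPA", "bisphenol A", "C15H16O2"),
    ("TOX_DDT", "p,p'-DDT", "C14H9Cl5"),
    ("TOX_DEHP", "bis(2-ethylhexyl) phthalate", "C24H38O4"),
    ("TOX_PFOA", "perfluorooctanoic acid", "C8HF15O2"),
    ("TOX_ATRA", "atrazine", "C8H14ClN5"),
    ("TOX_BAP", "benzo[a]pyrene", "C20H12"),
    ("TOX_TCDD", "2,3,7,8-tetrachlorodibenzodioxin", "C12H4Cl4O2"),
    ("TOX_CPF", "chlorpyrifos", "C9H11Cl3NO3PS"),
    ("TOX_HCB", "hexachlorobenzene", "C6Cl6"),
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic two-group tri-omics study.

    Attributes
    ----------
    n_case, n_control : int
        Biological samples per group (transcriptomics/metabolomics).
    protein_n_per_group : int
        Proteomics subset size per group (the assayed subset of donors).
    n_features_per_layer : dict
        Feature counts for the ``rna``, ``protein`` and ``metabolite`` layers.
    n_factors : int
        Number of latent cross-layer factors (planted communities).
    loading_density : float
        Fraction of features with a nonzero factor loading, in (0, 1].
    group_effect_size : float
        Standardized mean shift added to case samples for differential
        features (units of latent standard deviation).
    differential_fraction : float
        Fraction of features per layer carrying the group effect.
    noise_sd : float
        Feature-level noise standard deviation on the latent scale for hub
        (factor 0) features, relative to unit factor variance.  Condition
        networks are built from only a handful of samples, so recoverable
        co-regulation must be tight.
    secondary_noise_sd : float
        Noise standard deviation for features of the non-hub factors; the
        secondary co-regulation modules are looser than the hub module, as
        is typical of module structure in co-expression data.
    control_hub_noise_sd : float
        Noise standard deviation of hub-factor features in control samples.
        The hub module is driven by the case-only toxicant exposure, so its
        co-regulation is coherent in cases and dysregulated in controls;
        this plants the connectivity difference (positive delta centrality
        for hub members) that the differential-network stage recovers.
    lod_quantile : float
        Metabolite intensities below this quantile of the layer are censored
        (reported missing), in [0, 1).
    n_toxicants : int
        Planted case-only toxicant metabolite features (load on factor 0).
    hub_factor_share : float
        Fraction of features assigned to factor 0, the designated hub
        factor; remaining factors split the rest evenly.  The hub factor is
        the dominant co-regulation block, so its members carry the bulk of
        eigenvector-centrality mass.
    triplicates : int
        LC-MS injections per metabolomics sample (>= 1).
    seed : int
        Master seed; all layer substreams derive from it.
    """

    n_case: int = 5
    n_control: int = 5
    protein_n_per_group: int = 3
    n_features_per_layer: dict = field(
        default_factory=lambda: {"rna": 300, "protein": 150, "metabolite": 240}
    )
    n_factors: int = 3
    loading_density: float = 1.0
    group_effect_size: float = 2.0
    differential_fraction: float = 0.1
    noise_sd: float = 0.1
    secondary_noise_sd: float = 0.35
    control_hub_noise_sd: float = 1.2
    lod_quantile: float = 0.15
    n_toxicants: int = 3
    hub_factor_share: float = 0.5
    triplicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_case", "n_control", "protein_n_per_group", "n_factors", "triplicates"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_toxicants < 0:
            raise ValidationError(f"n_toxicants must be >= 0, got {self.n_toxicants}")
        if set(self.n_features_per_layer) != set(LAYERS):
            raise ValidationError(
                f"n_features_per_layer must have keys {set(LAYERS)}, got {set(self.n_features_per_layer)}"
            )
        for layer, n in self.n_features_per_layer.items():
            if int(n) < 1:
                raise ValidationError(f"n_features_per_layer[{layer!r}] must be >= 1, got {n}")
        if not (0 < self.loading_density <= 1):
            raise ValidationError(f"loading_density must be in (0,1], got {self.loading_density}")
        if not (0 <= self.lod_quantile < 1):
            raise ValidationError(f"lod_quantile must be in [0,1), got {self.lod_quantile}")
        if self.protein_n_per_group > min(self.n_case, self.n_control):
            raise ValidationError("protein_n_per_group exceeds group size")
        if self.n_toxicants > self.n_features_per_layer["metabolite"]:
            raise ValidationError("n_toxicants exceeds metabolite feature count")
        if min(self.noise_sd, self.secondary_noise_sd, self.control_hub_noise_sd) < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if self.group_effect_size < 0:
            raise ValidationError("group_effect_size must be >= 0")
        if not (0 <= self.differential_fraction <= 1):
            raise ValidationError(
                f"differential_fraction must be in [0,1], got {self.differential_fraction}"
            )
        if not (0 < self.hub_factor_share < 1):
            raise ValidationError(
                f"hub_factor_share must be in (0,1), got {self.hub_factor_share}"
            )


@dataclass
class SyntheticStudy:
    """Generated study: matrices plus ground truth."""

    config: SimConfig
    matrices: dict[str, OmicsMatrix]
    metadata: SampleMetadata
    truth_communities: dict[str, int]
    truth_differential: dict[str, float]
    truth_toxicants: list[str]
    truth_compounds: dict[str, str] = field(default_factory=dict)

    def case_samples(self) -> list[str]:
        return self.metadata.samples_in_group("case")

    def control_samples(self) -> list[str]:
        return self.metadata.samples_in_group("control")


def _orthonormal_factors(z: np.ndarray) -> np.ndarray:
    """Center, orthogonalize, and unit-scale factor rows (factors x samples).

    Raw Gaussian factor draws at a handful of samples carry large chance
    correlations and variance imbalances between factors, which would make
    the planted community truth ill-defined.  The generator therefore
    enforces exactly orthogonal, unit-sample-variance factor scores within
    the given sample block (requires n_samples > n_factors; otherwise the
    rows are only centered and scaled).  Signs are aligned with the raw
    draws for determinism.
    """
    k, m = z.shape
    centered = z - z.mean(axis=1, keepdims=True)
    if m - 1 <= k:
        sd = centered.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        return centered / sd
    q, _ = np.linalg.qr(centered.T)  # columns orthonormal, zero-mean
    out = q[:, :k].T * np.sqrt(m - 1)
    for i in range(k):
        if out[i] @ centered[i] < 0:
            out[i] = -out[i]
    return out


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ["factors", "rna", "protein", "metabolite", "mz", "sets"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# internal latent->observed scales (log10 units per latent sd)
_RNA_LOG_SCALE = 0.35  # natural-log units
_PROTEIN_LOG10_SCALE = 0.3
_MET_LOG10_SCALE = 0.5


def generate_multiomics(config: SimConfig) -> SyntheticStudy:
    """Generate a seeded tri-omics study with planted structure.

    Per sample ``s`` latent factors ``z_k(s) ~ N(0,1)`` are drawn once and
    shared across layers.  A feature ``f`` in community ``k`` has latent value
    ``lambda_f * z_k(s) + delta_f * 1[s in case] + eps`` with ``eps ~
    N(0, noise_sd)``.  RNA is observed as Poisson counts of the exponentiated
    latent with per-sample library-size offsets; protein as positive
    heavy/light ratios log-normal in the latent; metabolite as intensities
    log-normal in the latent, left-censored below the layer's
    ``lod_quantile`` and expanded into ``triplicates`` injection columns with
    multiplicative noise.  Toxicant features are metabolite features detected
    only in case samples, loading on factor 0 (the designated hub factor).
    """
    config.validate()
    rngs = _substreams(config.seed)

    case = [f"CASE{i+1}" for i in range(config.n_case)]
    control = [f"CTRL{i+1}" for i in range(config.n_control)]
    samples = case + control
    n = len(samples)
    is_case = np.array([1.0] * config.n_case + [0.0] * config.n_control)

    z = rngs["factors"].standard_normal((config.n_factors, n))
    # factor scores are orthonormalized within each group so that planted
    # module strength is identical across conditions (see _orthonormal_factors)
    case_idx = np.flatnonzero(is_case == 1)
    ctrl_idx = np.flatnonzero(is_case == 0)
    z[:, case_idx] = _orthonormal_factors(z[:, case_idx])
    z[:, ctrl_idx] = _orthonormal_factors(z[:, ctrl_idx])

    matrices: dict[str, OmicsMatrix] = {}
    truth_comm: dict[str, int] = {}
    truth_diff: dict[str, float] = {}
    truth_tox: list[str] = []

    if config.n_factors > 1:
        rest = (1.0 - config.hub_factor_share) / (config.n_factors - 1)
        factor_probs = np.array([config.hub_factor_share] + [rest] * (config.n_factors - 1))
    else:
        factor_probs = np.array([1.0])

    def latent_block(rng, n_feat, prefix, n_cols):
        """Latent values + truth bookkeeping for one layer."""
        ids = [f"{prefix}{i:04d}" for i in range(n_feat)]
        factor = rng.choice(config.n_factors, size=n_feat, p=factor_probs)
        loaded = rng.random(n_feat) < config.loading_density
        lam = rng.uniform(0.9, 1.2, size=n_feat) * rng.choice([-1.0, 1.0], size=n_feat)
        lam[~loaded] = 0.0
        diff = rng.random(n_feat) < config.differential_fraction
        delta = np.where(diff, rng.choice([-1.0, 1.0], size=n_feat) * config.group_effect_size, 0.0)
        # hub-factor features: tight in cases, dysregulated in controls
        sd_case = np.where(factor == 0, config.noise_sd, config.secondary_noise_sd)
        sd_ctrl = np.where(factor == 0, config.control_hub_noise_sd, config.secondary_noise_sd)
        sd = sd_case[:, None] * is_case[None, :n_cols] + sd_ctrl[:, None] * (1 - is_case[None, :n_cols])
        eps = rng.normal(0.0, 1.0, size=(n_feat, n_cols)) * sd
        latent = lam[:, None] * z[factor, :n_cols] + delta[:, None] * is_case[None, :n_cols] + eps
        for i, fid in enumerate(ids):
            if loaded[i]:
                truth_comm[fid] = int(factor[i])
            if diff[i]:
                truth_diff[fid] = float(delta[i])
        return ids, latent

    # --- RNA: Poisson counts with library-size offsets -----------------
    rng = rngs["rna"]
    n_rna = int(config.n_features_per_layer["rna"])
    rna_ids, rna_latent = latent_block(rng, n_rna, "RNA", n)
    baseline = rng.uniform(np.log(100), np.log(2000), size=n_rna)
    size_factor = np.exp(rng.normal(0.0, 0.05, size=n))
    lam_counts = size_factor[None, :] * np.exp(baseline[:, None] + _RNA_LOG_SCALE * rna_latent)
    counts = rng.poisson(lam_counts).astype(float)
    rna_meta = pd.DataFrame({"symbol": [f"GENE_R{i:04d}" for i in range(n_rna)]}, index=rna_ids)
    matrices["rna"] = OmicsMatrix("rna", pd.DataFrame(counts, index=rna_ids, columns=samples), rna_meta)

    # --- protein: positive heavy/light ratios, 3+3 donor subset --------
    rng = rngs["protein"]
    prot_samples = case[: config.protein_n_per_group] + control[: config.protein_n_per_group]
    prot_cols = [samples.index(s) for s in prot_samples]
    n_prot = int(config.n_features_per_layer["protein"])
    prot_ids, prot_latent_full = latent_block(rng, n_prot, "PROT", n)
    prot_latent = prot_latent_full[:, prot_cols]
    prot_base = rng.uniform(-0.5, 0.5, size=n_prot)
    ratios = 10 ** (prot_base[:, None] + _PROTEIN_LOG10_SCALE * prot_latent)
    prot_meta = pd.DataFrame({"symbol": [f"GENE_P{i:04d}" for i in range(n_prot)]}, index=prot_ids)
    matrices["protein"] = OmicsMatrix(
        "protein", pd.DataFrame(ratios, index=prot_ids, columns=prot_samples), prot_meta
    )

    # --- metabolite: censored log-normal intensities, triplicates ------
    rng = rngs["metabolite"]
    n_met = int(config.n_features_per_layer["metabolite"])
    met_ids, met_latent = latent_block(rng, n_met, "MZF", n)
    met_base = rng.uniform(4.0, 6.0, size=n_met)

    # plant toxicants: overwrite the last n_toxicants features
    tox_idx = np.arange(n_met - config.n_toxicants, n_met)
    for i in tox_idx:
        fid = met_ids[i]
        # exposure heterogeneity: exogenous chemicals vary far more between
        # donors than endogenous metabolites, so their loading on the hub
        # factor is amplified (high relative standard deviation)
        lam_t = rng.uniform(2.0, 2.4)
        eps_t = rng.normal(0.0, config.noise_sd, size=n)
        met_latent[i] = lam_t * z[0] + eps_t  # hub factor 0
        met_base[i] = 5.5  # above detection in case samples
        truth_comm[fid] = 0
        truth_diff[fid] = float(config.group_effect_size)
        truth_tox.append(fid)

    log10_int = met_base[:, None] + _MET_LOG10_SCALE * met_latent
    intensity = 10**log10_int
    # left-censoring at the layer's detection quantile (non-toxicant cells)
    nontox = np.ones(n_met, dtype=bool)
    nontox[tox_idx] = False
    if config.lod_quantile > 0 and nontox.any():
        lod = np.quantile(intensity[nontox], config.lod_quantile)
        intensity[nontox] = np.where(intensity[nontox] < lod, np.nan, intensity[nontox])
    # toxicants: below detection in every control sample
    intensity[np.ix_(~nontox, is_case == 0)] = np.nan

    # expand to injection columns with multiplicative noise
    inj_cols, inj_vals, rep_rows = [], [], []
    for j, s in enumerate(samples):
        for r in range(1, config.triplicates + 1):
            inj = f"{s}_{r}"
            inj_cols.append(inj)
            noise = np.exp(rng.normal(0.0, 0.05, size=n_met))
            inj_vals.append(intensity[:, j] * noise)
            rep_rows.append({"sample_id": inj, "group": "case" if is_case[j] else "control", "replicate_of": s})
    met_values = pd.DataFrame(np.column_stack(inj_vals), index=met_ids, columns=inj_cols)
    met_meta = pd.DataFrame({"mz": np.nan, "rt": np.nan}, index=met_ids)
    matrices["metabolite"] = OmicsMatrix("metabolite", met_values, met_meta)

    meta_rows = [{"sample_id": s, "group": "case" if is_case[j] else "control", "replicate_of": pd.NA}
                 for j, s in enumerate(samples)]
    metadata = SampleMetadata(pd.DataFrame(meta_rows + rep_rows))

    return SyntheticStudy(
        config=config,
        matrices=matrices,
        metadata=metadata,
        truth_communities=truth_comm,
        truth_differential=truth_diff,
        truth_toxicants=truth_tox,
    )


def build_mass_table(
    n_metabolite_compounds: int = 300,
    n_toxicant_compounds: int = 12,
    seed: int = 0,
) -> MassTable:
    """Synthetic compound reference table (metabolites + toxicants).

    The curated formula-derived compounds are always included; if more are
    requested, filler compounds with random masses in 120-700 Da are appended
    and assigned to the curated pathways at random.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    rows = []
    pathways = sorted({p for *_, pw in CURATED_METABOLITES for p in pw.split(";")})
    for cid, name, formula, pw in CURATED_METABOLITES:
        rows.append(
            {"compound_id": cid, "name": name,
             "monoisotopic_mass": round(formula_mass(formula), 6),
             "category": "metabolite", "pathways": pw}
        )
    for i in range(len(rows), n_metabolite_compounds):
        pw = ";".join(sorted(rng.choice(pathways, size=rng.integers(1, 3), replace=False)))
        rows.append(
            {"compound_id": f"SYNMET{i:04d}", "name": f"synthetic compound {i}",
             "monoisotopic_mass": round(float(rng.uniform(120.0, 700.0)), 6),
             "category": "metabolite", "pathways": pw}
        )
    for i, (cid, name, formula) in enumerate(CURATED_TOXICANTS):
        if i >= n_toxicant_compounds:
            break
        rows.append(
            {"compound_id": cid, "name": name,
             "monoisotopic_mass": round(formula_mass(formula), 6),
             "category": "toxicant", "pathways": ""}
        )
    for i in range(len(CURATED_TOXICANTS), n_toxicant_compounds):
        rows.append(
            {"compound_id": f"SYNTOX{i:03d}", "name": f"synthetic toxicant {i}",
             "monoisotopic_mass": round(float(rng.uniform(150.0, 900.0)), 6),
             "category": "toxicant", "pathways": ""}
        )
    return MassTable(pd.DataFrame(rows))


def assign_mz_identities(
    study: SyntheticStudy,
    mass_table: MassTable,
    ppm_noise: float = 2.0,
    rt_window: tuple[float, float] = (10.0, 600.0),
) -> SyntheticStudy:
    """Assign each metabolite feature a compound identity and an observed m/z.

    The observed m/z is the protonated monoisotopic mass perturbed by a
    uniform relative error bounded by ``ppm_noise`` parts per million.
    Toxicant features draw from the toxicant table, all others from the
    metabolite table, each without replacement.  Retention times are uniform
    in ``rt_window`` (seconds).  Updates ``truth_compounds`` and the
    metabolite matrix's ``feature_meta`` in a returned copy of the study.
    """
    if ppm_noise < 0:
        raise ValidationError("ppm_noise must be >= 0")
    rng = _substreams(study.config.seed)["mz"]
    met = study.matrices["metabolite"]
    ids = met.feature_ids
    tox = set(study.truth_toxicants)
    regular = [f for f in ids if f not in tox]

    met_pool = mass_table.restrict("metabolite").table
    tox_pool = mass_table.restrict("toxicant").table
    if len(regular) > len(met_pool):
        raise ValidationError(
            f"{len(regular)} metabolite features but only {len(met_pool)} metabolite compounds"
        )
    if len(tox) > len(tox_pool):
        raise ValidationError(
            f"{len(tox)} toxicant features but only {len(tox_pool)} toxicant compounds"
        )

    compounds: dict[str, str] = {}
    mz = pd.Series(np.nan, index=ids)
    rt = pd.Series(rng.uniform(rt_window[0], rt_window[1], size=len(ids)), index=ids)

    pick = rng.choice(len(met_pool), size=len(regular), replace=False)
    for fid, k in zip(regular, pick):
        compounds[fid] = str(met_pool["compound_id"].iloc[k])
        u = rng.uniform(-ppm_noise, ppm_noise) * 1e-6
        mz[fid] = (float(met_pool["monoisotopic_mass"].iloc[k]) + PROTON_MASS) * (1 + u)
    pick = rng.choice(len(tox_pool), size=len(tox), replace=False)
    for fid, k in zip(study.truth_toxicants, pick):
        compounds[fid] = str(tox_pool["compound_id"].iloc[k])
        u = rng.uniform(-ppm_noise, ppm_noise) * 1e-6
        mz[fid] = (float(tox_pool["monoisotopic_mass"].iloc[k]) + PROTON_MASS) * (1 + u)

    new_meta = pd.DataFrame({"mz": mz, "rt": rt}, index=ids)
    new_met = OmicsMatrix("metabolite", met.values.copy(), new_meta)
    matrices = dict(study.matrices)
    matrices["metabolite"] = new_met
    return SyntheticStudy(
        config=study.config,
        matrices=matrices,
        metadata=study.metadata,
        truth_communities=dict(study.truth_communities),
        truth_differential=dict(study.truth_differential),
        truth_toxicants=list(study.truth_toxicants),
        truth_compounds=compounds,
    )


def truth_gene_sets(
    study: SyntheticStudy,
    layer: str = "rna",
    n_decoys: int = 10,
    decoy_size: int = 20,
) -> dict[str, tuple[str, list[str]]]:
    """Gene-set collection over a layer's feature ids: one set per planted
    factor plus random decoy sets, for enrichment power/calibration tests."""
    rng = _substreams(study.config.seed)["sets"]
    ids = study.matrices[layer].feature_ids
    sets: dict[str, tuple[str, list[str]]] = {}
    for k in range(study.config.n_factors):
        members = sorted(f for f in ids if study.truth_communities.get(f) == k)
        if members:
            sets[f"FACTOR{k}_{layer.upper()}"] = (f"planted factor {k} features", members)
    for d in range(n_decoys):
        size = min(decoy_size, len(ids))
        members = sorted(rng.choice(ids, size=size, replace=False).tolist())
        sets[f"DECOY{d}_{layer.upper()}"] = (f"random decoy set {d}", members)
    return sets


def simulate_study(config: SimConfig | None = None, ppm_noise: float = 2.0) -> tuple[SyntheticStudy, MassTable]:
    """Convenience wrapper: generate a study, build a matching mass table, and
    assign m/z identities."""
    config = config or SimConfig()
    n_met = int(config.n_features_per_layer["metabolite"])
    table = build_mass_table(
        n_metabolite_compounds=max(300, n_met),
        n_toxicant_compounds=max(12, config.n_toxicants),
        seed=config.seed,
    )
    study = generate_multiomics(config)
    study = assign_mz_identities(study, table, ppm_noise=ppm_noise)
    return study, table


def write_fixtures(study: SyntheticStudy, directory) -> dict[str, str]:
    """Write layer TSVs, sample metadata, truth tables, and a run manifest.

    The metabolite table is written apLCMS-style: ``mz``, ``time``, then one
    intensity column per injection.  Returns a manifest mapping of file paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    for layer in ("rna", "protein"):
        m = study.matrices[layer]
        p = directory / f"{layer}.tsv"
        out = m.values.copy()
        out.insert(0, "feature_id", out.index)
        out.to_csv(p, sep="\t", index=False)
        paths[layer] = str(p)

    met = study.matrices["metabolite"]
    p = directory / "metabolite.tsv"
    out = met.values.copy()
    meta = met.feature_meta if met.feature_meta is not None else pd.DataFrame(index=out.index)
    out.insert(0, "time", meta["rt"] if "rt" in meta else np.nan)
    out.insert(0, "mz", meta["mz"] if "mz" in meta else np.nan)
    out.to_csv(p, sep="\t", index_label="feature_id")
    paths["metabolite"] = str(p)

    p = directory / "samples.tsv"
    study.metadata.table.to_csv(p, sep="\t", index=False)
    paths["samples"] = str(p)

    truth = {
        "truth_communities": pd.DataFrame(
            sorted(study.truth_communities.items()), columns=["feature_id", "community"]
        ),
        "truth_differential": pd.DataFrame(
            sorted(study.truth_differential.items()), columns=["feature_id", "effect"]
        ),
        "truth_toxicants": pd.DataFrame({"feature_id": sorted(study.truth_toxicants)}),
        "truth_compounds": pd.DataFrame(
            sorted(study.truth_compounds.items()), columns=["feature_id", "compound_id"]
        ),
    }
    for name, df in truth.items():
        p = directory / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)

    manifest = {
        "seed": study.config.seed,
        "config": dataclasses.asdict(study.config),
        "files": paths,
    }
    p = directory / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest"] = str(p)
    return paths
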