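# Methods

This note documents the models and numerical choices behind `isletnet`: what
each stage computes, what the synthetic-data generator does and does not
emulate, and where the design was genuinely open.

## Study design assumed throughout

Two donor groups (case/control).  Transcript counts and LC-MS metabolomic
intensities are available for all donors (default 5+5, metabolomics measured
as 3 injections per donor); proteomic heavy/light ratios exist only for a 3+3
donor subset.  All thresholds are configuration-visible; the defaults are:

| parameter | default | meaning |
|---|---|---|
| `prevalence.rna` / `.metabolite` | 0.80 | feature detected in ≥ 80% of either group |
| `prevalence.protein` | 2/3 | detected in ≥ two-thirds of either group |
| `alpha_raw` | 0.05 | "differential" selection on raw Welch p |
| `alpha_fdr` | 0.10 | "significant" selection on BH-adjusted p |
| `gsea.min_size` / `.max_size` | 6 / 500 | set-size window after intersection with the ranked list |
| `gsea.weight_exponent` | 1 | weighted-KS exponent (standard GSEA) |
| annotation ppm | 5 | m/z tolerance, positive-mode adducts M+H, M+Na, M+K, M+NH₄ |
| `pathway.alpha` / min DA | 0.05 / 3 | retention: BH p < 0.05 and ≥ 3 DA metabolites |
| direction fraction | 0.80 | ≥ 80% of DA compounds up → "upregulated" (down analogous) |
| `network.cap` | 0.30 | per-layer feature cap, floor(0.30·N) top features by RSD |
| `network.threshold` / `.alpha` | 0.5 / 0.05 | edge retention on association score and correlation p (df = n−2) |
| `network.max_components` | 10 | PLS component ceiling |
| Q² limit | 0.0975 | conventional significance limit for component inclusion (min. 1) |
| `diffnet.delta` | 0.1 | strict \|Δ centrality\| flag threshold |

## Preprocessing

Stage order per layer is fixed: injection medians (metabolomics) →
prevalence filter → half-minimum imputation → log₁₀ → autoscaling where a
stage requires it.  Decisions worth stating:

- "Minimum value in the data set" is read as the **global matrix minimum**
  (one detection limit per platform), not per-feature.
- RNA zeros count as "not detected" for the prevalence filter but are kept
  as 0 counts afterwards — counts are not censored intensities and are never
  imputed.  For the transcript differential stage counts are normalized by
  median-of-ratios size factors and tested on log₁₀(x+1); networks consume
  non-normalized counts.
- Autoscaling before a Welch test does not change t or p (the statistic is
  invariant to per-feature affine maps); it is applied so that exported
  matrices match the stated metabolomics workflow.
- Duplicate-gene collapsing keeps the feature with the lowest raw p
  (ties → lexicographically smaller id); with no statistics available the
  fallback is highest mean abundance.
- Exactly-at-boundary prevalences (4/5 = 0.80, 2/3) are kept: the rules are
  "at least", implemented with a 1e−12 float guard.

## Differential statistics

Welch's t with Welch–Satterthwaite df; degenerate inputs are defined rather
than erroring (both variances zero: p = 1 for equal means, p = 0 with a
warning otherwise — this arises for case-only features whose control values
are all imputed to the same constant).  BH adjustment is statsmodels'
step-up.  The GSEA rank score is `log₂FC × (−log₁₀ p)` with p = 0 floored at
1e−300 so ranks stay finite and ordered.  Fold changes are emitted on both
interpretations: for log-scale data `log₂FC = Δmean × log₂10`, otherwise the
direct ratio of raw-scale means.

## Preranked GSEA

Weighted-KS running sum: hits advance by |score|^w / Σ_hits |score|^w,
misses retreat by 1/(N−N_hits); ES is the signed maximum deviation and the
leading edge the members at or before (after, for negative ES) the extremum.
The null is **random member sets of identical size** drawn from the ranked
ids — a preranked-style null is the only option when the ranks are delta
centralities or proximity weights, for which no phenotype permutation
exists.  p = (1 + #{same-sign null with |ES_null| ≥ |ES|}) / (1 + #same-sign
null), BH across surviving sets; null draws are shared between sets of equal
size (they are exchangeable), which keeps 200-set runs fast.  Ranking ties
break by id; everything is deterministic under the seed.  ES is invariant to
positive rescaling of the scores only for w = 0; with the default w = 1 it
is not, by construction.

## m/z annotation and pathway enrichment

Matching is pure m/z: |observed − theoretical|/theoretical ≤ ppm over the
four singly charged positive-mode adducts, with an optional primary-ion rule
(a compound counts only if one of its features matches as M+H).  The
multistage retention-time/intensity clustering of full annotation suites is
deliberately not reproduced — a documented fidelity reduction; matching is
monotone in the tolerance and checked against an all-pairs oracle.

Pathway enrichment is compound-level: features annotating the same compound
count once.  The observed statistic is the one-sided hypergeometric tail;
significance comes from re-drawing |DA| features from all annotated features
(1000 permutations by default).  Because the hypergeometric statistic is
heavily discrete, permutation ties are counted with half weight (mid-p);
with full tie-counting the permutation p is visibly conservative and fails a
KS uniformity check under the null.  A gamma fit to the null scores, as some
metabolomics tools apply, is intentionally omitted: at this scale the raw
empirical p needs no parametric smoothing.  The 80% direction rule counts
unique compounds, not features, and "exactly 80%" meets the criterion.

## Network integration

The feature cap is floor(0.30·N) by RSD = sd/|mean| (this floor uniquely
matches both worked examples: 8842 → 2652 and 5323 → 1596).  Per layer pair
(X = transcripts against proteins and metabolites; X = proteins against
metabolites), blocks are column-standardized and components extracted as the
dominant singular pair of the residual cross-covariance, with optional
soft-thresholding of loadings (`keep_x`/`keep_y`; off by default — the 30%
cap already supplies sparsity), deflating both blocks on the X variate.

**Component count.**  Components are added while leave-one-out Q² =
1 − PRESS/RSS ≥ 0.0975 (minimum one, maximum ten).  The Q² here holds the
component direction fixed at its full-sample estimate and refits only the
variate→Y regression in each fold.  Refitting the direction per fold is the
textbook variant, but when two latent factors of similar strength compete
for the dominant singular pair the per-fold direction flips between them and
PRESS collapses to the baseline — Q² ≈ 0 for strongly structured data.  The
fixed-direction form is stable in that regime and remains null-calibrated
(pure-noise blocks stop at one component).

**Association scores.**  score(i,j) = Σ_h cor(xᵢ, t_h)·cor(yⱼ, t_h) over the
retained X variates, clipped to [−1,1].  When the variates span the X block's
column space this reduces exactly to the Pearson correlation between blocks
(the module's primary correctness anchor, tested to 1e−6); with fewer
components it is a low-rank filtered correlation.  Edge p-values treat the
score as a Pearson r with df = n−2 — whether an adjustment for PLS
dimensionality would be more faithful is unknowable from the published
descriptions; df = n−2 is declared.  Edges require |score| ≥ 0.5 AND
p < 0.05; at n = 5 this means sampled |r| ≥ 0.878, at n = 3, |r| ≥ 0.997 —
the binding constraint of tiny-n condition networks.

Only inter-layer edges exist (pairwise integration produces no intra-layer
scores).  Communities are igraph's multilevel (Louvain) modularity
optimization on |weight|, seeded; centrality is the principal eigenvector of
the |weight| adjacency by power iteration (tolerance 1e−12; a +I spectral
shift guarantees convergence on bipartite components), computed per
connected component, each component's vector normalized to max 1 and scaled
by its principal eigenvalue relative to the graph's largest, so the global
maximum is exactly 1.  Edge signs are kept as attributes for
direction-of-correlation reporting.

## Differential network and toxicant nexus

Delta centrality unions the node sets; a node absent from one network has
centrality 0 there ("no connectivity"), and |Δ| > 0.1 (strict) flags changed
features.  The nexus rule is the three-way intersection: toxicant-annotated,
more abundant in cases (raw p < 0.05 and case mean > control mean), and
Δ > 0.1.  Proximity weights are the **signed** sum of direct case-network
edge weights to nexus chemicals (one hop — the analysis examines direct
connections; an inverse-shortest-path alternative is exposed nowhere because
one-hop is the declared reading).  Signed weights mean inverse associations
rank at the bottom of the list and appear as negative-ES enrichments, which
is the readout the signed choice exists to preserve.

## Synthetic-data generator

Per sample, latent factors z_k ~ N(0,1) are shared across layers; feature f
in factor k has latent λ_f·z_k + δ_f·1[case] + ε.  RNA is observed as
Poisson counts of exp(baseline + 0.35·latent) with log-normal library-size
offsets (sd 0.05); protein as positive ratios 10^(baseline + 0.3·latent) on
a 3+3 donor subset; metabolite as 10^(baseline + 0.5·latent) with cells
below the `lod_quantile` (default 0.15) of the layer censored, expanded into
3 injection columns with multiplicative noise (sd 0.05 on the log scale).
Toxicant features (default 3) are metabolite features that are below
detection in every control sample and load on factor 0 with amplified
loadings (U(2.0, 2.4)) — exogenous chemicals vary far more between exposed
donors than endogenous metabolites, which is also what carries them through
the RSD cap.

Three generator-design choices deserve emphasis, because they define what
passing tests do and do not show:

1. **Group-wise orthonormal factor scores.**  Within each donor group the
   factor score matrix is centered, orthogonalized and scaled to unit sample
   variance.  At n = 5 raw Gaussian draws carry large chance inter-factor
   correlations and variance imbalances; these would dominate every
   downstream result (whole factors vanish from the RSD cap, communities
   merge) and make the planted truth ill-defined.  The generator therefore
   plants *exactly* orthogonal modules; real data is noisier in ways these
   simulations do not probe.
2. **A dominant hub module with condition-dependent coherence.**  Factor 0
   holds half the features (`hub_factor_share`), is tight in cases
   (noise sd 0.1) and dysregulated in controls (noise sd 1.2); secondary
   factors have noise sd 0.35 in both groups.  This plants the
   connectivity-difference signal — positive delta centrality for hub
   members, toxicants central only in the case network — that the
   differential-network stage is supposed to recover.  Recovery rates
   measured on these simulations quantify the pipeline's behaviour *when
   such a signal exists*; they say nothing about its prevalence in real
   islets.
3. **Tight within-module correlation.**  With 5 (3 for protein) samples per
   condition, an edge requires sampled |r| ≥ 0.878 (0.997), so recoverable
   planted modules must have near-noiseless co-regulation (population
   r ≈ 0.99 in the case hub).  This is tighter than typical biology; it is
   the price of emulating a pilot-scale design at which the method operates.

Community-recovery ARI is evaluated on the **case-condition network**, where
the planted three-block structure is fully coherent by design (the control
condition deliberately carries the dysregulation).  Differential features
(10% of each layer, standardized shift 2.0 with random sign) are drawn
independently of pathways, so pathway enrichment on synthetic studies is a
specificity check, not a power check.  m/z identities are compound masses
plus the proton mass, perturbed by a uniform relative error bounded by
`ppm_noise` (default 2 ppm); mass tables are synthetic stand-ins built from
curated elemental formulas plus random-mass filler compounds.  Not emulated:
batch effects, retention-time structure, isotopologues and multi-adduct
degeneracy, missingness mechanisms other than left-censoring, and any
realistic pathway topology.

## Problem sizes and determinism

Default synthetic studies use 300/150/240 features per layer — large enough
that the 30% cap, community detection and centrality operate in their
intended regime, small enough that the full 20-seed recovery simulation runs
in seconds.  The two worked-example caps run at the full published sizes
(8842, 5323).  A single master seed drives named substreams (factors, one
per layer, m/z, gene sets), so partial reruns are reproducible; igraph's RNG
is re-seeded at each community-detection call; permutation tests derive all
draws from their seed argument.

## Known limitations

- DESeq2's negative-binomial Wald test and limma's moderated t are replaced
  by Welch on transformed data for all layers; the integration and network
  logic, not the per-feature GLM, is the target of this package.
- The sparse-PLS association formula and its p-value treatment follow the
  declared conventions above; other integration suites may differ in
  deflation mode, score orientation, and df.
- Eigenvector centrality concentrates mass on the dominant community; nodes
  of subdominant components are scaled by eigenvalue ratios, a convention
  (documented above) that affects absolute Δ values near the 0.1 threshold.
- At n = 3 per condition the protein layer contributes edges only at
  |r| ≥ 0.997; protein-side power in condition networks is structurally
  minimal, and enrichment power properties are therefore demonstrated on
  the transcript layer.
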