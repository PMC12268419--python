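"""Per-layer filtering, summarization, imputation, and transformation.

The stage order for each layer is fixed: triplicate medians (metabolomics
only) -> group-wise prevalence filter -> half-minimum imputation -> log10 ->
autoscaling where a stage requires it.  Thresholds follow the study design:
features must be detected in at least 80% of either group (two-thirds for
proteomics), and missing below-detection intensities are replaced with half
of the minimum observed value in the data set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import OmicsMatrix, SampleMetadata, ValidationError, group_columns

__all__ = [
    "summarize_triplicate_medians",
    "prevalence_filter",
    "impute_below_detection",
    "log10_transform",
    "autoscale",
    "collapse_duplicates",
    "size_factors",
    "PREVALENCE_DEFAULTS",
]

logger = logging.getLogger(__name__)

PREVALENCE_DEFAULTS = {"rna": 0.8, "protein": 2.0 / 3.0, "metabolite": 0.8}


def summarize_triplicate_medians(m: OmicsMatrix, meta: SampleMetadata) -> OmicsMatrix:
    """Collapse injection columns to one column per biological sample.

    Each feature's value is the median over that sample's injections,
    ignoring missing values; a sample whose injections are all missing stays
    missing.
    """
    if m.layer != "metabolite":
        raise ValidationError("triplicate summarization applies to the metabolite layer")
    rep_map = meta.replicate_map()
    known = {inj for injections in rep_map.values() for inj in injections} | set(rep_map)
    orphans = [c for c in m.sample_ids if c not in known]
    if orphans:
        raise ValidationError(f"injection columns without replicate_of mapping: {orphans[:5]}")

    cols = {}
    order = []
    for bio in meta.table.loc[meta.table["replicate_of"].isna(), "sample_id"]:
        injections = [c for c in rep_map.get(bio, []) if c in m.values.columns]
        if not injections:
            continue
        cols[bio] = m.values[injections].median(axis=1, skipna=True)
        order.append(bio)
    out = pd.DataFrame(cols, columns=order, index=m.values.index)
    return m.with_values(out)


def _detected(m: OmicsMatrix) -> pd.DataFrame:
    """Boolean detection mask: nonmissing, and for counts, > 0."""
    mask = m.values.notna()
    if m.layer == "rna":
        mask &= m.values > 0
    return mask


def prevalence_filter(m: OmicsMatrix, meta: SampleMetadata, threshold: float) -> OmicsMatrix:
    """Keep features detected in at least ``threshold`` of either group.

    Detection means nonmissing (and nonzero for counts).  A feature survives
    when its detected fraction reaches the threshold in the case group OR in
    the control group — the "at least 80% of either" rule (two-thirds for
    proteomics).
    """
    if not (0 < threshold <= 1):
        raise ValidationError(f"threshold must be in (0,1], got {threshold}")
    groups = group_columns(m, meta)
    for g, cols in groups.items():
        if not cols:
            raise ValidationError(f"no samples in group {g!r}")
    det = _detected(m)
    keep = pd.Series(False, index=m.values.index)
    eps = 1e-12  # float-safe boundary: 4/5 >= 0.8 must hold
    for cols in groups.values():
        frac = det[cols].sum(axis=1) / len(cols)
        keep |= frac >= threshold - eps
    kept = m.values.index[keep]
    logger.info(
        "prevalence_filter(%s, threshold=%.4f): kept %d / %d features",
        m.layer, threshold, keep.sum(), m.n_features,
    )
    if not keep.any():
        logger.warning("prevalence_filter removed every feature")
    return m.subset_features(kept)


def impute_below_detection(m: OmicsMatrix) -> OmicsMatrix:
    """Replace missing cells with half of the data set's minimum observed value."""
    vals = m.values
    observed = vals.stack()
    if observed.empty:
        raise ValidationError("cannot impute an all-missing matrix")
    fill = float(observed.min()) / 2.0
    out = vals.fillna(fill)
    return m.with_values(out)


def log10_transform(m: OmicsMatrix) -> OmicsMatrix:
    """Elementwise log10; every value must be strictly positive."""
    vals = m.values
    bad = (vals <= 0) & vals.notna()
    if bad.any().any():
        feat = bad.any(axis=1).idxmax()
        samp = bad.loc[feat].idxmax()
        raise ValidationError(
            f"log10_transform: nonpositive value at feature {feat!r}, sample {samp!r}"
        )
    return m.with_values(np.log10(vals), transformed=True)


def autoscale(m: OmicsMatrix) -> OmicsMatrix:
    """Per-feature standardization: mean 0, sample standard deviation 1 (ddof=1).

    Zero-variance rows become all zeros (with a warning) rather than NaN.
    """
    vals = m.values
    if vals.shape[1] < 2:
        raise ValidationError("autoscale needs at least 2 samples")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.warning("autoscale: %d zero-variance features set to all zeros", int(zero.sum()))
    sd_safe = sd.mask(zero, 1.0)
    out = vals.sub(mean, axis=0).div(sd_safe, axis=0)
    out[zero] = 0.0
    return m.with_values(out, transformed=True)


def collapse_duplicates(
    m: OmicsMatrix,
    key: str = "symbol",
    stats: pd.DataFrame | None = None,
    rule: str = "lowest_p",
) -> OmicsMatrix:
    """One feature per annotation key; unannotated features are dropped.

    ``rule='lowest_p'`` keeps, among features sharing a key, the one with the
    smallest raw p-value in ``stats`` (a per-feature table with a ``p``
    column indexed by feature id); ties break to the lexicographically
    smallest feature id.  ``rule='highest_mean'`` keeps the feature with the
    largest mean value — the fallback when no statistics exist yet.
    """
    if m.feature_meta is None or key not in m.feature_meta.columns:
        raise ValidationError(f"feature metadata has no {key!r} column")
    keys = m.feature_meta[key]
    annotated = keys.notna() & (keys.astype(str) != "")
    ids = m.values.index[annotated]
    keys = keys[annotated]

    if rule == "lowest_p":
        if stats is None:
            raise ValidationError("rule='lowest_p' requires a stats table")
        missing = [f for f in ids if f not in stats.index]
        if missing:
            raise ValidationError(f"stats table missing features: {missing[:5]}")
        score = stats.loc[ids, "p"]
        ascending = True
    elif rule == "highest_mean":
        score = m.values.loc[ids].mean(axis=1)
        ascending = False
    else:
        raise ValidationError(f"unknown duplicate rule {rule!r}")

    df = pd.DataFrame({"key": keys, "score": score, "feature_id": ids}, index=ids)
    df = df.sort_values(["key", "score", "feature_id"], ascending=[True, ascending, True])
    winners = df.drop_duplicates("key", keep="first")["feature_id"]
    keep = [f for f in m.values.index if f in set(winners)]  # preserve original order
    logger.info("collapse_duplicates(%s): %d -> %d features", m.layer, m.n_features, len(keep))
    return m.subset_features(keep)


def size_factors(m: OmicsMatrix) -> pd.Series:
    """Median-of-ratios library-size factors for a count matrix.

    Used only to normalize counts before differential testing; network
    construction consumes non-normalized counts.
    """
    if m.layer != "rna":
        raise ValidationError("size factors are defined for count (rna) matrices")
    counts = m.values
    log_counts = np.log(counts.where(counts > 0))
    ref = log_counts.mean(axis=1)  # geometric mean over samples (detected only)
    usable = log_counts.notna().all(axis=1)
    if not usable.any():
        raise ValidationError("no feature detected in all samples; cannot compute size factors")
    ratios = log_counts.loc[usable].sub(ref[usable], axis=0)
    return np.exp(ratios.median(axis=0))
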