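"""Metabolite pathway enrichment over m/z annotations, mummichog-style.

Pathway membership is evaluated on unique annotated compounds.  The observed
statistic per pathway is a one-sided hypergeometric overrepresentation
p-value; significance comes from a permutation null in which random feature
sets of the same size as the differentially abundant (DA) set are drawn from
all annotated features, followed by BH adjustment.  A pathway is retained
when its adjusted p is below 0.05 and it contains at least three DA
metabolites; retained pathways are classified upregulated/downregulated when
at least 80% of their DA metabolites shift in one direction, else mixed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ValidationError
from .diff import bh_adjust

__all__ = [
    "overrepresentation_test",
    "permutation_pathways",
    "classify_direction",
    "PATHWAY_ALPHA",
    "PATHWAY_MIN_DA",
    "DIRECTION_FRACTION",
]

logger = logging.getLogger(__name__)

PATHWAY_ALPHA = 0.05
PATHWAY_MIN_DA = 3
DIRECTION_FRACTION = 0.8


def overrepresentation_test(n_da_in: int, n_total_in: int, n_da_all: int, n_universe: int) -> float:
    """One-sided hypergeometric tail P(X >= n_da_in).

    Population ``n_universe`` compounds, of which ``n_total_in`` belong to
    the pathway; ``n_da_all`` DA compounds are drawn; ``n_da_in`` of them
    land in the pathway.
    """
    if not (0 <= n_da_in <= min(n_total_in, n_da_all)):
        raise ValidationError(
            f"inconsistent counts: n_da_in={n_da_in}, n_total_in={n_total_in}, n_da_all={n_da_all}"
        )
    if n_total_in > n_universe or n_da_all > n_universe:
        raise ValidationError("pathway or DA count exceeds universe size")
    return float(sps.hypergeom.sf(n_da_in - 1, n_universe, n_total_in, n_da_all))


def _compounds_of(annotations: pd.DataFrame, features) -> set[str]:
    feats = set(features)
    hit = annotations["feature_id"].isin(feats)
    return set(annotations.loc[hit, "compound_id"])


def permutation_pathways(
    annotations: pd.DataFrame,
    da_features,
    pathways: dict[str, tuple[str, list[str]]],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-calibrated pathway overrepresentation on annotated features.

    Parameters
    ----------
    annotations : DataFrame with ``feature_id`` and ``compound_id`` columns
        (one row per tentative match; a compound is DA if any DA feature
        matches it — the primary-ion rule is applied upstream).
    da_features : iterable of differentially abundant feature ids
        (must be a subset of the annotated features).
    pathways : mapping pathway_id -> (name, member compound ids).

    Returns a DataFrame indexed by pathway id with ``n_da``, ``n_total``,
    ``p_obs`` (hypergeometric), ``p_raw`` (permutation), ``p_adj`` (BH) and
    ``retained`` (p_adj < 0.05 and n_da >= 3).  Deterministic under ``seed``.
    """
    if annotations.empty:
        logger.warning("permutation_pathways: no annotations; empty result")
        return pd.DataFrame(
            columns=["n_da", "n_total", "p_obs", "p_raw", "p_adj", "retained"]
        ).rename_axis("pathway_id")
    da_features = sorted(set(da_features))
    all_features = sorted(set(annotations["feature_id"]))
    stray = set(da_features) - set(all_features)
    if stray:
        raise ValidationError(f"DA features not annotated: {sorted(stray)[:5]}")

    universe = sorted(set(annotations["compound_id"]))
    comp_index = {c: i for i, c in enumerate(universe)}
    n_universe = len(universe)

    pw_ids = sorted(pathways)
    membership = np.zeros((len(pw_ids), n_universe), dtype=np.int64)
    for r, pid in enumerate(pw_ids):
        _, members = pathways[pid]
        for c in members:
            if c in comp_index:
                membership[r, comp_index[c]] = 1
    n_total_in = membership.sum(axis=1)

    def pathway_pvals(features) -> tuple[np.ndarray, np.ndarray, int]:
        da_comp = _compounds_of(annotations, features)
        da_vec = np.zeros(n_universe, dtype=np.int64)
        for c in da_comp:
            da_vec[comp_index[c]] = 1
        n_da_all = int(da_vec.sum())
        n_da_in = membership @ da_vec
        p = sps.hypergeom.sf(n_da_in - 1, n_universe, n_total_in, n_da_all)
        return n_da_in, p, n_da_all

    n_da_obs, p_obs, _ = pathway_pvals(da_features)

    rng = np.random.default_rng(seed)
    k = len(da_features)
    null_less = np.zeros(len(pw_ids), dtype=float)
    null_ties = np.zeros(len(pw_ids), dtype=float)
    for _ in range(n_perm):
        draw = rng.choice(all_features, size=k, replace=False)
        _, p_null, _ = pathway_pvals(draw)
        null_less += p_null < p_obs - 1e-12
        null_ties += np.abs(p_null - p_obs) <= 1e-12
    # mid-p convention: the hypergeometric statistic is heavily discrete, so
    # counting ties fully would make the permutation p conservative; half
    # weight on ties keeps it calibrated (approximately uniform under null)
    p_perm = (0.5 + null_less + 0.5 * null_ties) / (1 + n_perm)

    out = pd.DataFrame(
        {
            "n_da": n_da_obs.astype(int),
            "n_total": n_total_in.astype(int),
            "p_obs": p_obs,
            "p_raw": p_perm,
        },
        index=pd.Index(pw_ids, name="pathway_id"),
    )
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["retained"] = (out["p_adj"] < PATHWAY_ALPHA) & (out["n_da"] >= PATHWAY_MIN_DA)
    return out


def classify_direction(da_compound_signs: dict[str, float]) -> str:
    """Direction label from per-compound abundance signs (case vs control).

    At least 80% of DA compounds up -> ``upregulated``; at least 80% down ->
    ``downregulated``; anything else ``mixed``.
    """
    if not da_compound_signs:
        raise ValidationError("direction is undefined with zero DA members")
    signs = np.sign(list(da_compound_signs.values()))
    n = len(signs)
    frac_up = (signs > 0).sum() / n
    frac_down = (signs < 0).sum() / n
    if frac_up >= DIRECTION_FRACTION - 1e-12:
        return "upregulated"
    if frac_down >= DIRECTION_FRACTION - 1e-12:
        return "downregulated"
    return "mixed"


def pathway_directions(
    annotations: pd.DataFrame,
    da_features,
    feature_signs: pd.Series,
    pathways: dict[str, tuple[str, list[str]]],
) -> pd.Series:
    """Direction label per pathway with at least one DA compound.

    A compound's sign is the sign of the summed effect of its DA features
    (features annotating the same compound count once, via their net sign).
    """
    da_features = sorted(set(da_features))
    sub = annotations[annotations["feature_id"].isin(da_features)]
    comp_sign: dict[str, float] = {}
    for cid, grp in sub.groupby("compound_id"):
        comp_sign[str(cid)] = float(np.sign(feature_signs.reindex(grp["feature_id"]).sum()))
    labels = {}
    for pid in sorted(pathways):
        _, members = pathways[pid]
        signs = {c: s for c, s in comp_sign.items() if c in set(members) and s != 0}
        if signs:
            labels[pid] = classify_direction(signs)
    return pd.Series(labels, name="direction")
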