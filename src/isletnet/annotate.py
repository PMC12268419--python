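"""m/z-based annotation of LC-MS features against compound mass tables.

Untargeted metabolomics reports features as (m/z, retention time) pairs;
tentative identities come from matching observed m/z values to theoretical
adduct masses of known compounds within a parts-per-million tolerance.  Two
tables are used here: a general metabolite reference and a toxicant table
(T3DB-style) for hazardous-chemical annotation at 5 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import ADDUCT_SHIFTS, PRIMARY_ADDUCT
from .containers import OmicsMatrix, ValidationError

__all__ = [
    "MassTable",
    "adduct_mz",
    "match_features",
    "annotate_toxicants",
    "read_mass_table",
    "write_mass_table",
]

MASS_TABLE_COLUMNS = ["compound_id", "name", "monoisotopic_mass", "category", "pathways"]


@dataclass
class MassTable:
    """Compound reference table: id, name, monoisotopic mass (Da), category.

    ``category`` is ``metabolite`` or ``toxicant``; ``pathways`` is a
    semicolon-joined list of pathway ids (may be empty).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(MASS_TABLE_COLUMNS[:4]) - set(self.table.columns)
        if missing:
            raise ValidationError(f"mass table missing columns: {sorted(missing)}")
        if "pathways" not in self.table.columns:
            self.table = self.table.assign(pathways="")
        if self.table.empty:
            raise ValidationError("mass table is empty")
        if self.table["compound_id"].duplicated().any():
            raise ValidationError("duplicate compound_id in mass table")
        if (self.table["monoisotopic_mass"] <= 0).any():
            raise ValidationError("monoisotopic masses must be positive")
        bad = set(self.table["category"]) - {"metabolite", "toxicant"}
        if bad:
            raise ValidationError(f"unknown mass-table categories: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    def restrict(self, category: str) -> "MassTable":
        sub = self.table[self.table["category"] == category]
        return MassTable(sub.reset_index(drop=True))

    def pathway_members(self) -> dict[str, list[str]]:
        """Pathway id -> member compound ids (deduplicated, sorted)."""
        members: dict[str, set[str]] = {}
        for _, row in self.table.iterrows():
            raw = row.get("pathways", "")
            if not isinstance(raw, str) or not raw:
                continue
            for pid in raw.split(";"):
                if pid:
                    members.setdefault(pid, set()).add(row["compound_id"])
        return {pid: sorted(ids) for pid, ids in sorted(members.items())}

    def __len__(self) -> int:
        return len(self.table)


def adduct_mz(mass: float, adduct: str) -> float:
    """Theoretical m/z of a singly charged positive-mode adduct of ``mass``."""
    if mass <= 0:
        raise ValidationError(f"compound mass must be positive, got {mass}")
    if adduct not in ADDUCT_SHIFTS:
        raise ValidationError(f"unknown adduct {adduct!r}; known: {sorted(ADDUCT_SHIFTS)}")
    return mass + ADDUCT_SHIFTS[adduct]


def match_features(
    feature_meta: pd.DataFrame,
    table: MassTable,
    ppm: float = 5.0,
    require_primary: bool = False,
    adducts: tuple[str, ...] = tuple(ADDUCT_SHIFTS),
) -> pd.DataFrame:
    """Match feature m/z values to compound adduct masses at a ppm tolerance.

    A feature matches a compound under adduct ``a`` when
    ``|observed - theoretical| / theoretical * 1e6 <= ppm``.  With
    ``require_primary`` a compound's matches are reported only if at least one
    of them is the protonated (M+H) form, mirroring the primary-ion rule of
    pathway-analysis tools.  All qualifying (feature, compound, adduct) triples
    are returned sorted by absolute ppm error (ties by feature then compound id).

    Parameters
    ----------
    feature_meta : DataFrame indexed by feature id with an ``mz`` column.
    """
    if ppm <= 0:
        raise ValidationError("ppm tolerance must be positive")
    if "mz" not in feature_meta.columns:
        raise ValidationError("feature metadata has no 'mz' column")
    feats = feature_meta.dropna(subset=["mz"])
    rows = []
    observed = feats["mz"].to_numpy(dtype=float)
    feat_ids = feats.index.to_numpy()
    masses = table.table["monoisotopic_mass"].to_numpy(dtype=float)
    comp_ids = table.table["compound_id"].to_numpy()
    for adduct in adducts:
        theoretical = masses + ADDUCT_SHIFTS[adduct]
        # all-pairs ppm errors: features x compounds
        err = (observed[:, None] - theoretical[None, :]) / theoretical[None, :] * 1e6
        fi, ci = np.nonzero(np.abs(err) <= ppm)
        for f, c in zip(fi, ci):
            rows.append(
                {
                    "feature_id": feat_ids[f],
                    "compound_id": comp_ids[c],
                    "adduct": adduct,
                    "theoretical_mz": theoretical[c],
                    "ppm_error": err[f, c],
                }
            )
    ann = pd.DataFrame(rows, columns=["feature_id", "compound_id", "adduct", "theoretical_mz", "ppm_error"])
    if require_primary and not ann.empty:
        primary_compounds = set(ann.loc[ann["adduct"] == PRIMARY_ADDUCT, "compound_id"])
        ann = ann[ann["compound_id"].isin(primary_compounds)]
    if not ann.empty:
        ann = ann.assign(_abs=ann["ppm_error"].abs())
        ann = ann.sort_values(["_abs", "feature_id", "compound_id"]).drop(columns="_abs")
    return ann.reset_index(drop=True)


def annotate_toxicants(
    features: OmicsMatrix | pd.DataFrame,
    toxicant_table: MassTable,
    ppm: float = 5.0,
) -> pd.DataFrame:
    """Annotate features against the toxicant mass table at (default) 5 ppm.

    Multiple annotations per feature are preserved; dual annotations across
    tables are resolved downstream, never collapsed here.
    """
    meta = features.feature_meta if isinstance(features, OmicsMatrix) else features
    if meta is None:
        raise ValidationError("features carry no m/z metadata")
    return match_features(meta, toxicant_table.restrict("toxicant"), ppm=ppm)


def read_mass_table(path) -> MassTable:
    return MassTable(pd.read_csv(path, sep="\t"))


def write_mass_table(table: MassTable, path) -> None:
    table.table.to_csv(path, sep="\t", index=False)
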