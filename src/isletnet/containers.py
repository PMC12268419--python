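"""Core in-memory containers for the tri-omics pipeline.

An :class:`OmicsMatrix` is a features x samples table tagged with its omics
layer (``rna`` counts, ``protein`` log-scale heavy/light ratios, or
``metabolite`` LC-MS intensities), optionally carrying per-feature metadata
such as m/z and retention time.  :class:`SampleMetadata` maps sample columns
to case/control groups and, for metabolomic injection columns, to the
biological sample they replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LAYERS = ("rna", "protein", "metabolite")
GROUPS = ("case", "control")

__all__ = ["LAYERS", "GROUPS", "OmicsMatrix", "SampleMetadata", "ValidationError"]


class ValidationError(ValueError):
    """Raised when a container or configuration violates its invariants."""


@dataclass
class OmicsMatrix:
    """Features x samples numeric table for one omics layer.

    Parameters
    ----------
    layer : str
        One of ``rna``, ``protein``, ``metabolite``.
    values : pandas.DataFrame
        Numeric matrix, rows indexed by unique feature ids, columns by unique
        sample ids.  Missing (below-detection) cells are NaN.
    feature_meta : pandas.DataFrame, optional
        Per-feature metadata aligned to ``values.index``; metabolite layers
        typically carry ``mz`` (Da) and ``rt`` (seconds), rna/protein layers a
        ``symbol`` column for gene-level collapsing.
    """

    layer: str
    values: pd.DataFrame
    feature_meta: pd.DataFrame | None = None
    transformed: bool = False  # log/scaled values: raw-scale invariants not checked

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:3].tolist()
            raise ValidationError(f"duplicate feature ids: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][:3].tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        vals = self.values.to_numpy(dtype=float)
        if not self.transformed:
            if self.layer == "rna":
                finite = vals[np.isfinite(vals)]
                if finite.size and ((finite < 0).any() or (finite % 1 != 0).any()):
                    raise ValidationError("rna values must be nonnegative integer counts")
            elif self.layer == "metabolite":
                finite = vals[np.isfinite(vals)]
                if finite.size and (finite < 0).any():
                    raise ValidationError("metabolite intensities must be nonnegative or missing")
        if self.feature_meta is not None:
            if not self.feature_meta.index.equals(self.values.index):
                self.feature_meta = self.feature_meta.reindex(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        meta = None if self.feature_meta is None else self.feature_meta.loc[feature_ids]
        return OmicsMatrix(self.layer, self.values.loc[feature_ids], meta, self.transformed)

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.layer, self.values[list(sample_ids)], self.feature_meta, self.transformed)

    def with_values(self, values: pd.DataFrame, transformed: bool | None = None) -> "OmicsMatrix":
        meta = None
        if self.feature_meta is not None:
            meta = self.feature_meta.reindex(values.index)
        if transformed is None:
            transformed = self.transformed
        return OmicsMatrix(self.layer, values, meta, transformed)

    def copy(self) -> "OmicsMatrix":
        meta = None if self.feature_meta is None else self.feature_meta.copy()
        return OmicsMatrix(self.layer, self.values.copy(), meta, self.transformed)


@dataclass
class SampleMetadata:
    """Sample-to-group mapping, with optional injection-replicate structure.

    ``table`` columns: ``sample_id``, ``group`` (case|control) and optionally
    ``replicate_of`` linking a metabolomic injection column to its biological
    sample.  Biological samples have ``replicate_of`` empty/NaN.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"sample metadata missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)} (expected {GROUPS})")
        if "replicate_of" not in self.table.columns:
            self.table = self.table.assign(replicate_of=pd.NA)
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def group_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in metadata")
        return str(row["group"].iloc[0])

    def samples_in_group(self, group: str, biological_only: bool = True) -> list[str]:
        tbl = self.table
        mask = tbl["group"] == group
        if biological_only:
            mask &= tbl["replicate_of"].isna()
        return tbl.loc[mask, "sample_id"].tolist()

    def replicate_map(self) -> dict[str, list[str]]:
        """Biological sample id -> its injection column ids (possibly itself)."""
        tbl = self.table
        out: dict[str, list[str]] = {}
        for _, row in tbl.iterrows():
            parent = row["replicate_of"]
            sid = row["sample_id"]
            if pd.isna(parent) or parent == "":
                out.setdefault(sid, [])
            else:
                out.setdefault(str(parent), []).append(sid)
        # biological samples with no separate injection columns map to themselves
        return {k: (v if v else [k]) for k, v in out.items()}

    def subset(self, sample_ids) -> "SampleMetadata":
        keep = set(sample_ids)
        tbl = self.table[self.table["sample_id"].isin(keep)].reset_index(drop=True)
        return SampleMetadata(tbl)


def group_columns(m, meta: SampleMetadata) -> dict[str, list[str]]:
    """Matrix columns split by group, in matrix column order.

    ``m`` may be an OmicsMatrix or a plain features x samples DataFrame.
    Injection columns inherit the group of their biological sample.
    """
    sample_ids = m.sample_ids if isinstance(m, OmicsMatrix) else list(m.columns)
    tbl = meta.table.set_index("sample_id")
    out: dict[str, list[str]] = {g: [] for g in GROUPS}
    for sid in sample_ids:
        if sid not in tbl.index:
            raise ValidationError(f"matrix sample {sid!r} has no metadata row")
        out[str(tbl.loc[sid, "group"])].append(sid)
    return out
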