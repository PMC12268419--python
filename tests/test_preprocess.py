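"""Filtering, summarization, imputation, and transformation rules."""

import numpy as np
import pandas as pd
import pytest

from isletnet.containers import OmicsMatrix, SampleMetadata, ValidationError
from isletnet.preprocess import (
    autoscale,
    collapse_duplicates,
    impute_below_detection,
    log10_transform,
    prevalence_filter,
    summarize_triplicate_medians,
)


def _meta(case, control, replicates=None):
    rows = [{"sample_id": s, "group": "case"} for s in case]
    rows += [{"sample_id": s, "group": "control"} for s in control]
    if replicates:
        for inj, bio in replicates.items():
            grp = "case" if bio in case else "control"
            rows.append({"sample_id": inj, "group": grp, "replicate_of": bio})
    return SampleMetadata(pd.DataFrame(rows))


class TestTriplicateMedians:
    def test_median_rules(self):
        meta = _meta(["S1"], ["S2"], replicates={f"S1_{r}": "S1" for r in (1, 2, 3)}
                     | {f"S2_{r}": "S2" for r in (1, 2, 3)})
        vals = pd.DataFrame(
            {
                "S1_1": [1.0, 4.0, np.nan],
                "S1_2": [2.0, np.nan, np.nan],
                "S1_3": [9.0, 6.0, np.nan],
                "S2_1": [1.0, 1.0, 1.0],
                "S2_2": [1.0, 1.0, 1.0],
                "S2_3": [1.0, 1.0, 1.0],
            },
            index=["f1", "f2", "f3"],
        )
        m = OmicsMatrix("metabolite", vals)
        out = summarize_triplicate_medians(m, meta)
        assert out.sample_ids == ["S1", "S2"]
        assert out.values.loc["f1", "S1"] == 2.0  # median of 1,2,9
        assert out.values.loc["f2", "S1"] == 5.0  # median ignoring missing
        assert np.isnan(out.values.loc["f3", "S1"])  # all missing stays missing

    def test_orphan_injection_column_rejected(self):
        meta = _meta(["S1"], ["S2"])
        vals = pd.DataFrame({"S1": [1.0], "S2": [2.0], "S3_1": [3.0]}, index=["f"])
        with pytest.raises(ValidationError, match="replicate_of"):
            summarize_triplicate_medians(OmicsMatrix("metabolite", vals), meta)


class TestPrevalenceFilter:
    def test_boundary_rules(self):
        # 4/5 in case only passes at 0.8; 3/5 both fails; 2/3 passes at 2/3
        meta = _meta([f"C{i}" for i in range(5)], [f"N{i}" for i in range(5)])
        vals = pd.DataFrame(
            np.array(
                [
                    [1, 1, 1, 1, np.nan] + [np.nan] * 5,  # 4/5 case, 0/5 control
                    [1, 1, 1, np.nan, np.nan, 1, 1, 1, np.nan, np.nan],  # 3/5 both
                ]
            ),
            index=["kept", "dropped"],
            columns=meta.sample_ids,
        )
        out = prevalence_filter(OmicsMatrix("metabolite", vals), meta, 0.8)
        assert out.feature_ids == ["kept"]

        meta3 = _meta(["C1", "C2", "C3"], ["N1", "N2", "N3"])
        vals3 = pd.DataFrame(
            [[1.0, 1.0, np.nan, np.nan, np.nan, np.nan]],  # 2/3 case exactly
            index=["p"], columns=meta3.sample_ids,
        )
        out3 = prevalence_filter(OmicsMatrix("protein", vals3), meta3, 2.0 / 3.0)
        assert out3.feature_ids == ["p"]

    def test_rna_zero_counts_are_undetected(self):
        meta = _meta(["C1", "C2"], ["N1", "N2"])
        vals = pd.DataFrame([[0, 0, 5, 7]], index=["g"], columns=meta.sample_ids, dtype=float)
        out = prevalence_filter(OmicsMatrix("rna", vals), meta, 1.0)
        assert out.feature_ids == ["g"]  # 2/2 detected in control
        out2 = prevalence_filter(OmicsMatrix("rna", vals), meta, 1.0)
        # zeros retained as counts, not imputed away
        assert out2.values.loc["g", "C1"] == 0

    def test_matches_bruteforce_oracle(self, rng):
        meta = _meta([f"C{i}" for i in range(5)], [f"N{i}" for i in range(5)])
        vals = rng.uniform(1, 10, size=(20, 10))
        vals[rng.random((20, 10)) < 0.4] = np.nan
        df = pd.DataFrame(vals, index=[f"f{i}" for i in range(20)], columns=meta.sample_ids)
        threshold = 0.6
        out = prevalence_filter(OmicsMatrix("metabolite", df), meta, threshold)
        expected = []
        for fid in df.index:  # brute-force per-feature loop
            case_frac = df.loc[fid, meta.samples_in_group("case")].notna().mean()
            ctrl_frac = df.loc[fid, meta.samples_in_group("control")].notna().mean()
            if case_frac >= threshold or ctrl_frac >= threshold:
                expected.append(fid)
        assert out.feature_ids == expected

    def test_preserves_feature_order(self, rng):
        meta = _meta(["C1", "C2"], ["N1", "N2"])
        vals = pd.DataFrame(rng.uniform(1, 5, (6, 4)), index=list("fedcba"), columns=meta.sample_ids)
        out = prevalence_filter(OmicsMatrix("metabolite", vals), meta, 0.5)
        assert out.feature_ids == list("fedcba")


class TestImputeAndTransform:
    def test_half_minimum_rule(self):
        vals = pd.DataFrame({"a": [10.0, np.nan], "b": [20.0, 40.0]}, index=["f1", "f2"]).T
        m = OmicsMatrix("metabolite", pd.DataFrame(
            [[10.0, 20.0], [np.nan, 40.0]], index=["f1", "f2"], columns=["s1", "s2"]))
        out = impute_below_detection(m)
        assert out.values.loc["f2", "s1"] == 5.0  # half of global min 10
        assert out.values.loc["f1", "s1"] == 10.0  # observed untouched

    def test_complete_matrix_unchanged_and_idempotent(self):
        m = OmicsMatrix("metabolite", pd.DataFrame(
            [[1.0, 2.0]], index=["f"], columns=["s1", "s2"]))
        out = impute_below_detection(m)
        pd.testing.assert_frame_equal(out.values, m.values)
        pd.testing.assert_frame_equal(impute_below_detection(out).values, out.values)

    def test_all_missing_is_error(self):
        m = OmicsMatrix("metabolite", pd.DataFrame(
            [[np.nan, np.nan]], index=["f"], columns=["s1", "s2"]))
        with pytest.raises(ValidationError):
            impute_below_detection(m)

    def test_log10_values_and_composition_with_imputation(self):
        m = OmicsMatrix("metabolite", pd.DataFrame(
            [[100.0, 1.0], [10.0, np.nan]], index=["f1", "f2"], columns=["s1", "s2"]))
        out = log10_transform(impute_below_detection(m))
        assert out.values.loc["f1", "s1"] == pytest.approx(2.0)
        assert out.values.loc["f1", "s2"] == pytest.approx(0.0)
        assert out.values.loc["f2", "s2"] == pytest.approx(np.log10(0.5), abs=1e-9)

    def test_log10_rejects_nonpositive_naming_cell(self):
        m = OmicsMatrix("protein", pd.DataFrame(
            [[1.0, -2.0]], index=["bad_feature"], columns=["s1", "s2"]))
        with pytest.raises(ValidationError, match="bad_feature"):
            log10_transform(m)

    def test_autoscale_definition_and_degenerate_row(self):
        m = OmicsMatrix("metabolite", pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["f1", "f2"], columns=list("abc")))
        out = autoscale(m)
        assert out.values.loc["f1"].tolist() == [-1.0, 0.0, 1.0]
        assert out.values.loc["f2"].tolist() == [0.0, 0.0, 0.0]

    def test_autoscale_rowwise_moments(self, rng):
        vals = pd.DataFrame(rng.normal(3, 2, (10, 8)),
                            index=[f"f{i}" for i in range(10)], columns=[f"s{i}" for i in range(8)])
        out = autoscale(OmicsMatrix("metabolite", vals.abs()))
        assert np.all(np.abs(out.values.mean(axis=1)) < 1e-12)
        assert np.all(np.abs(out.values.std(axis=1, ddof=1) - 1) < 1e-9)


class TestCollapseDuplicates:
    def _matrix(self):
        vals = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]],
            index=["pA", "pB", "pC", "pD"], columns=["s1", "s2"],
        )
        meta = pd.DataFrame({"symbol": ["G1", "G1", "", "G2"]}, index=vals.index)
        return OmicsMatrix("protein", vals, meta)

    def test_lowest_p_wins_and_unannotated_dropped(self):
        stats = pd.DataFrame({"p": [0.2, 0.01, 0.5, 0.03]}, index=["pA", "pB", "pC", "pD"])
        out = collapse_duplicates(self._matrix(), stats=stats)
        assert out.feature_ids == ["pB", "pD"]  # pB beats pA on p; pC unannotated

    def test_tie_breaks_to_smaller_feature_id(self):
        stats = pd.DataFrame({"p": [0.05, 0.05, 0.5, 0.03]}, index=["pA", "pB", "pC", "pD"])
        out = collapse_duplicates(self._matrix(), stats=stats)
        assert "pA" in out.feature_ids and "pB" not in out.feature_ids

    def test_highest_mean_fallback(self):
        out = collapse_duplicates(self._matrix(), rule="highest_mean")
        assert out.feature_ids == ["pB", "pD"]  # pB has larger mean than pA

    def test_missing_stats_row_is_error(self):
        stats = pd.DataFrame({"p": [0.2]}, index=["pA"])
        with pytest.raises(ValidationError):
            collapse_duplicates(self._matrix(), stats=stats)
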