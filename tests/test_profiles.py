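"""Profile/metadata parsing, the arcsine transform, prevalence and filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cohortmeta import (
    ProfileMatrix,
    ProfileFormatError,
    ValidationError,
    arcsin_sqrt_transform,
    cohort_summaries,
    compute_prevalence,
    filter_features,
    read_merged_profiles,
    read_sample_metadata,
    write_sample_metadata,
)
from cohortmeta.profiles import PrevalenceTable, feature_info_from_clade


def _matrix(values: dict[str, list[float]], known=None) -> ProfileMatrix:
    ab = pd.DataFrame(values).T
    ab.columns = [f"S{i}" for i in range(ab.shape[1])]
    feats = pd.DataFrame(
        {
            "clade_name": [f"t__{f}" for f in ab.index],
            "known": known if known is not None else [True] * len(ab),
            "genus_level_assigned": [True] * len(ab),
        },
        index=ab.index,
    )
    return ProfileMatrix(feats, ab)


class TestReadMergedProfiles:
    def test_known_unknown_flags_from_clade_naming(self, profile_path):
        pm = read_merged_profiles(profile_path)
        assert pm.feature_ids == ["SGB7272", "SGB43546"]
        assert pm.features.loc["SGB7272", "known"]
        assert not pm.features.loc["SGB43546", "known"]
        assert pm.features.loc["SGB7272", "genus_level_assigned"]
        assert not pm.features.loc["SGB43546", "genus_level_assigned"]

    def test_unclassified_dropped_without_renormalisation(self, profile_path):
        pm = read_merged_profiles(profile_path)
        # S1 keeps 35 + 25 = 60, not rescaled to 100
        assert pm.abundances["S1"].sum() == pytest.approx(60.0)
        assert pm.abundances["S3"].sum() == pytest.approx(0.0)

    def test_full_column_sum_accepted(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("clade_name\tS1\ns__A|t__SGB1\t100.0\n")
        pm = read_merged_profiles(p)
        assert pm.abundances["S1"].sum() == pytest.approx(100.0)

    def test_negative_abundance_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("clade_name\tS1\ns__A|t__SGB1\t-1.0\n")
        with pytest.raises(ValidationError):
            read_merged_profiles(p)

    def test_missing_header_is_format_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("taxon\tS1\ns__A|t__SGB1\t1.0\n")
        with pytest.raises(ProfileFormatError):
            read_merged_profiles(p)

    def test_duplicate_sample_column_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("clade_name\tS1\tS1\ns__A|t__SGB1\t1.0\t1.0\n")
        with pytest.raises(ValidationError):
            read_merged_profiles(p)

    def test_write_read_roundtrip_with_residual(self, profile_path, tmp_path):
        pm = read_merged_profiles(profile_path)
        out = tmp_path / "rt.tsv"
        pm.write_tsv(out, include_unclassified=True)
        text = out.read_text()
        assert text.startswith("clade_name")
        assert "UNCLASSIFIED" in text
        again = read_merged_profiles(out)
        pd.testing.assert_frame_equal(pm.abundances, again.abundances)
        # emitted composition (SGBs + residual) closes to 100
        raw = pd.read_csv(out, sep="\t")
        assert np.allclose(raw.iloc[:, 1:].sum(axis=0), 100.0, atol=1e-6)

    @pytest.mark.parametrize(
        "clade,known,genus",
        [
            ("k__B|g__Turicibacter|s__Turicibacter_sp_TS3|t__SGB39153", True, True),
            ("k__B|g__GGB1|s__GGB1_SGB2|t__SGB2", False, False),
            ("k__B|g__Genus|s__SGB99|t__SGB99", False, True),
        ],
    )
    def test_clade_parsing_rules(self, clade, known, genus):
        info = feature_info_from_clade(clade)
        assert info["known"] is known
        assert info["genus_level_assigned"] is genus


class TestArcsinSqrt:
    @pytest.mark.parametrize(
        "x,expected", [(0.0, 0.0), (100.0, np.pi / 2), (25.0, np.pi / 6)]
    )
    def test_closed_forms(self, x, expected):
        df = pd.DataFrame({"S0": [x]}, index=["F0"])
        assert arcsin_sqrt_transform(df).iloc[0, 0] == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        df = pd.DataFrame({"S0": [101.0]}, index=["F0"])
        with pytest.raises(ValidationError):
            arcsin_sqrt_transform(df)

    @given(
        st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False),
            min_size=2,
            max_size=10,
            unique=True,
        )
    )
    def test_strictly_monotone(self, values):
        df = pd.DataFrame({"S0": sorted(values)})
        out = arcsin_sqrt_transform(df)["S0"].to_numpy()
        assert np.all(np.diff(out) > 0)
        assert out.min() >= 0 and out.max() <= np.pi / 2 + 1e-12


class TestPrevalence:
    def _meta(self, assignment: dict[str, str]) -> pd.DataFrame:
        meta = pd.DataFrame(
            {"sample_id": list(assignment), "dataset_id": list(assignment.values())}
        )
        return meta.set_index("sample_id", drop=False)

    def test_saturated_feature_has_overall_one(self):
        pm = _matrix({"F1": [1.0, 2.0, 3.0, 4.0]})
        meta = self._meta({"S0": "A", "S1": "A", "S2": "B", "S3": "B"})
        prev = compute_prevalence(pm, meta)
        assert prev.overall["F1"] == pytest.approx(1.0)

    def test_two_dataset_symmetry(self):
        pm = _matrix({"F1": [1.0, 2.0, 0.0, 0.0]})
        meta = self._meta({"S0": "A", "S1": "A", "S2": "B", "S3": "B"})
        prev = compute_prevalence(pm, meta)
        assert prev.overall["F1"] == pytest.approx(0.5)

    def test_absent_dataset_contributes_zero_and_is_not_counted(self):
        # 3 datasets x 2 samples; F1 fully detected in A, half in B, absent in C
        pm = _matrix({"F1": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]})
        meta = self._meta(
            {"S0": "A", "S1": "A", "S2": "B", "S3": "B", "S4": "C", "S5": "C"}
        )
        prev = compute_prevalence(pm, meta)
        assert prev.overall["F1"] == pytest.approx((1.0 + 0.5 + 0.0) / 3)
        assert prev.n_datasets_detected["F1"] == 2

    def test_sample_without_metadata_raises(self):
        pm = _matrix({"F1": [1.0, 1.0]})
        meta = self._meta({"S0": "A"})
        with pytest.raises(KeyError):
            compute_prevalence(pm, meta)


class TestFilterFeatures:
    def _prev(self, per_dataset: dict[str, list[float]]) -> PrevalenceTable:
        return PrevalenceTable(pd.DataFrame(per_dataset).T)

    def test_prevalent_in_five_datasets_retained(self):
        prev = self._prev({"F1": [0.25] * 5})
        assert filter_features(prev, 0.20, 5) == ["F1"]

    def test_four_dataset_feature_needs_relaxed_threshold(self):
        prev = self._prev({"F1": [0.5, 0.5, 0.5, 0.5, 0.0]})
        assert filter_features(prev, 0.20, 5) == []
        assert filter_features(prev, 0.20, 4) == ["F1"]

    def test_boundary_prevalence_is_excluded(self):
        prev = self._prev({"F1": [0.20] * 5})
        assert filter_features(prev, 0.20, 5) == []

    def test_filtering_is_idempotent(self):
        prev = self._prev(
            {"F1": [0.25] * 5, "F2": [0.1] * 5, "F3": [0.9, 0.9, 0.0, 0.0, 0.0]}
        )
        first = filter_features(prev, 0.20, 5)
        sub = PrevalenceTable(prev.per_dataset.loc[first])
        assert filter_features(sub, 0.20, 5) == first


class TestCohortSummaries:
    def test_counts_and_sums(self):
        pm = _matrix(
            {f"F{i}": [20.0] for i in range(5)},
            known=[True, True, False, False, False],
        )
        out = cohort_summaries(pm)
        row = out.loc["S0"]
        assert (row["ksgb_count"], row["usgb_count"]) == (2, 3)
        assert (row["ksgb_pct"], row["usgb_pct"]) == (40.0, 60.0)

    def test_all_zero_sample(self):
        pm = _matrix({"F1": [0.0], "F2": [0.0]}, known=[True, False])
        row = cohort_summaries(pm).loc["S0"]
        assert row.tolist() == [0, 0, 0.0, 0.0]

    def test_known_unknown_mass_conservation(self, small_study):
        pm, _, _ = small_study
        out = cohort_summaries(pm)
        total = pm.abundances.sum(axis=0)
        assert np.allclose(out["ksgb_pct"] + out["usgb_pct"], total)

    def test_two_thirds_unknown_composition(self):
        from cohortmeta import SyntheticSpec, generate

        spec = SyntheticSpec(
            n_datasets=2,
            samples_per_arm=50,
            n_features=150,
            fraction_unknown=2 / 3,
            n_biomarkers=0,
            prevalence_range=(0.6, 0.6),
            seed=3,
        )
        pm, _, _ = generate(spec)
        out = cohort_summaries(pm)
        ratio = out["usgb_count"].mean() / out["ksgb_count"].mean()
        assert ratio == pytest.approx(2.0, rel=0.2)


class TestMetadataIO:
    def test_roundtrip_and_validation(self, tiny_meta, tmp_path):
        path = tmp_path / "meta.tsv"
        write_sample_metadata(tiny_meta, path)
        again = read_sample_metadata(path)
        assert list(again.index) == list(tiny_meta.index)
        assert again["fat_pct"].tolist() == tiny_meta["fat_pct"].tolist()

    def test_bad_diet_class_rejected(self, tiny_meta, tmp_path):
        bad = tiny_meta.copy()
        bad.loc["S1", "diet_class"] = "keto"
        path = tmp_path / "meta.tsv"
        write_sample_metadata(bad, path)
        with pytest.raises(ValidationError):
            read_sample_metadata(path)

    def test_fat_out_of_range_rejected(self, tiny_meta, tmp_path):
        bad = tiny_meta.copy()
        bad.loc["S1", "fat_pct"] = 120.0
        path = tmp_path / "meta.tsv"
        write_sample_metadata(bad, path)
        with pytest.raises(ValidationError):
            read_sample_metadata(path)
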