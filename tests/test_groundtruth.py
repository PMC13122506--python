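import numpy as np
import pandas as pd
import pytest

import wormdeconv as wd
from wormdeconv.datatypes import ValidationError
from wormdeconv.groundtruth import CURATED_TISSUES


def truth_table(rows):
    return pd.DataFrame(rows, columns=["tissue", "nuclei_count",
                                       "total_cell_volume"])


class TestTissueFractions:
    def test_simple_fractions(self):
        truth = truth_table([("intestine", 30, 10.0), ("muscle", 70, 30.0)])
        out = wd.tissue_fractions(truth)
        assert out.loc["intestine", "nuclei_fraction"] == pytest.approx(0.3)
        assert out.loc["muscle", "nuclei_fraction"] == pytest.approx(0.7)
        assert out.loc["intestine", "volume_fraction"] == pytest.approx(0.25)

    def test_fractions_sum_to_one(self):
        truth = truth_table([("intestine", 34, 7.1), ("muscle", 120, 9.2),
                             ("neurons", 302, 2.4), ("gonadal", 56, 4.8)])
        out = wd.tissue_fractions(truth)
        assert out["nuclei_fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        assert out["volume_fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_volume_rejected(self):
        truth = truth_table([("intestine", 30, 0.0), ("muscle", 70, 0.0)])
        with pytest.raises(ValidationError):
            wd.tissue_fractions(truth)

    def test_duplicate_tissue_rejected(self):
        truth = truth_table([("muscle", 30, 1.0), ("muscle", 70, 2.0)])
        with pytest.raises(ValidationError, match="duplicate"):
            wd.tissue_fractions(truth)


class TestAggregateProportions:
    def _props(self):
        values = pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.4], [0.25, 0.25, 0.25, 0.25]],
            index=["s1", "s2"],
            columns=["germline", "somatic_gonad", "body_muscle", "gut"],
        )
        return wd.ProportionMatrix(
            values=values, day=pd.Series([1, 1], index=values.index)
        )

    def test_additivity_within_tissue(self):
        mapping = {"germline": "gonadal", "somatic_gonad": "gonadal",
                   "body_muscle": "muscle", "gut": "intestine"}
        out = wd.aggregate_proportions(self._props(), mapping)
        assert out.values.loc["s1", "gonadal"] == pytest.approx(0.3)
        assert out.values.loc["s1", "muscle"] == pytest.approx(0.3)

    def test_identity_mapping_preserves_values(self):
        values = pd.DataFrame([[0.5, 0.3, 0.2]], index=["s1"],
                              columns=["muscle", "intestine", "neurons"])
        props = wd.ProportionMatrix(values=values,
                                    day=pd.Series([1], index=["s1"]))
        out = wd.aggregate_proportions(props, {c: c for c in values.columns})
        for c in values.columns:
            assert out.values.loc["s1", c] == values.loc["s1", c]

    def test_row_sums_preserved_with_unmapped_residual(self):
        mapping = {"germline": "gonadal", "somatic_gonad": "gonadal"}
        out = wd.aggregate_proportions(self._props(), mapping)
        assert "unmapped" in out.values.columns
        assert np.allclose(out.values.sum(axis=1), 1.0, atol=1e-9)

    def test_target_outside_curated_set_rejected(self):
        mapping = {"germline": "gonadal", "somatic_gonad": "gonadal",
                   "body_muscle": "muscle", "gut": "stomach"}
        with pytest.raises(ValidationError, match="stomach"):
            wd.aggregate_proportions(self._props(), mapping)

    def test_default_mapping_targets_are_curated(self):
        assert set(wd.DEFAULT_TISSUE_MAPPING.values()) <= set(CURATED_TISSUES)


class TestCorrelateWithTruth:
    def _fractions(self, n=6):
        nuclei = np.array([300, 200, 150, 120, 130, 100])[:n]
        volume = np.array([20.0, 35.0, 10.0, 8.0, 17.0, 10.0])[:n]
        truth = truth_table(list(zip(
            ["neurons", "intestine", "muscle", "gonadal", "hypodermal cells",
             "vulval"][:n], nuclei, volume,
        )))
        return wd.tissue_fractions(truth)

    def test_perfect_agreement(self):
        fractions = self._fractions()
        predicted = fractions["nuclei_fraction"].copy()
        out = wd.correlate_with_truth(predicted, fractions, "pearson")
        assert out.corr_nuclei == pytest.approx(1.0)
        assert np.allclose(out.residuals["residual_nuclei"], 0.0, atol=1e-12)
        assert out.outliers_nuclei == []

    def test_displaced_tissue_is_the_only_flag(self):
        """Five tissues exactly on a line, one displaced at the centroid
        of x: hand calculation gives standardized residuals of
        +/-(5/6)/sqrt(5/36+25/216*6)... i.e. |z|=2.236 for the displaced
        tissue and 0.447 for the rest, so threshold 2.0 flags exactly it."""
        x = np.array([0.10, 0.15, 0.20, 0.25, 0.30, 0.20])
        y = 0.5 * x + 0.05
        y[5] += 0.12  # displaced tissue sits at mean(x) of the others
        tissues = ["muscle", "gonadal", "hypodermal cells", "vulval",
                   "spermatheca", "neurons"]
        fractions = pd.DataFrame(
            {"nuclei_fraction": x, "volume_fraction": x},
            index=pd.Index(tissues, name="tissue"),
        )
        predicted = pd.Series(y, index=tissues)
        out = wd.correlate_with_truth(predicted, fractions, "pearson",
                                      outlier_threshold=2.0)
        assert out.outliers_nuclei == ["neurons"]

    def test_threshold_boundaries(self):
        fractions = self._fractions()
        rng = np.random.default_rng(0)
        predicted = pd.Series(
            fractions["nuclei_fraction"].to_numpy()
            + rng.normal(0, 0.02, len(fractions)),
            index=fractions.index,
        )
        none = wd.correlate_with_truth(predicted, fractions, "pearson",
                                       outlier_threshold=np.inf)
        assert none.outliers_nuclei == []
        every = wd.correlate_with_truth(predicted, fractions, "pearson",
                                        outlier_threshold=0.0)
        nonzero = (np.abs(every.residuals["residual_nuclei"]) > 0).sum()
        assert len(every.outliers_nuclei) == nonzero

    def test_unshared_tissues_excluded(self):
        fractions = self._fractions()
        predicted = pd.Series(
            [0.2, 0.3, 0.25, 0.25],
            index=["neurons", "intestine", "muscle", "coelomocytes"],
        )
        out = wd.correlate_with_truth(predicted, fractions, "spearman")
        assert set(out.shared_tissues) == {"neurons", "intestine", "muscle"}
        assert "coelomocytes" in out.excluded_tissues
        assert "gonadal" in out.excluded_tissues

    def test_swapping_truth_column_keeps_shared_set(self):
        fractions = self._fractions()
        predicted = fractions["volume_fraction"] * 0.9 + 0.01
        out = wd.correlate_with_truth(predicted, fractions, "pearson")
        assert out.corr_volume == pytest.approx(1.0)
        assert out.shared_tissues == list(fractions.index)

    def test_too_few_shared_tissues_rejected(self):
        fractions = self._fractions()
        predicted = pd.Series([0.5, 0.5], index=["neurons", "intestine"])
        with pytest.raises(ValidationError, match=">= 3"):
            wd.correlate_with_truth(predicted, fractions)
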