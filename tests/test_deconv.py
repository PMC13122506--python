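import numpy as np
import pandas as pd
import pytest

import wormdeconv as wd
from wormdeconv.deconv import DeconvolutionError
from conftest import mixture_from


class TestFitSample:
    def test_pure_type_mixture_recovers_that_type(self, five_type_signature):
        _, _, signature = five_type_signature
        ct = signature.values.columns[2]
        mixture = signature.values[ct].rename("pure")
        raw = wd.fit_sample(signature, mixture)
        props = wd.coefficients_to_proportions(raw)
        assert props[ct] == pytest.approx(1.0, abs=0.02)

    def test_two_type_mixture_matches_nnls_oracle(self, five_type_signature):
        _, _, signature = five_type_signature
        w = np.array([0.3, 0.7, 0.0, 0.0, 0.0])
        mixture = mixture_from(signature, w)
        props = wd.coefficients_to_proportions(wd.fit_sample(signature, mixture))
        oracle = wd.nnls_proportions(signature, mixture)
        assert np.abs(props.to_numpy() - oracle.to_numpy()).max() < 0.02
        assert props.iloc[0] == pytest.approx(0.3, abs=0.02)
        assert props.iloc[1] == pytest.approx(0.7, abs=0.02)

    def test_defaults_equal_explicit_default_config(self, five_type_signature):
        _, _, signature = five_type_signature
        mixture = mixture_from(signature, [0.2, 0.2, 0.2, 0.2, 0.2])
        a = wd.fit_sample(signature, mixture)
        b = wd.fit_sample(signature, mixture,
                          wd.DeconvolutionConfig(C=0.001, epsilon=0.01))
        pd.testing.assert_series_equal(a, b)

    def test_too_few_shared_features_rejected(self, five_type_signature):
        _, _, signature = five_type_signature
        mixture = pd.Series([1.0], index=[signature.values.index[0]])
        with pytest.raises(DeconvolutionError, match="shared"):
            wd.fit_sample(signature, mixture)

    def test_zero_variance_mixture_rejected(self, five_type_signature):
        _, _, signature = five_type_signature
        mixture = pd.Series(1.0, index=signature.values.index)
        with pytest.raises(DeconvolutionError, match="variance"):
            wd.fit_sample(signature, mixture)


class TestCoefficientsToProportions:
    @pytest.mark.parametrize("raw,expected", [
        ([2.0, -1.0, 3.0], [0.4, 0.0, 0.6]),
        ([1.0, 1.0], [0.5, 0.5]),
        ([0.0, 5.0], [0.0, 1.0]),
    ])
    def test_clip_and_renormalize(self, raw, expected):
        out = wd.coefficients_to_proportions(np.array(raw))
        assert np.allclose(out, expected)

    def test_all_nonpositive_rejected(self):
        with pytest.raises(DeconvolutionError, match="unidentifiable"):
            wd.coefficients_to_proportions(np.array([0.0, 0.0, -5.0]))


class TestDeconvolve:
    def test_noiseless_cohort_recovers_truth(self, five_type_config,
                                             five_type_signature):
        profiles, _, signature = five_type_signature
        bulk, truth = wd.simulate_aging_cohort(five_type_config, profiles)
        result = wd.deconvolve(signature, bulk)
        est = result.proportions.values
        mae = np.abs(
            est.to_numpy()
            - truth.values.loc[est.index, est.columns].to_numpy()
        ).mean()
        assert mae < 0.01
        assert result.failures == {}

    def test_rows_on_simplex(self, five_type_config, five_type_signature):
        profiles, _, signature = five_type_signature
        bulk, _ = wd.simulate_aging_cohort(five_type_config, profiles)
        result = wd.deconvolve(signature, bulk)
        arr = result.proportions.values.to_numpy()
        assert (arr >= 0).all()
        assert np.allclose(arr.sum(axis=1), 1.0, atol=1e-6)

    def test_feature_row_order_invariance(self, five_type_signature):
        _, _, signature = five_type_signature
        mixture = mixture_from(signature, [0.1, 0.2, 0.3, 0.2, 0.2])
        shuffled = mixture.sample(frac=1.0, random_state=4)
        a = wd.coefficients_to_proportions(wd.fit_sample(signature, mixture))
        b = wd.coefficients_to_proportions(wd.fit_sample(signature, shuffled))
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_signature_column_permutation_invariance(self, five_type_signature):
        _, _, signature = five_type_signature
        mixture = mixture_from(signature, [0.1, 0.2, 0.3, 0.2, 0.2])
        perm = wd.SignatureMatrix(
            values=signature.values[list(signature.values.columns[::-1])]
        )
        a = wd.coefficients_to_proportions(wd.fit_sample(signature, mixture))
        b = wd.coefficients_to_proportions(wd.fit_sample(perm, mixture))
        for ct in signature.values.columns:
            assert a[ct] == pytest.approx(b[ct], abs=1e-9)

    def test_mixture_scale_invariance(self, five_type_signature):
        _, _, signature = five_type_signature
        mixture = mixture_from(signature, [0.4, 0.1, 0.3, 0.1, 0.1])
        a = wd.coefficients_to_proportions(wd.fit_sample(signature, mixture))
        b = wd.coefficients_to_proportions(
            wd.fit_sample(signature, mixture * 10.0)
        )
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_recovery_error_monotone_in_noise(self, five_type_config):
        """Average MAE over replicates does not decrease as noise grows."""
        profiles, markers = wd.simulate_reference(five_type_config)
        kept, _ = wd.prepare_markers(markers, profiles.index,
                                     wd.SignatureConfig.rna())
        signature = wd.build_signature(profiles, kept)
        ladder = [0.0, 0.2, 0.6]
        maes = []
        for cv in ladder:
            errs = []
            for rep in range(20):
                cfg = wd.SimulationConfig(
                    **{**five_type_config.__dict__, "noise_cv": cv,
                       "seed": 1000 + rep, "n_days": 2,
                       "replicates_per_day": 1}
                )
                bulk, truth = wd.simulate_aging_cohort(cfg, profiles)
                est = wd.deconvolve(signature, bulk).proportions.values
                errs.append(np.abs(
                    est.to_numpy()
                    - truth.values.loc[est.index, est.columns].to_numpy()
                ).mean())
            maes.append(np.mean(errs))
        assert maes[0] <= maes[1] <= maes[2]


class TestGridSearch:
    def test_singleton_grid_returns_defaults(self, five_type_config,
                                             five_type_signature):
        profiles, _, signature = five_type_signature
        bulk, truth = wd.simulate_aging_cohort(five_type_config, profiles)
        best, surface = wd.grid_search(signature, bulk, truth,
                                       [0.001], [0.01])
        assert best.C == 0.001 and best.epsilon == 0.01
        assert len(surface) == 1

    def test_grid_outside_search_range_rejected(self, five_type_config,
                                                five_type_signature):
        profiles, _, signature = five_type_signature
        bulk, truth = wd.simulate_aging_cohort(five_type_config, profiles)
        with pytest.raises(ValueError, match="search range"):
            wd.grid_search(signature, bulk, truth, [1.0], [0.01])

    def test_optimum_beats_worst_corner_on_noiseless_data(
            self, five_type_config, five_type_signature):
        profiles, _, signature = five_type_signature
        cfg = wd.SimulationConfig(
            **{**five_type_config.__dict__, "n_days": 3,
               "replicates_per_day": 1}
        )
        bulk, truth = wd.simulate_aging_cohort(cfg, profiles)
        C_grid = [0.0001, 0.001, 0.1]
        e_grid = [0.001, 0.01, 0.5]
        best, surface = wd.grid_search(signature, bulk, truth, C_grid, e_grid)
        best_mae = surface.set_index(["C", "epsilon"]).loc[
            (best.C, best.epsilon), "mae"]
        corners = [
            surface.set_index(["C", "epsilon"]).loc[(c, e), "mae"]
            for c in (C_grid[0], C_grid[-1]) for e in (e_grid[0], e_grid[-1])
        ]
        assert all(best_mae <= c for c in corners)
        assert best_mae < max(corners)
        # brute-force cross-check of the reported surface at one point
        cand = wd.DeconvolutionConfig(C=0.0001, epsilon=0.5)
        est = wd.deconvolve(signature, bulk, cand).proportions.values
        mae = np.abs(
            est.to_numpy()
            - truth.values.loc[est.index, est.columns].to_numpy()
        ).mean()
        assert mae == pytest.approx(
            surface.set_index(["C", "epsilon"]).loc[(0.0001, 0.5), "mae"],
            rel=1e-9,
        )

    def test_empty_grid_rejected(self, five_type_config, five_type_signature):
        profiles, _, signature = five_type_signature
        bulk, truth = wd.simulate_aging_cohort(five_type_config, profiles)
        with pytest.raises(ValueError, match="non-empty"):
            wd.grid_search(signature, bulk, truth, [], [0.01])


class TestMeanProportionsByDay:
    def test_identical_samples_mean_is_either(self):
        values = pd.DataFrame([[0.2, 0.8], [0.2, 0.8]], index=["s1", "s2"],
                              columns=["a", "b"])
        props = wd.ProportionMatrix(
            values=values, day=pd.Series([4, 4], index=values.index)
        )
        out = wd.mean_proportions_by_day(props)
        assert np.allclose(out.loc[4].to_numpy(), [0.2, 0.8])

    def test_arithmetic_mean(self):
        values = pd.DataFrame([[0.2, 0.8], [0.4, 0.6]], index=["s1", "s2"],
                              columns=["a", "b"])
        props = wd.ProportionMatrix(
            values=values, day=pd.Series([1, 1], index=values.index)
        )
        out = wd.mean_proportions_by_day(props)
        assert np.allclose(out.loc[1].to_numpy(), [0.3, 0.7])

    def test_rows_sum_to_one(self, toy_proportions):
        out = wd.mean_proportions_by_day(toy_proportions)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)
        assert list(out.index) == [1, 2, 3]
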