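"""ROI means, equivalent grouping, prevalence filters, adequacy."""

import numpy as np
import pandas as pd
import pytest

from msicyto import (
    FeatureMatrix,
    InadequateROIError,
    MSIDataset,
    PixelSpectrum,
    ROIAnnotation,
    adequacy_check,
    inter_patient_filter,
    intra_patient_filter,
    make_equivalent_groups,
    roi_mean_spectrum,
)
from msicyto.preprocessing import ProcessingParams, process_profiles_matrix
from msicyto.roi_features import group_mean_observations
from msicyto.types import FeatureGrid


def _uniform_dataset(n=6, n_points=300, value=None, seed=0):
    rng = np.random.default_rng(seed)
    mz = np.linspace(3000, 20000, n_points)
    ds = MSIDataset(specimen_id="S", patient_id="P")
    for i in range(n):
        y = value if value is not None else rng.gamma(2.0, 3.0, n_points)
        ds.add(PixelSpectrum(x=i + 1, y=1, mz=mz, intensity=np.asarray(y, float)))
    return ds


def _roi(pixels, roi_id="r", clusters=1, cells=10):
    return ROIAnnotation(roi_id, "S", set(pixels), clusters, cells)


class TestRoiMeanSpectrum:
    def test_identical_pixels_mean_equals_member(self):
        y = np.abs(np.sin(np.linspace(0, 20, 300))) * 10 + 1
        ds = _uniform_dataset(n=4, value=y)
        ms = roi_mean_spectrum(ds, _roi([(1, 1), (2, 1), (3, 1)]))
        single = roi_mean_spectrum(ds, _roi([(4, 1)]))
        np.testing.assert_allclose(ms.intensity, single.intensity, rtol=1e-12)

    def test_two_pixel_mean_is_pointwise_average(self):
        ds = _uniform_dataset(n=2, seed=3)
        params = ProcessingParams()
        M = np.stack([ds.spectra[(1, 1)].intensity, ds.spectra[(2, 1)].intensity])
        processed, _ = process_profiles_matrix(M, params)
        ms = roi_mean_spectrum(ds, _roi([(1, 1), (2, 1)]), params)
        np.testing.assert_allclose(ms.intensity, processed.mean(axis=0), rtol=1e-12)

    def test_all_empty_roi_is_inadequate(self):
        ds = _uniform_dataset(n=2, value=np.zeros(300))
        with pytest.raises(InadequateROIError):
            roi_mean_spectrum(ds, _roi([(1, 1), (2, 1)]))

    def test_empty_pixels_excluded_from_mean(self):
        ds = _uniform_dataset(n=2, seed=4)
        ds.add(PixelSpectrum(x=3, y=1, mz=ds.shared_axis(), intensity=np.zeros(300)))
        with_zero = roi_mean_spectrum(ds, _roi([(1, 1), (2, 1), (3, 1)]))
        without = roi_mean_spectrum(ds, _roi([(1, 1), (2, 1)]))
        np.testing.assert_allclose(with_zero.intensity, without.intensity)
        assert with_zero.n_pixels == 2

    def test_averaging_reduces_noise_like_sqrt_n(self):
        """sd of the mean of 10 replicates ~ sd/sqrt(10), within 20%.

        The Monte-Carlo reference is the processed mean of many independent
        replicates, so the deterministic bias of the processing chain
        (zero-clipping after baseline subtraction) cancels and only the
        stochastic residual is compared.
        """
        rng = np.random.default_rng(12)
        n_points = 1000
        mz = np.linspace(3000, 20000, n_points)
        clean = 60.0 + 40.0 * np.exp(-0.5 * ((mz - 8000) / 300.0) ** 2)
        params = ProcessingParams(baseline_half_window=200)
        ref_batch = clean + rng.normal(0, 3.0, (400, n_points))
        ref = process_profiles_matrix(ref_batch, params)[0].mean(axis=0)
        ratios = []
        for _ in range(8):
            noisy = clean + rng.normal(0, 3.0, (10, n_points))
            processed, _ = process_profiles_matrix(noisy, params)
            resid_single = processed[0] - ref
            resid_mean = processed.mean(axis=0) - ref
            ratios.append(resid_mean.std() / resid_single.std())
        assert np.mean(ratios) == pytest.approx(1 / np.sqrt(10), rel=0.2)


class TestEquivalentGroups:
    def _rois(self, sizes):
        return [
            ROIAnnotation(f"r{i}", "S", {(i * 300 + j, 1) for j in range(s)})
            for i, s in enumerate(sizes)
        ]

    def test_five_rois_into_five_singletons(self):
        groups = make_equivalent_groups(self._rois([4, 5, 6, 7, 8]), 5, seed=0)
        assert sorted(len(g.roi_ids) for g in groups) == [1] * 5

    def test_nine_equal_rois_into_five_groups(self):
        groups = make_equivalent_groups(self._rois([5] * 9), 5, seed=0)
        assert sorted(len(g.roi_ids) for g in groups) == [1, 2, 2, 2, 2]

    def test_twentytwo_rois_fit_five_groups_exactly(self):
        rois = self._rois(list(range(3, 25)))
        groups = make_equivalent_groups(rois, 5, seed=0)
        sizes = [len(g.roi_ids) for g in groups]
        assert max(sizes) <= 7
        all_ids = [r for g in groups for r in g.roi_ids]
        assert sorted(all_ids) == sorted(r.roi_id for r in rois)

    def test_more_than_seven_per_group_rejected(self):
        with pytest.raises(ValueError, match="at most 7"):
            make_equivalent_groups(self._rois([3] * 15), 2, seed=0)

    def test_fewer_rois_than_groups_reduces_groups(self):
        groups = make_equivalent_groups(self._rois([3, 4, 5]), 5, seed=0)
        assert len(groups) == 3

    def test_matches_greedy_balance_oracle(self, rng):
        for trial in range(10):
            sizes = rng.integers(1, 40, size=int(rng.integers(5, 20))).tolist()
            rois = self._rois(sizes)
            n_groups = 4
            groups = make_equivalent_groups(rois, n_groups, seed=trial)
            # oracle: same greedy rule, written independently
            tb = np.random.default_rng(trial).permutation(len(rois))
            order = sorted(range(len(rois)), key=lambda i: (-sizes[i], tb[i]))
            oracle = [[] for _ in range(n_groups)]
            totals = [0] * n_groups
            for i in order:
                cands = [g for g in range(n_groups) if len(oracle[g]) < 7]
                g = min(cands, key=lambda g: (totals[g], g))
                oracle[g].append(f"r{i}")
                totals[g] += sizes[i]
            assert [g.roi_ids for g in groups] == oracle

    def test_partition_is_exact_and_deterministic(self, rng):
        sizes = rng.integers(1, 30, size=12).tolist()
        rois = self._rois(sizes)
        g1 = make_equivalent_groups(rois, 4, seed=7)
        g2 = make_equivalent_groups(rois, 4, seed=7)
        assert [g.roi_ids for g in g1] == [g.roi_ids for g in g2]
        flat = [r for g in g1 for r in g.roi_ids]
        assert len(flat) == len(set(flat)) == len(rois)


class TestGroupMeanObservations:
    def test_single_roi_group_equals_roi_projection(self):
        ds = _uniform_dataset(n=3, seed=5)
        params = ProcessingParams()
        roi = _roi([(1, 1), (2, 1), (3, 1)])
        ms = roi_mean_spectrum(ds, roi, params)
        groups = make_equivalent_groups([roi], 1, seed=0, patient_id="P")
        grid = FeatureGrid(features=np.array([5000.0, 8000.0, 12000.0]), tolerance_ppm=2000)
        fm = group_mean_observations(groups, {"r": ms}, grid, params, labels={"P": 0})
        assert fm.n_observations == 1
        from msicyto.preprocessing import peaks_from_processed, project_onto_grid
        pl = peaks_from_processed(ms.mz, ms.intensity, params)
        x, _ = project_onto_grid(pl, grid)
        np.testing.assert_allclose(fm.intensities[0], x)


class TestPrevalenceFilters:
    def _fm(self, detected, patients):
        detected = np.asarray(detected, dtype=np.int8)
        return FeatureMatrix(
            observation_ids=[f"o{i}" for i in range(detected.shape[0])],
            feature_mz=np.arange(detected.shape[1], dtype=float) + 4000.0,
            intensities=detected.astype(float),
            detected=detected,
            patient_of=list(patients),
        )

    def test_quarter_boundary_is_inclusive(self):
        # 1 detection out of 4 ROIs = 25% -> present
        fm = self._fm([[1], [0], [0], [0]], ["p"] * 4)
        presence = intra_patient_filter(fm, 0.25)
        assert presence.loc["p"].iloc[0] == 1

    def test_never_detected_is_absent(self):
        fm = self._fm([[0], [0], [0]], ["p"] * 3)
        assert intra_patient_filter(fm).loc["p"].iloc[0] == 0

    def test_matches_brute_force_counts(self, rng):
        n_pat, n_roi, n_feat = 20, 6, 30
        det = rng.integers(0, 2, size=(n_pat * n_roi, n_feat))
        patients = [f"p{i // n_roi}" for i in range(n_pat * n_roi)]
        presence = intra_patient_filter(self._fm(det, patients), 0.25)
        for pi in range(n_pat):
            block = det[pi * n_roi:(pi + 1) * n_roi]
            for f in range(n_feat):
                expected = int(block[:, f].sum() / n_roi >= 0.25)
                assert presence.loc[f"p{pi}"].iloc[f] == expected

    def test_class_representative_union(self):
        presence = pd.DataFrame(
            {4000.0: [1, 1, 1] + [0] * 6 + [0] * 9,  # 3/9 benign only
             5000.0: [1, 1] + [0] * 7 + [1, 1] + [0] * 7,  # 2/9 each
             6000.0: [0] * 9 + [1] * 9},  # all malignant
            index=[f"b{i}" for i in range(9)] + [f"m{i}" for i in range(9)],
        )
        benign = [f"b{i}" for i in range(9)]
        malignant = [f"m{i}" for i in range(9)]
        kept = inter_patient_filter(presence, benign, malignant, 0.25)
        assert kept == [4000.0, 6000.0]

    def test_zero_fraction_keeps_everything(self):
        presence = pd.DataFrame({4000.0: [0, 1], 5000.0: [0, 0]}, index=["b", "m"])
        assert inter_patient_filter(presence, ["b"], ["m"], 0.0) == [4000.0, 5000.0]

    def test_intersection_mode_requires_both_classes(self):
        presence = pd.DataFrame(
            {4000.0: [1, 0], 5000.0: [1, 1]}, index=["b", "m"]
        )
        kept = inter_patient_filter(presence, ["b"], ["m"], 0.25, mode="intersection")
        assert kept == [5000.0]

    def test_raising_fraction_never_adds_features(self, rng):
        det = rng.integers(0, 2, size=(40, 15))
        patients = [f"p{i // 4}" for i in range(40)]
        fm = self._fm(det, patients)
        benign = [f"p{i}" for i in range(5)]
        malignant = [f"p{i}" for i in range(5, 10)]
        prev = None
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            presence = intra_patient_filter(fm, frac)
            try:
                kept = set(inter_patient_filter(presence, benign, malignant, frac))
            except ValueError:
                kept = set()
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_empty_result_is_an_error(self):
        presence = pd.DataFrame({4000.0: [0, 0]}, index=["b", "m"])
        with pytest.raises(ValueError, match="no representative"):
            inter_patient_filter(presence, ["b"], ["m"], 0.25)


class TestAdequacy:
    def test_six_clusters_of_ten_is_adequate(self):
        rois = [_roi([(i, 1)], f"r{i}", clusters=1, cells=10) for i in range(6)]
        assert adequacy_check(rois) is True

    def test_five_clusters_is_inadequate(self):
        rois = [_roi([(i, 1)], f"r{i}", clusters=1, cells=10) for i in range(5)]
        assert adequacy_check(rois) is False

    def test_small_clusters_do_not_count(self):
        rois = [_roi([(i, 1)], f"r{i}", clusters=2, cells=5) for i in range(6)]
        assert adequacy_check(rois) is False

    def test_missing_metadata_is_indeterminate(self):
        rois = [ROIAnnotation(f"r{i}", "S", {(i, 1)}) for i in range(8)]
        assert adequacy_check(rois) is None

    def test_cluster_counts_accumulate_across_rois(self):
        rois = [_roi([(i, 1)], f"r{i}", clusters=3, cells=12) for i in range(2)]
        assert adequacy_check(rois) is True


class TestFiltersOnSyntheticCohort:
    def test_planted_features_survive_filters(self, small_training):
        """Class-discriminant m/z pass both prevalence filters."""
        config, result, truth = small_training
        tol = 2000e-6
        for mz, _ in truth.discriminant_mz:
            assert any(abs(f - mz) <= mz * tol for f in result.filtered_mz), mz
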