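"""Synthetic observed-data generator: statistical structure and determinism."""

import numpy as np
import pytest

from henapbpk.metrics import aafe, afe, aape, compute_metrics, pairs_from_profiles
from henapbpk.synthetic import (expected_aafe, generate_observed,
                                generate_study_suite, lognormal_sigma)


class TestGenerateObserved:
    def test_noiseless_identity_gives_perfect_metrics(self, single_dose_profile,
                                                      sampling_times):
        ds = generate_observed(single_dose_profile, sampling_times,
                               residual_cv=0.0, lloq=0.0, n_subjects=3, seed=1)
        pred = np.interp(ds.records.time, single_dose_profile.time,
                         single_dose_profile.plasma_concentration)
        pairs, n_excluded = pairs_from_profiles(
            pred, ds.records.concentration.to_numpy())
        assert n_excluded == 0
        assert afe(pairs) == pytest.approx(1.0)
        assert aafe(pairs) == pytest.approx(1.0)
        assert aape(pairs) == pytest.approx(0.0, abs=1e-12)

    def test_aafe_converges_to_lognormal_expectation(self, single_dose_profile,
                                                     sampling_times):
        cv = 0.3
        ds = generate_observed(single_dose_profile, sampling_times,
                               residual_cv=cv, lloq=0.0, n_subjects=1000, seed=7)
        pred = np.interp(ds.records.time, single_dose_profile.time,
                         single_dose_profile.plasma_concentration)
        pairs, _ = pairs_from_profiles(pred, ds.records.concentration.to_numpy())
        assert aafe(pairs) == pytest.approx(expected_aafe(cv), rel=0.02)

    def test_total_censoring_refused_downstream(self, single_dose_profile,
                                                sampling_times):
        ds = generate_observed(single_dose_profile, sampling_times,
                               residual_cv=0.0, lloq=1e9, n_subjects=2, seed=1)
        assert ds.records.censored.all()
        pred = np.interp(ds.records.time, single_dose_profile.time,
                         single_dose_profile.plasma_concentration)
        uncensored = ds.records[~ds.records.censored]
        with pytest.raises(ValueError, match="censored"):
            pairs_from_profiles(pred[:0], uncensored.concentration.to_numpy())

    def test_empty_schedule_rejected(self, single_dose_profile):
        with pytest.raises(ValueError, match="empty"):
            generate_observed(single_dose_profile, [], n_subjects=1, seed=0)

    def test_seeded_reproducibility(self, single_dose_profile, sampling_times):
        a = generate_observed(single_dose_profile, sampling_times,
                              residual_cv=0.25, n_subjects=5, seed=11)
        b = generate_observed(single_dose_profile, sampling_times,
                              residual_cv=0.25, n_subjects=5, seed=11)
        assert a.records.equals(b.records)

    def test_lognormal_sigma_matches_cv(self):
        assert lognormal_sigma(0.3) == pytest.approx(np.sqrt(np.log(1.09)))


@pytest.fixture(scope="module")
def suite(compound):
    return generate_study_suite(compound, seed=0, n_subjects=4, output_step=0.5)


class TestStudySuite:
    def test_contains_seven_single_dose_strengths(self, suite):
        singles = [d for d in suite if "single" in d.study_label
                   and "fasted" in d.study_label]
        doses = sorted(d.regimen.dose for d in singles)
        assert doses == [2.5, 5.0, 10.0, 25.0, 50.0, 100.0, 200.0]

    def test_labels_are_namespaced(self, suite):
        assert all(d.study_label.startswith("synthetic:") for d in suite)

    def test_export_is_byte_identical_under_seed(self, compound, tmp_path):
        paths = []
        for run in ("a", "b"):
            suite = generate_study_suite(
                compound, seed=3, n_subjects=2, output_step=0.5,
                regimens=None)[:2]
            p = tmp_path / f"{run}.csv"
            suite[0].to_csv(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_null_model_classification_within_band(self, suite,
                                                   single_dose_profile):
        """Metrics computed on data generated by the generating model itself
        stay in the strict fold band at modest residual error."""
        ds = generate_observed(single_dose_profile,
                               np.array([1, 2, 4, 8, 12, 24.0]),
                               residual_cv=0.1, lloq=0.0, n_subjects=100,
                               seed=5)
        times, geo = ds.geometric_mean_profile()
        pred = np.interp(times, single_dose_profile.time,
                         single_dose_profile.plasma_concentration)
        pairs, _ = pairs_from_profiles(pred, geo)
        assert compute_metrics(pairs).classification["fold_band"] == "within_1.25"
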