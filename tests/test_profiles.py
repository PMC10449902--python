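import numpy as np
import pandas as pd
import pytest

from cofrac.profiles import (ElutionPeak, ProfileConfigError, detect_peaks,
                             infer_protein_profiles, pearson, primary_peak,
                             replicate_correlation, smooth_and_rescale)
from cofrac.simulate import SimulationConfig, simulate_dataset
from tests.conftest import gaussian_profile


def records_from_traces(traces: dict[tuple[str, str], list[float]],
                        condition: str = "ctrl", replicate: int = 1) -> pd.DataFrame:
    rows = []
    for (pid, pep), vals in traces.items():
        for f, v in enumerate(vals, start=1):
            rows.append((pid, pep, condition, replicate, f, float(v)))
    return pd.DataFrame(rows, columns=["protein_id", "peptide", "condition",
                                       "replicate", "fraction", "intensity"])


class TestSiblingPeptideInference:
    def test_single_peptide_passes_through(self):
        rec = records_from_traces({("P1", "AAK"): [0, 1, 4, 1, 0]})
        pset = infer_protein_profiles(rec, 5)
        np.testing.assert_allclose(
            pset.replicate_profiles[("ctrl", 1)].loc["P1"], [0, 1, 4, 1, 0])
        assert pset.selected_peptides["P1"] == ("AAK",)

    def test_top2_pair_is_the_max_correlation_pair(self):
        # two identical triangles and one flat noise trace: enumerating all
        # three pairs by hand, the triangle pair wins and its mean is the triangle
        rec = records_from_traces({
            ("P1", "AAK"): [0, 1, 2, 1, 0],
            ("P1", "CCK"): [0, 2, 4, 2, 0],
            ("P1", "DDR"): [1, 1, 1, 1, 1],
        })
        pset = infer_protein_profiles(rec, 5)
        assert set(pset.selected_peptides["P1"]) == {"AAK", "CCK"}
        np.testing.assert_allclose(
            pset.replicate_profiles[("ctrl", 1)].loc["P1"], [0, 1.5, 3, 1.5, 0])

    def test_two_peptides_are_averaged(self):
        rec = records_from_traces({
            ("P1", "AAK"): [0, 1, 2, 1, 0],
            ("P1", "CCK"): [0, 3, 6, 3, 0],
        })
        pset = infer_protein_profiles(rec, 5)
        np.testing.assert_allclose(
            pset.replicate_profiles[("ctrl", 1)].loc["P1"], [0, 2, 4, 2, 0])

    def test_same_peptides_used_across_conditions(self):
        # selection is computed on traces concatenated across samples, so a
        # peptide pair that is best overall is used everywhere
        a = pd.concat([
            records_from_traces({("P1", "AAK"): [0, 1, 2, 1, 0],
                                 ("P1", "CCK"): [0, 2, 4, 2, 0],
                                 ("P1", "DDR"): [5, 0, 0, 0, 5]}, condition="c1"),
            records_from_traces({("P1", "AAK"): [1, 3, 1, 0, 0],
                                 ("P1", "CCK"): [2, 6, 2, 0, 0],
                                 ("P1", "DDR"): [0, 0, 4, 4, 0]}, condition="c2"),
        ], ignore_index=True)
        pset = infer_protein_profiles(a, 5)
        assert set(pset.selected_peptides["P1"]) == {"AAK", "CCK"}

    def test_zero_intensity_protein_dropped_with_warning(self):
        rec = pd.concat([
            records_from_traces({("P1", "AAK"): [0, 1, 0]}),
            records_from_traces({("P2", "CCK"): [0, 0, 0]}),
        ], ignore_index=True)
        with pytest.warns(UserWarning, match="P2"):
            pset = infer_protein_profiles(rec, 3)
        assert pset.proteins == ["P1"]

    def test_inference_invariant_to_row_order(self):
        cfg = SimulationConfig(seed=8, n_complexes=2, n_monomers=4)
        records, _, _ = simulate_dataset(cfg)
        shuffled = records.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = infer_protein_profiles(records, cfg.n_fractions)
        b = infer_protein_profiles(shuffled, cfg.n_fractions)
        for key in a.replicate_profiles:
            pd.testing.assert_frame_equal(a.replicate_profiles[key],
                                          b.replicate_profiles[key])


class TestSmoothAndRescale:
    def test_output_spans_unit_range(self):
        out = smooth_and_rescale(gaussian_profile(30.0) * 17.3)
        assert out.min() == pytest.approx(0.0)
        assert out.max() == pytest.approx(1.0)

    def test_all_zero_profile_stays_zero(self):
        np.testing.assert_array_equal(smooth_and_rescale(np.zeros(72)), np.zeros(72))

    def test_impulse_matches_closed_form_sg_coefficients(self):
        # quadratic SG smoothing coefficients for window 5: (-3,12,17,12,3)/35;
        # the negatives clip to 0 and the max (17/35) rescales to 1
        x = np.zeros(31)
        x[15] = 1.0
        out = smooth_and_rescale(x, window=5, order=2)
        expected = np.zeros(31)
        expected[13:18] = np.array([0.0, 12 / 17, 1.0, 12 / 17, 0.0])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_rescaling_is_idempotent(self):
        out = smooth_and_rescale(gaussian_profile(20.0))
        again = (out - out.min()) / (out.max() - out.min())
        np.testing.assert_allclose(out, again, atol=1e-15)

    def test_window_larger_than_profile_rejected(self):
        with pytest.raises(ProfileConfigError):
            smooth_and_rescale(np.ones(4), window=5)


class TestPeakDetection:
    def test_single_gaussian_single_peak(self):
        peaks = detect_peaks(gaussian_profile(30.0))
        assert len(peaks) == 1
        assert peaks[0].apex_fraction == 30

    def test_two_separated_gaussians_two_peaks(self):
        x = gaussian_profile(20.0) + gaussian_profile(40.0)
        peaks = detect_peaks(x / x.max())
        assert [p.apex_fraction for p in peaks] == [20, 40]

    def test_merged_gaussians_one_peak_by_prominence(self):
        # 1 fraction apart: the minor bump's prominence is far below 0.1
        x = gaussian_profile(30.0) + gaussian_profile(31.0)
        x = x / x.max()
        peaks = detect_peaks(x, min_prominence=0.1)
        assert len(peaks) == 1
        # explicit prominence check: profile is unimodal, max prominence = full height
        assert peaks[0].prominence == pytest.approx(x.max() - x.min(), abs=1e-6)

    def test_primary_peak_is_highest_prominence(self):
        x = gaussian_profile(20.0) + 0.4 * gaussian_profile(50.0)
        peaks = detect_peaks(x / x.max())
        assert primary_peak(peaks).apex_fraction == 20

    def test_noiseless_peak_counts_equal_planted_assembly_counts(self):
        cfg = SimulationConfig(seed=12, noise_cv=0.0, apex_jitter_sd=0.0,
                               monomer_peak_prob=0.0, n_complexes=4, n_monomers=6)
        records, _, truth = simulate_dataset(cfg)
        pset = infer_protein_profiles(records, cfg.n_fractions)
        mat = pset.processed_matrix("control")
        for pid in truth.proteins:  # every protein participates in one assembly
            assert len(detect_peaks(mat.loc[pid].to_numpy())) == 1

    def test_members_with_monomer_peak_show_two_assemblies(self):
        cfg = SimulationConfig(seed=12, noise_cv=0.0, apex_jitter_sd=0.0,
                               monomer_peak_prob=1.0, n_complexes=4, n_monomers=2)
        records, _, truth = simulate_dataset(cfg)
        pset = infer_protein_profiles(records, cfg.n_fractions)
        mat = pset.processed_matrix("control")
        for cx in truth.complexes:
            for pid in cx.members:
                mono_f = truth.config.mw_to_fraction(truth.monomer_mw[pid])
                if abs(mono_f - cx.apex_by_condition["control"]) > 6:
                    assert len(detect_peaks(mat.loc[pid].to_numpy())) == 2


class TestReplicateCorrelation:
    def test_identical_replicates(self):
        mat = pd.DataFrame(np.random.default_rng(0).random((5, 20)))
        per_protein, global_r2, excluded = replicate_correlation(mat, mat)
        np.testing.assert_allclose(per_protein, 1.0, atol=1e-12)
        assert global_r2 == pytest.approx(1.0)
        assert excluded == 0

    def test_scale_invariance(self):
        mat = pd.DataFrame(np.random.default_rng(1).random((5, 20)))
        per_protein, _, _ = replicate_correlation(mat, mat * 5.0)
        np.testing.assert_allclose(per_protein, 1.0, atol=1e-12)

    def test_protein_in_one_replicate_excluded_and_counted(self):
        mat = pd.DataFrame(np.random.default_rng(2).random((4, 10)),
                           index=["a", "b", "c", "d"])
        _, _, excluded = replicate_correlation(mat, mat.drop(index="d"))
        assert excluded == 1

    def test_global_r2_matches_pooled_brute_force(self, default_bundle):
        pset = default_bundle["profiles"]
        a = pset.replicate_profiles[("control", 1)]
        b = pset.replicate_profiles[("control", 2)]
        _, global_r2, _ = replicate_correlation(a, b)
        x, y = a.to_numpy().ravel(), b.to_numpy().ravel()
        expected = np.corrcoef(x, y)[0, 1] ** 2
        assert global_r2 == pytest.approx(expected, abs=1e-12)

    def test_replicate_agreement_is_high_at_default_noise(self, default_bundle):
        pset = default_bundle["profiles"]
        per_protein, global_r2, _ = replicate_correlation(
            pset.replicate_profiles[("control", 1)],
            pset.replicate_profiles[("control", 2)])
        assert per_protein.mean() > 0.8  # the replicate-robustness benchmark
        assert global_r2 > 0.8
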