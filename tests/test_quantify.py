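"""Quantification chain: T1 fits, NMRD assembly, power law, features,
clustering, classification and concentration estimation."""

import warnings

import numpy as np
import pytest

from ffcmri.dispersion import larmor_frequency, phantom_reference_library
from ffcmri.quantify import (
    NMRDProfile,
    assemble_nmrd,
    classify_material,
    cluster_voxels,
    estimate_concentration,
    extract_features,
    fit_power_law,
    fit_t1_ir,
    restore_ir_sign,
)

LIB = phantom_reference_library()
FIELDS = np.array([0.002, 0.010, 0.030, 0.065, 0.120, 0.200])


def model_profile(model, fields=FIELDS, noise=0.0, seed=0):
    r1 = model.r1(field_T=fields)
    if noise:
        rng = np.random.default_rng(seed)
        r1 = r1 * (1.0 + noise * rng.standard_normal(fields.size))
    return NMRDProfile(fields=fields, r1=r1)


class TestFitT1IR:
    def test_noiseless_exact(self):
        t1 = 0.3
        t = np.geomspace(0.05, 1.5, 8)
        s = 0.2 + (-1.0 - 0.2) * np.exp(-t / t1)
        fit = fit_t1_ir(s, t)
        assert fit["t1"] == pytest.approx(t1, rel=1e-8)
        assert fit["s_inf"] == pytest.approx(0.2, rel=1e-6)

    def test_magnitude_input_sign_restoration(self):
        # magnitude-only IR data at SNR 100 still recovers T1 to ~1%
        t1 = 0.25
        t = np.concatenate([np.geomspace(0.01, 1.8, 11), [2.5]])
        s_true = 0.9 + (-0.9 - 0.9) * np.exp(-t / t1)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            s = np.abs(s_true + 0.009 * rng.standard_normal(t.size))  # SNR 100
            fit = fit_t1_ir(s, t, magnitude=True)
            errs.append(abs(fit["t1"] - t1) / t1)
        assert np.mean(errs) < 0.01

    def test_restore_sign_flips_before_minimum(self):
        s = np.array([0.9, 0.4, 0.05, 0.5, 1.0])
        restored = restore_ir_sign(s)
        assert np.all(restored[:3] <= 0) and np.all(restored[3:] > 0)

    def test_degenerate_two_point_input_raises(self):
        with pytest.raises(ValueError):
            fit_t1_ir(np.array([0.1, 0.2]), np.array([0.1, 0.5]))

    def test_unfittable_voxel_flagged_not_raised(self):
        # corrupted voxel data must come back as NaN, not an exception
        t = np.linspace(0.1, 1.0, 6)
        s = np.array([1.0, 1.0, 1.0, 1.0, 1.0, np.inf])
        fit = fit_t1_ir(s, t)
        assert np.isnan(fit["t1"])


class TestAssembleNMRD:
    def test_roi_mean_matches_uniform_voxels(self):
        t1_maps = [np.full((4, 4), 0.1), np.full((4, 4), 0.2), np.full((4, 4), 0.4)]
        prof = assemble_nmrd(t1_maps, [0.002, 0.02, 0.2], roi_mask=np.ones((4, 4), bool))
        assert np.allclose(prof.r1, [10.0, 5.0, 2.5])
        assert np.allclose(prof.r1_err, 0.0)

    def test_requires_three_fields(self):
        with pytest.raises(ValueError):
            assemble_nmrd([np.ones((2, 2))] * 2, [0.01, 0.1])

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError):
            assemble_nmrd([np.ones((2, 2))] * 3, [0.01, 0.1, 0.2], roi_mask=np.zeros((2, 2), bool))

    def test_nan_voxels_excluded(self):
        m = np.full((3, 3), 0.5)
        m[0, 0] = np.nan
        prof = assemble_nmrd([m, m, m], [0.01, 0.1, 0.2], roi_mask=np.ones((3, 3), bool))
        assert np.allclose(prof.r1, 2.0)


class TestPowerLaw:
    def test_exact_recovery(self):
        f = larmor_frequency(FIELDS)
        a_true, b_true = 50.0, -0.25
        prof = NMRDProfile(fields=FIELDS, r1=a_true * f**b_true)
        a, b, resid = fit_power_law(prof)
        assert a == pytest.approx(a_true, rel=1e-10)
        assert b == pytest.approx(b_true, rel=1e-10)
        assert resid < 1e-20

    def test_constant_profile(self):
        prof = NMRDProfile(fields=FIELDS, r1=np.full(FIELDS.size, 7.0))
        a, b, _ = fit_power_law(prof)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert a == pytest.approx(7.0, rel=1e-10)

    def test_weighted_beats_unweighted_on_heteroscedastic_data(self):
        f = larmor_frequency(FIELDS)
        a_true, b_true = 30.0, -0.2
        r1_true = a_true * f**b_true
        # relative error grows strongly with field
        rel_sd = np.linspace(0.005, 0.15, FIELDS.size)
        err_w, err_u = [], []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            r1 = r1_true * (1 + rel_sd * rng.standard_normal(FIELDS.size))
            if np.any(r1 <= 0):
                continue
            prof = NMRDProfile(fields=FIELDS, r1=r1, r1_err=rel_sd * r1_true)
            _, bw, _ = fit_power_law(prof, weighted=True)
            _, bu, _ = fit_power_law(prof, weighted=False)
            err_w.append((bw - b_true) ** 2)
            err_u.append((bu - b_true) ** 2)
        assert np.sqrt(np.mean(err_w)) < np.sqrt(np.mean(err_u))

    def test_direct_fit_agrees_on_clean_data(self):
        f = larmor_frequency(FIELDS)
        prof = NMRDProfile(fields=FIELDS, r1=20.0 * f**-0.15)
        a, b, _ = fit_power_law(prof, direct=True)
        assert b == pytest.approx(-0.15, rel=1e-6)


class TestFeatures:
    def test_bsa_has_quadrupolar_amplitude_mncl2_does_not(self):
        bsa = extract_features(model_profile(LIB["references"]["BSA"]))
        mn = extract_features(model_profile(LIB["references"]["MnCl2"]))
        assert bsa.quad_amplitude > 0.5
        assert mn.quad_amplitude < 0.15 * bsa.quad_amplitude

    def test_flat_profile_all_zero(self):
        prof = NMRDProfile(fields=FIELDS, r1=np.full(FIELDS.size, 3.0))
        feats = extract_features(prof)
        assert feats.span == 0.0
        assert feats.local_dispersion_20mT == 0.0
        assert feats.quad_amplitude == 0.0

    def test_doubling_concentration_doubles_span(self):
        m = LIB["references"]["MnCl2"]
        base = m.diamagnetic_baseline
        f1 = extract_features(model_profile(m.at_concentration(0.5)))
        f2 = extract_features(model_profile(m.at_concentration(1.0)))
        base_span = float(base.r1(larmor_frequency(FIELDS[0])) - base.r1(larmor_frequency(FIELDS[-1])))
        assert (f2.span - base_span) == pytest.approx(2 * (f1.span - base_span), rel=1e-9)

    def test_grid_must_cover_feature_fields(self):
        narrow = np.array([0.1, 0.15, 0.2])
        with pytest.raises(ValueError):
            extract_features(model_profile(LIB["references"]["BSA"], fields=narrow))


class TestClustering:
    def _voxel_features(self, n_per=60, noise=0.03, seed=0):
        rng = np.random.default_rng(seed)
        feats, truth = [], []
        for name, ref in (("MnCl2", LIB["references"]["MnCl2"]), ("BSA", LIB["references"]["BSA"])):
            for i in range(n_per):
                prof = model_profile(ref, noise=noise, seed=rng.integers(2**31))
                feats.append(extract_features(prof).as_array())
                truth.append(name)
        return np.asarray(feats), np.asarray(truth)

    def test_two_material_separation_with_matching(self):
        feats, truth = self._voxel_features()
        labels, info = cluster_voxels(
            feats, k=2, seed=42,
            reference_library={"MnCl2": LIB["references"]["MnCl2"], "BSA": LIB["references"]["BSA"]},
            fields=FIELDS,
        )
        assigned = np.array([info["materials"][l] for l in labels])
        assert np.mean(assigned == truth) >= 0.95

    def test_matching_invariant_under_cluster_permutation(self):
        feats, truth = self._voxel_features(seed=3)
        ref = {"MnCl2": LIB["references"]["MnCl2"], "BSA": LIB["references"]["BSA"]}
        out = []
        for seed in (0, 1, 7):  # different k-means seeds permute the indices
            labels, info = cluster_voxels(feats, k=2, seed=seed, reference_library=ref, fields=FIELDS)
            out.append(np.array([info["materials"][l] for l in labels]))
        assert all(np.array_equal(out[0], o) for o in out[1:])

    def test_identical_features_flag_degenerate(self):
        feats = np.ones((20, 3))
        labels, info = cluster_voxels(feats, k=2, seed=0)
        assert info["degenerate"]

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cluster_voxels(np.ones((3, 2)), k=5)
        with pytest.raises(ValueError):
            cluster_voxels(np.ones((10, 2)), k=1)


class TestClassification:
    def test_self_consistency(self):
        bsa10 = [m for m in LIB["bottles"].values() if m.name.startswith("BSA 10")][0]
        name, c, _ = classify_material(model_profile(bsa10), LIB["references"])
        assert name == "BSA"
        assert c == pytest.approx(10.0, rel=1e-6)

    def test_noisy_mncl2_classified_in_at_least_99_of_100_seeds(self):
        mn052 = [m for m in LIB["bottles"].values() if "0.52" in m.name][0]
        hits = 0
        for seed in range(100):
            prof = model_profile(mn052, noise=0.05, seed=seed)
            name, _, _ = classify_material(prof, LIB["references"])
            hits += name == "MnCl2"
        assert hits >= 99

    def test_tie_breaks_by_library_order(self):
        m = LIB["references"]["MnCl2"]
        prof = model_profile(m)
        duplicated = {"first": m, "second": m}
        name, _, _ = classify_material(prof, duplicated)
        assert name == "first"

    def test_empty_library_raises(self):
        with pytest.raises(ValueError):
            classify_material(model_profile(LIB["references"]["MnCl2"]), {})


class TestConcentration:
    def test_exactly_linear_in_noiseless_limit(self):
        ref = LIB["references"]["BSA"]
        prof = model_profile(ref.at_concentration(40.0))
        assert estimate_concentration(prof, ref) == pytest.approx(40.0, rel=1e-10)

    def test_reference_recovers_itself(self):
        ref = LIB["references"]["MnCl2"]
        assert estimate_concentration(model_profile(ref), ref) == pytest.approx(0.74, rel=1e-12)

    def test_negative_scale_clipped_with_warning(self):
        ref = LIB["references"]["MnCl2"]
        f = larmor_frequency(FIELDS)
        base = ref.diamagnetic_baseline.r1(f)
        prof = NMRDProfile(fields=FIELDS, r1=np.maximum(base - 0.5 * (ref.r1(field_T=FIELDS) - base), 1e-3))
        with pytest.warns(UserWarning):
            c = estimate_concentration(prof, ref)
        assert c == 0.0

    def test_estimator_slope_one_over_seeds(self):
        # noisy profiles across a concentration ladder: regression of
        # estimate on truth has slope 1 within its confidence interval
        ref = LIB["references"]["BSA"]
        truths, estimates = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            c = rng.uniform(3.0, 25.0)
            prof = model_profile(ref.at_concentration(c), noise=0.02, seed=seed + 1000)
            truths.append(c)
            estimates.append(estimate_concentration(prof, ref))
        slope, intercept = np.polyfit(truths, estimates, 1)
        resid = np.array(estimates) - (slope * np.array(truths) + intercept)
        se = np.sqrt(np.sum(resid**2) / (len(truths) - 2) / np.sum((truths - np.mean(truths)) ** 2))
        assert abs(slope - 1.0) < 3 * se + 0.02

    def test_classification_accuracy_monotone_in_snr(self):
        ref = LIB["references"]
        bottles = list(LIB["bottles"].values())
        accs = []
        for snr in (20, 50, 100):
            hits = total = 0
            for seed in range(40):
                rng = np.random.default_rng(seed)
                m = bottles[seed % len(bottles)]
                prof = model_profile(m, noise=1.0 / snr, seed=seed + snr)
                name, _, _ = classify_material(prof, ref)
                hits += name == ("BSA" if "BSA" in m.name else "MnCl2")
                total += 1
            accs.append(hits / total)
        assert accs[0] <= accs[1] + 0.05 and accs[1] <= accs[2] + 0.05
        assert accs[-1] >= 0.95
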