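"""Synthetic cohort generator: determinism, noise model, planted truth."""

import numpy as np
import pytest

from deltapls.simulate import (
    EffectSpec, SimulationConfig, default_effects, ellipsoid_mask,
    simulate_cohort, smooth_gaussian_field, sphere_mask, truth_report,
)
from deltapls.io import SESSIONS


def _tiny_config(**kwargs):
    defaults = dict(n_control=6, n_concussed=4, dims=(8, 8, 8),
                    modalities=("CBF",), seed=11)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestSmoothField:
    def test_unsmoothed_field_is_standard_normal(self):
        field = smooth_gaussian_field((20, 20, 20), 3.0, 0.0, rng=0)
        assert field.std() == pytest.approx(1.0, abs=0.05)
        assert field.mean() == pytest.approx(0.0, abs=0.05)

    def test_deterministic_given_seed(self):
        a = smooth_gaussian_field((10, 10, 10), 3.0, 6.0, rng=5)
        b = smooth_gaussian_field((10, 10, 10), 3.0, 6.0, rng=5)
        assert np.array_equal(a, b)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian_field((8, 8, 8), 3.0, -1.0, rng=0)

    def test_unit_variance_preserved_after_smoothing(self):
        rng = np.random.default_rng(0)
        stds = [smooth_gaussian_field((16, 16, 16), 3.0, 6.0, rng).std()
                for _ in range(30)]
        assert np.mean(stds) == pytest.approx(1.0, abs=0.05)

    def test_lag1_autocorrelation_matches_gaussian_kernel(self):
        # smoothing white noise with a Gaussian of sd sigma gives field
        # autocorrelation exp(-h^2 / (4 sigma^2)) at lag h
        fwhm, voxel = 6.0, 3.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / voxel
        expected = np.exp(-1.0 / (4 * sigma ** 2))
        rng = np.random.default_rng(1)
        rhos = []
        for _ in range(10):
            f = smooth_gaussian_field((24, 24, 24), voxel, fwhm, rng)
            rhos.append(np.corrcoef(f[:-1].ravel(), f[1:].ravel())[0, 1])
        assert np.mean(rhos) == pytest.approx(expected, abs=0.05)


class TestCohortGeneration:
    def test_seed_reproducibility(self):
        cfg = _tiny_config()
        r1, m1, s1, t1 = simulate_cohort(cfg)
        r2, m2, s2, t2 = simulate_cohort(_tiny_config())
        assert [r.subject_id for r in r1] == [r.subject_id for r in r2]
        for a, b in zip(m1, m2):
            assert np.array_equal(a.values, b.values)
        assert s1.equals(s2)
        assert t1.retained.equals(t2.retained)

    def test_controls_single_session_concussed_longitudinal(self):
        records, maps, _, truth = simulate_cohort(_tiny_config())
        sessions = {}
        for m in maps:
            sessions.setdefault(m.subject_id, set()).add(m.session)
        for r in records:
            if r.group == "control":
                assert sessions[r.subject_id] == {"CONTROL"}
            else:
                expected = {s for s in SESSIONS
                            if truth.retained.loc[r.subject_id, s]}
                assert sessions[r.subject_id] == expected

    def test_dropout_matches_cohort_retention_rates(self):
        # the emulated study retained 53/51/32 of 61 at ACU/RTP/1YR
        cfg = _tiny_config(n_control=2, n_concussed=61, seed=0)
        retained = np.zeros(3)
        n_rep = 30
        for rep in range(n_rep):
            cfg = _tiny_config(n_control=2, n_concussed=61, seed=rep)
            _, _, _, truth = simulate_cohort(cfg)
            retained += truth.retained[list(SESSIONS)].sum().to_numpy()
        rates = retained / (n_rep * 61)
        expected = np.array([53, 51, 32]) / 61
        se = np.sqrt(expected * (1 - expected) / (n_rep * 61))
        assert np.all(np.abs(rates - expected) < 3 * se)

    def test_symptoms_elevated_at_acute_injury(self):
        cfg = _tiny_config(n_control=10, n_concussed=30, seed=2)
        _, _, symptoms, _ = simulate_cohort(cfg)
        item_cols = symptoms.columns[2:]
        acu = symptoms[symptoms["session"] == "ACU"][item_cols].sum(axis=1)
        base = symptoms[symptoms["session"] == "baseline"][item_cols].sum(axis=1)
        assert acu.mean() > 3 * base.mean()

    def test_fa_values_within_range(self):
        cfg = _tiny_config(modalities=("FA",))
        _, maps, _, _ = simulate_cohort(cfg)
        for m in maps:
            assert m.values.min() >= 0.0 and m.values.max() <= 1.0

    def test_effect_region_outside_mask_rejected(self):
        with pytest.raises(ValueError, match="region"):
            _tiny_config(
                mask=ellipsoid_mask((8, 8, 8), (0.3, 0.3, 0.3)),
                main_effect=EffectSpec(center=(7, 7, 7), radius=0.5,
                                       amplitudes={"ACU": 1.0}),
            )


class TestPlantedTruth:
    def test_null_config_has_zero_contrasts(self):
        _, _, _, truth = simulate_cohort(_tiny_config())
        report = truth_report(truth)
        assert (report["main_contrast"] == 0).all()
        assert (report["sex_contrast"] == 0).all()

    def test_sex_amplitude_maps_to_contrast_in_map_units(self):
        cfg = _tiny_config(
            sex_effect=EffectSpec(center=(4, 4, 4), radius=2.0,
                                  amplitudes={"YR1": 0.8}),
        )
        report = truth_report(simulate_cohort(cfg)[3])
        noise_sd = cfg.modality_params["CBF"].noise_sd
        yr1 = report[report["session"] == "YR1"].iloc[0]
        acu = report[report["session"] == "ACU"].iloc[0]
        assert yr1["sex_contrast"] == pytest.approx(0.8 * noise_sd)
        assert acu["sex_contrast"] == 0.0

    def test_planted_contrasts_recovered_by_group_means(self):
        # brute-force oracle: direct group-mean differencing at large n
        amp = 1.0
        cfg = SimulationConfig(
            n_control=400, n_concussed=400, dims=(8, 8, 8),
            modalities=("CBF",), seed=3,
            dropout_probs={"ACU": 0.0, "RTP": 1.0, "YR1": 1.0},
            main_effect=EffectSpec(center=(4, 4, 4), radius=2.5,
                                   amplitudes={"ACU": amp}),
        )
        records, maps, _, truth = simulate_cohort(cfg)
        par = cfg.modality_params["CBF"]
        by_group = {"control": [], "concussed": []}
        demo = {r.subject_id: r for r in records}
        for m in maps:
            r = demo[m.subject_id]
            adj = (m.values - par.sex_offset * r.sex
                   - par.age_slope * (r.age - 20.0) - par.hoc_offset * r.hoc)
            by_group[r.group].append(adj)
        diff = (np.mean(by_group["concussed"], axis=0)
                - np.mean(by_group["control"], axis=0))
        region = truth.main_region
        n_eff = 400
        se = np.sqrt(2 * (par.noise_sd ** 2 + par.intercept_sd ** 2) / n_eff)
        assert np.all(np.abs(diff[region] - amp * par.noise_sd)
                      < 3 * se + 0.2)
        assert abs(diff[~region].mean()) < 3 * se

    def test_default_effects_are_disjoint_and_in_mask(self):
        cfg = default_effects(SimulationConfig())
        main = cfg.main_effect.region(cfg.dims)
        sexr = cfg.sex_effect.region(cfg.dims)
        assert not (main & sexr).any()
        assert (main & cfg.mask).sum() > 50
        assert (sexr & cfg.mask).sum() > 50


def test_sphere_mask_size():
    m = sphere_mask((10, 10, 10), (5, 5, 5), 2.0)
    # 33 lattice points fall within radius 2 of the center
    assert m.sum() == 33
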