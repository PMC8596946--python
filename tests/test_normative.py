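"""Control matching, Huber robust location, and difference-map scoring."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from deltapls.io import MaskGeometry, ParameterMap, SubjectRecord
from deltapls.normative import (
    DifferenceMap, MatchCriteria, ScoringError, difference_maps,
    huber_location, match_controls, score_cohort,
)


def _athlete(sex=1, hoc=1, age=20.0):
    return SubjectRecord("A", "concussed", sex=sex, age=age, hoc=hoc,
                         n_prior_concussions=hoc)


def _control(sid, sex, hoc, age):
    return SubjectRecord(sid, "control", sex=sex, age=age, hoc=hoc,
                         n_prior_concussions=hoc)


class TestMatching:
    def test_matches_on_sex_hoc_and_age(self):
        controls = [
            _control("c1", 1, 1, 20.0),   # match
            _control("c2", 1, 1, 18.0),   # match (gap exactly 2)
            _control("c3", 1, 1, 22.0),   # match (gap exactly 2)
            _control("c4", 0, 1, 20.0),   # wrong sex
            _control("c5", 1, 0, 20.0),   # wrong hoc
            _control("c6", 1, 1, 23.0),   # too old
        ]
        assert match_controls(_athlete(), controls) == ["c1", "c2", "c3"]

    def test_age_gap_is_inclusive(self):
        ok = [_control("c", 1, 1, 22.0)]
        near = [_control("c", 1, 1, 22.01)]
        assert match_controls(_athlete(age=20.0), ok) == ["c"]
        with pytest.warns(UserWarning):
            assert match_controls(_athlete(age=20.0), near) == []

    def test_zero_matches_warns(self):
        with pytest.warns(UserWarning, match="A"):
            match_controls(_athlete(), [_control("c", 0, 0, 50.0)])

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            MatchCriteria(max_age_gap=-1)


def huber_objective(values, mu, k, sigma):
    u = np.abs(values - mu) / sigma
    rho = np.where(u <= k, 0.5 * u ** 2, k * u - 0.5 * k ** 2)
    return rho.sum()


class TestHuberLocation:
    def test_constant_sample(self):
        assert huber_location([3.5, 3.5, 3.5]) == 3.5

    def test_symmetric_sample(self):
        assert huber_location([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_outlier_sample_matches_direct_minimization(self):
        x = np.array([1.0, 2.0, 3.0, 100.0])
        est = huber_location(x, k=1.35)
        assert 2.0 < est <= 3.0
        sigma = 1.4826 * np.median(np.abs(x - np.median(x)))
        direct = minimize_scalar(
            lambda m: huber_objective(x, m, 1.35, sigma),
            bracket=(x.min(), x.max()), method="golden",
            options={"xtol": 1e-12},
        ).x
        assert est == pytest.approx(direct, abs=1e-6)

    def test_large_k_recovers_arithmetic_mean(self, rng):
        x = rng.normal(size=40)
        assert huber_location(x, k=1e6) == pytest.approx(x.mean(), abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_affine_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_cauchy(size=31)
        a, b = 2.5, -7.0
        assert huber_location(a * x + b) == pytest.approx(
            a * huber_location(x) + b, abs=1e-6
        )

    def test_vectorized_matches_scalar(self, rng):
        X = rng.normal(size=(15, 8))
        X[0] += 50  # gross outlier row
        cols = huber_location(X, axis=0)
        for j in range(8):
            assert cols[j] == pytest.approx(huber_location(X[:, j]), abs=1e-8)

    def test_bounded_influence_vs_mean(self):
        # one arbitrary outlier moves the Huber estimate strictly less
        # than it moves the arithmetic mean
        clean = np.array([10.0, 10.5, 9.5, 10.2, 9.8])
        spiked = np.append(clean, 1000.0)
        shift_huber = abs(huber_location(spiked) - huber_location(clean))
        shift_mean = abs(spiked.mean() - clean.mean())
        assert shift_huber < shift_mean

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            huber_location([])


def _pmap(geom, sid, session, values):
    return ParameterMap(sid, session, "CBF", values, geom)


class TestDifferenceMaps:
    def test_athlete_at_robust_mean_gives_zero(self, small_geometry, rng):
        V = small_geometry.n_voxels
        ctrl_vals = rng.normal(50, 5, size=(6, V))
        m = huber_location(ctrl_vals, axis=0)
        controls = [_pmap(small_geometry, f"c{i}", "CONTROL", v)
                    for i, v in enumerate(ctrl_vals)]
        athlete = [_pmap(small_geometry, "A", "ACU", m)]
        (dm,) = difference_maps(athlete, controls)
        assert np.allclose(dm.delta_values, 0.0, atol=1e-10)

    def test_reference_reused_across_sessions(self, small_geometry, rng):
        V = small_geometry.n_voxels
        controls = [_pmap(small_geometry, f"c{i}", "CONTROL",
                          rng.normal(50, 5, V)) for i in range(5)]
        athlete = [_pmap(small_geometry, "A", s, rng.normal(50, 5, V))
                   for s in ("ACU", "RTP", "YR1")]
        dms = difference_maps(athlete, controls)
        assert all(np.array_equal(d.m_values, dms[0].m_values) for d in dms)
        assert all(d.matched_control_ids == dms[0].matched_control_ids
                   for d in dms)

    def test_outlier_control_barely_moves_delta(self, small_geometry, rng):
        V = small_geometry.n_voxels
        # Huber's worst-case shift from one outlier is ~ k*sigma_hat/n; at
        # the cohort's typical subgroup size (29) this sits below
        # 0.1*noise_sd even for the voxel with the largest MAD estimate
        noise_sd = 5.0
        clean = rng.normal(50, noise_sd, size=(29, V))
        outlier = clean[0] + 100.0
        athlete = [_pmap(small_geometry, "A", "ACU", rng.normal(50, 5, V))]
        ctrl_clean = [_pmap(small_geometry, f"c{i}", "CONTROL", v)
                      for i, v in enumerate(clean)]
        ctrl_spiked = ctrl_clean + [_pmap(small_geometry, "cx", "CONTROL",
                                          outlier)]
        (d_clean,) = difference_maps(athlete, ctrl_clean)
        (d_spiked,) = difference_maps(athlete, ctrl_spiked)
        assert np.max(np.abs(d_spiked.delta_values - d_clean.delta_values)) \
            < 0.1 * noise_sd

    def test_huge_k_equals_mean_reference(self, small_geometry, rng):
        V = small_geometry.n_voxels
        vals = rng.normal(50, 5, size=(5, V))
        controls = [_pmap(small_geometry, f"c{i}", "CONTROL", v)
                    for i, v in enumerate(vals)]
        athlete = [_pmap(small_geometry, "A", "ACU", rng.normal(50, 5, V))]
        (dm,) = difference_maps(athlete, controls, k=1e6)
        expected = athlete[0].values - vals.mean(axis=0)
        assert np.allclose(dm.delta_values, expected, atol=1e-8)

    def test_small_subgroup_rejected(self, small_geometry, rng):
        V = small_geometry.n_voxels
        controls = [_pmap(small_geometry, "c0", "CONTROL",
                          rng.normal(size=V))]
        athlete = [_pmap(small_geometry, "A", "ACU", rng.normal(size=V))]
        with pytest.raises(ScoringError):
            difference_maps(athlete, controls)


class TestScoreCohort:
    def test_excluded_subjects_are_dropped(self, small_geometry, rng):
        V = small_geometry.n_voxels
        records = [_control(f"c{i}", 1, 0, 20.0) for i in range(6)]
        records += [SubjectRecord("A", "concussed", sex=1, age=20.0, hoc=0)]
        maps = [_pmap(small_geometry, f"c{i}", "CONTROL",
                      rng.normal(50, 5, V)) for i in range(6)]
        maps += [_pmap(small_geometry, "A", "ACU", rng.normal(50, 5, V))]
        ids, sex, deltas, report = score_cohort(
            records, maps, "CBF", excluded_ids={"c0"}
        )
        assert ids == ["A"]
        assert report.loc[0, "n_matched"] == 5
        assert "c0" not in report.loc[0, "matched_ids"]
        # ACU present, RTP/YR1 missing
        assert np.isfinite(deltas[0, 0]).all()
        assert np.isnan(deltas[0, 1]).all() and np.isnan(deltas[0, 2]).all()
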