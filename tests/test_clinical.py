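"""Symptom scoring, Wilcoxon tests vs exact enumeration, BH-FDR, attrition."""

import itertools

import numpy as np
import pandas as pd
import pytest

from deltapls.clinical import (
    DOMAINS, SYMPTOM_ITEMS, attrition_check, fdr_adjust, score_symptoms,
    wilcoxon_paired, wilcoxon_twosample,
)


class TestSymptomScoring:
    def test_all_zero(self):
        rec = score_symptoms(np.zeros(22, dtype=int))
        assert rec.total_symptoms == 0
        assert rec.total_severity == 0
        assert all(v == 0 for v in rec.domain_sums.values())

    def test_maximum_ratings(self):
        rec = score_symptoms(np.full(22, 6))
        assert rec.total_severity == 132
        assert rec.domain_sums == {"somatic": 54, "cognitive": 36,
                                   "sleep": 18, "mood": 24}

    def test_headache_is_somatic(self):
        items = np.zeros(22, dtype=int)
        items[SYMPTOM_ITEMS.index("headache")] = 3
        rec = score_symptoms(items)
        assert rec.domain_sums["somatic"] == 3
        assert rec.total_symptoms == 1
        assert sum(v for k, v in rec.domain_sums.items() if k != "somatic") == 0

    def test_domains_partition_the_items(self):
        all_items = [i for members in DOMAINS.values() for i in members]
        assert sorted(all_items) == sorted(SYMPTOM_ITEMS)
        assert [len(m) for m in DOMAINS.values()] == [9, 6, 3, 4]

    def test_domain_sums_add_to_total(self, rng):
        items = rng.integers(0, 7, size=22)
        rec = score_symptoms(items)
        assert sum(rec.domain_sums.values()) == rec.total_severity

    @pytest.mark.parametrize("bad", [np.full(22, 7), np.full(22, -1),
                                     np.zeros(10, dtype=int)])
    def test_invalid_ratings_rejected(self, bad):
        with pytest.raises(ValueError):
            score_symptoms(bad)


def exact_signed_rank_p(d, alternative="greater"):
    """Exact p of the signed-rank statistic by enumerating all 2^n signs."""
    from scipy.stats import rankdata
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats = [np.asarray(signs) @ ranks
             for signs in itertools.product([0, 1], repeat=n)]
    stats = np.asarray(stats)
    if alternative == "greater":
        return np.mean(stats >= w_obs)
    if alternative == "less":
        return np.mean(stats <= w_obs)
    hi = np.mean(stats >= w_obs)
    lo = np.mean(stats <= w_obs)
    return min(1.0, 2 * min(hi, lo))


def exact_ranksum_p(x, y, alternative="two-sided"):
    """Exact p of the rank-sum statistic over all group assignments."""
    from scipy.stats import rankdata
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    r_obs = ranks[:n1].sum()
    sums = np.array([ranks[list(c)].sum()
                     for c in itertools.combinations(range(len(pooled)), n1)])
    hi = np.mean(sums >= r_obs)
    lo = np.mean(sums <= r_obs)
    if alternative == "greater":
        return hi
    if alternative == "less":
        return lo
    return min(1.0, 2 * min(hi, lo))


class TestWilcoxon:
    def test_identical_pairs(self):
        x = np.arange(10.0)
        z, p = wilcoxon_paired(x, x, alternative="greater")
        assert z == 0.0 and p == 0.5

    def test_uniform_shift_highly_significant(self):
        x = np.arange(20.0)
        z, p = wilcoxon_paired(x + 10, x, alternative="greater")
        assert z > 3 and p < 1e-3

    @pytest.mark.parametrize("seed", range(4))
    def test_paired_normal_approx_tracks_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = x + rng.normal(scale=1.0, size=8) + 0.5
        for alt in ("greater", "less", "two-sided"):
            _, p = wilcoxon_paired(x, y, alternative=alt)
            p_exact = exact_signed_rank_p(np.asarray(x) - np.asarray(y), alt)
            assert abs(p - p_exact) < 0.05

    def test_two_sample_identical_groups(self, rng):
        x = rng.normal(size=12)
        z, p = wilcoxon_twosample(x, x)
        assert abs(z) < 1e-9 and p == pytest.approx(1.0)

    def test_two_sample_full_separation(self):
        z, p = wilcoxon_twosample(np.arange(10) + 100.0, np.arange(10.0))
        assert z > 3 and p < 1e-3

    @pytest.mark.parametrize("seed", range(4))
    def test_ranksum_normal_approx_tracks_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6) + 0.8
        y = rng.normal(size=5)
        for alt in ("greater", "less", "two-sided"):
            _, p = wilcoxon_twosample(x, y, alternative=alt)
            p_exact = exact_ranksum_p(x, y, alt)
            assert abs(p - p_exact) < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_twosample(np.array([]), np.array([1.0]))


def bh_stepup_oracle(pvals, q):
    """Largest k with p_(k) <= k q / m defines the rejection set."""
    pvals = np.asarray(pvals)
    m = len(pvals)
    order = np.argsort(pvals)
    k_max = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k * q / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestFDR:
    def test_all_ones_never_rejected(self):
        assert not fdr_adjust(np.ones(5)).any()

    def test_single_small_p_rejected(self):
        assert fdr_adjust(np.array([0.01])).all()

    def test_stepup_example(self):
        p = np.array([0.01, 0.02, 0.04, 0.5])
        assert np.array_equal(fdr_adjust(p, q=0.05),
                              bh_stepup_oracle(p, 0.05))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_stepup_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            m = rng.integers(1, 20)
            p = rng.random(m)
            assert np.array_equal(fdr_adjust(p, q=0.05),
                                  bh_stepup_oracle(p, 0.05))

    def test_rejections_monotone_in_p(self, rng):
        p = rng.random(12)
        before = fdr_adjust(p, q=0.05)
        p2 = p.copy()
        p2[3] = p2[3] / 10
        after = fdr_adjust(p2, q=0.05)
        assert np.all(after[before])   # no rejection is lost


class TestAttrition:
    def _frame(self, n, rng):
        idx = [f"s{i}" for i in range(n)]
        variables = pd.DataFrame({
            "age": rng.integers(17, 28, n).astype(float),
            "sex": rng.integers(0, 2, n).astype(float),
            "symptoms": rng.poisson(3, n).astype(float),
        }, index=idx)
        return idx, variables

    def test_perfect_association_flagged(self, rng):
        idx, variables = self._frame(60, rng)
        retained = pd.DataFrame(
            {"YR1": variables["age"] > variables["age"].median()}, index=idx
        )
        out = attrition_check(retained, variables)
        age_row = out[(out["variable"] == "age")]
        assert age_row["significant"].all()

    def test_constant_variable_reported_missing(self, rng):
        idx, variables = self._frame(30, rng)
        variables["sex"] = 1.0
        retained = pd.DataFrame({"YR1": rng.random(30) < 0.5}, index=idx)
        out = attrition_check(retained, variables)
        row = out[out["variable"] == "sex"].iloc[0]
        assert np.isnan(row["rho"]) and not row["significant"]

    def test_null_flag_rate_controlled(self):
        rng = np.random.default_rng(0)
        flags = 0
        tests = 0
        for _ in range(40):
            idx, variables = self._frame(60, rng)
            retained = pd.DataFrame(
                {s: rng.random(60) < 0.7 for s in ("ACU", "RTP", "YR1")},
                index=idx,
            )
            out = attrition_check(retained, variables)
            flags += out["significant"].sum()
            tests += len(out)
        assert flags / tests <= 0.05

    def test_too_few_subjects_rejected(self, rng):
        idx, variables = self._frame(5, rng)
        retained = pd.DataFrame({"YR1": [True] * 5}, index=idx)
        with pytest.raises(ValueError):
            attrition_check(retained, variables)
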