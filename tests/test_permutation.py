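"""Permutation machinery: shuffles, p-values, multiplicity, export."""
import numpy as np
import pandas as pd
import pytest

import pushpull as pp
from pushpull.errors import (ConfigurationError, DegenerateInputError,
                             NumericalError)
from pushpull.permutation import apply_permutation, log_bonferroni


def cohort_visits(small_null_cohort):
    _, _, pre = small_null_cohort
    return pp.pivot_visits(pre.normalized)


class TestPermutationSet:
    def test_each_trial_is_a_within_animal_bijection(self, small_null_cohort):
        visits = cohort_visits(small_null_cohort)
        pset = pp.build_permutation_set(visits, K=5, seed=3)
        for animal, t in zip(visits.animal_ids, visits.times):
            perm = pset.perms[animal]
            assert perm.shape == (5, t.size)
            for k in range(5):
                assert sorted(perm[k]) == list(range(t.size))

    def test_out_of_window_slots_stay_fixed(self, small_null_cohort):
        visits = cohort_visits(small_null_cohort)
        lo, hi = 18.0, 22.0
        pset = pp.build_permutation_set(visits, K=4, seed=0,
                                        age_window=(lo, hi))
        for animal, t in zip(visits.animal_ids, visits.times):
            outside = np.flatnonzero((t < lo) | (t > hi))
            perm = pset.perms[animal]
            assert np.array_equal(perm[:, outside],
                                  np.tile(outside, (4, 1)))

    def test_same_seed_reproduces_same_permutations(self, small_null_cohort):
        visits = cohort_visits(small_null_cohort)
        p1 = pp.build_permutation_set(visits, K=3, seed=9)
        p2 = pp.build_permutation_set(visits, K=3, seed=9)
        for a in visits.animal_ids:
            np.testing.assert_array_equal(p1.perms[a], p2.perms[a])

    def test_empty_window_rejected(self, small_null_cohort):
        visits = cohort_visits(small_null_cohort)
        with pytest.raises(ConfigurationError):
            pp.build_permutation_set(visits, K=2, seed=0,
                                     age_window=(500.0, 600.0))
        with pytest.raises(ConfigurationError):
            pp.build_permutation_set(visits, K=0, seed=0)

    def test_apply_preserves_times_and_multiset_of_rows(self,
                                                        small_null_cohort):
        visits = cohort_visits(small_null_cohort)
        pset = pp.build_permutation_set(visits, K=2, seed=1)
        packed = visits.pair_packed(("B0", "B1"))
        shuf = apply_permutation(packed, pset, 0)
        np.testing.assert_array_equal(shuf.times, packed.times)
        for s, e in zip(packed.starts, packed.ends):
            a = np.sort(packed.y[s:e], axis=0)
            b = np.sort(shuf.y[s:e], axis=0)
            np.testing.assert_array_equal(np.nan_to_num(a, nan=9e9),
                                          np.nan_to_num(b, nan=9e9))

    def test_shuffling_preserves_contemporaneous_pairing(self,
                                                         small_null_cohort):
        """Whole visit vectors move together: cross-biomarker pairing at one
        visit is invariant under the shuffle."""
        visits = cohort_visits(small_null_cohort)
        pset = pp.build_permutation_set(visits, K=1, seed=4)
        packed = visits.pair_packed(("B0", "B1"))
        shuf = apply_permutation(packed, pset, 0)
        orig = {tuple(np.round(r, 9)) for r in packed.y if not
                np.isnan(r).any()}
        new = {tuple(np.round(r, 9)) for r in shuf.y if not
               np.isnan(r).any()}
        assert orig == new


class TestZscorePvalue:
    def test_reference_normal_quantile(self):
        rng = np.random.default_rng(0)
        nulls = rng.standard_normal(200_000)
        mu, sd = nulls.mean(), nulls.std(ddof=1)
        z0, p0, logp0 = pp.zscore_pvalue(mu + 1.959964 * sd, nulls)
        assert z0 == pytest.approx(1.959964, abs=1e-9)
        assert p0 == pytest.approx(0.05, abs=1e-4)
        assert logp0 == pytest.approx(np.log(p0), rel=1e-12)

    def test_extreme_z_stays_finite_in_log_space(self):
        nulls = np.concatenate([np.zeros(5), np.ones(5)])  # mean .5, sd ~.527
        z0, p0, logp0 = pp.zscore_pvalue(0.5 + 10 * nulls.std(ddof=1), nulls)
        assert z0 == pytest.approx(10.0, abs=1e-9)
        assert p0 == 0.0 or p0 < 1e-22
        assert logp0 == pytest.approx(-52.53, abs=0.01)

    def test_observed_at_null_mean_gives_p_one(self):
        nulls = np.arange(20.0)
        _, p0, logp0 = pp.zscore_pvalue(nulls.mean(), nulls)
        assert p0 == 1.0 and logp0 == 0.0

    def test_guards(self):
        with pytest.raises(DegenerateInputError):
            pp.zscore_pvalue(0.0, np.arange(5.0))
        with pytest.raises(NumericalError):
            pp.zscore_pvalue(0.0, np.full(10, 3.0))

    def test_nan_trials_are_ignored(self):
        nulls = np.concatenate([np.arange(12.0), [np.nan, np.nan]])
        z_full = pp.zscore_pvalue(3.0, np.arange(12.0))
        z_nan = pp.zscore_pvalue(3.0, nulls)
        assert z_full == z_nan


class TestBonferroni:
    @pytest.mark.parametrize("p0,J,expect", [
        (0.001, 10, 0.01),
        (0.2, 10, 1.0),
        (1e-5, 1806, 1806e-5),   # directed terms on a 43-biomarker panel
        (1e-5, 903, 903e-5),     # covariance terms
    ])
    def test_examples(self, p0, J, expect):
        assert pp.adjust_bonferroni(p0, J) == pytest.approx(expect)

    def test_log_form_matches(self):
        lp = log_bonferroni(np.log(1e-5), 1806)
        assert lp == pytest.approx(np.log(1806e-5), rel=1e-12)
        assert log_bonferroni(np.log(0.2), 10) == 0.0

    def test_bad_J_rejected(self):
        with pytest.raises(ConfigurationError):
            pp.adjust_bonferroni(0.01, 0)


class TestHolmEmpirical:
    def test_single_hypothesis_is_smoothed_tail_fraction(self):
        z_null = np.array([[0.1, 0.5, 1.5, 2.5, -3.0]])
        out = pp.adjust_holm_empirical([2.0], z_null)
        # trials with |z| >= 2.0: {2.5, -3.0} -> (1+2)/(5+1)
        assert out[0] == pytest.approx(3.0 / 6.0)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(8)
        z_null = rng.standard_normal((6, 400))
        z_obs = np.array([3.0, 0.2, 1.4, -2.2, 0.7, -0.1])
        out = pp.adjust_holm_empirical(z_obs, z_null)
        order = np.argsort(-np.abs(z_obs))
        assert np.all(np.diff(out[order]) >= 0)
        assert np.all((out > 0) & (out <= 1))

    def test_uniform_under_exchangeable_null(self):
        """Adjusted p of the top hypothesis is super-uniform under the null."""
        rng = np.random.default_rng(13)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            z = rng.standard_normal((5, 60))
            out = pp.adjust_holm_empirical(z[:, 0], z[:, 1:])
            hits += out.min() <= 0.05
        assert hits / n_rep <= 0.09

    def test_invariant_to_duplicated_hypothesis(self):
        rng = np.random.default_rng(4)
        z_null = rng.standard_normal((3, 200))
        z_obs = np.array([2.0, -1.0, 0.5])
        base = pp.adjust_holm_empirical(z_obs, z_null)
        dup = pp.adjust_holm_empirical(np.append(z_obs, z_obs[0]),
                                       np.vstack([z_null, z_null[0]]))
        # duplicating the leading hypothesis cannot change its adjusted p
        assert dup[0] == pytest.approx(base[0])

    def test_misaligned_matrix_rejected(self):
        with pytest.raises(ConfigurationError):
            pp.adjust_holm_empirical([1.0, 2.0], np.zeros((3, 10)))


class TestEnsembleAndExport:
    def test_ensemble_bookkeeping(self, small_null_cohort):
        visits = cohort_visits(small_null_cohort)
        pset = pp.build_permutation_set(visits, K=10, seed=2)
        packed = visits.pair_packed(("B0", "B1"))
        ens = pp.estimate_null_ensemble(packed, pset, pp.FitConfig(
            max_iters=30))
        assert ens.nulls.shape == (10, 12)
        assert ens.observed.shape == (12,)
        assert ens.effective_K == ens.ok.sum() >= 9
        assert np.isfinite(ens.nulls[ens.ok]).all()

    def test_signed_logp_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        names = ["Iron", "MCH", "HGB"]
        sign = pd.DataFrame(np.sign(rng.standard_normal((3, 3))),
                            index=names, columns=names)
        logp = pd.DataFrame(-np.abs(rng.standard_normal((3, 3))) * 30,
                            index=names, columns=names)
        frame = pp.signed_logp_frame(sign, logp)
        path = tmp_path / "signed.csv"
        pp.write_signed_logp(frame, path,
                             {"seed": 7, "K": 64, "age_window": [0.0, 200.0]})
        text = path.read_text()
        assert text.startswith("#")
        assert "seed=7" in text and "K=64" in text
        back = pp.read_signed_logp(path)
        assert list(back.index) == names and list(back.columns) == names
        np.testing.assert_allclose(back.to_numpy(), frame.to_numpy(),
                                   rtol=1e-14)

    def test_run_pair_analysis_layout(self, small_null_cohort):
        _, _, pre = small_null_cohort
        res = pp.run_pair_analysis(pre.normalized, K=12, seed=5,
                                   pairs=[("B0", "B1"), ("B2", "B4")],
                                   cfg=pp.FitConfig(max_iters=40))
        assert res.biomarkers == [f"B{i}" for i in range(6)]
        # directed matrix filled in both orientations for requested pairs
        for (v, w) in (("B0", "B1"), ("B2", "B4")):
            assert np.isfinite(res.A_est.loc[v, w])
            assert np.isfinite(res.A_est.loc[w, v])
            assert res.Q_est.loc[v, w] == res.Q_est.loc[w, v]
            assert 0 < res.A_ph.loc[v, w] <= 1
        # unrequested entries stay NaN; diagonal always NaN
        assert np.isnan(res.A_est.loc["B0", "B2"])
        assert np.isnan(np.diag(res.A_est)).all()
        assert res.fingerprint == {"seed": 5, "K": 12,
                                   "age_window": [0.0, 200.0]}
        # signs match estimates
        s = np.sign(res.A_est.loc["B0", "B1"])
        assert res.A_sign.loc["B0", "B1"] == s
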