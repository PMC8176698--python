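import datetime

import numpy as np
import pytest

from brackish.otu_table import OtuTable, SampleMetadata
from brackish.diversity import (
    DistanceMatrix,
    alpha_diversity,
    anosim,
    bray_curtis,
    mantel,
    mantel_exact,
    multi_nutrient_cycling_index,
    partial_mantel,
    time_lag_analysis,
)


def _dm(seed, n, ids=None):
    rng = np.random.default_rng(seed)
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return DistanceMatrix(ids or tuple(str(i) for i in range(n)), m)


class TestAlphaDiversity:
    def test_uniform_sample_closed_forms(self):
        t = OtuTable(("s",), tuple(f"o{i}" for i in range(10)),
                     np.full((1, 10), 17))
        a = alpha_diversity(t)[0]
        assert a.richness == 10
        assert a.shannon == pytest.approx(np.log(10), abs=1e-9)
        assert a.pielou == pytest.approx(1.0, abs=1e-9)
        assert a.simpson == pytest.approx(0.9, abs=1e-9)

    def test_chao1_singleton_doubleton_formula(self):
        # S_obs=5, F1=2, F2=1 -> Chao1 = 5 + 2^2/(2*1) = 7
        t = OtuTable(("s",), tuple("abcde"), np.array([[1, 1, 2, 5, 9]]))
        a = alpha_diversity(t)[0]
        assert a.chao1 == pytest.approx(7.0)

    def test_single_otu_sample(self):
        t = OtuTable(("s",), ("a", "b"), np.array([[9, 0]]))
        a = alpha_diversity(t)[0]
        assert a.shannon == pytest.approx(0.0)
        assert a.simpson == pytest.approx(0.0)

    def test_estimators_bounded_below_by_richness(self, neutral_table):
        for a in alpha_diversity(neutral_table):
            assert a.chao1 >= a.richness - 1e-9
            assert a.ace >= a.richness - 1e-9

    def test_empty_sample_flagged(self):
        t = OtuTable(("s1", "s2"), ("a",), np.array([[0], [3]]))
        a = alpha_diversity(t)
        assert a[0].richness == 0 and np.isnan(a[0].shannon)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = OtuTable(("x", "y", "z"), ("a", "b"),
                     np.array([[3, 3], [3, 3], [0, 9]]))
        d = bray_curtis(t)
        assert d.d[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports(self):
        t = OtuTable(("x", "y"), ("a", "b"), np.array([[5, 0], [0, 7]]))
        assert bray_curtis(t).d[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        t = OtuTable(("x", "y"), ("a", "b"), np.array([[2, 0], [1, 1]]))
        # relative: (1,0) vs (0.5,0.5) -> (0.5+0.5)/2 = 0.5
        assert bray_curtis(t).d[0, 1] == pytest.approx(0.5)

    def test_all_zero_sample_rejected(self):
        t = OtuTable(("x", "y"), ("a",), np.array([[0], [3]]))
        with pytest.raises(ValueError):
            bray_curtis(t)


class TestAnosim:
    def _clustered(self, seed=0, n=20):
        rng = np.random.default_rng(seed)
        x = rng.random((n, 40))
        x[: n // 2, :20] += 3.0  # the two groups favour disjoint OTU blocks
        x[n // 2:, 20:] += 3.0
        t = OtuTable(tuple(f"s{i}" for i in range(n)),
                     tuple(f"o{j}" for j in range(40)),
                     (x * 50).astype(int))
        return bray_curtis(t), ["a"] * (n // 2) + ["b"] * (n - n // 2)

    def test_separated_clusters_high_r(self):
        d, groups = self._clustered()
        res = anosim(d, groups, n_perm=199, seed=1)
        assert res.statistic > 0.9
        assert res.p_value <= 0.05

    def test_matches_reference_implementation(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import anosim as sk_anosim

        d, groups = self._clustered(seed=5)
        mine = anosim(d, groups, n_perm=99, seed=2).statistic
        ref = sk_anosim(SkDM(d.d, d.ids), groups, permutations=99)["test statistic"]
        assert mine == pytest.approx(float(ref), abs=1e-12)

    def test_random_labels_small_r(self):
        rng = np.random.default_rng(3)
        rs = []
        for rep in range(20):
            d = _dm(rep, 40)
            groups = list(rng.permutation(["a"] * 20 + ["b"] * 20))
            rs.append(anosim(d, groups, n_perm=49, seed=rep).statistic)
        assert np.mean(np.abs(rs)) < 0.1

    def test_label_name_symmetry(self):
        d, groups = self._clustered(seed=7)
        swapped = ["b" if g == "a" else "a" for g in groups]
        a = anosim(d, groups, n_perm=99, seed=4).statistic
        b = anosim(d, swapped, n_perm=99, seed=4).statistic
        assert a == pytest.approx(b)

    def test_singleton_group_rejected(self):
        d = _dm(1, 5)
        with pytest.raises(ValueError):
            anosim(d, ["a", "a", "a", "a", "b"])


class TestMantel:
    def test_self_correlation_is_one(self):
        d = _dm(1, 10)
        res = mantel(d, d, n_perm=99, seed=1)
        assert res.statistic == pytest.approx(1.0)

    def test_affine_invariance(self):
        d = _dm(2, 10)
        d2 = DistanceMatrix(d.ids, 3.0 * d.d + 0.0)
        assert mantel(d, d2, n_perm=99, seed=1).statistic == pytest.approx(1.0)

    def test_matches_reference_statistic(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel

        dA, dB = _dm(3, 12), _dm(4, 12)
        mine = mantel(dA, dB, "spearman", n_perm=99, seed=1).statistic
        ref, _, _ = sk_mantel(SkDM(dA.d, dA.ids), SkDM(dB.d, dB.ids),
                              method="spearman", permutations=0)
        assert mine == pytest.approx(float(ref), abs=1e-12)

    def test_id_mismatch_rejected(self):
        dA = _dm(1, 5)
        dB = _dm(2, 5, ids=tuple("vwxyz"))
        with pytest.raises(ValueError):
            mantel(dA, dB)

    def test_p_floor_respected(self):
        dA = _dm(5, 8)
        res = mantel(dA, dA, n_perm=99, seed=2)
        assert res.p_value >= 1 / 100

    def test_exact_enumeration_close_to_sampled(self):
        dA = _dm(6, 6)
        noise = _dm(7, 6)
        dB = DistanceMatrix(dA.ids, 0.7 * dA.d + 0.3 * noise.d)
        pe = mantel_exact(dA, dB).p_value
        ps = mantel(dA, dB, n_perm=4999, seed=3).p_value
        assert abs(pe - ps) < 0.02


class TestPartialMantel:
    def test_uncorrelated_control_changes_little(self):
        dA, dB, dC = _dm(10, 15), _dm(11, 15), _dm(12, 15)
        dB = DistanceMatrix(dA.ids, 0.6 * dA.d + 0.4 * dB.d)
        plain = mantel(dA, dB, n_perm=99, seed=1).statistic
        part = partial_mantel(dA, dB, dC, n_perm=99, seed=1).statistic
        assert abs(plain - part) < 0.05

    def test_confounded_relationship_vanishes(self):
        dA, dC, noise = _dm(13, 15), _dm(14, 15), _dm(15, 15)
        dA = DistanceMatrix(dC.ids, 0.8 * dC.d + 0.2 * dA.d)
        # B driven almost entirely by C: controlling for C removes the A-B link
        dB = DistanceMatrix(dC.ids, 0.98 * dC.d + 0.02 * noise.d)
        plain = mantel(dA, dB, n_perm=99, seed=1).statistic
        part = partial_mantel(dA, dB, dC, n_perm=99, seed=1)
        assert plain > 0.5
        assert abs(part.statistic) < 0.1


class TestTimeLag:
    def _d(self, n):
        return _dm(20, n)

    def test_annual_wrap_january_december(self):
        d = self._d(2)
        frame, _ = time_lag_analysis(
            d, [datetime.date(2016, 1, 15), datetime.date(2016, 12, 15)], "annual")
        assert frame["lag"].iloc[0] == pytest.approx(1.0, abs=0.1)

    def test_annual_max_separation(self):
        d = self._d(2)
        frame, _ = time_lag_analysis(
            d, [datetime.date(2016, 1, 15), datetime.date(2016, 7, 15)], "annual")
        assert frame["lag"].iloc[0] == pytest.approx(6.0, abs=0.1)

    def test_identical_dates_zero_lag(self):
        d = self._d(2)
        frame, _ = time_lag_analysis(
            d, [datetime.date(2016, 3, 1)] * 2, "absolute")
        assert frame["lag"].iloc[0] == 0.0

    def test_monotone_drift_positive_rho(self):
        n = 12
        pos = np.arange(n, dtype=float)
        dmat = np.abs(pos[:, None] - pos[None, :]) / n
        d = DistanceMatrix(tuple(str(i) for i in range(n)), dmat)
        dates = [datetime.date(2016, 1, 1) + datetime.timedelta(days=7 * i)
                 for i in range(n)]
        _, rho = time_lag_analysis(d, dates, "absolute")
        assert rho == pytest.approx(1.0)


class TestMultiNutrientIndex:
    def _meta(self, tc, tn):
        return [SampleMetadata(f"s{i}", env={"TC": c, "TN": n})
                for i, (c, n) in enumerate(zip(tc, tn))]

    def test_mean_sample_scores_zero(self):
        idx = multi_nutrient_cycling_index(
            self._meta([1, 2, 3], [10, 20, 30]), ["TC", "TN"])
        assert idx.iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_dominant_sample_is_largest(self):
        idx = multi_nutrient_cycling_index(
            self._meta([1, 2, 9], [10, 20, 90]), ["TC", "TN"])
        assert idx.idxmax() == "s2"

    def test_unit_invariance(self):
        a = multi_nutrient_cycling_index(
            self._meta([1, 2, 3], [10, 20, 30]), ["TC", "TN"])
        b = multi_nutrient_cycling_index(
            self._meta([2, 4, 6], [20, 40, 60]), ["TC", "TN"])
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_constant_variable_excluded(self):
        meta = [SampleMetadata(f"s{i}", env={"TC": 5.0, "TN": t, "TP": p})
                for i, (t, p) in enumerate(zip([1, 2, 3], [4, 5, 6]))]
        with pytest.warns(UserWarning, match="constant"):
            idx = multi_nutrient_cycling_index(meta, ["TC", "TN", "TP"])
        assert len(idx) == 3
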