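"""Genotype coding, single-marker regression, ANOVA, Duncan's MRT."""

import numpy as np
import pytest
from scipy import stats

from nilscan.association import (
    NotEstimableError,
    analyze_markers,
    anova_from_summary,
    code_genotypes,
    duncan_mrt,
    duncan_mrt_from_summary,
    load_marker_genotypes,
    load_phenotypes,
    one_way_anova,
    single_marker_r2,
)


class TestCoding:
    def test_additive_codes(self):
        assert code_genotypes({"c1": "hh", "c2": "ll", "c3": "hl"}) == {
            "c1": 2, "c2": 0, "c3": 1,
        }

    def test_failed_pcr_excluded(self):
        assert code_genotypes({"c1": "hh", "c2": "m"}) == {"c1": 2}

    def test_dominant_code_not_estimable(self):
        with pytest.raises(NotEstimableError, match="c2"):
            code_genotypes({"c1": "hh", "c2": "d"})

    def test_unknown_code_names_cultivar_and_marker(self):
        with pytest.raises(ValueError, match="c9.*M7"):
            code_genotypes({"c9": "xx"}, marker="M7")


class TestSingleMarkerR2:
    def test_perfectly_linear_trait_gives_r2_one(self):
        res = single_marker_r2([0, 1, 2, 0, 1, 2], [10, 20, 30, 10, 20, 30])
        assert res.r2 == pytest.approx(1.0)

    def test_constant_genotype_not_estimable(self):
        res = single_marker_r2([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.status == "NOT_ESTIMABLE"

    def test_affine_rescaling_of_trait_preserves_r2(self):
        rng = np.random.default_rng(21)
        x = rng.integers(0, 3, 30).astype(float)
        y = 5 * x + rng.normal(0, 2, 30)
        r1 = single_marker_r2(x, y).r2
        r2 = single_marker_r2(x, 3.7 * y - 100).r2
        assert r1 == pytest.approx(r2)

    def test_flipping_coding_direction_preserves_r2(self):
        rng = np.random.default_rng(22)
        x = rng.integers(0, 3, 30).astype(float)
        y = 5 * x + rng.normal(0, 2, 30)
        assert single_marker_r2(x, y).r2 == pytest.approx(
            single_marker_r2(2 - x, y).r2
        )

    def test_two_class_r2_equals_squared_point_biserial(self):
        rng = np.random.default_rng(23)
        x = np.repeat([0.0, 2.0], [12, 8])
        y = np.where(x > 0, 30, 10) + rng.normal(0, 4, 20)
        r2 = single_marker_r2(x, y).r2
        r_pb = stats.pointbiserialr((x > 0).astype(int), y).correlation
        assert r2 == pytest.approx(r_pb**2)


@pytest.fixture(scope="module")
def results():
    return analyze_markers(load_phenotypes(), load_marker_genotypes())


class TestTableReproduction:

    def test_strongest_marker_r2(self, results):
        row = results.set_index("marker").loc["CIR6-M1"]
        assert row["r2"] == pytest.approx(0.722, abs=0.005)
        assert row["n"] == 20

    def test_weakest_marker_r2(self, results):
        row = results.set_index("marker").loc["CIR9-M8"]
        assert row["r2"] == pytest.approx(0.149, abs=0.005)

    def test_dominant_markers_not_estimable(self, results):
        by = results.set_index("marker")
        for marker in ("CIR10-M3", "CIR10-M4"):
            assert by.loc[marker, "status"] == "NOT_ESTIMABLE"
            assert np.isnan(by.loc[marker, "r2"]) or by.loc[marker, "r2"] is None

    def test_failed_pcr_reduces_n(self, results):
        assert results.set_index("marker").loc["CIR9-M2", "n"] == 19


class TestAnova:
    def test_identical_group_means_give_f_near_zero(self):
        groups = {"a": [10, 11, 9], "b": [10.0, 9.0, 11.0], "c": [9.5, 10.5, 10.0]}
        f, p = one_way_anova(groups)
        assert f < 0.1 and p > 0.9

    def test_two_group_f_equals_squared_t(self):
        a = [12.1, 13.4, 11.8, 12.9]
        b = [15.2, 16.1, 14.8, 15.5]
        f, p_f = one_way_anova({"a": a, "b": b})
        t, p_t = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_fixed_table_matches_hand_decomposition(self):
        """3x5 table checked against explicitly expanded sums of squares."""
        groups = {
            "g1": [12.0, 14.0, 11.0, 13.0, 15.0],
            "g2": [22.0, 20.0, 23.0, 21.0, 24.0],
            "g3": [17.0, 16.0, 18.0, 19.0, 15.0],
        }
        vals = np.concatenate(list(groups.values()))
        grand = vals.mean()
        ss_b = sum(5 * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_w = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        f_expected = (ss_b / 2) / (ss_w / 12)
        f, p = one_way_anova(groups)
        assert f == pytest.approx(f_expected)
        assert p == pytest.approx(float(stats.f.sf(f_expected, 2, 12)))

    def test_summary_anova_equals_replicate_anova(self):
        rng = np.random.default_rng(24)
        groups = {k: rng.normal(10 + 3 * i, 2, 5) for i, k in enumerate("abcd")}
        f1, p1 = one_way_anova(groups)
        f2, p2 = anova_from_summary(
            [v.mean() for v in groups.values()],
            [v.std(ddof=1) for v in groups.values()],
            [5] * 4,
        )
        assert f1 == pytest.approx(f2)
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            one_way_anova({"a": [1, 2], "b": []})


_ORACLE_Q: dict = {}


def duncan_oracle(means, sds, ns, alpha=0.05):
    """Exhaustive pairwise Duncan comparisons with the containment rule.

    Two groups are non-significantly different iff some ranked span
    enclosing both has a mean range below its least significant range.
    """
    labels = list(means)
    order = sorted(labels, key=lambda l: means[l], reverse=True)
    k = len(order)
    n_arr = np.array([ns[l] for l in order], float)
    df_e = int(n_arr.sum()) - k
    mse = np.sum((n_arr - 1) * np.array([sds[l] for l in order]) ** 2) / df_e
    n_h = k / np.sum(1.0 / n_arr)
    m = np.array([means[l] for l in order])
    def lsr(span):
        key = (alpha, span, df_e)
        if key not in _ORACLE_Q:
            a_r = 1 - (1 - alpha) ** (span - 1)
            _ORACLE_Q[key] = stats.studentized_range.ppf(1 - a_r, span, df_e)
        return _ORACLE_Q[key] * np.sqrt(mse / n_h)
    nonsig = {}
    for i in range(k):
        for j in range(i + 1, k):
            nonsig[(order[i], order[j])] = any(
                m[a] - m[b] <= lsr(b - a + 1)
                for a in range(0, i + 1)
                for b in range(j, k)
            )
    return order, nonsig


class TestDuncan:
    def test_identical_groups_share_one_letter(self):
        groups = {k: [10.0, 10.0, 10.0] for k in "abc"}
        # zero MSE: add tiny jitter to keep the ranges defined
        groups = {k: [9.9, 10.0, 10.1] for k in "abc"}
        letters = duncan_mrt(groups)
        assert set(letters.values()) == {"a"}

    def test_widely_separated_groups_get_distinct_letters(self):
        groups = {"low": [1.0, 1.1, 0.9], "high": [100.0, 99.8, 100.2]}
        letters = duncan_mrt(groups)
        assert letters["low"] == "a" and letters["high"] == "b"

    def test_letters_match_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(25)
        for trial in range(50):
            means = {f"g{i}": float(rng.uniform(0, 20)) for i in range(4)}
            sds = {k: float(rng.uniform(0.5, 4.0)) for k in means}
            ns = {k: 5 for k in means}
            letters = duncan_mrt_from_summary(means, sds, ns)
            order, nonsig = duncan_oracle(means, sds, ns)
            for i, a in enumerate(order):
                for b in order[i + 1 :]:
                    share = bool(set(letters[a]) & set(letters[b]))
                    assert share == nonsig[(a, b)], (
                        f"trial {trial}: {a} vs {b}: letters {letters}, "
                        f"oracle {nonsig[(a, b)]}"
                    )

    def test_transitive_letter_consistency_on_trait_table(self):
        """If two cultivars share a letter, every cultivar with an
        intermediate mean shares it too."""
        pheno = load_phenotypes()
        means = dict(zip(pheno["cultivar"], pheno["mean"]))
        sds = dict(zip(pheno["cultivar"], pheno["sd"]))
        ns = dict(zip(pheno["cultivar"], pheno["n"]))
        letters = duncan_mrt_from_summary(means, sds, ns)
        order = sorted(means, key=means.get)
        for ch in set("".join(letters.values())):
            idx = [i for i, c in enumerate(order) if ch in letters[c]]
            assert idx == list(range(min(idx), max(idx) + 1))

    def test_unbalanced_groups_warn_and_use_harmonic_n(self, caplog):
        groups = {"a": [1.0, 2.0, 3.0], "b": [10.0, 11.0], "c": [20.0, 21.0, 19.0]}
        with caplog.at_level("WARNING"):
            letters = duncan_mrt(groups)
        assert "harmonic" in caplog.text
        assert len(set(letters.values())) == 3
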