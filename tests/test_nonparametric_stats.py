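import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from napscope import (
    StudyTable,
    bonferroni,
    condition_comparison,
    friedman,
    kendalls_w,
    spearman,
    wilcoxon_signed_rank,
)
from napscope.errors import DegenerateDataError, DesignError, DomainError
from napscope.nonparametric_stats import CONDITIONS
from napscope.pose_topology import ANGLE_ORDER


# --- independent oracles -----------------------------------------------------

def naive_ranks(row):
    """Average ranks by naive sorting, written independently of scipy."""
    order = sorted(range(len(row)), key=lambda i: row[i])
    ranks = [0.0] * len(row)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and row[order[j + 1]] == row[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def friedman_oracle(matrix):
    n, k = len(matrix), len(matrix[0])
    sums = [0.0] * k
    for row in matrix:
        for j, r in enumerate(naive_ranks(row)):
            sums[j] += r
    return 12.0 / (n * k * (k + 1)) * sum(s * s for s in sums) - 3.0 * n * (k + 1)


def wilcoxon_exact_oracle(diffs, alternative):
    """Tail probability of W+ by brute-force enumeration of sign assignments."""
    d = [x for x in diffs if x != 0]
    ranks = naive_ranks([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    n = len(d)
    ge = le = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    total = 2 ** n
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2.0 * min(ge, le) / total)


# --- friedman ----------------------------------------------------------------

class TestFriedman:
    def test_perfect_concordance_3x3(self):
        res = friedman([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.chi2 == pytest.approx(6.0)
        assert res.W == pytest.approx(1.0)
        assert res.df == 2

    def test_all_tied_rows_give_zero_not_error(self):
        res = friedman([[5, 5, 5]] * 4)
        assert res.chi2 == 0.0
        assert res.W == 0.0
        assert res.p == pytest.approx(1.0)

    def test_matches_bruteforce_oracle_on_seeded_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = rng.normal(size=(6, 4))
            res = friedman(m)
            assert res.chi2 == pytest.approx(friedman_oracle(m.tolist()), abs=1e-9)
            assert res.W == pytest.approx(res.chi2 / (6 * 3), abs=1e-12)

    def test_handles_ties_with_average_ranks(self):
        m = [[1, 1, 2], [3, 2, 2], [1, 2, 3], [2, 2, 2]]
        assert friedman(m).chi2 == pytest.approx(friedman_oracle(m), abs=1e-12)

    def test_agrees_with_scipy_on_untied_data(self):
        rng = np.random.default_rng(7)
        m = rng.normal(size=(8, 3))
        res = friedman(m)  # without ties the tie-corrected statistic coincides
        ref = scipy.stats.friedmanchisquare(*[m[:, j] for j in range(3)])
        assert res.chi2 == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_tie_corrected_variant_inflates_statistic_under_ties(self):
        m = [[1, 1, 2], [3, 2, 2], [1, 2, 3], [2, 1, 1]]
        assert friedman(m, tie_correction=True).chi2 > friedman(m).chi2

    def test_rejects_missing_cells_and_tiny_designs(self):
        with pytest.raises(DesignError):
            friedman([[1.0, np.nan, 2.0], [1, 2, 3]])
        with pytest.raises(DesignError):
            friedman([[1, 2, 3]])

    @given(seed=st.integers(0, 1000), scale=st.floats(0.1, 10))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_invariant_to_monotone_transforms_within_blocks(self, seed, scale):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(5, 4))
        res = friedman(m)
        transformed = np.exp(scale * m)  # strictly increasing
        assert friedman(transformed).chi2 == pytest.approx(res.chi2, abs=1e-9)

    def test_w_identity_holds_for_every_result(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n, k = int(rng.integers(2, 12)), int(rng.integers(2, 8))
            res = friedman(rng.normal(size=(n, k)))
            assert res.W == pytest.approx(res.chi2 / (n * (k - 1)), abs=1e-12)
            assert 0.0 <= res.W <= 1.0 + 1e-12


class TestKendallsW:
    @pytest.mark.parametrize(
        "chi2,n,k,expected",
        [
            (42.518, 10, 12, 0.387),
            (0.6, 10, 3, 0.03),
            (0.0, 10, 3, 0.0),
        ],
    )
    def test_reported_chi2_w_pairs(self, chi2, n, k, expected):
        assert round(kendalls_w(chi2, n, k), 3) == pytest.approx(expected)

    def test_rejects_invalid_domain(self):
        with pytest.raises(DomainError):
            kendalls_w(-1.0, 10, 3)
        with pytest.raises(DomainError):
            kendalls_w(1.0, 0, 3)
        with pytest.raises(DomainError):
            kendalls_w(1.0, 10, 1)


# --- wilcoxon ----------------------------------------------------------------

class TestWilcoxon:
    def test_all_positive_differences_small_n(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], alternative="greater")
        assert res.w_plus == 15.0
        assert res.p == pytest.approx(0.03125)
        assert res.method == "exact"

    def test_sign_flip_symmetry(self):
        d = [1.5, -2.0, 3.0, 4.5, -0.5, 2.2]
        a = wilcoxon_signed_rank(d)
        b = wilcoxon_signed_rank([-x for x in d])
        assert a.z == pytest.approx(-b.z)
        assert a.r == pytest.approx(b.r)
        assert a.p == pytest.approx(b.p)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(4, 11))
            d = np.round(rng.normal(size=n), 1)
            d = d[d != 0]
            if d.size < 2:
                continue
            for alt in ("two-sided", "greater", "less"):
                res = wilcoxon_signed_rank(d, alternative=alt)
                assert res.method == "exact"
                assert res.p == pytest.approx(wilcoxon_exact_oracle(d.tolist(), alt), abs=1e-12)

    def test_agrees_with_scipy_exact_on_clean_data(self):
        rng = np.random.default_rng(5)
        d = rng.normal(size=10)
        res = wilcoxon_signed_rank(d)
        ref = scipy.stats.wilcoxon(d, method="exact")
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_matches_step_by_step_oracle(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "normal"
        d = x - y
        d = d[d != 0]
        n = d.size
        ranks = np.array(naive_ranks(np.abs(d).tolist()))
        w_plus = ranks[d > 0].sum()
        mean = n * (n + 1) / 4
        var = n * (n + 1) * (2 * n + 1) / 24
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        assert res.z == pytest.approx(z, abs=1e-9)
        assert res.r == pytest.approx(abs(z) / math.sqrt(n), abs=1e-9)

    def test_exact_and_normal_p_close_at_n_12(self):
        rng = np.random.default_rng(17)
        gaps = []
        for _ in range(100):
            d = rng.normal(0.3, 1.0, size=12)
            d = d[d != 0]
            pe = wilcoxon_signed_rank(d, method="exact").p
            pn = wilcoxon_signed_rank(d, method="normal").p
            gaps.append(abs(pe - pn))
        # the continuity-corrected normal approximation tracks the exact
        # distribution closely at n = 12; mid-range p-values can still be
        # off by slightly over 0.01
        assert np.mean(gaps) < 0.01
        assert max(gaps) < 0.02

    def test_effect_size_uses_effective_n(self):
        d = [0.0, 0.0, 1.0, 2.0, -3.0, 4.0, 5.0]
        res = wilcoxon_signed_rank(d)
        assert res.n_effective == 5
        assert res.r == pytest.approx(abs(res.z) / math.sqrt(5))

    def test_all_zero_differences_raise(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])


# --- spearman ----------------------------------------------------------------

class TestSpearman:
    def test_perfect_monotone_relations(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 8, 16, 32]).rho == pytest.approx(1.0)
        assert spearman(x, [5, 4, 3, 1, 0]).rho == pytest.approx(-1.0)
        assert spearman(x, [2, 4, 8, 16, 32]).p == pytest.approx(0.0, abs=1e-12)

    def test_matches_rank_then_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            x = np.round(rng.normal(size=12), 1)  # rounding induces ties
            y = np.round(x + rng.normal(size=12), 1)
            try:
                res = spearman(x, y)
            except DegenerateDataError:
                continue
            rx = np.array(naive_ranks(x.tolist()))
            ry = np.array(naive_ranks(y.tolist()))
            rho_oracle = np.corrcoef(rx, ry)[0, 1]
            assert res.rho == pytest.approx(rho_oracle, abs=1e-12)
            ref = scipy.stats.spearmanr(x, y)
            assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateDataError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


# --- bonferroni --------------------------------------------------------------

class TestBonferroni:
    def test_scales_and_caps(self):
        assert bonferroni([0.01]) == [0.01]
        assert bonferroni([0.01], m=5) == [pytest.approx(0.05)]
        assert bonferroni([0.4], m=5) == [1.0]

    def test_order_preserved_and_never_decreases(self):
        ps = [0.04, 0.001, 0.2]
        adj = bonferroni(ps)
        assert all(a >= p for a, p in zip(adj, ps))
        assert adj == [min(1, 3 * p) for p in ps]

    def test_rejects_out_of_range(self):
        with pytest.raises(DomainError):
            bonferroni([1.2])


# --- full design -------------------------------------------------------------

def make_null_study(seed=0, n_subjects=10):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for c in CONDITIONS:
            for a in ANGLE_ORDER:
                rows.append(
                    {
                        "subject": f"S{s:02d}", "condition": c, "angle": a.value,
                        "index": "n_changes", "value": rng.normal(5, 2),
                    }
                )
    weights = {f"S{s:02d}": float(rng.normal(75, 12)) for s in range(n_subjects)}
    return StudyTable(data=pd.DataFrame(rows), body_weight=weights)


class TestConditionComparison:
    def test_structural_degrees_of_freedom(self):
        report = condition_comparison(make_null_study(1))
        angle_sec = report.section("angle_omnibus")
        cond_sec = report.section("condition_omnibus")
        assert len(angle_sec) == 12 and (angle_sec["df"] == 2).all()
        assert len(cond_sec) == 3 and (cond_sec["df"] == 11).all()

    def test_incomplete_crossing_rejected(self):
        study = make_null_study(2)
        study.data = study.data.iloc[:-1]
        with pytest.raises(DesignError):
            condition_comparison(study)

    def test_effect_sizes_attached_to_significant_results_only(self):
        report = condition_comparison(make_null_study(3))
        t = report.tests
        assert t.loc[~t["significant"], "effect_size"].isna().all()
        sig_friedman = t[(t["test"] == "friedman") & t["significant"]]
        for _, row in sig_friedman.iterrows():
            assert row["effect_size"] == pytest.approx(
                row["statistic"] / (row["n"] * row["df"]), abs=1e-12
            )

    def test_injected_condition_effect_is_flagged_by_posthocs(self):
        # suppress the positive condition's index on the lower limbs
        study = make_null_study(4)
        lower = {"KR", "KL", "HR", "HL"}
        mask = (study.data["condition"] == "positive") & study.data["angle"].isin(lower)
        study.data.loc[mask, "value"] -= 6.0
        report = condition_comparison(study)
        post = report.section("posthoc")
        hits = post[post["significant"] & post["angle"].isin(lower)]
        assert not hits.empty
        # significant pairs involve the positive condition
        assert hits["comparison"].str.contains("positive").all()

    def test_weight_coupling_yields_negative_significant_correlations(self):
        rng = np.random.default_rng(6)
        study = make_null_study(5)
        weights = study.body_weight
        # re-generate values strongly anti-correlated with weight
        z = {s: (w - 75) / 12 for s, w in weights.items()}
        study.data["value"] = [
            10 - 4 * z[s] + rng.normal(0, 0.5) for s in study.data["subject"]
        ]
        report = condition_comparison(study)
        corr = report.section("correlation")
        assert (corr["statistic"] < 0).mean() > 0.9
        assert corr["significant"].mean() > 0.5

    def test_summary_mentions_every_scope(self):
        report = condition_comparison(make_null_study(8))
        text = report.summary()
        assert "Friedman across conditions" in text
        assert "Spearman" in text
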