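import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from clonecna import ValidationError
from clonecna.association_stats import (
    bh_adjust,
    chi_squared_test,
    cna_expression_screen,
    fisher_exact_two_sided,
    wilcoxon_rank_test,
)


def brute_force_rank_p(x, y, alternative):
    """Enumerate every assignment of the pooled values to the two groups and
    count assignments at least as extreme in U as the observed one."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    u_obs = sum((a > b) + 0.5 * (a == b) for a in x for b in y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in comb]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(sum((a > b) + 0.5 * (a == b) for a in g1 for b in g2))
    us = np.asarray(us)
    if alternative == "greater":
        return float(np.mean(us >= u_obs))
    return float(min(1.0, 2 * min(np.mean(us >= u_obs), np.mean(us <= u_obs))))


class TestWilcoxonRankTest:
    def test_fully_separated_small_groups(self):
        res = wilcoxon_rank_test([5, 6, 7], [1, 2, 3], "greater")
        assert res.statistic == 9 == res.n1 * res.n2
        assert res.p_value == pytest.approx(1 / math.comb(6, 3))
        assert res.method == "exact"

    def test_identical_groups_two_sided_p_is_one(self):
        res = wilcoxon_rank_test([1, 2, 3], [1, 2, 3], "two_sided")
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_test([], [1.0], "greater")

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        data=st.lists(st.integers(0, 10 ** 6), min_size=4, max_size=10, unique=True),
        split=st.integers(1, 9),
        alternative=st.sampled_from(["greater", "two_sided"]),
    )
    def test_exact_p_equals_enumeration(self, data, split, alternative):
        split = min(split, len(data) - 1)
        x, y = data[:split], data[split:]
        res = wilcoxon_rank_test(x, y, alternative)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_rank_p(x, y, alternative), rel=1e-9)

    def test_statistic_is_u_of_first_group(self, rng):
        x, y = rng.normal(1, 1, 30), rng.normal(0, 1, 25)
        res = wilcoxon_rank_test(x, y, "greater")
        u_direct = sum((a > b) + 0.5 * (a == b) for a in x for b in y)
        assert res.statistic == pytest.approx(u_direct)
        assert 0 <= res.statistic <= res.n1 * res.n2

    def test_normal_approx_matches_scipy_without_ties(self, rng):
        # orientation + tie-free sanity: large-sample p close to scipy's asymptotic
        x, y = rng.normal(0.5, 1, 40), rng.normal(0, 1, 35)
        res = wilcoxon_rank_test(x, y, "greater")
        ref = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert res.method == "normal_approx"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestChiSquared:
    TABLE = [[10, 20], [20, 10]]

    def test_pearson_matches_closed_form(self):
        # N(ad-bc)^2 / (r1 r2 c1 c2) = 60*(100-400)^2/810000
        res = chi_squared_test(self.TABLE, continuity=False)
        assert res.chi2 == pytest.approx(60 * (100 - 400) ** 2 / 810000)
        assert res.df == 1 and not res.continuity_corrected

    def test_yates_matches_closed_form(self):
        res = chi_squared_test(self.TABLE, continuity=True)
        assert res.chi2 == pytest.approx(60 * (abs(-300) - 30) ** 2 / 810000)  # 5.4
        assert res.continuity_corrected

    def test_identical_rows_give_zero(self):
        res = chi_squared_test([[5, 10], [5, 10]], continuity=False)
        assert res.chi2 == 0 and res.p_value == 1

    def test_no_correction_beyond_2x2(self):
        res = chi_squared_test([[10, 5, 3], [2, 8, 9]], continuity=True)
        assert res.df == 2 and not res.continuity_corrected
        plain = chi_squared_test([[10, 5, 3], [2, 8, 9]], continuity=False)
        assert res.chi2 == plain.chi2

    def test_invariant_under_permutation_and_scaling(self, rng):
        t = rng.integers(1, 30, (3, 4))
        base = chi_squared_test(t, continuity=False).chi2
        assert chi_squared_test(t[::-1, ::-1], continuity=False).chi2 == pytest.approx(base)
        assert chi_squared_test(t.T, continuity=False).chi2 == pytest.approx(base)
        assert chi_squared_test(3 * t, continuity=False).chi2 == pytest.approx(3 * base)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError, match="marginal"):
            chi_squared_test([[0, 0], [5, 5]])


class TestFisherExact:
    def test_diagonal_table_matches_enumeration(self):
        # margins (5,5;5,5): 6 tables, the two extremes each have prob 1/252
        assert fisher_exact_two_sided([[0, 5], [5, 0]]) == pytest.approx(2 / 252)

    def test_most_probable_table_gives_one(self):
        assert fisher_exact_two_sided([[1, 1], [1, 1]]) == 1.0

    def test_zero_margin_degenerate(self):
        assert fisher_exact_two_sided([[0, 0], [3, 4]]) == 1.0

    def test_hypergeometric_enumeration_oracle(self, rng):
        for _ in range(20):
            t = rng.integers(0, 8, (2, 2))
            r1, c1, n = t[0].sum(), t[:, 0].sum(), t.sum()
            if n == 0:
                continue
            probs = {a: stats.hypergeom.pmf(a, n, r1, c1)
                     for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1)}
            p_obs = probs[t[0, 0]]
            expected = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))
            assert fisher_exact_two_sided(t) == pytest.approx(expected, rel=1e-6)

    def test_symmetry(self, rng):
        t = rng.integers(0, 15, (2, 2))
        p = fisher_exact_two_sided(t)
        assert fisher_exact_two_sided(t.T) == pytest.approx(p)
        assert fisher_exact_two_sided(t[::-1]) == pytest.approx(p)
        assert fisher_exact_two_sided(t[:, ::-1]) == pytest.approx(p)

    def test_non_integer_rejected(self):
        with pytest.raises(ValidationError, match="integer"):
            fisher_exact_two_sided([[0.5, 1], [1, 1]])


class TestBenjaminiHochberg:
    def test_monotone_in_p_rank(self, rng):
        p = rng.uniform(0, 1, 50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all() and (q <= 1).all()


def _screen_frame(states, region_ids, gene="G1"):
    return pd.DataFrame({"region_id": region_ids, "gene": gene, "state": states})


class TestExpressionScreen:
    def _simulate(self, rng, n=60, beta=1.0, sigma=0.5, null=False):
        samples = [f"S{i}" for i in range(n)]
        gained = np.array([i < n // 2 for i in range(n)])
        lr = np.where(gained, math.log2(3 / 2), 0.0)
        log2tpm = math.log2(50) + beta * lr + rng.normal(0, sigma, n)
        if null:
            rng.shuffle(gained)
        calls = _screen_frame(np.where(gained, "gain", "neutral"), samples)
        expr = pd.DataFrame({"G1": 2.0 ** log2tpm}, index=pd.Index(samples, name="sample"))
        return calls, expr

    def test_planted_dosage_effect_detected(self, rng):
        """Dosage slope 1 log2-TPM per log2 CN ratio, sigma 0.5, n=60:
        the planted gene is flagged in >=95% of 100 replicates."""
        hits = sum(
            bool(cna_expression_screen(*self._simulate(rng))["significant"].iloc[0])
            for _ in range(100)
        )
        assert hits >= 95

    def test_permuted_labels_control_false_positives(self, rng):
        hits = sum(
            bool(cna_expression_screen(*self._simulate(rng, null=True))["significant"].iloc[0])
            for _ in range(100)
        )
        assert hits <= 5 + 5  # 5% nominal + MC slack at 100 replicates

    def test_all_gained_gene_reported_untested(self):
        calls = _screen_frame(["gain", "gain"], ["S1", "S2"])
        expr = pd.DataFrame({"G1": [1.0, 2.0]}, index=pd.Index(["S1", "S2"], name="sample"))
        out = cna_expression_screen(calls, expr)
        assert not out["tested"].iloc[0] and np.isnan(out["p"].iloc[0])

    def test_missing_calls_and_cells_are_excluded(self):
        calls = _screen_frame(["gain", "missing", "neutral", "gain"],
                              ["S1", "S2", "S3", "S4"])
        expr = pd.DataFrame({"G1": [5.0, 4.0, 1.0, np.nan]},
                            index=pd.Index(["S1", "S2", "S3", "S4"], name="sample"))
        out = cna_expression_screen(calls, expr)
        assert out["n_gain"].iloc[0] == 1 and out["n_nogain"].iloc[0] == 1
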