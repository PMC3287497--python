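"""The rank-statistics battery against closed forms and enumeration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import comb

from methmir.stats import (chi_square_2x2, fisher_exact_2x2, mann_whitney,
                           partial_spearman, per_tissue_correlation,
                           spearman)


def rank_pearson(x, y):
    """Independent midrank-Pearson oracle for Spearman's rho."""
    from scipy.stats import rankdata
    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_monotone_identity_and_reversal(self):
        assert spearman([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_matches_midrank_pearson_with_ties(self, rng):
        for _ in range(25):
            x = rng.integers(0, 8, size=20).astype(float)
            y = rng.integers(0, 8, size=20).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y).rho == pytest.approx(rank_pearson(x, y),
                                                       abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            spearman([1, 1, 1], [1, 2, 3])

    def test_ci_brackets_rho(self, rng):
        x = rng.normal(size=100)
        y = x + rng.normal(size=100)
        res = spearman(x, y)
        assert res.ci_low <= res.rho <= res.ci_high

    def test_missing_values_removed_pairwise(self):
        res = spearman([1, 2, 3, np.nan], [1, 2, 3, 100])
        assert res.n == 3

    @given(st.sampled_from([np.exp, np.cbrt,
                            lambda v: 3 * v + 7]))
    def test_invariant_under_monotone_transforms(self, f):
        x = np.linspace(-2, 2, 30)
        y = np.sin(x) + 0.3 * x
        assert spearman(f(x), y).rho == pytest.approx(spearman(x, y).rho)


class TestPartialSpearman:
    def test_independent_covariate_leaves_rho(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        raw = spearman(x, y).rho
        part = partial_spearman(x, y, z).rho
        assert part == pytest.approx(raw, abs=0.03)

    def test_degenerate_conditioning_raises(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        with pytest.raises(ValueError, match="degenerate conditioning"):
            partial_spearman(x, [2, 1, 4, 3, 5], x)

    def test_trivariate_population_value(self, rng):
        """Monte-Carlo oracle: rho_xy=0.5, rho_xz=rho_yz=0.6 gives a
        first-order partial of (0.5-0.36)/0.64 = 0.219 on the population
        correlations."""
        pop_partial = (0.5 - 0.6 * 0.6) / (1 - 0.6 ** 2)
        cov = np.array([[1, 0.5, 0.6], [0.5, 1, 0.6], [0.6, 0.6, 1]])
        sample = rng.multivariate_normal(np.zeros(3), cov, size=5000)
        res = partial_spearman(sample[:, 0], sample[:, 1], sample[:, 2])
        assert res.rho == pytest.approx(pop_partial, abs=0.03)

    def test_first_order_formula(self, rng):
        """The result equals the textbook first-order formula applied to
        independently computed pairwise rank correlations."""
        from scipy.stats import spearmanr
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        z = 0.5 * x + 0.2 * y + rng.normal(size=60)
        r_xy, r_xz, r_yz = (spearmanr(x, y)[0], spearmanr(x, z)[0],
                            spearmanr(y, z)[0])
        expected = (r_xy - r_xz * r_yz) / math.sqrt(
            (1 - r_xz ** 2) * (1 - r_yz ** 2))
        assert partial_spearman(x, y, z).rho == pytest.approx(expected,
                                                              abs=1e-12)


class TestMannWhitney:
    def test_disjoint_samples_exact_p(self):
        # a entirely below b: one-sided p = 1 / C(6, 3)
        u, p = mann_whitney([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(1 / comb(6, 3, exact=True))

    def test_identical_samples_two_sided(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_mode_matches_enumeration(self, rng):
        """Full enumeration over rank assignments for small samples."""
        for _ in range(10):
            a = rng.permutation(14)[:4].astype(float)
            b = rng.permutation(30)[14:21].astype(float)
            pooled = np.concatenate([a, b])
            if np.unique(pooled).size < pooled.size:
                continue
            u_obs, p_obs = mann_whitney(a, b, alternative="less")
            n_a = len(a)
            # enumeration of U for sample a over all rank assignments
            ranks = np.argsort(np.argsort(pooled)) + 1
            all_u = []
            for combo in itertools.combinations(range(len(pooled)), n_a):
                r = ranks[list(combo)].sum()
                all_u.append(r - n_a * (n_a + 1) / 2)
            all_u = np.array(all_u)
            p_enum = (all_u <= u_obs).mean()
            assert p_obs == pytest.approx(p_enum, abs=1e-12)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestFisherExact:
    def test_extreme_table_hypergeometric_term(self):
        odds, p, flagged = fisher_exact_2x2([[10, 0], [0, 10]],
                                            alternative="greater")
        assert not flagged
        assert p == pytest.approx(1 / comb(20, 10, exact=True))

    def test_balanced_table_two_sided(self):
        _, p, _ = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_zero_margin_flagged(self):
        _, p, flagged = fisher_exact_2x2([[0, 0], [3, 4]])
        assert flagged and p == 1.0

    def test_matches_enumeration_oracle(self, rng):
        """Exact p equals the sum of hypergeometric terms at least as
        extreme, for random tables with total <= 12."""
        for _ in range(40):
            t = rng.integers(0, 4, size=4)
            a, b, c, d = (int(v) for v in t)
            n = a + b + c + d
            if n == 0 or min(a + b, c + d, a + c, b + d) == 0:
                continue
            _, p_obs, _ = fisher_exact_2x2([[a, b], [c, d]])
            r1, c1 = a + b, a + c

            def prob(k):
                return (comb(r1, k, exact=True)
                        * comb(n - r1, c1 - k, exact=True)
                        / comb(n, c1, exact=True))

            p_a = prob(a)
            support = range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
            p_enum = sum(prob(k) for k in support
                         if prob(k) <= p_a * (1 + 1e-12))
            assert p_obs == pytest.approx(p_enum, abs=1e-12)


class TestChiSquare:
    def test_balanced_table_is_zero(self):
        stat, p = chi_square_2x2([[50, 50], [50, 50]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # margins 40/40: every expected cell is 20, so sum (O-E)^2/E = 20
        stat, p = chi_square_2x2([[30, 10], [10, 30]])
        assert stat == pytest.approx(20.0)
        assert p == pytest.approx(7.744216e-06, rel=1e-5)

    def test_zero_expected_cell_raises(self):
        with pytest.raises(ValueError, match="expected"):
            chi_square_2x2([[0, 0], [5, 5]])

    def test_continuity_correction_never_larger(self, rng):
        for _ in range(20):
            t = rng.integers(1, 30, size=(2, 2))
            plain, _ = chi_square_2x2(t, correction=False)
            corrected, _ = chi_square_2x2(t, correction=True)
            assert corrected <= plain + 1e-12


class TestPerTissueCorrelation:
    def test_monotone_tissue_has_rho_one(self, rng):
        import pandas as pd
        genes = [f"g{i}" for i in range(50)]
        feature = pd.Series(rng.uniform(size=50), index=genes)
        m = pd.DataFrame({
            "monotone": np.exp(feature.to_numpy()),
            "noise": rng.uniform(size=50),
        }, index=genes)
        out = per_tissue_correlation(feature, m,
                                     {"monotone": "germline",
                                      "noise": "somatic"})
        assert out.iloc[-1]["sample"] == "monotone"
        assert out.iloc[-1]["rho"] == pytest.approx(1.0)
        # sorted ascending by rho
        assert out["rho"].is_monotonic_increasing

    def test_germline_bars_sort_right_of_somatic(self, big_run):
        """Tissues generated with a germline coupling rank above the
        uncoupled somatic tissues in the correlation profile."""
        prof = big_run["tissue_profile"]
        germ = prof.loc[prof["tissue_class"] == "germline", "rho"]
        soma = prof.loc[prof["tissue_class"] == "somatic", "rho"]
        assert germ.mean() > soma.mean()
        assert germ.median() > soma.quantile(0.75)
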