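"""SES index construction, Spearman permutation inference and BCa bootstrap."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from urbanaudit.ecology import (
    bca_bootstrap_ci,
    correlate_determinants,
    ses_index,
    spearman_permutation,
    spearman_rho,
)


def components(n=5, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "pct_low_income": rng.uniform(5, 40, n),
            "avg_household_income": rng.uniform(40, 120, n),
            "pct_unemployed": rng.uniform(2, 15, n),
            "pct_less_than_high_school": rng.uniform(5, 30, n),
            "pct_single_parent": rng.uniform(5, 25, n),
        },
        index=[f"n{i}" for i in range(n)],
    )


class TestSesIndex:
    def test_t_score_construction_mean_fifty_sd_ten(self):
        out = ses_index(components(8))
        assert out["ses_index"].mean() == pytest.approx(50.0, abs=1e-9)
        assert out["ses_index"].std(ddof=1) == pytest.approx(10.0, abs=1e-9)

    def test_income_polarity_gives_rank_one_to_richer(self):
        df = components(2, seed=1)
        df.iloc[:] = df.iloc[[0]].to_numpy()  # identical rows...
        df.loc[df.index[1], "avg_household_income"] += 30  # ...except income
        with pytest.raises(ValueError, match="zero variance"):
            ses_index(df)  # other components now constant: named error
        # perturb the rest minimally so only income dominates
        rng = np.random.default_rng(2)
        for c in df.columns:
            if c != "avg_household_income":
                df[c] += rng.normal(0, 1e-6, 2)
        out = ses_index(df)
        assert out.loc[df.index[1], "ses_rank"] == 1

    def test_matches_stepwise_standardization_oracle(self):
        df = components(5, seed=3)
        polarity = {
            "pct_low_income": -1,
            "avg_household_income": +1,
            "pct_unemployed": -1,
            "pct_less_than_high_school": -1,
            "pct_single_parent": -1,
        }
        z = np.column_stack(
            [
                polarity[c] * (df[c] - df[c].mean()) / df[c].std(ddof=1)
                for c in df.columns
            ]
        )
        avg = z.mean(axis=1)
        oracle = 50 + 10 * (avg - avg.mean()) / avg.std(ddof=1)
        out = ses_index(df)
        np.testing.assert_allclose(out["ses_index"].to_numpy(), oracle, atol=1e-12)

    def test_undeclared_component_rejected(self):
        df = components(5)
        df["mystery"] = 1.0
        with pytest.raises(ValueError, match="mystery"):
            ses_index(df)


class TestSpearmanPermutation:
    def test_season_pairing_reproduces_printed_rank_correlation(self, season_scores):
        """Spearman rho of the 15 Q_s pairs across seasons is 0.51 (2 dp)."""
        rho, p = spearman_permutation(
            season_scores["qs_2011"].to_numpy(),
            season_scores["qs_2012"].to_numpy(),
            n_perm=9999,
            seed=0,
        )
        assert round(rho, 2) == 0.51
        assert p < 0.05  # significant, as reported (one-sided p ~ 0.024)

    def test_monotone_pair_gives_rho_one_and_minimal_p(self):
        x = np.arange(10.0)
        y = x**3 + 2
        rho, p = spearman_permutation(x, y, n_perm=999, seed=1)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_rho_invariant_under_monotone_transforms(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, 3 * y + 1) == pytest.approx(base, abs=1e-12)

    def test_small_n_matches_exhaustive_enumeration(self):
        """n=4: compare against the exact p over all 24 permutations."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.3, 0.9, 2.2, 3.1])
        rho = spearman_rho(x, y)
        exact_hits = sum(
            spearman_rho(np.array(px), y) >= rho - 1e-12
            for px in permutations(x)
        )
        exact = exact_hits / 24
        # large n_perm: the sampled empirical p approaches the exhaustive value
        _, p = spearman_permutation(x, y, n_perm=19_999, seed=2)
        assert p == pytest.approx(exact, abs=0.02)

    def test_empirical_p_uniformish_under_null(self, rng):
        """Fraction of p <= 0.05 over 500 independent null pairs (n=15)
        stays near the nominal level."""
        hits = 0
        for i in range(500):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            _, p = spearman_permutation(x, y, n_perm=199, seed=i, sidedness="two")
            hits += p <= 0.05
        assert 0.02 <= hits / 500 <= 0.09

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_permutation(np.ones(6), np.arange(6.0))


class TestBcaBootstrap:
    def test_forcing_corrections_to_zero_recovers_percentile_interval(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        lo, hi = bca_bootstrap_ci(
            x, y, n_boot=2000, seed=5, force_z0=0.0, force_a=0.0
        )
        boot = []
        rng2 = np.random.default_rng(5)
        for _ in range(2000):
            idx = rng2.integers(0, 30, 30)
            boot.append(spearman_rho(x[idx], y[idx]))
        plo, phi = np.quantile(boot, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=1e-9)
        assert hi == pytest.approx(phi, abs=1e-9)

    def test_mean_statistic_close_to_normal_theory_interval(self):
        """BCa on the mean of 50 standard-normal draws lands within 0.05 of
        the analytic t-interval endpoints across seeds."""
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            x = rng.normal(size=50)
            lo, hi = bca_bootstrap_ci(
                x, None, statistic=lambda a: float(np.mean(a)),
                n_boot=2000, seed=seed,
            )
            tlo, thi = stats.t.interval(
                0.95, 49, loc=x.mean(), scale=x.std(ddof=1) / np.sqrt(50)
            )
            assert abs(lo - tlo) < 0.05
            assert abs(hi - thi) < 0.05

    def test_season_pairs_reproduce_published_interval(self, season_scores):
        """BCa 95% CI for the inter-season rank correlation comes out within
        Monte-Carlo tolerance of [0.0273, 0.8226]."""
        lo, hi = bca_bootstrap_ci(
            season_scores["qs_2011"].to_numpy(),
            season_scores["qs_2012"].to_numpy(),
            n_boot=10_000,
            seed=0,
        )
        assert lo == pytest.approx(0.0273, abs=0.05)
        assert hi == pytest.approx(0.8226, abs=0.05)

    def test_agrees_with_scipy_bca_on_the_mean(self, rng):
        x = rng.normal(size=40)
        lo, hi = bca_bootstrap_ci(
            x, None, statistic=lambda a: float(np.mean(a)), n_boot=4000, seed=3
        )
        ref = stats.bootstrap(
            (x,), np.mean, n_resamples=4000, method="BCa",
            random_state=4, vectorized=False,
        ).confidence_interval
        assert lo == pytest.approx(ref.low, abs=0.03)
        assert hi == pytest.approx(ref.high, abs=0.03)

    def test_intervals_shrink_with_n(self, rng):
        x = rng.normal(size=400)
        widths = []
        for n in (25, 100, 400):
            lo, hi = bca_bootstrap_ci(
                x[:n], None, statistic=lambda a: float(np.mean(a)),
                n_boot=1500, seed=n,
            )
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_degenerate_bootstrap_falls_back_with_warning(self):
        x = np.ones(10)
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bca_bootstrap_ci(
                x, None, statistic=lambda a: float(np.mean(a)), n_boot=100, seed=0
            )
        assert lo == hi == 1.0


class TestDeterminantsTable:
    def test_pairwise_deletion_and_columns(self, season_scores, rng):
        qs = season_scores.set_index("neighbourhood_id")["qs_2011"]
        det = pd.DataFrame(index=qs.index)
        det["ses"] = 30 + 2 * qs + rng.normal(0, 1, len(qs))
        det["bmi"] = 60 - 3 * qs + rng.normal(0, 1.5, len(qs))
        det.loc[det.index[:2], "bmi"] = np.nan  # two neighbourhoods unsurveyed
        res = correlate_determinants(qs, det, n_perm=499, n_boot=500, seed=0)
        assert res.loc["ses", "n"] == 15
        assert res.loc["bmi", "n"] == 13
        assert res.loc["ses", "rho"] > 0
        assert res.loc["bmi", "rho"] < 0
        assert res.loc["ses", "empirical_p"] >= 1 / 500
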