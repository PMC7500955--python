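"""Statistical battery: exact oracles, adjustment properties, reporting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from centromorph.errors import InvalidInputError
from centromorph.stats_report import (
    GroupSample,
    anova_holm_sidak,
    build_report,
    fisher_exact,
    holm_sidak,
    mann_whitney,
    significance_stars,
    unpaired_t,
)


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        a = GroupSample("a", [1.0, 2.0, 3.0])
        assert mann_whitney(a, GroupSample("b", [1.0, 2.0, 3.0])).p_value == 1.0

    def test_fully_separated_small_sample(self):
        """{1,2,3} vs {4,5,6}: 2 of the 20 labelings are as extreme -> p=0.1."""
        res = mann_whitney(GroupSample("a", [1, 2, 3]), GroupSample("b", [4, 5, 6]))
        assert res.p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_scipy_enumeration(self, seed):
        """Tie-free small samples agree with scipy's exact method."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        y = rng.normal(0.8, 1.0, size=6)
        ours = mann_whitney(GroupSample("x", x), GroupSample("y", y)).p_value
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=6)
        y = rng.normal(0.5, 1.0, size=6)
        exact = mann_whitney(GroupSample("x", x), GroupSample("y", y)).p_value
        approx = mann_whitney(
            GroupSample("x", x), GroupSample("y", y), exact_max_n=0
        ).p_value
        assert approx == pytest.approx(exact, abs=0.01 + 0.05 * exact)


class TestFisherExact:
    def test_diagonal_table(self):
        assert fisher_exact([[5, 0], [0, 5]]).p_value == pytest.approx(0.00794, abs=5e-5)

    def test_symmetric_null(self):
        assert fisher_exact([[3, 3], [3, 3]]).p_value == pytest.approx(1.0)

    def test_zero_margin_p_one(self):
        assert fisher_exact([[0, 0], [2, 3]]).p_value == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        """Every 2x2 table with both margins <= 6 agrees with the
        exhaustive hypergeometric enumeration oracle."""
        for n1, n2, c1 in itertools.product(range(1, 7), range(1, 7), range(0, 13)):
            if c1 > n1 + n2:
                continue
            ks = np.arange(max(0, c1 - n2), min(n1, c1) + 1)
            pmf = sps.hypergeom.pmf(ks, n1 + n2, n1, c1)
            for a in ks:
                table = [[int(a), n1 - int(a)], [c1 - int(a), n2 - (c1 - int(a))]]
                p_obs = sps.hypergeom.pmf(a, n1 + n2, n1, c1)
                expected = min(pmf[pmf <= p_obs * (1 + 1e-9)].sum(), 1.0)
                assert fisher_exact(table).p_value == pytest.approx(expected, abs=1e-9)


class TestHolmSidak:
    def test_single_comparison_passthrough(self):
        assert holm_sidak([0.04])[0] == pytest.approx(0.04)

    def test_never_below_raw_and_monotone(self):
        raw = [0.001, 0.02, 0.04, 0.3]
        adj = holm_sidak(raw)
        assert (adj >= np.asarray(raw) - 1e-15).all()
        assert (np.diff(adj[np.argsort(raw)]) >= -1e-15).all()

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8),
           st.randoms(use_true_random=False))
    def test_order_invariance(self, ps, rnd):
        shuffled = list(ps)
        rnd.shuffle(shuffled)
        a = np.sort(holm_sidak(ps))
        b = np.sort(holm_sidak(shuffled))
        assert np.allclose(a, b, atol=1e-12)


class TestAnova:
    def test_pairwise_adjustment_structure(self):
        rng = np.random.default_rng(0)
        groups = [GroupSample(f"g{i}", rng.normal(i * 0.5, 1.0, 20)) for i in range(3)]
        res = anova_holm_sidak(groups)
        assert res.p_value <= 1.0
        assert len(res.pairwise) == 3
        for pw in res.pairwise:
            assert pw["p_adj"] >= pw["p_raw"] - 1e-15

    def test_requires_three_groups(self):
        g = GroupSample("g", [1.0, 2.0])
        with pytest.raises(InvalidInputError):
            anova_holm_sidak([g, g])

    def test_null_rejection_rate_calibrated(self):
        """Type-I error at alpha=0.05 across simulated null datasets."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            groups = [GroupSample(f"g{i}", rng.normal(size=20)) for i in range(3)]
            if anova_holm_sidak(groups).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07


class TestUnpairedT:
    def test_identical_groups(self):
        g = GroupSample("a", [1.0, 2.0, 3.0])
        res = unpaired_t(g, GroupSample("b", [1.0, 2.0, 3.0]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_pair(self):
        res = unpaired_t(GroupSample("a", [1, 2, 3, 4]), GroupSample("b", [2, 3, 4, 5]))
        assert res.statistic == pytest.approx(-1.095, abs=0.001)
        assert res.p_value == pytest.approx(0.315, abs=0.001)

    def test_welch_equals_pooled_for_equal_variances(self):
        a = GroupSample("a", [1.0, 2.0, 3.0, 4.0])
        b = GroupSample("b", [11.0, 12.0, 13.0, 14.0])
        assert unpaired_t(a, b).p_value == pytest.approx(unpaired_t(a, b, welch=True).p_value)


class TestStarsAndReport:
    @pytest.mark.parametrize(
        "p, stars",
        [(0.3, "ns"), (0.03, "*"), (0.003, "**"), (0.0003, "***"), (0.00003, "****")],
    )
    def test_star_convention(self, p, stars):
        assert significance_stars(p) == stars

    def test_single_group_summary_only(self):
        df = pd.DataFrame({"metric": "length", "group": "ctrl", "value": [1.0, 2.0, 3.0]})
        bundle = build_report(df)
        assert bundle.stats == {}
        assert len(bundle.summary) == 1

    def test_report_means_match_brute_force(self, tmp_path):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "metric": ["coverage"] * 40,
                "group": ["ctrl"] * 20 + ["si"] * 20,
                "value": np.concatenate([rng.normal(57, 13, 20), rng.normal(24, 14, 20)]),
            }
        )
        bundle = build_report(df, tests={"coverage": "mann_whitney"})
        for grp in ("ctrl", "si"):
            row = bundle.summary.query("group == @grp").iloc[0]
            assert row["mean"] == pytest.approx(df.query("group == @grp").value.mean())
        assert "coverage" in bundle.stats
        bundle.save(tmp_path)
        assert (tmp_path / "summary.csv").exists()
        assert (tmp_path / "stats.json").exists()
        assert (tmp_path / "run.log").exists()
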