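"""The global association test: statistic, nulls, signs, contributions."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirotype.globaltest import (
    GlobalTestConfig,
    GlobalTestInput,
    Sign,
    Transform,
    UntestableError,
    _null_statistics,
    global_statistic,
    group_target_test,
    p_value_exhaustive,
    p_value_gamma,
    p_value_permutation,
    pair_association,
    permutation_null_moments,
)

TOY_Y = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
TOY_X = [2.0, 1.0, 3.0, 5.0, 4.0, 6.0]


def _oracle_statistic(y, x_cols):
    """Independent plain-Python evaluation of Q and its decomposition."""
    n, m = len(y), len(x_cols)
    ybar = sum(y) / n
    r = [v - ybar for v in y]
    s2 = sum(v * v for v in r) / n
    contribs = []
    for col in x_cols:
        xbar = sum(col) / n
        sd = math.sqrt(sum((v - xbar) ** 2 for v in col) / n)
        xs = [(v - xbar) / sd for v in col]
        cross = sum(a * b for a, b in zip(xs, r))
        contribs.append(cross * cross / (m * s2))
    return sum(contribs), contribs


class TestStatistic:
    def test_toy_matches_independent_arithmetic(self):
        q, contribs = global_statistic(
            GlobalTestInput(y=TOY_Y, X=np.array(TOY_X)[:, None], min_samples=4)
        )
        q_oracle, c_oracle = _oracle_statistic(TOY_Y, [TOY_X])
        assert q == pytest.approx(q_oracle, rel=1e-12)
        assert contribs[0].contribution == pytest.approx(c_oracle[0], rel=1e-12)
        assert contribs[0].sign is Sign.POSITIVE

    def test_perfect_association_is_permutation_maximum(self):
        y = np.array(TOY_Y)
        inp = GlobalTestInput(y=y, X=y[:, None], min_samples=4)
        q, contribs = global_statistic(inp)
        assert contribs[0].sign is Sign.POSITIVE
        prep = inp.prepare()
        perms = np.array(list(itertools.permutations(range(6))))
        assert q == pytest.approx(_null_statistics(prep, perms).max(), rel=1e-12)

    def test_orthogonal_covariate_contributes_zero(self):
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        x = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        assert float(x @ (y - y.mean())) == 0.0
        _, contribs = global_statistic(GlobalTestInput(y=y, X=x, min_samples=4))
        assert contribs[0].contribution == 0.0
        assert contribs[0].sign is Sign.ZERO

    def test_constant_profiles_untestable(self):
        const = np.ones(8)
        var = np.arange(8.0)
        with pytest.raises(UntestableError, match="response"):
            global_statistic(GlobalTestInput(y=const, X=var))
        with pytest.raises(UntestableError, match="x0"):
            global_statistic(GlobalTestInput(y=var, X=const))

    @given(
        data=st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
            ),
            min_size=6,
            max_size=25,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_contributions_sum_to_statistic(self, data):
        arr = np.array(data)
        y, X = arr[:, 0], arr[:, 1:]
        if y.std() == 0 or (X.std(axis=0) == 0).any():
            return
        q, contribs = global_statistic(GlobalTestInput(y=y, X=X, min_samples=4))
        assert sum(c.contribution for c in contribs) == pytest.approx(
            q, rel=1e-10, abs=1e-12
        )


class TestExhaustive:
    def test_toy_p_equals_enumeration_count(self):
        inp = GlobalTestInput(y=TOY_Y, X=np.array(TOY_X)[:, None], min_samples=4)
        result = p_value_exhaustive(inp)
        # independent enumeration in a different order (reversed), plain
        # Python arithmetic; ties counted as >= (integer data reversed about
        # its midpoint produces exactly tied squared statistics)
        q_obs, _ = _oracle_statistic(TOY_Y, [TOY_X])
        count = 0
        for perm in reversed(list(itertools.permutations(TOY_Y))):
            q, _ = _oracle_statistic(list(perm), [TOY_X])
            count += q >= q_obs or math.isclose(q, q_obs, rel_tol=1e-9)
        assert result.p_value == count / 720
        assert result.method == "exhaustive"

    def test_maximal_statistic_p_counts_ties(self):
        y = np.array(TOY_Y)
        result = p_value_exhaustive(GlobalTestInput(y=y, X=y, min_samples=4))
        # y == x on 1..6: the squared statistic is maximized by the identity
        # AND the full reversal (centered y is antisymmetric), so two tied
        # maxima are counted
        assert result.p_value == 2 / 720

    def test_statistic_zero_gives_p_one(self):
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        x = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0])
        assert p_value_exhaustive(
            GlobalTestInput(y=y, X=x, min_samples=4)
        ).p_value == 1.0

    def test_refuses_large_n(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="permutation"):
            p_value_exhaustive(
                GlobalTestInput(y=rng.normal(size=12), X=rng.normal(size=12))
            )

    def test_constant_covariate_untestable(self):
        with pytest.raises(UntestableError):
            p_value_exhaustive(
                GlobalTestInput(y=np.arange(6.0), X=np.ones(6), min_samples=4)
            )


class TestPermutation:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        inp = GlobalTestInput(y=rng.normal(size=30), X=rng.normal(size=30))
        p1 = p_value_permutation(inp, n_perm=2000, seed=5).p_value
        p2 = p_value_permutation(inp, n_perm=2000, seed=5).p_value
        assert p1 == p2

    def test_agrees_with_exhaustive_within_mc_error(self):
        inp = GlobalTestInput(y=TOY_Y, X=np.array(TOY_X)[:, None], min_samples=4)
        pe = p_value_exhaustive(inp).p_value
        pp = p_value_permutation(inp, n_perm=100_000, seed=3).p_value
        se = math.sqrt(pe * (1 - pe) / 100_000)
        assert abs(pp - pe) <= 3 * se + 1 / 100_001

    def test_p_floor_and_range(self):
        y = np.arange(20.0)
        pp = p_value_permutation(
            GlobalTestInput(y=y, X=y), n_perm=999, seed=0
        ).p_value
        assert pp == 1 / 1000

    def test_rejects_too_few_permutations(self):
        with pytest.raises(ValueError, match="n_perm"):
            p_value_permutation(
                GlobalTestInput(y=np.arange(10.0), X=np.arange(10.0)), n_perm=100
            )


class TestGamma:
    def test_null_moments_match_enumeration(self):
        rng = np.random.default_rng(2)
        for n, m in [(6, 1), (7, 2), (6, 3)]:
            prep = GlobalTestInput(
                y=rng.normal(size=n), X=rng.normal(size=(n, m)), min_samples=4
            ).prepare()
            perms = np.array(list(itertools.permutations(range(n))))
            qs = _null_statistics(prep, perms)
            mean, var = permutation_null_moments(prep)
            assert mean == pytest.approx(qs.mean(), rel=1e-10)
            assert var == pytest.approx(qs.var(), rel=1e-10)

    def test_within_factor_two_of_permutation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        y = 0.25 * x + rng.normal(size=200)
        inp = GlobalTestInput(y=y, X=x)
        pg = p_value_gamma(inp).p_value
        pp = p_value_permutation(inp, n_perm=100_000, seed=1).p_value
        assert pg == pytest.approx(pp, rel=1.0)  # within a factor of 2

    def test_zero_statistic_p_one(self):
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        x = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        assert p_value_gamma(GlobalTestInput(y=y, X=x, min_samples=4)).p_value == 1.0

    def test_null_calibration_in_binomial_envelope(self):
        rng = np.random.default_rng(17)
        n_rep, alpha = 1000, 0.05
        rej = 0
        for _ in range(n_rep):
            inp = GlobalTestInput(y=rng.normal(size=100), X=rng.normal(size=100))
            rej += p_value_gamma(inp).p_value <= alpha
        lo = alpha - 1.96 * math.sqrt(alpha * (1 - alpha) / n_rep)
        hi = alpha + 1.96 * math.sqrt(alpha * (1 - alpha) / n_rep)
        assert lo <= rej / n_rep <= hi


class TestInvariances:
    def test_affine_covariate_and_shifted_response_invariance(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=15)
        x = rng.normal(size=15)
        base = p_value_exhaustive(
            GlobalTestInput(y=y[:8], X=x[:8], min_samples=4)
        )
        shifted = p_value_exhaustive(
            GlobalTestInput(y=y[:8] + 100.0, X=3.5 * x[:8] + 2.0, min_samples=4)
        )
        assert shifted.p_value == base.p_value
        assert shifted.statistic == pytest.approx(base.statistic, rel=1e-9)

    def test_sign_matches_pearson_correlation(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            y = rng.lognormal(2, 1, size=40)
            x = rng.lognormal(2, 1, size=40)
            assoc = pair_association(
                y, x, response_id="g", covariate_id="m",
                config=GlobalTestConfig(n_perm=1000, seed=0),
            )
            rho = np.corrcoef(np.log2(x + 1), np.log2(y + 1))[0, 1]
            expected = Sign.POSITIVE if rho > 0 else Sign.NEGATIVE
            assert assoc.sign is expected


class TestPairAssociation:
    def test_identical_profiles_minimal_p_positive_sign(self):
        y = np.linspace(1, 50, 20)
        assoc = pair_association(
            y, y, response_id="g", covariate_id="m",
            config=GlobalTestConfig(method="permutation", n_perm=999, seed=0),
        )
        assert assoc.sign is Sign.POSITIVE
        assert assoc.p_value == 1 / 1000

    def test_planted_negative_slope_detected(self):
        rng = np.random.default_rng(21)
        x = rng.normal(5, 1, size=100)
        y = -x + rng.normal(0, 0.1, size=100)
        assoc = pair_association(
            y, x, response_id="g", covariate_id="m",
            response_transform=Transform.NONE, covariate_transform=Transform.NONE,
            config=GlobalTestConfig(n_perm=2000, seed=2),
        )
        assert assoc.sign is Sign.NEGATIVE
        assert assoc.p_value < 0.05

    def test_na_samples_reduce_n_used(self):
        rng = np.random.default_rng(4)
        y = rng.uniform(1, 10, size=20)
        x = rng.uniform(1, 10, size=20)
        x[3] = np.nan
        assoc = pair_association(
            y, x, response_id="g", covariate_id="m",
            config=GlobalTestConfig(n_perm=999, seed=0),
        )
        assert assoc.n_used == 19

    def test_constant_profile_flagged_untestable(self):
        assoc = pair_association(
            np.ones(20), np.arange(20.0), response_id="g", covariate_id="m",
        )
        assert assoc.untestable
        assert assoc.p_value is None

    def test_too_few_complete_cases_untestable(self):
        y = np.full(20, np.nan)
        y[:5] = [1, 2, 3, 4, 5]
        assoc = pair_association(
            y, np.arange(20.0), response_id="g", covariate_id="m",
        )
        assert assoc.untestable
        assert "complete cases" in assoc.reason


class TestGroupTargetTest:
    def test_single_target_matches_swapped_pair_association(self):
        import pandas as pd

        rng = np.random.default_rng(6)
        mirna = rng.lognormal(2, 1, size=8)
        gene = rng.lognormal(2, 1, size=8)
        targets = pd.DataFrame([gene], index=["G1"])
        config = GlobalTestConfig(method="exhaustive", min_samples=4)
        result, contribs = group_target_test(
            mirna, targets, mirna_id="miR-1", config=config
        )
        swapped = pair_association(
            mirna, gene, response_id="miR-1", covariate_id="G1", config=config
        )
        assert result.p_value == pytest.approx(swapped.p_value, abs=10 / 40320)
        assert contribs[0].covariate_id == "G1"

    def test_anti_correlated_target_ranked_first(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        mirna = rng.lognormal(3, 1, size=60)
        anti = 2 ** (-np.log2(mirna + 1) + rng.normal(0, 0.3, size=60) + 12)
        null = rng.lognormal(3, 1, size=60)
        targets = pd.DataFrame([null, anti], index=["Gnull", "Ganti"])
        _, contribs = group_target_test(
            mirna, targets, mirna_id="miR-1",
            config=GlobalTestConfig(n_perm=999, seed=0),
        )
        assert contribs[0].covariate_id == "Ganti"
        assert contribs[0].sign is Sign.NEGATIVE

    def test_all_constant_targets_untestable(self):
        import pandas as pd

        targets = pd.DataFrame([np.ones(10), np.full(10, 2.0)], index=["a", "b"])
        with pytest.raises(UntestableError, match="constant"):
            group_target_test(np.arange(10.0), targets, mirna_id="miR-1")
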