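from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metapathways import association as asc


def make_clinical(groups, extra=None):
    df = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(len(groups))], "group": groups}
    )
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


def activity_frame(rows, n):
    return pd.DataFrame(rows, columns=[f"s{i}" for i in range(n)])


class TestAssociate:
    def test_indicator_pattern_matches_t_test_oracle(self, rng):
        """OLS contrast p on a 0/1 design equals the pooled two-sample
        t-test computed independently."""
        n = 40
        groups = ["a"] * 20 + ["b"] * 20
        y = np.array([0.0] * 20 + [1.0] * 20) + rng.normal(0, 0.01, n)
        res = asc.associate(
            activity_frame([y], n), make_clinical(groups), ["group"], side="one"
        )
        row = res.iloc[0]
        t_oracle = stats.ttest_ind(
            y[20:], y[:20], equal_var=True, alternative="greater"
        )
        assert row["one_sided_p"] == pytest.approx(t_oracle.pvalue, rel=1e-9)
        assert row["adjusted_p"] < 1e-6
        assert row["adjusted_p"] >= row["one_sided_p"]

    def test_null_p_uniform_over_permutations(self, rng):
        """With activity independent of labels, one-sided p is U(0,1)."""
        n = 60
        groups = ["a"] * 30 + ["b"] * 30
        clin = make_clinical(groups)
        pvals = []
        for _ in range(200):
            y = rng.normal(0, 1, n)
            res = asc.associate(activity_frame([y], n), clin, ["group"], side="one")
            pvals.append(res["one_sided_p"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_type_one_error_controlled(self, rng):
        """Adjusted p < 0.05 in at most ~5% of null replicates."""
        n = 30
        clin = make_clinical(
            ["a"] * 15 + ["b"] * 15, extra={"hpv": ["y", "n"] * 15}
        )
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            y = rng.normal(0, 1, n)
            res = asc.associate(
                activity_frame([y], n), clin, ["group", "hpv"], side="one"
            )
            hits += (res["adjusted_p"] < 0.05).any()
        assert hits / n_rep <= 0.07

    def test_constant_activity(self):
        n = 12
        res = asc.associate(
            activity_frame([[1.0] * n], n),
            make_clinical(["a"] * 6 + ["b"] * 6),
            ["group"],
        )
        assert res["estimate"].iloc[0] == 0.0
        assert res["one_sided_p"].iloc[0] == 1.0

    def test_singular_design_named(self):
        n = 12
        clin = make_clinical(
            ["a"] * 6 + ["b"] * 6, extra={"dup": ["a"] * 6 + ["b"] * 6}
        )
        with pytest.raises(ValueError, match="collinear.*group.*dup"):
            asc.associate(
                activity_frame([np.arange(n)], n), clin, ["group", "dup"]
            )

    def test_one_vs_rest_tests_every_level(self, rng):
        n = 18
        groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        res = asc.associate(
            activity_frame([rng.normal(0, 1, n)], n),
            make_clinical(groups),
            ["group"],
            encoding="one_vs_rest",
        )
        assert sorted(res["contrast"]) == [
            "group[a vs rest]", "group[b vs rest]", "group[c vs rest]"
        ]

    def test_too_few_samples_per_level(self):
        clin = make_clinical(["a"] * 2 + ["b"] * 8)
        with pytest.raises(ValueError, match="< 3 samples"):
            asc.associate(activity_frame([np.arange(10.0)], 10), clin, ["group"])


class TestClusterSamples:
    def two_clouds(self, rng, m=16, n=40):
        base1 = rng.normal(0, 1, n)
        base2 = rng.normal(0, 1, n)
        cols = [base1 + rng.normal(0, 0.1, n) for _ in range(m // 2)]
        cols += [base2 + rng.normal(0, 0.1, n) for _ in range(m // 2)]
        return np.column_stack(cols)

    def test_two_clouds_separated_at_k2(self, rng):
        X = self.two_clouds(rng)
        labels = asc.cluster_samples(X, k_range=[2])[2]
        assert len(set(labels[:8])) == 1
        assert len(set(labels[8:])) == 1
        assert labels[0] != labels[-1]

    def test_duplicated_sample_stays_together(self, rng):
        X = self.two_clouds(rng)
        X = np.column_stack([X, X[:, 0]])  # duplicate first sample
        labels = asc.cluster_samples(X, k_range=range(2, 17))
        for k in range(2, 17):
            assert labels[k][0] == labels[k][-1]

    def test_k_equals_m_every_sample_alone(self, rng):
        X = rng.normal(0, 1, (30, 6))
        labels = asc.cluster_samples(X, k_range=[6])[6]
        assert len(set(labels)) == 6

    def test_zero_variance_column_rejected(self, rng):
        X = rng.normal(0, 1, (10, 4))
        X[:, 2] = 3.0
        with pytest.raises(ValueError, match="zero-variance"):
            asc.cluster_samples(X, k_range=[2])

    def test_invariant_to_sample_order(self, rng):
        X = self.two_clouds(rng)
        labels = asc.cluster_samples(X, k_range=[2, 3])
        perm = rng.permutation(X.shape[1])
        labels_p = asc.cluster_samples(X[:, perm], k_range=[2, 3])
        for k in (2, 3):
            partition = {frozenset(np.where(labels[k] == c)[0]) for c in set(labels[k])}
            partition_p = {
                frozenset(perm[np.where(labels_p[k] == c)[0]]) for c in set(labels_p[k])
            }
            assert partition == partition_p


def fisher_2x2_oracle(table) -> float:
    """Exact two-sided Fisher p by enumeration in rational arithmetic."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if px <= p_obs:
            total += px
    return float(total)


class TestFisher:
    def test_diagonal_table(self):
        p, method = asc.cluster_phenotype_test([1] * 10 + [2] * 10, ["x"] * 10 + ["y"] * 10)
        assert method == "exact_2x2"
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_independent_table(self):
        labels = [1] * 10 + [2] * 10
        pheno = (["x"] * 5 + ["y"] * 5) * 2  # table [[5,5],[5,5]]
        p, _ = asc.cluster_phenotype_test(labels, pheno)
        assert p == pytest.approx(1.0)

    def test_two_by_two_unit_margins(self):
        p, _ = asc.cluster_phenotype_test([1, 2], ["x", "y"])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_sample(self, rng):
        for _ in range(50):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            labels = np.repeat([1, 2], t.sum(axis=1))
            pheno = np.concatenate(
                [np.repeat(["x", "y"], row) for row in t]
            )
            p, _ = asc.cluster_phenotype_test(labels, pheno)
            assert p == pytest.approx(fisher_2x2_oracle(t), abs=1e-10)

    def test_degenerate_margins_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            p, method = asc.cluster_phenotype_test([1] * 8, ["x", "y"] * 4)
        assert p == 1.0 and method == "degenerate"

    def test_rxc_exact_vs_monte_carlo(self):
        labels = [1] * 8 + [2] * 8 + [3] * 8
        pheno = (["x"] * 4 + ["y"] * 4) * 3
        p_exact, m1 = asc.cluster_phenotype_test(labels, pheno)
        p_mc, m2 = asc.cluster_phenotype_test(
            labels, pheno, exact_total_limit=0, n_mc=20000, seed=1
        )
        assert m1 == "exact_enum" and m2 == "monte_carlo"
        assert p_mc == pytest.approx(p_exact, abs=0.02)

    def test_monte_carlo_deterministic_given_seed(self):
        labels = [1, 2, 3] * 12
        pheno = ["x", "y"] * 18
        p1, _ = asc.cluster_phenotype_test(labels, pheno, exact_total_limit=0, n_mc=5000, seed=7)
        p2, _ = asc.cluster_phenotype_test(labels, pheno, exact_total_limit=0, n_mc=5000, seed=7)
        assert p1 == p2
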