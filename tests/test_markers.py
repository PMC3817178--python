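import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metapathways import markers as mk


def probe_frame(rows, samples):
    return pd.DataFrame(rows, index=[f"pr{i}" for i in range(len(rows))], columns=samples)


class TestProbeDifferential:
    def setup_data(self, rng, shift=0.0, n=10, sd=1.0):
        samples = [f"s{i}" for i in range(2 * n)]
        groups = pd.Series(["normal"] * n + ["tumor"] * n, index=samples)
        vals = rng.normal(0, sd, (3, 2 * n))
        vals[:, n:] += shift
        return probe_frame(vals, samples), groups

    def test_null_p_near_half(self, rng):
        expr, groups = self.setup_data(rng, shift=0.0, n=100, sd=1.0)
        report = mk.probe_differential(expr, groups)
        assert ((report.probe_p["tumor"] > 0.05) & (report.probe_p["tumor"] < 0.95)).all()

    def test_strong_shift_matches_t_oracle(self, rng):
        expr, groups = self.setup_data(rng, shift=10.0, n=10, sd=0.1)
        report = mk.probe_differential(expr, groups)
        assert (report.min_p < 1e-10).all()
        pr = expr.index[0]
        oracle = stats.ttest_ind(
            expr.loc[pr, groups == "tumor"],
            expr.loc[pr, groups == "normal"],
            equal_var=False,
            alternative="greater",
        ).pvalue
        assert report.probe_p.loc[pr, "tumor"] == pytest.approx(oracle)

    def test_min_rule(self):
        samples = [f"s{i}" for i in range(8)]
        groups = pd.Series(["normal"] * 4 + ["tumor"] * 4, index=samples)
        expr = probe_frame(np.random.default_rng(1).normal(0, 1, (3, 8)), samples)
        report = mk.probe_differential(expr, groups)
        assert report.min_p["tumor"] == pytest.approx(report.probe_p["tumor"].min())

    def test_opposite_sides_sum_to_one(self, rng):
        expr, groups = self.setup_data(rng, shift=1.0, n=8)
        up = mk.probe_differential(expr, groups, side="one")
        flipped = expr.copy()
        flipped.loc[:, groups == "tumor"] *= -1
        flipped.loc[:, groups == "normal"] *= -1
        # one-sided p of contrast + one-sided p of the negated data = 1
        down = mk.probe_differential(-expr, groups, side="one")
        total = up.probe_p["tumor"] + down.probe_p["tumor"]
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_single_sample_group_rejected(self, rng):
        samples = [f"s{i}" for i in range(5)]
        groups = pd.Series(["normal"] * 4 + ["tumor"], index=samples)
        expr = probe_frame(rng.normal(0, 1, (2, 5)), samples)
        with pytest.raises(ValueError, match="single sample"):
            mk.probe_differential(expr, groups)


class TestOutlierOverexpression:
    def test_inclusive_boundary(self):
        values = pd.Series(
            [1.0, 2.0, 3.0, 3.5, 3.49], index=["n1", "n2", "n3", "t1", "t2"]
        )
        flags, _ = mk.outlier_overexpression(values, ["n1", "n2", "n3"])
        assert bool(flags["t1"]) is True
        assert bool(flags["t2"]) is False

    def test_planted_counts_recovered(self, rng):
        normals = {f"n{i}": v for i, v in enumerate(rng.normal(0, 0.2, 10))}
        cutoff = max(normals.values())
        tumors_a = {f"a{i}": cutoff + 0.6 for i in range(6)}
        tumors_a.update({f"a{i}": cutoff - 0.2 for i in range(6, 15)})
        tumors_b = {f"b{i}": cutoff + 0.7 if i == 0 else cutoff for i in range(10)}
        values = pd.Series({**normals, **tumors_a, **tumors_b})
        groups = pd.Series(
            {**{k: "normal" for k in normals},
             **{k: "hpv_negative" for k in tumors_a},
             **{k: "hpv_positive" for k in tumors_b}}
        )
        _, counts = mk.outlier_overexpression(values, list(normals), groups)
        assert counts == {"hpv_negative": 6, "hpv_positive": 1}

    def test_monotone_in_threshold(self, rng):
        values = pd.Series(rng.normal(0, 1, 30), index=[f"s{i}" for i in range(30)])
        normals = [f"s{i}" for i in range(10)]
        f_low, _ = mk.outlier_overexpression(values, normals, threshold_log_fc=0.2)
        f_high, _ = mk.outlier_overexpression(values, normals, threshold_log_fc=0.8)
        assert set(f_high[f_high].index) <= set(f_low[f_low].index)


class TestDeltaCt:
    def make_table(self, d_normal, d_tumor):
        rows = []
        for i, d in enumerate(d_normal):
            rows.append({"sample_id": f"n{i}", "ct_target": 20 + d, "ct_reference": 20.0,
                         "group": "normal"})
        for i, d in enumerate(d_tumor):
            rows.append({"sample_id": f"t{i}", "ct_target": 20 + d, "ct_reference": 20.0,
                         "group": "tumor"})
        return pd.DataFrame(rows)

    def test_fold_change_definition(self):
        out = mk.delta_ct(self.make_table([1.0, 1.0, 1.2], [0.0, 0.0, 0.2]))
        assert out["delta_delta_ct"] == pytest.approx(-1.0, abs=0.01)
        assert out["fold_change"] == pytest.approx(2.0, rel=0.01)

    def test_null_gives_fold_one(self):
        out = mk.delta_ct(self.make_table([1.0, 1.2, 0.8, 1.0], [1.0, 1.2, 0.8, 1.0]))
        assert out["fold_change"] == pytest.approx(1.0)

    def test_fold_inversion(self):
        """ddCt implied by a 3.1-fold change inverts the definition."""
        ddct = -np.log2(3.1)
        d_tumor = [ddct, ddct + 0.01, ddct - 0.01]
        out = mk.delta_ct(self.make_table([0.0, 0.01, -0.01], d_tumor))
        assert out["fold_change"] == pytest.approx(3.1, rel=0.01)
        assert out["delta_delta_ct"] == pytest.approx(-1.632, abs=0.01)

    def test_missing_reference_dropped(self):
        tab = self.make_table([1.0, 1.1, 0.9], [0.2, 0.1, 0.3])
        tab.loc[0, "ct_reference"] = np.nan
        with pytest.warns(UserWarning, match="missing Ct"):
            out = mk.delta_ct(tab)
        assert len(out["delta_ct"]) == 5


class TestGroupTLogCounts:
    def make_counts(self, rng, n_genes=30, shift_first=1.0, n=20):
        samples = [f"s{i}" for i in range(2 * n)]
        groups = pd.Series(["a"] * n + ["b"] * n, index=samples)
        base = rng.lognormal(5, 0.5, (n_genes, 1))
        counts = base * rng.lognormal(0, 0.1, (n_genes, 2 * n))
        counts[0, n:] *= np.exp(shift_first)
        return pd.DataFrame(counts, columns=samples), groups

    def test_all_zero_gene_flagged(self, rng):
        counts, groups = self.make_counts(rng)
        counts.iloc[1] = 0.0
        res = mk.group_t_log_counts(counts, groups)
        assert np.isnan(res["p"].iloc[1])
        assert bool(res["degenerate"].iloc[1])

    def test_planted_fourfold_shift_detected(self):
        """A 4-fold shift at dispersion 0.1 reaches p < 0.01 in >= 95% of sims."""
        hits = 0
        n_sims = 50
        for s in range(n_sims):
            rng = np.random.default_rng(s)
            counts, groups = self.make_counts(rng, shift_first=np.log(4.0))
            res = mk.group_t_log_counts(counts, groups)
            hits += res["p"].iloc[0] < 0.01
        assert hits >= int(0.95 * n_sims)

    def test_pseudo_count_invariance_for_high_counts(self, rng):
        counts, groups = self.make_counts(rng)
        p1 = mk.group_t_log_counts(counts, groups, pseudo=1.0)["p"]
        p2 = mk.group_t_log_counts(counts, groups, pseudo=2.0)["p"]
        assert np.nanmax(np.abs(p1 - p2)) < 0.05

    def test_negative_counts_rejected(self, rng):
        counts, groups = self.make_counts(rng)
        counts.iloc[0, 0] = -1.0
        with pytest.raises(ValueError):
            mk.group_t_log_counts(counts, groups)
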