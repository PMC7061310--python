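"""Cohort statistics: differential tests, Me/CNA features, MLR, survival."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codon_sda.cohort import (
    benjamini_hochberg,
    coefficient_sign_test,
    differential,
    fit_isoacceptor_mlr,
    gene_cna,
    promoter_methylation,
    select_survival_candidates,
    survival_by_sdaw,
    survival_scan,
)
from codon_sda.reference import TRNAGene
from codon_sda.simulate import SimulationConfig, simulate_mlr_cohort, simulate_survival


def _gene(gene_id="g1", start=5000, end=5072, strand="+", anticodon="AGG"):
    return TRNAGene(gene_id, "chr1", start, end, strand, "Pro", anticodon)


class TestDifferential:
    def test_identical_groups(self):
        m = pd.DataFrame({"f": [1.0, 2, 3, 1, 2, 3]})
        res = differential(m, ["a"] * 3 + ["b"] * 3, "a", "b")
        assert res.loc["f", "log2fc"] == 0.0
        assert res.loc["f", "p"] > 0.5

    def test_degenerate_constant_feature_flagged(self):
        m = pd.DataFrame({"f": [2.0] * 8})
        res = differential(m, ["a"] * 4 + ["b"] * 4, "a", "b")
        assert res.loc["f", "p"] == 1.0 and res.loc["f", "degenerate"]

    def test_large_shift_detected(self):
        rng = np.random.default_rng(8)
        base = rng.lognormal(0, 0.2, 50)
        m = pd.DataFrame({"f": np.concatenate([base, base * 4])})
        res = differential(m, ["a"] * 50 + ["b"] * 50, "a", "b")
        assert res.loc["f", "q"] < 0.05 and res.loc["f", "log2fc"] > 0

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 1, 8)
        res = differential(
            pd.DataFrame({"f": np.concatenate([a, b])}), ["a"] * 8 + ["b"] * 8, "a", "b"
        )
        # oracle: permutation distribution of the rank-sum statistic
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        obs = ranks[:8].sum()
        n_perm = 20000
        stat = np.array(
            [ranks[rng.permutation(16)[:8]].sum() for _ in range(n_perm)]
        )
        p_perm = np.mean(np.abs(stat - ranks.sum() / 2) >= abs(obs - ranks.sum() / 2))
        assert res.loc["f", "p"] == pytest.approx(p_perm, abs=0.02)

    def test_label_swap_negates_log2fc_and_preserves_p(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame({"f": rng.lognormal(0, 0.5, 40)})
        groups = ["a"] * 20 + ["b"] * 20
        r1 = differential(m, groups, "a", "b")
        r2 = differential(m, groups, "b", "a")
        assert r1.loc["f", "log2fc"] == pytest.approx(-r2.loc["f", "log2fc"])
        assert r1.loc["f", "p"] == pytest.approx(r2.loc["f", "p"])

    def test_bh_hand_example(self):
        q = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bh_matches_bruteforce_definition(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            p = rng.uniform(0, 1, 37)
            order = np.argsort(p)
            m = len(p)
            q_sorted = np.minimum.accumulate(
                (p[order] * m / np.arange(1, m + 1))[::-1]
            )[::-1]
            brute = np.empty(m)
            brute[order] = np.minimum(q_sorted, 1.0)
            assert benjamini_hochberg(p) == pytest.approx(brute)


class TestMethylationWindow:
    def _betas(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "beta"])

    def test_window_mean(self):
        g = _gene()
        betas = self._betas([("chr1", 4000, 0.2), ("chr1", 5050, 0.4)])
        per_gene, per_iso, cov = promoter_methylation([g], betas)
        assert per_gene["g1"] == pytest.approx(0.3)
        assert per_iso["AGG"] == pytest.approx(0.3)
        assert cov == 1.0

    def test_minus_strand_window_is_downstream_on_plus_axis(self):
        g = _gene(strand="-")
        # 1 kb 3' of the gene end on the + axis is upstream of the minus-strand TSS
        betas = self._betas([("chr1", 6072, 0.8)])
        per_gene, _, _ = promoter_methylation([g], betas)
        assert per_gene["g1"] == pytest.approx(0.8)
        # and the same probe is outside a + strand gene's window
        per_gene_plus, _, _ = promoter_methylation([_gene(strand="+")], betas)
        assert np.isnan(per_gene_plus["g1"])

    def test_bisulfite_mode_restricts_to_gene_body(self):
        g = _gene()
        betas = self._betas([("chr1", 4000, 0.9), ("chr1", 5010, 0.1)])
        per_gene, _, _ = promoter_methylation([g], betas, mode="bisulfite")
        assert per_gene["g1"] == pytest.approx(0.1)

    def test_no_positions_gives_missing_and_coverage(self):
        per_gene, _, cov = promoter_methylation(
            [_gene("g1"), _gene("g2", start=9000, end=9072)],
            self._betas([("chr1", 5010, 0.5)]),
        )
        assert np.isnan(per_gene["g2"]) and cov == 0.5

    def test_isoacceptor_average_over_member_genes(self):
        genes = [_gene("g1"), _gene("g2", start=9000, end=9072)]
        betas = self._betas([("chr1", 5010, 0.2), ("chr1", 9010, 0.6)])
        _, per_iso, _ = promoter_methylation(genes, betas)
        assert per_iso["AGG"] == pytest.approx(0.4)


class TestCNA:
    def _segments(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    def test_gene_inside_one_segment(self):
        segs = self._segments([("chr1", 0, 10000, 0.5)])
        per_gene, _ = gene_cna([_gene()], segs)
        assert per_gene["g1"] == pytest.approx(0.5)

    def test_split_gene_overlap_weighted(self):
        g = _gene(start=5000, end=5100)
        segs = self._segments([("chr1", 0, 5030, 0.0), ("chr1", 5030, 9000, 1.0)])
        per_gene, _ = gene_cna([g], segs)
        assert per_gene["g1"] == pytest.approx(0.7)

    def test_no_overlap_is_missing(self):
        per_gene, _ = gene_cna([_gene()], self._segments([("chr2", 0, 100, 1.0)]))
        assert np.isnan(per_gene["g1"])


class TestMLR:
    def test_noiseless_exact_recovery(self):
        cfg = SimulationConfig(
            seed=31, n_conditions=1, n_isoacceptors=2, regression_truth=(2, -3, 1.5, 0.0)
        )
        res = fit_isoacceptor_mlr(simulate_mlr_cohort(cfg))
        assert (~res["skipped"]).all()
        assert res["beta0"].to_numpy() == pytest.approx(2.0, abs=1e-9)
        assert res["beta_me"].to_numpy() == pytest.approx(-3.0, abs=1e-9)
        assert res["beta_cna"].to_numpy() == pytest.approx(1.5, abs=1e-9)
        assert res["r2"].to_numpy() == pytest.approx(1.0)

    def test_constant_regressor_skipped(self):
        df = pd.DataFrame(
            {
                "isoacceptor": ["AAA"] * 10,
                "condition": ["c"] * 10,
                "me": [0.5] * 10,
                "cna": np.linspace(-1, 1, 10),
                "abundance": np.linspace(0, 1, 10),
            }
        )
        res = fit_isoacceptor_mlr(df)
        assert res["skipped"].all()

    def test_insufficient_samples_skipped(self):
        df = pd.DataFrame(
            {
                "isoacceptor": ["AAA"] * 3,
                "condition": ["c"] * 3,
                "me": [0.1, 0.5, 0.9],
                "cna": [0.2, -0.1, 0.4],
                "abundance": [1.0, 2.0, 3.0],
            }
        )
        assert fit_isoacceptor_mlr(df)["skipped"].all()

    def test_ci_coverage_at_moderate_noise(self):
        # 95% CIs should contain each true coefficient in >= 90% of replicates
        import statsmodels.api as sm

        rng = np.random.default_rng(55)
        truth = {"me": -3.0, "cna": 1.5}
        hits = {"me": 0, "cna": 0}
        n_rep = 100
        for _ in range(n_rep):
            me = rng.uniform(0, 1, 100)
            cna = rng.normal(0, 0.5, 100)
            y = 2.0 + truth["me"] * me + truth["cna"] * cna + rng.normal(0, 0.1, 100)
            X = sm.add_constant(pd.DataFrame({"me": me, "cna": cna}))
            ci = sm.OLS(y, X).fit().conf_int(alpha=0.05)
            for k in truth:
                if ci.loc[k, 0] <= truth[k] <= ci.loc[k, 1]:
                    hits[k] += 1
        assert hits["me"] >= 0.9 * n_rep and hits["cna"] >= 0.9 * n_rep

    def test_bias_shrinks_with_sample_size(self):
        errs = {}
        for n in (100, 1000):
            rng = np.random.default_rng(77)
            me = rng.uniform(0, 1, n)
            cna = rng.normal(0, 0.5, n)
            y = 2.0 - 3.0 * me + 1.5 * cna + rng.normal(0, 0.5, n)
            df = pd.DataFrame(
                {
                    "isoacceptor": "AAA",
                    "condition": "c",
                    "me": me,
                    "cna": cna,
                    "abundance": y,
                }
            )
            res = fit_isoacceptor_mlr(df)
            errs[n] = abs(res["beta_me"].iloc[0] + 3.0)
        assert errs[1000] < errs[100]


class TestSignTest:
    def _results(self, signs_me):
        n = len(signs_me)
        return pd.DataFrame(
            {
                "skipped": [False] * n,
                "beta_me": signs_me,
                "q_me": [0.01] * n,
                "beta_cna": [1.0] * n,
                "q_cna": [0.01] * n,
            }
        )

    def test_exact_binomial_values(self):
        p, n_pos, n_neg = coefficient_sign_test(self._results([1] * 8 + [-1] * 2), "me")
        assert (n_pos, n_neg) == (8, 2)
        assert p == pytest.approx(0.109375)
        p, *_ = coefficient_sign_test(self._results([1] * 5 + [-1] * 5), "me")
        assert p == pytest.approx(1.0)
        p, *_ = coefficient_sign_test(self._results([1] * 10), "me")
        assert p == pytest.approx(2 * 0.5**10)

    def test_no_significant_coefficients_flagged(self):
        res = self._results([1.0])
        res["q_me"] = 0.9
        p, n_pos, n_neg = coefficient_sign_test(res, "me")
        assert np.isnan(p) and n_pos == n_neg == 0


class TestSurvival:
    def _clinical(self, times, events):
        idx = [f"p{i}" for i in range(len(times))]
        return pd.DataFrame({"time": times, "event": events}, index=idx)

    def test_km_product_limit_by_hand(self):
        clin = self._clinical([1.0, 2.0, 3.0, 5.0, 6.0], [1, 1, 1, 1, 1])
        values = pd.Series([0.1, 0.2, 0.3, 0.8, 0.9], index=clin.index)
        res = survival_by_sdaw(values, clin, fraction=0.4)
        # low group = 2 lowest scores; its KM drops 1/2 then 0
        km = dict(zip(res.km_low["time"], res.km_low["survival"]))
        assert km[1.0] == pytest.approx(0.5) and km[2.0] == pytest.approx(0.0)

    def test_km_matches_closed_form_with_censoring(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(19)
        times = rng.exponential(10, 60)
        events = rng.integers(0, 2, 60)
        kmf = KaplanMeierFitter().fit(times, events)
        # oracle: direct product over event times
        order = np.argsort(times, kind="stable")
        t_sorted, e_sorted = times[order], events[order]
        surv = 1.0
        expected = {}
        for i, (t, e) in enumerate(zip(t_sorted, e_sorted)):
            at_risk = np.sum(t_sorted >= t)
            if e:
                d = np.sum((t_sorted == t) & (e_sorted == 1))
                if t not in expected:
                    surv *= 1 - d / at_risk
                    expected[t] = surv
        for t, s in expected.items():
            assert kmf.predict(t) == pytest.approx(s)

    def test_no_event_group_curve_is_one(self):
        clin = self._clinical([1, 2, 3, 4, 5], [0, 0, 0, 1, 1])
        values = pd.Series([0.1, 0.2, 0.3, 0.8, 0.9], index=clin.index)
        res = survival_by_sdaw(values, clin, fraction=0.4)
        assert (res.km_low["survival"] == 1.0).all()

    def test_identical_groups_logrank_p_near_one(self):
        clin = self._clinical([1, 2, 3, 1, 2, 3, 9, 9], [1, 1, 1, 1, 1, 1, 0, 0])
        values = pd.Series([0.1, 0.2, 0.3, 0.7, 0.8, 0.9, 0.5, 0.5], index=clin.index)
        res = survival_by_sdaw(values, clin, fraction=0.375)
        assert res.logrank_p > 0.9

    def test_empty_group_errors(self):
        clin = self._clinical([1.0], [1])
        with pytest.raises(ValueError):
            survival_by_sdaw(pd.Series([1.0], index=clin.index), clin, fraction=0.4)

    def test_hazard_ratio_three_gives_significant_logrank(self):
        hits = 0
        n_rep = 40
        for r in range(n_rep):
            sdaw, clin = simulate_survival(SimulationConfig(seed=1000 + r))
            res = survival_by_sdaw(sdaw, clin, fraction=0.4)
            hits += res.logrank_p < 0.01
        assert hits >= 0.95 * n_rep

    def test_candidate_selection_and_scan(self):
        rows = []
        for cond in range(10):
            rows.append({"feature": "CCA", "condition": cond, "log2fc": 1.0, "q": 0.01})
            rows.append({"feature": "GGG", "condition": cond, "log2fc": (-1) ** cond, "q": 0.01})
        cands = select_survival_candidates(pd.DataFrame(rows), min_net=5)
        assert cands == ["CCA"]
        rng = np.random.default_rng(2)
        idx = [f"p{i}" for i in range(60)]
        mat = pd.DataFrame({"CCA": rng.lognormal(0, 0.3, 60)}, index=idx)
        clin = pd.DataFrame(
            {"time": rng.exponential(10, 60), "event": 1}, index=idx
        )
        scan = survival_scan(mat, clin, cands)
        assert set(scan.index) == {"CCA"} and "q" in scan
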