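"""Plot-level preprocessing: splitting, outliers, BLUEs, parent inference,
VanRaden GRM."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from metfactor.prep import (assemble_trait_matrix, fit_blues, filter_outliers,
                            filter_sites, flag_outliers,
                            infer_parent_genotypes, split_experiments,
                            vanraden_grm)


def plot_table(rows):
    return pd.DataFrame(rows, columns=["trial", "tester", "hybrid", "P1",
                                       "replicate", "block", "value"])


class TestSplitExperiments:
    def _plots(self, n_a=60, n_b=40, reps=1):
        rows = []
        for tester, n in (("A", n_a), ("B", n_b)):
            for h in range(n):
                for r in range(reps):
                    rows.append(("LOC_2020", tester, f"{tester}h{h}",
                                 f"p{h}", r, 0, float(h)))
        return plot_table(rows)

    def test_threshold_on_distinct_hybrids(self):
        out = split_experiments(self._plots(), min_hybrids=50)
        assert list(out) == [("LOC_2020", "A")]

    def test_no_filter_limit(self):
        out = split_experiments(self._plots(), min_hybrids=1)
        assert len(out) == 2

    def test_counts_genotypes_not_plots(self):
        # 60 hybrids × 2 reps = 120 plots still counts as 60
        out = split_experiments(self._plots(n_a=60, n_b=40, reps=2),
                                min_hybrids=60)
        assert list(out) == [("LOC_2020", "A")]


class TestOutliers:
    def test_hand_computed_example(self):
        """(1,2,3,4,100): expected count for 100 is 5·2(1−Φ(78/43.62)) ≈ 0.37
        < 1 → flagged; the others are not."""
        v = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        z = abs(100 - v.mean()) / v.std(ddof=1)
        assert 5 * 2 * norm.sf(z) == pytest.approx(0.37, abs=0.01)
        mask = flag_outliers(v)
        assert mask.tolist() == [False, False, False, False, True]

    def test_no_extremes_none_flagged(self):
        rng = np.random.default_rng(0)
        v = np.clip(rng.standard_normal(10), -1, 1)
        assert not flag_outliers(v).any()

    def test_zero_sd_flags_nothing(self):
        assert not flag_outliers(np.full(5, 2.0)).any()

    def test_criterion_threshold_is_exact(self):
        """Nothing is flagged when all |z| < z* solving m·2(1−Φ(z*)) = 1."""
        m = 20
        z_star = norm.isf(1.0 / (2 * m))
        rng = np.random.default_rng(1)
        v = rng.standard_normal(m)
        z = np.abs(v - v.mean()) / v.std(ddof=1)
        assert flag_outliers(v).any() == bool((z > z_star).any())

    def test_m_dependence_documented(self):
        """Duplicating a dataset can newly flag a borderline point (criterion
        is monotone in m)."""
        base = np.array([0.0, 0.1, -0.1, 0.2, -0.2, 2.2])
        doubled = np.concatenate([base, base])
        assert flag_outliers(base).sum() <= flag_outliers(doubled).sum()

    def test_two_level_filter_removes_outlying_experiment(self):
        exps = {}
        rng = np.random.default_rng(2)
        for i in range(10):
            shift = 100.0 if i == 0 else 0.0
            exps[("t", f"T{i}")] = plot_table(
                [("t", f"T{i}", f"h{j}", f"p{j}", 0, 0,
                  shift + rng.standard_normal()) for j in range(20)])
        out = filter_outliers(exps)
        assert ("t", "T0") not in out and len(out) == 9


class TestBlues:
    def _balanced(self, rep_effect=0.0, seed=0, n_h=5, n_rep=2):
        rng = np.random.default_rng(seed)
        rows = []
        for h in range(n_h):
            for r in range(n_rep):
                rows.append(("t", "T", f"h{h}", f"p{h}", r, 0,
                             h * 1.0 + rep_effect * r))
        return plot_table(rows)

    def test_balanced_no_rep_effect_equals_means(self):
        blues = fit_blues(self._balanced())
        np.testing.assert_allclose(blues.to_numpy(),
                                   np.arange(5.0) + 0.0, atol=1e-10)

    def test_additive_rep_effect_removed_in_balance(self):
        b0 = fit_blues(self._balanced(rep_effect=0.0))
        b1 = fit_blues(self._balanced(rep_effect=1.0))
        # marginal means shift by the average rep effect, differences don't
        np.testing.assert_allclose(b1.to_numpy() - b0.to_numpy(),
                                   np.full(5, 0.5), atol=1e-10)
        np.testing.assert_allclose(np.diff(b1.to_numpy()),
                                   np.diff(b0.to_numpy()), atol=1e-10)

    def test_single_rep_multi_block_runs(self):
        rng = np.random.default_rng(3)
        rows = []
        for h in range(20):
            blk = h % 4
            rows.append(("t", "T", f"h{h}", f"p{h}", 0, blk,
                         h * 0.1 + 0.5 * blk + 0.01 * rng.standard_normal()))
        blues = fit_blues(plot_table(rows))
        assert len(blues) == 20 and np.isfinite(blues).all()

    def test_block_variance_recovered_by_reml(self):
        """Simulated block variance: the REML estimate is within ±30% of
        truth on average over replicates."""
        from metfactor.prep import _reml_block_ratio
        rng = np.random.default_rng(4)
        ratios = []
        true_ratio = 4.0                      # σ²_block / σ²_e
        for _ in range(20):
            n_h, n_rep, n_blk = 50, 2, 5   # 200 plots, 10 block effects
            rows = []
            for r in range(n_rep):
                b_eff = rng.standard_normal(n_blk) * np.sqrt(true_ratio)
                for h in range(n_h):
                    blk = h % n_blk
                    rows.append(("t", "T", f"h{h}", f"p{h}", r, blk,
                                 b_eff[blk] + rng.standard_normal() * 1.0))
            sub = plot_table(rows)
            X_h = pd.get_dummies(sub["hybrid"]).to_numpy(dtype=float)
            X_r = pd.get_dummies(sub["replicate"], drop_first=True
                                 ).to_numpy(dtype=float)
            rb = sub["replicate"].astype(str) + ":" + sub["block"].astype(str)
            Z = pd.get_dummies(rb).to_numpy(dtype=float)
            ratios.append(_reml_block_ratio(
                sub["value"].to_numpy(), np.hstack([X_h, X_r]), Z))
        assert abs(np.mean(ratios) - true_ratio) / true_ratio < 0.3


class TestAssemble:
    def test_crossed_layout(self):
        blues = {("L_2020", "A"): pd.Series({"h1": 1.0, "h2": 2.0}),
                 ("L_2020", "B"): pd.Series({"h3": 3.0, "h4": 4.0})}
        p1_of = {"h1": "p1", "h2": "p2", "h3": "p1", "h4": "p2"}
        tm = assemble_trait_matrix(blues, p1_of)
        assert tm.values.shape == (2, 2)
        assert tm.observed_mask.all()
        assert tm.col_meta.loc[tm.col_ids[0], "tester"] == "A"

    def test_absent_p1_is_missing(self):
        blues = {("L_2020", "A"): pd.Series({"h1": 1.0}),
                 ("L_2020", "B"): pd.Series({"h3": 3.0, "h4": 4.0})}
        p1_of = {"h1": "p1", "h3": "p1", "h4": "p2"}
        tm = assemble_trait_matrix(blues, p1_of)
        assert (~tm.observed_mask).sum() == 1

    def test_duplicate_blue_raises(self):
        blues = {("L_2020", "A"): pd.Series({"h1": 1.0, "h2": 2.0})}
        p1_of = {"h1": "p1", "h2": "p1"}   # two hybrids, same P1, same exp
        with pytest.raises(ValueError, match="duplicate"):
            assemble_trait_matrix(blues, p1_of)


class TestParentInference:
    def _run(self, dosages, testers):
        hyb = pd.DataFrame(np.array(dosages, dtype=float),
                           index=[f"h{i}" for i in range(len(dosages))],
                           columns=["s1"])
        tester_of = {f"h{i}": t for i, t in enumerate(testers)}
        return infer_parent_genotypes(hyb, tester_of)

    def test_homozygous_hybrid_sets_both_parents(self):
        p1, t, _ = self._run([[2], [2]], ["T1", "T1"])
        assert p1.loc["h0", "s1"] == 2 and t.loc["T1", "s1"] == 2

    def test_het_with_zero_sibling(self):
        """(1, 0) same tester → tester 0, focal P1 2."""
        p1, t, _ = self._run([[1], [0]], ["T1", "T1"])
        assert t.loc["T1", "s1"] == 0
        assert p1.loc["h0", "s1"] == 2
        assert p1.loc["h1", "s1"] == 0

    def test_het_without_zero_sibling(self):
        """No 0 anywhere: tester takes the alternate homozygote, P1 gets 0."""
        p1, t, _ = self._run([[1], [1]], ["T1", "T1"])
        assert t.loc["T1", "s1"] == 2
        assert p1.loc["h0", "s1"] == 0

    def test_trio_conflict_sets_missing(self):
        """(1, 0, 2) same tester: irreconcilable → focal parents missing."""
        p1, t, conflicts = self._run([[1], [0], [2]], ["T1", "T1", "T1"])
        assert np.isnan(p1.loc["h0", "s1"])
        assert np.isnan(t.loc["T1", "s1"])
        assert p1.loc["h1", "s1"] == 0 and p1.loc["h2", "s1"] == 2
        assert len(conflicts) == 1

    def test_unreplicated_tester_dropped(self):
        p1, t, _ = self._run([[2], [0], [0]], ["T1", "T2", "T2"])
        assert "h0" not in p1.index

    def test_self_consistency_on_simulated_crosses(self):
        """Non-conflicting hybrid dosages equal the average of the two
        inferred parental dosages."""
        rng = np.random.default_rng(5)
        n_p1, n_sites = 8, 40
        tester_geno = rng.choice([0, 2], size=n_sites)
        p1_geno = rng.choice([0, 2], size=(n_p1, n_sites))
        hyb = (p1_geno + tester_geno[None, :]) / 2
        hyb_df = pd.DataFrame(hyb, index=[f"h{i}" for i in range(n_p1)],
                              columns=[f"s{j}" for j in range(n_sites)])
        p1, t, conflicts = infer_parent_genotypes(
            hyb_df, {f"h{i}": "T1" for i in range(n_p1)})
        recon = (p1.to_numpy() + t.loc["T1"].to_numpy()[None, :]) / 2
        ok = np.isfinite(p1.to_numpy())
        np.testing.assert_allclose(recon[ok], hyb[ok])


class TestVanRaden:
    def test_two_individual_toy(self):
        """Dosages (0, 2) at one site, p=0.5 → G = [[2,−2],[−2,2]]."""
        G = vanraden_grm(np.array([[0.0], [2.0]]), ids=["a", "b"])
        np.testing.assert_allclose(G.matrix, [[2.0, -2.0], [-2.0, 2.0]])

    def test_identical_individuals(self):
        M = np.array([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0], [2.0, 1.0, 0.0]])
        G = vanraden_grm(M)
        assert G.matrix[0, 0] == pytest.approx(G.matrix[1, 1])
        assert G.matrix[0, 1] == pytest.approx(G.matrix[0, 0])

    def test_symmetric_psd(self):
        rng = np.random.default_rng(6)
        M = rng.choice([0, 1, 2], size=(12, 50)).astype(float)
        G = vanraden_grm(M)
        assert G.is_symmetric()
        assert G.min_eigenvalue() > -1e-8

    def test_mean_diagonal_near_one_under_hardy_weinberg(self):
        rng = np.random.default_rng(7)
        diags = []
        for _ in range(10):
            p = rng.uniform(0.1, 0.9, 300)
            M = rng.binomial(2, p[None, :], size=(40, 300)).astype(float)
            diags.append(np.mean(np.diag(vanraden_grm(M).matrix)))
        se = np.std(diags, ddof=1) / np.sqrt(10)
        assert abs(np.mean(diags) - 1.0) < 3 * se + 0.02

    def test_site_filter(self):
        df = pd.DataFrame({"s1": [0, 0, 0, 2], "s2": [0, 0, 0, 0],
                           "s3": [1, np.nan, np.nan, np.nan]},
                          index=list("abcd"), dtype=float)
        kept = filter_sites(df, maf_min=0.05, max_missing=0.5)
        assert list(kept.columns) == ["s1"]
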