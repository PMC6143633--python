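"""Fold-changes, group tests, BH correction, and cohort-level contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from msinmd.decay_stats import (
    NMD_FACTORS,
    QPCRMeasurement,
    benjamini_hochberg,
    compare_factor_expression,
    decay_test_table,
    group_test,
    inhibition_response_ratio,
    le_nle_contrast,
    log2_fold_change,
    relative_expression,
    select_downregulated,
)


def _expr(data, samples):
    return pd.DataFrame(data, index=[f"g{i}" for i in range(len(data))], columns=samples)


def _meta(groups, treatments=None, pairs=None):
    idx = list(groups)
    return pd.DataFrame(
        {
            "group": list(groups.values()),
            "treatment": treatments or ["UNTREATED"] * len(idx),
            "pair_id": pairs or [""] * len(idx),
        },
        index=pd.Index(idx, name="sample_id"),
    )


def hand_bh(p):
    """Independent BH step-up: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(p, float)
    order = np.argsort(p, kind="stable")
    n = len(p)
    q_sorted = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


class TestFoldChange:
    def test_identical_groups_give_zero(self):
        e = _expr([[7, 7, 7, 7]], ["a1", "a2", "b1", "b2"])
        assert log2_fold_change(e, "g0", ["a1", "a2"], ["b1", "b2"]) == 0.0

    def test_mean_difference(self):
        e = _expr([[7.0, 7.0, 8.0, 8.0]], ["a1", "a2", "b1", "b2"])
        assert log2_fold_change(e, "g0", ["a1", "a2"], ["b1", "b2"]) == -1.0

    def test_matches_hand_computed_means(self, rng):
        vals = rng.normal(8, 1, 10)
        e = _expr([vals], [f"s{i}" for i in range(10)])
        a, b = [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 10)]
        expected = vals[:4].mean() - vals[4:].mean()
        assert log2_fold_change(e, "g0", a, b) == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry(self, rng):
        vals = rng.normal(8, 1, 8)
        e = _expr([vals], [f"s{i}" for i in range(8)])
        a, b = [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]
        assert log2_fold_change(e, "g0", a, b) == pytest.approx(
            -log2_fold_change(e, "g0", b, a), abs=1e-12
        )

    def test_empty_group_rejected(self):
        e = _expr([[1, 2]], ["a", "b"])
        with pytest.raises(ValueError):
            log2_fold_change(e, "g0", [], ["a"])


class TestGroupTest:
    def test_clear_separation(self):
        e = _expr([[0, 0, 0, 1, 1 + 1e-9, 1 - 1e-9]], list("abcdef"))
        _, p = group_test(e, "g0", [list("abc"), list("def")])
        assert p < 1e-3

    def test_matches_textbook_welch_formula(self):
        a = np.array([4.2, 5.1, 6.3, 5.5])
        b = np.array([7.0, 6.1, 8.2, 7.4, 6.9])
        e = _expr([np.concatenate([a, b])], [f"s{i}" for i in range(9)])
        t, p = group_test(e, "g0", [[f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 9)]])
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert t == pytest.approx((a.mean() - b.mean()) / se, rel=1e-12)

    def test_null_rejection_rate_is_nominal(self, rng):
        # 1000 null replicates, 6 vs 6 samples; rate at alpha=.05 must sit
        # within +-2 binomial SE of the nominal level
        rej = 0
        samples = [f"s{i}" for i in range(12)]
        ga, gb = samples[:6], samples[6:]
        for _ in range(1000):
            e = _expr([rng.normal(0, 1, 12)], samples)
            _, p = group_test(e, "g0", [ga, gb])
            rej += p < 0.05
        assert abs(rej / 1000 - 0.05) <= 0.014

    def test_anova_path_for_three_groups(self, rng):
        e = _expr([np.r_[rng.normal(0, 1, 4), rng.normal(0, 1, 4), rng.normal(3, 1, 4)]],
                  [f"s{i}" for i in range(12)])
        groups = [[f"s{i}" for i in range(j, j + 4)] for j in (0, 4, 8)]
        stat, p = group_test(e, "g0", groups)
        assert p < 0.01

    def test_degenerate_equal_constant_groups(self):
        e = _expr([[5, 5, 5, 5]], list("abcd"))
        assert group_test(e, "g0", [["a", "b"], ["c", "d"]]) == (0.0, 1.0)

    def test_single_sample_group_rejected(self):
        e = _expr([[1, 2, 3]], list("abc"))
        with pytest.raises(ValueError):
            group_test(e, "g0", [["a"], ["b", "c"]])


class TestBenjaminiHochberg:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.9]), [0.03, 0.03, 0.9]
        )

    def test_all_equal_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2] * 5), [0.2] * 5)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.37]), [0.37])

    def test_matches_independent_step_up_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            np.testing.assert_allclose(benjamini_hochberg(p), hand_bh(p), atol=1e-12)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(0, 1, 25)
        q = benjamini_hochberg(p)
        for _ in range(5):
            perm = rng.permutation(25)
            np.testing.assert_allclose(benjamini_hochberg(p[perm]), q[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.2])


def _results_frame(fc_nle, fc_le, q=None):
    fcs = np.concatenate([fc_nle, fc_le])
    n = len(fcs)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "log2_fc": fcs,
            "t_stat": 0.0,
            "p_value": 0.5,
            "q_value": q if q is not None else np.full(n, 0.5),
            "location_class": ["NLE"] * len(fc_nle) + ["LE"] * len(fc_le),
            "nmd_class": "SUBSTRATE",
            "passes_downregulation_filter": False,
        }
    )


class TestLeNleContrast:
    def test_power_under_injected_decay(self, rng):
        # NLE fold-changes shifted by -1.0 vs LE, n=60/30, sd 0.5: the
        # contrast must reach p < 0.001 in at least 95 of 100 seeds
        hits = 0
        for _ in range(100):
            res = _results_frame(rng.normal(-1, 0.5, 60), rng.normal(0, 0.5, 30))
            c = le_nle_contrast(res)
            hits += (c.p_value < 1e-3) and (c.statistic < 0)
        assert hits >= 95

    def test_null_rejection_rate_nominal(self, rng):
        rej = 0
        n = 1000
        for _ in range(n):
            res = _results_frame(rng.normal(0, 0.5, 60), rng.normal(0, 0.5, 30))
            rej += le_nle_contrast(res).p_value < 0.05
        # 3 binomial SE band around the nominal level
        assert abs(rej / n - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n)

    def test_degenerate_two_gene_input_rejected(self):
        res = _results_frame([-1.0], [0.0])
        with pytest.raises(ValueError):
            le_nle_contrast(res)

    def test_missing_class_error_names_it(self):
        res = _results_frame([-1.0, -0.5, 0.1], [])
        with pytest.raises(ValueError, match="LE"):
            le_nle_contrast(res)


class TestSelectDownregulated:
    def test_boundary_fc_excluded(self):
        res = _results_frame([-0.5, -0.6], [0.0, 0.0], q=np.array([0.001] * 4))
        assert select_downregulated(res) == ["g1"]

    def test_no_downregulation_gives_empty_list(self):
        res = _results_frame([0.2, 0.0], [0.4, 0.1], q=np.array([0.001] * 4))
        assert select_downregulated(res) == []

    def test_matches_independent_filter(self, rng):
        fc = rng.normal(-0.5, 0.5, 80)
        q = rng.uniform(0, 0.2, 80)
        res = _results_frame(fc[:60], fc[60:], q=q)
        expected = sorted(
            (res.loc[(q < 0.05) & (fc < -0.5), "gene_id"]),
            key=lambda g: (fc[int(g[1:])], g),
        )
        assert select_downregulated(res) == expected

    def test_null_false_positive_rate_bounded(self, rng):
        # with no decay effect the filter admits on average <= alpha * n genes
        counts = []
        for _ in range(50):
            n = 100
            t = rng.standard_t(20, n)  # null-ish statistics
            p = 2 * sps.t.sf(np.abs(t), 20)
            res = _results_frame(rng.normal(0, 0.3, n), [], q=None)
            res = res.iloc[:n].copy()
            res["q_value"] = benjamini_hochberg(p)
            counts.append(len(select_downregulated(res)))
        assert np.mean(counts) <= 0.05 * 100


class TestFactorComparison:
    def _factor_matrix(self, rng, shift_upf1=0.0, shift_upf3a=0.0):
        msi = [f"MSI_{i}" for i in range(20)]
        mss = [f"MSS_{i}" for i in range(20)]
        data = rng.normal(8, 0.5, (len(NMD_FACTORS), 40))
        e = pd.DataFrame(data, index=list(NMD_FACTORS), columns=msi + mss)
        e.loc["UPF1", msi] += shift_upf1
        e.loc["UPF3A", msi] += shift_upf3a
        meta = _meta({s: "MSI" for s in msi} | {s: "MSS" for s in mss})
        return e, meta

    def test_injected_shifts_recovered_with_signs(self, rng):
        e, meta = self._factor_matrix(rng, shift_upf1=1.0, shift_upf3a=-1.0)
        out = compare_factor_expression(e, meta).set_index("factor")
        assert out.loc["UPF1", "log2_fc"] > 0 and out.loc["UPF1", "q_value"] < 0.05
        assert out.loc["UPF3A", "log2_fc"] < 0 and out.loc["UPF3A", "q_value"] < 0.05

    def test_null_rarely_significant(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            e, meta = self._factor_matrix(rng)
            out = compare_factor_expression(e, meta)
            hits += (out["q_value"] < 0.05).any()
        assert hits <= 0.1 * n_seeds  # >=90% of seeds clean

    def test_missing_factor_gets_na_row(self, rng):
        e, meta = self._factor_matrix(rng)
        e = e.drop(index="SMG6")
        out = compare_factor_expression(e, meta).set_index("factor")
        assert np.isnan(out.loc["SMG6", "log2_fc"])
        assert out.drop(index="SMG6")["q_value"].notna().all()


class TestQpcr:
    def test_equal_ct_is_unity(self):
        assert relative_expression(QPCRMeasurement(22.0, 22.0)) == 1.0

    def test_one_cycle_halves_expression(self):
        assert relative_expression(QPCRMeasurement(23.0, 22.0)) == 0.5

    def test_table_matches_hand_computation(self, rng):
        for _ in range(10):
            tgt, ref = rng.uniform(18, 30), rng.uniform(18, 30)
            assert relative_expression(QPCRMeasurement(tgt, ref)) == pytest.approx(
                2.0 ** -(tgt - ref), rel=1e-12
            )

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            relative_expression(QPCRMeasurement(np.nan, 22.0))


class TestInhibitionRatio:
    def test_treated_equals_untreated_gives_unity(self):
        e = _expr([[8, 8], [5, 5]], ["u1", "t1"])
        meta = _meta(
            {"u1": "MSI", "t1": "MSI"},
            treatments=["UNTREATED", "NMD_INHIBITED"],
            pairs=["p1", "p1"],
        )
        ratios = inhibition_response_ratio(e, meta)
        assert (ratios == 1.0).all()

    def test_single_pair_hand_values(self):
        e = _expr([[8.0, 9.0]], ["u1", "t1"])
        meta = _meta(
            {"u1": "MSI", "t1": "MSI"},
            treatments=["UNTREATED", "NMD_INHIBITED"],
            pairs=["p1", "p1"],
        )
        assert inhibition_response_ratio(e, meta).iloc[0] == pytest.approx(2.0)

    def test_unpaired_sample_error_names_it(self):
        e = _expr([[8, 9, 7]], ["u1", "t1", "odd"])
        meta = _meta(
            {"u1": "MSI", "t1": "MSI", "odd": "MSI"},
            treatments=["UNTREATED", "NMD_INHIBITED", "NMD_INHIBITED"],
            pairs=["p1", "p1", "p2"],
        )
        with pytest.raises(ValueError, match="p2"):
            inhibition_response_ratio(e, meta)


class TestDecayTable:
    def _cohort(self, rng):
        msi = [f"MSI_{i}" for i in range(10)]
        nor = [f"N_{i}" for i in range(10)]
        genes = [f"g{i}" for i in range(30)]
        data = rng.normal(8, 0.5, (30, 20))
        data[:10, :10] -= 1.0  # first 10 genes decayed in MSI
        e = pd.DataFrame(data, index=genes, columns=msi + nor)
        meta = _meta({s: "MSI" for s in msi} | {s: "NORMAL" for s in nor})
        cls = pd.DataFrame(
            {
                "gene_id": genes,
                "location_class": ["NLE"] * 25 + ["LE"] * 5,
                "nmd_class": ["SUBSTRATE"] * 10 + ["NO_PTC"] * 20,
            }
        )
        return e, meta, cls

    def test_detects_injected_decay(self, rng):
        e, meta, cls = self._cohort(rng)
        res = decay_test_table(e, meta, cls)
        assert set(res.loc[res["passes_downregulation_filter"], "gene_id"]) == {
            f"g{i}" for i in range(10)
        }

    def test_byte_identical_reruns(self, rng):
        e, meta, cls = self._cohort(rng)
        a = decay_test_table(e, meta, cls).to_csv()
        b = decay_test_table(e, meta, cls).to_csv()
        assert a == b

    def test_missing_gene_in_matrix_rejected(self, rng):
        e, meta, cls = self._cohort(rng)
        cls.loc[0, "gene_id"] = "absent"
        with pytest.raises(KeyError):
            decay_test_table(e, meta, cls)
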