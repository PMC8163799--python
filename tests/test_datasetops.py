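"""Dataset preprocessing, rank normalization, duplicate handling, fusion."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from guideeff import datasetops as ds
from guideeff import synthdata as sd
from conftest import random_mer30


def _frame(**cols):
    return pd.DataFrame(cols)


class TestPreprocess:
    def test_non_ngg_pam_removed(self):
        df = _frame(mer30=["x", "y"], pam=["TAG", "TGG"], category=["indel", "indel"])
        kept, removed = ds.preprocess(df)
        assert kept["mer30"].tolist() == ["y"]
        assert removed["criterion"].tolist() == ["5_non_ngg_pam"]

    def test_cds_tail_removed_for_lof_only(self):
        df = _frame(mer30=["a", "b"], pam=["AGG", "AGG"],
                    category=["lof", "indel"], cds_relative_position=[0.95, 0.95])
        kept, removed = ds.preprocess(df)
        assert kept["mer30"].tolist() == ["b"]
        assert removed["criterion"].tolist() == ["7_cds_tail"]

    def test_variance_outlier_removed_by_quartile_rule(self):
        # oracle: direct quartile computation with linear interpolation
        variances = [1.0, 1.0, 1.0, 1.0, 100.0]
        q1, q3 = np.percentile(variances, [25, 75])
        assert ds.variance_threshold(variances) == q3 + 1.5 * (q3 - q1)
        eff_a = [10.0] * 5
        eff_b = [10 + np.sqrt(2 * v) for v in variances]  # var of (a,b) pairs
        df = _frame(mer30=list("abcde"), pam=["AGG"] * 5, category=["indel"] * 5,
                    efficiency_a=eff_a, efficiency_b=eff_b)
        kept, removed = ds.preprocess(df)
        assert removed["mer30"].tolist() == ["e"]
        assert removed["criterion"].tolist() == ["3_high_variance"]

    def test_few_guides_per_gene_lof_only(self):
        df = _frame(mer30=["a", "b"], pam=["AGG", "AGG"], category=["lof", "indel"],
                    target_gene=["G1", "G1"])
        kept, removed = ds.preprocess(df, gene_table={"G1": 3})
        assert kept["mer30"].tolist() == ["b"]
        assert removed["criterion"].tolist() == ["4_few_guides_per_gene"]

    def test_missing_inputs_skip_criteria(self):
        df = _frame(mer30=["a"], pam=["AGG"], category=["lof"])
        kept, removed = ds.preprocess(df)  # no tables provided
        assert len(kept) == 1 and removed.empty

    def test_idempotent_and_reasons_partition_removed(self):
        rng = np.random.default_rng(5)
        df = _frame(mer30=[f"m{i}" for i in range(40)],
                    pam=rng.choice(["AGG", "TAG"], 40),
                    category=rng.choice(["lof", "indel"], 40),
                    cds_relative_position=rng.uniform(0, 1, 40))
        kept, removed = ds.preprocess(df)
        assert len(kept) + len(removed) == 40
        assert (removed["criterion"] != "").all()
        kept2, removed2 = ds.preprocess(kept)
        assert removed2.empty and len(kept2) == len(kept)


class TestRankNormalize:
    def test_strict_order(self):
        assert np.allclose(ds.rank_normalize([10, 20, 30]), [1 / 3, 2 / 3, 1.0])

    def test_all_ties(self):
        n = 5
        assert np.allclose(ds.rank_normalize([7.0] * n), [(n + 1) / (2 * n)] * n)

    def test_monotone_invariance_and_spearman(self, rng):
        x = rng.normal(size=200)
        r1 = ds.rank_normalize(x)
        r2 = ds.rank_normalize(np.exp(3 * x))  # strictly monotone transform
        assert np.allclose(r1, r2)
        assert stats.spearmanr(r1, x)[0] == pytest.approx(1.0)


class TestAverageDuplicates:
    def test_mean_and_spread(self):
        df = _frame(mer30=["m", "m", "n"], efficiency=[40.0, 60.0, 5.0])
        out, spread = ds.average_duplicates(df)
        assert out.set_index("mer30").loc["m", "efficiency"] == 50.0
        assert spread.set_index("mer30").loc["m", "spread"] == 20.0

    def test_identity_without_duplicates(self):
        df = _frame(mer30=["a", "b"], efficiency=[1.0, 2.0])
        out, spread = ds.average_duplicates(df)
        assert len(out) == 2 and spread.empty

    def test_planted_triplicate_spreads(self, rng):
        mers = [random_mer30(rng) for _ in range(10)]
        rows, want = [], {}
        for m in mers:
            base = float(rng.uniform(10, 90))
            offsets = np.array([-3.0, 0.0, 5.0])
            for o in offsets:
                rows.append({"mer30": m, "efficiency": base + o})
            want[m] = offsets.max() - offsets.min()
        out, spread = ds.average_duplicates(pd.DataFrame(rows))
        got = spread.set_index("mer30")["spread"].to_dict()
        assert got == pytest.approx(want)


class TestFusion:
    def test_identity_fit(self):
        a = _frame(mer30=list("abc"), efficiency=[10.0, 50.0, 90.0])
        m = ds.fit_fusion(a, a)
        assert m.slope == pytest.approx(1.0) and m.intercept == pytest.approx(0.0)

    def test_noiseless_linear_recovery(self, rng):
        # oracle: closed-form OLS on a planted linear relation
        x = rng.uniform(0, 100, 30)
        src = _frame(mer30=[f"m{i}" for i in range(30)], efficiency=x)
        ref = _frame(mer30=[f"m{i}" for i in range(30)], efficiency=0.8 * x + 7)
        m = ds.fit_fusion(src, ref)
        assert m.slope == pytest.approx(0.8, abs=1e-9)
        assert m.intercept == pytest.approx(7.0, abs=1e-9)
        merged = ds.apply_fusion(m, src, ref).set_index("mer30")
        for i, xi in enumerate(x):
            assert merged.loc[f"m{i}", "efficiency"] == pytest.approx(0.8 * xi + 7, abs=1e-9)

    def test_single_overlap_error(self):
        a = _frame(mer30=["a"], efficiency=[1.0])
        with pytest.raises(ds.FusionError):
            ds.fit_fusion(a, a)

    def test_constant_source_error(self):
        a = _frame(mer30=["a", "b"], efficiency=[5.0, 5.0])
        b = _frame(mer30=["a", "b"], efficiency=[1.0, 2.0])
        with pytest.raises(ds.FusionError):
            ds.fit_fusion(a, b)

    def test_merged_size_is_union(self, rng):
        src, ref, truth = sd.gen_dataset_pair(
            sd.GeneratorSpec(n_guides=200, seed=12, overlap_fraction=0.1))
        m = ds.fit_fusion(src, ref)
        merged = ds.apply_fusion(m, src, ref)
        assert len(merged) == len(src) + len(ref) - truth["n_overlap"]
        assert merged["overlap"].sum() == truth["n_overlap"]

    def test_overlap_gets_mean_of_scaled_and_reference(self):
        m = ds.FusionModel(1.0, 0.0, 2, 0.0)
        src = _frame(mer30=["a", "b"], efficiency=[40.0, 10.0])
        ref = _frame(mer30=["a", "c"], efficiency=[60.0, 5.0])
        merged = ds.apply_fusion(m, src, ref).set_index("mer30")
        assert merged.loc["a", "efficiency"] == 50.0
        assert merged.loc["b", "efficiency"] == 10.0
        assert merged.loc["c", "efficiency"] == 5.0
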