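import numpy as np
import pandas as pd
import pytest

from slrkit import expression as ex


class TestFpkm:
    def test_formula(self):
        counts = pd.DataFrame({"s1": [100]}, index=["g"])
        lengths = pd.Series([1000], index=["g"])
        totals = pd.Series([1_000_000], index=["s1"])
        assert ex.fpkm(counts, lengths, totals).iloc[0, 0] == \
            pytest.approx(100.0)

    def test_zero_count_zero_fpkm(self):
        counts = pd.DataFrame({"s1": [0]}, index=["g"])
        out = ex.fpkm(counts, pd.Series([500], index=["g"]),
                      pd.Series([1000], index=["s1"]))
        assert out.iloc[0, 0] == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, (20, 3)),
                              index=[f"g{i}" for i in range(20)],
                              columns=list("abc"))
        lengths = pd.Series(rng.integers(200, 3000, 20), index=counts.index)
        f1 = ex.fpkm(counts, lengths)
        f2 = ex.fpkm(counts * 2, lengths)
        pd.testing.assert_frame_equal(f1, f2)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ex.fpkm(pd.DataFrame({"s": [1]}, index=["g"]),
                    pd.Series([0], index=["g"]), pd.Series([1], index=["s"]))


class TestExpressedFlag:
    def _setup(self, values):
        fp = pd.DataFrame({"s1": values, "s2": values}, index=["g"])
        samples = pd.DataFrame({"sample": ["s1", "s2"],
                                "sex": ["F", "F"],
                                "tissue": ["leaf", "leaf"],
                                "replicate": [1, 2]})
        return fp, samples

    @pytest.mark.parametrize("value,expressed", [
        (5.0, True), (1.0, False), (0.0, False)])  # strict FPKM > 1
    def test_threshold(self, value, expressed):
        fp, samples = self._setup([value])
        flags = ex.expressed_flag(fp, samples)
        assert bool(flags[("F", "leaf")].iloc[0]) is expressed

    def test_all_replicates_rule(self):
        fp = pd.DataFrame({"s1": [5.0], "s2": [0.5]}, index=["g"])
        samples = pd.DataFrame({"sample": ["s1", "s2"], "sex": "F",
                                "tissue": "leaf", "replicate": [1, 2]})
        assert bool(ex.expressed_flag(fp, samples, rule="mean")
                    [("F", "leaf")].iloc[0])
        assert not bool(ex.expressed_flag(fp, samples, rule="all")
                        [("F", "leaf")].iloc[0])


class TestDeTest:
    def _counts(self, n_genes=200, n=5, seed=0, mu=None, fold=None):
        rng = np.random.default_rng(seed)
        mu = mu if mu is not None else \
            np.exp(rng.normal(np.log(100), 1, n_genes))
        r = 10.0
        cols = {}
        for i in range(n):
            cols[f"F{i}"] = rng.negative_binomial(r, r / (r + mu))
        # implant the fold change in the first 20% of genes only, so
        # median-of-ratios normalization is anchored on unchanged genes
        mu2 = mu.copy()
        if fold is not None:
            k = max(1, n_genes // 5)
            mu2[:k] = mu[:k] * fold
        for i in range(n):
            cols[f"M{i}"] = rng.negative_binomial(r, r / (r + mu2))
        counts = pd.DataFrame(cols,
                              index=[f"g{i}" for i in range(n_genes)])
        groups = pd.Series(["F"] * n + ["M"] * n, index=counts.columns)
        return counts, groups

    def test_identical_groups_null_results(self):
        counts, groups = self._counts(seed=3)
        dup = counts.copy()
        dup[[f"M{i}" for i in range(5)]] = counts[[f"F{i}"
                                                   for i in range(5)]].values
        res = ex.de_test(dup, groups)
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["q"] > 0.9).all()

    def test_all_zero_gene_excluded(self):
        counts, groups = self._counts(n_genes=5)
        counts.iloc[0] = 0
        res = ex.de_test(counts, groups)
        assert np.isnan(res["p"].iloc[0])
        assert res["p"].iloc[1:].notna().all()

    def test_too_few_replicates_rejected(self):
        counts, groups = self._counts(n=5)
        sub = counts[["F0", "M0", "M1"]]
        with pytest.raises(ValueError, match="2 replicates"):
            ex.de_test(sub, groups[["F0", "M0", "M1"]])

    def test_null_type_one_error_calibrated(self):
        counts, groups = self._counts(n_genes=2000, seed=7)
        res = ex.de_test(counts, groups)
        frac = (res["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.03

    def test_power_on_implanted_fold_change(self):
        counts, groups = self._counts(n_genes=300, seed=9, fold=4.0)
        res = ex.de_test(counts, groups)
        implanted = res.iloc[:60]
        recall = ((implanted["q"] < 0.05)
                  & (implanted["log2fc"].abs() > 1)).mean()
        assert recall >= 0.9


class TestAgainstEstablishedTester:
    def test_agrees_with_pydeseq2(self):
        """The native NB test is an approximation of the classic count
        tester; on a simulated matrix its fold changes and its called set
        (|log2FC| > 1, q < 0.05) must closely match pydeseq2's."""
        import warnings
        rng = np.random.default_rng(3)
        G, r = 300, 10.0
        mu = np.exp(rng.normal(np.log(100), 1, G))
        mu2 = mu.copy()
        mu2[:60] = mu[:60] * 4
        cols = {}
        for i in range(5):
            cols[f"F{i}"] = rng.negative_binomial(r, r / (r + mu))
        for i in range(5):
            cols[f"M{i}"] = rng.negative_binomial(r, r / (r + mu2))
        counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(G)])
        groups = pd.Series(["F"] * 5 + ["M"] * 5, index=counts.columns)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from pydeseq2.dds import DeseqDataSet
            from pydeseq2.ds import DeseqStats
            meta = pd.DataFrame({"condition": groups.values},
                                index=counts.columns)
            dds = DeseqDataSet(counts=counts.T, metadata=meta,
                               design="~condition", quiet=True)
            dds.deseq2()
            stats = DeseqStats(dds, contrast=["condition", "M", "F"],
                               quiet=True)
            stats.summary()
        reference = stats.results_df
        native = ex.de_test(counts, groups)

        corr = reference["log2FoldChange"].corr(native["log2fc"])
        assert corr > 0.99
        ref_called = set(reference.index[(reference.padj < 0.05)
                                         & (reference.log2FoldChange
                                            .abs() > 1)])
        nat_called = set(native.index[(native.q < 0.05)
                                      & (native.log2fc.abs() > 1)])
        jaccard = len(ref_called & nat_called) / len(ref_called | nat_called)
        assert jaccard >= 0.85


def build_classify_inputs(fpkm_f, fpkm_m, log2fc, q):
    """One gene, one tissue, two replicates per sex."""
    flags = pd.DataFrame({("F", "t"): [fpkm_f > 1.0],
                          ("M", "t"): [fpkm_m > 1.0]}, index=["g"])
    de = {"t": pd.DataFrame({"log2fc": [log2fc], "p": [q], "q": [q]},
                            index=["g"])}
    return flags, de


class TestClassify:
    def test_eleven_fold_female_catkin_bias(self):
        flags, de = build_classify_inputs(
            fpkm_f=33.0, fpkm_m=3.0, log2fc=-np.log2(11), q=1e-4)
        out = ex.classify(flags, de)
        assert out.loc["g", "t"] == "female-biased"

    def test_limited_precedence_over_test(self):
        # male 5 FPKM, female 0.2 (not expressed): limited regardless of q
        flags, de = build_classify_inputs(0.2, 5.0, log2fc=4.0, q=1e-6)
        assert ex.classify(flags, de).loc["g", "t"] == "male-limited"

    def test_fold_change_guard(self):
        flags, de = build_classify_inputs(10.0, 15.0, log2fc=0.8, q=1e-6)
        assert ex.classify(flags, de).loc["g", "t"] == "unbiased"

    def test_not_expressed(self):
        flags, de = build_classify_inputs(0.1, 0.3, log2fc=0.0, q=1.0)
        assert ex.classify(flags, de).loc["g", "t"] == "not-expressed"

    def test_antisymmetric_under_sex_swap(self):
        cases = [(33.0, 3.0, -np.log2(11), 1e-4),
                 (0.2, 5.0, 4.0, 1e-6),
                 (10.0, 15.0, 0.8, 1e-6),
                 (5.0, 5.0, 0.0, 0.9)]
        flip = {"male-limited": "female-limited",
                "female-limited": "male-limited",
                "male-biased": "female-biased",
                "female-biased": "male-biased",
                "unbiased": "unbiased", "not-expressed": "not-expressed"}
        for f, m, lfc, q in cases:
            flags, de = build_classify_inputs(f, m, lfc, q)
            sflags, sde = build_classify_inputs(m, f, -lfc, q)
            a = ex.classify(flags, de).loc["g", "t"]
            b = ex.classify(sflags, sde).loc["g", "t"]
            assert b == flip[a]


class TestTissuePartition:
    def test_ten_gene_toy_matches_enumeration(self):
        classes = pd.DataFrame({
            "catkin": ["male-limited", "male-limited", "female-biased",
                       "unbiased", "unbiased", "male-biased",
                       "not-expressed", "female-limited", "unbiased",
                       "male-limited"],
            "leaf": ["male-limited", "unbiased", "female-biased",
                     "unbiased", "male-biased", "unbiased",
                     "not-expressed", "unbiased", "unbiased",
                     "female-limited"]},
            index=[f"g{i}" for i in range(10)])
        part = ex.tissue_partition(classes)
        assert part.loc["male-limited"].to_dict() == {
            "catkin_specific": 2, "leaf_specific": 0, "both": 1}
        assert part.loc["female-biased", "both"] == 1
        assert part.loc["unbiased"].to_dict() == {
            "catkin_specific": 1, "leaf_specific": 3, "both": 2}

    def test_buckets_partition_class_totals(self):
        rng = np.random.default_rng(5)
        classes = pd.DataFrame({
            "catkin": rng.choice(ex.CLASSES, 100),
            "leaf": rng.choice(ex.CLASSES, 100)})
        part = ex.tissue_partition(classes)
        for cls in ex.CLASSES:
            assert part.loc[cls, "catkin_specific"] + part.loc[cls, "both"] \
                == (classes["catkin"] == cls).sum()
            assert part.loc[cls, "leaf_specific"] + part.loc[cls, "both"] \
                == (classes["leaf"] == cls).sum()
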