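import dataclasses

import numpy as np
import pandas as pd
import pytest

from slrkit import formats, palindrome, simdata
from slrkit.sequtils import revcomp
from slrkit.simdata import ConfigurationError, ScenarioConfig


def small_config(**kw):
    """A minimal SLR-chromosome-only scenario for fast structure checks."""
    base = dict(n_chromosomes=2, chrom_length=300_000,
                slr=("chr2", 200_000, 290_000),
                msy_segments=(), inversion=None, seed=1)
    base.update(kw)
    return ScenarioConfig(**base)


class TestGenomeConstruction:
    def test_no_features_means_identical_haplotypes(self):
        cfg = small_config()
        refs, truth = simdata.simulate_genome(cfg)
        assert refs["chr2_X"] == refs["chr2_Y"]

    def test_inversion_is_reverse_complement(self):
        cfg = small_config(inversion=(240_000, 260_000))
        refs, truth = simdata.simulate_genome(cfg)
        x, y = refs["chr2_X"], refs["chr2_Y"]
        s, e = 240_000, 260_000
        assert y[s:e] == revcomp(x[s:e])
        assert y[:s] == x[:s] and y[e:] == x[e:]

    def test_msy_inserts_lengthen_y(self, genome, default_config):
        refs, truth = genome
        extra = default_config.msy_total
        assert len(refs["chr4_Y"]) == len(refs["chr4_X"]) + extra
        for iv in truth.msy:
            assert truth.slr.contains(iv)

    def test_overlapping_features_rejected(self):
        cfg = small_config(msy_segments=((210_000, 230_000),),
                           inversion=(220_000, 240_000))
        with pytest.raises(ConfigurationError, match="overlap"):
            simdata.simulate_genome(cfg)

    def test_implanted_arms_recovered_by_finder(self, genome, default_config):
        refs, truth = genome
        slr_seq = refs["chr4_Y"][truth.slr.start:truth.slr.end]
        pairs = palindrome.find_inverted_repeats(slr_seq)
        (a1, a2), = [truth.arm_pairs[0]]
        off = truth.slr.start
        # recovered within seed resolution (greedy extension may run up to
        # ~exact_seed + step into the random flanks at identity 0.9)
        tol = 100 + 20
        hits = [p for p in pairs
                if abs(p.arm1.start + off - a1.start) <= tol
                and abs(p.arm1.end + off - a1.end) <= tol
                and abs(p.arm2.start + off - a2.start) <= tol
                and abs(p.arm2.end + off - a2.end) <= tol]
        assert len(hits) == 1
        assert hits[0].identity >= 0.9
        # the exact implanted arm is fully contained in the reported arm
        assert hits[0].arm1.start + off <= a1.start
        assert hits[0].arm1.end + off >= a1.end

    def test_determinism_byte_identical(self, default_config):
        cfg2 = dataclasses.replace(default_config)
        refs1, _ = simdata.simulate_genome(default_config)
        refs2, _ = simdata.simulate_genome(cfg2)
        assert refs1 == refs2


class TestPools:
    def test_y_specific_expectations_without_error(self):
        cfg = small_config(error_rate=0.0, slr_snp_factor=50.0,
                           depth_mean=60.0, chrom_length=400_000,
                           slr=("chr2", 100_000, 300_000))
        refs, truth = simdata.simulate_genome(cfg)
        calls = simdata.simulate_pools(refs, truth, cfg)
        in_slr = (calls["chrom"] == "chr2") \
            & (calls["pos"] - 1 >= 100_000) & (calls["pos"] - 1 < 300_000)
        sub = calls[in_slr]
        assert len(sub) >= 9000
        assert (sub["ad_alt_f"] == 0).all()          # no female carriers
        idx_m = sub["ad_alt_m"] / (sub["ad_ref_m"] + sub["ad_alt_m"])
        # mean male SNP-index within 3 SE of the binomial expectation 0.5
        se = np.sqrt(0.25 / 60.0 / len(sub))
        assert abs(idx_m.mean() - 0.5) < 3 * se

    def test_autosomal_delta_centered_on_zero(self, pool_calls):
        auto = pool_calls[pool_calls["chrom"] != "chr4"]
        idx_f = auto["ad_alt_f"] / (auto["ad_ref_f"] + auto["ad_alt_f"])
        idx_m = auto["ad_alt_m"] / (auto["ad_ref_m"] + auto["ad_alt_m"])
        delta = idx_m - idx_f
        se = delta.std() / np.sqrt(len(delta))
        assert abs(delta.mean()) < 3 * se

    def test_zero_depth_mean_rejected(self, genome):
        cfg = dataclasses.replace(ScenarioConfig(), depth_mean=0.0)
        with pytest.raises(ConfigurationError, match="depth_mean"):
            simdata.simulate_pools(genome[0], genome[1], cfg)

    def test_vcf_and_tsv_encode_identical_depths(self, tmp_path, pool_calls):
        sub = pool_calls.head(300)
        formats.write_pool_calls_vcf(sub, tmp_path / "p.vcf")
        formats.write_pool_calls_tsv(sub, tmp_path / "p.tsv")
        vcf = formats.read_pool_calls(tmp_path / "p.vcf")
        tsv = formats.read_pool_calls(tmp_path / "p.tsv")
        pd.testing.assert_frame_equal(vcf, tsv, check_dtype=False)


class TestGenePairs:
    def test_zero_target_gives_identical_pair(self):
        (pair,) = simdata.simulate_gene_pairs([0.0], 300, 1)
        assert pair.cds_x == pair.cds_y
        assert pair.realized_ks == 0.0

    def test_saturated_target_rejected(self):
        with pytest.raises(ValueError, match="0.75"):
            simdata.simulate_gene_pairs([0.8], 300, 1)

    def test_non_codon_length_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            simdata.simulate_gene_pairs([0.1], 100, 1)

    def test_no_stop_codons(self):
        (pair,) = simdata.simulate_gene_pairs([0.3], 3000, 2)
        stops = {"TAA", "TAG", "TGA"}
        for cds in (pair.cds_x, pair.cds_y):
            assert not any(cds[i:i + 3] in stops
                           for i in range(0, len(cds), 3))


class TestMethylome:
    def test_zero_effect_zero_difference(self):
        cfg = ScenarioConfig(meth_effect=0.0, seed=4)
        records, genes, _ = simdata.simulate_methylome(cfg)
        env1 = records[records["environment"] == 1]
        by_sex = env1.groupby("sex").apply(
            lambda d: d["n_methylated"].sum()
            / (d["n_methylated"] + d["n_unmethylated"]).sum(),
            include_groups=False)
        assert abs(by_sex["M"] - by_sex["F"]) < 0.02

    def test_sample_layout(self, default_config):
        records, genes, truth = simdata.simulate_methylome(default_config)
        assert set(records["sex"]) == {"F", "M"}
        assert set(records["environment"]) == {1, 2}
        assert records["replicate"].max() == default_config.meth_replicates


class TestSmallRNA:
    def test_concentrated_lengths(self, genome, default_config):
        refs, truth = genome
        segs = {k: s for k, (iv, s) in truth.smallrna_segments.items()}
        cfg = dataclasses.replace(default_config,
                                  smallrna_len_probs={24: 1.0})
        reads = simdata.simulate_smallrna(cfg, segs)
        assert (reads["length"] == 24).all()

    def test_short_segment_rejected(self, default_config):
        with pytest.raises(ValueError, match="shorter"):
            simdata.simulate_smallrna(default_config, {"S1": "ACGT" * 100,
                                                       "S2": "ACGTACGT"})


class TestExpression:
    def test_too_few_replicates_rejected(self):
        cfg = ScenarioConfig(expr=simdata.ExpressionDesign(n_reps=1))
        with pytest.raises(ValueError, match="replicates"):
            simdata.simulate_expression(cfg)

    def test_limited_genes_have_zero_counts_in_other_sex(self, default_config):
        counts, lengths, samples, labels = \
            simdata.simulate_expression(default_config)
        fem_limited = labels.index[labels["catkin"] == "female-limited"]
        male_catkin = samples.loc[(samples.sex == "M")
                                  & (samples.tissue == "catkin"), "sample"]
        assert (counts.loc[fem_limited, male_catkin] == 0).all().all()

    def test_deterministic(self, default_config):
        c1 = simdata.simulate_expression(default_config)[0]
        c2 = simdata.simulate_expression(default_config)[0]
        pd.testing.assert_frame_equal(c1, c2)
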