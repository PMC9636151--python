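import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from slrkit import bsa
from slrkit.formats import GenomeInterval

from oracles import brute_force_window_means


def make_calls(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "ad_ref_f", "ad_alt_f",
                                       "ad_ref_m", "ad_alt_m"])


class TestSiteSnpIndex:
    def test_hemizygous_expectation(self):
        calls = make_calls([("chr1", 100, "A", "T", 20, 0, 10, 10)])
        site = bsa.site_snp_index(calls).iloc[0]
        assert (site.snp_index_f, site.snp_index_m) == (0.0, 0.5)
        assert site.delta == 0.5

    def test_identical_pools_zero_delta(self):
        calls = make_calls([("chr1", 100, "A", "T", 10, 10, 10, 10)])
        assert bsa.site_snp_index(calls).iloc[0].delta == 0.0

    def test_min_depth_filter_excludes_zero_depth(self):
        calls = make_calls([
            ("chr1", 100, "A", "T", 0, 0, 10, 10),    # zero female depth
            ("chr1", 200, "A", "T", 5, 4, 10, 10),    # below min_depth
            ("chr1", 300, "A", "T", 10, 0, 10, 10),
        ])
        out = bsa.site_snp_index(calls, min_depth=10)
        assert list(out["pos"]) == [300]


class TestWindowScan:
    def test_single_site_everywhere(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [150],
                              "delta": [0.4]})
        w = bsa.window_scan(sites, window=100, step=50, min_sites=1,
                            chrom_lengths={"chr1": 300})
        covered = w[(w.start <= 149) & (w.end > 149)]
        assert (covered["mean_delta"] == 0.4).all()
        assert w[~w.index.isin(covered.index)]["mean_delta"].isna().all()

    def test_constant_delta_constant_means(self):
        sites = pd.DataFrame({"chrom": "chr1",
                              "pos": np.arange(1, 1001, 10),
                              "delta": 0.25})
        w = bsa.window_scan(sites, window=200, step=100, min_sites=1,
                            chrom_lengths={"chr1": 1000})
        nonempty = w[w.n_sites > 0]
        assert np.allclose(nonempty["mean_delta"], 0.25)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force(self, data):
        n = data.draw(st.integers(1, 1000))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
        chrom_len = data.draw(st.integers(100, 5000))
        window = data.draw(st.integers(10, 1000))
        step = data.draw(st.integers(1, window))
        pos0 = np.sort(rng.integers(0, chrom_len, n))
        delta = rng.uniform(-1, 1, n)
        sites = pd.DataFrame({"chrom": "c", "pos": pos0 + 1, "delta": delta})
        got = bsa.window_scan(sites, window, step, min_sites=1,
                              chrom_lengths={"c": chrom_len})
        expected = brute_force_window_means(pos0, delta, chrom_len,
                                            window, step)
        assert len(got) == len(expected)
        for row, (start, end, n_exp, mean_exp) in zip(
                got.itertuples(), expected):
            assert (row.start, row.end, row.n_sites) == (start, end, n_exp)
            if mean_exp is None:
                assert np.isnan(row.mean_delta)
            else:
                assert row.mean_delta == pytest.approx(mean_exp)


class TestPermutationEnvelope:
    def _toy_sites(self):
        return pd.DataFrame({"chrom": "chr1", "pos": [10, 60],
                             "delta": [0.3, -0.7]})

    def test_matches_seeded_swap_quantiles(self):
        """Envelope equals quantiles of the window means recomputed from
        the identical seeded swap draws."""
        sites = self._toy_sites()
        w = bsa.permutation_envelope(sites, window=100, step=100,
                                     n_permutations=100, level=0.95,
                                     seed=123, min_sites=1,
                                     chrom_lengths={"chr1": 100})
        rng = np.random.default_rng(123)
        signs = np.where(rng.random((2, 100)) < 0.5, -1.0, 1.0)
        means = (signs * np.array([0.3, -0.7])[:, None]).mean(axis=0)
        assert w.iloc[0]["env_low"] == pytest.approx(
            np.quantile(means, 0.025))
        assert w.iloc[0]["env_high"] == pytest.approx(
            np.quantile(means, 0.975))

    def test_zero_deltas_envelope_contains_zero(self):
        sites = pd.DataFrame({"chrom": "chr1",
                              "pos": np.arange(1, 500, 7),
                              "delta": 0.0})
        w = bsa.permutation_envelope(sites, 100, 50, 200, 0.95, seed=5,
                                     min_sites=1,
                                     chrom_lengths={"chr1": 500})
        ne = w[w.n_sites > 0]
        assert ((ne.env_low <= 0) & (0 <= ne.env_high)).all()

    def test_envelope_narrows_with_lower_level(self):
        rng = np.random.default_rng(9)
        sites = pd.DataFrame({"chrom": "chr1",
                              "pos": np.sort(rng.integers(1, 2000, 200)),
                              "delta": rng.uniform(-1, 1, 200)})
        kw = dict(window=500, step=250, n_permutations=400, min_sites=1,
                  chrom_lengths={"chr1": 2000})
        w95 = bsa.permutation_envelope(sites, level=0.95, seed=7, **kw)
        w50 = bsa.permutation_envelope(sites, level=0.50, seed=7, **kw)
        width95 = (w95.env_high - w95.env_low).dropna()
        width50 = (w50.env_high - w50.env_low).dropna()
        assert (width50 <= width95 + 1e-12).all()

    def test_no_nonempty_windows_errors(self):
        sites = pd.DataFrame({"chrom": [], "pos": [], "delta": []})
        with pytest.raises(ValueError):
            bsa.permutation_envelope(sites, 100, 50, 100, 0.95, seed=1)


def windows_frame(means, step=10, env=(-0.1, 0.1), flagged=None):
    n = len(means)
    return pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n) * step,
        "end": np.arange(n) * step + step,
        "n_sites": [0 if f else 10 for f in (flagged or [False] * n)],
        "mean_delta": [np.nan if f else m
                       for m, f in zip(means, flagged or [False] * n)],
        "flagged": flagged or [False] * n,
        "env_low": env[0], "env_high": env[1],
    })


class TestCallCandidates:
    def test_runs_separated_by_below_threshold_window_split(self):
        w = windows_frame([0.5, 0.5, 0.0, 0.5, 0.5])
        cands = bsa.call_candidates(w, step=10)
        assert [(c.interval.start, c.interval.end) for c in cands] == \
            [(0, 20), (30, 50)]

    def test_flagged_windows_bridge_runs(self):
        w = windows_frame([0.5, 0.5, 0.0, 0.5, 0.5],
                          flagged=[False, False, True, False, False])
        cands = bsa.call_candidates(w, step=10)
        assert [(c.interval.start, c.interval.end) for c in cands] == \
            [(0, 50)]

    def test_directions_and_none(self):
        w = windows_frame([0.5, -0.5, 0.0])
        cands = bsa.call_candidates(w, step=10)
        assert [c.direction for c in cands] == ["male-enriched",
                                                "female-enriched"]
        assert bsa.call_candidates(windows_frame([0.0, 0.05, -0.05])) == []

    def test_printed_style_span_length(self):
        # windows above threshold spanning the printed peritelomeric region
        starts = np.arange(24_021_000, 24_782_000, 10_000)
        w = pd.DataFrame({
            "chrom": "chr14", "start": starts,
            "end": np.minimum(starts + 10_000, 24_782_000),
            "n_sites": 50, "mean_delta": 0.4, "flagged": False,
            "env_low": -0.1, "env_high": 0.1})
        (cand,) = bsa.call_candidates(w, step=10_000)
        assert (cand.interval.start, cand.interval.end) == \
            (24_021_000, 24_782_000)
        assert cand.length_kb == 761


class TestSelectSlr:
    def _cand(self, chrom, start, end, direction="male-enriched"):
        return bsa.CandidateInterval(GenomeInterval(chrom, start, end),
                                     direction)

    def test_male_reference_candidate_selected_over_short(self):
        male = [self._cand("chr5", 31_845_000, 31_849_000),
                self._cand("chr14", 24_021_000, 24_782_000)]
        female = [self._cand("chr14", 22_677_000, 22_684_000)]
        sel = bsa.select_slr(male, female, min_len=None)
        assert sel.interval.chrom == "chr14"
        assert sel.length_kb == 761

    def test_none_when_all_below_min_len(self):
        male = [self._cand("chr5", 0, 4000)]
        assert bsa.select_slr(male, min_len=7000) is None

    def test_tie_breaks_by_chrom_then_start(self):
        male = [self._cand("chr2", 100_000, 200_000),
                self._cand("chr1", 500_000, 600_000)]
        sel = bsa.select_slr(male, min_len=7000)
        assert sel.interval.chrom == "chr1"


class TestAntisymmetry:
    def test_pool_swap_negates_deltas_and_mirrors_direction(self):
        rng = np.random.default_rng(13)
        n = 300
        rows = []
        for i in range(n):
            f = rng.integers(0, 30, 2)
            m = rng.integers(0, 30, 2)
            rows.append(("chr1", 10 * i + 1, "A", "T", f[0] + 10, f[1],
                         m[0] + 10, m[1]))
        calls = make_calls(rows)
        swapped = calls.rename(columns={
            "ad_ref_f": "ad_ref_m", "ad_alt_f": "ad_alt_m",
            "ad_ref_m": "ad_ref_f", "ad_alt_m": "ad_alt_f"})
        s1 = bsa.site_snp_index(calls)
        s2 = bsa.site_snp_index(swapped)
        assert np.allclose(s1["delta"], -s2["delta"])
        kw = dict(window=500, step=250, n_permutations=200, level=0.8,
                  min_sites=1, chrom_lengths={"chr1": 3001})
        w1 = bsa.permutation_envelope(s1, seed=3, **kw)
        w2 = bsa.permutation_envelope(s2, seed=3, **kw)
        c1 = bsa.call_candidates(w1, step=250)
        c2 = bsa.call_candidates(w2, step=250)
        flip = {"male-enriched": "female-enriched",
                "female-enriched": "male-enriched"}
        assert [(c.interval, flip[c.direction]) for c in c1] == \
            [(c.interval, c.direction) for c in c2]
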