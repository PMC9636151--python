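"""Bulked-segregant ΔSNP-index scan with a permutation confidence envelope.

The statistic is the per-site SNP-index (alt-depth / total-depth) of each
sex pool and their difference Δ = male − female, averaged in sliding
windows (default 1 Mb windows, 10 kb step).  Significance is assessed with
a permutation envelope: each replicate swaps the two pools' allele-depth
vectors independently per site with probability ½ — with pooled DNA the
individual labels cannot be permuted, but under the null of no sex
association the two pools are exchangeable site by site, and a swap simply
negates that site's Δ.  The envelope is the central γ-level band of the
replicate window means, either per window (default) or genome-wide
(quantiles of the extreme window mean across the genome, a family-wise
band useful for candidate calling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import GenomeInterval

DEFAULT_WINDOW = 1_000_000
DEFAULT_STEP = 10_000
DEFAULT_PERMUTATIONS = 1000
DEFAULT_LEVEL = 0.95
DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_SITES = 10

SITE_COLUMNS = ["chrom", "pos", "snp_index_f", "snp_index_m", "delta"]


@dataclass(frozen=True)
class CandidateInterval:
    """A run of envelope-exceeding windows merged into one interval."""

    interval: GenomeInterval
    direction: str                   # 'male-enriched' | 'female-enriched'

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def length_kb(self) -> int:
        return self.interval.length_kb


def site_snp_index(calls: pd.DataFrame,
                   min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Per-site SNP-indexes and Δ for sites passing the depth filter.

    A site is retained when both pools have total depth ≥ ``min_depth``
    (zero-depth sites can therefore never divide by zero).  Returns a
    DataFrame with columns chrom, pos, snp_index_f, snp_index_m, delta,
    sorted by (chrom, pos).
    """
    tot_f = calls["ad_ref_f"] + calls["ad_alt_f"]
    tot_m = calls["ad_ref_m"] + calls["ad_alt_m"]
    keep = (tot_f >= max(min_depth, 1)) & (tot_m >= max(min_depth, 1))
    kept = calls[keep]
    out = pd.DataFrame({
        "chrom": kept["chrom"].astype(str),
        "pos": kept["pos"].astype(int),
        "snp_index_f": kept["ad_alt_f"] / tot_f[keep],
        "snp_index_m": kept["ad_alt_m"] / tot_m[keep],
    })
    out["delta"] = out["snp_index_m"] - out["snp_index_f"]
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _window_starts(chrom_len: int, step: int) -> np.ndarray:
    return np.arange(0, max(chrom_len, 1), step, dtype=np.int64)


def _window_index(pos0: np.ndarray, starts: np.ndarray, window: int,
                  chrom_len: int):
    """(lo, hi) site-index bounds per window for sorted 0-based positions."""
    ends = np.minimum(starts + window, chrom_len)
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, ends, side="left")
    return lo, hi, ends


def window_scan(sites: pd.DataFrame, window: int = DEFAULT_WINDOW,
                step: int = DEFAULT_STEP, min_sites: int = DEFAULT_MIN_SITES,
                chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Sliding-window mean Δ per chromosome.

    Windows tile each chromosome from 0 by ``step`` and are truncated at the
    chromosome end.  Windows with fewer than ``min_sites`` sites are kept but
    flagged (``mean_delta`` = NaN, ``flagged`` = True).
    """
    if window < step:
        raise ValueError("window must be >= step")
    frames = []
    for chrom, grp in sites.groupby("chrom", sort=True):
        pos0 = grp["pos"].to_numpy(np.int64) - 1
        delta = grp["delta"].to_numpy(float)
        order = np.argsort(pos0, kind="stable")
        pos0, delta = pos0[order], delta[order]
        chrom_len = (chrom_lengths or {}).get(
            chrom, int(pos0[-1]) + 1 if pos0.size else 1)
        starts = _window_starts(chrom_len, step)
        lo, hi, ends = _window_index(pos0, starts, window, chrom_len)
        csum = np.concatenate([[0.0], np.cumsum(delta)])
        n = hi - lo
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1),
                            np.nan)
        flagged = n < min_sites
        mean = np.where(flagged, np.nan, mean)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "n_sites": n, "mean_delta": mean, "flagged": flagged,
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_sites",
                                     "mean_delta", "flagged"])
    return pd.concat(frames, ignore_index=True)


def permutation_envelope(sites: pd.DataFrame, window: int = DEFAULT_WINDOW,
                         step: int = DEFAULT_STEP,
                         n_permutations: int = DEFAULT_PERMUTATIONS,
                         level: float = DEFAULT_LEVEL,
                         seed: int | np.random.Generator = 0,
                         min_sites: int = DEFAULT_MIN_SITES,
                         chrom_lengths: dict[str, int] | None = None,
                         genome_wide: bool = False) -> pd.DataFrame:
    """Windowed scan plus the γ-level permutation envelope.

    Per replicate every site's pool assignment is swapped independently with
    probability ½ (negating its Δ) and the window means recomputed;
    ``env_low``/``env_high`` are the (1−γ)/2 and 1−(1−γ)/2 empirical
    quantiles of the replicate means per window.  With ``genome_wide=True``
    the quantiles are taken over each replicate's extreme window mean across
    all windows, giving one family-wise band applied to every window.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutation replicates")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    windows = window_scan(sites, window, step, min_sites, chrom_lengths)
    if windows.empty or not (windows["n_sites"] > 0).any():
        raise ValueError("no non-empty windows; cannot build an envelope")

    alpha = (1.0 - level) / 2.0
    per_chrom_means = []        # replicate window means, non-empty windows only
    env_low = np.full(len(windows), np.nan)
    env_high = np.full(len(windows), np.nan)
    row0 = 0
    for chrom, grp in sites.groupby("chrom", sort=True):
        sel = windows.index[windows["chrom"] == chrom].to_numpy()
        pos0 = grp["pos"].to_numpy(np.int64) - 1
        delta = grp["delta"].to_numpy(float)
        order = np.argsort(pos0, kind="stable")
        pos0, delta = pos0[order], delta[order]
        chrom_len = (chrom_lengths or {}).get(
            chrom, int(pos0[-1]) + 1 if pos0.size else 1)
        starts = windows.loc[sel, "start"].to_numpy(np.int64)
        lo, hi, _ = _window_index(pos0, starts, window, chrom_len)
        n = (hi - lo).astype(float)

        signs = np.where(
            rng.random((pos0.size, n_permutations)) < 0.5, -1.0, 1.0)
        perturbed = delta[:, None] * signs
        csum = np.vstack([np.zeros((1, n_permutations)),
                          np.cumsum(perturbed, axis=0)])
        sums = csum[hi] - csum[lo]                     # windows x replicates
        nonempty = n > 0
        means = sums[nonempty] / n[nonempty, None]
        if genome_wide:
            per_chrom_means.append(means)
        else:
            env_low[sel[nonempty]] = np.quantile(means, alpha, axis=1)
            env_high[sel[nonempty]] = np.quantile(means, 1 - alpha, axis=1)
        row0 += len(sel)

    if genome_wide:
        stacked = np.vstack(per_chrom_means)
        lo_q = float(np.quantile(stacked.min(axis=0), alpha))
        hi_q = float(np.quantile(stacked.max(axis=0), 1 - alpha))
        nonempty = windows["n_sites"].to_numpy() > 0
        env_low[nonempty] = lo_q
        env_high[nonempty] = hi_q

    out = windows.copy()
    out["env_low"] = env_low
    out["env_high"] = env_high
    return out


def call_candidates(windows: pd.DataFrame,
                    step: int | None = None) -> list[CandidateInterval]:
    """Merge step-adjacent envelope-exceeding windows into candidates.

    Windows with ``mean_delta`` above ``env_high`` (male-enriched) or below
    ``env_low`` (female-enriched) are merged when consecutive on the step
    grid and in the same direction; the candidate spans the union of the
    merged windows.  Flagged (low-site) windows are never called and never
    break a run either: a coverage dropout carries no evidence against sex
    linkage (hemizygous male-specific segments inside a true SLR produce
    exactly such dropouts).  Only an evaluated below-threshold window ends
    a run.
    """
    needed = {"env_low", "env_high"}
    if not needed <= set(windows.columns):
        raise ValueError("windows lack envelope columns; run "
                         "permutation_envelope first")
    out: list[CandidateInterval] = []
    for chrom, grp in windows.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        if step is None:
            starts = grp["start"].to_numpy()
            step_c = int(np.diff(starts).min()) if len(starts) > 1 else 1
        else:
            step_c = step
        mean = grp["mean_delta"].to_numpy()
        up = mean > grp["env_high"].to_numpy()
        down = mean < grp["env_low"].to_numpy()
        ok = ~grp["flagged"].to_numpy() & ~np.isnan(mean)
        direction = np.where(up & ok, 1, np.where(down & ok, -1, 0))
        cur = None                      # [dir, start, end, last_window_start]
        for s, e, d, evaluated in zip(grp["start"].to_numpy(),
                                      grp["end"].to_numpy(), direction, ok):
            if cur is not None and not evaluated and s - cur[3] <= step_c:
                cur[3] = int(s)         # bridge a no-data window
                continue
            if cur is not None and d == cur[0] and s - cur[3] <= step_c:
                cur[2] = max(cur[2], int(e))
                cur[3] = int(s)
                continue
            if cur is not None:
                out.append(_mk_candidate(chrom, cur[1], cur[2], cur[0]))
            cur = [int(d), int(s), int(e), int(s)] if d != 0 else None
        if cur is not None:
            out.append(_mk_candidate(chrom, cur[1], cur[2], cur[0]))
    return out


def _mk_candidate(chrom, start, end, direction) -> CandidateInterval:
    return CandidateInterval(
        interval=GenomeInterval(str(chrom), int(start), int(end)),
        direction="male-enriched" if direction > 0 else "female-enriched")


def select_slr(candidates_male_ref: list[CandidateInterval],
               candidates_female_ref: list[CandidateInterval] | None = None,
               min_len: int | None = 7_000) -> CandidateInterval | None:
    """Pick the sex-linked region among male-reference candidates.

    A true SLR exists only on the male (XY) reference, so any candidate not
    exceeding ``min_len`` — by default 7 kb, the scale of the largest
    artifactual female-reference candidate; when ``min_len`` is None it is
    taken as the longest female-reference candidate length — is discarded.
    Ties break deterministically by (chromosome, start).  Returns None when
    no candidate qualifies.
    """
    if min_len is None:
        min_len = max((c.length for c in candidates_female_ref or []),
                      default=0)
    qualified = [c for c in candidates_male_ref if c.length > min_len]
    if not qualified:
        return None
    best_len = max(c.length for c in qualified)
    best = [c for c in qualified if c.length == best_len]
    return min(best, key=lambda c: (c.interval.chrom, c.interval.start))


def envelope_coverage(windows: pd.DataFrame) -> float:
    """Fraction of non-empty windows whose observed mean lies inside the
    envelope (used for null calibration)."""
    ok = windows["n_sites"].to_numpy() > 0
    mean = windows["mean_delta"].to_numpy()
    ok &= ~np.isnan(mean)
    inside = (mean[ok] >= windows["env_low"].to_numpy()[ok]) & \
             (mean[ok] <= windows["env_high"].to_numpy()[ok])
    return float(inside.mean())
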