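"""Pooled depth-of-coverage differential and male-specific region calling.

A hemizygous male-specific region (MSY) is present on the Y but absent from
the X, so female-pool reads have nowhere to map: the normalized
female/male depth ratio collapses.  Depths are normalized per pool by the
genome-wide median (optionally excluding the candidate SLR) so calls are
invariant to overall sequencing effort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .formats import GenomeInterval

DEFAULT_BIN = 1000
DEFAULT_RATIO_MAX = 0.2
#: a hemizygous segment has male normalized depth ~0.5 (one copy instead of
#: two); the floor must sit clearly below that to separate "present at one
#: copy" from "absent/unmappable" without cutting true bins in half.
DEFAULT_MALE_FLOOR = 0.25
DEFAULT_GAP_BINS = 1


def binned_depth(depth_f: pd.DataFrame, depth_m: pd.DataFrame,
                 bin_size: int = DEFAULT_BIN,
                 exclude: list[GenomeInterval] | None = None) -> pd.DataFrame:
    """Mean depth per bin per pool with normalized female/male ratio.

    Inputs are per-base or per-bin tables with columns chrom, pos-or-start,
    depth; both pools must cover the same coordinate space.  Normalizing
    medians are computed over the background (bins outside ``exclude``,
    e.g. outside the candidate SLR).  Bins where the male normalized depth
    falls below the call floor get ``norm_ratio`` = NaN (flagged, never
    dropped).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    f = _rebin(depth_f, bin_size)
    m = _rebin(depth_m, bin_size)
    merged = f.merge(m, on=["chrom", "start"], how="outer",
                     suffixes=("_f", "_m")).fillna({"depth_f": 0.0,
                                                    "depth_m": 0.0})
    merged = merged.sort_values(["chrom", "start"]).reset_index(drop=True)

    bg = np.ones(len(merged), dtype=bool)
    for iv in exclude or []:
        bg &= ~((merged["chrom"] == iv.chrom)
                & (merged["start"] < iv.end)
                & (merged["start"] + bin_size > iv.start))
    med_f = float(np.median(merged.loc[bg, "depth_f"])) if bg.any() else np.nan
    med_m = float(np.median(merged.loc[bg, "depth_m"])) if bg.any() else np.nan
    if not med_f or not med_m or np.isnan(med_f) or np.isnan(med_m):
        raise ValueError("cannot normalize: zero or undefined median depth")

    merged["norm_f"] = merged["depth_f"] / med_f
    merged["norm_m"] = merged["depth_m"] / med_m
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = merged["norm_f"] / merged["norm_m"]
    merged["norm_ratio"] = np.where(
        merged["norm_m"] >= DEFAULT_MALE_FLOOR, ratio, np.nan)
    merged["end"] = merged["start"] + bin_size
    return merged[["chrom", "start", "end", "depth_f", "depth_m",
                   "norm_f", "norm_m", "norm_ratio"]]


def _rebin(depth: pd.DataFrame, bin_size: int) -> pd.DataFrame:
    pos_col = "start" if "start" in depth.columns else "pos"
    df = depth[["chrom", pos_col, "depth"]].rename(columns={pos_col: "start"})
    if (df["depth"] < 0).any():
        raise ValueError("negative depths")
    df = df.copy()
    df["start"] = (df["start"] // bin_size) * bin_size
    return (df.groupby(["chrom", "start"], as_index=False)["depth"]
            .mean())


def call_msy(bins: pd.DataFrame, ratio_max: float = DEFAULT_RATIO_MAX,
             min_len: int = 5000,
             gap_bins: int = DEFAULT_GAP_BINS,
             male_floor: float = DEFAULT_MALE_FLOOR) -> list[GenomeInterval]:
    """Call male-specific regions from normalized depth bins.

    Maximal runs of bins with ``norm_ratio`` ≤ ``ratio_max`` and male
    normalized depth ≥ ``male_floor`` are merged across gaps of at most
    ``gap_bins`` bins; runs of total length ≥ ``min_len`` are reported.
    """
    out: list[GenomeInterval] = []
    for chrom, grp in bins.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        hit = (grp["norm_ratio"].to_numpy() <= ratio_max) \
            & (grp["norm_m"].to_numpy() >= male_floor)
        hit &= ~np.isnan(grp["norm_ratio"].to_numpy())
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        bin_size = int(ends[0] - starts[0]) if len(starts) else 1
        cur = None                                   # [start, end]
        for s, e, h in zip(starts, ends, hit):
            if not h:
                continue
            if cur is not None and s - cur[1] <= gap_bins * bin_size:
                cur[1] = int(e)
            else:
                if cur is not None and cur[1] - cur[0] >= min_len:
                    out.append(GenomeInterval(str(chrom), cur[0], cur[1]))
                cur = [int(s), int(e)]
        if cur is not None and cur[1] - cur[0] >= min_len:
            out.append(GenomeInterval(str(chrom), cur[0], cur[1]))
    return out
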