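"""Weighted methylation levels, sex-differential region calling and
DMR→gene assignment.

Methylation level of a region is the count-weighted level
Σ methylated / Σ total over covered cytosines, per context (CG/CHG/CHH).
Sex-differential calling is a deliberately simple, deterministic
approximation of dispersion-shrinkage DMR callers: counts are pooled
across replicates per sex, each fixed-width window is tested with a
Fisher exact test on the pooled 2×2 table, p-values are
Benjamini-Hochberg adjusted across windows, and a DMR additionally
requires a minimum absolute level difference and cytosine count.
Adjacent significant windows of the same context and direction merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import GeneModel, GenomeInterval, VALID_CONTEXTS

PROMOTER_BP = 2000
DEFAULT_DMR_WINDOW = 200
DEFAULT_MIN_CYTOSINES = 5
DEFAULT_MIN_DIFF = 0.1
DEFAULT_Q = 0.05


@dataclass(frozen=True)
class RegionMethylation:
    region: GenomeInterval
    context: str
    level: float | None              # None when no covered cytosine
    n_cytosines: int


@dataclass(frozen=True)
class DMR:
    interval: GenomeInterval
    context: str
    direction: str                   # 'male-hyper' | 'female-hyper'
    diff: float                      # male level - female level
    p: float
    q: float


def weighted_level(records: pd.DataFrame, region: GenomeInterval,
                   context: str | None = None) -> RegionMethylation:
    """Pooled-count weighted methylation level of a region.

    All rows falling in the region (and context, if given) are pooled:
    level = Σ n_methylated / Σ (n_methylated + n_unmethylated).  The level
    is therefore invariant to splitting a cytosine's counts across rows.
    Zero covered cytosines yield an undefined (None) level.
    """
    sel = (records["chrom"] == region.chrom) \
        & (records["pos"] - 1 >= region.start) \
        & (records["pos"] - 1 < region.end)
    if context is not None:
        if context not in VALID_CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        sel &= records["context"] == context
    sub = records[sel]
    meth = int(sub["n_methylated"].sum())
    total = meth + int(sub["n_unmethylated"].sum())
    n_cyt = int(sub.groupby(["chrom", "pos"]).ngroups)
    level = meth / total if total > 0 else None
    return RegionMethylation(region, context or "all", level, n_cyt)


def promoter_of(gene: GeneModel, upstream: int = PROMOTER_BP,
                chrom_length: int | None = None) -> GenomeInterval:
    """Promoter = ``upstream`` bp upstream of the translation start site.

    Plus strand: [start - upstream, start); minus strand: [end, end +
    upstream), both clipped at chromosome bounds.
    """
    if gene.strand == "+":
        lo, hi = gene.start - upstream, gene.start
    else:
        lo, hi = gene.end, gene.end + upstream
    lo = max(0, lo)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return GenomeInterval(gene.chrom, lo, hi)


def call_dmrs(records: pd.DataFrame, window: int = DEFAULT_DMR_WINDOW,
              min_cytosines: int = DEFAULT_MIN_CYTOSINES,
              min_diff: float = DEFAULT_MIN_DIFF,
              q_threshold: float = DEFAULT_Q) -> list[DMR]:
    """Call sex-differentially methylated regions from one environment.

    ``records`` is a long per-cytosine table (one row per cytosine per
    sample) with a ``sex`` column ('F'/'M'); replicate counts are pooled.
    Per (chrom, window, context): Fisher exact test on the pooled
    (methylated, unmethylated) F vs M table, BH across all tested windows,
    DMR when q < ``q_threshold`` AND |level difference| >= ``min_diff``
    AND the window covers >= ``min_cytosines`` cytosines.  Adjacent
    significant windows (same context/direction) are merged.
    """
    if records.empty:
        return []
    df = records.copy()
    df["win"] = ((df["pos"] - 1) // window) * window
    grouped = df.groupby(["chrom", "win", "context", "sex"]).agg(
        meth=("n_methylated", "sum"),
        unmeth=("n_unmethylated", "sum"),
        n_pos=("pos", "nunique"),
    ).reset_index()
    wide = grouped.pivot_table(
        index=["chrom", "win", "context"], columns="sex",
        values=["meth", "unmeth", "n_pos"], fill_value=0)
    if wide.empty:
        return []
    for sex in ("F", "M"):
        for col in ("meth", "unmeth", "n_pos"):
            if (col, sex) not in wide.columns:
                wide[(col, sex)] = 0
    rows = []
    for (chrom, win, ctx), r in wide.iterrows():
        mf, uf = int(r[("meth", "F")]), int(r[("unmeth", "F")])
        mm, um = int(r[("meth", "M")]), int(r[("unmeth", "M")])
        if mf + uf == 0 or mm + um == 0:
            continue
        n_cyt = int(max(r[("n_pos", "F")], r[("n_pos", "M")]))
        lf = mf / (mf + uf)
        lm = mm / (mm + um)
        _, p = stats.fisher_exact([[mf, uf], [mm, um]])
        rows.append((chrom, win, ctx, n_cyt, lm - lf, p))
    if not rows:
        return []
    tab = pd.DataFrame(rows, columns=["chrom", "win", "context",
                                      "n_cyt", "diff", "p"])
    tab["q"] = multipletests(tab["p"], method="fdr_bh")[1]
    sig = tab[(tab["q"] < q_threshold)
              & (tab["diff"].abs() >= min_diff)
              & (tab["n_cyt"] >= min_cytosines)].copy()
    if sig.empty:
        return []
    sig["direction"] = np.where(sig["diff"] > 0, "male-hyper", "female-hyper")

    out: list[DMR] = []
    sig = sig.sort_values(["chrom", "context", "direction", "win"])
    for (chrom, ctx, direction), grp in sig.groupby(
            ["chrom", "context", "direction"], sort=True):
        cur = None
        for r in grp.itertuples(index=False):
            if cur is not None and r.win == cur["end"]:
                cur["end"] = r.win + window
                cur["rows"].append(r)
            else:
                if cur is not None:
                    out.append(_merge_dmr(chrom, ctx, direction, cur, window))
                cur = {"start": r.win, "end": r.win + window, "rows": [r]}
        if cur is not None:
            out.append(_merge_dmr(chrom, ctx, direction, cur, window))
    out.sort(key=lambda d: (d.interval.chrom, d.interval.start, d.context))
    return out


def _merge_dmr(chrom, ctx, direction, cur, window) -> DMR:
    rows = cur["rows"]
    return DMR(
        interval=GenomeInterval(str(chrom), int(cur["start"]),
                                int(cur["end"])),
        context=str(ctx), direction=str(direction),
        diff=float(np.mean([r.diff for r in rows])),
        p=float(np.min([r.p for r in rows])),
        q=float(np.min([r.q for r in rows])),
    )


def dmr_gene_link(dmrs: list[DMR], genes: list[GeneModel],
                  upstream: int = PROMOTER_BP) -> dict[str, set[str]]:
    """Sex-specific hypermethylated gene sets.

    A gene joins the male-hyper (resp. female-hyper) set when any
    male-hyper (resp. female-hyper) DMR overlaps its body (translation
    start to termination) or its promoter by at least 1 bp.
    """
    sets: dict[str, set[str]] = {"male-hyper": set(), "female-hyper": set()}
    for gene in genes:
        body = gene.body
        prom = promoter_of(gene, upstream)
        for dmr in dmrs:
            if dmr.interval.overlaps(body) or dmr.interval.overlaps(prom):
                sets[dmr.direction].add(gene.id)
    return sets


def shared_across_environments(sets_env1: dict[str, set[str]],
                               sets_env2: dict[str, set[str]]
                               ) -> dict[str, set[str]]:
    """Per-direction intersection of two environments' gene sets."""
    return {d: sets_env1.get(d, set()) & sets_env2.get(d, set())
            for d in ("male-hyper", "female-hyper")}
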