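"""FPKM computation and sex-limited / sex-biased gene classification.

A gene is *expressed* in a sex-tissue group when its mean FPKM exceeds 1;
*sex-limited* (SLG) when expressed in one sex only within a tissue;
*sex-biased* (SBG) when expressed in both sexes but differentially
(|log2 fold change| > 1 at Benjamini-Hochberg q < 0.05).  The
differential test is a native negative-binomial approximation of the
classic count-based testers: library sizes are normalized by
median-of-ratios, a common dispersion is estimated per gene by method of
moments, and the log-fold-change is tested with a Wald statistic on the
t distribution.  Externally computed p-values can be slotted in through
``classify``'s ``de`` argument, so a published tester can replace the
native one without touching the classification rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FPKM_EXPRESSED = 1.0
LOG2FC_THRESHOLD = 1.0
Q_THRESHOLD = 0.05

CLASSES = ("male-limited", "female-limited", "male-biased", "female-biased",
           "unbiased", "not-expressed")


def fpkm(counts: pd.DataFrame, lengths: pd.Series,
         totals: pd.Series | None = None) -> pd.DataFrame:
    """FPKM = count / (length/1e3) / (total/1e6).

    ``totals`` are per-sample mapped-read totals; column sums are used when
    omitted.  Zero gene lengths or non-positive totals raise.
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for all genes")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if (totals <= 0).any():
        raise ValueError("per-sample totals must be positive")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def expressed_flag(fpkm_matrix: pd.DataFrame, samples: pd.DataFrame,
                   threshold: float = FPKM_EXPRESSED,
                   rule: str = "mean") -> pd.DataFrame:
    """Expressed-gene flags per (sex, tissue) group.

    ``rule='mean'``: group-mean FPKM strictly greater than ``threshold``;
    ``rule='all'``: every replicate strictly greater.  Returns a boolean
    DataFrame indexed by gene with (sex, tissue) column MultiIndex.
    """
    flags = {}
    for (sex, tissue), grp in samples.groupby(["sex", "tissue"], sort=True):
        cols = grp["sample"].tolist()
        sub = fpkm_matrix[cols]
        if rule == "mean":
            flags[(sex, tissue)] = sub.mean(axis=1) > threshold
        elif rule == "all":
            flags[(sex, tissue)] = (sub > threshold).all(axis=1)
        else:
            raise ValueError(f"unknown expressed rule {rule!r}")
    return pd.DataFrame(flags)


def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors via the median-of-ratios method."""
    log_counts = np.log(counts.replace(0, np.nan))
    log_geo = log_counts.mean(axis=1)
    usable = log_geo.notna()
    ratios = log_counts[usable].sub(log_geo[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf / np.exp(np.log(sf).mean())


def de_test(counts: pd.DataFrame, groups: pd.Series,
            pseudo: float = 0.5) -> pd.DataFrame:
    """Per-gene differential test between two groups of samples.

    ``groups`` maps sample name to one of exactly two labels (the log2
    fold change is second level over first, in sorted label order).  Genes
    with all-zero counts are excluded from testing (NaN p).  Returns a
    DataFrame with log2fc, p, q (BH) indexed by gene.
    """
    groups = groups.reindex(counts.columns)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError("de_test requires exactly two groups")
    g1 = counts.columns[groups == levels[0]]
    g2 = counts.columns[groups == levels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 replicates per group")

    sf = median_of_ratios(counts)
    norm = counts.div(sf, axis=1)
    x1 = norm[g1].to_numpy(float)
    x2 = norm[g2].to_numpy(float)
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)

    # method-of-moments NB dispersion, pooled across groups:
    # var = mu + alpha * mu^2  =>  alpha = (var - mu) / mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = (v1 - m1) / m1 ** 2
        a2 = (v2 - m2) / m2 ** 2
    stacked = np.vstack([a1, a2])
    valid = np.isfinite(stacked)
    alpha = np.where(valid, stacked, 0.0).sum(axis=0) \
        / np.maximum(valid.sum(axis=0), 1)
    alpha = np.clip(np.nan_to_num(alpha, nan=0.0), 0.0, None)

    log2fc = np.log2(m2 + pseudo) - np.log2(m1 + pseudo)
    # delta-method variance of log(mean) under NB sampling
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = (1.0 / np.maximum(m1, pseudo) + alpha) / n1 \
            + (1.0 / np.maximum(m2, pseudo) + alpha) / n2
    se_log2 = np.sqrt(se2) / np.log(2)
    t_stat = log2fc / np.maximum(se_log2, 1e-12)
    df_t = n1 + n2 - 2
    p = 2.0 * stats.t.sf(np.abs(t_stat), df_t)

    allzero = (counts[list(g1) + list(g2)].sum(axis=1) == 0).to_numpy()
    p[allzero] = np.nan
    q = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    return pd.DataFrame({"log2fc": log2fc, "p": p, "q": q},
                        index=counts.index)


def classify(flags: pd.DataFrame, de: dict[str, pd.DataFrame],
             tissues: tuple[str, ...] | None = None,
             log2fc_threshold: float = LOG2FC_THRESHOLD,
             q_threshold: float = Q_THRESHOLD) -> pd.DataFrame:
    """Per-gene per-tissue class labels.

    ``flags`` comes from :func:`expressed_flag`; ``de`` maps tissue ->
    de_test result where log2fc > 0 means male-higher (groups tested in
    ('F', 'M') order).  Rule precedence per tissue: not-expressed (neither
    sex) > limited (one sex only, regardless of the test) > biased (both
    expressed AND |log2fc| > 1 AND q < 0.05) > unbiased.
    """
    if tissues is None:
        tissues = tuple(sorted({t for _, t in flags.columns}))
    out = {}
    for t in tissues:
        f_expr = flags[("F", t)]
        m_expr = flags[("M", t)]
        res = de[t].reindex(flags.index)
        biased = (res["log2fc"].abs() > log2fc_threshold) \
            & (res["q"] < q_threshold)
        label = pd.Series("unbiased", index=flags.index)
        label[biased & (res["log2fc"] > 0)] = "male-biased"
        label[biased & (res["log2fc"] < 0)] = "female-biased"
        label[~(f_expr & m_expr)] = "unbiased"      # test needs both sexes
        label[m_expr & ~f_expr] = "male-limited"
        label[f_expr & ~m_expr] = "female-limited"
        label[~f_expr & ~m_expr] = "not-expressed"
        out[t] = label
    return pd.DataFrame(out)


def tissue_partition(classes: pd.DataFrame) -> pd.DataFrame:
    """Venn-style partition of each class across two tissues.

    For each class, genes split into tissue-specific buckets (class in
    exactly that tissue) and a 'both' bucket; buckets are disjoint and sum
    to the per-tissue class totals appropriately.
    """
    if classes.shape[1] != 2:
        raise ValueError("tissue_partition expects exactly two tissues")
    t0, t1 = classes.columns
    rows = []
    for cls in CLASSES:
        in0 = classes[t0] == cls
        in1 = classes[t1] == cls
        rows.append({
            "class": cls,
            f"{t0}_specific": int((in0 & ~in1).sum()),
            f"{t1}_specific": int((in1 & ~in0).sum()),
            "both": int((in0 & in1).sum()),
        })
    return pd.DataFrame(rows).set_index("class")
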