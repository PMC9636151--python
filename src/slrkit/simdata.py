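"""Synthetic XY-population datasets with known ground truth.

This module emulates the data layout of a dioecious-tree sex-determination
study: two wild bulks (females and males) sequenced as pools, an XY pair of
haplotypes for one chromosome carrying a hemizygous, SNP-dense sex-linked
region (SLR), an inversion inside the SLR, male-specific (MSY) inserts, a
palindrome-arm construct flanking inverted copies of a feminizing-gene
fragment, X/Y coding-sequence pairs at controlled synonymous divergence,
male-hypermethylated promoter cytosines in two environments, 24-nt-peaked
small-RNA reads from the inverted fragments, and count matrices with
implanted sex-limited / sex-biased genes.

Every generator draws from a stream derived from the single
``ScenarioConfig.seed``; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import GeneModel, GenomeInterval
from .sequtils import random_dna, revcomp

# fixed sub-stream indices so stages are independent of call order
_STREAMS = {
    "genome": 0, "pools": 1, "gene_pairs": 2, "methylome": 3,
    "smallrna": 4, "expression": 5, "depth": 6,
}


class ConfigurationError(ValueError):
    """Raised when a ScenarioConfig is internally inconsistent."""


@dataclass
class ExpressionDesign:
    """Counts of implanted expression classes and the simulation scale."""

    n_genes: int = 2000
    n_reps: int = 5
    tissues: tuple[str, ...] = ("catkin", "leaf")
    n_male_limited: int = 30          # per tissue-pattern bucket, see below
    n_female_limited: int = 30
    n_sbg: int = 200                  # implanted sex-biased genes (catkin)
    log2fc: float = 2.0
    dispersion: float = 0.1
    base_mean_log: float = math.log(100.0)
    base_mean_sigma: float = 1.0
    n_silent: int = 50


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic scenario.

    Coordinates of ``slr``, ``msy_segments`` and ``inversion`` are on the
    Y haplotype (0-based half-open).  The default scale is deliberately a
    toy genome (4 x 2 Mb, 200-kb SLR, 1 SNP/kb, 60x pools) that runs in
    seconds while keeping the study's pool sizes and error structure.
    """

    n_chromosomes: int = 4
    chrom_length: int = 2_000_000
    snp_density: float = 1.0                       # sites per kb
    slr: tuple[str, int, int] = ("chr4", 1_700_000, 1_900_000)
    msy_segments: tuple[tuple[int, int], ...] = (
        (1_740_000, 1_760_000),
        (1_780_000, 1_790_000),
        (1_810_000, 1_840_000),
    )
    inversion: tuple[int, int] = (1_860_000, 1_890_000)
    n_females: int = 100
    n_males: int = 96
    depth_mean: float = 60.0
    error_rate: float = 0.002
    slr_snp_factor: float = 3.0                    # SNP-density multiplier in SLR
    ks_targets: tuple[float, ...] = (0.02, 0.04, 0.12)
    cds_length: int = 30_000
    meth_effect: float = 0.4                       # male - female at target promoter
    meth_baseline: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.8, "CHG": 0.4, "CHH": 0.1})
    meth_replicates: int = 3
    meth_depth: float = 30.0
    smallrna_len_probs: Mapping[int, float] = field(
        default_factory=lambda: {24: 0.8, 21: 0.1, 22: 0.1})
    n_smallrna_reads: int = 5000
    smallrna_background_rate: float = 0.1
    expr: ExpressionDesign = field(default_factory=ExpressionDesign)
    seed: int = 0

    # -- internals ---------------------------------------------------------
    def rng(self, stage: str) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stage],))
        return np.random.default_rng(ss)

    @property
    def slr_chrom(self) -> str:
        return self.slr[0]

    @property
    def msy_total(self) -> int:
        return sum(e - s for s, e in self.msy_segments)

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def validate(self) -> None:
        chrom, s0, e0 = self.slr
        if chrom not in self.chrom_names():
            raise ConfigurationError(f"SLR chromosome {chrom} not in genome")
        y_len = self.chrom_length + self.msy_total
        if not (0 <= s0 < e0 <= y_len):
            raise ConfigurationError("SLR outside its chromosome")
        segs = sorted(self.msy_segments)
        feats = list(segs)
        if self.inversion is not None:
            inv = tuple(self.inversion)
            if not (s0 <= inv[0] < inv[1] <= e0):
                raise ConfigurationError("inversion must lie inside the SLR")
            feats = sorted(feats + [inv])
        for (a1, a2), (b1, b2) in zip(feats, feats[1:]):
            if b1 < a2:
                raise ConfigurationError(
                    f"overlapping truth intervals ({a1},{a2}) and ({b1},{b2})")
        for s, e in segs:
            if not (s0 <= s < e <= e0):
                raise ConfigurationError("MSY segments must lie inside the SLR")
        if self.n_females <= 0 or self.n_males <= 0:
            raise ConfigurationError("pool sizes must be positive")
        for p in (self.error_rate, self.smallrna_background_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must be in [0, 1]")
        lp = sum(self.smallrna_len_probs.values())
        if abs(lp - 1.0) > 1e-9:
            raise ConfigurationError("smallrna_len_probs must sum to 1")


@dataclass
class SimulatedTruth:
    """Ground truth recorded by the generators, in Y-haplotype coordinates."""

    slr: GenomeInterval | None = None
    slr_x: GenomeInterval | None = None
    msy: list[GenomeInterval] = field(default_factory=list)
    inversion: GenomeInterval | None = None
    inversion_x: GenomeInterval | None = None
    arm_pairs: list[tuple[GenomeInterval, GenomeInterval]] = field(
        default_factory=list)
    smallrna_segments: dict[str, tuple[GenomeInterval, str]] = field(
        default_factory=dict)
    target_gene: GeneModel | None = None           # the autosomal feminizing gene
    gene_pairs_ks: dict[str, float] = field(default_factory=dict)
    dmrs: list[tuple[GenomeInterval, str]] = field(default_factory=list)
    expression_labels: pd.DataFrame | None = None

    def check(self) -> None:
        for iv in self.msy + [self.slr, self.inversion]:
            if iv is not None and iv.length <= 0:
                raise ValueError("truth interval with non-positive length")


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

# layout of the palindrome construct placed inside the largest MSY segment
_ARM_LEN = 600
_FRAG_LEN = 300          # the inverted feminizing-gene fragments S1/S2 (and S3)
_L2_LEN = 1200
_PAD = 400


def simulate_genome(config: ScenarioConfig):
    """Build reference sequences and ground truth.

    Returns ``(refs, truth)`` where ``refs`` maps each autosome name to its
    sequence and additionally carries ``"<slr_chrom>_X"`` and
    ``"<slr_chrom>_Y"`` haplotypes of the SLR chromosome.  The Y haplotype
    carries the reverse-complemented inversion, the hemizygous MSY inserts,
    and — inside the largest MSY insert — two inverted copies of a fragment
    of an autosomal feminizing gene flanked by a palindromic arm pair.
    """
    config.validate()
    rng = config.rng("genome")
    chrom, slr_s, slr_e = config.slr

    refs: dict[str, str] = {}
    for name in config.chrom_names():
        if name != chrom:
            refs[name] = random_dna(config.chrom_length, rng)
    x_seq = random_dna(config.chrom_length, rng)

    truth = SimulatedTruth()
    y_len = config.chrom_length + config.msy_total
    truth.slr = GenomeInterval(chrom, slr_s, slr_e)

    # the autosomal feminizing-gene locus donating the duplicated fragments
    donor_chrom = next(c for c in config.chrom_names() if c != chrom)
    donor_start = 100_000
    donor_seq = refs[donor_chrom]
    truth.target_gene = GeneModel(
        id="ARR17_like", chrom=donor_chrom, strand="+",
        start=donor_start, end=donor_start + 1_500,
    )
    # disjoint donor spans: the inverted pair (S1/S2), a third forward copy
    # from elsewhere in the gene (S3) and a larger forward segment (L2)
    frag = donor_seq[donor_start + 300: donor_start + 300 + _FRAG_LEN]
    s3 = donor_seq[donor_start + 700: donor_start + 700 + _FRAG_LEN]
    l2 = donor_seq[donor_start + 1100: donor_start + 1100 + _L2_LEN]

    # MSY insert contents; the largest insert hosts the palindrome construct
    segs = sorted(config.msy_segments)
    contents: list[str] = []
    host_idx = max(range(len(segs)), key=lambda i: segs[i][1] - segs[i][0]) \
        if segs else -1
    for i, (s, e) in enumerate(segs):
        length = e - s
        if i == host_idx:
            contents.append(_palindrome_construct(s, length, frag, s3, l2,
                                                  rng, truth, chrom))
        else:
            contents.append(random_dna(length, rng))

    # assemble Y: X backbone with novel inserts, then in-place inversion
    pieces = []
    x_cur = 0
    y_cur = 0
    for (s, e), content in zip(segs, contents):
        span = s - y_cur
        if span < 0 or x_cur + span > len(x_seq):
            raise ConfigurationError("MSY segments inconsistent with backbone")
        pieces.append(x_seq[x_cur:x_cur + span])
        pieces.append(content)
        x_cur += span
        y_cur = e
        truth.msy.append(GenomeInterval(chrom, s, e))
    pieces.append(x_seq[x_cur:])
    y_seq = "".join(pieces)
    assert len(y_seq) == y_len

    if config.inversion is not None:
        inv_s, inv_e = config.inversion
        y_seq = y_seq[:inv_s] + revcomp(y_seq[inv_s:inv_e]) + y_seq[inv_e:]
        offset = sum(e - s for s, e in segs if e <= inv_s)
        truth.inversion = GenomeInterval(chrom, inv_s, inv_e)
        truth.inversion_x = GenomeInterval(chrom, inv_s - offset, inv_e - offset)

    inserted_in_slr = sum(e - s for s, e in segs)
    truth.slr_x = GenomeInterval(chrom, slr_s, slr_e - inserted_in_slr)

    refs[f"{chrom}_X"] = x_seq
    refs[f"{chrom}_Y"] = y_seq
    truth.check()
    return refs, truth


def _palindrome_construct(seg_start: int, length: int, frag: str, s3: str,
                          l2: str, rng: np.random.Generator,
                          truth: SimulatedTruth, chrom: str) -> str:
    """ARM .. S1 .. S2=revcomp(S1) .. S3 .. L2 .. revcomp(ARM), padded."""
    arm = random_dna(_ARM_LEN, rng)
    parts: list[str] = []
    cursor = seg_start

    def emit(seq: str, name: str | None = None):
        nonlocal cursor
        if name is not None:
            iv = GenomeInterval(chrom, cursor, cursor + len(seq))
            if name == "arm":
                truth.arm_pairs.append((iv, None))  # second arm fills in later
            elif name == "arm2":
                a1, _ = truth.arm_pairs[-1]
                truth.arm_pairs[-1] = (a1, iv)
            else:
                truth.smallrna_segments[name] = (iv, seq)
        parts.append(seq)
        cursor += len(seq)

    needed = 2 * _ARM_LEN + 3 * _FRAG_LEN + _L2_LEN + 7 * _PAD
    if length < needed:
        raise ConfigurationError(
            f"largest MSY segment ({length} bp) too small for the palindrome "
            f"construct ({needed} bp)")
    emit(random_dna(_PAD, rng))
    emit(arm, "arm")
    emit(random_dna(_PAD, rng))
    emit(frag, "S1")
    emit(random_dna(_PAD, rng))
    emit(revcomp(frag), "S2")
    emit(random_dna(_PAD, rng))
    emit(s3, "S3")
    emit(random_dna(_PAD, rng))
    emit(l2, "L2")
    emit(random_dna(_PAD, rng))
    emit(revcomp(arm), "arm2")
    emit(random_dna(length - (cursor - seg_start), rng))
    return "".join(parts)


def male_reference(refs: dict[str, str], config: ScenarioConfig) -> dict[str, str]:
    """Male-genome reference: autosomes + the Y haplotype as the SLR chromosome."""
    out = {c: refs[c] for c in config.chrom_names() if c != config.slr_chrom}
    out[config.slr_chrom] = refs[f"{config.slr_chrom}_Y"]
    return dict(sorted(out.items()))


def female_reference(refs: dict[str, str], config: ScenarioConfig) -> dict[str, str]:
    out = {c: refs[c] for c in config.chrom_names() if c != config.slr_chrom}
    out[config.slr_chrom] = refs[f"{config.slr_chrom}_X"]
    return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# Pooled allele depths
# ---------------------------------------------------------------------------

def simulate_pools(refs: dict[str, str], truth: SimulatedTruth,
                   config: ScenarioConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-site allele depths for the female and male bulks.

    Sampling model, per site: the population allele frequency at autosomal
    sites is Uniform(0.2, 0.8) and shared by the sexes; each finite pool
    resamples its allele frequency as Binomial(2N, p)/2N.  Y-specific sites
    inside the SLR are heterozygous in every male (pool frequency exactly
    1/2) and absent from females.  Pool depth is Poisson(depth_mean) and the
    alt count Binomial(depth, f') with f' = f(1-e) + (1-f)e for symmetric
    per-base error e.  Positions are 1-based on the male reference.
    """
    if config.depth_mean <= 0:
        raise ConfigurationError("depth_mean must be positive")
    if rng is None:
        rng = config.rng("pools")
    mref = male_reference(refs, config)
    chrom, slr_s, slr_e = config.slr
    msy = [(s, e) for s, e in sorted(config.msy_segments)]

    frames = []
    for name, seq in mref.items():
        length = len(seq)
        n_sites = int(round(length / 1000 * config.snp_density))
        pos0 = np.sort(rng.choice(length, size=min(n_sites, length),
                                  replace=False))
        if name == chrom:
            in_slr = (pos0 >= slr_s) & (pos0 < slr_e)
            pos0 = pos0[~in_slr]
            # Y-specific sites: dense, in the SLR but outside hemizygous MSY
            n_extra = int(round((slr_e - slr_s) / 1000
                                * config.snp_density * config.slr_snp_factor))
            cand = rng.choice(np.arange(slr_s, slr_e), size=min(
                n_extra * 3, slr_e - slr_s), replace=False)
            keep = np.ones(cand.size, dtype=bool)
            for s, e in msy:
                keep &= ~((cand >= s) & (cand < e))
            yspec = np.sort(cand[keep][:n_extra])
            frames.append(_sample_sites(name, seq, pos0, False, config, rng))
            frames.append(_sample_sites(name, seq, yspec, True, config, rng))
        else:
            frames.append(_sample_sites(name, seq, pos0, False, config, rng))

    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return df


def _sample_sites(chrom: str, seq: str, pos0: np.ndarray, y_specific: bool,
                  config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = pos0.size
    e = config.error_rate
    if y_specific:
        f_f = np.zeros(n)
        f_m = np.full(n, 0.5)
    else:
        p = rng.uniform(0.2, 0.8, n)
        f_f = rng.binomial(2 * config.n_females, p) / (2 * config.n_females)
        f_m = rng.binomial(2 * config.n_males, p) / (2 * config.n_males)
    f_f = f_f * (1 - e) + (1 - f_f) * e
    f_m = f_m * (1 - e) + (1 - f_m) * e
    dp_f = rng.poisson(config.depth_mean, n)
    dp_m = rng.poisson(config.depth_mean, n)
    alt_f = rng.binomial(dp_f, f_f)
    alt_m = rng.binomial(dp_m, f_m)
    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    refs = seq_arr[pos0].tobytes().decode()
    alt_choices = np.array(list("ACGT"))
    alts = []
    draws = rng.integers(0, 3, n)
    for rb, d in zip(refs, draws):
        others = [b for b in "ACGT" if b != rb]
        alts.append(others[d] if rb in "ACGT" else alt_choices[d])
    return pd.DataFrame({
        "chrom": chrom,
        "pos": pos0 + 1,
        "ref": list(refs),
        "alt": alts,
        "ad_ref_f": dp_f - alt_f, "ad_alt_f": alt_f,
        "ad_ref_m": dp_m - alt_m, "ad_alt_m": alt_m,
    })


def simulate_null_sites(n_sites: int, chrom_length: int, n_females: int,
                        n_males: int, depth_mean: float, error_rate: float,
                        rng: np.random.Generator,
                        chrom: str = "chr1") -> pd.DataFrame:
    """A single chromosome with no sex-linked region (null scan input)."""
    pos0 = np.sort(rng.choice(chrom_length, size=n_sites, replace=False))
    n = pos0.size
    e = error_rate
    p = rng.uniform(0.2, 0.8, n)
    f_f = rng.binomial(2 * n_females, p) / (2 * n_females)
    f_m = rng.binomial(2 * n_males, p) / (2 * n_males)
    f_f = f_f * (1 - e) + (1 - f_f) * e
    f_m = f_m * (1 - e) + (1 - f_m) * e
    dp_f = rng.poisson(depth_mean, n)
    dp_m = rng.poisson(depth_mean, n)
    alt_f = rng.binomial(dp_f, f_f)
    alt_m = rng.binomial(dp_m, f_m)
    return pd.DataFrame({
        "chrom": chrom, "pos": pos0 + 1, "ref": "A", "alt": "T",
        "ad_ref_f": dp_f - alt_f, "ad_alt_f": alt_f,
        "ad_ref_m": dp_m - alt_m, "ad_alt_m": alt_m,
    })


# ---------------------------------------------------------------------------
# Binned depth-of-coverage tables
# ---------------------------------------------------------------------------

def simulate_depth(refs: dict[str, str], truth: SimulatedTruth,
                   config: ScenarioConfig, bin_size: int = 1000,
                   rng: np.random.Generator | None = None):
    """Per-bin mean depth per pool on the male reference.

    Hemizygous MSY bins: the female pool retains only a trace of mismapped
    coverage (2% of depth_mean) while the male pool drops to half depth
    (single copy).  Returns ``(depth_f, depth_m)`` DataFrames with columns
    chrom, start, depth.
    """
    if rng is None:
        rng = config.rng("depth")
    mref = male_reference(refs, config)
    rows_f, rows_m = [], []
    msy = sorted(config.msy_segments)
    for name, seq in mref.items():
        n_bins = len(seq) // bin_size
        starts = np.arange(n_bins) * bin_size
        mean_f = np.full(n_bins, config.depth_mean)
        mean_m = np.full(n_bins, config.depth_mean)
        if name == config.slr_chrom:
            for s, e in msy:
                sel = (starts >= s - bin_size + 1) & (starts < e)
                full = (starts >= s) & (starts + bin_size <= e)
                mean_f[full] = config.depth_mean * 0.02
                mean_m[full] = config.depth_mean * 0.5
                part = sel & ~full
                mean_f[part] = config.depth_mean * 0.5
                mean_m[part] = config.depth_mean * 0.75
        d_f = rng.poisson(mean_f * bin_size) / bin_size
        d_m = rng.poisson(mean_m * bin_size) / bin_size
        rows_f.append(pd.DataFrame({"chrom": name, "start": starts, "depth": d_f}))
        rows_m.append(pd.DataFrame({"chrom": name, "start": starts, "depth": d_m}))
    return (pd.concat(rows_f, ignore_index=True),
            pd.concat(rows_m, ignore_index=True))


# ---------------------------------------------------------------------------
# CDS pairs at controlled synonymous divergence
# ---------------------------------------------------------------------------

#: codon prefixes whose 3rd position is 4-fold degenerate while changes at
#: positions 1-2 are always nonsynonymous; under NG86 each such codon
#: contributes exactly one synonymous site.
_FOURFOLD_PREFIXES = ("TC", "CC", "AC", "GT", "GC", "GG")


@dataclass
class SimulatedCodingPair:
    id_x: str
    id_y: str
    cds_x: str
    cds_y: str
    target_ks: float
    realized_p: float          # raw proportion of differing synonymous sites
    in_inversion: bool = False

    @property
    def realized_ks(self) -> float:
        p = self.realized_p
        return -0.75 * math.log1p(-4.0 * p / 3.0)


def simulate_gene_pairs(ks_targets: Sequence[float], cds_length: int,
                        rng: np.random.Generator | int = 0
                        ) -> list[SimulatedCodingPair]:
    """One X/Y CDS pair per target Ks.

    Codons are drawn from 4-fold-degenerate families and only third
    positions mutate, each flipped with probability
    p = (3/4)(1 - exp(-4 Ks / 3)) to a uniformly chosen other base, so the
    Jukes-Cantor-corrected expectation of the synonymous divergence equals
    the target.  No stop codons can arise.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if cds_length % 3:
        raise ValueError("cds_length must be a multiple of 3")
    out = []
    for k, ks in enumerate(ks_targets):
        if not 0.0 <= ks < 0.75:
            raise ValueError(
                f"target Ks {ks} outside [0, 0.75) (Jukes-Cantor domain)")
        n_codons = cds_length // 3
        prefixes = rng.integers(0, len(_FOURFOLD_PREFIXES), n_codons)
        thirds = rng.integers(0, 4, n_codons)
        bases = "ACGT"
        cds_x = "".join(_FOURFOLD_PREFIXES[p] + bases[t]
                        for p, t in zip(prefixes, thirds))
        p_sub = 0.75 * -math.expm1(-4.0 * ks / 3.0)
        flip = rng.random(n_codons) < p_sub
        y_thirds = thirds.copy()
        shift = rng.integers(1, 4, n_codons)
        y_thirds[flip] = (thirds[flip] + shift[flip]) % 4
        cds_y = "".join(_FOURFOLD_PREFIXES[p] + bases[t]
                        for p, t in zip(prefixes, y_thirds))
        realized_p = float(np.mean(thirds != y_thirds))
        out.append(SimulatedCodingPair(
            id_x=f"pairX_{k}", id_y=f"pairY_{k}", cds_x=cds_x, cds_y=cds_y,
            target_ks=float(ks), realized_p=realized_p))
    return out


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def simulate_methylome(config: ScenarioConfig,
                       rng: np.random.Generator | None = None):
    """Per-cytosine counts for two environments x two sexes x replicates.

    The target promoter (2 kb upstream of the feminizing gene's translation
    start) carries ``meth_effect`` extra methylation in males only, in both
    environments.  Returns ``(records, genes, truth_dmrs)``: a long table
    with sample metadata columns (sample, sex, environment, replicate), the
    gene models, and the implanted male-hyper promoter interval.
    """
    if rng is None:
        rng = config.rng("methylome")
    chrom = "chr1"
    target = GeneModel("ARR17_like", chrom, "+", 100_000, 101_500)
    genes = [target]
    for i in range(20):
        s = 200_000 + i * 10_000
        genes.append(GeneModel(f"bg{i:02d}", chrom, "+" if i % 2 else "-",
                               s, s + 1_500))

    contexts = np.array(["CG", "CHG", "CHH"])
    ctx_probs = np.array([0.4, 0.3, 0.3])

    def promoter_positions(g: GeneModel, n: int):
        if g.strand == "+":
            lo, hi = max(0, g.start - 2000), g.start
        else:
            lo, hi = g.end, g.end + 2000
        return np.sort(rng.choice(np.arange(lo, hi), size=n, replace=False))

    # fixed cytosine map shared by all samples
    cyt_rows = []
    for g in genes:
        n = 200 if g is target else 60
        pos = promoter_positions(g, n)
        ctx = contexts[rng.choice(3, size=n, p=ctx_probs)]
        strand = np.where(rng.random(n) < 0.5, "+", "-")
        cyt_rows.append(pd.DataFrame({
            "chrom": g.chrom, "pos": pos + 1, "strand": strand,
            "context": ctx, "gene": g.id,
        }))
    cyt = pd.concat(cyt_rows, ignore_index=True)
    base = cyt["context"].map(config.meth_baseline).to_numpy(float)

    records = []
    for env in (1, 2):
        for sex in ("F", "M"):
            for rep in range(1, config.meth_replicates + 1):
                level = base.copy()
                if sex == "M":
                    at_target = (cyt["gene"] == target.id).to_numpy()
                    level[at_target] = level[at_target] + config.meth_effect
                if (level > 1).any() or (level < 0).any():
                    import warnings
                    warnings.warn("methylation level clipped to [0, 1]",
                                  stacklevel=2)
                    level = np.clip(level, 0.0, 1.0)
                total = rng.poisson(config.meth_depth, level.size)
                meth = rng.binomial(total, level)
                df = cyt[["chrom", "pos", "strand", "context"]].copy()
                df["n_methylated"] = meth
                df["n_unmethylated"] = total - meth
                df["sample"] = f"E{env}_{sex}{rep}"
                df["sex"] = sex
                df["environment"] = env
                df["replicate"] = rep
                records.append(df)
    records = pd.concat(records, ignore_index=True)

    promoter = GenomeInterval(chrom, target.start - 2000, target.start)
    truth_dmrs = [(promoter, "male-hyper")]
    return records, genes, truth_dmrs


# ---------------------------------------------------------------------------
# Small RNA reads
# ---------------------------------------------------------------------------

def simulate_smallrna(config: ScenarioConfig,
                      segments: Mapping[str, str],
                      inverted: Sequence[str] = ("S1", "S2"),
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Reads sampled as substrings of the inverted segments, plus background.

    ``segments`` maps segment names to sequences; names in ``inverted`` share
    1 - background_rate of the reads, the rest share the remainder.  Lengths
    follow ``smallrna_len_probs``; strand is random.  Returns a DataFrame
    with columns read_id, origin, length, seq.
    """
    if rng is None:
        rng = config.rng("smallrna")
    lens = np.array(sorted(config.smallrna_len_probs))
    lprobs = np.array([config.smallrna_len_probs[l] for l in lens], float)
    lprobs = lprobs / lprobs.sum()
    max_len = int(lens.max())
    for name, seq in segments.items():
        if len(seq) < max_len:
            raise ValueError(
                f"segment {name} ({len(seq)} bp) shorter than the longest "
                f"read length ({max_len} nt)")
    names = list(segments)
    fg = [n for n in names if n in inverted]
    bg = [n for n in names if n not in inverted]
    weights = np.zeros(len(names))
    for n in fg:
        weights[names.index(n)] = (1 - config.smallrna_background_rate) / len(fg)
    for n in bg:
        weights[names.index(n)] = config.smallrna_background_rate / max(len(bg), 1)
    weights = weights / weights.sum()

    origin = rng.choice(len(names), size=config.n_smallrna_reads, p=weights)
    rlen = lens[rng.choice(lens.size, size=config.n_smallrna_reads, p=lprobs)]
    rows = []
    for i, (oi, L) in enumerate(zip(origin, rlen)):
        seq = segments[names[oi]]
        start = rng.integers(0, len(seq) - L + 1)
        read = seq[start:start + L]
        if rng.random() < 0.5:
            read = revcomp(read)
        rows.append((f"read{i:05d}", names[oi], int(L), read))
    return pd.DataFrame(rows, columns=["read_id", "origin", "length", "seq"])


# ---------------------------------------------------------------------------
# Expression count matrices
# ---------------------------------------------------------------------------

def simulate_expression(config: ScenarioConfig,
                        rng: np.random.Generator | None = None):
    """Negative-binomial count matrix with implanted SLG/SBG genes.

    Returns ``(counts, lengths, samples, labels)``: integer counts
    (genes x samples), per-gene lengths (bp), a sample sheet with sex,
    tissue and replicate, and the per-gene per-tissue truth labels
    ('male-limited', 'female-limited', 'male-biased', 'female-biased',
    'unbiased', 'not-expressed').
    """
    d = config.expr
    if d.n_reps < 2:
        raise ValueError("need >= 2 replicates per sex x tissue for DE testing")
    if rng is None:
        rng = config.rng("expression")
    G = d.n_genes
    genes = [f"g{i:05d}" for i in range(G)]
    lengths = pd.Series(rng.integers(500, 5001, G), index=genes, name="length")
    base = np.exp(rng.normal(d.base_mean_log, d.base_mean_sigma, G))

    labels = pd.DataFrame("unbiased", index=genes, columns=list(d.tissues))
    # multiplier[gene, sex, tissue]
    mult = {(sex, t): np.ones(G) for sex in "FM" for t in d.tissues}

    cursor = 0

    def take(n):
        nonlocal cursor
        idx = np.arange(cursor, cursor + n)
        cursor += n
        return idx

    fold = 2.0 ** d.log2fc
    t0, t1 = d.tissues[0], d.tissues[1]
    # sex-limited genes: a 'both tissues' bucket and one bucket per tissue
    for sex, other in (("M", "F"), ("F", "M")):
        n = d.n_male_limited if sex == "M" else d.n_female_limited
        for pattern in ("both", t0, t1):
            idx = take(n)
            tissues = d.tissues if pattern == "both" else (pattern,)
            for t in tissues:
                mult[(other, t)][idx] = 0.0
                labels.iloc[idx, labels.columns.get_loc(t)] = \
                    f"{'male' if sex == 'M' else 'female'}-limited"
    # sex-biased genes, implanted in the first tissue only
    for sex, frac in (("M", 0.5), ("F", 0.5)):
        idx = take(int(d.n_sbg * frac))
        mult[(sex, t0)][idx] = fold
        labels.iloc[idx, labels.columns.get_loc(t0)] = \
            f"{'male' if sex == 'M' else 'female'}-biased"
    # silent genes
    idx = take(d.n_silent)
    for key in mult:
        mult[key][idx] = 0.0
    base[idx] = 0.0
    labels.iloc[idx, :] = "not-expressed"

    r = 1.0 / d.dispersion
    cols, meta = {}, []
    for sex in ("F", "M"):
        for t in d.tissues:
            for rep in range(1, d.n_reps + 1):
                mu = base * mult[(sex, t)]
                counts = np.zeros(G, dtype=np.int64)
                nz = mu > 0
                counts[nz] = rng.negative_binomial(r, r / (r + mu[nz]))
                name = f"{sex}_{t}_{rep}"
                cols[name] = counts
                meta.append((name, sex, t, rep))
    counts = pd.DataFrame(cols, index=genes)
    samples = pd.DataFrame(meta, columns=["sample", "sex", "tissue", "replicate"])
    return counts, lengths, samples, labels
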