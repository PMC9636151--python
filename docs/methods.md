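# Methods

This note documents the statistical models, defaults and design choices
behind each stage, what the synthetic generator does and does not
emulate, and the package's known limitations.

## Coordinate conventions

All intervals are 0-based, half-open internally; VCF and GFF3 use 1-based
inclusive coordinates only at the I/O boundary, BED is written natively.
Reported "kb" values are integer kb truncated toward zero, matching the
way such intervals are usually printed.

## Synthetic scenario (`simdata`)

The generator produces a toy XY genome whose structure — not its scale —
mirrors a wild-population sex-determination study:

- **Genome.** 4 chromosomes × 2 Mb of i.i.d. sequence. The last
  chromosome exists as an X and a Y haplotype. The Y carries a 200-kb
  peritelomeric SLR containing three novel (hemizygous) MSY inserts
  (20/10/30 kb), an in-place reverse-complemented inversion (30 kb), and,
  inside the largest insert, a palindrome construct: a 600-bp arm pair in
  inverted orientation flanking two inverted 300-bp copies (S1/S2) of a
  fragment of an autosomal "feminizing" gene, a third forward copy (S3)
  and a larger forward segment (L2) from disjoint parts of the same gene.
- **Pools.** 100 female and 96 male diploids, matching the bulk sizes a
  wild BSA design of this kind uses. Autosomal sites share a population
  allele frequency p ~ Uniform(0.2, 0.8) (the wild-bulk frequency
  distribution is not identifiable from such a study; uniform on a
  mid-range band is a neutral stand-in and is configurable); each finite
  pool resamples its frequency as Binomial(2N, p)/2N, so pool size enters
  the sampling model. Y-specific sites (SLR outside the MSY inserts, at
  3× the background SNP density) are heterozygous in every male and
  absent in females. Pool depth is Poisson(60); alt counts are
  Binomial(depth, f′) with f′ = f(1−e) + (1−f)e for symmetric per-base
  error e = 0.002. No SNP sites are placed inside MSY inserts — a variant
  caller sees no female reads there.
- **Depth tables.** Per-kb binned depth per pool; MSY bins give the male
  pool half depth (one copy) and the female pool a 2% mismapping residue.
- **CDS pairs.** For each target Ks, a CDS built from codon families
  whose third position is 4-fold degenerate while first/second-position
  changes are always nonsynonymous ({TC,CC,AC,GT,GC,GG}N). Only third
  positions mutate, with probability p = (3/4)(1 − exp(−4Ks/3)), so under
  NG86 the synonymous site count is exactly one per codon and the
  Jukes–Cantor-corrected expectation equals the target — the estimator
  recovery test is exact by construction, not by tuning. Targets ≥ 0.75
  (saturation) are rejected.
- **Methylome.** Two environments × two sexes × three replicates at
  Poisson(30) coverage; baselines 0.8/0.4/0.1 for CG/CHG/CHH; the target
  promoter gains +0.4 in males only, in both environments (clipped at 1
  with a warning, so the realized CG effect is smaller — as in real data,
  where CG sites are near-saturated).
- **Small RNA.** 5,000 reads as substrings of S1/S2 (90%) and of the
  background segments (10%), lengths 24:21:22 at 0.8:0.1:0.1, random
  strand.
- **Expression.** 2,000 genes × 2 tissues × 2 sexes × 5 replicates;
  negative-binomial counts (dispersion 0.1, lognormal base means around
  100); implanted sex-limited genes (zero mean in one sex; 30 per sex per
  tissue-pattern bucket), 200 sex-biased genes at |log2FC| = 2 in the
  first tissue, and 50 silent genes.

All randomness flows from one seed through fixed named substreams, so
stages are reproducible independently of call order; identical seeds give
byte-identical outputs.

What the generator does **not** emulate: read-level errors and mapping
bias, linkage disequilibrium and population structure, recombination
within pools, TE content, replicate-level methylation dispersion beyond
binomial sampling, and library-composition artifacts. Passing recovery
tests therefore demonstrate the correctness and calibration of the
statistics under their stated sampling models, not robustness to every
real-data pathology.

## ΔSNP-index scan (`bsa`)

SNP-index is alt-over-total depth relative to the mapping reference (the
"fraction of mismatching reads" reading is available by swapping ref/alt
conventions upstream); Δ = male − female, so a Y-specific allele absent
from females gives Δ ≈ +0.5. Sites need total depth ≥ 10 in both pools.

**Permutation scheme.** Individual labels cannot be permuted in pooled
data, so each replicate swaps the two pools' depth vectors independently
per site with probability ½ — under the null of no sex association the
pools are exchangeable site by site, and a swap negates that site's Δ
while preserving the depth structure. The envelope is two-sided: the
(1−γ)/2 and 1−(1−γ)/2 empirical quantiles of the B = 1000 replicate
window means, per window by default. A `genome_wide` option instead takes
the quantiles of each replicate's extreme window mean across the genome,
giving one family-wise band — by construction a per-window γ = 0.95 band
leaves ~5% of null windows outside (that is what the calibration test
measures), so candidate *calling* on a many-window scan should use the
family-wise band.

**Windows.** Tiling from 0 by `step`, truncated at chromosome ends, no
wraparound. Windows with fewer than 10 sites are reported but flagged and
never called. Flagged windows also never *break* a candidate run: a
coverage dropout carries no evidence against sex linkage, and hemizygous
MSY segments inside a true SLR produce exactly such dropouts. An
evaluated below-threshold window does end a run.

**Scales.** Module defaults are the full-size geometry (1-Mb window,
10-kb step). The pipeline's toy scenario uses window = step = 10 kb so a
candidate boundary is resolvable to one step, the family-wise envelope,
and a two-window minimum candidate span (15 kb): a single-window
exceedance at the family-wise level is rare, and requiring two adjacent
exceedances drives the autosomal false-call rate to effectively zero
while a 200-kb SLR spans 20 windows. `select_slr` keeps the longest
male-reference candidate above the minimum length (on real data: the
length of the largest female-reference artifact, ~7 kb in the motivating
study), breaking ties by (chromosome, start).

## MSY calling (`coverage`)

Depths are normalized per pool by the genome-wide median (excluding the
candidate SLR), making calls invariant to sequencing effort. A bin is
male-specific when the normalized female/male ratio is ≤ 0.2 and the male
normalized depth is ≥ 0.25; runs merge across single-bin gaps and must
total ≥ 5 kb. The male-depth floor sits at 0.25 rather than the
hemizygous expectation of 0.5 because a floor at the expectation would
reject half of all true one-copy bins on noise alone; 0.25 separates
"present at one copy" from "absent/unmappable". The ratio ceiling of 0.2
is far above the simulated mismapping residue (~0.04) and far below
diploid balance; at 60× the female-null signal never triggers calls.

## Inverted-repeat finder (`palindrome`)

Seeds are exact matches of length ≥ 100 between the sequence and its
reverse complement, sampled every 20 positions; each seed extends
ungapped in both directions while the running identity stays ≥ 0.9,
committing only up to the last matching position. Arms stay equal length
(anti-diagonal geometry) and never overlap; N runs break seeds;
co-diagonal seeds converge to the same maximal pair and overlapping pairs
deduplicate keeping the longest. Gapped extension is deliberately not
implemented: ungapped extension keeps the finder exactly testable against
a brute-force all-substring-pairs oracle (at min_identity = 1.0 the two
enumerate identical maximal inverted matches). Greedy identity-bounded
extension can overrun a true arm by up to roughly seed-length into random
flanks before identity drops below the floor, so reported boundaries
carry ~seed-length resolution; reported identity is always recomputable
from coordinates and ≥ the floor.

## Ka/Ks, clock and strata (`divergence`)

Homolog pairs are aligned globally at the protein level (BLOSUM62, gap
open −10 / extend −0.5) and back-translated; gapped columns are dropped.
NG86 counting: per-codon synonymous site fractions averaged over the two
sequences, with changes to stop codons counted as nonsynonymous; multiple
mutational pathways averaged with equal weight, excluding pathways
through stops (falling back to all orderings if every pathway is
blocked); Jukes–Cantor correction d = −(3/4)ln(1 − 4p/3) applied to both
proportions, with p ≥ 0.75 reported as undefined (NaN) rather than a
number. NG86 was chosen over ML codon models because it is exactly
enumerable (site/path oracle tests) and adequate at the Ks ≤ 0.15 range
strata dating needs; the implementation is cross-checked against an
independent library implementation in the tests.

Mean Ks over a gene set drops undefined values and Tukey-fence outliers
(1.5 × IQR) before averaging. The clock is linear, T = Ks·t_cal/ks_cal
(the per-lineage factor 2 cancels); the default calibration is a 60-My
genus split at Ks = 0.146. The companion literature sometimes prints the
calibration as 0.0146, which is inconsistent by exactly ×10 with the ages
derived from it (0.040 × 60/0.146 = 16.44 My); both values are
selectable. Strata: old if mean Ks > 0.1, young if < 0.05, otherwise
unassigned — the gap between thresholds is deliberate. Ka/Ks > 1 flags
relaxed/positive selection; Ks = 0 yields an undefined flag, not
infinity.

## Small RNA (`smallrna`)

Reads (18–30 nt) are assigned to every segment containing an exact match
on either strand (≤ 1 mismatch optional, via edlib); multi-mapping reads
count once per segment — fractional assignment is not attempted since the
typical question is "which segments are covered", not quantitative
apportioning. Per segment: a length histogram, the 24-nt fraction, and a
flag when it exceeds 0.75 strictly. "Hairpin" is operationalized as
inverted-repeat complementarity: the best ungapped sliding-offset
identity between one segment and the reverse complement of the other,
over overlaps covering ≥ 80% of the shorter segment, paired at ≥ 0.8.
Thermodynamic RNA folding is intentionally out of scope; complementarity
is the property the biology invokes.

## Methylation (`methylome`)

Region levels are pooled-count weighted: Σ methylated / Σ total over
covered cytosines, per context — invariant to how counts are split across
rows and dominated by well-covered cytosines, as a weighted level should
be. Promoters are the 2 kb upstream of the translation start site
(strand-aware, clipped at chromosome bounds).

The DMR caller is a deliberately simple, deterministic approximation of
dispersion-shrinkage callers: replicate counts pool per sex; each 200-bp
window × context gets a Fisher exact test on the pooled 2×2 table; BH
across all tested windows; a DMR needs q < 0.05, |level difference| ≥
0.1 and ≥ 5 covered cytosines; adjacent significant windows of one
context and direction merge. Pooling ignores replicate-level dispersion,
so on real data with biological replicate variance its p-values are
anticonservative relative to a shrinkage model — the min-difference guard
is the practical defense, and the caller is documented as an
approximation, not a reimplementation of the shrinkage approach. Genes
link to DMRs through ≥ 1 bp overlap with body or promoter; per-direction
gene sets intersect across environments.

## Expression (`expression`)

FPKM = count/(length/10³)/(total/10⁶), with per-sample totals defaulting
to column sums. "Expressed" is group-mean FPKM strictly > 1 (an
every-replicate rule is available; the mean rule is the default because
it is monotone in depth and robust to one dropout replicate). The native
differential test normalizes libraries by median-of-ratios, estimates a
per-gene NB dispersion by method of moments pooled across groups
(var = μ + αμ²), and tests the log2 fold change (pseudo-count 0.5) with a
Wald statistic referred to t with n₁+n₂−2 df — calibrated to ~5% type-I
at the simulated scale and agreeing closely with an established NB tester
(fold-change correlation > 0.99 on the cross-check fixture). Externally
computed p-values can be slotted into `classify`, which applies the
decision rule with precedence: not-expressed → limited (one sex only,
regardless of the test) → biased (both expressed, |log2FC| > 1, q <
0.05) → unbiased. The tissue partition splits every class into
tissue-specific and shared buckets.

## Orchestration (`pipeline`, CLI)

`run_all` chains simulate → scan → MSY → palindrome → Ks → small RNA →
methylation → expression in one process, writing each stage to its own
directory and recording a manifest (config hash, seed, per-stage output
content hashes and wall times). Identical config + seed gives identical
output hashes; stages never mutate each other's outputs. The report
includes truth-comparison sections only when truth is available. Problem
sizes throughout (toy genome, 20-seed calibration runs, 30-kb CDS,
2,000-gene matrices) are chosen so the full suite and the acceptance
script run in minutes on a single CPU — desk scale, by design.

## Known limitations

- The permutation envelope assumes sites are independent under the null;
  strong LD between nearby sites would make the envelope anticonservative
  at real-data densities.
- The scan reports candidate boundaries at window resolution; sub-step
  localization is out of scope.
- NG86 saturates above Ks ≈ 0.75 and is biased for very short alignments;
  use the replicate median (as the tests do) for generator-noise-free
  recovery statements.
- The DMR and DE tests are documented approximations of shrinkage-based
  tools; effect-size guards, not dispersion shrinkage, control their
  real-data behavior.
- MSY-calling thresholds are heuristics surfaced in configuration, not
  estimates; they were chosen so the simulated female-null never triggers
  at 60× and should be revisited for other depths.
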