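"""Native inverted-repeat (palindrome-arm) finder.

Replaces an external self-alignment: the sequence is compared against its
own reverse complement with exact seeds of length ``exact_seed`` sampled
every ``step`` positions, each seed extended ungapped in both directions
while the running identity stays at or above ``min_identity``.  Gapped
extension is deliberately not implemented; co-diagonal seeds extend to the
same maximal pair and are deduplicated keeping the longest.  On a Y
chromosome such arm pairs flanking a male-specific region are the
palindromes that enable arm-to-arm gene conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats import GenomeInterval
from .sequtils import revcomp

_ALPHABET = set("ACGTN")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "\0"}
_MAX_MISMATCH_RUN = 10


@dataclass(frozen=True)
class ArmPair:
    """Two arms where arm2 aligns to the reverse complement of arm1."""

    arm1: GenomeInterval
    arm2: GenomeInterval
    identity: float

    def __post_init__(self):
        if self.arm1.start >= self.arm2.start:
            raise ValueError("arm1 must precede arm2")
        if self.arm1.end > self.arm2.start:
            raise ValueError("arms must not overlap")

    @property
    def spacer(self) -> int:
        return self.arm2.start - self.arm1.end

    @property
    def arm_length(self) -> int:
        return self.arm1.length


def pair_identity(seq: str, a1: int, a2: int, b1: int, b2: int) -> float:
    """Ungapped identity between seq[a1:a2] and revcomp(seq[b1:b2])."""
    x = seq[a1:a2]
    y = revcomp(seq[b1:b2])
    n = min(len(x), len(y))
    if n == 0:
        return 0.0
    return sum(cx == cy for cx, cy in zip(x[:n], y[:n])) / n


def find_inverted_repeats(seq: str, exact_seed: int = 100, step: int = 20,
                          min_identity: float = 0.9,
                          max_spacer: int | None = None,
                          min_arm: int | None = None,
                          chrom: str = "seq") -> list[ArmPair]:
    """Find inverted-repeat arm pairs within ``seq``.

    Parameters mirror a self-alignment: ``exact_seed`` is the exact-match
    seed length, ``step`` the seed sampling stride on the reverse
    complement, ``min_identity`` the running-identity floor during ungapped
    extension.  ``min_arm`` (default ``exact_seed``) filters short pairs and
    ``max_spacer`` (default unlimited) bounds the arm separation.  N runs
    break seeds; characters outside A/C/G/T/N raise.
    """
    seq = seq.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters {bad}")
    if min_arm is None:
        min_arm = exact_seed
    L = len(seq)
    if L < 2 * min_arm:
        raise ValueError("sequence shorter than twice the minimum arm length")
    k = exact_seed
    rc = revcomp(seq)

    index: dict[str, list[int]] = {}
    for a in range(0, L - k + 1):
        kmer = seq[a:a + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(a)

    raw: set[tuple[int, int, int, int]] = set()
    for j in range(0, L - k + 1, step):
        kmer = rc[j:j + k]
        for a in index.get(kmer, ()):
            b = L - j - k            # seq[b:b+k] revcomp-matches seq[a:a+k]
            if a > b:
                a, b = b, a
            if a == b:
                # a segment matching its own reverse complement: split once
                half = k // 2
                if half >= min_arm:
                    raw.add((a, a + half, a + k - half, a + k))
                continue
            if a + k > b:            # overlapping arms: trim to the midpoint
                continue
            raw.add(_extend(seq, a, a + k, b, b + k, min_identity))

    pairs: list[ArmPair] = []
    for a1, a2, b1, b2 in raw:
        if a2 - a1 < min_arm:
            continue
        if max_spacer is not None and b1 - a2 > max_spacer:
            continue
        ident = pair_identity(seq, a1, a2, b1, b2)
        if ident < min_identity:
            continue
        pairs.append(ArmPair(GenomeInterval(chrom, a1, a2),
                             GenomeInterval(chrom, b1, b2), ident))

    # deduplicate overlapping pairs, keeping the longest
    pairs.sort(key=lambda p: (-p.arm_length, p.arm1.start, p.arm2.start))
    kept: list[ArmPair] = []
    for p in pairs:
        if any(p.arm1.overlaps(q.arm1) and p.arm2.overlaps(q.arm2)
               for q in kept):
            continue
        kept.append(p)
    kept.sort(key=lambda p: (p.arm1.start, p.arm2.start))
    return kept


def _extend(seq: str, a1: int, a2: int, b1: int, b2: int,
            min_identity: float) -> tuple[int, int, int, int]:
    """Grow an exact seed outward while running identity >= min_identity.

    Arms stay equal length: growing arm1 rightward grows arm2 leftward and
    vice versa (anti-diagonal geometry of an inverted match).  An extension
    is committed only up to the last matching position that keeps the
    running identity above the floor.
    """
    L = len(seq)
    matches = a2 - a1
    total = a2 - a1

    # rightward on arm1 / leftward on arm2
    t, miss_run = 0, 0
    best = 0
    m, tot = matches, total
    while a2 + t < b1 - 1 - t and a2 + t < L and b1 - 1 - t >= 0:
        hit = _COMP.get(seq[a2 + t], "\0") == seq[b1 - 1 - t]
        m += hit
        tot += 1
        if hit and m / tot >= min_identity:
            best = t + 1
            matches, total = m, tot
            miss_run = 0
        elif hit:
            miss_run = 0
        else:
            miss_run += 1
            if miss_run >= _MAX_MISMATCH_RUN or m / tot < min_identity:
                break
        t += 1
    a2 += best
    b1 -= best

    # leftward on arm1 / rightward on arm2
    t, miss_run = 0, 0
    best = 0
    m, tot = matches, total
    while a1 - 1 - t >= 0 and b2 + t < L:
        hit = _COMP.get(seq[a1 - 1 - t], "\0") == seq[b2 + t]
        m += hit
        tot += 1
        if hit and m / tot >= min_identity:
            best = t + 1
            miss_run = 0
        elif hit:
            miss_run = 0
        else:
            miss_run += 1
            if miss_run >= _MAX_MISMATCH_RUN or m / tot < min_identity:
                break
        t += 1
    a1 -= best
    b2 += best
    return a1, a2, b1, b2


def text_dotplot(seq: str, width: int = 60) -> str:
    """Coarse text self-dotplot against the reverse complement (debugging)."""
    n = len(seq)
    stride = max(1, n // width)
    rc = revcomp(seq)
    rows = []
    for i in range(0, n - stride, stride):
        row = []
        for j in range(0, n - stride, stride):
            row.append("#" if seq[i:i + stride] == rc[j:j + stride] else ".")
        rows.append("".join(row))
    return "\n".join(rows)
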