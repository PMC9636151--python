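"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a quantity by direct enumeration, staying
deliberately independent of the implementation path it checks.
"""

from __future__ import annotations

import itertools
import math

from Bio.Data.CodonTable import standard_dna_table

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = set(standard_dna_table.stop_codons)


def brute_force_window_means(positions, deltas, chrom_len, window, step):
    """O(n * windows) windowed means over 0-based positions."""
    out = []
    for start in range(0, max(chrom_len, 1), step):
        end = min(start + window, chrom_len)
        vals = [d for p, d in zip(positions, deltas) if start <= p < end]
        out.append((start, end, len(vals),
                    sum(vals) / len(vals) if vals else None))
    return out


def brute_force_inverted_repeats(seq, min_arm):
    """All maximal exact inverted matches via anti-diagonal runs.

    Returns a set of (a1, a2, b1, b2) with seq[a1:a2] equal to the reverse
    complement of seq[b1:b2], arms non-overlapping and of length >= min_arm.
    """
    n = len(seq)
    hits = set()
    # positions (p, q) with seq[p] complementary to seq[q] lie on runs of
    # constant p + q for an inverted match
    for c in range(2 * n - 1):
        run = []
        p_lo = max(0, c - n + 1)
        for p in range(p_lo, min(c + 1, n)):
            q = c - p
            if q < p:
                break
            ok = seq[p] in _COMP and _COMP[seq[p]] == seq[q]
            run.append((p, q, ok))
        # maximal runs of ok positions along this anti-diagonal
        i = 0
        while i < len(run):
            if not run[i][2]:
                i += 1
                continue
            j = i
            while j + 1 < len(run) and run[j + 1][2]:
                j += 1
            p1, q1, _ = run[i]       # p ascending, q descending
            p2, q2, _ = run[j]
            # the full match pairs (p1..p2) with (q2..q1); by symmetry the
            # run continues on the q side, total length p2 - p1 + 1 + ...
            a1, a2 = p1, p2 + 1
            b1, b2 = q2, q1 + 1
            length = a2 - a1
            if length >= min_arm and a2 <= b1:
                hits.add((a1, a2, b1, b2))
            i = j + 1
    return hits


def _aa(codon):
    if codon in _STOPS:
        return "*"
    return standard_dna_table.forward_table[codon]


def ng86_enumeration(codons_x, codons_y):
    """NG86 by direct enumeration: returns (ka, ks, S_sites, N_sites)."""
    assert len(codons_x) == len(codons_y) and len(codons_x) % 3 == 0
    n_codons = len(codons_x) // 3
    s_sites = sd = nd = 0.0
    for i in range(n_codons):
        cx = codons_x[3 * i:3 * i + 3]
        cy = codons_y[3 * i:3 * i + 3]
        for codon in (cx, cy):
            syn = 0
            for pos in range(3):
                for b in "ACGT":
                    if b == codon[pos]:
                        continue
                    mut = codon[:pos] + b + codon[pos + 1:]
                    if mut not in _STOPS and _aa(mut) == _aa(codon):
                        syn += 1
            s_sites += 0.5 * syn / 3.0
        diff = [p for p in range(3) if cx[p] != cy[p]]
        if not diff:
            continue
        paths = []
        for order in itertools.permutations(diff):
            cur, s_cnt, n_cnt, blocked = cx, 0.0, 0.0, False
            for pos in order:
                nxt = cur[:pos] + cy[pos] + cur[pos + 1:]
                if nxt in _STOPS:
                    blocked = True
                if not blocked:
                    if _aa(nxt) == _aa(cur):
                        s_cnt += 1
                    else:
                        n_cnt += 1
                cur = nxt
            if not blocked:
                paths.append((s_cnt, n_cnt))
        if not paths:
            for order in itertools.permutations(diff):
                cur, s_cnt, n_cnt = cx, 0.0, 0.0
                for pos in order:
                    nxt = cur[:pos] + cy[pos] + cur[pos + 1:]
                    if nxt in _STOPS or _aa(nxt) != _aa(cur):
                        n_cnt += 1
                    else:
                        s_cnt += 1
                    cur = nxt
                paths.append((s_cnt, n_cnt))
        sd += sum(p[0] for p in paths) / len(paths)
        nd += sum(p[1] for p in paths) / len(paths)
    n_sites = 3.0 * n_codons - s_sites

    def jc(p):
        return math.nan if p >= 0.75 else -0.75 * math.log1p(-4 * p / 3)

    ks = jc(sd / s_sites) if s_sites else 0.0
    ka = jc(nd / n_sites) if n_sites else 0.0
    return ka, ks, s_sites, n_sites


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher exact p for [[a, b], [c, d]] by hypergeometric
    enumeration (sum of all tables with probability <= observed)."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def log_comb(n_, k_):
        return (math.lgamma(n_ + 1) - math.lgamma(k_ + 1)
                - math.lgamma(n_ - k_ + 1))

    def prob(x):
        return math.exp(log_comb(col1, x) + log_comb(n - col1, row1 - x)
                        - log_comb(n, row1))

    p_obs = prob(a)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    total = 0.0
    for x in range(lo, hi + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def naive_read_assignment(reads, segments):
    """Exact substring search of each read (both strands) in each segment."""
    comp = str.maketrans("ACGT", "TGCA")
    out = set()
    for rid, seq in reads:
        rc = seq.translate(comp)[::-1]
        for name, target in segments.items():
            if seq in target or rc in target:
                out.add((rid, name))
    return out
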