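"""Small-RNA size-class profiling over target segments.

In poplar-type sex determination, partial duplicates of the feminizing
gene on the Y generate 24-nt siRNAs (the RNA-directed-DNA-methylation
size class).  This module assigns reads to target segments by exact (or
≤1-mismatch) matching on either strand, profiles the read-length
distribution per segment and flags segments whose 24-nt fraction exceeds
75%, and checks inverted-repeat complementarity between segments — the
property behind the hairpin precursor; thermodynamic folding is not
computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequtils import revcomp

MIN_READ = 18
MAX_READ = 30
FRACTION_24_FLAG = 0.75


@dataclass
class SegmentProfile:
    segment: str
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fraction_24(self) -> float | None:
        """count(24)/total, or None for an empty profile."""
        t = self.total
        if t == 0:
            return None
        return self.counts.get(24, 0) / t

    @property
    def flagged(self) -> bool:
        f = self.fraction_24
        return f is not None and f > FRACTION_24_FLAG


def map_reads(reads, segments: dict[str, str],
              max_mismatch: int = 0) -> tuple[pd.DataFrame, int]:
    """Assign reads to every segment containing a match on either strand.

    ``reads`` is an iterable of sequences, of (id, sequence) tuples, or a
    DataFrame with a ``seq`` column.  A read multi-mapping to several
    segments is counted once per segment.  Reads with non-nucleotide
    characters are skipped and counted.  Returns ``(assignments,
    n_skipped)`` where assignments has columns read_id, segment, length.
    """
    if isinstance(reads, pd.DataFrame):
        items = list(zip(reads.get("read_id", reads.index.astype(str)),
                         reads["seq"]))
    else:
        items = [(r if isinstance(r, tuple) else (f"read{i}", r))
                 for i, r in enumerate(reads)]
        items = [(str(a), b) for a, b in items]
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")

    rows = []
    n_skipped = 0
    for rid, seq in items:
        seq = seq.upper()
        if set(seq) - set("ACGT"):
            n_skipped += 1
            continue
        rc = revcomp(seq)
        for name, target in segments.items():
            if _matches(seq, target, max_mismatch) or \
               _matches(rc, target, max_mismatch):
                rows.append((rid, name, len(seq)))
    df = pd.DataFrame(rows, columns=["read_id", "segment", "length"])
    return df, n_skipped


def _matches(read: str, target: str, max_mismatch: int) -> bool:
    if max_mismatch == 0:
        return read in target
    import edlib
    res = edlib.align(read, target, mode="HW", task="distance",
                      k=max_mismatch)
    return res["editDistance"] != -1


def size_profile(assignments: pd.DataFrame,
                 segments: list[str] | None = None) -> list[SegmentProfile]:
    """Per-segment read-length histograms (18-30 nt) with the 24-nt flag.

    Segments with zero assigned reads yield a profile with total 0 and an
    undefined (None) 24-nt fraction.
    """
    names = segments if segments is not None else \
        sorted(assignments["segment"].unique())
    out = []
    for name in names:
        sub = assignments[assignments["segment"] == name]
        counts = sub["length"].value_counts().to_dict()
        counts = {int(k): int(v) for k, v in counts.items()}
        out.append(SegmentProfile(name, counts))
    return out


def hairpin_pairing(seg_a: str, seg_b: str, min_identity: float = 0.8,
                    min_overlap_frac: float = 0.8) -> tuple[float, bool]:
    """Best ungapped identity of seg_a against revcomp(seg_b).

    All sliding offsets whose overlap covers at least ``min_overlap_frac``
    of the shorter segment are scored; pairing is declared when the best
    identity reaches ``min_identity``.  Symmetric in its arguments.
    Returns ``(identity, paired)``.
    """
    if not seg_a or not seg_b:
        raise ValueError("segments must be non-empty")
    a = np.frombuffer(seg_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(revcomp(seg_b.upper()).encode(), dtype=np.uint8)
    min_overlap = max(1, int(np.ceil(min_overlap_frac * min(a.size, b.size))))
    best = 0.0
    for off in range(-(b.size - min_overlap), a.size - min_overlap + 1):
        lo_a = max(0, off)
        lo_b = lo_a - off
        n = min(a.size - lo_a, b.size - lo_b)
        if n < min_overlap:
            continue
        ident = float(np.mean(a[lo_a:lo_a + n] == b[lo_b:lo_b + n]))
        best = max(best, ident)
    return best, best >= min_identity
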