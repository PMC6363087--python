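"""Paired-end read collapse, fixed-length trimming and exact clustering.

Amplicon read pairs from a 2 x 250 run of a sub-500-bp amplicon always
overlap in "innie" orientation; a pair is collapsed to a single consensus
read over the best overlap, fixed-length flanks are trimmed to remove
primer-proximal noise, and identical sequences are clustered with exact
counts.  No similarity threshold is applied when clustering: two merged
reads differing at a single base form two distinct clusters.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import NucSeq, QualRead, revcomp

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MergeConfig:
    """Overlap-merge parameters (FLASH-style defaults).

    ``min_overlap`` is the smallest admissible overlap in bases;
    ``max_mismatch_frac`` the largest tolerated fraction of mismatching
    positions within the overlap.
    """

    min_overlap: int = 10
    max_mismatch_frac: float = 0.25
    quality_offset: int = 33

    def __post_init__(self) -> None:
        if self.min_overlap < 4:
            raise ValueError("min_overlap must be >= 4")
        if not 0 <= self.max_mismatch_frac < 0.5:
            raise ValueError("max_mismatch_frac must be in [0, 0.5)")


@dataclass(frozen=True)
class Cluster:
    """A distinct observed amplicon sequence with exact read support."""

    seq: NucSeq
    count: int
    prevalence: float

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("cluster count must be >= 1")


@dataclass
class PrepStats:
    """Per-stage read accounting: pairs in = merged + unmerged;
    merged = trimmed-kept + discarded."""

    pairs_in: int = 0
    merged: int = 0
    unmerged: int = 0
    trimmed_kept: int = 0
    discarded_short: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def merge_pair(r1: QualRead, r2: QualRead, cfg: MergeConfig | None = None
               ) -> QualRead | None:
    """Collapse an innie read pair into one consensus read, or ``None``.

    ``r2`` is given in sequencer orientation (reverse strand) and is
    reverse-complemented internally.  Among admissible overlaps (length
    >= ``min_overlap``, mismatch fraction <= ``max_mismatch_frac``) the
    longest is chosen.  At each overlap mismatch the base with the higher
    Phred score wins; on a quality tie the base comes from ``r1`` and the
    consensus quality is the minimum of the two.
    """
    cfg = cfg or MergeConfig()
    s2 = revcomp(r2.seq)
    q2 = r2.quals[::-1]
    a1, a2 = _encode(r1.seq), _encode(s2)
    n1, n2 = len(a1), len(a2)
    max_l = min(n1, n2)

    chosen = None
    for L in range(max_l, cfg.min_overlap - 1, -1):
        seg1 = a1[n1 - L:]
        seg2 = a2[:L]
        if r1.seq[n1 - L:] == s2[:L]:
            chosen = (L, np.zeros(0, dtype=np.int64))
            break
        mism = np.flatnonzero(seg1 != seg2)
        if len(mism) <= cfg.max_mismatch_frac * L:
            chosen = (L, mism)
            break
    if chosen is None:
        return None

    L, mism = chosen
    head = r1.seq[: n1 - L]
    head_q = list(r1.quals[: n1 - L])
    tail = s2[L:]
    tail_q = list(q2[L:])

    ov = list(r1.seq[n1 - L:])
    ov_q = [max(qa, qb) for qa, qb in zip(r1.quals[n1 - L:], q2[:L])]
    for i in mism:
        qa = r1.quals[n1 - L + i]
        qb = q2[i]
        if qb > qa:
            ov[i] = s2[i]
            ov_q[i] = qb
        elif qa > qb:
            ov[i] = r1.seq[n1 - L + i]
            ov_q[i] = qa
        else:  # tie: base from r1, quality set to the minimum
            ov[i] = r1.seq[n1 - L + i]
            ov_q[i] = min(qa, qb)
    return QualRead(
        id=r1.id,
        seq=head + "".join(ov) + tail,
        quals=tuple(head_q + ov_q + tail_q),
    )


def trim_fixed(read: QualRead, n5: int = 35, n3: int = 35) -> QualRead | None:
    """Trim fixed-length 5' and 3' flanks; too-short reads are discarded.

    Returns ``None`` (and logs) when ``len(read) <= n5 + n3``.
    """
    if len(read) <= n5 + n3:
        log.debug("read %s (%d nt) shorter than trim %d+%d; discarded",
                  read.id, len(read), n5, n3)
        return None
    end = len(read) - n3
    return QualRead(read.id, read.seq[n5:end], read.quals[n5:end])


def cluster_exact(reads: list[NucSeq | QualRead | str]) -> list[Cluster]:
    """Cluster identical sequences with exact counts.

    One cluster per distinct sequence string, sorted by count descending
    with lexicographic tie-break; prevalence is computed over the input
    total.  No similarity threshold is applied.
    """
    seqs = [r if isinstance(r, str) else r.seq for r in reads]
    total = len(seqs)
    if total == 0:
        return []
    counts = Counter(seqs)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        Cluster(seq=NucSeq(f"cluster_{rank:05d}", seq), count=n,
                prevalence=n / total)
        for rank, (seq, n) in enumerate(ordered, start=1)
    ]


def prep_sample(pairs, cfg: MergeConfig | None = None, trim5: int = 35,
                trim3: int = 35, stats: PrepStats | None = None,
                ) -> tuple[list[Cluster], PrepStats]:
    """Merge, trim and cluster a stream of ``(r1, r2)`` pairs.

    Identical (sequence, sequence) pairs share one consensus computation;
    this is exact because all reads of a run carry the same quality
    profile, so the consensus depends only on the two sequences.
    Unmergeable pairs and too-short merges are excluded from the
    prevalence denominator.
    """
    cfg = cfg or MergeConfig()
    stats = stats or PrepStats()
    cache: dict[tuple[str, str, tuple, tuple], QualRead | None] = {}
    kept: list[str] = []
    for r1, r2 in pairs:
        stats.pairs_in += 1
        key = (r1.seq, r2.seq, r1.quals, r2.quals)
        if key in cache:
            merged = cache[key]
        else:
            merged = merge_pair(r1, r2, cfg)
            cache[key] = merged
        if merged is None:
            stats.unmerged += 1
            continue
        stats.merged += 1
        trimmed = trim_fixed(merged, trim5, trim3)
        if trimmed is None:
            stats.discarded_short += 1
            continue
        stats.trimmed_kept += 1
        kept.append(trimmed.seq)
    return cluster_exact(kept), stats
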