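"""Shared fixtures and independent oracles.

The oracle implementations here are deliberately naive (character loops,
exhaustive enumeration) and independent of the package's vectorized /
aligner-based code paths they are used to check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from polyamp.sequence_io import QualRead, revcomp
from polyamp.synthetic_data import SimConfig, simulate_locus


@pytest.fixture(scope="session")
def default_locus():
    """The default five-allele synthetic locus (seed 1)."""
    return simulate_locus(SimConfig(seed=1))


@pytest.fixture(scope="session")
def anchor_seq(default_locus):
    return default_locus.anchor.seq


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def merge_oracle(r1: QualRead, r2: QualRead, min_overlap: int,
                 max_mismatch_frac: float) -> QualRead | None:
    """Brute-force overlap merge: score every overlap length explicitly."""
    s2 = revcomp(r2.seq)
    q2 = r2.quals[::-1]
    n1, n2 = len(r1.seq), len(s2)
    admissible = []
    for L in range(min_overlap, min(n1, n2) + 1):
        mism = [i for i in range(L) if r1.seq[n1 - L + i] != s2[i]]
        if len(mism) <= max_mismatch_frac * L:
            admissible.append((L, mism))
    if not admissible:
        return None
    L, mism = max(admissible, key=lambda lm: (lm[0], -len(lm[1])))
    seq, quals = [], []
    for i in range(n1 - L):
        seq.append(r1.seq[i]); quals.append(r1.quals[i])
    for i in range(L):
        qa, qb = r1.quals[n1 - L + i], q2[i]
        ba, bb = r1.seq[n1 - L + i], s2[i]
        if ba == bb:
            seq.append(ba); quals.append(max(qa, qb))
        elif qb > qa:
            seq.append(bb); quals.append(qb)
        elif qa > qb:
            seq.append(ba); quals.append(qa)
        else:
            seq.append(ba); quals.append(min(qa, qb))
    for i in range(L, n2):
        seq.append(s2[i]); quals.append(q2[i])
    return QualRead(r1.id, "".join(seq), tuple(quals))


def affine_score_oracle(a: str, b: str, match: int = 2, mismatch: int = -3,
                        gap_open: int = -6, gap_extend: int = -1) -> float:
    """Exhaustive recursion over all global alignments with affine gaps.

    A length-L gap scores gap_open + L * gap_extend.  Only usable for
    very short sequences (no memoisation on purpose)."""
    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "m"))
        if i < len(a):
            cost = gap_extend + (gap_open if state != "ga" else 0)
            best = max(best, cost + rec(i + 1, j, "ga"))
        if j < len(b):
            cost = gap_extend + (gap_open if state != "gb" else 0)
            best = max(best, cost + rec(i, j + 1, "gb"))
        return best

    return rec(0, 0, "m")


def offtarget_oracle(protospacer: str, seq_id: str, seq: str,
                     max_mismatches: int,
                     pam_tails: tuple[str, ...] = ("GG", "AG")
                     ) -> set[tuple[str, str, int, int, int]]:
    """Exhaustive Hamming scan: (seq_id, strand, start, end, mismatches)."""
    hits = set()
    n = len(seq)
    for i in range(n - 22):
        pam = seq[i + 20:i + 23]
        if pam[1:] in pam_tails:
            mm = sum(a != b for a, b in zip(seq[i:i + 20], protospacer))
            if mm <= max_mismatches:
                hits.add((seq_id, "+", i, i + 20, mm))
        window_rc = revcomp(seq[i:i + 23])
        if window_rc[21:] in pam_tails:
            mm = sum(a != b for a, b in zip(window_rc[:20], protospacer))
            if mm <= max_mismatches:
                hits.add((seq_id, "-", i + 3, i + 23, mm))
    return hits


def fingerprint_oracle(seqs: dict[str, str], masked: list[tuple[int, int]],
                       visible_range: tuple[int, int] | None = None):
    """Column-scan fingerprints for equal-length (indel-free) alleles.

    Returns (class-membership per allele, diagnostic set per allele)."""
    length = len(next(iter(seqs.values())))
    assert all(len(s) == length for s in seqs.values())
    lo, hi = visible_range or (0, length)
    visible = [c for c in range(lo, hi)
               if not any(s <= c < e for s, e in masked)]
    klass = {}
    for aid, s in seqs.items():
        key = tuple(s[c] for c in visible)
        klass.setdefault(key, []).append(aid)
    members = {aid: tuple(m) for m in klass.values() for aid in m}
    diag = {}
    for aid, s in seqs.items():
        others = [o for o in seqs if o not in members[aid]]
        diag[aid] = {
            (c, s[c]) for c in visible
            if all(seqs[o][c] != s[c] for o in others)
        } if others else set()
    return members, diag


def random_read(rng: np.random.Generator, length: int, quality=None) -> QualRead:
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    if quality is None:
        quals = tuple(int(q) for q in rng.integers(2, 41, size=length))
    else:
        quals = (quality,) * length
    return QualRead("r", seq, quals)


def overlapping_pair(rng: np.random.Generator, len1: int, len2: int,
                     overlap: int, n_errors: int = 0
                     ) -> tuple[QualRead, QualRead]:
    """A read pair sharing a planted innie overlap, with optional
    mismatches sprinkled into r2's copy of the overlap."""
    template = "".join("ACGT"[i] for i in
                       rng.integers(0, 4, size=len1 + len2 - overlap))
    r1_seq = template[:len1]
    r2_fwd = list(template[len1 - overlap:])
    for _ in range(n_errors):
        i = int(rng.integers(0, overlap))
        r2_fwd[i] = "ACGT"[(("ACGT".index(r2_fwd[i])) + 1) % 4]
    r1 = QualRead("r1", r1_seq,
                  tuple(int(q) for q in rng.integers(2, 41, size=len1)))
    r2 = QualRead("r2", revcomp("".join(r2_fwd)),
                  tuple(int(q) for q in rng.integers(2, 41, size=len2)))
    return r1, r2
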