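"""sgRNA placement, per-allele compatibility and off-target scanning.

Places protospacer+PAM sites on a multi-allele locus, evaluates whether
each allele is predicted cleavable (mismatches in the PAM or in the
PAM-proximal seed abolish cleavage), measures dual-guide PAM-to-PAM
spacing, and scans a sequence database for Hamming-distance off-target
hits.  The cut site is fixed 3 bp 5' of the PAM (blunt SpCas9 cut).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_io import IUPAC, AlleleSet, GuideSpec, NucSeq, revcomp

PROTO_LEN = 20
CUT_OFFSET = 3  # cut position is 3 bp 5' of the PAM


@dataclass(frozen=True)
class Mismatch:
    """One protospacer mismatch: position 1-20 counted from the PAM-distal
    end, the base observed on the allele (guide-strand orientation), and
    whether the position lies in the seed."""

    position: int
    allele_base: str
    in_seed: bool


@dataclass(frozen=True)
class GuideSite:
    """A guide placed on one allele."""

    guide: GuideSpec
    allele_id: str
    strand: str
    proto_interval: tuple[int, int]
    pam_interval: tuple[int, int]
    cut: int
    mismatches: tuple[Mismatch, ...] = ()
    pam_matches: bool = True
    predicted_cleavage: bool = True

    @property
    def pam_proximal_boundary(self) -> int:
        """Coordinate of the PAM boundary adjacent to the protospacer."""
        return self.pam_interval[0] if self.strand == "+" else self.pam_interval[1]


def _pam_match(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in IUPAC[p] for b, p in zip(seq, pattern))


def find_sites(seq: str, pam_pattern: str = "NGG") -> list[dict]:
    """Enumerate every protospacer+PAM window on both strands.

    Returns dicts with keys protospacer, pam, strand, proto_interval,
    pam_interval (forward-strand coordinates; protospacer and pam strings
    in guide orientation), ordered by (position, strand).
    """
    plen = len(pam_pattern)
    win = PROTO_LEN + plen
    sites = []
    for i in range(len(seq) - win + 1):
        # + strand: protospacer then PAM
        pam = seq[i + PROTO_LEN:i + win]
        if _pam_match(pam, pam_pattern):
            sites.append({
                "protospacer": seq[i:i + PROTO_LEN], "pam": pam, "strand": "+",
                "proto_interval": (i, i + PROTO_LEN),
                "pam_interval": (i + PROTO_LEN, i + win),
            })
        # - strand: PAM (revcomp) then protospacer, guide reads rightward on -
        pam_rc = revcomp(seq[i:i + plen])
        if _pam_match(pam_rc, pam_pattern):
            sites.append({
                "protospacer": revcomp(seq[i + plen:i + win]), "pam": pam_rc,
                "strand": "-",
                "proto_interval": (i + plen, i + win),
                "pam_interval": (i, i + plen),
            })
    sites.sort(key=lambda s: (s["proto_interval"][0], s["strand"]))
    return sites


def _cut_position(proto_interval: tuple[int, int], strand: str) -> int:
    if strand == "+":
        return proto_interval[1] - CUT_OFFSET
    return proto_interval[0] + CUT_OFFSET


def check_allele_compatibility(guide: GuideSpec, alleles: AlleleSet,
                               max_mismatches: int = 4
                               ) -> dict[str, GuideSite | None]:
    """Place a guide on every allele and predict per-allele cleavage.

    For each allele the best-matching protospacer window (fewest
    protospacer mismatches, then fewest PAM mismatches, then position) is
    selected; ``None`` when the protospacer mismatch count exceeds
    ``max_mismatches`` everywhere.  ``predicted_cleavage`` is False iff
    any mismatch falls in the seed or the PAM does not match; PAM-distal
    mismatches leave it True (they are carried as warnings in
    ``mismatches``).
    """
    out: dict[str, GuideSite | None] = {}
    for aid, rec in alleles.alleles.items():
        out[aid] = _best_site(guide, rec.seq, aid, max_mismatches)
    return out


def _best_site(guide: GuideSpec, seq: str, allele_id: str,
               max_mismatches: int) -> GuideSite | None:
    plen = len(guide.pam_pattern)
    win = PROTO_LEN + plen
    best = None
    for i in range(len(seq) - win + 1):
        for strand in "+-":
            if strand == "+":
                proto = seq[i:i + PROTO_LEN]
                pam = seq[i + PROTO_LEN:i + win]
                proto_iv = (i, i + PROTO_LEN)
                pam_iv = (i + PROTO_LEN, i + win)
            else:
                proto = revcomp(seq[i + plen:i + win])
                pam = revcomp(seq[i:i + plen])
                proto_iv = (i + plen, i + win)
                pam_iv = (i, i + plen)
            mm = sum(a != b for a, b in zip(proto, guide.protospacer))
            if mm > max_mismatches:
                continue
            pam_mm = sum(b not in IUPAC[p] for b, p in zip(pam, guide.pam_pattern))
            key = (mm, pam_mm, i, strand)
            if best is None or key < best[0]:
                best = (key, proto, proto_iv, pam_iv, strand, pam_mm)
    if best is None:
        return None
    _key, proto, proto_iv, pam_iv, strand, pam_mm = best
    mismatches = tuple(
        Mismatch(position=p + 1, allele_base=proto[p],
                 in_seed=(p + 1) > PROTO_LEN - guide.seed_len)
        for p in range(PROTO_LEN) if proto[p] != guide.protospacer[p]
    )
    seed_hit = any(m.in_seed for m in mismatches)
    return GuideSite(
        guide=guide, allele_id=allele_id, strand=strand,
        proto_interval=proto_iv, pam_interval=pam_iv,
        cut=_cut_position(proto_iv, strand),
        mismatches=mismatches, pam_matches=(pam_mm == 0),
        predicted_cleavage=(pam_mm == 0 and not seed_hit),
    )


def pair_spacing(site1: GuideSite, site2: GuideSite) -> int:
    """PAM-to-PAM distance: bases between the PAM-proximal boundaries of
    the two PAMs, on the shared allele."""
    if site1.allele_id != site2.allele_id:
        raise ValueError(
            f"sites on different alleles: {site1.allele_id!r} vs {site2.allele_id!r}")
    return abs(site2.pam_proximal_boundary - site1.pam_proximal_boundary)


# ---------------------------------------------------------------------------
# Off-target scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OffTargetHit:
    seq_id: str
    strand: str
    proto_interval: tuple[int, int]
    pam: str
    mismatches: int
    seed_mismatches: int
    cds_overlap: bool = False


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _pam_ok_matrix(seq_arr: np.ndarray, starts: np.ndarray, pattern: str,
                   rc: bool) -> np.ndarray:
    """Vectorized IUPAC PAM match at each start offset."""
    ok = np.ones(len(starts), dtype=bool)
    pat = pattern if not rc else pattern[::-1]
    for j, p in enumerate(pat):
        allowed = IUPAC[p] if not rc else revcomp_set(IUPAC[p])
        col = seq_arr[starts + j]
        m = np.zeros(len(starts), dtype=bool)
        for b in allowed:
            m |= col == ord(b)
        ok &= m
    return ok


def revcomp_set(bases: str) -> str:
    return "".join(sorted({revcomp(b) for b in bases}))


def off_target_scan(guide: GuideSpec, database: list[NucSeq],
                    max_mismatches: int = 5,
                    pam_patterns: tuple[str, ...] = ("NGG", "NAG"),
                    cds_intervals: dict[str, list[tuple[int, int]]] | None = None,
                    ) -> list[OffTargetHit]:
    """Every PAM-adjacent 20-mer within Hamming distance ``max_mismatches``
    of the protospacer, on both strands of every database sequence.

    Hits carry mismatch and seed-mismatch counts and, when
    ``cds_intervals`` is given, a CDS-overlap flag; they are ranked by
    (mismatch count, seed mismatch count, sequence, position).  No bulges
    are considered (pure Hamming on the 20-mer).
    """
    proto = _encode(guide.protospacer)
    proto_rc = _encode(revcomp(guide.protospacer))
    seed_mask = np.zeros(PROTO_LEN, dtype=bool)
    seed_mask[PROTO_LEN - guide.seed_len:] = True  # PAM-proximal seed
    plen = len(guide.pam_pattern)
    assert all(len(p) == plen for p in pam_patterns)
    win = PROTO_LEN + plen

    hits: list[OffTargetHit] = []
    for rec in database:
        seq = rec.seq
        n = len(seq)
        if n < win:
            continue
        arr = _encode(seq)
        windows = np.lib.stride_tricks.sliding_window_view(arr, PROTO_LEN)

        # + strand: protospacer at i, PAM at i+20
        starts = np.arange(0, n - win + 1)
        neq = windows[starts] != proto
        mm = neq.sum(axis=1)
        seed_mm = (neq & seed_mask).sum(axis=1)
        pam_ok = np.zeros(len(starts), dtype=bool)
        for pat in pam_patterns:
            pam_ok |= _pam_ok_matrix(arr, starts + PROTO_LEN, pat, rc=False)
        for i in np.flatnonzero(pam_ok & (mm <= max_mismatches)):
            hits.append(OffTargetHit(
                seq_id=rec.id, strand="+",
                proto_interval=(int(i), int(i) + PROTO_LEN),
                pam=seq[i + PROTO_LEN:i + win],
                mismatches=int(mm[i]), seed_mismatches=int(seed_mm[i]),
                cds_overlap=_overlaps(cds_intervals, rec.id, int(i), int(i) + win),
            ))

        # - strand: PAM at i (revcomp), protospacer at i+plen; compare the
        # forward-strand window to revcomp(protospacer)
        neq_rc = windows[starts + plen] != proto_rc
        mm_rc = neq_rc.sum(axis=1)
        seed_mm_rc = (neq_rc & seed_mask[::-1]).sum(axis=1)
        pam_ok_rc = np.zeros(len(starts), dtype=bool)
        for pat in pam_patterns:
            pam_ok_rc |= _pam_ok_matrix(arr, starts, pat, rc=True)
        for i in np.flatnonzero(pam_ok_rc & (mm_rc <= max_mismatches)):
            hits.append(OffTargetHit(
                seq_id=rec.id, strand="-",
                proto_interval=(int(i) + plen, int(i) + win),
                pam=revcomp(seq[i:i + plen]),
                mismatches=int(mm_rc[i]), seed_mismatches=int(seed_mm_rc[i]),
                cds_overlap=_overlaps(cds_intervals, rec.id, int(i), int(i) + win),
            ))
    hits.sort(key=lambda h: (h.mismatches, h.seed_mismatches, h.seq_id,
                             h.proto_interval[0], h.strand))
    return hits


def _overlaps(cds: dict[str, list[tuple[int, int]]] | None, seq_id: str,
              start: int, end: int) -> bool:
    if not cds or seq_id not in cds:
        return False
    return any(start < e and end > s for s, e in cds[seq_id])


def target_masks(sites: list[GuideSite], flank: int = 10,
                 span_between: bool = True) -> list[tuple[int, int]]:
    """Masked windows around guide target sites on one allele.

    Each site contributes protospacer+PAM +/- ``flank``.  With
    ``span_between`` (default) and >= 2 sites, the full hull from the
    first to the last window is masked: any base between two cut sites
    can be lost to a dual-cut deletion, so no diagnostic SNP may be
    placed there.  Returns merged, sorted intervals.
    """
    windows = []
    for s in sites:
        lo = min(s.proto_interval[0], s.pam_interval[0]) - flank
        hi = max(s.proto_interval[1], s.pam_interval[1]) + flank
        windows.append((max(lo, 0), hi))
    if not windows:
        return []
    if span_between and len(windows) >= 2:
        return [(min(w[0] for w in windows), max(w[1] for w in windows))]
    windows.sort()
    merged = [windows[0]]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    return merged
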