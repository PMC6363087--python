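"""Allelic variant calling and fingerprint-based allele assignment.

Clusters at >= 1% prevalence are called as possible allelic variants.
Each is assigned to a reference allele by its diagnostic SNP fingerprint:
the set of alignment columns, outside the masked CRISPR target windows,
where that allele (or its class of indistinguishable alleles) differs
from every other allele.  Masking the editable windows -- including the
whole span between two cut sites, which a dual-cut deletion can remove
-- makes assignment robust to any induced edit.  An expected allele
absent from the >= 1% call set (PCR dropout) is rescued from the
sub-threshold clusters by requiring a full match of its exclusive SNPs.

Columns live on the coordinate frame of a designated *anchor* allele;
every other allele and every cluster is related to it by one pairwise
global alignment.  Alleles that are insertion-free relative to the
anchor are fully representable in this frame (deletions appear as '-'
symbols); allele insertions relative to the anchor are not column-coded
and should be avoided by choosing the longest haplotype as anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .edit_classifier import Variant, align_global
from .guide_design import check_allele_compatibility, target_masks
from .read_prep import Cluster
from .sequence_io import AlleleSet

log = logging.getLogger(__name__)

GAP = "-"


@dataclass(frozen=True)
class Fingerprint:
    """Diagnostic column set of one allele (shared by its class).

    ``diagnostic`` holds (anchor column, symbol) pairs where this
    allele's symbol differs from every allele outside its
    ``shared_class`` (the alleles indistinguishable from it outside the
    masked windows).  Deleted columns carry the symbol '-'.
    """

    allele_id: str
    diagnostic: frozenset[tuple[int, str]]
    shared_class: tuple[str, ...]

    @property
    def class_label(self) -> str:
        return "/".join(self.shared_class)


@dataclass
class VariantCall:
    """Assignment of one cluster to an allele or ambiguity class."""

    cluster: Cluster
    assigned: tuple[str, ...] | None  # allele class members; None = unassigned
    rescued: bool = False
    match_detail: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def assigned_label(self) -> str:
        return "/".join(self.assigned) if self.assigned else "unassigned"


def call_variant_clusters(clusters: list[Cluster], min_prev: float = 0.01
                          ) -> tuple[list[Cluster], list[Cluster]]:
    """Split clusters at the prevalence threshold (inclusive keep).

    Returns (kept, below); the sub-threshold list is retained for
    dropout rescue.
    """
    kept = [c for c in clusters if c.prevalence >= min_prev]
    below = [c for c in clusters if c.prevalence < min_prev]
    return kept, below


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

def _anchor_columns(seq: str, anchor: str) -> dict[int, str]:
    """Symbol of ``seq`` at every anchor column, via global alignment.

    Columns deleted in ``seq`` carry '-'; insertions in ``seq`` relative
    to the anchor do not create columns.
    """
    if seq == anchor:
        return {i: b for i, b in enumerate(anchor)}
    variants = align_global(seq, anchor)
    symbols = {i: b for i, b in enumerate(anchor)}
    for v in variants:
        if v.type == "substitution":
            symbols[v.position] = v.alt
        elif v.type == "deletion":
            for p in range(v.position, v.position + len(v.ref)):
                symbols[p] = GAP
        elif v.type == "complex":
            for p in range(v.position, v.position + len(v.ref)):
                symbols[p] = GAP
    return symbols


def _masked(col: int, windows: list[tuple[int, int]]) -> bool:
    return any(lo <= col < hi for lo, hi in windows)


def build_fingerprints(alleles: AlleleSet,
                       masked_windows: list[tuple[int, int]] | None = None,
                       trim5: int = 0, trim3: int = 0,
                       ) -> list[Fingerprint]:
    """Compute per-allele diagnostic SNP fingerprints outside the masks.

    ``masked_windows`` are intervals on the anchor allele; when ``None``
    they are derived from the guide placements on the anchor (protospacer
    + PAM +/- 10, hull between multiple sites).  ``trim5``/``trim3``
    additionally exclude the untrimmable flanks from the visible window.
    Alleles identical over all visible columns form one shared class and
    carry identical fingerprints; exclusivity is evaluated against
    alleles outside the class.  With a single allele the fingerprint is
    empty and every read assigns to it.
    """
    anchor = alleles.anchor.seq
    if masked_windows is None:
        anchor_sites = []
        for guide in alleles.guides:
            sites = check_allele_compatibility(guide, alleles)
            if sites.get(alleles.anchor_id) is not None:
                anchor_sites.append(sites[alleles.anchor_id])
        masked_windows = target_masks(anchor_sites)

    visible = [
        c for c in range(len(anchor))
        if trim5 <= c < len(anchor) - trim3 and not _masked(c, masked_windows)
    ]
    profiles = {
        aid: _anchor_columns(rec.seq, anchor)
        for aid, rec in alleles.alleles.items()
    }

    # group alleles indistinguishable over the visible columns
    by_profile: dict[tuple, list[str]] = {}
    for aid in alleles.allele_ids:
        key = tuple(profiles[aid][c] for c in visible)
        by_profile.setdefault(key, []).append(aid)
    klass = {aid: tuple(members)
             for members in by_profile.values() for aid in members}

    fingerprints = []
    for aid in alleles.allele_ids:
        members = klass[aid]
        others = [o for o in alleles.allele_ids if o not in members]
        diag = frozenset(
            (c, profiles[aid][c]) for c in visible
            if all(profiles[o][c] != profiles[aid][c] for o in others)
        ) if others else frozenset()
        fingerprints.append(Fingerprint(allele_id=aid, diagnostic=diag,
                                        shared_class=members))
    return fingerprints


# ---------------------------------------------------------------------------
# Assignment and rescue
# ---------------------------------------------------------------------------

def _cluster_symbols(cluster_seq: str, anchor: str, trim5: int, trim3: int
                     ) -> dict[int, str]:
    """Anchor-column symbols of a (trimmed) cluster sequence.

    The cluster is aligned to the correspondingly trimmed anchor; columns
    outside the trimmed window are absent from the result.
    """
    ref = anchor[trim5:len(anchor) - trim3 if trim3 else len(anchor)]
    sym = _anchor_columns(cluster_seq, ref)
    return {c + trim5: b for c, b in sym.items()}


def assign_allele(cluster: Cluster | str, fingerprints: list[Fingerprint],
                  alleles: AlleleSet, trim5: int = 0, trim3: int = 0,
                  min_score: float = 0.8) -> VariantCall:
    """Assign a cluster to the allele class whose diagnostic positions it
    matches best.

    Each class is scored by the fraction of its diagnostic positions
    carrying the matching symbol in the aligned cluster; the uniquely
    best class wins if its score is >= ``min_score``, otherwise the call
    is unassigned.  A class with no diagnostics (single-allele genotype)
    scores 1.0 vacuously.
    """
    if isinstance(cluster, str):
        from .sequence_io import NucSeq
        cluster = Cluster(NucSeq("cluster", cluster), count=1, prevalence=1.0)
    symbols = _cluster_symbols(cluster.seq.seq, alleles.anchor.seq, trim5, trim3)

    classes: dict[tuple[str, ...], Fingerprint] = {}
    for fp in fingerprints:
        classes.setdefault(fp.shared_class, fp)

    detail: dict[str, tuple[int, int]] = {}
    scores: dict[tuple[str, ...], float] = {}
    for members, fp in classes.items():
        usable = [(c, b) for c, b in fp.diagnostic if c in symbols]
        matched = sum(1 for c, b in usable if symbols[c] == b)
        detail[fp.class_label] = (matched, len(usable))
        scores[members] = matched / len(usable) if usable else 1.0

    best = max(scores.values())
    winners = [m for m, s in scores.items() if s == best]
    if best >= min_score and len(winners) == 1:
        return VariantCall(cluster=cluster, assigned=winners[0],
                           match_detail=detail)
    return VariantCall(cluster=cluster, assigned=None, match_detail=detail)


def rescue_missing(below_threshold: list[Cluster], missing_fp: Fingerprint,
                   alleles: AlleleSet, trim5: int = 0, trim3: int = 0,
                   ) -> list[VariantCall]:
    """Recover a PCR-dropout allele from sub-threshold clusters.

    A sub-threshold cluster is rescued when its aligned symbols match
    *all* diagnostic positions of the missing allele's class, regardless
    of differences inside the masked windows.  Returns rescued calls
    sorted by read count (descending); empty when no cluster qualifies,
    which is reported as "allele not detected".
    """
    if not missing_fp.diagnostic:
        log.warning("rescue for %s: empty fingerprint, cannot rescue",
                    missing_fp.allele_id)
        return []
    rescued = []
    for cluster in below_threshold:
        symbols = _cluster_symbols(cluster.seq.seq, alleles.anchor.seq,
                                   trim5, trim3)
        usable = [(c, b) for c, b in missing_fp.diagnostic if c in symbols]
        if not usable:
            continue
        matched = sum(1 for c, b in usable if symbols[c] == b)
        if matched == len(usable):
            rescued.append(VariantCall(
                cluster=cluster, assigned=missing_fp.shared_class,
                rescued=True,
                match_detail={missing_fp.class_label: (matched, len(usable))},
            ))
    rescued.sort(key=lambda vc: (-vc.cluster.count, vc.cluster.seq.seq))
    if not rescued:
        log.info("allele not detected: %s", missing_fp.class_label)
    return rescued
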