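"""Variant derivation and editing-outcome classification.

Each called amplicon variant is globally aligned to its assigned
reference allele under affine-gap scoring, normalized variants are
extracted (VCF-style left alignment), per-guide-site edit status and
dual-cut deletions are derived from cut-site windows, and the protein
consequence is predicted by rebuilding the transcript through the gene
model and translating it.  A clone mode handles Sanger-sequenced
plasmid clones from transient assays, where no prevalence or allele
assignment applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from .guide_design import GuideSite
from .protein_homology import translate_str
from .sequence_io import GeneModel, NucSeq

# Affine-gap scoring: match +2, mismatch -3, a gap of length L scores
# -(6 + L).  Chosen to favour one long deletion over scattered gaps,
# matching the biology of dual-cut repair.
DEFAULT_SCORING = {"match": 2, "mismatch": -3, "gap_open": -6, "gap_extend": -1}


@dataclass(frozen=True)
class Variant:
    """A normalized edit on reference coordinates (0-based).

    Insertions are placed *before* ``position`` and have empty ``ref``;
    deletions have empty ``alt``.  Indels are left-aligned: shifted to
    the lowest position that produces an identical edited sequence.
    """

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def type(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "substitution"
        if not self.ref:
            return "insertion"
        if not self.alt:
            return "deletion"
        return "complex"

    def interval(self) -> tuple[int, int]:
        """Footprint on the reference; insertions get a 1-base footprint
        at their anchor so window intersection is well defined."""
        if self.type == "insertion":
            return (self.position, self.position + 1)
        return (self.position, self.position + len(self.ref))

    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass(frozen=True)
class CdsEffect:
    """Predicted consequence on the coding sequence.

    ``kind`` is one of: none, silent, missense, in_frame_deletion,
    in_frame_insertion, frameshift, frameshift_with_PTC, premature_stop,
    splice_disrupted, start_lost.  ``n_aa`` carries the amino-acid count
    for in-frame indels; ``stop_aa`` the 1-based residue position of a
    premature stop.
    """

    kind: str
    n_aa: int | None = None
    stop_aa: int | None = None

    def __str__(self) -> str:
        if self.kind in ("in_frame_deletion", "in_frame_insertion"):
            return f"{self.kind}({self.n_aa}aa)"
        if self.kind in ("frameshift_with_PTC", "premature_stop"):
            return f"{self.kind}(stop@aa{self.stop_aa})"
        return self.kind


@dataclass
class EditCall:
    """Allele-resolved editing outcome for one cluster or clone."""

    variants: list[Variant]
    site_status: dict[str, str]  # guide name -> wild-type | edited | not_assessable
    dual_cut: bool
    cds_effect: CdsEffect
    assigned: tuple[str, ...] | None = None
    prevalence: float | None = None
    rescued: bool = False
    cluster_id: str | None = None


def _aligner(scoring: dict | None = None) -> Align.PairwiseAligner:
    sc = dict(DEFAULT_SCORING)
    if scoring:
        sc.update(scoring)
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = sc["match"]
    al.mismatch_score = sc["mismatch"]
    # first gapped position carries open + extend, so a length-L gap
    # scores gap_open + L * gap_extend
    al.open_gap_score = sc["gap_open"] + sc["gap_extend"]
    al.extend_gap_score = sc["gap_extend"]
    return al


def left_align(variant: Variant, ref: str, floor: int = 0) -> Variant:
    """Shift an indel to its lowest equivalent position (VCF convention).

    ``floor`` bounds the shift so a variant never slides across an
    upstream variant's footprint.
    """
    if variant.type == "deletion":
        pos, dele = variant.position, variant.ref
        k = len(dele)
        while pos > floor and ref[pos - 1] == ref[pos + k - 1]:
            pos -= 1
        return Variant(pos, ref[pos:pos + k], "")
    if variant.type == "insertion":
        pos, ins = variant.position, variant.alt
        while pos > floor and ref[pos - 1] == ins[-1]:
            ins = ref[pos - 1] + ins[:-1]
            pos -= 1
        return Variant(pos, "", ins)
    return variant


def align_global(seq: str, ref: str, scoring: dict | None = None
                 ) -> list[Variant]:
    """Optimal global alignment of ``seq`` against ``ref``; returns the
    left-aligned variants that transform ``ref`` into ``seq``.

    Identical sequences yield an empty list.  The traceback is
    deterministic (the aligner's first reported optimum).
    """
    if seq == ref:
        return []
    if not seq or not ref:
        raise ValueError("both sequences must be non-empty")
    aln = _aligner(scoring).align(ref, seq)[0]
    ref_blocks, seq_blocks = aln.aligned
    variants: list[Variant] = []
    prev_r, prev_s = 0, 0
    for (rs, re), (ss, se) in zip(ref_blocks, seq_blocks):
        if rs > prev_r and ss > prev_s:
            # simultaneous gap in both: emit as deletion + insertion
            variants.append(Variant(prev_r, ref[prev_r:rs], ""))
            variants.append(Variant(rs, "", seq[prev_s:ss]))
        elif rs > prev_r:
            variants.append(Variant(prev_r, ref[prev_r:rs], ""))
        elif ss > prev_s:
            variants.append(Variant(prev_r, "", seq[prev_s:ss]))
        for i in range(re - rs):
            if ref[rs + i] != seq[ss + i]:
                variants.append(Variant(rs + i, ref[rs + i], seq[ss + i]))
        prev_r, prev_s = re, se
    if prev_r < len(ref) and prev_s < len(seq):
        variants.append(Variant(prev_r, ref[prev_r:], ""))
        variants.append(Variant(len(ref), "", seq[prev_s:]))
    elif prev_r < len(ref):
        variants.append(Variant(prev_r, ref[prev_r:], ""))
    elif prev_s < len(seq):
        variants.append(Variant(prev_r, "", seq[prev_s:]))
    variants.sort(key=lambda v: (v.position, v.type == "insertion"))
    out: list[Variant] = []
    prev_end = 0
    for v in variants:
        la = left_align(v, ref, floor=prev_end)
        out.append(la)
        prev_end = max(prev_end, la.position + len(la.ref))
    return out


def apply_variants(ref: str, variants: Sequence[Variant]) -> str:
    """Apply variants (non-overlapping, any order) to the reference."""
    out = []
    pos = 0
    # insertions land before the base at their position, so they apply first
    for v in sorted(variants, key=lambda v: (v.position, v.type != "insertion")):
        if v.position < pos:
            raise ValueError(f"overlapping variants at {v.position}")
        out.append(ref[pos:v.position])
        out.append(v.alt)
        pos = v.position + len(v.ref)
    out.append(ref[pos:])
    return "".join(out)


# ---------------------------------------------------------------------------
# Site-level edit status
# ---------------------------------------------------------------------------

def call_site_edits(variants: Sequence[Variant],
                    guide_sites: Sequence[GuideSite | None],
                    flank: int = 10) -> tuple[dict[str, str], bool]:
    """Per-guide-site edit status and the dual-cut flag.

    A site is "edited" iff some variant's footprint intersects
    ``[cut - flank, cut + flank)``.  ``dual_cut`` is true iff a single
    deletion's interval contains every assessable cut position (>= 2
    sites required).  A ``None`` site (guide has no placement on the
    assigned allele) is reported "not_assessable".
    """
    status: dict[str, str] = {}
    cuts: list[int] = []
    for site in guide_sites:
        if site is None:
            continue
        name = site.guide.name
        window = (site.cut - flank, site.cut + flank)
        edited = any(
            v.interval()[0] < window[1] and v.interval()[1] > window[0]
            for v in variants
        )
        status[name] = "edited" if edited else "wild-type"
        cuts.append(site.cut)
    dual = False
    if len(cuts) >= 2:
        for v in variants:
            if v.type == "deletion":
                s, e = v.interval()
                if all(s <= c < e for c in cuts):
                    dual = True
                    break
    return status, dual


def call_site_edits_named(variants: Sequence[Variant],
                          sites: dict[str, GuideSite | None],
                          flank: int = 10) -> tuple[dict[str, str], bool]:
    """Like :func:`call_site_edits` but keeps "not_assessable" entries for
    guides without a site on the assigned allele."""
    status, dual = call_site_edits(variants, [s for s in sites.values() if s],
                                   flank=flank)
    for name, site in sites.items():
        if site is None:
            status[name] = "not_assessable"
    return {name: status[name] for name in sites}, dual


# ---------------------------------------------------------------------------
# Coding-effect prediction
# ---------------------------------------------------------------------------

def _deleted_mask(n: int, variants: Sequence[Variant]) -> list[bool]:
    deleted = [False] * n
    for v in variants:
        if v.type in ("deletion", "complex"):
            for p in range(v.position, v.position + len(v.ref)):
                deleted[p] = True
    return deleted


def predict_coding_effect(variants: Sequence[Variant], ref: str,
                          model: GeneModel) -> CdsEffect:
    """Predict the protein consequence of edits on a genomic allele.

    The edited transcript is rebuilt through the gene model: exon
    segments surviving the edits are concatenated, a deletion removing an
    entire intron together with flanking exon ends fuses the remaining
    exon parts, and a deletion breaking exactly one splice boundary (the
    GT donor or AG acceptor dinucleotide, without removing the whole
    intron) yields ``splice_disrupted`` with no translation attempted.
    The reconstructed CDS is translated with the standard genetic code
    and classified by net CDS length change and first stop position.
    """
    if not variants:
        return CdsEffect("none")
    model.validate_against(ref)
    deleted = _deleted_mask(len(ref), variants)
    insertions: dict[int, str] = {}
    subs: dict[int, str] = {}
    for v in variants:
        if v.type == "insertion":
            insertions[v.position] = insertions.get(v.position, "") + v.alt
        elif v.type == "substitution":
            subs[v.position] = v.alt
        elif v.type == "complex":
            insertions[v.position + len(v.ref)] = (
                insertions.get(v.position + len(v.ref), "") + v.alt)

    exons = model.exons
    introns = model.introns()

    # splice fate per intron
    label = ["flank"] * len(ref)
    for s, e in exons:
        for p in range(s, e):
            label[p] = "exon"
    for s, e in introns:
        for p in range(s, e):
            label[p] = "intron"

    for (istart, iend) in introns:
        span = range(istart, iend)
        if all(deleted[p] for p in span):
            continue  # fully removed: flanking exon parts fuse
        splice_bases = [istart, istart + 1, iend - 2, iend - 1]
        if any(deleted[p] for p in splice_bases):
            return CdsEffect("splice_disrupted")
        if any(p in subs for p in splice_bases):
            return CdsEffect("splice_disrupted")

    # mature edited transcript with provenance (ref position, or x-0.5
    # for bases inserted before ref position x)
    def include_insertion(p: int) -> bool:
        here = label[p] if p < len(ref) else "flank"
        before = label[p - 1] if p > 0 else "flank"
        return here == "exon" or (before == "exon" and here == "intron")

    chars: list[str] = []
    prov: list[float] = []
    for p in range(len(ref) + 1):
        if p in insertions and include_insertion(p):
            for ch in insertions[p]:
                chars.append(ch)
                prov.append(p - 0.5)
        if p < len(ref) and label[p] == "exon" and not deleted[p]:
            chars.append(subs.get(p, ref[p]))
            prov.append(p)
    transcript = "".join(chars)

    cds_locus = model.cds_start_on_locus()
    idx = next((i for i, q in enumerate(prov) if q >= cds_locus), len(transcript))
    new_cds = transcript[idx:]
    wt_cds = model.cds(ref)
    wt_prot = translate_str(wt_cds)  # up to and excluding the stop
    wt_len = len(wt_prot)

    if len(new_cds) < 3 or not new_cds.startswith("ATG"):
        return CdsEffect("start_lost", stop_aa=0)

    # net CDS nucleotide change over the wild-type CDS footprint
    wt_stop_end = _locus_pos_of_cds_index(model, len(wt_prot) * 3 + 3)
    delta = 0
    for v in variants:
        if v.type == "insertion":
            if cds_locus <= v.position <= wt_stop_end and include_insertion(v.position):
                delta += len(v.alt)
        elif v.type in ("deletion", "complex"):
            for p in range(v.position, v.position + len(v.ref)):
                if label[p] == "exon" and cds_locus <= p < wt_stop_end:
                    delta -= 1
            if v.type == "complex":
                delta += len(v.alt)

    new_prot, new_has_stop = _translate_to_stop(new_cds)

    if delta % 3 != 0:
        if new_has_stop and len(new_prot) < wt_len:
            return CdsEffect("frameshift_with_PTC", stop_aa=len(new_prot) + 1)
        return CdsEffect("frameshift")

    expected_len = wt_len + delta // 3
    if new_has_stop and len(new_prot) < expected_len:
        return CdsEffect("premature_stop", stop_aa=len(new_prot) + 1)
    if delta < 0:
        return CdsEffect("in_frame_deletion", n_aa=-delta // 3)
    if delta > 0:
        return CdsEffect("in_frame_insertion", n_aa=delta // 3)
    if new_prot == wt_prot:
        exonic = any(
            label[p] == "exon" and p >= cds_locus
            for v in variants for p in range(*v.interval())
            if v.type != "insertion"
        )
        return CdsEffect("silent" if exonic else "none")
    return CdsEffect("missense")


def _locus_pos_of_cds_index(model: GeneModel, cds_index: int) -> int:
    """Locus coordinate of spliced CDS index (clamped to transcript end)."""
    off = model.cds_start_offset + cds_index
    for s, e in model.exons:
        if off < e - s:
            return s + off
        off -= e - s
    return model.exons[-1][1]


def _translate_to_stop(cds: str) -> tuple[str, bool]:
    prot = translate_str(cds, include_stop=True)
    if prot.endswith("*"):
        return prot[:-1], True
    return prot, False


# ---------------------------------------------------------------------------
# Clone mode (transient assay) and per-sample summary
# ---------------------------------------------------------------------------

@dataclass
class CloneCall:
    clone_id: str
    variants: list[Variant]
    site_status: dict[str, str]
    dual_cut: bool
    deletion_size: int
    foreign: bool = False


def classify_clones(clones: Iterable[NucSeq], ref: str,
                    guide_sites: dict[str, GuideSite | None],
                    flank: int = 10, scoring: dict | None = None
                    ) -> list[CloneCall]:
    """Per-clone edit calls for Sanger-sequenced plasmid clones.

    No prevalence logic applies; clones with global identity < 50% to the
    reference are flagged as foreign sequence.  ``deletion_size`` is the
    largest single deletion (0 if none).
    """
    out = []
    for clone in clones:
        variants = align_global(clone.seq, ref, scoring)
        mismatched = sum(len(v.ref) or len(v.alt) for v in variants)
        identity = 1 - mismatched / max(len(ref), len(clone.seq))
        if identity < 0.5:
            out.append(CloneCall(clone.id, [], {}, False, 0, foreign=True))
            continue
        status, dual = call_site_edits_named(variants, guide_sites, flank)
        del_size = max((len(v.ref) for v in variants if v.type == "deletion"),
                       default=0)
        out.append(CloneCall(clone.id, variants, status, dual, del_size))
    return out


def deletion_histogram(calls: Sequence[CloneCall]) -> dict[int, int]:
    """Histogram of per-clone largest deletion sizes (non-foreign, size > 0)."""
    hist: dict[int, int] = {}
    for c in calls:
        if not c.foreign and c.deletion_size > 0:
            hist[c.deletion_size] = hist.get(c.deletion_size, 0) + 1
    return dict(sorted(hist.items()))


@dataclass
class VariantGroup:
    """A distinct (allele class, edit) combination within one sample."""

    assigned: tuple[str, ...] | None
    variants: tuple[Variant, ...]
    prevalence: float
    site_status: dict[str, str]
    dual_cut: bool
    cds_effect: CdsEffect
    rescued: bool = False
    cluster_ids: list[str] = field(default_factory=list)


def summarize_sample(edit_calls: Sequence[EditCall]) -> list[VariantGroup]:
    """Collapse edit calls into distinct variant groups.

    One group per distinct (assigned allele/class, variant tuple); group
    count and membership are invariant to read order and depth scaling.
    Groups are ordered by total prevalence (descending), then by label.
    """
    groups: dict[tuple, VariantGroup] = {}
    for call in edit_calls:
        key = (call.assigned, tuple(call.variants))
        if key not in groups:
            groups[key] = VariantGroup(
                assigned=call.assigned,
                variants=tuple(call.variants),
                prevalence=0.0,
                site_status=call.site_status,
                dual_cut=call.dual_cut,
                cds_effect=call.cds_effect,
                rescued=call.rescued,
            )
        g = groups[key]
        g.prevalence += call.prevalence or 0.0
        g.rescued = g.rescued and call.rescued
        if call.cluster_id:
            g.cluster_ids.append(call.cluster_id)
    return sorted(
        groups.values(),
        key=lambda g: (-g.prevalence, str(g.assigned), str(g.variants)),
    )
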