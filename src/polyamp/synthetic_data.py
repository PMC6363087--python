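"""Synthetic octoploid-locus fixtures with truth labels.

Generates a multi-allele amplicon locus with the statistical structure
the analysis assumes -- five haplotypes of one gene differing by
intronic deletions and coding SNPs, one allele carrying a G->T seed
mismatch that abolishes cleavage by the first guide, NHEJ indel spectra
at two cut sites, dual-cut deletions of the intervening fragment, PCR
allele bias with optional dropout, and Phred-scaled substitution errors
on 2 x 250 paired-end reads -- so that every pipeline stage can be
verified against known truth without any download.

The default locus is a 455-bp genomic amplicon with three exons, a
106-nt first intron separating the two cut sites (177 bp apart), and
constant 35-bp primer flanks.  The guide/PAM neighbourhoods and the SNP
columns are fixed constants engineered so that (a) dual-cut deletions
spanning the 106-nt intron classify cleanly (e.g. a 187-nt genomic
deletion removes 81 coding nt = 27 aa in frame; 188 nt frameshifts into
an immediate premature stop), and (b) every distinguishable allele
class keeps >= 3 diagnostic SNP columns outside the editable region.
Only the neutral filler sequence varies with the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .edit_classifier import (CdsEffect, Variant, apply_variants, left_align,
                              predict_coding_effect)
from .guide_design import check_allele_compatibility
from .sequence_io import AlleleSet, GeneModel, GuideSpec, NucSeq, QualRead, revcomp

# ---------------------------------------------------------------------------
# Fixed locus architecture (anchor-allele coordinates)
# ---------------------------------------------------------------------------

FLANK5 = (0, 35)
EXON1 = (35, 135)
INTRON1 = (135, 241)     # 106 nt
EXON2 = (241, 321)       # 80 nt
INTRON2 = (321, 366)     # 45 nt
EXON3 = (366, 420)       # 46 nt CDS + 8 nt 3'UTR
FLANK3 = (420, 455)
CDS_START_OFFSET = 10    # into exon 1; CDS begins at locus 45
N_CODONS = 72            # ATG + 70 aa + stop

GUIDE1_PROTO = "CCTGGAGAGCTGAACTGGTC"   # locus [100, 120), PAM AGG [120, 123)
GUIDE2_PROTO = "GATCGTTACCAGCAAGCACG"   # locus [277, 297), PAM AGG [297, 300)
CUT1 = 117
CUT2 = 294

# fixed codons (index -> codon) carving out the guide neighbourhoods, the
# SNP host codons, and stop codons in the +1/+2 frames of exon 3 so that
# any frameshift terminates inside the sequenced region
_FIXED_CODONS = {
    0: "ATG",
    5: "CTG", 6: "AAG", 8: "GAT", 10: "CGT", 12: "TTC", 13: "GGA",
    # guide 1 block, locus [99, 123)
    18: "ACC", 19: "TGG", 20: "AGA", 21: "GCT", 22: "GAA", 23: "CTG",
    24: "GTC", 25: "AGG",
    # guide 2 block and downstream junction context, locus [277, 310)
    42: "GAT", 43: "CGT", 44: "TAC", 45: "CAG", 46: "CAA", 47: "GCA",
    48: "CGA", 49: "GGA", 50: "CTA", 51: "ATC", 52: "GGT",
    # frameshift stop motif: TAA in +1 frame, TAG in +2 frame, no stop in 0
    57: "CTA", 58: "ACT", 59: "AGT",
    60: "ACT", 62: "TCT", 65: "GCT", 67: "CTT", 69: "ATG",
    71: "TAA",
}

_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)

# SNP columns are listed inline in simulate_locus; shared-derived columns
# (carried by alleles 3+4+5) give the indistinguishable class {a1, a2}
# its own exclusive fingerprint, and one shared intron-2 SNP backs it up.
_SHARED_INTRON_SNP = {340: "C"}

# intronic deletions relative to the anchor (locus intervals)
_A3_INTRON_DELS = [(180, 184), (330, 334)]
_A4_INTRON_DELS = [(200, 202), (348, 354)]

_DUAL_JITTER = ((2, 0.08), (3, 0.15), (4, 0.08), (5, 0.45), (6, 0.12),
                (7, 0.05), (10, 0.04), (13, 0.03))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic locus and run.

    Defaults emulate the five-allele situation: a highly heterozygous
    octoploid locus with 4 synonymous + 8 non-synonymous coding SNPs and
    intronic indels across alleles, one seed-mismatched allele with zero
    guide-1 cleavage, MiSeq 2 x 250 reads at Q30, and mild PCR allele
    bias.  All randomness flows from ``seed``.
    """

    seed: int = 0
    n_alleles: int = 5
    coding_snps: tuple[int, int] = (4, 8)      # (synonymous, non-synonymous)
    intron_indels: bool = True
    cleavage_efficiency: tuple[float, ...] = (0.85, 0.85)  # per guide
    indel_p: float = 0.3                       # geometric size parameter
    indel_max: int = 30
    deletion_frac: float = 0.7                 # del vs ins at a single cut
    dual_cut_prob: float = 0.55
    pcr_allele_weights: tuple[float, ...] = (1.0, 0.8, 1.0, 0.9, 0.7)
    read_len: int = 250
    depth: int = 5000                          # read pairs
    quality: int = 30                          # flat Phred curve
    seed_mismatch_allele: bool = True          # plant the blocked-allele SNP

    def __post_init__(self) -> None:
        if not 1 <= self.n_alleles <= 5:
            raise ValueError("n_alleles must be in [1, 5]")
        if not 0 <= self.dual_cut_prob <= 1:
            raise ValueError("dual_cut_prob must be in [0, 1]")
        if any(not 0 <= e <= 1 for e in self.cleavage_efficiency):
            raise ValueError("cleavage efficiencies must be in [0, 1]")
        w = self.pcr_allele_weights[:self.n_alleles]
        if any(x < 0 for x in w) or sum(w) <= 0:
            raise ValueError("pcr_allele_weights must be >= 0 with positive sum")
        if not 0 <= self.quality <= 60:
            raise ValueError("quality must be a Phred score in [0, 60]")


@dataclass
class Molecule:
    """One template molecule entering library prep."""

    id: str
    allele_id: str
    variants: tuple[Variant, ...]   # on the allele's own coordinates
    seq: str
    dual_cut: bool
    site_edited: dict[str, bool]
    cds_effect: CdsEffect


@dataclass
class TruthTable:
    """Ground truth for simulated molecules and the reads drawn from them."""

    molecules: dict[str, Molecule]
    read_to_molecule: dict[str, str] = field(default_factory=dict)

    def groups(self, trim5: int = 35, trim3: int = 35
               ) -> dict[str, dict]:
        """Distinct (allele, edit) groups keyed by trimmed molecule sequence.

        Prevalence is the fraction of molecules carrying the sequence.
        """
        total = len(self.molecules)
        out: dict[str, dict] = {}
        for mol in self.molecules.values():
            key = mol.seq[trim5:len(mol.seq) - trim3]
            if key not in out:
                out[key] = {
                    "allele_id": mol.allele_id,
                    "variants": mol.variants,
                    "dual_cut": mol.dual_cut,
                    "site_edited": mol.site_edited,
                    "cds_effect": mol.cds_effect,
                    "count": 0,
                }
            out[key]["count"] += 1
        for g in out.values():
            g["prevalence"] = g["count"] / total
        return out


# ---------------------------------------------------------------------------
# Locus simulation
# ---------------------------------------------------------------------------

def _random_codon(rng: np.random.Generator) -> str:
    return _NON_STOP_CODONS[rng.integers(len(_NON_STOP_CODONS))]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def simulate_locus(cfg: SimConfig) -> AlleleSet:
    """Build the reference allele set (the genotype before editing).

    Deterministic under a fixed seed.  With ``coding_snps=(0, 0)``,
    ``intron_indels=False`` and ``seed_mismatch_allele=False`` all
    alleles are identical.
    """
    rng = np.random.default_rng(cfg.seed)

    codons = [_random_codon(rng) for _ in range(N_CODONS)]
    for idx, codon in _FIXED_CODONS.items():
        codons[idx] = codon
    cds = "".join(codons)
    assert len(cds) == 216

    utr5 = _random_bases(rng, CDS_START_OFFSET)
    exon1 = utr5 + cds[0:90]
    exon2 = cds[90:170]
    utr3 = _random_bases(rng, 8)
    exon3 = cds[170:216] + utr3
    intron1 = "GT" + _random_bases(rng, 102) + "AG"
    i2_interior = list(_random_bases(rng, 41))
    i2_interior[340 - INTRON2[0] - 2] = "T"   # anchor base at shared intron SNP
    intron2 = "GT" + "".join(i2_interior) + "AG"
    flank5 = _random_bases(rng, 35)
    flank3 = _random_bases(rng, 35)

    anchor = flank5 + exon1 + intron1 + exon2 + intron2 + exon3 + flank3
    assert len(anchor) == 455
    assert anchor[100:120] == GUIDE1_PROTO and anchor[120:123] == "AGG"
    assert anchor[277:297] == GUIDE2_PROTO and anchor[297:300] == "AGG"

    n_syn, n_nonsyn = cfg.coding_snps
    syn_order = [(62, "C", ("a3", "a4", "a5")), (393, "A", ("a3", "a4", "a5")),
                 (378, "C", ("a3",)),
                 (116, "T", ("a5",)) if cfg.seed_mismatch_allele else None]
    nonsyn_order = [(69, "A", ("a3",)), (383, "G", ("a3",)),
                    (75, "T", ("a4",)), (85, "A", ("a4",)), (398, "C", ("a4",)),
                    (63, "G", ("a5",)), (82, "A", ("a5",)), (404, "G", ("a5",))]
    snps: dict[str, dict[int, str]] = {f"a{i}": {} for i in range(1, 6)}
    for entry in [e for e in syn_order if e][:n_syn]:
        pos, alt, targets = entry
        for t in targets:
            snps[t][pos] = alt
    for pos, alt, targets in nonsyn_order[:n_nonsyn]:
        for t in targets:
            snps[t][pos] = alt
    if cfg.seed_mismatch_allele and 116 not in snps["a5"]:
        snps["a5"][116] = "T"
    if n_syn + n_nonsyn > 0:
        for aid in ("a3", "a4", "a5"):
            snps[aid].update({p: a for p, a in _SHARED_INTRON_SNP.items()})

    intron_dels = {
        "a3": _A3_INTRON_DELS if cfg.intron_indels else [],
        "a4": _A4_INTRON_DELS if cfg.intron_indels else [],
    }

    alleles: dict[str, NucSeq] = {}
    models: dict[str, GeneModel] = {}
    for i in range(1, cfg.n_alleles + 1):
        aid = f"a{i}"
        variants = [Variant(p, anchor[p], alt) for p, alt in
                    sorted(snps.get(aid, {}).items())]
        variants += [Variant(s, anchor[s:e], "")
                     for s, e in intron_dels.get(aid, [])]
        variants.sort(key=lambda v: v.position)
        seq = apply_variants(anchor, variants)
        alleles[aid] = NucSeq(aid, seq)
        models[aid] = _shift_model(intron_dels.get(aid, []))

    guides = [
        GuideSpec("sgRNA1", GUIDE1_PROTO, "NGG", seed_len=12),
        GuideSpec("sgRNA2", GUIDE2_PROTO, "NGG", seed_len=12),
    ]
    return AlleleSet(locus_id=f"synthetic_locus_seed{cfg.seed}",
                     alleles=alleles, gene_models=models, guides=guides,
                     anchor_id="a1")


def _shift_model(deletions: list[tuple[int, int]]) -> GeneModel:
    """Anchor gene model with intronic deletions folded into coordinates."""
    def shift(p: int) -> int:
        return p - sum(min(e, p) - s for s, e in deletions if s < p)
    exons = tuple(
        (shift(s), shift(e)) for s, e in (EXON1, EXON2, EXON3)
    )
    return GeneModel(exons=exons, strand="+", cds_start_offset=CDS_START_OFFSET)


def anchor_gene_model() -> GeneModel:
    """The anchor-allele gene model (106-nt intron 1 between the cuts)."""
    return GeneModel(exons=(EXON1, EXON2, EXON3), strand="+",
                     cds_start_offset=CDS_START_OFFSET)


# ---------------------------------------------------------------------------
# Editing simulation
# ---------------------------------------------------------------------------

def _draw_jitter(rng: np.random.Generator) -> int:
    vals, probs = zip(*_DUAL_JITTER)
    return int(rng.choice(vals, p=probs))


def _indel_size(rng: np.random.Generator, cfg: SimConfig) -> int:
    return int(min(rng.geometric(cfg.indel_p), cfg.indel_max))


def simulate_editing(alleles: AlleleSet, cfg: SimConfig) -> TruthTable:
    """Draw one edited template molecule per future read pair.

    Per molecule: the source allele is drawn from the PCR weights; if
    both guide sites are predicted cleavable, a dual-cut deletion of the
    intervening fragment (cut1 - j1 .. cut2 + j2, jitter emulating end
    resection) occurs with ``dual_cut_prob``; otherwise each cleavable
    site independently acquires an NHEJ indel with its guide's
    efficiency (geometric sizes, ``deletion_frac`` deletions, insertions
    of random bases at the cut).  A seed-mismatched allele is never cut
    by the affected guide.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    ids = alleles.allele_ids
    weights = np.array(cfg.pcr_allele_weights[:len(ids)], dtype=float)
    weights /= weights.sum()

    sites = {
        g.name: check_allele_compatibility(g, alleles) for g in alleles.guides
    }
    cleavable = {
        aid: {name: (s[aid] is not None and s[aid].predicted_cleavage)
              for name, s in sites.items()}
        for aid in ids
    }
    cuts = {
        aid: {name: (s[aid].cut if s[aid] is not None else None)
              for name, s in sites.items()}
        for aid in ids
    }
    eff = {g.name: cfg.cleavage_efficiency[i]
           for i, g in enumerate(alleles.guides)}

    molecules: dict[str, Molecule] = {}
    for i in range(cfg.depth):
        aid = ids[int(rng.choice(len(ids), p=weights))]
        ref = alleles.alleles[aid].seq
        guide_names = list(sites)
        can = cleavable[aid]
        variants: list[Variant] = []
        dual = False
        edited: dict[str, bool] = {name: False for name in guide_names}
        if (len(guide_names) >= 2 and all(can.values())
                and rng.random() < cfg.dual_cut_prob):
            c1 = cuts[aid][guide_names[0]]
            c2 = cuts[aid][guide_names[1]]
            lo, hi = min(c1, c2), max(c1, c2)
            start = lo - _draw_jitter(rng)
            end = hi + _draw_jitter(rng)
            variants.append(Variant(start, ref[start:end], ""))
            dual = True
            edited = {name: True for name in guide_names}
        else:
            for name in guide_names:
                if not can[name] or rng.random() >= eff[name]:
                    continue
                cut = cuts[aid][name]
                size = _indel_size(rng, cfg)
                if rng.random() < cfg.deletion_frac:
                    start = cut - size // 2
                    variants.append(Variant(start, ref[start:start + size], ""))
                else:
                    variants.append(Variant(cut, "", _random_bases(rng, size)))
                edited[name] = True
        # left-align so truth variants are in the same normal form the
        # pipeline reports
        variants = sorted((left_align(v, ref) for v in variants),
                          key=lambda v: v.position)
        seq = apply_variants(ref, variants)
        effect = predict_coding_effect(variants, ref, alleles.gene_models[aid])
        mol_id = f"mol{i:05d}"
        molecules[mol_id] = Molecule(
            id=mol_id, allele_id=aid, variants=tuple(variants), seq=seq,
            dual_cut=dual, site_edited=edited, cds_effect=effect,
        )
    return TruthTable(molecules=molecules)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(truth: TruthTable, cfg: SimConfig
                   ) -> tuple[list[QualRead], list[QualRead]]:
    """Emit one 2 x ``read_len`` pair per molecule with Phred-scaled
    substitution errors.

    R1 reads from the 5' end, R2 is the reverse complement from the 3'
    end; qualities follow the flat ``quality`` curve.  Byte-identical
    output under a fixed seed.  Updates ``truth.read_to_molecule``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    err_p = 10.0 ** (-cfg.quality / 10.0)
    r1_list: list[QualRead] = []
    r2_list: list[QualRead] = []
    for mol in truth.molecules.values():
        # a molecule shorter than the read length is sequenced end to end
        # (adapter read-through removed upstream of this model)
        rlen = min(cfg.read_len, len(mol.seq))
        quals = (cfg.quality,) * rlen
        fwd = mol.seq[:rlen]
        rev = revcomp(mol.seq)[:rlen]
        rid = f"sim_{mol.id}"
        r1_list.append(QualRead(rid, _with_errors(fwd, err_p, rng), quals))
        r2_list.append(QualRead(rid, _with_errors(rev, err_p, rng), quals))
        truth.read_to_molecule[rid] = mol.id
    return r1_list, r2_list


_OTHER = {b: "ACGT".replace(b, "") for b in "ACGT"}


def _with_errors(seq: str, err_p: float, rng: np.random.Generator) -> str:
    hits = np.flatnonzero(rng.random(len(seq)) < err_p)
    if len(hits) == 0:
        return seq
    out = list(seq)
    for i in hits:
        out[i] = _OTHER[out[i]][rng.integers(3)]
    return "".join(out)


def simulate_run(cfg: SimConfig) -> tuple[AlleleSet, TruthTable,
                                          list[QualRead], list[QualRead]]:
    """Locus + editing + reads in one call (shared config/seed)."""
    alleles = simulate_locus(cfg)
    truth = simulate_editing(alleles, cfg)
    r1, r2 = simulate_reads(truth, cfg)
    return alleles, truth, r1, r2


def dropout_config(cfg: SimConfig | None = None, allele: str = "a5",
                   weight: float = 0.004) -> SimConfig:
    """Variant of a config with one allele weighted down to PCR dropout."""
    cfg = cfg or SimConfig()
    idx = int(allele[1:]) - 1
    weights = list(cfg.pcr_allele_weights[:cfg.n_alleles])
    others = sum(w for i, w in enumerate(weights) if i != idx)
    weights[idx] = weight / (1 - weight) * others
    return replace(cfg, pcr_allele_weights=tuple(weights))
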