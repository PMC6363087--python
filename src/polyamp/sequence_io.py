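"""Sequence I/O and locus specification loading.

Reads and writes the standard formats touched by the pipeline (FASTA,
FASTQ with Phred+33 qualities, GFF3 gene models) and loads a "locus
specification" -- the reference allele haplotypes of one amplified locus,
their gene models, and the sgRNAs placed on it -- into validated
in-memory objects.  All internal coordinates are 0-based, half-open;
report files use 1-based inclusive coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

from Bio import SeqIO

NUC_ALPHABET = frozenset("ACGTN")
MAX_PHRED = 60
PHRED_OFFSET = 33  # Sanger / Illumina 1.8+ encoding; offset-64 input is rejected

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed record in a sequence file (reports the record number)."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


def _check_alphabet(seq: str, context: str) -> None:
    bad = set(seq) - NUC_ALPHABET
    if bad:
        raise ValidationError(
            f"{context}: non-ACGTN symbol(s) {sorted(bad)!r} in sequence"
        )
    if not seq:
        raise ValidationError(f"{context}: empty sequence")


@dataclass(frozen=True)
class NucSeq:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        _check_alphabet(self.seq, self.id)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class QualRead:
    """A read with per-base Phred scores (decoded from ASCII offset 33)."""

    id: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("read id must be non-empty")
        _check_alphabet(self.seq, self.id)
        if len(self.quals) != len(self.seq):
            raise ValidationError(
                f"{self.id}: {len(self.quals)} quality values for "
                f"{len(self.seq)} bases"
            )
        for q in self.quals:
            if not 0 <= q <= MAX_PHRED:
                raise ValidationError(
                    f"{self.id}: Phred score {q} outside [0, {MAX_PHRED}] "
                    "(is the file Phred+64 encoded?)"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """Exon structure and CDS frame of a gene on locus coordinates.

    ``exons`` are 0-based half-open intervals, sorted and non-overlapping.
    ``cds_start_offset`` counts bases into the *first exon* (i.e. across
    the spliced transcript) at which the coding sequence begins.
    """

    exons: tuple[tuple[int, int], ...]
    strand: str = "+"
    cds_start_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValidationError("gene model needs at least one exon")
        prev_end = None
        for start, end in self.exons:
            if start >= end or start < 0:
                raise ValidationError(f"bad exon interval [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValidationError("exons overlap or are unsorted")
            prev_end = end
        if self.cds_start_offset < 0:
            raise ValidationError("cds_start_offset must be >= 0")
        if self.cds_start_offset >= self.spliced_length():
            raise ValidationError("CDS start beyond spliced transcript")

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intervals between consecutive exons."""
        out = []
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            out.append((e0, s1))
        return tuple(out)

    def spliced(self, locus_seq: str) -> str:
        """Concatenated exon sequence (the mature transcript)."""
        return "".join(locus_seq[s:e] for s, e in self.exons)

    def cds(self, locus_seq: str) -> str:
        """Spliced sequence from the CDS start onward."""
        return self.spliced(locus_seq)[self.cds_start_offset:]

    def cds_start_on_locus(self) -> int:
        """Locus coordinate of the first CDS base."""
        off = self.cds_start_offset
        for s, e in self.exons:
            if off < e - s:
                return s + off
            off -= e - s
        raise ValidationError("CDS start beyond spliced transcript")

    def validate_against(self, seq: str) -> None:
        if self.exons[-1][1] > len(seq):
            raise ValidationError(
                f"exon interval {self.exons[-1]} outside sequence of length {len(seq)}"
            )


IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class GuideSpec:
    """An sgRNA: 20-nt protospacer, PAM pattern, and seed definition.

    The seed is the ``seed_len`` PAM-proximal protospacer bases, where
    mismatches strongly suppress Cas9 cleavage.
    """

    name: str
    protospacer: str
    pam_pattern: str = "NGG"
    seed_len: int = 12

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValidationError(
                f"{self.name}: protospacer must be 20 nt, got {len(self.protospacer)}"
            )
        _check_alphabet(self.protospacer, self.name)
        for sym in self.pam_pattern:
            if sym not in IUPAC:
                raise ValidationError(f"{self.name}: invalid IUPAC symbol {sym!r} in PAM")
        if not 1 <= self.seed_len <= 20:
            raise ValidationError(f"{self.name}: seed_len must be in [1, 20]")


@dataclass
class AlleleSet:
    """The reference haplotypes of one locus in one genotype.

    This is the coordinate frame for everything downstream: fingerprints,
    variant calls and coding-effect prediction are all expressed against
    these sequences and their gene models.  The first allele id in
    ``order`` is the *anchor* used as the common alignment frame.
    """

    locus_id: str
    alleles: dict[str, NucSeq]
    gene_models: dict[str, GeneModel]
    guides: list[GuideSpec] = field(default_factory=list)
    anchor_id: str | None = None

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValidationError("allele set needs at least one allele")
        for aid, rec in self.alleles.items():
            if aid not in self.gene_models:
                raise ValidationError(f"allele {aid!r} has no gene model")
            self.gene_models[aid].validate_against(rec.seq)
        if self.anchor_id is None:
            self.anchor_id = next(iter(self.alleles))
        elif self.anchor_id not in self.alleles:
            raise ValidationError(f"anchor allele {self.anchor_id!r} not in allele set")

    @property
    def allele_ids(self) -> list[str]:
        return list(self.alleles)

    @property
    def anchor(self) -> NucSeq:
        return self.alleles[self.anchor_id]


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def parse_fastx(path: str | Path, format: str) -> Iterator[NucSeq | QualRead]:
    """Stream records from a FASTA or FASTQ file in file order.

    FASTQ qualities are decoded at ASCII offset 33.  Malformed records
    raise :class:`ParseError` naming the record number; non-ACGTN symbols
    raise :class:`ValidationError` naming the symbol.
    """
    path = Path(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"format must be 'fasta' or 'fastq', got {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    def _records():
        n = 0
        try:
            with open(path) as fh:
                for rec in SeqIO.parse(fh, format):
                    n += 1
                    seq = str(rec.seq).upper()
                    if format == "fastq":
                        quals = tuple(rec.letter_annotations["phred_quality"])
                        yield QualRead(rec.id, seq, quals)
                    else:
                        yield NucSeq(rec.id, seq)
        except ValidationError:
            raise
        except ValueError as exc:  # Biopython parse failure
            raise ParseError(f"{path}: malformed record #{n + 1}: {exc}") from exc

    return _records()


def write_fastx(records: Sequence[NucSeq | QualRead], path: str | Path) -> None:
    """Write records as single-line FASTA or 4-line FASTQ.

    The format is chosen by record type; a byte-identical round trip with
    :func:`parse_fastx` holds for these normalized layouts.
    """
    records = list(records)
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, QualRead):
                qual = "".join(chr(q + PHRED_OFFSET) for q in rec.quals)
                fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")
            else:
                fh.write(f">{rec.id}\n{rec.seq}\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def gene_model_from_gff3(path: str | Path, seqid: str,
                         cds_start_offset: int | None = None) -> GeneModel:
    """Build a :class:`GeneModel` from the exon/CDS features of one seqid.

    GFF3 is 1-based inclusive; intervals are converted to 0-based
    half-open.  If ``cds_start_offset`` is not given it is derived from
    the first CDS feature relative to the first exon.
    """
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    strand = "+"
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise ParseError(f"{path}: bad GFF3 line: {line!r}")
            sid, _source, ftype, start, end, _score, fstrand, _frame = parts[:8]
            if sid != seqid:
                continue
            iv = (int(start) - 1, int(end))
            if ftype.lower() == "exon":
                exons.append(iv)
                strand = fstrand if fstrand in "+-" else "+"
            elif ftype.lower() == "cds":
                cds.append(iv)
    if not exons:
        raise ValidationError(f"{path}: no exon features for seqid {seqid!r}")
    exons.sort()
    if cds_start_offset is None:
        if cds:
            cds_start = min(s for s, _ in cds)
            off = 0
            for s, e in exons:
                if s <= cds_start < e:
                    off += cds_start - s
                    break
                off += e - s
            cds_start_offset = off
        else:
            cds_start_offset = 0
    return GeneModel(exons=tuple(exons), strand=strand,
                     cds_start_offset=cds_start_offset)


def write_gene_model_gff3(model: GeneModel, seqid: str, path: str | Path,
                          gene_id: str = "gene1") -> None:
    """Write a gene model as minimal GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        g_start = model.exons[0][0] + 1
        g_end = model.exons[-1][1]
        fh.write(f"{seqid}\tpolyamp\tgene\t{g_start}\t{g_end}\t.\t{model.strand}\t.\t"
                 f"ID={gene_id}\n")
        for i, (s, e) in enumerate(model.exons, 1):
            fh.write(f"{seqid}\tpolyamp\texon\t{s + 1}\t{e}\t.\t{model.strand}\t.\t"
                     f"ID={gene_id}.exon{i};Parent={gene_id}\n")
        cds_locus = model.cds_start_on_locus()
        for s, e in model.exons:
            cs = max(s, cds_locus)
            if cs < e:
                fh.write(f"{seqid}\tpolyamp\tCDS\t{cs + 1}\t{e}\t.\t{model.strand}\t0\t"
                         f"ID={gene_id}.cds;Parent={gene_id}\n")


# ---------------------------------------------------------------------------
# Locus specification (JSON)
# ---------------------------------------------------------------------------

def load_locus_spec(config_path: str | Path) -> AlleleSet:
    """Load a locus specification JSON document into a validated AlleleSet.

    Alleles may inline their sequence (``"seq"``) or reference a FASTA
    file (``"fasta"`` + optional ``"fasta_id"``); gene models may be
    inlined (exons + cds_start_offset) or reference a GFF3 file.  Paths
    are resolved relative to the config file.  See
    ``polyamp/schema/locus_spec.schema.json`` for the document layout.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        doc = json.load(fh)
    base = config_path.parent

    def _need(obj: Mapping, key: str, where: str):
        if key not in obj:
            raise ValidationError(f"locus spec: missing {key!r} in {where}")
        return obj[key]

    locus_id = _need(doc, "locus_id", "document")
    alleles: dict[str, NucSeq] = {}
    models: dict[str, GeneModel] = {}
    for entry in _need(doc, "alleles", "document"):
        aid = _need(entry, "id", "allele entry")
        if aid in alleles:
            raise ValidationError(f"duplicate allele id {aid!r}")
        if "seq" in entry:
            seq = entry["seq"].upper()
        elif "fasta" in entry:
            wanted = entry.get("fasta_id", aid)
            seq = None
            for rec in parse_fastx(base / entry["fasta"], "fasta"):
                if rec.id == wanted:
                    seq = rec.seq
                    break
            if seq is None:
                raise ValidationError(
                    f"allele {aid!r}: id {wanted!r} not found in {entry['fasta']}")
        else:
            raise ValidationError(f"allele {aid!r}: needs 'seq' or 'fasta'")
        alleles[aid] = NucSeq(aid, seq)

        gm = _need(entry, "gene_model", f"allele {aid!r}")
        if "gff3" in gm:
            models[aid] = gene_model_from_gff3(
                base / gm["gff3"], gm.get("seqid", aid),
                gm.get("cds_start_offset"))
        else:
            models[aid] = GeneModel(
                exons=tuple(tuple(iv) for iv in _need(gm, "exons", f"gene model of {aid!r}")),
                strand=gm.get("strand", "+"),
                cds_start_offset=gm.get("cds_start_offset", 0),
            )

    guides = [
        GuideSpec(
            name=_need(g, "name", "guide entry"),
            protospacer=_need(g, "protospacer", "guide entry").upper(),
            pam_pattern=g.get("pam", "NGG").upper(),
            seed_len=g.get("seed_len", 12),
        )
        for g in doc.get("guides", [])
    ]
    return AlleleSet(locus_id=locus_id, alleles=alleles, gene_models=models,
                     guides=guides, anchor_id=doc.get("anchor"))


def write_locus_spec(alleles: AlleleSet, path: str | Path) -> None:
    """Serialize an AlleleSet as an inline locus specification JSON."""
    doc = {
        "locus_id": alleles.locus_id,
        "anchor": alleles.anchor_id,
        "alleles": [
            {
                "id": aid,
                "seq": rec.seq,
                "gene_model": {
                    "exons": [list(iv) for iv in alleles.gene_models[aid].exons],
                    "strand": alleles.gene_models[aid].strand,
                    "cds_start_offset": alleles.gene_models[aid].cds_start_offset,
                },
            }
            for aid, rec in alleles.alleles.items()
        ],
        "guides": [
            {"name": g.name, "protospacer": g.protospacer,
             "pam": g.pam_pattern, "seed_len": g.seed_len}
            for g in alleles.guides
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
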