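"""Translation and pairwise protein percent identity.

Supports homolog identification by BLASTP-like pairwise alignment:
local (Smith-Waterman, BLOSUM62, gap open -11 / extend -1) or global
(Needleman-Wunsch, same scoring).  Percent identity is identical columns
divided by aligned columns (gap columns included) within the reported
span -- the BLASTP convention; the value is sensitive to this choice of
denominator and to the mode, so both are always reported alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON[_stop] = "*"


@dataclass(frozen=True)
class ProtSeq:
    """A protein sequence; '*' only terminal unless flagged truncated."""

    id: str
    residues: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty protein")
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)!r}")
        internal = self.residues[:-1]
        if "*" in internal and not self.truncated:
            raise ValueError(f"{self.id}: internal stop in non-truncated protein")

    def __len__(self) -> int:
        return len(self.residues)


def translate_str(cds: str, include_stop: bool = False) -> str:
    """Translate frame 0 with the standard genetic code, stopping at the
    first stop codon.  Codons containing N become 'X'; a trailing partial
    codon is ignored."""
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3]
        aa = _CODON.get(codon, "X")
        if aa == "*":
            if include_stop:
                out.append("*")
            break
        out.append(aa)
    return "".join(out)


def translate(cds, id: str | None = None, require_start: bool = False) -> ProtSeq:
    """Translate a CDS to a :class:`ProtSeq` (see :func:`translate_str`).

    With ``require_start`` the sequence must begin with ATG.
    """
    seq = cds if isinstance(cds, str) else cds.seq
    name = id or (getattr(cds, "id", None) or "translation")
    if len(seq) < 3:
        raise ValueError(f"{name}: CDS shorter than one codon")
    if require_start and not seq.startswith("ATG"):
        raise ValueError(f"{name}: CDS does not start with ATG")
    prot = translate_str(seq)
    if not prot:
        raise ValueError(f"{name}: translation empty (immediate stop codon)")
    return ProtSeq(name, prot)


def read_protein_fasta(path: str | Path) -> list[ProtSeq]:
    """Load protein sequences from FASTA."""
    with open(path) as fh:
        return [ProtSeq(rec.id, str(rec.seq).upper())
                for rec in SeqIO.parse(fh, "fasta")]


@dataclass(frozen=True)
class IdentityResult:
    query: str
    subject: str
    mode: str
    percent_identity: float
    identical: int
    aligned_columns: int
    score: float
    alignment: str


def _protein_aligner(mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLASTP default gap costs: open 11, extend 1 (a length-L gap costs 11 + L)
    al.open_gap_score = -12
    al.extend_gap_score = -1
    return al


def pairwise_identity(a: ProtSeq, b: ProtSeq, mode: str = "local"
                      ) -> IdentityResult:
    """Percent amino-acid identity between two proteins.

    ``mode="local"`` reports the best local alignment (BLASTP-like);
    ``mode="global"`` aligns end to end under the same scoring.  Identity
    is identical columns / aligned columns x 100, counting gap columns
    within the aligned span.
    """
    if mode not in ("local", "global"):
        raise ValueError(f"mode must be 'local' or 'global', got {mode!r}")
    seq_a = a.residues.rstrip("*")
    seq_b = b.residues.rstrip("*")
    aln = _protein_aligner(mode).align(seq_a, seq_b)[0]
    a_blocks, b_blocks = aln.aligned
    identical = 0
    columns = 0
    prev_a = prev_b = None
    for (as_, ae), (bs, be) in zip(a_blocks, b_blocks):
        if prev_a is not None:
            columns += max(as_ - prev_a, bs - prev_b)  # internal gap columns
        for i in range(ae - as_):
            columns += 1
            if seq_a[as_ + i] == seq_b[bs + i]:
                identical += 1
        prev_a, prev_b = ae, be
    if mode == "global":
        # end gaps count as columns in a global alignment
        if a_blocks.size:
            columns += max(a_blocks[0][0], b_blocks[0][0])
            columns += max(len(seq_a) - a_blocks[-1][1], len(seq_b) - b_blocks[-1][1])
        else:
            columns = max(len(seq_a), len(seq_b))
    pct = 100.0 * identical / columns if columns else 0.0
    return IdentityResult(
        query=a.id, subject=b.id, mode=mode,
        percent_identity=pct, identical=identical, aligned_columns=columns,
        score=aln.score, alignment=str(aln),
    )
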