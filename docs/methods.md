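# Methods

This note documents the models, parameter choices and numerical
conventions behind `polyamp`, and what the synthetic-data validation
does and does not demonstrate.

## Coordinates and formats

All internal coordinates are 0-based half-open; report files (VCF, GFF3)
use the 1-based inclusive convention of those formats. FASTQ qualities
are fixed at the Phred+33 (Sanger/Illumina 1.8+) encoding; a file whose
decoded scores exceed 60 is rejected as presumably Phred+64 rather than
silently re-interpreted. FASTA is written single-line and FASTQ 4-line,
so write∘parse is byte-identical on normalized files.

## Read preparation

Read pairs are collapsed by their best overlap ("innie" orientation
only: for an amplicon shorter than twice the read length the pair is
guaranteed to overlap; outie/adapter-readthrough geometries return
no-merge and are counted). Defaults `min_overlap = 10`,
`max_mismatch_frac = 0.25` follow the published FLASH defaults. Among
admissible overlaps the longest wins. At an overlap mismatch the base
with the higher Phred score is kept; on a tie the forward read's base is
kept and the consensus quality set to the minimum of the two, so a tied
disagreement is marked low-confidence. At agreeing positions the
consensus quality is the maximum of the two scores.

Fixed trimming removes 35 nt from each end of the merged read (the
primer-proximal, index-adjacent region); merged reads not longer than
`trim5 + trim3` are discarded and counted. Clustering is exact string
identity — deliberately no similarity threshold — and prevalence is
`count / (merged reads surviving trim)`. Unmerged pairs are excluded
from the denominator.

## Variant calling and allele assignment

Clusters with prevalence ≥ 1% (inclusive) are candidate allelic
variants; the threshold applies per sample per amplicon.

**Fingerprints.** One allele is the *anchor* (the coordinate frame); all
other alleles and all clusters relate to it by one pairwise global
alignment. Alleles identical over all visible columns form an
*indistinguishable class* (e.g. a twin pair that differs only outside
the amplicon); exclusivity is evaluated per class: a diagnostic column
is one where the class's symbol (base or '-') differs from every allele
outside the class. Per-allele exclusivity would leave twins with empty
fingerprints and make their class unassignable and unrescuable, which is
why the class-level definition is used. Columns inside the masked target
region, inside the trimmed flanks, or deleted in the anchor frame are
never diagnostic. Allele insertions relative to the anchor are not
column-coded; choose the longest haplotype as anchor (the generator
does).

**Masking.** Each guide masks protospacer + PAM ± 10 nt around its cut.
With two or more guides the full hull from the first to the last window
is masked, because a dual-cut deletion can remove any base between the
cuts; diagnostic SNPs must survive every plausible edit.

**Assignment.** A cluster is aligned to the (trimmed) anchor once, its
symbol at every diagnostic column is read off, and each class is scored
by the fraction of its diagnostics matched. The uniquely best class with
score ≥ 0.8 wins; ties or lower scores leave the cluster unassigned.
The 0.8 default tolerates one sequencing error over a small diagnostic
set while preventing cross-assignment; clusters above the 1% threshold
are dominated by error-free reads, so in practice scored fractions are
1.0 or far below. A class with no diagnostics at all (single-allele
genotype) scores 1.0 vacuously, so every read assigns to it.

**Dropout rescue.** For each expected class absent from the ≥ 1% call
set, sub-threshold clusters are scanned; a cluster matching *all* of the
missing class's diagnostic columns (differences inside masked windows
ignored) is returned as a rescued call. Full match is required because a
sub-threshold cluster has no frequency support — its only evidence is
the complete exclusive-SNP signature. No matching cluster means "allele
not detected".

## Alignment and variant normalization

Global alignment uses affine-gap scoring: match +2, mismatch −3, a gap
of length L scores −(6 + L) (implemented as open −7 / extend −1 in the
underlying aligner, i.e. the opening position carries both penalties).
The strong opening penalty makes one long deletion beat scattered gaps,
matching dual-cut repair products. Traceback is deterministic (the
aligner's first optimum); extracted indels are then left-aligned to the
lowest position producing the same edited sequence (VCF convention),
with the shift floored at the previous variant's footprint so variants
never collide. Applying the variant list to the reference reconstructs
the query exactly; this round trip is fuzz-tested and re-measured by the
acceptance script.

## Site-level edit calls

The cut sits 3 bp 5′ of the PAM (blunt SpCas9 cut). A site is *edited*
iff a variant's reference footprint intersects `[cut − 10, cut + 10)`
(insertions get a 1-base footprint at their anchor). *Dual-cut* requires
a single deletion whose interval contains both cut positions. A guide
with no placement on the assigned allele reports `not_assessable`.

## Coding-effect prediction

Variants are applied to the genomic allele and the mature transcript is
rebuilt through the gene model:

- an intron fully deleted fuses the flanking exon remnants;
- a deletion or substitution touching the GT donor or AG acceptor
  dinucleotide of a surviving intron yields `splice_disrupted` and no
  translation is attempted (translation would be speculative);
- insertions strictly inside introns are spliced away; insertions in
  exons (and at exon/intron junction points on the exon side) are
  transcribed.

The CDS is translated with the standard genetic code from the mapped
start (a destroyed ATG is `start_lost`). Classification: net CDS length
change Δ ≢ 0 (mod 3) is a frameshift, reported `frameshift_with_PTC`
with the 1-based stop residue when the new translation terminates before
the wild-type length; Δ ≡ 0 with an earlier-than-expected stop is
`premature_stop` (an in-frame nonsense outcome — kept distinct from the
frameshift class rather than mislabelled); otherwise
`in_frame_deletion`/`in_frame_insertion` of |Δ|/3 aa, `missense`, or
`silent` (protein identical despite an exonic variant; purely intronic
or flank edits are `none`).

Deletion sizes are reported in the coordinates of the analysed molecule
(genomic for gDNA amplicons, spliced for cDNA amplicons — both are
expressible through the gene model; the locus spec decides per run).

## Guide design checks

Site enumeration slides every protospacer+PAM window on both strands
(IUPAC PAM patterns). Per-allele compatibility picks the best-matching
window (fewest protospacer mismatches, then fewest PAM mismatches, then
position) within ≤ 4 protospacer mismatches; `predicted_cleavage` is a
binary rule — false iff any mismatch lies in the 12 PAM-proximal seed
bases or the PAM — because the usable biological signal (an allele whose
seed mismatch abolished editing entirely) is all-or-nothing, not
quantitative. PAM-distal mismatches are carried as warnings. PAM-to-PAM
spacing is the distance between the PAM-proximal PAM boundaries.
Off-target scanning is pure Hamming distance on the 20-mer (no bulges)
over NGG and NAG PAMs, both strands, ranked by (mismatches, seed
mismatches); CDS overlap is flagged when annotation intervals are
supplied. Quantitative efficiency scores (MIT/CFD-style) are out of
scope.

## Protein homology

Translation uses the standard code, stops at the first stop codon,
renders N-containing codons as X, and ignores a trailing partial codon.
Percent identity is computed from a pairwise alignment under BLOSUM62
with gap open −11 / extend −1 (BLASTP's defaults): local
(Smith-Waterman, BLASTP-like) or global mode, identity = identical
columns / aligned columns × 100 **including gap columns in the aligned
span** — the BLASTP `pident` convention. The value depends on both the
mode and this denominator, so both are always reported with it; the
local mode is cross-checked against the `blastp` binary (composition
statistics disabled) in the test suite.

## Synthetic data: what it emulates

The generator builds a 455-bp genomic amplicon: 35-nt constant primer
flanks, three exons (CDS = 72 codons), a 106-nt first intron separating
the two guides (cuts 177 bp apart, both PAMs on the forward strand), and
a 45-nt second intron. Five alleles: a twin pair identical within the
amplicon; two alleles with intronic deletions (first and second introns)
plus private coding SNPs; one allele whose only target-region
polymorphism is a G→T substitution in the sgRNA1 seed. Across the set
there are 4 synonymous + 8 non-synonymous coding SNP columns; two
synonymous columns plus one intron-2 column are shared by the three
non-twin alleles so that the twin class keeps ≥ 3 exclusive columns of
its own — every distinguishable class has ≥ 3 diagnostics outside the
editable hull.

The guide neighbourhoods and SNP host codons are fixed constants; only
neutral filler varies with the seed. The constants are engineered so
that (a) a dual-cut genomic deletion spanning the intron always removes
(size − 106) coding nt — 187 nt → 27 aa in frame, 193 nt → 29 aa,
188 nt → frameshift; (b) the sequence downstream of cut 2 contains stop
codons in both shifted frames (so every frameshift yields a PTC inside
the sequenced region) and no in-frame junction stop for the canonical
deletion sizes; the cut-to-cut distance is kept below 187 nt so those
deletion sizes can contain both cuts.

Editing model: per molecule, the source allele is drawn from PCR weights
(default (1.0, 0.8, 1.0, 0.9, 0.7), normalized — mild bias; the dropout
scenario reweights one allele to 0.4%); if both sites are cleavable a
dual-cut deletion occurs with probability 0.55, its ends resected by a
small discrete jitter (mode 5 nt per side, so 187-nt products are the
most common); otherwise each cleavable site independently acquires an
NHEJ indel with efficiency 0.85 — geometric(0.3) sizes capped at 30 nt,
70% deletions, insertions of random bases at the cut. A seed-mismatched
allele is never cut by the affected guide (the binary cleavage rule).
Reads are 2 × 250 with a flat Q30 substitution-error curve (0.1%/base);
indel sequencing errors are off by default (negligible for this
instrument class at this scale). Default depth is 5,000 pairs per
sample. All randomness derives from one seed; output is byte-identical
across runs.

**What passing validation shows — and does not.** Recovery ≥ 99% of
planted variant groups (≥ 2% prevalence, correct allele class and coding
effect, 20 seeds) and 19/20 dropout rescues demonstrate that the
algorithms are correct under the modelled noise: substitution sequencing
error, PCR allele bias, heavy edit loads, allele-confounded indels. The
generator does **not** model PCR chimeras between alleles, cycle-
dependent quality decay, indel sequencing errors, or more than five
alleles; real libraries can contain chimeric reads that would appear as
low-prevalence unassigned or mis-assigned clusters, which is one reason
the 1% prevalence floor and the full-match rescue rule are conservative.

## Validation problem sizes

The acceptance script and the acceptance-level tests use 20 simulated
samples of 5,000 read pairs for recovery and rescue, a 50-kb random
genome with 30 planted near-target decoys for the off-target oracle,
300 random pairs for the merge oracle, 1,000 fuzzed edits for the
alignment round trip, and ≤ 6-allele × ≤ 600-bp fixtures for the
fingerprint oracle. These sizes give stable statistics at desk scale;
all are parameters, not limits.

## Known limitations

- Allele insertions relative to the anchor are invisible to the
  fingerprint column code (mitigated by anchoring on the longest
  haplotype).
- The accession-backed homolog identities (an Arabidopsis AP3 query
  against the two strawberry B-class proteins) require the three
  reference protein sequences, which are not distributable with the
  package; the corresponding check runs only when
  `data/reference/ap3_tm6.faa` is supplied. The identity machinery
  itself is validated against `blastp` on fixture proteins.
- No dosage/copy-number inference across homoeologs; the pipeline
  reports allele classes and prevalences only.
- Chimera detection between alleles is out of scope.
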