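# polyamp

Quantifying CRISPR/Cas9 editing outcomes at a **multi-allelic amplicon in a
polyploid genome**, from paired-end reads to per-allele edit calls and
predicted protein consequences.

## The problem

In a highly heterozygous polyploid (the motivating case is the octoploid
cultivated strawberry, with up to eight homoeologous copies of a locus and
five distinct alleles of a single *TM6*-class MADS-box gene), a deep-sequenced
amplicon over the CRISPR target region mixes reads from all alleles, each
possibly carrying different induced edits. Attributing each observed sequence
to its source allele is the crux: the edits themselves destroy part of the
sequence you would use to tell the alleles apart, and PCR bias can drop an
allele below any sensible prevalence threshold.

`polyamp` implements the full analysis as a tested, reusable pipeline:

1. **Read prep** — overlap-merge each innie read pair (consensus by Phred
   score, FLASH-style), trim fixed 35-nt flanks, and cluster *identical*
   sequences with exact counts (no similarity threshold).
2. **Variant calling** — clusters with prevalence ≥ 1% are candidate allelic
   variants (threshold inclusive; denominator = merged, trimmed reads).
3. **Allele assignment by SNP fingerprints** — for each allele (or class of
   alleles indistinguishable within the amplicon) the *diagnostic columns*
   are the alignment positions, **outside** the editable target windows,
   where it differs from every other allele. A cluster is assigned to the
   class whose diagnostics it matches best (fraction ≥ 0.8, unique maximum).
   Because the whole span between the two cut sites can be removed by a
   dual-cut deletion, that entire region is masked when fingerprints are
   built — so even a read missing 190 nt remains assignable.
4. **Dropout rescue** — an expected allele absent from the ≥ 1% call set is
   searched for among sub-threshold clusters by requiring a *full* match of
   its exclusive SNPs, edits at the target sites notwithstanding.
5. **Edit classification** — each called cluster is globally aligned to its
   assigned allele (affine gaps: match +2, mismatch −3, gap of length *L*
   scores −(6+*L*)), variants are extracted and left-aligned (VCF
   convention), each sgRNA site is called edited if a variant falls within
   ±10 nt of its cut (3 bp 5′ of the PAM), and a single deletion containing
   both cut positions flags a **dual-cut** event.
6. **Protein consequence** — variants are pushed through the gene model:
   the edited transcript is rebuilt (a deletion removing an intron plus
   flanking exon ends fuses the remaining exon parts; breaking a GT/AG
   splice dinucleotide without removing the intron is `splice_disrupted`),
   translated, and classified: `silent`, `missense`,
   `in_frame_deletion(n aa)`, `in_frame_insertion(n aa)`, `frameshift`,
   `frameshift_with_PTC(stop)`, `premature_stop`, `start_lost`.

Around the core pipeline the package provides **dual-sgRNA design checks**
(site enumeration, per-allele seed/PAM mismatch compatibility — a single
seed mismatch predicts zero cleavage — PAM-to-PAM spacing, Hamming
off-target scan with CDS-overlap flags), **protein homology** (translation
and BLASTP-like percent identity for homolog identification), a **Sanger
clone mode** for transient assays, and a **synthetic-data generator** that
emulates the whole study design with truth labels, so every stage is
verifiable without any sequencing download.

## Worked example

Simulate a five-allele locus (one allele carries a G→T seed mismatch under
sgRNA1), 5,000 read pairs at Q30, then run the pipeline:

```bash
polyamp simulate --seed 7 --depth 5000 --out-dir demo/fixture
polyamp run --r1 demo/fixture/reads_R1.fastq --r2 demo/fixture/reads_R2.fastq \
            --locus demo/fixture/locus_spec.json --out-dir demo/out
# -> 12 variant group(s); reports in demo/out
```

Top of `demo/out/edit_calls.tsv`:

```
cluster         assigned  prevalence  rescued  n_variants  variants    site_status                  dual_cut  cds_effect
cluster_00001   a1/a2     0.036200    0        1           del187@111  sgRNA1=edited;sgRNA2=edited  1         in_frame_deletion(27aa)
cluster_00002   a3        0.020200    0        1           del183@111  sgRNA1=edited;sgRNA2=edited  1         in_frame_deletion(27aa)
cluster_00003   a5        0.018600    0        1           del1@294    sgRNA1=wild-type;sgRNA2=edited  0      frameshift_with_PTC(stop@aa51)
cluster_00006   a1/a2     0.017000    0        1           del188@111  sgRNA1=edited;sgRNA2=edited  1         frameshift_with_PTC(stop@aa24)
cluster_00007   a5        0.016000    0        0           .           sgRNA1=wild-type;sgRNA2=wild-type  0   none
```

Reading this: a 187-nt dual-cut genomic deletion on the `a1/a2` ambiguity
class (those two alleles are indistinguishable within the amplicon) removes
the 106-nt first intron plus 81 coding nt — an in-frame loss of 27 amino
acids — while the 188-nt version frameshifts into a premature termination
codon. Allele `a5`, whose sgRNA1 seed is mismatched, is only ever edited at
the sgRNA2 site, and a residual wild-type `a5` variant persists at low
prevalence. `summary.json` reports the distinct variant-group count (the
per-sample figure of merit), and `variants.vcf` exports all edits as
left-aligned, 1-based REF/ALT records.

## Layout

```
src/polyamp/
  sequence_io.py     FASTA/FASTQ/GFF3 I/O, locus-spec JSON, core types
  read_prep.py       pair merging, fixed trimming, exact clustering
  allele_caller.py   prevalence threshold, fingerprints, assignment, rescue
  edit_classifier.py alignment, variants, site/dual-cut calls, CDS effects
  guide_design.py    site search, allele compatibility, spacing, off-targets
  protein_homology.py translation, pairwise percent identity
  synthetic_data.py  truth-labelled simulation of the whole study design
  pipeline.py        one-command orchestration and report bundle
  cli.py             `polyamp` verbs: simulate, prep, call, classify,
                     guides, identity, run
docs/methods.md      model, parameters, numerical choices, limitations
```
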