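"""End-to-end amplicon analysis: prep -> call -> classify -> report.

One sample per invocation.  The run writes clusters.tsv,
variant_calls.tsv, edit_calls.tsv, variants.vcf, summary.json and
run_manifest.json into the output directory; all outputs are
deterministic functions of the inputs and the manifest parameters, so a
re-run with the same manifest is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .allele_caller import (Fingerprint, VariantCall, assign_allele,
                            build_fingerprints, call_variant_clusters,
                            rescue_missing)
from .edit_classifier import (CdsEffect, EditCall, VariantGroup, align_global,
                              call_site_edits_named, predict_coding_effect,
                              summarize_sample)
from .guide_design import check_allele_compatibility
from .read_prep import Cluster, MergeConfig, PrepStats, prep_sample
from .sequence_io import AlleleSet, load_locus_spec, parse_fastx

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All parameters of one amplicon analysis run."""

    r1: str
    r2: str
    locus_spec: str
    out_dir: str
    min_overlap: int = 10
    max_mismatch_frac: float = 0.25
    trim5: int = 35
    trim3: int = 35
    min_prev: float = 0.01
    mask_flank: int = 10
    assign_min_score: float = 0.8
    scoring: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.min_prev <= 0.5:
            raise ValueError("min_prev must be in (0, 0.5]")

    def validate_paths(self) -> None:
        for p in (self.r1, self.r2, self.locus_spec):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class RunResult:
    clusters: list[Cluster]
    calls: list[VariantCall]
    edit_calls: list[EditCall]
    groups: list[VariantGroup]
    fingerprints: list[Fingerprint]
    stats: PrepStats


def analyse_sample(alleles: AlleleSet, pairs, *, merge_cfg: MergeConfig | None = None,
                   trim5: int = 35, trim3: int = 35, min_prev: float = 0.01,
                   mask_flank: int = 10, assign_min_score: float = 0.8,
                   scoring: dict | None = None) -> RunResult:
    """Run the full analysis on an iterable of (r1, r2) read pairs.

    This is the library entry point; :func:`run_amplicon` wraps it with
    file I/O and report writing.
    """
    clusters, stats = prep_sample(pairs, merge_cfg, trim5, trim3)
    log.info("prep: %s", stats.as_dict())

    kept, below = call_variant_clusters(clusters, min_prev)
    guide_sites = {
        g.name: check_allele_compatibility(g, alleles) for g in alleles.guides
    }
    fingerprints = build_fingerprints(alleles, trim5=trim5, trim3=trim3)

    calls = [
        assign_allele(c, fingerprints, alleles, trim5=trim5, trim3=trim3,
                      min_score=assign_min_score)
        for c in kept
    ]

    # dropout rescue: every expected class absent from the >=1% call set
    assigned_classes = {vc.assigned for vc in calls if vc.assigned}
    seen_fp = set()
    for fp in fingerprints:
        if fp.shared_class in seen_fp or fp.shared_class in assigned_classes:
            continue
        seen_fp.add(fp.shared_class)
        rescued = rescue_missing(below, fp, alleles, trim5=trim5, trim3=trim3)
        if rescued:
            log.info("rescued %d sub-threshold cluster(s) for %s",
                     len(rescued), fp.class_label)
        calls.extend(rescued)

    edit_calls = [
        _classify_call(vc, alleles, guide_sites, trim5, trim3, mask_flank,
                       scoring)
        for vc in calls
    ]
    groups = summarize_sample([ec for ec in edit_calls if ec is not None])
    return RunResult(clusters=clusters, calls=calls,
                     edit_calls=[ec for ec in edit_calls if ec is not None],
                     groups=groups, fingerprints=fingerprints, stats=stats)


def _classify_call(vc: VariantCall, alleles: AlleleSet, guide_sites,
                   trim5: int, trim3: int, flank: int,
                   scoring: dict | None) -> EditCall | None:
    if vc.assigned is None:
        return EditCall(variants=[], site_status={}, dual_cut=False,
                        cds_effect=CdsEffect("none"), assigned=None,
                        prevalence=vc.cluster.prevalence, rescued=vc.rescued,
                        cluster_id=vc.cluster.seq.id)
    rep = vc.assigned[0]  # class representative (members are identical here)
    ref = alleles.alleles[rep].seq
    trimmed_ref = ref[trim5:len(ref) - trim3 if trim3 else len(ref)]
    variants = align_global(vc.cluster.seq.seq, trimmed_ref, scoring or None)
    variants = [  # lift to full-allele coordinates
        type(v)(v.position + trim5, v.ref, v.alt) for v in variants
    ]
    sites = {name: per_allele[rep] for name, per_allele in guide_sites.items()}
    status, dual = call_site_edits_named(variants, sites, flank=flank)
    effect = predict_coding_effect(variants, ref, alleles.gene_models[rep])
    return EditCall(variants=variants, site_status=status, dual_cut=dual,
                    cds_effect=effect, assigned=vc.assigned,
                    prevalence=vc.cluster.prevalence, rescued=vc.rescued,
                    cluster_id=vc.cluster.seq.id)


# ---------------------------------------------------------------------------
# File-level run
# ---------------------------------------------------------------------------

def run_amplicon(cfg: RunConfig) -> RunResult:
    """Run the pipeline on FASTQ input and write the report bundle.

    On stage failure the partially written outputs are removed and a
    :class:`StageError` naming the stage is raised.
    """
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        try:
            alleles = load_locus_spec(cfg.locus_spec)
        except Exception as exc:
            raise StageError("load_locus_spec", str(exc)) from exc
        try:
            pairs = zip(parse_fastx(cfg.r1, "fastq"), parse_fastx(cfg.r2, "fastq"))
            result = analyse_sample(
                alleles, pairs,
                merge_cfg=MergeConfig(cfg.min_overlap, cfg.max_mismatch_frac),
                trim5=cfg.trim5, trim3=cfg.trim3, min_prev=cfg.min_prev,
                mask_flank=cfg.mask_flank,
                assign_min_score=cfg.assign_min_score,
                scoring=cfg.scoring or None)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("analyse_sample", str(exc)) from exc
        try:
            written = _write_reports(result, alleles, cfg, out)
        except Exception as exc:
            raise StageError("write_reports", str(exc)) from exc
    except StageError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return result


def _write_reports(result: RunResult, alleles: AlleleSet, cfg: RunConfig,
                   out: Path) -> list[Path]:
    written = []

    p = out / "clusters.tsv"
    with open(p, "w") as fh:
        fh.write("rank\tsequence\tcount\tprevalence\n")
        for i, c in enumerate(result.clusters, 1):
            fh.write(f"{i}\t{c.seq.seq}\t{c.count}\t{c.prevalence:.6f}\n")
    written.append(p)

    p = out / "variant_calls.tsv"
    with open(p, "w") as fh:
        fh.write("cluster\tprevalence\tassigned\trescued\tmatch_detail\n")
        for vc in result.calls:
            detail = ";".join(f"{k}:{m}/{t}" for k, (m, t)
                              in sorted(vc.match_detail.items()))
            fh.write(f"{vc.cluster.seq.id}\t{vc.cluster.prevalence:.6f}\t"
                     f"{vc.assigned_label}\t{int(vc.rescued)}\t{detail}\n")
    written.append(p)

    p = out / "edit_calls.tsv"
    with open(p, "w") as fh:
        fh.write("cluster\tassigned\tprevalence\trescued\tn_variants\t"
                 "variants\tsite_status\tdual_cut\tcds_effect\n")
        for ec in result.edit_calls:
            vstr = ";".join(_variant_str(v) for v in ec.variants) or "."
            sstr = ";".join(f"{k}={v}" for k, v in ec.site_status.items()) or "."
            label = "/".join(ec.assigned) if ec.assigned else "unassigned"
            fh.write(f"{ec.cluster_id}\t{label}\t{ec.prevalence:.6f}\t"
                     f"{int(ec.rescued)}\t{len(ec.variants)}\t{vstr}\t{sstr}\t"
                     f"{int(ec.dual_cut)}\t{ec.cds_effect}\n")
    written.append(p)

    p = out / "variants.vcf"
    _write_vcf(result, alleles, p)
    written.append(p)

    p = out / "summary.json"
    groups = [
        {
            "assigned": "/".join(g.assigned) if g.assigned else "unassigned",
            "prevalence": round(g.prevalence, 6),
            "n_variants": len(g.variants),
            "dual_cut": g.dual_cut,
            "site_status": g.site_status,
            "cds_effect": str(g.cds_effect),
            "rescued": g.rescued,
        }
        for g in result.groups
    ]
    with open(p, "w") as fh:
        json.dump({
            "locus_id": alleles.locus_id,
            "n_variant_groups": len(result.groups),
            "groups": groups,
            "read_accounting": result.stats.as_dict(),
        }, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)

    p = out / "run_manifest.json"
    with open(p, "w") as fh:
        json.dump({
            "polyamp_version": __version__,
            "parameters": cfg.as_dict(),
        }, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)
    return written


def _variant_str(v) -> str:
    if v.type == "deletion":
        return f"del{len(v.ref)}@{v.position}"
    if v.type == "insertion":
        return f"ins{v.alt}@{v.position}"
    return f"{v.ref}{v.position}{v.alt}"


def _write_vcf(result: RunResult, alleles: AlleleSet, path: Path) -> None:
    """Minimal VCF export: left-aligned, 1-based, anchored REF/ALT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=polyamp {__version__}\n")
        for aid, rec in alleles.alleles.items():
            fh.write(f"##contig=<ID={aid},length={len(rec.seq)}>\n")
        fh.write("##INFO=<ID=PREV,Number=1,Type=Float,"
                 "Description=\"Cluster prevalence\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        rows = []
        for ec in result.edit_calls:
            if not ec.assigned:
                continue
            chrom = ec.assigned[0]
            ref = alleles.alleles[chrom].seq
            for v in ec.variants:
                if v.type == "substitution":
                    pos, r, a = v.position + 1, v.ref, v.alt
                elif v.type == "deletion":
                    if v.position == 0:
                        pos = v.position + len(v.ref)
                        r, a = v.ref + ref[pos], ref[pos]
                        pos += 1
                    else:
                        pos = v.position
                        r, a = ref[pos - 1] + v.ref, ref[pos - 1]
                else:  # insertion (or complex, exported anchored)
                    pos = v.position
                    if pos == 0:
                        r, a = ref[0], v.alt + ref[0]
                        pos = 1
                    else:
                        r, a = ref[pos - 1], ref[pos - 1] + v.alt
                rows.append((chrom, pos, r, a, ec.prevalence or 0.0))
        for chrom, pos, r, a, prev in sorted(set(rows)):
            fh.write(f"{chrom}\t{pos}\t.\t{r}\t{a}\t.\tPASS\tPREV={prev:.6f}\n")
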