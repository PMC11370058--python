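"""Variant spike-in: allele painting, duplicate-group mixing, dataset grids.

The simulation builds two copies of the template library — one with every
panel locus painted to the alternate allele in 100% of overlapping reads,
one painted to the reference allele — and then composes each dataset by
choosing, per PCR duplicate group, the alternate or reference copy.  The
expected alternate-read fraction at a panel locus therefore equals the
requested VAF, and because groups are never split between origins, every
read of a putative molecule carries the same allele; synthetic UMI families
assigned afterwards cannot straddle the ref/alt boundary.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_left, bisect_right
from pathlib import Path

import pandas as pd

import numpy as np

from . import formats
from .model import (
    DuplicateGroup,
    SpikePlan,
    SyntheticReference,
    TemplateLibrary,
    TruthSet,
    VariantRecord,
    revcomp,
)
from .seeds import derive_seed

log = logging.getLogger(__name__)

__all__ = ["paint_alleles", "mix_to_vaf", "generate_datasets",
           "groups_from_fragments", "truth_for"]


def paint_alleles(template: TemplateLibrary, panel: list[VariantRecord],
                  allele: str) -> tuple[TemplateLibrary, list[VariantRecord]]:
    """Return a copy of the template with panel loci at 100% ref or alt.

    Every read base overlapping a panel locus is set to the chosen allele;
    all other bases and all qualities are untouched.  Fragments in the copy
    get ``origin`` set to ``allele``.  Loci covered by no read are returned
    as the uncovered list (and warned about): sensitivity loss at shallow
    depth is a measured phenomenon, not an error.
    """
    if allele not in ("ref", "alt"):
        raise ValueError("allele must be 'ref' or 'alt'")
    by_contig: dict[str, list[tuple[int, VariantRecord]]] = {}
    for var in panel:
        by_contig.setdefault(var.contig, []).append((var.pos - 1, var))
    for loci in by_contig.values():
        loci.sort(key=lambda t: t[0])

    covered: set[tuple[str, int, str, str]] = set()
    painted = []
    for frag in template.fragments:
        frag = frag.copy()
        frag.origin = allele
        loci = by_contig.get(frag.contig)
        if loci:
            positions = [p for p, _ in loci]
            for window_start, attr in ((frag.frag_start, "r1"),
                                       (frag.r2_start, "r2")):
                lo = bisect_left(positions, window_start)
                hi = bisect_right(positions, window_start + frag.read_len - 1)
                for pos0, var in loci[lo:hi]:
                    base = var.alt if allele == "alt" else var.ref
                    seq = getattr(frag, attr + "_seq")
                    i = pos0 - window_start
                    setattr(frag, attr + "_seq", seq[:i] + base + seq[i + 1:])
                    covered.add(var.key())
        painted.append(frag)

    uncovered = [v for v in panel if v.key() not in covered]
    if uncovered:
        warnings.warn(f"{len(uncovered)} panel loci covered by no read", stacklevel=2)
    lib = TemplateLibrary(
        fragments=painted, targets=list(template.targets),
        read_len=template.read_len, frag_mean=template.frag_mean,
        frag_sd=template.frag_sd, mean_dupset_size=template.mean_dupset_size,
        error_rate=template.error_rate)
    return lib, uncovered


def groups_from_fragments(fragments) -> list[DuplicateGroup]:
    """Group fragments into DuplicateGroups by their group identifier.

    Group identity keys on the simulator's group id (coordinates alone
    would merge coincident ref- and alt-origin groups and break atomicity).
    """
    by_id: dict[str, list] = {}
    for frag in fragments:
        by_id.setdefault(frag.group_id, []).append(frag)
    out = []
    for members in by_id.values():
        origins = {m.origin for m in members}
        out.append(DuplicateGroup(members[0].key(), members,
                                  origin=origins.pop() if len(origins) == 1 else None))
    return out


def _groups_by_id(lib: TemplateLibrary) -> dict[str, list]:
    by_id: dict[str, list] = {}
    for frag in lib.fragments:
        by_id.setdefault(frag.group_id, []).append(frag)
    return by_id


def mix_to_vaf(ref_lib: TemplateLibrary, alt_lib: TemplateLibrary, vaf: float,
               depth_target: float, seed: int, mode: str = "bernoulli",
               copy_fragments: bool = False) -> list[DuplicateGroup]:
    """Compose one dataset by per-group choice between ref and alt copies.

    Duplicate groups are first uniformly subsampled to approach
    ``depth_target`` mean on-target depth, then each kept group takes its
    alternate-painted copy with probability ``vaf`` (mode ``"bernoulli"``).
    Mode ``"exact"`` instead accumulates alt groups in random order until
    the alt read-pair count reaches ``round(vaf * total_read_pairs)``,
    pinning the read-level alt fraction to the target with sub-group
    granularity.  Either way groups are atomic: no group mixes ref- and
    alt-origin fragments, so the expected per-locus alt fraction is ``vaf``.
    """
    if not (0.0 < vaf < 1.0):
        raise ValueError("vaf must lie in (0, 1)")
    if mode not in ("bernoulli", "exact"):
        raise ValueError("mode must be 'bernoulli' or 'exact'")
    ref_groups = _groups_by_id(ref_lib)
    alt_groups = _groups_by_id(alt_lib)
    if set(ref_groups) != set(alt_groups):
        raise ValueError("ref and alt libraries derive from different templates")
    rng = np.random.default_rng(seed)

    gids = sorted(ref_groups)
    template_depth = ref_lib.mean_target_depth()
    keep_p = depth_target / template_depth if template_depth > 0 else 1.0
    if keep_p > 1.0:
        warnings.warn(
            f"depth target {depth_target:.0f}x exceeds template depth "
            f"{template_depth:.0f}x; capped", stacklevel=2)
        keep_p = 1.0
    n_keep = int(round(keep_p * len(gids)))
    kept = sorted(rng.choice(len(gids), size=n_keep, replace=False))

    if mode == "bernoulli":
        take_alt = rng.random(n_keep) < vaf
    else:
        sizes = np.array([len(ref_groups[gids[i]]) for i in kept], dtype=int)
        target_reads = int(round(vaf * sizes.sum()))
        order = rng.permutation(n_keep)
        take_alt = np.zeros(n_keep, dtype=bool)
        acc = 0
        for i in order:
            if acc >= target_reads:
                break
            take_alt[i] = True
            acc += sizes[i]

    out = []
    for idx, is_alt in zip(kept, take_alt):
        gid = gids[idx]
        members = alt_groups[gid] if is_alt else ref_groups[gid]
        if copy_fragments:
            members = [f.copy() for f in members]
        out.append(DuplicateGroup(members[0].key(), list(members),
                                  origin="alt" if is_alt else "ref"))
    return out


def truth_for(panel: list[VariantRecord], depth: float, vaf: float,
              replicate: int) -> TruthSet:
    """Truth set for one dataset: every panel variant at the intended VAF."""
    variants = [VariantRecord(contig=v.contig, pos=v.pos, ref=v.ref, alt=v.alt,
                              info={"TVAF": float(vaf)}) for v in panel]
    return TruthSet(variants=variants, depth=depth, vaf=vaf, replicate=replicate)


def generate_datasets(template: TemplateLibrary, ref: SyntheticReference,
                      plan: SpikePlan, outdir: str | Path,
                      mode: str = "bernoulli") -> pd.DataFrame:
    """Emit the full dataset grid of a SpikePlan; return the manifest.

    One dataset per (depth, VAF, replicate) triple the plan allows (the
    shallow-depth exclusion rule applies).  Each dataset gets a unique seed
    derived from the plan's master seed, a coordinate-sorted SAM, R1/R2
    FASTQ, and a truth VCF; the manifest TSV records paths, seeds and
    intended depth/VAF for exact reruns.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref_lib, _ = paint_alleles(template, plan.panel, "ref")
    alt_lib, uncovered = paint_alleles(template, plan.panel, "alt")
    if uncovered:
        log.info("%d panel loci uncovered in template", len(uncovered))
    contig_lens = {name: len(seq) for name, seq in ref.contigs.items()}

    rows = []
    for depth, vaf, rep in plan.combinations():
        ds_seed = derive_seed(plan.seed, "dataset", depth, vaf, rep)
        groups = mix_to_vaf(ref_lib, alt_lib, vaf, depth, ds_seed, mode=mode,
                            copy_fragments=True)
        stem = f"d{depth:g}x_v{vaf:g}_r{rep}"
        sam = outdir / f"{stem}.sam"
        fq1 = outdir / f"{stem}.R1.fastq"
        fq2 = outdir / f"{stem}.R2.fastq"
        truth_vcf = outdir / f"{stem}.truth.vcf"
        fragments = [f for g in groups for f in g.members]
        formats.write_sam(fragments, ref, sam)
        formats.write_fastq(
            [(f.id, f.r1_seq, f.r1_qual) for f in fragments], fq1)
        formats.write_fastq(
            [(f.id, revcomp(f.r2_seq), f.r2_qual[::-1]) for f in fragments], fq2)
        truth = truth_for(plan.panel, depth, vaf, rep)
        formats.write_vcf(truth.variants, contig_lens, truth_vcf)
        rows.append({
            "dataset": stem, "depth": depth, "vaf": vaf, "replicate": rep,
            "seed": ds_seed, "n_read_pairs": len(fragments),
            "n_groups": len(groups), "sam": str(sam), "r1": str(fq1),
            "r2": str(fq2), "truth_vcf": str(truth_vcf),
        })
    manifest = pd.DataFrame(rows)
    formats.write_tsv(manifest, outdir / "manifest.tsv")
    return manifest
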