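"""Offline stand-ins for every external input of the benchmarking pipeline.

Real runs of this kind of benchmark start from an archived cfDNA capture
library aligned to a human reference, a somatic-catalogue variant panel and
public annotation databases.  This module generates desk-scale synthetic
equivalents — a small reference with capture targets, a duplicated
cfDNA-like template library, an SNV panel, and toy dbSNP/COSMIC-style
databases — so the whole pipeline runs and is testable with no downloads.

Defaults model targeted cfDNA sequencing: 100 bp paired-end reads, fragment
lengths ~N(166, 40) (the mononucleosomal cfDNA mode), per-base substitution
error 1e-3 at a constant Q30, and PCR duplicate sets of mean size 3.
"""

from __future__ import annotations

import numpy as np

from .model import (
    AnnotationDb,
    Fragment,
    SyntheticReference,
    TemplateLibrary,
    VariantRecord,
    DEFAULT_PANEL_SIZE,
)

__all__ = [
    "make_reference", "make_template", "make_variant_panel", "make_annotation_dbs",
    "DEFAULT_READ_LEN",
]

DEFAULT_READ_LEN = 100
_BASES = np.frombuffer(b"ACGT", dtype="S1")
_TARGET_GAP = 300  # bp of off-target sequence between and around targets


def make_reference(n_contigs: int, target_count: int, target_len: int,
                   seed: int, read_len: int = DEFAULT_READ_LEN) -> SyntheticReference:
    """Random reference with ``target_count`` disjoint capture targets.

    Targets are laid out with fixed off-target gaps, distributed round-robin
    over contigs.  ``target_len`` must be at least 3x the read length so a
    full fragment can be placed inside a target.
    """
    if target_len < 3 * read_len:
        raise ValueError(
            f"target_len {target_len} < 3x read length {read_len}: "
            "targets cannot hold a read pair")
    rng = np.random.default_rng(seed)
    per_contig = [target_count // n_contigs + (1 if i < target_count % n_contigs else 0)
                  for i in range(n_contigs)]
    contigs: dict[str, str] = {}
    targets: list[tuple[str, int, int]] = []
    for ci, n_targets in enumerate(per_contig):
        name = f"chrS{ci + 1}"
        length = _TARGET_GAP + n_targets * (target_len + _TARGET_GAP)
        seq = rng.choice(_BASES, size=length)
        contigs[name] = seq.tobytes().decode("ascii")
        for ti in range(n_targets):
            start = _TARGET_GAP + ti * (target_len + _TARGET_GAP)
            targets.append((name, start, start + target_len))
    return SyntheticReference(contigs=contigs, targets=targets)


def _apply_errors(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Independent per-base substitution to a uniformly chosen other base."""
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    if hits.size:
        seq = seq.copy()
        # shift by 1..3 in base space guarantees a different base
        idx = np.searchsorted(_BASES, seq[hits])
        seq[hits] = _BASES[(idx + rng.integers(1, 4, hits.size)) % 4]
    return seq


def make_template(ref: SyntheticReference, mean_target_depth: float,
                  mean_dupset_size: float = 3.0, seed: int = 0,
                  read_len: int = DEFAULT_READ_LEN, frag_mean: float = 166.0,
                  frag_sd: float = 40.0, error_rate: float = 0.001,
                  base_qual: int = 30) -> TemplateLibrary:
    """Simulate a duplicated cfDNA-like template library over the targets.

    Duplicate-set sizes are ``1 + Poisson(mean_dupset_size - 1)`` (zero
    truncation by construction).  Groups are emitted per target until the
    cumulative aligned bases reach the requested mean depth, so the realized
    depth tracks the request to within one duplicate set.
    """
    if mean_target_depth <= 0:
        raise ValueError("mean_target_depth must be positive")
    if mean_dupset_size < 1.0:
        raise ValueError("mean duplicate-set size must be >= 1")
    rng = np.random.default_rng(seed)
    qual_str = chr(base_qual + 33)
    fragments: list[Fragment] = []
    group_counter = 0
    for contig, t_start, t_end in ref.targets:
        contig_arr = np.frombuffer(ref.contigs[contig].encode("ascii"), dtype="S1")
        t_len = t_end - t_start
        need = mean_target_depth * t_len
        covered = 0.0
        while covered < need:
            group_counter += 1
            gid = f"g{group_counter:07d}"
            size = 1 + (rng.poisson(mean_dupset_size - 1.0) if mean_dupset_size > 1.0 else 0)
            frag_len = int(np.clip(round(rng.normal(frag_mean, frag_sd)),
                                   read_len, t_len))
            start = int(rng.integers(t_start, t_end - frag_len + 1))
            end = start + frag_len
            r1_ref = contig_arr[start:start + read_len]
            r2_ref = contig_arr[end - read_len:end]
            for mi in range(size):
                r1 = _apply_errors(r1_ref, error_rate, rng)
                r2 = _apply_errors(r2_ref, error_rate, rng)
                fragments.append(Fragment(
                    id=f"{gid}.{mi + 1}",
                    contig=contig,
                    frag_start=start,
                    frag_end=end,
                    r1_seq=r1.tobytes().decode("ascii"),
                    r1_qual=qual_str * read_len,
                    r2_seq=r2.tobytes().decode("ascii"),
                    r2_qual=qual_str * read_len,
                    group_id=gid,
                ))
            # depth counts aligned read bases (mate overlap counted twice,
            # as samtools depth does); fragments lie inside the target
            covered += size * 2 * read_len
    return TemplateLibrary(
        fragments=fragments, targets=list(ref.targets), read_len=read_len,
        frag_mean=frag_mean, frag_sd=frag_sd,
        mean_dupset_size=mean_dupset_size, error_rate=error_rate)


def make_variant_panel(ref: SyntheticReference, n_variants: int = DEFAULT_PANEL_SIZE,
                       seed: int = 0) -> list[VariantRecord]:
    """Random SNV panel at unique target loci; the spike-in truth variants.

    Mimics a somatic-catalogue panel restricted to the capture targets: one
    SNV per locus, reference allele read from the reference sequence,
    alternate drawn uniformly from the other three bases.
    """
    total = ref.target_bases
    if n_variants > total:
        raise ValueError(f"panel of {n_variants} exceeds {total} target bases")
    rng = np.random.default_rng(seed)
    # flatten target space, sample unique offsets
    offsets = rng.choice(total, size=n_variants, replace=False)
    offsets.sort()
    bounds = []
    acc = 0
    for contig, start, end in ref.targets:
        bounds.append((acc, contig, start))
        acc += end - start
    panel = []
    for off in offsets:
        base_off, contig, t_start = next(
            b for b in reversed(bounds) if b[0] <= off)
        pos0 = t_start + (int(off) - base_off)
        ref_base = ref.base_at(contig, pos0)
        alts = [b for b in "ACGT" if b != ref_base]
        alt = alts[rng.integers(0, 3)]
        panel.append(VariantRecord(contig=contig, pos=pos0 + 1, ref=ref_base, alt=alt))
    return panel


def make_annotation_dbs(panel: list[VariantRecord], ref: SyntheticReference,
                        seed: int = 0, n_dbsnp: int = 20, n_cosmic_decoys: int = 10,
                        dbsnp_afs: list[float] | None = None,
                        ) -> tuple[AnnotationDb, AnnotationDb]:
    """Toy dbSNP-style and COSMIC-style databases for the filtering stages.

    The dbSNP database holds decoy germline entries off the panel with
    allele frequencies straddling the 5% somatic-filter cutoff (default:
    1%..10% in 1% steps, recycled).  The COSMIC database contains every
    panel locus with sample count >= 3 — so true spiked variants survive the
    count >= 3 pre-filter — plus decoys with counts spanning 1..10.
    """
    rng = np.random.default_rng(seed)
    if dbsnp_afs is None:
        dbsnp_afs = [round(0.01 * k, 2) for k in range(1, 11)]
    panel_keys = {v.key() for v in panel}

    def random_snv(exclude: set) -> tuple[str, int, str, str]:
        while True:
            contig, start, end = ref.targets[rng.integers(0, len(ref.targets))]
            pos0 = int(rng.integers(start, end))
            ref_base = ref.base_at(contig, pos0)
            alt = [b for b in "ACGT" if b != ref_base][rng.integers(0, 3)]
            key = (contig, pos0 + 1, ref_base, alt)
            if key not in exclude:
                return key

    dbsnp: dict[tuple, tuple] = {}
    taken = set(panel_keys)
    for i in range(n_dbsnp):
        key = random_snv(taken)
        taken.add(key)
        dbsnp[key] = (dbsnp_afs[i % len(dbsnp_afs)],)

    cosmic: dict[tuple, tuple] = {}
    for var in panel:
        cosmic[var.key()] = (int(rng.integers(3, 51)),)
    for i in range(n_cosmic_decoys):
        key = random_snv(taken)
        taken.add(key)
        cosmic[key] = (1 + i % 10,)  # counts span 1..10
    return AnnotationDb("dbsnp", dbsnp), AnnotationDb("cosmic", cosmic)
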