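"""Core domain types shared across the toolkit.

The simulator models cell-free DNA (cfDNA) targeted sequencing: short
template fragments (~166 bp, the nucleosome-protected mode) sequenced as
paired-end reads, with PCR amplification producing sets of duplicate read
pairs that share fragment start/end coordinates.  These duplicate sets are
the atomic unit of variant spiking (so that a spiked allele is consistent
within a putative molecule) and of synthetic UMI family assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "SyntheticReference",
    "Fragment",
    "DuplicateGroup",
    "TemplateLibrary",
    "VariantRecord",
    "AnnotationDb",
    "UmiFamily",
    "SpikePlan",
    "TruthSet",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticReference:
    """A small reference genome plus the target intervals of a capture panel.

    ``contigs`` maps contig name to an uppercase A/C/G/T sequence;
    ``targets`` are 0-based half-open intervals, the stand-in for a
    targeted-panel BED file.
    """

    contigs: dict[str, str]
    targets: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name}: sequence must be A/C/G/T only")
        for contig, start, end in self.targets:
            if contig not in self.contigs:
                raise ValueError(f"target on unknown contig {contig}")
            if not (0 <= start < end <= len(self.contigs[contig])):
                raise ValueError(f"target {contig}:{start}-{end} outside contig")

    @property
    def target_bases(self) -> int:
        return sum(end - start for _, start, end in self.targets)

    def base_at(self, contig: str, pos: int) -> str:
        """Reference base at a 0-based position."""
        return self.contigs[contig][pos]


@dataclass
class Fragment:
    """One sequenced cfDNA fragment: a properly oriented read pair.

    R1 covers the forward strand from ``frag_start``; R2 covers the reverse
    strand ending at ``frag_end``.  Both mates' bases are stored in
    reference (forward) orientation, as in a SAM record; FASTQ writers
    reverse-complement R2.  ``group_id`` identifies the PCR duplicate set
    the fragment belongs to; ``origin`` records whether the fragment came
    from the reference-painted or alternate-painted copy of the template.
    """

    id: str
    contig: str
    frag_start: int
    frag_end: int
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str
    group_id: str = ""
    origin: Optional[str] = None  # "ref" | "alt"
    umi: Optional[str] = None

    def __post_init__(self) -> None:
        if self.frag_start >= self.frag_end:
            raise ValueError("frag_start must precede frag_end")
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise ValueError("sequence/quality length mismatch")

    @property
    def read_len(self) -> int:
        return len(self.r1_seq)

    @property
    def r2_start(self) -> int:
        """0-based reference start of the R2 alignment."""
        return self.frag_end - len(self.r2_seq)

    def key(self) -> tuple[str, int, int, str]:
        """Duplicate key: coordinates plus orientation (always FR here)."""
        return (self.contig, self.frag_start, self.frag_end, "FR")

    def copy(self) -> "Fragment":
        return replace(self)


@dataclass
class DuplicateGroup:
    """Fragments sharing a duplicate key — the unit of mixing and UMI work."""

    key: tuple[str, int, int, str]
    members: list[Fragment]
    origin: Optional[str] = None

    def __post_init__(self) -> None:
        for frag in self.members:
            if frag.key() != self.key:
                raise ValueError("member key does not match group key")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class TemplateLibrary:
    """A duplicated cfDNA-like read library over a reference's targets.

    Emulates an aligned targeted-sequencing template: every fragment carries
    a duplicate-group identifier, and the library remembers the generation
    parameters so downstream stages can reason about depth.
    """

    fragments: list[Fragment]
    targets: list[tuple[str, int, int]]
    read_len: int
    frag_mean: float
    frag_sd: float
    mean_dupset_size: float
    error_rate: float

    def groups(self) -> list[DuplicateGroup]:
        """Duplicate groups in order of first appearance, keyed by group_id."""
        by_id: dict[str, list[Fragment]] = {}
        for frag in self.fragments:
            by_id.setdefault(frag.group_id, []).append(frag)
        return [DuplicateGroup(members[0].key(), members, members[0].origin)
                for members in by_id.values()]

    def mean_target_depth(self) -> float:
        """Mean aligned-base depth over target bases.

        Counts read bases (mate overlap counted twice), the convention of
        ``samtools depth``; fragments are placed inside targets, so every
        aligned base is on-target.
        """
        covered = sum(2 * frag.read_len for frag in self.fragments)
        total = sum(end - start for _, start, end in self.targets)
        return covered / total if total else 0.0


@dataclass
class VariantRecord:
    """A single-nucleotide variant, the unit of spiking, filtering, scoring.

    Positions are 1-based as in VCF.  ``dp``/``qual`` are the caller-reported
    depth and PHRED variant quality (``None`` when absent).  Annotation
    stages fill ``dbsnp_afs`` (per-population allele frequencies of the
    matching dbSNP entry) and ``cosmic``/``cosmic_count``.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    dp: Optional[int] = None
    qual: Optional[float] = None
    info: dict = field(default_factory=dict)
    dbsnp_afs: Optional[tuple[float, ...]] = None
    cosmic: Optional[bool] = None
    cosmic_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("VCF position is 1-based; pos must be >= 1")
        if self.dp is not None and self.dp < 0:
            raise ValueError("DP must be non-negative")
        if self.qual is not None and self.qual < 0:
            raise ValueError("QUAL must be non-negative")

    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass
class AnnotationDb:
    """A toy variant annotation database.

    ``kind`` is ``"dbsnp"`` (germline polymorphisms; each record carries one
    or more population allele frequencies) or ``"cosmic"`` (somatic
    catalogue; each record carries a sample count).  Records map exact
    (contig, pos, ref, alt) keys to their annotation payload.
    """

    kind: str
    records: dict[tuple[str, int, str, str], tuple]

    def __post_init__(self) -> None:
        if self.kind not in ("dbsnp", "cosmic"):
            raise ValueError("kind must be 'dbsnp' or 'cosmic'")
        for key, payload in self.records.items():
            if self.kind == "dbsnp":
                if not payload or any(not (0.0 <= af <= 1.0) for af in payload):
                    raise ValueError(f"dbsnp frequencies out of [0,1] at {key}")
            else:
                (count,) = payload
                if count < 0:
                    raise ValueError(f"cosmic sample count < 0 at {key}")


@dataclass
class UmiFamily:
    """Reads within one duplicate set that share a synthetic UMI string."""

    umi: str
    members: list[Fragment]
    parent_key: tuple[str, int, int, str]

    def __post_init__(self) -> None:
        for frag in self.members:
            if frag.key() != self.parent_key:
                raise ValueError("family member outside parent duplicate set")

    @property
    def size(self) -> int:
        return len(self.members)


# VAF ladder, depth grid and replicate count used throughout.
DEFAULT_VAF_LEVELS = (0.005, 0.01, 0.02, 0.04, 0.05, 0.075)
DEFAULT_DEPTHS = (200.0, 450.0, 850.0)
DEFAULT_REPLICATES = 5
DEFAULT_PANEL_SIZE = 303
# The shallowest dataset omits the two lowest ladder levels: at ~200x the
# expected alt-read count at VAF 0.005-0.01 is ~1-2, so loci frequently
# have no supporting reads at all.
DEFAULT_MIN_VAF_BY_DEPTH = {200.0: 0.02}


@dataclass
class SpikePlan:
    """Full factorial spike-in design: panel x VAF ladder x depth x replicate."""

    panel: list[VariantRecord]
    vaf_levels: tuple[float, ...] = DEFAULT_VAF_LEVELS
    depth_targets: tuple[float, ...] = DEFAULT_DEPTHS
    replicates: int = DEFAULT_REPLICATES
    seed: int = 0
    min_vaf_by_depth: dict = field(default_factory=lambda: dict(DEFAULT_MIN_VAF_BY_DEPTH))

    def __post_init__(self) -> None:
        if any(not (0.0 < v <= 0.5) for v in self.vaf_levels):
            raise ValueError("vaf_levels must lie in (0, 0.5]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def combinations(self) -> list[tuple[float, float, int]]:
        """(depth, vaf, replicate) triples honouring the low-depth exclusion."""
        out = []
        for depth in self.depth_targets:
            floor = self.min_vaf_by_depth.get(depth, 0.0)
            for vaf in self.vaf_levels:
                if vaf < floor:
                    continue
                for rep in range(1, self.replicates + 1):
                    out.append((depth, vaf, rep))
        return out


@dataclass
class TruthSet:
    """The spiked-in variants of one dataset, with the intended VAF."""

    variants: list[VariantRecord]
    depth: float
    vaf: float
    replicate: int

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key() for v in self.variants}
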