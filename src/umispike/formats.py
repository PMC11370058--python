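"""Standard-format I/O: FASTA, BED, FASTQ, SAM, VCF, TSV.

SAM and VCF go through pysam; FASTA/FASTQ parsing through Biopython.
Plain (uncompressed, text) SAM and VCF are the canonical artifacts so every
output stays inspectable and diffable; BAM works wherever pysam does.

Conventions: BED and internal coordinates are 0-based half-open; VCF is
1-based.  R2 bases are stored in reference orientation in memory and in SAM,
and reverse-complemented on the way to FASTQ.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pysam
from Bio import SeqIO

from .model import AnnotationDb, Fragment, SyntheticReference, VariantRecord

log = logging.getLogger(__name__)

__all__ = [
    "write_fasta", "read_fasta", "write_bed", "read_bed",
    "write_fastq", "read_fastq", "write_sam", "read_sam_fragments",
    "write_vcf", "read_vcf", "write_tsv",
]


# ---------------------------------------------------------------- FASTA/BED

def write_fasta(ref: SyntheticReference, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(targets: list[tuple[str, int, int]], path: str | Path) -> None:
    """BED3, 0-based half-open."""
    with open(path, "w") as fh:
        for contig, start, end in targets:
            fh.write(f"{contig}\t{start}\t{end}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    for lineno, line in enumerate(open(path), 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED line has < 3 columns")
        contig, start, end = fields[0], int(fields[1]), int(fields[2])
        if start < 0 or end <= start:
            raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
        out.append((contig, start, end))
    return out


# ------------------------------------------------------------------- FASTQ

def write_fastq(records: list[tuple[str, str, str]], path: str | Path) -> None:
    """Write (name, seq, qual) triples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(f"read {name}: sequence/quality length mismatch")
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq), quals))
    return out


# --------------------------------------------------------------------- SAM

#: custom SAM tags carrying simulator provenance (lower-case-free, X* = local)
TAG_ORIGIN = "XO"
TAG_GROUP = "XG"


def write_sam(fragments: list[Fragment], ref: SyntheticReference,
              path: str | Path, rx_tag: bool = False) -> None:
    """Coordinate-sorted plain SAM with @HD/@SQ headers.

    Each fragment becomes a properly paired forward R1 / reverse R2 record.
    ``rx_tag=True`` stores the fragment's UMI in the standard RX tag.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in ref.contigs.items()],
    }
    names = list(ref.contigs)
    segments = []
    for frag in fragments:
        tid = names.index(frag.contig)
        tlen = frag.frag_end - frag.frag_start
        for mate, (flag, pos, seq, qual) in enumerate([
            (99, frag.frag_start, frag.r1_seq, frag.r1_qual),
            (147, frag.r2_start, frag.r2_seq, frag.r2_qual),
        ]):
            seg = pysam.AlignedSegment()
            seg.query_name = frag.id
            seg.flag = flag
            seg.reference_id = tid
            seg.reference_start = pos
            seg.mapping_quality = 60
            seg.cigarstring = f"{len(seq)}M"
            seg.next_reference_id = tid
            seg.next_reference_start = frag.r2_start if mate == 0 else frag.frag_start
            seg.template_length = tlen if mate == 0 else -tlen
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array(qual)
            tags = [(TAG_GROUP, frag.group_id)]
            if frag.origin is not None:
                tags.append((TAG_ORIGIN, frag.origin))
            if rx_tag:
                if frag.umi is None:
                    raise ValueError(f"fragment {frag.id} has no UMI for RX tagging")
                tags.append(("RX", frag.umi))
            seg.set_tags(tags)
            segments.append((tid, pos, seg))
    segments.sort(key=lambda t: (t[0], t[1]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for _, _, seg in segments:
            out.write(seg)


def read_sam_fragments(path: str | Path) -> list[Fragment]:
    """Rebuild fragments from a SAM/BAM written by :func:`write_sam`."""
    mates: dict[str, dict[int, pysam.AlignedSegment]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            mates.setdefault(seg.query_name, {})[1 if seg.is_read1 else 2] = seg
    fragments = []
    for name, pair in mates.items():
        if set(pair) != {1, 2}:
            raise ValueError(f"read {name}: missing mate in SAM")
        r1, r2 = pair[1], pair[2]
        frag = Fragment(
            id=name,
            contig=r1.reference_name,
            frag_start=r1.reference_start,
            frag_end=r2.reference_end,
            r1_seq=r1.query_sequence,
            r1_qual=pysam.qualities_to_qualitystring(r1.query_qualities),
            r2_seq=r2.query_sequence,
            r2_qual=pysam.qualities_to_qualitystring(r2.query_qualities),
            group_id=r1.get_tag(TAG_GROUP) if r1.has_tag(TAG_GROUP) else "",
            origin=r1.get_tag(TAG_ORIGIN) if r1.has_tag(TAG_ORIGIN) else None,
            umi=r1.get_tag("RX") if r1.has_tag("RX") else None,
        )
        fragments.append(frag)
    fragments.sort(key=lambda f: (f.contig, f.frag_start, f.frag_end, f.id))
    return fragments


# --------------------------------------------------------------------- VCF

_INFO_DEFS = [
    ("DP", "1", "Integer", "Read depth at the locus"),
    ("TVAF", "1", "Float", "Intended spike-in variant allele frequency"),
    ("AF", ".", "Float", "Population allele frequencies"),
    ("CNT", "1", "Integer", "Sample count in the somatic catalogue"),
    ("COSMIC", "0", "Flag", "Matched the somatic catalogue after count filtering"),
]


def _vcf_header(contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for name, number, typ, desc in _INFO_DEFS:
        header.info.add(name, number, typ, desc)
    # multiallelic inputs are split to biallelic records before filtering
    header.add_line("##umispike_representation=biallelic-split,SNV-only")
    return header


def write_vcf(records: list[VariantRecord], contigs: dict[str, int],
              path: str | Path) -> None:
    """Plain VCF v4.2; INFO carries DP/TVAF/AF/CNT/COSMIC where present."""
    header = _vcf_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.contig, r.pos, r.ref, r.alt)):
            row = out.new_record(contig=rec.contig, start=rec.pos - 1,
                                 alleles=(rec.ref, rec.alt))
            row.qual = rec.qual
            if rec.dp is not None:
                row.info["DP"] = rec.dp
            for key in ("TVAF", "CNT"):
                if key in rec.info:
                    row.info[key] = rec.info[key]
            if "AF" in rec.info:
                row.info["AF"] = tuple(rec.info["AF"])
            if rec.cosmic:
                row.info["COSMIC"] = True
            out.write(row)


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF into VariantRecords, splitting multiallelic sites.

    DP and QUAL are taken as reported and left ``None`` when absent; a
    position below 1 or a malformed row raises with the offending locus.
    """
    out = []
    with pysam.VariantFile(str(path)) as fh:
        for row in fh:
            for alt in row.alts or ():
                try:
                    try:
                        dp = row.info["DP"]
                    except (KeyError, ValueError):
                        # absent, or undeclared in a minimal header
                        dp = None
                    rec = VariantRecord(
                        contig=row.contig,
                        pos=row.pos,
                        ref=row.ref,
                        alt=alt,
                        dp=int(dp) if dp is not None else None,
                        qual=row.qual,
                        info={k: v for k, v in row.info.items()},
                    )
                except (TypeError, ValueError) as exc:
                    raise ValueError(
                        f"{path}: malformed record at {row.contig}:{row.pos}: {exc}"
                    ) from exc
                out.append(rec)
    return out


def write_annotation_db(db: AnnotationDb, contigs: dict[str, int],
                        path: str | Path) -> None:
    """Serialise a toy annotation database as VCF (AF for dbsnp, CNT for cosmic)."""
    records = []
    for (contig, pos, ref, alt), payload in db.records.items():
        info = ({"AF": tuple(payload)} if db.kind == "dbsnp"
                else {"CNT": int(payload[0])})
        records.append(VariantRecord(contig=contig, pos=pos, ref=ref, alt=alt,
                                     info=info))
    write_vcf(records, contigs, path)


def read_annotation_db(path: str | Path, kind: str) -> AnnotationDb:
    records: dict[tuple, tuple] = {}
    for rec in read_vcf(path):
        if kind == "dbsnp":
            afs = rec.info.get("AF")
            # VCF stores AF as 32-bit float; round away the representation noise
            payload = (tuple(round(float(a), 6) for a in afs)
                       if afs is not None else ())
        else:
            payload = (int(rec.info.get("CNT", 0)),)
        records[rec.key()] = payload
    return AnnotationDb(kind, records)


# --------------------------------------------------------------------- TSV

def write_tsv(df, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
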