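"""Variant filtering and annotation pipeline applied to caller VCFs.

Stages, in order: (1) discard calls with read depth or PHRED variant
quality below 50 — QUAL 50 keeps calls with a 99.999% probability of being
correct, and the quality stage auto-disables for callers that do not report
QUAL at all (Mutect2 behaviour); (2) discard calls matching a dbSNP entry
whose allele frequency is >= 5% in all recorded populations (likely
germline); (3) annotate, without dropping anything, calls found in a
COSMIC-style somatic catalogue pre-filtered to sample counts >= 3.

Matching is exact on (contig, pos, ref, alt); only SNVs are in scope, so no
left-alignment or normalisation is needed (multiallelic records are split
to biallelic on read).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .model import AnnotationDb, VariantRecord

log = logging.getLogger(__name__)

__all__ = [
    "FilterConfig", "depth_quality_filter", "qual_to_probability",
    "dbsnp_exclude", "cosmic_annotate", "run_pipeline",
]


@dataclass
class FilterConfig:
    min_depth: int = 50
    min_qual: float = 50.0
    qual_filter_enabled: bool = True
    dbsnp_af_cutoff: float = 0.05
    cosmic_min_samples: int = 3
    #: UMI-aware caller VCFs can carry unparseable depth/quality fields;
    #: with bypass on, such records skip the depth/quality stage (logged).
    bypass_unparseable: bool = False

    def __post_init__(self) -> None:
        if min(self.min_depth, self.min_qual, self.dbsnp_af_cutoff,
               self.cosmic_min_samples) < 0:
            raise ValueError("thresholds must be non-negative")


def qual_to_probability(qual: float) -> float:
    """Probability a call is correct given its PHRED quality: 1 - 10^(-Q/10)."""
    if qual < 0:
        raise ValueError("PHRED quality must be non-negative")
    return 1.0 - 10.0 ** (-qual / 10.0)


def depth_quality_filter(records: list[VariantRecord],
                         config: FilterConfig) -> list[VariantRecord]:
    """Retain records with DP >= min_depth and QUAL >= min_qual.

    When the QUAL column is uniformly missing across the input, quality
    filtering auto-disables with a logged notice, so callers that never
    emit QUAL are filtered on depth alone.  Records with DP absent fail the
    depth filter (conservative) unless ``bypass_unparseable`` is set, in
    which case records with both DP and QUAL missing bypass the stage
    entirely.  Input order is preserved.
    """
    qual_enabled = config.qual_filter_enabled
    if qual_enabled and records and all(r.qual is None for r in records):
        log.info("QUAL uniformly missing: quality filtering disabled for this input")
        qual_enabled = False

    retained = []
    n_bypassed = n_no_dp = 0
    for rec in records:
        if config.bypass_unparseable and rec.dp is None and rec.qual is None:
            n_bypassed += 1
            retained.append(rec)
            continue
        if rec.dp is None:
            n_no_dp += 1
            continue
        if rec.dp < config.min_depth:
            continue
        if qual_enabled and (rec.qual is None or rec.qual < config.min_qual):
            continue
        retained.append(rec)
    if n_bypassed:
        log.info("%d records bypassed depth/quality filtering (unparseable fields)",
                 n_bypassed)
    if n_no_dp:
        log.info("%d records failed depth filter with DP absent", n_no_dp)
    return retained


def dbsnp_exclude(records: list[VariantRecord], db: AnnotationDb,
                  cutoff: float = 0.05) -> list[VariantRecord]:
    """Drop records matching a dbSNP entry common in all its populations.

    A record is discarded iff an exact-key database entry exists whose
    allele frequency is >= ``cutoff`` in every population recorded for it —
    an entry at {4%, 6%} is not excluded.  Matching records kept get their
    per-population frequencies attached.
    """
    if db.kind != "dbsnp":
        raise ValueError("dbsnp_exclude needs a dbsnp-kind database")
    retained = []
    for rec in records:
        afs = db.records.get(rec.key())
        if afs is not None:
            rec.dbsnp_afs = tuple(afs)
            if all(af >= cutoff for af in afs):
                continue
        retained.append(rec)
    return retained


def cosmic_annotate(records: list[VariantRecord], db: AnnotationDb,
                    min_samples: int = 3) -> list[VariantRecord]:
    """Flag records found in the count-filtered somatic catalogue.

    The database is first restricted to entries seen in >= ``min_samples``
    samples; each record is then flagged ``cosmic`` iff its exact key
    matches a surviving entry.  Annotation only — nothing is dropped.
    """
    if db.kind != "cosmic":
        raise ValueError("cosmic_annotate needs a cosmic-kind database")
    usable = {key: cnt for key, (cnt,) in db.records.items() if cnt >= min_samples}
    for rec in records:
        cnt = usable.get(rec.key())
        rec.cosmic = cnt is not None
        rec.cosmic_count = cnt
    return records


def run_pipeline(records: list[VariantRecord], config: FilterConfig,
                 dbsnp: AnnotationDb | None = None,
                 cosmic: AnnotationDb | None = None,
                 ) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Full pipeline in stage order; returns records and per-stage counts."""
    stages = []

    def record_stage(name: str, n_in: int, n_out: int) -> None:
        stages.append({"stage": name, "in": n_in, "retained": n_out,
                       "discarded": n_in - n_out})

    n0 = len(records)
    records = depth_quality_filter(records, config)
    record_stage("depth_quality", n0, len(records))
    if dbsnp is not None:
        n0 = len(records)
        records = dbsnp_exclude(records, dbsnp, config.dbsnp_af_cutoff)
        record_stage("dbsnp_exclude", n0, len(records))
    if cosmic is not None:
        n0 = len(records)
        records = cosmic_annotate(records, cosmic, config.cosmic_min_samples)
        record_stage("cosmic_annotate", n0, len(records))
    return records, pd.DataFrame(stages)
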