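"""Synthetic UMI family assignment and encoding.

Reads sharing fragment start/end coordinates are taken to be PCR duplicates
of one template molecule pool.  Each duplicate set is partitioned into UMI
families by Poisson sampling with lambda = 1/2: in the default "label" mode
every read independently draws an integer label k ~ Poisson(1/2) and reads
sharing a label form a family; the alternative "carve" mode sequentially
cuts family sizes max(1, Poisson(1/2)) off the set.  Each family then
receives a random 9-mer over {A, T, C, G} at PHRED quality 37, unique
within its duplicate set.

Three encoding dialects serve different downstream consumers: a separate
UMI FASTQ alongside R1/R2, UMIs prepended 5' of R1, or the standard SAM
``RX`` tag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import formats
from .model import DuplicateGroup, Fragment, SyntheticReference, UmiFamily, revcomp

__all__ = [
    "UMI_LENGTH", "UMI_QUAL", "DEFAULT_LAMBDA",
    "poisson_labels", "mint_umi", "assign_families", "assign_all",
    "encode", "decode_umi_map", "family_preservation_check",
]

UMI_LENGTH = 9
UMI_QUAL = 37          # PHRED quality of every UMI base
DEFAULT_LAMBDA = 0.5   # Poisson mean for family assignment
_UMI_ALPHABET = "ATCG"


def poisson_labels(n: int, lam: float, rng: np.random.Generator) -> np.ndarray:
    """The raw per-read Poisson draws; exposed for statistical testing."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return rng.poisson(lam, size=n)


def mint_umi(existing: set[str], length: int = UMI_LENGTH,
             rng: np.random.Generator | None = None) -> str:
    """Random UMI string not in ``existing`` (rejection on collision).

    Collisions are only rejected within one duplicate set; across sets they
    are allowed (and, at 4^9 strings, rare).
    """
    if len(existing) >= 4 ** length:
        raise ValueError(f"UMI space of length {length} exhausted")
    rng = rng if rng is not None else np.random.default_rng()
    while True:
        umi = "".join(_UMI_ALPHABET[i] for i in rng.integers(0, 4, size=length))
        if umi not in existing:
            return umi


def assign_families(group: DuplicateGroup, lam: float = DEFAULT_LAMBDA,
                    seed: int | np.random.Generator = 0, mode: str = "label",
                    umi_length: int = UMI_LENGTH,
                    draws_out: list | None = None) -> list[UmiFamily]:
    """Partition one duplicate set into UMI families.

    Every member ends up in exactly one family; both mates of a pair share
    the UMI (a fragment is a read pair, so the UMI is set once per
    fragment).  Passing a list as ``draws_out`` collects the raw Poisson
    draws for inspection.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not group.members:
        raise ValueError("duplicate group is empty")
    if mode not in ("label", "carve"):
        raise ValueError("mode must be 'label' or 'carve'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = group.size
    if mode == "label":
        labels = poisson_labels(n, lam, rng)
        if draws_out is not None:
            draws_out.extend(int(k) for k in labels)
        partition: dict[int, list[Fragment]] = {}
        for frag, k in zip(group.members, labels):
            partition.setdefault(int(k), []).append(frag)
        parts = [partition[k] for k in sorted(partition)]
    else:
        parts = []
        i = 0
        while i < n:
            draw = int(rng.poisson(lam))
            if draws_out is not None:
                draws_out.append(draw)
            size = max(1, draw)
            parts.append(group.members[i:i + size])
            i += size

    used: set[str] = set()
    families = []
    for members in parts:
        umi = mint_umi(used, umi_length, rng)
        used.add(umi)
        for frag in members:
            frag.umi = umi
        families.append(UmiFamily(umi=umi, members=members, parent_key=group.key))
    return families


def assign_all(groups: list[DuplicateGroup], lam: float = DEFAULT_LAMBDA,
               seed: int = 0, mode: str = "label") -> list[UmiFamily]:
    """Assign families across a whole dataset with one seeded stream."""
    rng = np.random.default_rng(seed)
    families = []
    for group in groups:
        families.extend(assign_families(group, lam=lam, seed=rng, mode=mode))
    return families


# ------------------------------------------------------------------ dialects

_DIALECTS = ("three_file", "prepended", "rx_tag")


def encode(fragments: list[Fragment], dialect: str, out: str | Path,
           ref: SyntheticReference | None = None) -> dict[str, Path]:
    """Write a dataset with assigned UMIs in one of three dialects.

    three_file
        ``<out>.R1.fastq`` / ``<out>.UMI.fastq`` / ``<out>.R2.fastq`` with
        matching read names and order; UMI record qualities all Q37.
    prepended
        ``<out>.R1.fastq`` / ``<out>.R2.fastq`` with the UMI and its Q37
        qualities concatenated 5' of R1.
    rx_tag
        ``<out>.sam`` whose records carry ``RX:Z:<umi>`` (needs ``ref``).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}")
    missing = [f.id for f in fragments if f.umi is None]
    if missing:
        raise ValueError(f"{len(missing)} fragments have no UMI assigned")
    out = Path(out)
    umi_qual = chr(UMI_QUAL + 33)
    if dialect == "rx_tag":
        if ref is None:
            raise ValueError("rx_tag dialect needs the reference for SAM headers")
        path = out.with_suffix(".sam")
        formats.write_sam(fragments, ref, path, rx_tag=True)
        return {"sam": path}
    r1 = []
    r2 = [(f.id, revcomp(f.r2_seq), f.r2_qual[::-1]) for f in fragments]
    if dialect == "three_file":
        umis = [(f.id, f.umi, umi_qual * len(f.umi)) for f in fragments]
        r1 = [(f.id, f.r1_seq, f.r1_qual) for f in fragments]
        paths = {"r1": out.parent / (out.name + ".R1.fastq"),
                 "umi": out.parent / (out.name + ".UMI.fastq"),
                 "r2": out.parent / (out.name + ".R2.fastq")}
        formats.write_fastq(r1, paths["r1"])
        formats.write_fastq(umis, paths["umi"])
        formats.write_fastq(r2, paths["r2"])
        return paths
    # prepended: UMI 5' of the R1 sequence with its qualities likewise
    r1 = [(f.id, f.umi + f.r1_seq, umi_qual * len(f.umi) + f.r1_qual)
          for f in fragments]
    paths = {"r1": out.parent / (out.name + ".R1.fastq"),
             "r2": out.parent / (out.name + ".R2.fastq")}
    formats.write_fastq(r1, paths["r1"])
    formats.write_fastq(r2, paths["r2"])
    return paths


def decode_umi_map(dialect: str, paths: dict[str, Path],
                   umi_length: int = UMI_LENGTH) -> dict[str, str]:
    """Recover the read-name -> UMI map from encoded files.

    All three dialects must decode to the identical map for one dataset;
    this is the round-trip check the encoders are tested against.
    """
    if dialect == "three_file":
        return {name: seq for name, seq, _ in formats.read_fastq(paths["umi"])}
    if dialect == "prepended":
        return {name: seq[:umi_length]
                for name, seq, _ in formats.read_fastq(paths["r1"])}
    if dialect == "rx_tag":
        return {f.id: f.umi for f in formats.read_sam_fragments(paths["sam"])}
    raise ValueError(f"dialect must be one of {_DIALECTS}")


# -------------------------------------------------------------- preservation

@dataclass
class PreservationReport:
    n_families: int
    violations: list[tuple]  # (contig, start, end, umi, origins seen)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.violations,
                            columns=["contig", "start", "end", "umi", "origins"])


def family_preservation_check(fragments: list[Fragment],
                              strict: bool = False) -> PreservationReport:
    """Verify no UMI family mixes ref- and alt-origin reads.

    Duplicate-group preservation during mixing exists precisely so that a
    spiked variant is shared by a whole UMI family; a family straddling the
    origin boundary would look like an intra-family artefact to a UMI-aware
    caller.  Families here are identified by (coordinates, UMI).
    """
    seen: dict[tuple, set] = {}
    for frag in fragments:
        if frag.umi is None or frag.origin is None:
            continue
        seen.setdefault((frag.contig, frag.frag_start, frag.frag_end, frag.umi),
                        set()).add(frag.origin)
    violations = [key + (sorted(origins),)
                  for key, origins in seen.items() if len(origins) > 1]
    report = PreservationReport(n_families=len(seen), violations=violations)
    if strict and violations:
        key = violations[0]
        raise RuntimeError(
            f"UMI family {key[3]} at {key[0]}:{key[1]}-{key[2]} mixes origins")
    return report


def family_report(families: list[UmiFamily]) -> pd.DataFrame:
    """Per-family TSV-able table: group key, UMI, size, origin."""
    rows = []
    for fam in families:
        origins = {m.origin for m in fam.members}
        rows.append({
            "contig": fam.parent_key[0], "start": fam.parent_key[1],
            "end": fam.parent_key[2], "umi": fam.umi, "size": fam.size,
            "origin": origins.pop() if len(origins) == 1 else "mixed",
        })
    return pd.DataFrame(rows)
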