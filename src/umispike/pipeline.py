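"""End-to-end orchestration: fixtures -> spike -> UMIs -> filter -> score.

``run_all`` wires every stage together on generated fixtures, using the
built-in naive pileup caller as the stand-in caller, and writes the report
TSVs.  It exists for demonstrations, smoke testing and determinism checks;
real benchmarking swaps the naive caller for external caller VCFs at the
``filter``/``evaluate`` stages.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import evaluate, filtering, fixtures, formats, spike, umi
from .model import SpikePlan, TruthSet
from .seeds import derive_seed

log = logging.getLogger(__name__)

__all__ = ["run_all"]

# desk-scale defaults: ~5 kb of targets keeps a full grid under a minute
SMALL = dict(n_contigs=1, target_count=3, target_len=1400, panel_size=40,
             template_depth=140.0, depth_targets=(60.0, 120.0),
             vaf_levels=(0.05, 0.075), replicates=2, mean_dupset_size=3.0)
FULL = dict(n_contigs=2, target_count=6, target_len=2000, panel_size=303,
            template_depth=900.0, depth_targets=(200.0, 450.0, 850.0),
            vaf_levels=(0.005, 0.01, 0.02, 0.04, 0.05, 0.075), replicates=5,
            mean_dupset_size=3.0)


def run_all(seed: int, outdir: str | Path, small: bool = True,
            umi_mode: str = "label", lam: float = umi.DEFAULT_LAMBDA,
            dialect: str = "rx_tag") -> dict:
    """Run the whole pipeline on generated fixtures; return the reports.

    Writes per-dataset scores, per-(depth, VAF) replicate means, an
    intersection table between two threshold settings of the naive caller,
    and a manifest of seeds and parameters, all under ``outdir``.
    """
    params = SMALL if small else FULL
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ref = fixtures.make_reference(params["n_contigs"], params["target_count"],
                                  params["target_len"],
                                  seed=derive_seed(seed, "reference"))
    template = fixtures.make_template(ref, params["template_depth"],
                                      params["mean_dupset_size"],
                                      seed=derive_seed(seed, "template"))
    panel = fixtures.make_variant_panel(ref, params["panel_size"],
                                        seed=derive_seed(seed, "panel"))
    dbsnp, cosmic = fixtures.make_annotation_dbs(panel, ref,
                                                 seed=derive_seed(seed, "dbs"))
    contig_lens = {name: len(s) for name, s in ref.contigs.items()}
    formats.write_fasta(ref, outdir / "reference.fasta")
    formats.write_bed(ref.targets, outdir / "targets.bed")
    formats.write_annotation_db(dbsnp, contig_lens, outdir / "dbsnp.vcf")
    formats.write_annotation_db(cosmic, contig_lens, outdir / "cosmic.vcf")

    plan = SpikePlan(panel=panel, vaf_levels=tuple(params["vaf_levels"]),
                     depth_targets=tuple(params["depth_targets"]),
                     replicates=params["replicates"], seed=seed,
                     min_vaf_by_depth={})
    manifest = spike.generate_datasets(template, ref, plan, outdir / "datasets")

    config = filtering.FilterConfig()
    rows = []
    loose_keys: set = set()
    strict_keys: set = set()
    for row in manifest.itertuples():
        fragments = formats.read_sam_fragments(row.sam)
        groups = spike.groups_from_fragments(fragments)
        umi.assign_all(groups, lam=lam,
                       seed=derive_seed(seed, "umi", row.dataset), mode=umi_mode)
        report = umi.family_preservation_check(fragments, strict=True)
        umi.encode(fragments, dialect, outdir / "datasets" / f"{row.dataset}.umi",
                   ref=ref)
        calls = evaluate.naive_pileup_caller(fragments, ref, targets=ref.targets)
        strict_calls = [c for c in calls if c.dp is not None and c.dp >= 10
                        and c.qual is not None and c.qual >= 100]
        filtered, _counts = filtering.run_pipeline(calls, config, dbsnp, cosmic)
        truth = spike.truth_for(panel, row.depth, row.vaf, row.replicate)
        tp, fp = evaluate.match_truth(filtered, truth)
        loose_keys |= {c.key() for c in filtered}
        strict_keys |= {c.key() for c in strict_calls}
        rows.append({"dataset": row.dataset, "depth": row.depth,
                     "vaf": row.vaf, "replicate": row.replicate,
                     "tp": len(tp), "putative_fp": len(fp),
                     "total_calls": len(tp) + len(fp),
                     "n_umi_families": report.n_families})
    per_dataset = pd.DataFrame(rows)
    summary = evaluate.summarize_replicates(per_dataset)
    table, private = evaluate.intersections(
        {"naive": loose_keys, "naive_strict": strict_keys})
    inter = pd.DataFrame(
        [{"callers": "+".join(sorted(s)), "exclusive_count": n}
         for s, n in sorted(table.items(), key=lambda kv: sorted(kv[0]))])
    private_df = pd.DataFrame(
        [{"caller": c, "private_pct": p} for c, p in sorted(private.items())])

    formats.write_tsv(per_dataset, outdir / "per_dataset.tsv")
    formats.write_tsv(summary, outdir / "summary.tsv")
    formats.write_tsv(inter, outdir / "intersections.tsv")
    formats.write_tsv(private_df, outdir / "private_fractions.tsv")
    return {"manifest": manifest, "per_dataset": per_dataset,
            "summary": summary, "intersections": table, "private": private,
            "outdir": outdir}
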