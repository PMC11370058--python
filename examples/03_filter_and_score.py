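"""Filter a caller VCF and score it against the spike-in truth set.

Runs the built-in naive pileup caller on a spiked dataset, pushes the
calls through the filtering pipeline (depth/quality >= 50, dbSNP >= 5%
exclusion, COSMIC count >= 3 annotation), and reports true positives and
putative false positives (total calls minus true positives).
"""

from umispike import evaluate, filtering, fixtures, spike

ref = fixtures.make_reference(1, 3, 1500, seed=1)
template = fixtures.make_template(ref, 200.0, 3.0, seed=2)
panel = fixtures.make_variant_panel(ref, 40, seed=3)
dbsnp, cosmic = fixtures.make_annotation_dbs(panel, ref, seed=4)

ref_lib, _ = spike.paint_alleles(template, panel, "ref")
alt_lib, _ = spike.paint_alleles(template, panel, "alt")
groups = spike.mix_to_vaf(ref_lib, alt_lib, 0.075, 180.0, seed=5)
fragments = [f for g in groups for f in g.members]

calls = evaluate.naive_pileup_caller(fragments, ref, targets=ref.targets)
config = filtering.FilterConfig()  # DP >= 50, QUAL >= 50, dbSNP 5%, COSMIC 3
retained, stage_counts = filtering.run_pipeline(calls, config, dbsnp, cosmic)
print(stage_counts.to_string(index=False))

truth = spike.truth_for(panel, depth=180.0, vaf=0.075, replicate=1)
tp, fp = evaluate.match_truth(retained, truth)
pct, total = evaluate.cosmic_fraction(retained)
print(f"\ntruth variants: {len(truth.variants)}")
print(f"true positives: {len(tp)}  putative false positives: {len(fp)}  "
      f"(TP + pFP = {len(tp) + len(fp)} = total retained calls)")
print(f"calls annotated in the somatic catalogue: {pct}% of {total}")
# QUAL >= 50 keeps calls with >= 99.999% probability of being correct:
print(f"QUAL 50 <-> P(correct) = {filtering.qual_to_probability(50.0):.5f}")
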