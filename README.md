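# umispike

Benchmarking machinery for low-frequency variant calling in circulating
tumour DNA (ctDNA): a spike-in read simulator, a synthetic-UMI encoder, and
a VCF filtering/evaluation pipeline.

## The problem

Somatic variants in ctDNA occur at allele fractions of 0.5–10%, at the edge
of what sequencing error allows a caller to detect. Benchmarking callers at
these fractions needs datasets where the truth is known exactly. This
package builds such datasets by *spiking*: starting from a duplicated
cfDNA-like template of aligned paired-end reads, it creates one copy with a
panel of known SNVs painted in at 100% allele frequency and one copy with
the reference allele at the same loci, then recombines PCR-duplicate groups
from the two copies so that each target variant appears at a controlled
variant allele frequency (VAF)

> VAF at a locus = alt-supporting reads / total reads.

Selection operates on whole PCR-duplicate groups (reads sharing fragment
start/end coordinates): each group takes its alternate copy with
probability equal to the target VAF, so the expected alt fraction at every
panel locus equals the VAF, and no putative molecule ever carries both
alleles. Because groups stay intact, synthetic unique molecular identifiers
(UMIs) assigned afterwards are consistent with the spiked alleles: every
read of a UMI family supports the same allele.

UMI families are assigned per duplicate set by Poisson sampling with
λ = 1/2 — each read draws an integer label k ~ Poisson(½) and reads sharing
a label form a family — then each family receives a random 9-mer over
{A,T,C,G} at PHRED quality 37. Encoded output comes in the three dialects
UMI-aware pipelines consume: a separate UMI FASTQ next to R1/R2, UMIs
prepended 5′ of R1, or the SAM `RX` tag.

Caller output VCFs are filtered the way ctDNA studies filter them — discard
calls with depth or variant quality below 50 (QUAL 50 ↔ 99.999% probability
of a correct call; the quality stage auto-disables for callers that report
no QUAL), discard calls in a dbSNP-style database at ≥ 5% frequency in all
populations, annotate calls found in a COSMIC-style somatic catalogue
pre-filtered to sample count ≥ 3 — and scored: true positives against the
truth VCF, *putative false positives* (total calls minus true positives)
where true negatives are unknowable, catalogue fractions, and UpSet-style
exclusive intersections across callers.

Everything external in a real run of this kind (reference genome, target
BED, template BAM, variant panel, annotation databases) is generated
synthetically by the `fixtures` module, so the whole pipeline runs offline
at desk scale.

## A worked example

```python
import numpy as np
from umispike import fixtures, spike, evaluate

ref = fixtures.make_reference(n_contigs=1, target_count=3, target_len=1500, seed=1)
template = fixtures.make_template(ref, mean_target_depth=150.0,
                                  mean_dupset_size=3.0, seed=2)
panel = fixtures.make_variant_panel(ref, n_variants=40, seed=3)

ref_lib, _ = spike.paint_alleles(template, panel, "ref")
alt_lib, _ = spike.paint_alleles(template, panel, "alt")
groups = spike.mix_to_vaf(ref_lib, alt_lib, vaf=0.05, depth_target=120.0, seed=11)
fragments = [f for g in groups for f in g.members]

fracs = [f for f in (evaluate.alt_fraction_at(fragments, ref, v)[0] for v in panel)
         if f is not None]
print(f"mean empirical VAF over {len(fracs)} covered loci: {np.mean(fracs):.4f}")
```

prints

```
mean empirical VAF over 40 covered loci: 0.0537
```

— the spiked dataset carries the 40 panel SNVs at an allele fraction
scattered binomially around the intended 5%. The `examples/` directory has
one short script per capability: spiking (`01`), UMI families and dialects
(`02`), filtering and truth scoring (`03`), and caller concordance (`04`).

The full grid a benchmark would use — VAF ladder
{0.005, 0.01, 0.02, 0.04, 0.05, 0.075} × depths {200x, 450x, 850x} × 5
replicates, with the two lowest VAFs dropped at 200x where they are rarely
supported by any read — is expressed as a `SpikePlan` and materialised by
`spike.generate_datasets`, which writes per-dataset SAM, R1/R2 FASTQ, a
truth VCF (INFO key `TVAF` holds the intended VAF) and a manifest TSV with
the derived per-dataset seeds.

A thin CLI mirrors the stages (`umispike fixtures | spike | umi-encode |
filter | evaluate | run-all`); `umispike run-all --seed 11 --outdir out
--small` chains everything on generated fixtures and is byte-reproducible
for a fixed seed.

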