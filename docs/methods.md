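# Methods

## The simulation model

The package models targeted sequencing of cell-free DNA (cfDNA): short
template fragments captured over a panel of target intervals, amplified by
PCR, and sequenced as paired-end reads. Three layers make up a dataset:

1. **Template library** (`fixtures.make_template`). Fragments are placed
   uniformly within target intervals, with lengths drawn from a normal
   distribution clipped to [read length, target length]. Each placement
   founds a *PCR duplicate set*: all of its read pairs share fragment start
   and end coordinates, which is also exactly how downstream stages
   recognise duplicates. Duplicate-set sizes are drawn as
   1 + Poisson(m − 1), a zero-truncated-by-construction model with
   tunable mean m ≥ 1. Every read base carries an independent substitution
   error; qualities are a constant Q30. Groups are emitted until the
   cumulative aligned read bases reach the requested mean on-target depth,
   so realized depth tracks the request to within one duplicate set. Depth
   counts aligned read bases per position (mate overlap counted twice),
   matching `samtools depth`.

2. **Allele painting and mixing** (`spike`). Two copies of the template are
   made: one with every panel locus set to the alternate allele in every
   overlapping read (100% VAF), one set to the reference allele. A dataset
   is composed per duplicate group: after uniform group subsampling to the
   target depth, each group takes its alt copy with probability equal to
   the target VAF (Bernoulli mode, the default). Groups are atomic — no
   group mixes origins — so (a) the expected alt fraction at every covered
   panel locus equals the VAF, and (b) any UMI family assigned later lies
   entirely on one side of the ref/alt boundary. An exact-count mode
   instead accumulates alt groups in random order until the alt read-pair
   count reaches round(VAF × total read pairs), pinning the global
   read-level fraction at the cost of no longer being i.i.d. per group.
   The per-locus empirical VAF is then a weighted sum of Bernoulli group
   indicators; its exact standard error,
   sqrt(p(1−p)·Σ w_g²) with w_g each group's share of locus-covering
   reads, is what the statistical tests assert against. Panel loci covered
   by no read are retained in the truth VCF and reported: missing support
   at low depth is the phenomenon being measured, not an error.

3. **Synthetic UMIs** (`umi`). Each duplicate set is partitioned into UMI
   families; each family receives a random 9-mer over {A,T,C,G} with all
   base qualities Q37, unique within its duplicate set (collisions across
   sets are allowed — the 4⁹ space makes them rare, and coordinate-distinct
   molecules with equal UMIs are biologically meaningful). Both mates of a
   pair share the fragment's UMI.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| read length | 100 bp | per-mate read length |
| fragment length | N(166, 40) bp | mononucleosomal cfDNA mode |
| per-base error | 1e-3 (Q30) | independent substitution per read base |
| mean duplicate-set size | 3.0 | mean PCR copies per template molecule |
| VAF ladder | 0.005, 0.01, 0.02, 0.04, 0.05, 0.075 | spike-in levels |
| depth grid | 200x, 450x, 850x | dataset mean on-target depths |
| replicates | 5 | datasets per (depth, VAF) cell |
| 200x exclusion | VAF < 0.02 dropped | ~1–2 expected alt reads is below reliable support |
| UMI λ | 0.5 | Poisson mean for family assignment |
| UMI length / quality | 9 / Q37 | synthetic UMI format |
| filter thresholds | DP ≥ 50, QUAL ≥ 50, dbSNP ≥ 5%, COSMIC count ≥ 3 | VCF pipeline |
| naive caller | alt reads ≥ 3 and alt fraction ≥ 0.004 | test/demo caller only |

## Interpretation ambiguity in family assignment

"Assign each read to a UMI family by Poisson sampling" admits two readings,
both honouring λ = ½. The default (`mode="label"`) draws an integer label
k ~ Poisson(½) per read and groups equal labels — the literal per-read
reading. The alternative (`mode="carve"`) sequentially cuts family sizes
max(1, Poisson(½)) off the duplicate set. The label mode produces more
singleton splits (a pair splits with probability ≈ 0.53); both are exposed,
and the partition-conservation and split-probability tests cover the
default against closed-form enumeration over the shared label value.

During UMI assignment, duplicate-set identity keys on the simulator's group
identifier, not on coordinates alone: the alt and ref copies of a locus
share coordinates by construction, and coordinate-only keying could merge
them into one set, contradicting the design goal that families never span
the origin boundary. `family_preservation_check` asserts this invariant on
every dataset.

## Filtering semantics

Filtering order is depth/quality → dbSNP exclusion → COSMIC annotation.
The first two stages commute (both are per-record predicates), which the
suite asserts. Specific choices:

* QUAL uniformly missing across an input auto-disables the quality stage
  (callers that never emit QUAL are filtered on depth alone); partially
  missing QUAL fails those records.
* A record with no parseable DP fails the depth filter (conservative).
  VCFs from UMI-aware callers whose fields do not parse can instead bypass
  the depth/quality stage entirely via an explicit, logged flag.
* dbSNP exclusion requires frequency ≥ cutoff in *all* populations recorded
  for the entry (an entry at {4%, 6%} survives); a single-frequency entry
  degenerates to a plain cutoff.
* Annotation matching is exact on (contig, pos, ref, alt). Only SNVs are in
  scope, so no left-alignment or normalisation is performed; multiallelic
  records are split to biallelic on read and the output header says so.
* Truth matching is exact-key; each truth record matches at most once.

## The naive pileup caller

`evaluate.naive_pileup_caller` calls the dominant non-reference base where
alt reads ≥ 3 and alt fraction ≥ 0.004, with QUAL the PHRED-scaled binomial
tail probability of that alt count under the sequencing-error rate. It
exists so filtering and scoring run end-to-end with no external caller; it
is deliberately simple and is not a contribution to variant calling. The
depth- and VAF-sensitivity trends the suite asserts (more true positives at
higher depth and higher VAF) are properties of the datasets that any
threshold caller exposes.

## What the synthetic data does and does not emulate

Emulated: targeted capture with off-target gaps; cfDNA fragment-length
scale; PCR duplicate structure with tunable mean; sequencing error as
independent substitutions; depth/VAF grids with replicates; truth-aware and
truth-free (catalogue-based) evaluation. Not emulated: GC and capture bias,
fragmentomics end motifs, strand-specific error, indels and multi-nucleotide
variants, real human polymorphism backgrounds, UMI sequencing errors, and
consensus collapsing. Passing tests therefore validate the machinery —
group-preserving mixing, family assignment, filtering arithmetic, scoring —
not any claim about how real callers rank on real ctDNA.

## Numerical and reproducibility choices

* One master seed fans out to every stage via SHA-256 over
  (seed, stage labels), truncated to 31 bits (`seeds.derive_seed`); each
  dataset's derived seed lands in the manifest, so any dataset can be
  regenerated in isolation. End-to-end reruns with the same seed are
  byte-identical.
* Coordinates are 0-based half-open internally and in BED; VCF is 1-based.
  R2 bases are stored in reference orientation (SAM convention) and
  reverse-complemented only in FASTQ output.
* Plain text SAM/VCF are the canonical artifacts so outputs stay diffable;
  BAM works wherever pysam reads it.
* Depth subsampling above the available template depth caps with a warning
  rather than failing.
* The acceptance computation sizes its fixture at 24 × 2 kb targets
  (~48 kb) — the scale of a multi-gene ctDNA capture panel — so the 303
  panel loci are spaced ~160 bp apart and rarely share a duplicate group,
  keeping per-locus fractions nearly independent. Test-suite fixtures use
  1.2–2 kb targets and 25–60-variant panels to keep the default run fast.

## Known limitations

* The whole library lives in memory as Python objects; the design targets
  desk-scale references (≤ 10 Mb), not genome-scale simulation.
* Group-level Bernoulli mixing gives the correct expectation but a
  group-count-limited variance; datasets at very low depth have VAF spread
  dominated by few covering groups, which is realistic but means single-
  locus VAFs are coarse.
* The alt/ref painting overwrites sequencing errors at panel loci, so
  spiked loci are error-free by construction; error-driven putative false
  positives arise only away from the panel.
* FASTQ output is unaligned by name only; realignment is out of scope, and
  the self-aligned SAM stands in for the aligner step.
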