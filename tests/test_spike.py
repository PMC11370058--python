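"""Spike module: allele painting, group-atomic mixing, dataset grids."""

import numpy as np
import pytest

from umispike import fixtures, formats, spike
from umispike.model import SpikePlan, DEFAULT_VAF_LEVELS

from conftest import brute_alt_fraction


class TestPaintAlleles:
    def test_alt_painting_reaches_full_allele_fraction(self, painted, panel_small):
        _, alt_lib = painted
        for var in panel_small:
            frac, depth = brute_alt_fraction(alt_lib.fragments, var)
            if depth:
                assert frac == 1.0

    def test_ref_painting_of_error_free_template_is_identity(self, ref_small, panel_small):
        clean = fixtures.make_template(ref_small, 30.0, 2.0, seed=5, error_rate=0.0)
        painted_lib, _ = spike.paint_alleles(clean, panel_small, "ref")
        for before, after in zip(clean.fragments, painted_lib.fragments):
            assert before.r1_seq == after.r1_seq and before.r2_seq == after.r2_seq
            assert before.r1_qual == after.r1_qual
            assert after.origin == "ref"

    def test_qualities_and_offpanel_bases_unchanged(self, template_small, painted,
                                                    panel_small):
        _, alt_lib = painted
        loci = {(v.contig, v.pos - 1) for v in panel_small}
        for before, after in zip(template_small.fragments, alt_lib.fragments):
            assert before.r1_qual == after.r1_qual
            for i, (a, b) in enumerate(zip(before.r1_seq, after.r1_seq)):
                if a != b:
                    assert (before.contig, before.frag_start + i) in loci

    def test_uncovered_locus_reported(self, ref_small):
        lib = fixtures.make_template(ref_small, 5.0, 1.0, seed=2)
        contig, start, end = ref_small.targets[0]
        # a locus the sparse library happens not to cover
        covered = set()
        for f in lib.fragments:
            covered.update(range(f.frag_start, f.frag_start + f.read_len))
            covered.update(f.r2_start + i for i in range(f.read_len))
        pos0 = next(p for p in range(start, end) if p not in covered)
        ref_base = ref_small.base_at(contig, pos0)
        alt = next(b for b in "ACGT" if b != ref_base)
        panel = [spike.VariantRecord(contig=contig, pos=pos0 + 1,
                                     ref=ref_base, alt=alt)]
        with pytest.warns(UserWarning, match="no read"):
            _, uncovered = spike.paint_alleles(lib, panel, "alt")
        assert [v.key() for v in uncovered] == [panel[0].key()]


class TestMixToVaf:
    def test_vaf_domain_error(self, painted):
        ref_lib, alt_lib = painted
        with pytest.raises(ValueError, match="vaf"):
            spike.mix_to_vaf(ref_lib, alt_lib, 1.5, 60, seed=1)

    def test_depth_cap_warns(self, painted):
        ref_lib, alt_lib = painted
        with pytest.warns(UserWarning, match="capped"):
            spike.mix_to_vaf(ref_lib, alt_lib, 0.05, 10_000, seed=1)

    def test_vaf_to_zero_limit_is_pure_ref(self, painted):
        ref_lib, alt_lib = painted
        groups = spike.mix_to_vaf(ref_lib, alt_lib, 1e-12, 60, seed=3)
        assert all(g.origin == "ref" for g in groups)

    def test_group_atomicity(self, painted):
        ref_lib, alt_lib = painted
        groups = spike.mix_to_vaf(ref_lib, alt_lib, 0.3, 60, seed=4)
        for g in groups:
            assert len({m.origin for m in g.members}) == 1

    def test_read_conservation(self, painted):
        ref_lib, alt_lib = painted
        groups = spike.mix_to_vaf(ref_lib, alt_lib, 0.1, 60, seed=5)
        frags = [f for g in groups for f in g.members]
        assert len(frags) == sum(g.size for g in groups)

    def test_empirical_vaf_matches_independent_pileup(self, painted, panel_small,
                                                      ref_small):
        from umispike import evaluate
        ref_lib, alt_lib = painted
        groups = spike.mix_to_vaf(ref_lib, alt_lib, 0.2, 70, seed=6)
        frags = [f for g in groups for f in g.members]
        for var in panel_small[:5]:
            expected, depth = brute_alt_fraction(frags, var)
            got, got_depth = evaluate.alt_fraction_at(frags, ref_small, var)
            assert got == expected and got_depth == depth

    def test_vaf_recovery_within_binomial_concentration(self):
        """Mean VAF over panel loci lands within 3 s.e. of the target.

        The Bernoulli sampling unit is the duplicate group, so the
        concentration bound uses the covering-group count.
        """
        ref = fixtures.make_reference(1, 3, 1500, seed=1)
        tpl = fixtures.make_template(ref, 300.0, 3.0, seed=2)
        panel = fixtures.make_variant_panel(ref, 60, seed=3)
        ref_lib, _ = spike.paint_alleles(tpl, panel, "ref")
        alt_lib, _ = spike.paint_alleles(tpl, panel, "alt")
        p = 0.075
        groups = spike.mix_to_vaf(ref_lib, alt_lib, p, 250, seed=11)
        frags = [f for g in groups for f in g.members]
        fracs, n_groups = [], 0
        for var in panel:
            frac, depth = brute_alt_fraction(frags, var)
            if frac is not None:
                fracs.append(frac)
        covering = {f.group_id for f in frags
                    if any(f.frag_start <= v.pos - 1 < f.frag_end for v in panel)}
        se = np.sqrt(p * (1 - p) / len(covering))
        assert abs(np.mean(fracs) - p) < 3 * se

    def test_exact_mode_pins_global_read_fraction(self, painted):
        ref_lib, alt_lib = painted
        groups = spike.mix_to_vaf(ref_lib, alt_lib, 0.1, 60, seed=7, mode="exact")
        total = sum(g.size for g in groups)
        alt = sum(g.size for g in groups if g.origin == "alt")
        # granularity is one group, so allow the largest group's size
        max_group = max(g.size for g in groups)
        assert abs(alt - round(0.1 * total)) <= max_group

    def test_expected_alt_reads_monotone_in_vaf(self, painted):
        ref_lib, alt_lib = painted
        alt_reads = []
        for vaf in (0.02, 0.05, 0.075, 0.2):
            groups = spike.mix_to_vaf(ref_lib, alt_lib, vaf, 60, seed=8,
                                      mode="exact")
            alt_reads.append(sum(g.size for g in groups if g.origin == "alt"))
        assert alt_reads == sorted(alt_reads)


class TestGenerateDatasets:
    def test_default_plan_counts_80_datasets(self, panel_small):
        plan = SpikePlan(panel=panel_small, seed=1)
        combos = plan.combinations()
        assert len(combos) == 80  # 5 x (6 + 6 + 4)
        at_200 = {vaf for depth, vaf, _ in combos if depth == 200.0}
        assert at_200 == {0.02, 0.04, 0.05, 0.075}

    def test_single_dataset_plan(self, template_small, ref_small, panel_small,
                                 tmp_path):
        plan = SpikePlan(panel=panel_small, vaf_levels=(0.075,),
                         depth_targets=(50.0,), replicates=1, seed=9,
                         min_vaf_by_depth={})
        manifest = spike.generate_datasets(template_small, ref_small, plan, tmp_path)
        assert len(manifest) == 1
        row = manifest.iloc[0]
        truth = formats.read_vcf(row.truth_vcf)
        assert len(truth) == len(panel_small)
        assert all(v.info["TVAF"] == pytest.approx(0.075) for v in truth)
        frags = formats.read_sam_fragments(row.sam)
        assert len(frags) == row.n_read_pairs
        assert len(formats.read_fastq(row.r1)) == row.n_read_pairs

    def test_dataset_seeds_unique_and_recorded(self, template_small, ref_small,
                                               panel_small, tmp_path):
        plan = SpikePlan(panel=panel_small, vaf_levels=(0.05, 0.075),
                         depth_targets=(40.0,), replicates=2, seed=9,
                         min_vaf_by_depth={})
        manifest = spike.generate_datasets(template_small, ref_small, plan,
                                           tmp_path / "grid")
        assert len(manifest) == 4
        assert manifest["seed"].nunique() == 4
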