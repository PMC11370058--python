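"""Filtering module: depth/quality thresholds, dbSNP exclusion, COSMIC flags."""

import pytest
from hypothesis import given, settings, strategies as st

from umispike import filtering
from umispike.model import AnnotationDb, VariantRecord


def toy_records(dps=range(1, 201), qual=99.0):
    return [VariantRecord(contig="chrT", pos=10 + i, ref="A", alt="G",
                          dp=dp, qual=qual)
            for i, dp in enumerate(dps)]


class TestDepthQualityFilter:
    def test_depth_threshold_is_50(self):
        retained = filtering.depth_quality_filter(toy_records(),
                                                  filtering.FilterConfig())
        assert min(r.dp for r in retained) == 50
        assert len(retained) == 151  # DP 50..200

    def test_quality_threshold_is_50(self):
        records = [VariantRecord(contig="chrT", pos=i + 1, ref="A", alt="G",
                                 dp=100, qual=float(q))
                   for i, q in enumerate(range(0, 100, 7))]
        retained = filtering.depth_quality_filter(records,
                                                  filtering.FilterConfig())
        assert min(r.qual for r in retained) >= 50.0
        assert all(q >= 50 or q < 50 for q in (r.qual for r in retained))

    def test_uniformly_missing_qual_disables_quality_stage(self, caplog):
        records = toy_records(qual=None)
        with caplog.at_level("INFO"):
            retained = filtering.depth_quality_filter(records,
                                                      filtering.FilterConfig())
        assert len(retained) == 151  # depth-only
        assert any("disabled" in m for m in caplog.messages)

    def test_partially_missing_qual_fails_those_records(self):
        records = [VariantRecord(contig="chrT", pos=1, ref="A", alt="G",
                                 dp=100, qual=None),
                   VariantRecord(contig="chrT", pos=2, ref="A", alt="G",
                                 dp=100, qual=80.0)]
        retained = filtering.depth_quality_filter(records,
                                                  filtering.FilterConfig())
        assert [r.pos for r in retained] == [2]

    def test_missing_dp_fails_conservatively(self):
        records = [VariantRecord(contig="chrT", pos=1, ref="A", alt="G",
                                 dp=None, qual=99.0)]
        assert filtering.depth_quality_filter(records,
                                              filtering.FilterConfig()) == []

    def test_bypass_for_unparseable_umi_caller_records(self, caplog):
        records = [VariantRecord(contig="chrT", pos=1, ref="A", alt="G")]
        config = filtering.FilterConfig(bypass_unparseable=True)
        with caplog.at_level("INFO"):
            retained = filtering.depth_quality_filter(records, config)
        assert retained == records
        assert any("bypass" in m for m in caplog.messages)

    def test_empty_input(self):
        assert filtering.depth_quality_filter([], filtering.FilterConfig()) == []

    def test_order_preserved(self):
        records = toy_records(dps=[200, 60, 70, 55])
        retained = filtering.depth_quality_filter(records,
                                                  filtering.FilterConfig())
        assert [r.dp for r in retained] == [200, 60, 70, 55]


class TestQualToProbability:
    @pytest.mark.parametrize("qual,prob", [(50.0, 0.99999), (0.0, 0.0), (10.0, 0.9)])
    def test_phred_identity(self, qual, prob):
        assert filtering.qual_to_probability(qual) == pytest.approx(prob, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            filtering.qual_to_probability(-1.0)


def ladder_db():
    """dbSNP toy: AFs 1%..10% in 1% steps at positions 1..10."""
    return AnnotationDb("dbsnp", {
        ("chrT", pos, "A", "G"): (round(0.01 * pos, 2),) for pos in range(1, 11)
    })


class TestDbsnpExclude:
    def test_five_percent_cutoff(self):
        records = [VariantRecord(contig="chrT", pos=p, ref="A", alt="G")
                   for p in range(1, 11)]
        retained = filtering.dbsnp_exclude(records, ladder_db(), cutoff=0.05)
        assert [r.pos for r in retained] == [1, 2, 3, 4]
        assert all(max(r.dbsnp_afs) <= 0.04 for r in retained)

    def test_absent_record_retained(self):
        records = [VariantRecord(contig="chrT", pos=999, ref="C", alt="T")]
        assert filtering.dbsnp_exclude(records, ladder_db()) == records

    def test_multi_population_conjunction(self):
        """An entry at {4%, 6%} is not >=5% in all populations: retained."""
        db = AnnotationDb("dbsnp", {
            ("chrT", 1, "A", "G"): (0.04, 0.06),
            ("chrT", 2, "A", "G"): (0.05, 0.06),
        })
        records = [VariantRecord(contig="chrT", pos=p, ref="A", alt="G")
                   for p in (1, 2)]
        retained = filtering.dbsnp_exclude(records, db, cutoff=0.05)
        assert [r.pos for r in retained] == [1]

    def test_wrong_db_kind_rejected(self):
        with pytest.raises(ValueError):
            filtering.dbsnp_exclude([], AnnotationDb("cosmic", {}))


class TestCosmicAnnotate:
    def make_db(self):
        return AnnotationDb("cosmic", {
            ("chrT", pos, "A", "G"): (pos,) for pos in range(1, 11)
        })

    def test_count_cutoff_three(self):
        records = [VariantRecord(contig="chrT", pos=p, ref="A", alt="G")
                   for p in range(1, 11)]
        filtering.cosmic_annotate(records, self.make_db(), min_samples=3)
        flagged = [r.pos for r in records if r.cosmic]
        assert flagged == [3, 4, 5, 6, 7, 8, 9, 10]
        assert min(r.cosmic_count for r in records if r.cosmic) == 3

    def test_below_cutoff_flagged_false(self):
        records = [VariantRecord(contig="chrT", pos=2, ref="A", alt="G")]
        filtering.cosmic_annotate(records, self.make_db(), min_samples=3)
        assert records[0].cosmic is False and records[0].cosmic_count is None

    def test_annotation_drops_nothing(self):
        records = [VariantRecord(contig="chrT", pos=p, ref="A", alt="G")
                   for p in range(1, 21)]
        out = filtering.cosmic_annotate(records, self.make_db())
        assert len(out) == 20


class TestPipelineProperties:
    @settings(derandomize=True, max_examples=40)
    @given(d1=st.integers(0, 120), d2=st.integers(0, 120),
           q1=st.floats(0, 120), q2=st.floats(0, 120))
    def test_monotone_in_thresholds(self, d1, d2, q1, q2):
        """Raising any threshold never enlarges the retained set."""
        records = toy_records(dps=range(1, 121, 3), qual=None)
        for i, r in enumerate(records):
            r.qual = float((i * 37) % 120)
        lo = filtering.FilterConfig(min_depth=min(d1, d2), min_qual=min(q1, q2))
        hi = filtering.FilterConfig(min_depth=max(d1, d2), min_qual=max(q1, q2))
        keep_lo = {r.key() for r in filtering.depth_quality_filter(records, lo)}
        keep_hi = {r.key() for r in filtering.depth_quality_filter(records, hi)}
        assert keep_hi <= keep_lo

    def test_depth_and_dbsnp_stages_commute(self):
        records = [VariantRecord(contig="chrT", pos=p, ref="A", alt="G",
                                 dp=10 * p, qual=99.0) for p in range(1, 11)]
        db = ladder_db()
        config = filtering.FilterConfig()
        a = filtering.dbsnp_exclude(
            filtering.depth_quality_filter(records, config), db)
        b = filtering.depth_quality_filter(
            filtering.dbsnp_exclude(records, db), config)
        assert [r.key() for r in a] == [r.key() for r in b]

    def test_run_pipeline_stage_counts(self, annotation_dbs):
        dbsnp, cosmic = annotation_dbs
        records = toy_records()
        retained, counts = filtering.run_pipeline(records,
                                                  filtering.FilterConfig(),
                                                  dbsnp, cosmic)
        assert list(counts["stage"]) == ["depth_quality", "dbsnp_exclude",
                                         "cosmic_annotate"]
        assert counts.iloc[0]["in"] == 200
        assert counts.iloc[-1]["retained"] == len(retained)
        for row in counts.to_dict("records"):
            assert row["discarded"] == row["in"] - row["retained"]
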