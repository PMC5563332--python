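"""Read-level classification: junctions, events, alleles, quantification."""

import numpy as np
import pandas as pd
import pytest

from ptcrescue.gene_model import SpliceEvent, mature_sequence, ptc_scan
from ptcrescue.hgvs import parse_chgvs
from ptcrescue.isoform import (
    AlignedRead,
    Segment,
    UndefinedFractionError,
    call_allele,
    classify_read,
    classify_reads,
    detect_events,
    event_frequency,
    junction_chain,
    quantify,
    read_sam,
)
from ptcrescue.simulate import (
    RescueIsoform,
    SimConfig,
    make_toy_locus,
    plant_variant,
    simulate_amplicon_reads,
)


def perfect_read(ref, model, events=(), variant=None, read_id="r1"):
    """Error-free read spanning the whole amplicon for a given isoform."""
    from ptcrescue.simulate import _template_segments

    template = _template_segments(model, ref, events, variant)
    segs = tuple(Segment(s, e, tuple(c), q) for s, e, c, q in template)
    return AlignedRead(read_id, ref.name, segs)


class TestJunctions:
    def test_canonical_read_has_one_junction_per_intron(self, toy):
        ref, model = toy
        read = perfect_read(ref, model)
        chain = junction_chain(read)
        assert len(chain) == model.n_exons - 1
        for (d, a), i in zip(chain, range(model.n_exons - 1)):
            assert (d, a) == model.intron(i)

    def test_unspliced_read_has_empty_chain(self, toy):
        ref, model = toy
        s, e = model.exons[1]
        read = AlignedRead("u", ref.name,
                           (Segment(s, e, (("M", e - s),), ref.sequence[s:e]),))
        assert junction_chain(read) == []

    def test_exon_skip_merges_junctions(self, toy):
        ref, model = toy
        read = perfect_read(ref, model, (SpliceEvent("exon_skip", 3),))
        chain = junction_chain(read)
        assert len(chain) == model.n_exons - 2
        assert (model.exons[2][1], model.exons[4][0]) in chain


class TestDetectEvents:
    def test_canonical_read_yields_no_events(self, toy):
        ref, model = toy
        events, unresolved = detect_events(perfect_read(ref, model), model)
        assert events == [] and not unresolved

    def test_exon_skip_detected(self, toy):
        ref, model = toy
        read = perfect_read(ref, model, (SpliceEvent("exon_skip", 3),))
        events, _ = detect_events(read, model)
        assert [e.key() for e in events] == [("exon_skip", 3, None)]

    def test_cryptic_donor_minus2_needs_tight_tolerance(self, toy):
        ref, model = toy
        read = perfect_read(ref, model, (SpliceEvent("cryptic_donor", 2, -2),))
        # within the default 3-nt wobble tolerance the shift is canonicalized
        events_default, _ = detect_events(read, model, tolerance=3)
        assert events_default == []
        events, _ = detect_events(read, model, tolerance=1)
        assert [e.key() for e in events] == [("cryptic_donor", 2, -2)]

    def test_cryptic_donor_extension_detected_at_default_tolerance(self, toy):
        ref, model = toy
        read = perfect_read(ref, model, (SpliceEvent("cryptic_donor", 2, 5),))
        events, _ = detect_events(read, model)
        assert [e.key() for e in events] == [("cryptic_donor", 2, 5)]

    def test_full_intron_retention_detected(self, toy):
        ref, model = toy
        read = perfect_read(ref, model, (SpliceEvent("intron_retention", 2),))
        events, _ = detect_events(read, model)
        assert [e.key() for e in events] == [("intron_retention", 2, None)]

    def test_unresolvable_junction_flagged(self, toy):
        ref, model = toy
        # junction from mid-exon-1 to mid-intron-3: matches nothing
        e0 = model.exons[0]
        glo = model.exons[3][0] + 40
        ghi = model.exons[3][1]
        read = AlignedRead(
            "x", ref.name,
            (
                Segment(e0[0], e0[1] - 10, (("M", e0[1] - 10 - e0[0]),),
                        ref.sequence[e0[0] : e0[1] - 10]),
                Segment(glo, ghi, (("M", ghi - glo),), ref.sequence[glo:ghi]),
            ),
        )
        _, unresolved = detect_events(read, model)
        assert unresolved


class TestCallAllele:
    def test_error_free_snv(self, toy):
        ref, model = toy
        v = plant_variant(model, ref, "nonsense", 2)
        mut = perfect_read(ref, model, (), v)
        wt = perfect_read(ref, model)
        assert call_allele(mut, v, model, reference=ref) == "MUT"
        assert call_allele(wt, v, model, reference=ref) == "WT"

    def test_exon_skip_removes_variant(self, toy):
        ref, model = toy
        v = plant_variant(model, ref, "frameshift_del", 1, span=7)
        read = perfect_read(ref, model, (SpliceEvent("exon_skip", 1),))
        events, _ = detect_events(read, model)
        assert call_allele(read, v, model, reference=ref, events=events) == "REMOVED"

    def test_splice_variant_abstains(self, toy):
        ref, model = toy
        v = plant_variant(model, ref, "splice_donor", 2)
        read = perfect_read(ref, model)
        assert call_allele(read, v, model, reference=ref) == "UNASSIGNED"

    def test_noisy_seven_nt_deletion_accuracy(self, toy):
        """1000 nanopore-error reads, 7-nt deletion, window 12:
        >= 95% of assigned calls match the generative truth."""
        ref, model = toy
        v = plant_variant(model, ref, "frameshift_del", 2, span=7, offset_in_exon=30)
        sim = simulate_amplicon_reads(
            model, ref, v, (), SimConfig(seed=17, n_reads=1000)
        )
        got = np.array([call_allele(r, v, model, window=12, reference=ref)
                        for r in sim.reads])
        truth = sim.truth["source_allele"].values
        assigned = got != "UNASSIGNED"
        assert assigned.mean() > 0.9
        assert (got[assigned] == truth[assigned]).mean() >= 0.95


class TestClassifyRead:
    def test_mut_nonsense_canonical_splicing_is_ptc(self, toy):
        ref, model = toy
        v = plant_variant(model, ref, "nonsense", 2)
        c = classify_read(perfect_read(ref, model, (), v), model, ref, v)
        assert c.transcript_class == "PTC" and c.allele == "MUT"

    def test_wt_read_is_wt(self, toy):
        ref, model = toy
        v = plant_variant(model, ref, "nonsense", 2)
        c = classify_read(perfect_read(ref, model), model, ref, v)
        assert c.transcript_class == "WT"

    def test_frameshift_plus_inframe_skip_is_rescue(self, toy):
        ref, model = toy
        v = plant_variant(model, ref, "frameshift_dup", 1, span=1)
        read = perfect_read(ref, model, (SpliceEvent("exon_skip", 1),))
        c = classify_read(read, model, ref, v)
        assert c.transcript_class == "RESCUE" and c.allele == "REMOVED"

    def test_splice_acceptor_variant_with_out_of_frame_skip_is_ptc(self, toy_oof):
        ref, model = toy_oof
        v = plant_variant(model, ref, "splice_acceptor", 2)
        read = perfect_read(ref, model, (SpliceEvent("exon_skip", 2),))
        c = classify_read(read, model, ref, v)
        assert c.transcript_class == "PTC"
        assert c.reason == "junction_inferred"

    def test_deleterious_event_on_wt_allele_is_other(self, toy_oof):
        ref, model = toy_oof
        v = plant_variant(model, ref, "nonsense", 1)
        read = perfect_read(ref, model, (SpliceEvent("exon_skip", 2),))  # out of frame
        c = classify_read(read, model, ref, v)
        assert c.allele == "WT" and c.transcript_class == "OTHER"

    def test_zero_error_truth_reproduction_all_variant_kinds(self, toy, toy_oof):
        """At zero simulated error, classification reproduces the generative
        truth for SNV, deletion, duplication, and canonical-splice variants."""
        noerr = dict(p_sub=0.0, p_ins=0.0, p_del=0.0)
        cases = []
        ref, model = toy
        cases.append((ref, model, plant_variant(model, ref, "nonsense", 2), (), ()))
        cases.append((ref, model,
                      plant_variant(model, ref, "frameshift_del", 2, span=7,
                                    offset_in_exon=30),
                      (RescueIsoform("cd", (SpliceEvent("cryptic_donor", 2, -5),), 0.1),),
                      ()))
        cases.append((ref, model,
                      plant_variant(model, ref, "frameshift_dup", 1, span=1),
                      (RescueIsoform("skip", (SpliceEvent("exon_skip", 1),), 0.1),),
                      ()))
        oref, omodel = toy_oof
        cases.append((oref, omodel, plant_variant(omodel, oref, "splice_donor", 2),
                      (), (SpliceEvent("exon_skip", 2),)))
        for ref_, model_, v, rescues, sv_events in cases:
            sim = simulate_amplicon_reads(
                model_, ref_, v, rescues,
                SimConfig(seed=23, n_reads=400, nmd_efficiency=0.3, **noerr),
                splice_variant_events=sv_events,
            )
            calls = classify_reads(sim.reads, model_, ref_, v)
            got = [c.transcript_class for c in calls]
            assert got == sim.truth["expected_class"].tolist(), v.raw


class TestQuantify:
    @staticmethod
    def _fake(n_wt, n_ptc, n_rescue=0, n_other=0):
        from ptcrescue.isoform import ReadClassification

        out = []
        for cls, n in (("WT", n_wt), ("PTC", n_ptc), ("RESCUE", n_rescue),
                       ("OTHER", n_other)):
            allele = {"WT": "WT", "PTC": "MUT", "RESCUE": "MUT",
                      "OTHER": "UNASSIGNED"}[cls]
            out += [ReadClassification(f"{cls}{i}", allele, (), cls)
                    for i in range(n)]
        return out

    def test_fraction_arithmetic(self):
        q = quantify(self._fake(59, 41))
        assert q.ptc_expression_fraction == pytest.approx(0.41)

    def test_complete_degradation_pole(self):
        assert quantify(self._fake(80, 0)).ptc_expression_fraction == 0.0

    def test_no_nmd_pole(self):
        assert quantify(self._fake(50, 50)).ptc_expression_fraction == 0.5

    def test_invariant_under_order_and_duplication(self):
        calls = self._fake(30, 20, 5, 3)
        f1 = quantify(calls).ptc_expression_fraction
        f2 = quantify(calls[::-1]).ptc_expression_fraction
        f3 = quantify(calls + calls).ptc_expression_fraction
        assert f1 == f2 == f3

    def test_undefined_without_wt_or_ptc(self):
        with pytest.raises(UndefinedFractionError):
            quantify(self._fake(0, 0, 5, 5))


class TestEventFrequency:
    def test_thirty_percent_skip(self, toy):
        ref, model = toy
        skip = SpliceEvent("exon_skip", 3)
        reads = [perfect_read(ref, model, (skip,), read_id=f"s{i}") for i in range(30)]
        reads += [perfect_read(ref, model, read_id=f"c{i}") for i in range(70)]
        assert event_frequency(reads, skip, model) == pytest.approx(0.30)

    def test_absent_event_frequency_zero(self, toy):
        ref, model = toy
        reads = [perfect_read(ref, model, read_id=f"c{i}") for i in range(10)]
        assert event_frequency(reads, SpliceEvent("exon_skip", 1), model) == 0.0

    def test_planted_ten_percent_cryptic_donor_recovered(self, toy):
        """n=2000 noisy reads with a 10% frame-restoring isoform: the estimated
        event frequency is within 2 percentage points of the plant."""
        ref, model = toy
        v = plant_variant(model, ref, "frameshift_del", 2, span=7, offset_in_exon=30)
        cd = SpliceEvent("cryptic_donor", 2, -5)
        sim = simulate_amplicon_reads(
            model, ref, v, (RescueIsoform("cd", (cd,), 0.20),),
            SimConfig(seed=31, n_reads=2000),
        )
        est = event_frequency(sim.reads, cd, model)
        planted = 0.20 * 0.5  # isoform usage on the mutant allele only
        assert abs(est - planted) <= 0.02


class TestSamRoundTrip:
    def test_write_and_read_sam_preserves_alignments(self, toy, tmp_path):
        ref, model = toy
        v = plant_variant(model, ref, "nonsense", 2)
        sim = simulate_amplicon_reads(model, ref, v, (),
                                      SimConfig(seed=5, n_reads=40))
        sam = tmp_path / "truth.sam"
        sim.write_sam(str(sam))
        back, stats = read_sam(str(sam), reference_name=ref.name)
        assert stats["total"] == 40 and len(back) == 40
        for orig, rt in zip(sim.reads, back):
            assert rt.blocks == orig.blocks
            assert rt.query_sequence() == orig.query_sequence()
            assert rt.segments == orig.segments

    def test_classification_identical_through_sam(self, toy, tmp_path):
        ref, model = toy
        v = plant_variant(model, ref, "frameshift_del", 2, span=7, offset_in_exon=30)
        sim = simulate_amplicon_reads(model, ref, v, (),
                                      SimConfig(seed=6, n_reads=60))
        sam = tmp_path / "t.sam"
        sim.write_sam(str(sam))
        back, _ = read_sam(str(sam))
        direct = [c.transcript_class for c in classify_reads(sim.reads, model, ref, v)]
        via_sam = [c.transcript_class for c in classify_reads(back, model, ref, v)]
        assert direct == via_sam
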