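"""Cross-sample event harmonization, zygosity linking, ambiguity reporting
and observation-matrix assembly."""

import pytest

from mosaiclone import (
    AlterationClass,
    Call,
    GenomicSegment,
    SampleMeta,
    SegmentRecord,
    Tier,
    ValidationError,
    build_observation_matrix,
    harmonize_events,
)
from mosaiclone.io import write_segments, read_segments
from mosaiclone.types import Host


def _rec(sid, chrom, start, end, cls=AlterationClass.DEL, zyg="het", status=Call.CLONAL):
    return SegmentRecord(sid, GenomicSegment(chrom, start, end), cls, zyg, status)


def _manifest(*sids, unassayed=()):
    out = [SampleMeta(sample_id=sids[0], patient="P", host=Host.PATIENT,
                      assayed=sids[0] not in unassayed)]
    for s in sids[1:]:
        out.append(
            SampleMeta(sample_id=s, patient="P", host=Host.PRIMARY_XENO,
                       parent_sample=sids[0], assayed=s not in unassayed)
        )
    return out


def test_identical_segments_merge_into_one_event_without_ambiguity():
    recs = [_rec(s, "chr9", 100, 900) for s in ("A", "B", "C")]
    harm = harmonize_events(recs, tolerance=0)
    assert len(harm.events) == 1
    assert harm.events[0].tier is Tier.FIRST_HIT
    assert not harm.merge_ambiguities and not harm.link_ambiguities


def test_hom_del_becomes_second_hit_linked_to_het_context():
    recs = [
        _rec("A", "chr9", 10, 100, zyg="het"),
        _rec("B", "chr9", 10, 100, zyg="hom"),
    ]
    harm = harmonize_events(recs, tolerance=0)
    tiers = {e.event_id: e.tier for e in harm.events}
    assert sorted(tiers.values(), key=lambda t: t.value) == [Tier.FIRST_HIT, Tier.SECOND_HIT]
    second = next(e for e in harm.events if e.tier is Tier.SECOND_HIT)
    first = next(e for e in harm.events if e.tier is Tier.FIRST_HIT)
    assert second.parent_event_id == first.event_id
    assert not harm.link_ambiguities  # a single candidate is not ambiguous


def test_second_hit_without_het_context_is_rejected():
    recs = [_rec("A", "chr9", 10, 100, zyg="hom")]
    with pytest.raises(ValidationError, match="heterozygous-deletion context"):
        harmonize_events(recs, tolerance=0)


def test_cnloh_can_be_configured_as_independent_first_hit():
    recs = [_rec("A", "chr9", 10, 100, cls=AlterationClass.CNLOH, zyg="na")]
    harm = harmonize_events(recs, tolerance=0, cnloh_independent=True)
    assert harm.events[0].tier is Tier.FIRST_HIT


def test_nearby_breakpoints_merge_or_become_an_ambiguity():
    recs = [_rec("A", "chr2", 1_000, 9_000), _rec("B", "chr2", 1_500, 9_500)]
    # endpoints 500 bp apart: merged at tolerance 1000
    merged = harmonize_events(recs, tolerance=1000)
    assert len(merged.events) == 1
    # kept separate at tolerance 100, but the wider ambiguity window records
    # the alternative one-event reading
    split = harmonize_events(recs, tolerance=100, ambiguity_tolerance=1000)
    assert len(split.events) == 2
    assert len(split.merge_ambiguities) == 1
    amb = split.merge_ambiguities[0]
    partitions = {tuple(sorted(len(b) for b in choice)) for choice in amb.choices}
    assert partitions == {(1, 1), (2,)}  # separate vs merged


def test_coreported_segments_are_never_offered_for_merging():
    # both variants seen side by side in one sample: provably distinct events
    recs = [
        _rec("A", "chr2", 1_000, 9_000),
        _rec("A", "chr2", 1_500, 9_500, status=Call.SUBCLONAL),
    ]
    harm = harmonize_events(recs, tolerance=100, ambiguity_tolerance=1000)
    assert len(harm.events) == 2
    assert not harm.merge_ambiguities


def test_second_hit_overlapping_several_het_dels_is_a_link_ambiguity():
    recs = [
        _rec("A", "chr9", 1_000, 9_000),
        _rec("B", "chr9", 2_000, 8_000),
        _rec("C", "chr9", 3_000, 7_000, zyg="hom"),
    ]
    harm = harmonize_events(recs, tolerance=0)
    assert len(harm.link_ambiguities) == 1
    assert len(harm.link_ambiguities[0].candidates) == 2


def test_merging_is_transitive_closure_with_documented_drift():
    # A-B and B-C within tolerance, A-C beyond it: single-linkage merges all
    recs = [
        _rec("A", "chr5", 1_000, 5_000),
        _rec("B", "chr5", 1_400, 5_400),
        _rec("C", "chr5", 1_800, 5_800),
    ]
    harm = harmonize_events(recs, tolerance=500)
    assert len(harm.events) == 1
    seg = harm.events[0].segment
    assert (seg.start, seg.end) == (1_000, 5_800)  # consensus span


def test_harmonization_is_idempotent(tmp_path):
    recs = [
        _rec("A", "chr5", 1_000, 5_000),
        _rec("B", "chr5", 1_400, 5_400),
        _rec("B", "chr7", 2_000, 3_000, status=Call.SUBCLONAL),
    ]
    harm1 = harmonize_events(recs, tolerance=500)
    # write the harmonized consensus back out and harmonize again
    consensus = [
        SegmentRecord("X", e.segment, e.alteration_class, "het", Call.CLONAL)
        for e in harm1.events
    ]
    p = tmp_path / "c.tsv"
    write_segments(consensus, p)
    harm2 = harmonize_events(read_segments(p), tolerance=500)
    assert [
        (e.segment.chromosome, e.segment.start, e.segment.end) for e in harm2.events
    ] == [(e.segment.chromosome, e.segment.start, e.segment.end) for e in harm1.events]


def test_matrix_defaults_absent_when_assayed_unknown_when_not():
    recs = [_rec("M2", "chr9", 10, 100)]
    manifest = _manifest("DX", "M1", "M2", "M3", unassayed={"M3"})
    harm = harmonize_events(recs, tolerance=0)
    m = build_observation_matrix(harm, manifest)
    eid = harm.events[0].event_id
    assert m.calls.at["M2", eid] is Call.CLONAL
    assert m.calls.at["M1", eid] is Call.ABSENT  # assayed, nothing reported
    assert m.calls.at["M3", eid] is Call.UNKNOWN  # no SNP-array data


def test_matrix_rejects_conflicting_statuses_naming_both_rows():
    recs = [
        _rec("A", "chr9", 10, 100, status=Call.CLONAL),
        _rec("A", "chr9", 10, 100, status=Call.SUBCLONAL),
    ]
    harm = harmonize_events(recs, tolerance=0)
    with pytest.raises(ValidationError, match="record 1 .*record 2"):
        build_observation_matrix(harm, _manifest("A"))


def test_matrix_rejects_records_from_unknown_samples():
    recs = [_rec("GHOST", "chr9", 10, 100)]
    harm = harmonize_events(recs, tolerance=0)
    with pytest.raises(ValidationError, match="GHOST"):
        build_observation_matrix(harm, _manifest("DX"))


def test_reported_second_hit_implies_first_hit_presence():
    # a sample reported as entirely homozygously deleted: the het first hit
    # is promoted to CLONAL rather than defaulting to ABSENT
    recs = [
        _rec("A", "chr9", 10, 100, zyg="het"),
        _rec("B", "chr9", 10, 100, zyg="hom"),
        _rec("C", "chr9", 10, 100, zyg="hom", status=Call.SUBCLONAL),
    ]
    harm = harmonize_events(recs, tolerance=0)
    m = build_observation_matrix(harm, _manifest("A", "B", "C"))
    first = next(e.event_id for e in harm.events if e.tier is Tier.FIRST_HIT)
    assert m.calls.at["B", first] is Call.CLONAL
    assert m.calls.at["C", first] is Call.UNKNOWN  # carriers exist; extent unknown
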