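"""Exact minimal clone-set search: oracles, bounds, resolutions, invariants."""

import numpy as np
import pytest

from mosaiclone import (
    AlterationClass,
    Call,
    CNAEvent,
    GenomicSegment,
    InfeasibleError,
    ObservationMatrix,
    Options,
    SampleMeta,
    SegmentRecord,
    build_observation_matrix,
    check_phylogeny,
    enumerate_resolutions,
    exhaustive_minimal,
    explain_sample,
    harmonize_events,
    lower_bound,
    minimal_clone_range,
    minimal_clone_set,
)
from mosaiclone.datasets import random_clone_matrix
from mosaiclone.types import Host


def _matrix(rows, n_events=None):
    """Build a matrix from {sample: {event: Call}} with DEL events."""
    eids = sorted({e for r in rows.values() for e in r}) if n_events is None else [
        f"e{i}" for i in range(n_events)
    ]
    events = [
        CNAEvent(e, GenomicSegment(f"chr{i + 1}", 10, 100), AlterationClass.DEL)
        for i, e in enumerate(eids)
    ]
    sids = list(rows)
    samples = [SampleMeta(sample_id=sids[0], patient="P", host=Host.PATIENT)] + [
        SampleMeta(sample_id=s, patient="P", host=Host.PRIMARY_XENO, parent_sample=sids[0])
        for s in sids[1:]
    ]
    return ObservationMatrix.from_rows(samples, events, rows)


def test_all_clonal_matrix_needs_exactly_one_clone(monoclonal_matrix):
    res = minimal_clone_set(monoclonal_matrix)
    assert res.minimum == 1
    (sol,) = res.solutions
    assert sol.clones[0].events == set(monoclonal_matrix.event_ids)


def test_three_sample_toy_needs_two_nested_clones(toy_matrix):
    res = minimal_clone_set(toy_matrix)
    assert res.minimum == 2
    genotypes = {tuple(sorted(g.events)) for g in res.solutions[0].clones}
    assert genotypes == {("e1",), ("e1", "e2")}
    assert res.minimum == exhaustive_minimal(toy_matrix).minimum


def test_reappearing_event_forces_two_clones(reappearing_matrix):
    assert minimal_clone_set(reappearing_matrix).minimum >= 2


def test_unknown_only_matrix_gets_trivial_single_clone():
    rows = {"S1": {"e0": Call.UNKNOWN}, "S2": {"e0": Call.UNKNOWN}}
    res = minimal_clone_set(_matrix(rows))
    assert res.minimum == 1
    # outputs stay total: every sample receives a non-empty assignment
    assert all(res.solutions[0].assignment.values())


def test_lower_bound_cases(toy_matrix, monoclonal_matrix):
    assert lower_bound(monoclonal_matrix) == 1
    assert lower_bound(_matrix({"S1": {"e0": Call.SUBCLONAL}})) == 2
    # toy: the bound is tight
    assert lower_bound(toy_matrix) == 2 == minimal_clone_set(toy_matrix).minimum


def test_lower_bound_counts_pairwise_incompatible_signatures():
    rows = {
        "S1": {"e0": Call.CLONAL, "e1": Call.ABSENT, "e2": Call.ABSENT},
        "S2": {"e0": Call.ABSENT, "e1": Call.CLONAL, "e2": Call.ABSENT},
        "S3": {"e0": Call.ABSENT, "e1": Call.ABSENT, "e2": Call.CLONAL},
    }
    m = _matrix(rows)
    assert lower_bound(m) == 3 == minimal_clone_set(m).minimum


def test_lower_bound_is_admissible_on_random_instances():
    rng = np.random.default_rng(11)
    for _ in range(40):
        m = random_clone_matrix(rng)
        assert lower_bound(m) <= minimal_clone_set(m).minimum


def test_branch_and_bound_matches_exhaustive_on_small_random_instances():
    rng = np.random.default_rng(5)
    for _ in range(40):
        m = random_clone_matrix(rng, max_events=5, max_samples=4)
        assert minimal_clone_set(m).minimum == exhaustive_minimal(m).minimum


def test_solutions_repass_explanation_and_phylogeny(patient2_like):
    """Soundness: every returned representative re-passes explain_sample on
    every assayed sample (under its own resolution) and check_phylogeny on
    its clone set."""
    harm, manifest, matrix = patient2_like
    rng = minimal_clone_range(matrix, harmonization=harm)
    checked = 0
    for t in rng.table:
        if t.minimum is None:
            continue
        sol = t.representative
        check_phylogeny([g.events for g in sol.clones])
        resolved = build_observation_matrix(harm, manifest, t.resolution)
        for s in resolved.assayed_samples():
            assert explain_sample(resolved.row(s.sample_id), sol.assignment[s.sample_id]).ok
        checked += 1
    assert checked > 0


def test_cominimal_solutions_are_deduplicated_and_deterministic(toy_matrix):
    a = minimal_clone_set(toy_matrix)
    b = minimal_clone_set(toy_matrix)
    key = lambda r: [
        tuple(sorted(tuple(sorted(g.events)) for g in s.clones)) for s in r.solutions
    ]
    assert key(a) == key(b)
    assert len(set(key(a))) == len(a.solutions)


def test_adding_a_sample_never_decreases_the_minimum():
    rng = np.random.default_rng(7)
    for _ in range(20):
        m = random_clone_matrix(rng, max_events=5, max_samples=4)
        base = minimal_clone_set(m).minimum
        dropped = ObservationMatrix(
            samples=m.samples[:-1],
            events=m.events,
            calls=m.calls.iloc[:-1].copy(),
        )
        assert minimal_clone_set(dropped).minimum <= base


def test_relaxing_clonal_to_unknown_never_increases_the_minimum():
    rng = np.random.default_rng(9)
    for _ in range(20):
        m = random_clone_matrix(rng, max_events=5, max_samples=4)
        base = minimal_clone_set(m).minimum
        calls = m.calls.copy()
        relaxed_any = False
        for sid in m.sample_ids:
            for eid in m.event_ids:
                if calls.at[sid, eid] is Call.CLONAL and not relaxed_any:
                    calls.at[sid, eid] = Call.UNKNOWN
                    relaxed_any = True
        m2 = ObservationMatrix(samples=m.samples, events=m.events, calls=calls)
        assert minimal_clone_set(m2).minimum <= base


def test_strict_lineage_reports_binding_constraints():
    """A CNA absent in an assayed mouse but clonal in its secondary is
    impossible under strictly nested detected-assignments; the binding
    constraint names the sample."""
    rows = {
        "DX": {"e0": Call.SUBCLONAL},
        "M1": {"e0": Call.ABSENT},
        "M1S1": {"e0": Call.CLONAL},
    }
    m = _matrix(rows)
    # re-wire M1S1 under M1 to make a three-deep chain
    samples = list(m.samples)
    samples[2] = SampleMeta(
        sample_id="M1S1", patient="P", host=Host.PRIMARY_XENO, parent_sample="M1"
    )
    m = ObservationMatrix(samples=samples, events=m.events, calls=m.calls)
    with pytest.raises(InfeasibleError, match="M1S1"):
        minimal_clone_set(m, options=Options(strict_lineage=True))
    # the same data is fine under the shared-clone-set default
    assert minimal_clone_set(m).minimum == 2


def test_clone_cap_is_enforced(toy_matrix):
    with pytest.raises(InfeasibleError, match="size <= 1"):
        minimal_clone_set(toy_matrix, options=Options(clone_cap=1))


# -- resolutions --------------------------------------------------------------


def _ambiguous_harmonization():
    recs = [
        SegmentRecord("S1", GenomicSegment("chr1", 1_000, 9_000),
                      AlterationClass.DEL, "het", Call.CLONAL),
        SegmentRecord("S2", GenomicSegment("chr1", 1_500, 9_500),
                      AlterationClass.DEL, "het", Call.CLONAL),
    ]
    return recs, harmonize_events(recs, tolerance=100, ambiguity_tolerance=1000)


def test_enumerate_resolutions_counts_and_order():
    _, harm = _ambiguous_harmonization()
    res = enumerate_resolutions(harm)
    assert len(res) == 2  # one binary merge ambiguity
    assert res == enumerate_resolutions(harm)  # stable order
    # no ambiguities -> exactly one resolution
    plain = harmonize_events(
        [SegmentRecord("S1", GenomicSegment("chr1", 10, 100),
                       AlterationClass.DEL, "het", Call.CLONAL)],
        tolerance=0,
    )
    assert len(enumerate_resolutions(plain)) == 1


def test_resolution_cap_fails_loudly():
    _, harm = _ambiguous_harmonization()
    from mosaiclone import CapExceededError

    with pytest.raises(CapExceededError, match="cap 1"):
        enumerate_resolutions(harm, cap=1)


def test_merge_ambiguity_widens_the_minimal_clone_range():
    """Two near-identical deletions seen in different samples: read as one
    event the cohort is monoclonal, read as two it needs two clones."""
    recs, harm = _ambiguous_harmonization()
    manifest = [
        SampleMeta(sample_id="S1", patient="P", host=Host.PATIENT),
        SampleMeta(sample_id="S2", patient="P", host=Host.PRIMARY_XENO, parent_sample="S1"),
    ]
    matrix = build_observation_matrix(harm, manifest)
    rng = minimal_clone_range(matrix, harmonization=harm)
    assert (rng.minimum, rng.maximum) == (1, 2)


def test_range_collapses_without_ambiguities(monoclonal_matrix):
    rng = minimal_clone_range(monoclonal_matrix)
    assert rng.minimum == rng.maximum == 1
    assert len(rng.table) == 1


def test_contradicted_resolutions_are_recorded_not_fatal(patient2_like):
    harm, _, matrix = patient2_like
    rng = minimal_clone_range(matrix, harmonization=harm)
    assert any(t.minimum is None for t in rng.table)  # some readings impossible
    assert rng.minimum <= rng.maximum
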