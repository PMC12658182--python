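"""Synthetic-cohort generator: determinism, bottleneck behaviour, censoring."""

import numpy as np
import pytest

from mosaiclone import (
    Call,
    SimulationConfig,
    Tier,
    ValidationError,
    build_observation_matrix,
    generate_case,
    harmonize_events,
    minimal_clone_set,
    observe,
    read_manifest,
    read_segments,
    simulate_case,
    simulate_cohort,
    simulate_tree,
    truth_identifiable,
)


def test_config_validation():
    with pytest.raises(ValidationError):
        SimulationConfig(detect_absent=0.9, detect_clonal=0.5)
    with pytest.raises(ValidationError):
        SimulationConfig(n_clones=0)
    with pytest.raises(ValidationError):
        SimulationConfig(n_clones=10, n_loci=3)


def test_single_clone_config_gives_eventless_root():
    tree, genotypes, events = simulate_tree(SimulationConfig(n_clones=1, seed=1))
    assert len(genotypes) == 1 and not genotypes[0].events and not events


def test_same_seed_gives_identical_trees_and_files(tmp_path):
    cfg = SimulationConfig(n_clones=5, seed=42)
    t1 = simulate_tree(cfg)
    t2 = simulate_tree(cfg)
    assert [sorted(g.events) for g in t1[1]] == [sorted(g.events) for g in t2[1]]
    a = generate_case(cfg, tmp_path / "a")
    b = generate_case(cfg, tmp_path / "b")
    for x, y in [
        (a.segments_path, b.segments_path),
        (a.manifest_path, b.manifest_path),
        (a.truth_path, b.truth_path),
    ]:
        assert x.read_text() == y.read_text()


def test_no_second_hits_when_probability_is_zero():
    branches = 0
    for seed in range(200):
        cfg = SimulationConfig(n_clones=8, n_loci=8, p_second_hit=0.0, seed=seed)
        _, _, events = simulate_tree(cfg)
        branches += 7
        assert not any(e.tier is Tier.SECOND_HIT for e in events)
    assert branches >= 1000


def test_second_hits_appear_and_respect_their_parents():
    found = 0
    for seed in range(50):
        cfg = SimulationConfig(n_clones=8, n_loci=8, p_second_hit=0.8, seed=seed)
        _, genotypes, events = simulate_tree(cfg)
        for e in events:
            if e.tier is Tier.SECOND_HIT:
                found += 1
                for g in genotypes:
                    if g.carries(e.event_id):
                        assert g.carries(e.parent_event_id)
    assert found > 0


def test_bottleneck_of_one_cell_gives_monoclonal_mice():
    cfg = SimulationConfig(n_clones=4, bottleneck_cells=1, seed=3)
    freqs, manifest = simulate_cohort(cfg, 4)
    for s in manifest:
        if s.host.value != "PATIENT":
            assert np.count_nonzero(freqs[s.sample_id]) == 1


def test_large_bottleneck_approaches_inoculum_frequencies():
    cfg = SimulationConfig(n_clones=4, bottleneck_cells=10_000_000, n_primary=2,
                           n_secondary=1, seed=5)
    freqs, manifest = simulate_cohort(cfg, 4)
    for s in manifest:
        if s.parent_sample is not None:
            drift = np.abs(freqs[s.sample_id] - freqs[s.parent_sample]).max()
            assert drift < 0.01


def test_clone_absent_in_primary_is_absent_in_its_secondaries():
    for seed in range(10):
        cfg = SimulationConfig(n_clones=5, bottleneck_cells=3, n_primary=3,
                               n_secondary=2, seed=seed)
        freqs, manifest = simulate_cohort(cfg, 5)
        for s in manifest:
            if s.parent_sample is not None:
                support = freqs[s.sample_id] > 0
                parent_support = freqs[s.parent_sample] > 0
                assert not np.any(support & ~parent_support)


def test_observe_boundary_semantics():
    cfg = SimulationConfig(n_clones=2, seed=0, detect_absent=0.05, detect_clonal=0.95)
    _, genotypes, events = simulate_tree(cfg)
    manifest = [s for s in simulate_cohort(cfg, 2)[1] if s.sample_id == "DX"]
    for f, expected in [(0.0, Call.ABSENT), (0.5, Call.SUBCLONAL), (1.0, Call.CLONAL)]:
        m = observe({"DX": np.array([1 - f, f])}, genotypes, events, manifest, cfg)
        eid = events[0].event_id
        assert m.calls.at["DX", eid] is expected


def test_lowering_clonal_threshold_never_demotes_clonal_calls():
    cfg = SimulationConfig(n_clones=4, bottleneck_cells=100, seed=8)
    matrix, truth = simulate_case(cfg)
    relaxed_cfg = SimulationConfig(**{**cfg.__dict__, "detect_clonal": 0.80})
    relaxed = observe(truth.frequencies, truth.genotypes, truth.events,
                      truth.manifest, relaxed_cfg)
    for sid in matrix.sample_ids:
        for eid in matrix.event_ids:
            if matrix.calls.at[sid, eid] is Call.CLONAL:
                assert relaxed.calls.at[sid, eid] is Call.CLONAL


def test_generated_files_parse_back_into_the_same_matrix(tmp_path):
    cfg = SimulationConfig(n_clones=4, seed=42)
    case = generate_case(cfg, tmp_path)
    recs = read_segments(case.segments_path)
    manifest = read_manifest(case.manifest_path)
    harm = harmonize_events(recs, tolerance=0)
    m = build_observation_matrix(harm, manifest)
    # same samples; events match by coordinates; calls match cell-for-cell
    assert m.sample_ids == case.matrix.sample_ids
    by_coord = {
        (e.segment.chromosome, e.segment.start, e.segment.end, e.alteration_class): e.event_id
        for e in m.events
    }
    for e in case.matrix.events:
        key = (e.segment.chromosome, e.segment.start, e.segment.end, e.alteration_class)
        assert key in by_coord
        for sid in m.sample_ids:
            assert m.calls.at[sid, by_coord[key]] is case.matrix.calls.at[sid, e.event_id]


def test_hiding_a_clone_below_threshold_understates_the_count():
    """Detection censoring biases the clone count downward: a clone kept
    below the absence threshold in every sample cannot be demanded by any
    call, so the inferred minimum undershoots the true count."""
    cfg = SimulationConfig(n_clones=3, n_loci=4, p_second_hit=0.0, seed=2,
                           detect_absent=0.1, detect_clonal=0.9)
    _, genotypes, events = simulate_tree(cfg)
    manifest = [s for s in simulate_cohort(cfg, 3)[1]]
    # clone 2 (a leaf) pinned at 5% everywhere: below theta_a
    hidden = np.array([0.475, 0.475, 0.05])
    freqs = {s.sample_id: hidden for s in manifest}
    m = observe(freqs, genotypes, events, manifest, cfg)
    assert minimal_clone_set(m).minimum <= 2 < 3


def test_identifiable_truth_is_recovered_exactly():
    recovered = 0
    for seed in range(120):
        cfg = SimulationConfig(n_clones=4, n_primary=8, n_secondary=1,
                               bottleneck_cells=1, seed=seed)
        matrix, truth = simulate_case(cfg)
        if not truth_identifiable(truth):
            continue
        assert minimal_clone_set(matrix).minimum == truth.n_clones
        recovered += 1
    assert recovered >= 5  # the filter leaves enough informative cases
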