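"""Small built-in cohorts, constructed programmatically.

All cohorts here are *synthetic*: they are hand-written to reproduce
qualitative clonal-architecture motifs seen in serially transplanted
childhood-ALL cohorts (stable monoclonal engraftment; disappearing and
re-appearing CNAs; breakpoint-nested chromosome 9 deletions progressing to
homozygous loss or cnLOH; a remission clone carrying only the earliest
deletion).  They are narrative reconstructions, not measured data, and are
used in examples, tests and the acceptance script.
"""

from __future__ import annotations

from .harmonize import Harmonization, build_observation_matrix, harmonize_events
from .io import SegmentRecord
from .types import (
    AlterationClass,
    Call,
    CNAEvent,
    Compartment,
    GenomicSegment,
    Host,
    ObservationMatrix,
    SampleMeta,
    Timepoint,
)

__all__ = [
    "monoclonal_cohort",
    "mosaic_toy_matrix",
    "reappearing_cna_matrix",
    "patient2_like_cohort",
    "remission_relapse_clones",
]


def _sample(sid: str, patient: str, host: Host, parent: str | None = None,
            timepoint: Timepoint = Timepoint.DIAGNOSIS,
            compartment: Compartment = Compartment.BULK,
            assayed: bool = True) -> SampleMeta:
    return SampleMeta(
        sample_id=sid, patient=patient, timepoint=timepoint,
        compartment=compartment, host=host, parent_sample=parent,
        assayed=assayed,
    )


def monoclonal_cohort() -> ObservationMatrix:
    """Synthetic stable single-clone cohort: deletions on chromosomes 1 and
    12 plus one amplification on chromosome 17, clonal in the diagnostic
    sample and in every primary and secondary transplant."""
    events = [
        CNAEvent("del_chr1", GenomicSegment("chr1", 40_000_000, 47_000_000), AlterationClass.DEL),
        CNAEvent("del_chr12", GenomicSegment("chr12", 11_000_000, 13_500_000), AlterationClass.DEL),
        CNAEvent("amp_chr17", GenomicSegment("chr17", 60_000_000, 64_000_000), AlterationClass.AMP),
    ]
    samples = [
        _sample("DX", "P1", Host.PATIENT),
        _sample("M1", "P1", Host.PRIMARY_XENO, "DX"),
        _sample("M2", "P1", Host.PRIMARY_XENO, "DX"),
        _sample("M1S1", "P1", Host.SECONDARY_XENO, "M1"),
        _sample("M2S1", "P1", Host.SECONDARY_XENO, "M2"),
    ]
    rows = {
        s.sample_id: {e.event_id: Call.CLONAL for e in events} for s in samples
    }
    return ObservationMatrix.from_rows(samples, events, rows)


def mosaic_toy_matrix() -> ObservationMatrix:
    """Three-sample toy whose minimal explanation needs two clones:
    {e1} and {e1, e2}."""
    events = [
        CNAEvent("e1", GenomicSegment("chr9", 10, 100), AlterationClass.DEL),
        CNAEvent("e2", GenomicSegment("chr14", 10, 100), AlterationClass.DEL),
    ]
    samples = [
        _sample("S1", "P", Host.PATIENT),
        _sample("S2", "P", Host.PRIMARY_XENO, "S1"),
        _sample("S3", "P", Host.PRIMARY_XENO, "S1"),
    ]
    rows = {
        "S1": {"e1": Call.CLONAL, "e2": Call.ABSENT},
        "S2": {"e1": Call.CLONAL, "e2": Call.CLONAL},
        "S3": {"e1": Call.CLONAL, "e2": Call.SUBCLONAL},
    }
    return ObservationMatrix.from_rows(samples, events, rows)


def reappearing_cna_matrix() -> ObservationMatrix:
    """An event clonal in one assayed mouse and absent in a sibling mouse —
    the disappearing/re-appearing CNA motif that forces >= 2 diagnostic
    clones."""
    events = [
        CNAEvent("del_chr9", GenomicSegment("chr9", 20_000_000, 22_000_000), AlterationClass.DEL),
    ]
    samples = [
        _sample("DX", "P", Host.PATIENT),
        _sample("M1", "P", Host.PRIMARY_XENO, "DX"),
        _sample("M2", "P", Host.PRIMARY_XENO, "DX"),
    ]
    rows = {
        "DX": {"del_chr9": Call.SUBCLONAL},
        "M1": {"del_chr9": Call.CLONAL},
        "M2": {"del_chr9": Call.ABSENT},
    }
    return ObservationMatrix.from_rows(samples, events, rows)


def patient2_like_cohort() -> tuple[Harmonization, list[SampleMeta], ObservationMatrix]:
    """Synthetic stand-in for a complex serially transplanted cohort.

    Hand-written narrative reconstruction (not measured data): a clonal
    chromosome 14 deletion, an X amplification drifting across recipients,
    and a chromosome 9 locus hit by three breakpoint-nested heterozygous
    deletions with progression to homozygous loss and cnLOH in different
    animals.  The nested breakpoints make the second-hit parentage ambiguous
    (the hom-del and the cnLOH each overlap all three het deletions), so the
    minimal diagnostic clone count is a range over resolutions.

    Returns the harmonization (with its ambiguity report), the manifest and
    the base observation matrix.
    """
    P = "P2"
    C = Call
    D, A, X = AlterationClass.DEL, AlterationClass.AMP, AlterationClass.CNLOH

    def seg(chrom, s, e):
        return GenomicSegment(chrom, s, e)

    # breakpoint-specific segments
    del9a = seg("chr9", 20_000_000, 22_000_000)   # large het del
    del9b = seg("chr9", 20_500_000, 21_500_000)   # nested het del
    del9c = seg("chr9", 20_800_000, 21_200_000)   # innermost het del
    hom9 = seg("chr9", 20_900_000, 21_100_000)    # homozygous loss
    loh9 = seg("chr9", 20_600_000, 21_400_000)    # copy-neutral LOH
    del14 = seg("chr14", 50_000_000, 60_000_000)
    ampx = seg("chrX", 10_000_000, 30_000_000)

    # underlying truth tree (used only to write consistent calls):
    #   root - del14 - +ampx - +del9b - +loh9(del9b)
    #                |        \ +del9c
    #                \ +del9a - +hom9(del9a)
    segments = {
        "del14": (del14, D, "het"),
        "ampx": (ampx, A, "na"),
        "del9a": (del9a, D, "het"),
        "del9b": (del9b, D, "het"),
        "del9c": (del9c, D, "het"),
        "hom9": (hom9, D, "hom"),
        "loh9": (loh9, X, "na"),
    }
    clones = {
        "c1": {"del14"},
        "c2": {"del14", "ampx"},
        "c3": {"del14", "ampx", "del9b"},
        "c4": {"del14", "ampx", "del9b", "loh9"},
        "c5": {"del14", "ampx", "del9c"},
        "c6": {"del14", "del9a"},
        "c7": {"del14", "del9a", "hom9"},
    }
    # detected clone mix per sample; nested chr9 deletions surface only in
    # the mice, and the chr9 deletion disappears in M4 then re-appears in
    # its secondary M4S1
    composition = {
        "DX": ["c1", "c2", "c6"],
        "M1": ["c6"],
        "M1S1": ["c6", "c7"],
        "M1S2": ["c3"],
        "M2": ["c2", "c3", "c5"],
        "M2S1": ["c4"],
        "M3": ["c2", "c6"],
        "M3S1": ["c7"],
        "M4": ["c2"],
        "M4S1": ["c6"],
        "M4S2": ["c2", "c4"],
    }
    # breakpoint wobble: M3's large chr9 deletion is the same lesion but its
    # array breakpoints land 100 kb off, so whether it is del9a or a distinct
    # deletion is a genuine merge ambiguity
    del9a_wobble = seg("chr9", 20_100_000, 21_900_000)
    records = []
    for sid, mix in composition.items():
        genos = [clones[c] for c in mix]
        for name, (segment, cls, zyg) in segments.items():
            n = sum(1 for g in genos if name in g)
            if n == 0:
                continue  # detected-only reporting; unreported means absent
            status = C.CLONAL if n == len(genos) else C.SUBCLONAL
            if sid == "M3" and name == "del9a":
                segment = del9a_wobble
            records.append(SegmentRecord(sid, segment, cls, zyg, status))
    manifest = [
        _sample("DX", P, Host.PATIENT),
        _sample("M1", P, Host.PRIMARY_XENO, "DX"),
        _sample("M2", P, Host.PRIMARY_XENO, "DX"),
        _sample("M3", P, Host.PRIMARY_XENO, "DX"),
        _sample("M4", P, Host.PRIMARY_XENO, "DX"),
        _sample("M1S1", P, Host.SECONDARY_XENO, "M1"),
        _sample("M1S2", P, Host.SECONDARY_XENO, "M1"),
        _sample("M2S1", P, Host.SECONDARY_XENO, "M2"),
        _sample("M3S1", P, Host.SECONDARY_XENO, "M3"),
        _sample("M4S1", P, Host.SECONDARY_XENO, "M4"),
        _sample("M4S2", P, Host.SECONDARY_XENO, "M4"),
    ]
    # exact-match merging, with a sub-megabase ambiguity window mirroring the
    # limited breakpoint resolution of SNP arrays: nearby het deletions never
    # co-reported in one sample may alternatively be one event
    harm = harmonize_events(records, tolerance=0, ambiguity_tolerance=500_000)
    matrix = build_observation_matrix(harm, manifest)
    return harm, manifest, matrix


def random_clone_matrix(
    rng,
    max_events: int = 6,
    max_samples: int = 5,
    unknown_rate: float = 0.1,
) -> ObservationMatrix:
    """Random observation matrix that is explainable by construction.

    Draws a random laminar clone family (random event tree, clones = root
    paths of random nodes), assigns each sample a random non-empty clone
    subset, derives the CLONAL/SUBCLONAL/ABSENT calls from the assignment
    and blanks cells to UNKNOWN at ``unknown_rate``.  Used for cross-checking
    the branch-and-bound search against exhaustive enumeration on instances
    where a perfect phylogeny exists.
    """
    m = int(rng.integers(2, max_events + 1))
    n = int(rng.integers(2, max_samples + 1))
    # random event forest: parent[j] < j or root (-1)
    parent = [int(rng.integers(-1, j)) for j in range(m)]
    paths = []
    for j in range(m):
        path, cur = set(), j
        while cur != -1:
            path.add(cur)
            cur = parent[cur]
        paths.append(frozenset(path))
    k = int(rng.integers(1, m + 2))
    clone_pool = [frozenset()] + paths
    clones = {clone_pool[int(rng.integers(0, len(clone_pool)))] for _ in range(k)}

    events = [
        CNAEvent(f"e{j}", GenomicSegment(f"chr{j + 1}", 1_000, 2_000), AlterationClass.DEL)
        for j in range(m)
    ]
    samples = [_sample("DX", "P", Host.PATIENT)] + [
        _sample(f"M{i}", "P", Host.PRIMARY_XENO, "DX") for i in range(1, n)
    ]
    clone_list = sorted(clones, key=sorted)
    rows = {}
    for s in samples:
        assigned = [g for g in clone_list if rng.random() < 0.6]
        if not assigned:
            assigned = [clone_list[int(rng.integers(0, len(clone_list)))]]
        row = {}
        for j, e in enumerate(events):
            carriers = sum(1 for g in assigned if j in g)
            if rng.random() < unknown_rate:
                row[e.event_id] = Call.UNKNOWN
            elif carriers == 0:
                row[e.event_id] = Call.ABSENT
            elif carriers == len(assigned):
                row[e.event_id] = Call.CLONAL
            else:
                row[e.event_id] = Call.SUBCLONAL
        rows[s.sample_id] = row
    return ObservationMatrix.from_rows(samples, events, rows)


def remission_relapse_clones() -> dict[str, list[frozenset[str]]]:
    """Clone sets across diagnosis / remission / relapse for ancestry
    tracing: the remission clone carries only the chr14 deletion, while
    diagnostic and relapse clones carry chr14+chr12 deletions plus private
    events — so del14 precedes del12 and the diagnosis/relapse branches hang
    off a shared ancestor that matches no dominant diagnostic clone."""
    return {
        "diagnosis": [frozenset({"del_chr14", "del_chr12", "amp_chrX"})],
        "remission": [frozenset({"del_chr14"})],
        "relapse": [frozenset({"del_chr14", "del_chr12", "del_chr7"})],
    }
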