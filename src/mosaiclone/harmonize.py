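"""Harmonize per-sample CNA segment calls into a cross-sample event catalog.

Segments observed in different samples are sightings of the *same* event when
they share chromosome and alteration class and their breakpoints agree within
a tolerance.  SNP arrays have limited breakpoint resolution, so whether two
nearby deletions are one event or two breakpoint-distinct events can be
genuinely undecidable; such cases are recorded in an ambiguity report and
every consistent reading (a :class:`Resolution`) is enumerated downstream.
The min-max range of minimal clone counts over resolutions is the package's
headline output.

Zygosity chains: a homozygous deletion or a cnLOH record is a SECOND_HIT
completing an overlapping heterozygous FIRST_HIT deletion.  A second hit
overlapping several candidate het deletions is a link ambiguity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io import SegmentRecord
from .types import (
    AlterationClass,
    Call,
    CNAEvent,
    GenomicSegment,
    ObservationMatrix,
    SampleMeta,
    Tier,
    ValidationError,
)

__all__ = [
    "MergeAmbiguity",
    "LinkAmbiguity",
    "Resolution",
    "Harmonization",
    "harmonize_events",
    "build_observation_matrix",
]

_MAX_PARTITION_CHOICES = 64


@dataclass(frozen=True)
class MergeAmbiguity:
    """A group of events that may alternatively be merged.

    ``choices`` lists every admissible partition of the member events into
    blocks (each block becomes one event); a block is admissible only if all
    its members are pairwise within the ambiguity tolerance and no sample
    reports two of them separately.
    """

    event_ids: tuple[str, ...]
    choices: tuple[tuple[tuple[str, ...], ...], ...]


@dataclass(frozen=True)
class LinkAmbiguity:
    """A SECOND_HIT event with several candidate FIRST_HIT parents."""

    second_hit_id: str
    candidates: tuple[str, ...]


@dataclass(frozen=True)
class Resolution:
    """One consistent reading of the ambiguity report.

    ``merge_choices[i]`` is the chosen partition for the i-th merge
    ambiguity; ``link_choices`` maps each ambiguous SECOND_HIT event to its
    chosen parent.
    """

    merge_choices: tuple[tuple[tuple[str, ...], ...], ...] = ()
    link_choices: tuple[tuple[str, str], ...] = ()

    def chosen_parent(self, second_hit_id: str) -> Optional[str]:
        for sid, parent in self.link_choices:
            if sid == second_hit_id:
                return parent
        return None


def _record_kind(rec: SegmentRecord, cnloh_independent: bool) -> tuple[str, Tier]:
    """Map a record to its clustering group tag and zygosity tier."""
    if rec.alteration_class is AlterationClass.AMP:
        return "amp", Tier.FIRST_HIT
    if rec.alteration_class is AlterationClass.CNLOH:
        if cnloh_independent:
            return "cnloh", Tier.FIRST_HIT
        return "cnloh", Tier.SECOND_HIT
    # deletions: zygosity decides the tier
    if rec.zygosity == "hom":
        return "homdel", Tier.SECOND_HIT
    return "del", Tier.FIRST_HIT


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _within(a: GenomicSegment, b: GenomicSegment, tol: int) -> bool:
    return abs(a.start - b.start) <= tol and abs(a.end - b.end) <= tol


def _partitions(items: Sequence[str], block_ok) -> list[tuple[tuple[str, ...], ...]]:
    """All set partitions of ``items`` whose blocks satisfy ``block_ok``."""
    items = list(items)
    if not items:
        return [()]
    first, rest = items[0], items[1:]
    out = []
    for sub in _partitions(rest, block_ok):
        # put `first` in its own block
        out.append(tuple(sorted(((first,),) + sub)))
        # or join each existing block
        for k, block in enumerate(sub):
            merged = tuple(sorted(block + (first,)))
            if block_ok(merged):
                out.append(tuple(sorted(sub[:k] + (merged,) + sub[k + 1 :])))
    # dedupe + deterministic order
    return sorted(set(out))


@dataclass
class Harmonization:
    """Event catalog plus the ambiguity report produced by harmonize_events."""

    records: list[SegmentRecord]
    events: list[CNAEvent] = field(default_factory=list)
    record_event: list[str] = field(default_factory=list)  # parallel to records
    merge_ambiguities: list[MergeAmbiguity] = field(default_factory=list)
    link_ambiguities: list[LinkAmbiguity] = field(default_factory=list)
    tolerance: int = 0
    ambiguity_tolerance: int = 0

    def resolve(
        self, resolution: Optional[Resolution] = None
    ) -> tuple[list[CNAEvent], list[str]]:
        """Apply a resolution, returning (catalog, per-record event ids).

        With ``resolution=None`` the canonical reading is used: no ambiguous
        merges, lexicographically-first parent for ambiguous second hits.
        """
        if resolution is None:
            resolution = Resolution()
        if len(resolution.merge_choices) not in (0, len(self.merge_ambiguities)):
            raise ValidationError(
                "resolution must decide all merge ambiguities or none"
            )

        # event id -> id of the merged event that absorbs it
        alias = {e.event_id: e.event_id for e in self.events}
        merged_members: dict[str, list[str]] = {e.event_id: [e.event_id] for e in self.events}
        for amb, choice in zip(self.merge_ambiguities, resolution.merge_choices):
            if choice not in amb.choices:
                raise ValidationError(f"invalid merge choice for {amb.event_ids}")
            for block in choice:
                rep = min(block)
                for eid in block:
                    alias[eid] = rep
                merged_members[rep] = sorted(block)

        by_id = {e.event_id: e for e in self.events}
        out_events: list[CNAEvent] = []
        seen = set()
        for e in self.events:
            rep = alias[e.event_id]
            if rep in seen:
                continue
            seen.add(rep)
            members = [by_id[m] for m in merged_members.get(rep, [rep])]
            seg = GenomicSegment(
                chromosome=members[0].segment.chromosome,
                start=min(m.segment.start for m in members),
                end=max(m.segment.end for m in members),
                genome_build=members[0].segment.genome_build,
            )
            parent = members[0].parent_event_id
            if members[0].tier is Tier.SECOND_HIT:
                chosen = resolution.chosen_parent(rep)
                if chosen is not None:
                    parent = chosen
                parent = alias.get(parent, parent)
            out_events.append(
                CNAEvent(
                    event_id=rep,
                    segment=seg,
                    alteration_class=members[0].alteration_class,
                    tier=members[0].tier,
                    parent_event_id=parent if members[0].tier is Tier.SECOND_HIT else None,
                )
            )
        record_event = [alias[eid] for eid in self.record_event]
        return out_events, record_event


def harmonize_events(
    records: list[SegmentRecord],
    tolerance: int = 0,
    ambiguity_tolerance: Optional[int] = None,
    cnloh_independent: bool = False,
) -> Harmonization:
    """Merge per-sample segments into events; report ambiguous merges/links.

    Segments from different samples become one FIRST_HIT event iff they share
    chromosome and class and both endpoints agree within ``tolerance``
    (single-linkage).  Pairs agreeing only within ``ambiguity_tolerance``
    (>= tolerance; default equal, i.e. off) stay separate in the base catalog
    but are offered as alternative merges in the ambiguity report.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    if ambiguity_tolerance is None:
        ambiguity_tolerance = tolerance
    if ambiguity_tolerance < tolerance:
        raise ValidationError("ambiguity_tolerance must be >= tolerance")
    if not records:
        raise ValidationError("no segment records to harmonize")

    # group records by (chromosome, kind)
    groups: dict[tuple[str, str], list[int]] = {}
    tiers: dict[str, Tier] = {}
    for i, rec in enumerate(records):
        tag, tier = _record_kind(rec, cnloh_independent)
        groups.setdefault((rec.segment.chromosome, tag), []).append(i)
        tiers[tag] = tier

    harm = Harmonization(
        records=list(records),
        tolerance=tolerance,
        ambiguity_tolerance=ambiguity_tolerance,
    )
    record_event: dict[int, str] = {}
    cluster_samples: dict[str, set[str]] = {}

    for (chrom, tag) in sorted(groups):
        idxs = groups[(chrom, tag)]
        uf = _UnionFind(len(idxs))
        for a, b in itertools.combinations(range(len(idxs)), 2):
            if _within(records[idxs[a]].segment, records[idxs[b]].segment, tolerance):
                uf.union(a, b)
        clusters: dict[int, list[int]] = {}
        for k in range(len(idxs)):
            clusters.setdefault(uf.find(k), []).append(idxs[k])
        ordered = sorted(
            clusters.values(),
            key=lambda c: (
                min(records[i].segment.start for i in c),
                max(records[i].segment.end for i in c),
            ),
        )
        cluster_ids = []
        for n, members in enumerate(ordered, start=1):
            eid = f"{tag}_{chrom}_{n}" if len(ordered) > 1 else f"{tag}_{chrom}"
            cluster_ids.append((eid, members))
            seg = GenomicSegment(
                chromosome=chrom,
                start=min(records[i].segment.start for i in members),
                end=max(records[i].segment.end for i in members),
                genome_build=records[members[0]].segment.genome_build,
            )
            tier = tiers[tag]
            harm.events.append(
                CNAEvent(
                    event_id=eid,
                    segment=seg,
                    alteration_class=records[members[0]].alteration_class,
                    tier=tier,
                    # parent filled in below for second hits
                    parent_event_id="__pending__" if tier is Tier.SECOND_HIT else None,
                )
            )
            for i in members:
                record_event[i] = eid
            cluster_samples[eid] = {records[i].sample_id for i in members}

        # merge ambiguities: soft links between hard clusters
        if ambiguity_tolerance > tolerance and len(cluster_ids) > 1:
            seg_of = {eid: next(e for e in harm.events if e.event_id == eid).segment
                      for eid, _ in cluster_ids}

            def soft(e1: str, e2: str) -> bool:
                if cluster_samples[e1] & cluster_samples[e2]:
                    return False  # co-reported in one sample: provably distinct
                return _within(seg_of[e1], seg_of[e2], ambiguity_tolerance)

            suf = _UnionFind(len(cluster_ids))
            for a, b in itertools.combinations(range(len(cluster_ids)), 2):
                if soft(cluster_ids[a][0], cluster_ids[b][0]):
                    suf.union(a, b)
            comps: dict[int, list[str]] = {}
            for k, (eid, _) in enumerate(cluster_ids):
                comps.setdefault(suf.find(k), []).append(eid)
            for comp in sorted(comps.values()):
                if len(comp) < 2:
                    continue

                def block_ok(block: tuple[str, ...]) -> bool:
                    return all(soft(x, y) for x, y in itertools.combinations(block, 2))

                choices = _partitions(sorted(comp), block_ok)
                if len(choices) > _MAX_PARTITION_CHOICES:
                    raise ValidationError(
                        f"merge ambiguity over {comp} admits {len(choices)} "
                        f"partitions (cap {_MAX_PARTITION_CHOICES}); "
                        "tighten ambiguity_tolerance"
                    )
                harm.merge_ambiguities.append(
                    MergeAmbiguity(event_ids=tuple(sorted(comp)), choices=tuple(choices))
                )

    # second-hit parent linking
    first_hits = [
        e for e in harm.events
        if e.tier is Tier.FIRST_HIT and e.alteration_class is AlterationClass.DEL
    ]
    patched: list[CNAEvent] = []
    for e in harm.events:
        if e.tier is not Tier.SECOND_HIT:
            patched.append(e)
            continue
        cands = sorted(
            (f.event_id for f in first_hits if f.segment.overlaps(e.segment)),
        )
        if not cands:
            raise ValidationError(
                f"second hit {e.event_id} ({e.segment.chromosome}:"
                f"[{e.segment.start},{e.segment.end})) has no overlapping "
                "heterozygous-deletion context in any sample"
            )
        if len(cands) > 1:
            harm.link_ambiguities.append(
                LinkAmbiguity(second_hit_id=e.event_id, candidates=tuple(cands))
            )
        patched.append(
            CNAEvent(
                event_id=e.event_id,
                segment=e.segment,
                alteration_class=e.alteration_class,
                tier=Tier.SECOND_HIT,
                parent_event_id=cands[0],
            )
        )
    harm.events = patched
    harm.link_ambiguities.sort(key=lambda a: a.second_hit_id)
    harm.record_event = [record_event[i] for i in range(len(records))]
    return harm


def build_observation_matrix(
    harmonization: Harmonization,
    manifest: list[SampleMeta],
    resolution: Optional[Resolution] = None,
) -> ObservationMatrix:
    """Assemble the samples x events call matrix.

    Events never reported in a sample default to ABSENT if the sample was
    assayed (supplementary-style tables report detected CNAs only) and to
    UNKNOWN otherwise.  A reported second hit implies its first-hit parent is
    carried by at least the same cells, so an unreported parent is promoted
    to CLONAL (second hit clonal) or UNKNOWN (second hit subclonal) rather
    than defaulting to ABSENT.
    """
    events, record_event = harmonization.resolve(resolution)
    sample_ids = {s.sample_id for s in manifest}
    rows: dict[str, dict[str, Call]] = {}
    provenance: dict[tuple[str, str], int] = {}
    for i, rec in enumerate(harmonization.records):
        if rec.sample_id not in sample_ids:
            raise ValidationError(
                f"record {i + 1}: sample {rec.sample_id!r} not in manifest"
            )
        eid = record_event[i]
        cell = (rec.sample_id, eid)
        prior = rows.get(rec.sample_id, {}).get(eid)
        if prior is not None and prior is not rec.status:
            raise ValidationError(
                f"conflicting statuses for sample {rec.sample_id}, event {eid}: "
                f"record {provenance[cell] + 1} says {prior.value}, "
                f"record {i + 1} says {rec.status.value}"
            )
        rows.setdefault(rec.sample_id, {})[eid] = rec.status
        provenance[cell] = i

    # implied first-hit presence under a reported second hit
    by_id = {e.event_id: e for e in events}
    for sid, row in rows.items():
        for eid, call in list(row.items()):
            ev = by_id[eid]
            if ev.tier is Tier.SECOND_HIT and call in (Call.SUBCLONAL, Call.CLONAL):
                if ev.parent_event_id not in row:
                    row[ev.parent_event_id] = (
                        Call.CLONAL if call is Call.CLONAL else Call.UNKNOWN
                    )

    return ObservationMatrix.from_rows(list(manifest), events, rows)
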