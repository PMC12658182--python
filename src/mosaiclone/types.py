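"""Domain types for CNA-based clonal deconvolution.

The package tracks copy-number alterations (CNAs) called per sample on SNP
arrays — deletions, amplifications and copy-neutral loss of heterozygosity
(cnLOH) — across a patient's diagnostic sample and its serially
xenotransplanted descendants.  Every alteration is a breakpoint-specific
*event*; a clone is identified with the set of events it carries.

Zygosity at a deleted locus is modelled as a chain

    WT  ->  HET_DEL  ->  { HOM_DEL | CNLOH }

where the heterozygous deletion is a FIRST_HIT event and the homozygous
deletion or cnLOH that completes it is a SECOND_HIT event referencing its
FIRST_HIT parent.  A clone may carry at most one SECOND_HIT per parent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "Call",
    "AlterationClass",
    "Tier",
    "Timepoint",
    "Compartment",
    "Host",
    "GenomicSegment",
    "CNAEvent",
    "SampleMeta",
    "ObservationMatrix",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when input data violates a structural invariant."""


class Call(str, enum.Enum):
    """Per-sample detection status of an event."""

    ABSENT = "ABSENT"
    SUBCLONAL = "SUBCLONAL"  # mosaicism: carriers and non-carriers coexist
    CLONAL = "CLONAL"
    UNKNOWN = "UNKNOWN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class AlterationClass(str, enum.Enum):
    DEL = "DEL"
    AMP = "AMP"
    CNLOH = "CNLOH"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Tier(str, enum.Enum):
    FIRST_HIT = "FIRST_HIT"
    SECOND_HIT = "SECOND_HIT"


class Timepoint(str, enum.Enum):
    DIAGNOSIS = "DIAGNOSIS"
    REMISSION = "REMISSION"
    RELAPSE = "RELAPSE"


class Compartment(str, enum.Enum):
    BULK = "BULK"
    STEMB = "STEMB"
    PROB = "PROB"
    PREB = "PREB"
    HSC = "HSC"
    PROGENITOR = "PROGENITOR"
    CD3POS = "CD3POS"
    CD3NEG = "CD3NEG"
    OTHER = "OTHER"


class Host(str, enum.Enum):
    PATIENT = "PATIENT"
    PRIMARY_XENO = "PRIMARY_XENO"
    SECONDARY_XENO = "SECONDARY_XENO"


@dataclass(frozen=True, order=True)
class GenomicSegment:
    """A genomic interval in 0-based half-open coordinates."""

    chromosome: str
    start: int
    end: int
    genome_build: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValidationError("chromosome label must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid segment {self.chromosome}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    def overlaps(self, other: "GenomicSegment") -> bool:
        if self.genome_build != other.genome_build:
            raise ValidationError(
                f"cannot compare segments from builds "
                f"{self.genome_build!r} and {other.genome_build!r}"
            )
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CNAEvent:
    """A breakpoint-specific alteration; the unit of clonal marking.

    SECOND_HIT events (homozygous deletion or cnLOH completing a het
    deletion) must reference a FIRST_HIT DEL via ``parent_event_id``.
    """

    event_id: str
    segment: GenomicSegment
    alteration_class: AlterationClass
    tier: Tier = Tier.FIRST_HIT
    parent_event_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tier is Tier.SECOND_HIT and self.parent_event_id is None:
            raise ValidationError(
                f"event {self.event_id}: SECOND_HIT requires parent_event_id"
            )
        if self.tier is Tier.FIRST_HIT and self.parent_event_id is not None:
            raise ValidationError(
                f"event {self.event_id}: FIRST_HIT must not have a parent"
            )
        if self.alteration_class is AlterationClass.AMP and self.tier is not Tier.FIRST_HIT:
            raise ValidationError(
                f"event {self.event_id}: amplifications are always FIRST_HIT"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Sample identity plus its position in the transplant lineage.

    ``parent_sample`` names the inoculum source and is required exactly for
    xenograft samples.  ``assayed`` is False for samples that exist in the
    lineage but yielded no SNP-array data (too few cells); their calls
    default to UNKNOWN instead of ABSENT.
    """

    sample_id: str
    patient: str
    timepoint: Timepoint = Timepoint.DIAGNOSIS
    compartment: Compartment = Compartment.BULK
    host: Host = Host.PATIENT
    parent_sample: Optional[str] = None
    assayed: bool = True

    def __post_init__(self) -> None:
        if self.host is Host.PATIENT and self.parent_sample is not None:
            raise ValidationError(
                f"sample {self.sample_id}: patient samples have no parent_sample"
            )
        if self.host is not Host.PATIENT and self.parent_sample is None:
            raise ValidationError(
                f"sample {self.sample_id}: xenograft samples require parent_sample"
            )


def validate_lineage(samples: Iterable[SampleMeta]) -> None:
    """Check that parent_sample references form a forest (no cycles, no orphans)."""
    by_id = {}
    for s in samples:
        if s.sample_id in by_id:
            raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
        by_id[s.sample_id] = s
    for s in by_id.values():
        if s.parent_sample is not None and s.parent_sample not in by_id:
            raise ValidationError(
                f"sample {s.sample_id}: parent_sample {s.parent_sample!r} not in manifest"
            )
    # cycle check by walking up
    for s in by_id.values():
        seen = {s.sample_id}
        cur = s
        while cur.parent_sample is not None:
            if cur.parent_sample in seen:
                raise ValidationError(
                    f"cycle in transplant lineage at sample {cur.parent_sample!r}"
                )
            seen.add(cur.parent_sample)
            cur = by_id[cur.parent_sample]


def validate_catalog(events: Iterable[CNAEvent]) -> dict[str, CNAEvent]:
    """Check event-id uniqueness and SECOND_HIT parent links; return id->event."""
    by_id: dict[str, CNAEvent] = {}
    for e in events:
        if e.event_id in by_id:
            raise ValidationError(f"duplicate event_id {e.event_id!r}")
        by_id[e.event_id] = e
    for e in by_id.values():
        if e.tier is Tier.SECOND_HIT:
            parent = by_id.get(e.parent_event_id)
            if parent is None:
                raise ValidationError(
                    f"event {e.event_id}: parent {e.parent_event_id!r} not in catalog"
                )
            if parent.tier is not Tier.FIRST_HIT or parent.alteration_class is not AlterationClass.DEL:
                raise ValidationError(
                    f"event {e.event_id}: parent {parent.event_id} must be a FIRST_HIT DEL"
                )
            if not e.segment.overlaps(parent.segment):
                raise ValidationError(
                    f"event {e.event_id}: segment does not overlap parent {parent.event_id}"
                )
    return by_id


@dataclass
class ObservationMatrix:
    """Samples x events call matrix with metadata.

    ``calls`` is a pandas DataFrame indexed by sample_id with event_id
    columns and :class:`Call` values.  Ordering of samples and events is
    preserved and deterministic.
    """

    samples: list[SampleMeta]
    events: list[CNAEvent]
    calls: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        validate_lineage(self.samples)
        by_id = validate_catalog(self.events)
        sample_ids = [s.sample_id for s in self.samples]
        event_ids = [e.event_id for e in self.events]
        if list(self.calls.index) != sample_ids or list(self.calls.columns) != event_ids:
            raise ValidationError("calls frame must be indexed by samples x events, in order")
        for sid in sample_ids:
            for eid in event_ids:
                v = self.calls.at[sid, eid]
                if not isinstance(v, Call):
                    raise ValidationError(
                        f"cell ({sid},{eid}) holds {v!r}, not a Call"
                    )
        # a SECOND_HIT cannot be fully clonal where its FIRST_HIT parent is absent
        for e in self.events:
            if e.tier is Tier.SECOND_HIT:
                for sid in sample_ids:
                    if (
                        self.calls.at[sid, e.event_id] is Call.CLONAL
                        and self.calls.at[sid, e.parent_event_id] is Call.ABSENT
                    ):
                        raise ValidationError(
                            f"sample {sid}: second hit {e.event_id} CLONAL but "
                            f"parent {e.parent_event_id} ABSENT"
                        )

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def event_ids(self) -> list[str]:
        return [e.event_id for e in self.events]

    def sample(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def event(self, event_id: str) -> CNAEvent:
        for e in self.events:
            if e.event_id == event_id:
                return e
        raise KeyError(event_id)

    def row(self, sample_id: str) -> dict[str, Call]:
        return {eid: self.calls.at[sample_id, eid] for eid in self.event_ids}

    def assayed_samples(self) -> list[SampleMeta]:
        return [s for s in self.samples if s.assayed]

    @classmethod
    def from_rows(
        cls,
        samples: list[SampleMeta],
        events: list[CNAEvent],
        rows: Mapping[str, Mapping[str, Call]],
    ) -> "ObservationMatrix":
        """Build from a nested mapping sample_id -> event_id -> Call.

        Missing cells default to ABSENT for assayed samples and UNKNOWN for
        unassayed ones (detected-only reporting convention).
        """
        data = {}
        for s in samples:
            fill = Call.ABSENT if s.assayed else Call.UNKNOWN
            r = rows.get(s.sample_id, {})
            data[s.sample_id] = [r.get(e.event_id, fill) for e in events]
        frame = pd.DataFrame.from_dict(
            data, orient="index", columns=[e.event_id for e in events]
        ).reindex([s.sample_id for s in samples])
        return cls(samples=samples, events=events, calls=frame)
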