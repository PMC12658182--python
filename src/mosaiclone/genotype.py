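"""Clone genotypes over a CNA event catalog, and per-sample explanation.

A clone is identified with the set of events it carries.  Genotype validity
encodes the zygosity chain: a SECOND_HIT (homozygous deletion or cnLOH) can
only be carried together with its FIRST_HIT heterozygous-deletion parent,
and two alternative second hits completing the same first hit are mutually
exclusive within one clone (a lineage resolves a locus one way).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .types import Call, CNAEvent, Tier, ValidationError

__all__ = ["CloneGenotype", "EventConstraints", "ExplainResult", "explain_sample"]


@dataclass(frozen=True)
class CloneGenotype:
    """One clone's state over all tracked events (carried / not carried)."""

    events: frozenset[str]

    def carries(self, event_id: str) -> bool:
        return event_id in self.events

    def locus_state(self, catalog: Iterable[CNAEvent], first_hit_id: str) -> str:
        """Derived state of a deleted locus: WT, HET_DEL, HOM_DEL or CNLOH."""
        if first_hit_id not in self.events:
            return "WT"
        for e in catalog:
            if (
                e.tier is Tier.SECOND_HIT
                and e.parent_event_id == first_hit_id
                and e.event_id in self.events
            ):
                return "HOM_DEL" if e.alteration_class.value == "DEL" else "CNLOH"
        return "HET_DEL"

    def __iter__(self):
        return iter(sorted(self.events))


class EventConstraints:
    """Catalog-derived structural constraints on genotypes."""

    def __init__(self, events: Iterable[CNAEvent]):
        self.events = list(events)
        self.parent: dict[str, str] = {
            e.event_id: e.parent_event_id
            for e in self.events
            if e.tier is Tier.SECOND_HIT
        }
        by_parent: dict[str, list[str]] = {}
        for child, par in self.parent.items():
            by_parent.setdefault(par, []).append(child)
        # second hits completing the same locus are mutually exclusive
        self.exclusive: list[tuple[str, str]] = [
            (a, b)
            for sibs in by_parent.values()
            for i, a in enumerate(sorted(sibs))
            for b in sorted(sibs)[i + 1 :]
        ]

    def genotype_valid(self, events: frozenset[str]) -> bool:
        for child, par in self.parent.items():
            if child in events and par not in events:
                return False
        for a, b in self.exclusive:
            if a in events and b in events:
                return False
        return True


@dataclass(frozen=True)
class ExplainResult:
    ok: bool
    violations: tuple[str, ...] = ()

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def explain_sample(
    calls_row: Mapping[str, Call],
    clone_subset: Iterable[CloneGenotype | frozenset],
) -> ExplainResult:
    """Does a clone subset explain a sample's per-event calls?

    Mosaicism semantics: a CLONAL event must be carried by every clone in the
    subset, an ABSENT event by none, and a SUBCLONAL event by at least one
    clone but not all (carriers and non-carriers coexist in the sample).
    UNKNOWN cells constrain nothing.
    """
    clones = [
        c.events if isinstance(c, CloneGenotype) else frozenset(c)
        for c in clone_subset
    ]
    if not clones:
        raise ValidationError("explain_sample: clone_subset must be non-empty")
    violations = []
    for eid, call in calls_row.items():
        carriers = sum(1 for c in clones if eid in c)
        if call is Call.CLONAL and carriers < len(clones):
            violations.append(f"{eid}: CLONAL but {len(clones) - carriers} assigned clone(s) lack it")
        elif call is Call.ABSENT and carriers > 0:
            violations.append(f"{eid}: ABSENT but {carriers} assigned clone(s) carry it")
        elif call is Call.SUBCLONAL:
            if carriers == 0:
                violations.append(f"{eid}: SUBCLONAL but no assigned clone carries it")
            elif carriers == len(clones):
                violations.append(f"{eid}: SUBCLONAL but every assigned clone carries it")
    return ExplainResult(ok=not violations, violations=tuple(violations))
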