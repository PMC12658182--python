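"""Clone trees and pre-leukemic hierarchies by event-containment ordering.

Under a perfect-phylogeny model every event arises exactly once and is never
lost, so the carrier sets of any two events must be nested or disjoint (a
laminar family).  The rooted clone tree follows directly: each edge is
labelled with the events gained on it, the root is the ancestor carrying no
events, and each clone's genotype is the union of edge labels on its root
path.  Crossing carrier sets yield an incompatibility certificate naming the
two events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .genotype import CloneGenotype
from .types import Call, ObservationMatrix, ValidationError

__all__ = [
    "CloneNode",
    "CloneTree",
    "IncompatibilityError",
    "check_phylogeny",
    "PartialOrder",
    "order_events",
    "build_hierarchy",
    "write_newick",
    "to_dot",
]


class IncompatibilityError(ValidationError):
    """Two events have crossing carrier sets; no perfect phylogeny exists."""

    def __init__(self, event_a: str, event_b: str):
        self.certificate = (event_a, event_b)
        super().__init__(
            f"events {event_a} and {event_b} have crossing carrier sets; "
            "no perfect phylogeny exists"
        )


@dataclass
class CloneNode:
    node_id: str
    gained: tuple[str, ...] = ()  # events gained on the edge from the parent
    genotype: frozenset[str] = frozenset()
    clone_labels: tuple[str, ...] = ()  # input clones sitting at this node
    children: list["CloneNode"] = field(default_factory=list)


@dataclass
class CloneTree:
    """Rooted clone tree; edges labelled with gained events."""

    root: CloneNode

    def nodes(self) -> list[CloneNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def events(self) -> set[str]:
        return {e for n in self.nodes() for e in n.gained}

    def node_for(self, genotype: frozenset[str]) -> Optional[CloneNode]:
        for n in self.nodes():
            if n.genotype == genotype:
                return n
        return None

    def to_json(self) -> dict:
        def rec(n: CloneNode) -> dict:
            return {
                "node_id": n.node_id,
                "gained": list(n.gained),
                "genotype": sorted(n.genotype),
                "clones": list(n.clone_labels),
                "children": [rec(c) for c in n.children],
            }

        return rec(self.root)


def _as_genosets(clones: Iterable[Union[CloneGenotype, frozenset, set]]) -> list[frozenset]:
    out = []
    for c in clones:
        g = c.events if isinstance(c, CloneGenotype) else frozenset(c)
        if g not in out:
            out.append(g)
    return out


def check_phylogeny(
    clones: Iterable[Union[CloneGenotype, frozenset, set]],
    clone_labels: Optional[Mapping[frozenset, Sequence[str]]] = None,
) -> CloneTree:
    """Build the perfect phylogeny over a clone set, or raise a certificate.

    Succeeds iff event-carrier sets form a laminar family.  Events with
    identical carrier sets are gained on the same edge (their order is not
    resolvable from the data); child ordering is lexicographic for
    deterministic output.
    """
    genos = _as_genosets(clones)
    if not genos:
        raise ValidationError("check_phylogeny: empty clone set")
    events = sorted({e for g in genos for e in g})
    carriers = {e: frozenset(i for i, g in enumerate(genos) if e in g) for e in events}

    for i, a in enumerate(events):
        for b in events[i + 1 :]:
            ca, cb = carriers[a], carriers[b]
            if ca & cb and not (ca <= cb or cb <= ca):
                raise IncompatibilityError(a, b)

    # bundle events gained together (identical carrier sets)
    bundles: dict[frozenset, list[str]] = {}
    for e in events:
        bundles.setdefault(carriers[e], []).append(e)
    ordered = sorted(
        bundles.items(), key=lambda kv: (-len(kv[0]), sorted(kv[1])[0])
    )

    root = CloneNode(node_id="root")
    node_of: dict[frozenset, CloneNode] = {}
    counter = 0
    for carr, evs in ordered:
        # parent = deepest strict superset bundle, else the root
        parent = root
        best = None
        for carr2, _ in ordered:
            if carr < carr2 and (best is None or carr2 < best):
                best = carr2
        if best is not None:
            parent = node_of[best]
        counter += 1
        node = CloneNode(
            node_id=f"n{counter}",
            gained=tuple(sorted(evs)),
            genotype=parent.genotype | set(evs),
        )
        parent.children.append(node)
        node_of[carr] = node

    for n in [root] + list(node_of.values()):
        n.children.sort(key=lambda c: c.gained)

    # attach clones; genotype of a clone equals the union of bundles carrying it
    labels = dict(clone_labels or {})
    for i, g in enumerate(genos):
        target = root
        for n in node_of.values():
            if n.genotype == g:
                target = n
                break
        else:
            if g:
                # cannot happen for laminar families; defensive
                raise ValidationError(f"clone {sorted(g)} does not map to a tree node")
        default = f"clone{i + 1}"
        target.clone_labels = tuple(
            sorted(set(target.clone_labels) | set(labels.get(g, [default])))
        )
    return CloneTree(root=root)


# -- event ordering -----------------------------------------------------------


@dataclass
class PartialOrder:
    """Strict partial order over events by carrier-set containment."""

    events: tuple[str, ...]
    pairs: frozenset[tuple[str, str]]  # (earlier, later)
    co_occurring: frozenset[tuple[str, str]]  # identical carrier sets

    def precedes(self, a: str, b: str) -> bool:
        return (a, b) in self.pairs

    def comparable(self, a: str, b: str) -> bool:
        return (a, b) in self.pairs or (b, a) in self.pairs


def _carriers_from_matrix(matrix: ObservationMatrix) -> dict[str, dict[str, bool]]:
    """Per event: sample -> carried?; UNKNOWN cells are left out entirely."""
    out: dict[str, dict[str, bool]] = {}
    for e in matrix.event_ids:
        col = {}
        for s in matrix.sample_ids:
            call = matrix.calls.at[s, e]
            if call is Call.UNKNOWN:
                continue
            col[s] = call in (Call.SUBCLONAL, Call.CLONAL)
        out[e] = col
    return out


def order_events(
    source: Union[ObservationMatrix, Iterable[Union[CloneGenotype, frozenset]]],
) -> PartialOrder:
    """Order events by carrier containment: A precedes B iff every carrier of
    B also carries A and the containment is strict in at least one
    observation.  Events with identical carrier sets are reported as
    co-occurring; missing (UNKNOWN) cells are excluded from both sides so
    they cannot fabricate order.
    """
    if isinstance(source, ObservationMatrix):
        cols = _carriers_from_matrix(source)
        events = sorted(cols)

        def contains(a: str, b: str) -> tuple[bool, bool]:
            # carriers(b) subseteq carriers(a) on the shared domain; strictness
            dom = set(cols[a]) & set(cols[b])
            sub = all(cols[a][s] for s in dom if cols[b][s])
            strict = any(cols[a][s] and not cols[b][s] for s in dom)
            return sub, strict

    else:
        genos = _as_genosets(source)
        events = sorted({e for g in genos for e in g})
        carr = {e: frozenset(i for i, g in enumerate(genos) if e in g) for e in events}

        def contains(a: str, b: str) -> tuple[bool, bool]:
            return carr[b] <= carr[a], carr[b] < carr[a]

    pairs = set()
    co = set()
    for a in events:
        for b in events:
            if a >= b:
                continue
            ab_sub, ab_strict = contains(a, b)
            ba_sub, ba_strict = contains(b, a)
            if ab_sub and ba_sub and not ab_strict and not ba_strict:
                co.add((a, b))
            elif ab_sub and ab_strict and not (ba_sub and ba_strict):
                pairs.add((a, b))
            elif ba_sub and ba_strict and not (ab_sub and ab_strict):
                pairs.add((b, a))

    # transitive closure; containment data cannot produce 2-cycles unless corrupt
    changed = True
    while changed:
        changed = False
        for x, y in list(pairs):
            for y2, z in list(pairs):
                if y2 == y and (x, z) not in pairs and x != z:
                    pairs.add((x, z))
                    changed = True
    for x, y in pairs:
        if (y, x) in pairs:
            raise RuntimeError(f"contradictory event order between {x} and {y}")
    return PartialOrder(
        events=tuple(events), pairs=frozenset(pairs), co_occurring=frozenset(co)
    )


def build_hierarchy(
    clones_by_group: Mapping[str, Sequence[Union[CloneGenotype, frozenset]]],
) -> CloneTree:
    """Join clone sets from several timepoints (diagnosis / remission /
    relapse) into one tree over the shared event catalog.

    Shared events define common ancestors; private events define branches.
    Each input clone maps to exactly one node, labelled ``group:index``.
    Raises :class:`IncompatibilityError` if clones cross between timepoints,
    signalling that a shared-ancestor model cannot hold.
    """
    labels: dict[frozenset, list[str]] = {}
    all_clones: list[frozenset] = []
    for group in sorted(clones_by_group):
        for i, c in enumerate(clones_by_group[group], start=1):
            g = c.events if isinstance(c, CloneGenotype) else frozenset(c)
            labels.setdefault(g, []).append(f"{group}:{i}")
            if g not in all_clones:
                all_clones.append(g)
    if not all_clones:
        raise ValidationError("build_hierarchy: no clones given")
    return check_phylogeny(all_clones, clone_labels=labels)


# -- serialization ------------------------------------------------------------


def _newick_label(n: CloneNode) -> str:
    base = "+".join(n.clone_labels) if n.clone_labels else n.node_id
    safe = base.replace(" ", "_").replace(",", "|").replace(":", ".")
    if n.gained:
        return f"{safe}[&gained={'|'.join(n.gained)}]"
    return safe


def newick_string(tree: CloneTree) -> str:
    def rec(n: CloneNode) -> str:
        if not n.children:
            return _newick_label(n)
        inner = ",".join(rec(c) for c in n.children)
        return f"({inner}){_newick_label(n)}"

    return rec(tree.root) + ";"


def write_newick(tree: CloneTree, path: Union[str, Path]) -> None:
    """Write the tree as Newick with gained-event annotations in comment
    blocks (``[&gained=...]``), parseable by standard readers."""
    Path(path).write_text(newick_string(tree) + "\n")


def to_dot(tree: CloneTree) -> str:
    """Graphviz DOT export for figures."""
    lines = ["digraph clonetree {", '  node [shape=box, fontname="Helvetica"];']
    for n in tree.nodes():
        label = "+".join(n.clone_labels) if n.clone_labels else n.node_id
        shape = ', style="rounded,filled", fillcolor="#dde8f4"' if n.clone_labels else ""
        lines.append(f'  "{n.node_id}" [label="{label}"{shape}];')
    for n in tree.nodes():
        for c in n.children:
            elabel = ", ".join(c.gained)
            lines.append(f'  "{n.node_id}" -> "{c.node_id}" [label="{elabel}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
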