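"""Exact enumeration of minimal diagnostic clone sets.

Under the no-new-mutation assumption every clone detected in any xenograft
already existed in the diagnostic sample, so a single set of diagnostic
clones must explain the detected state of every assayed sample: a CLONAL
event is carried by every assigned clone, an ABSENT event by none, and a
SUBCLONAL (mosaic) event by some but not all.  The clone set must also admit
a perfect phylogeny (laminar carrier sets) and respect zygosity chains.

The search is exact: iterative deepening over the clone count with an
admissible lower bound, over a candidate-genotype lattice generated from the
observed per-sample constraints.  The restriction to that lattice loses no
optimal solution: any clone in a minimal solution is assigned to at least
one assayed sample s (otherwise it can be dropped), hence carries all of
s's CLONAL events, none of its ABSENT events and an arbitrary subset of the
remaining ones — which is exactly how the lattice is generated.  An
exhaustive reference search over all valid genotypes is provided for
cross-checking on small instances.

Because SNP arrays censor low-abundance clones, a clone detected in a
xenograft may have been present but undetectable in its inoculum; the
shared-clone-set model is therefore the default reading of transplant
lineage.  ``strict_lineage`` additionally forces nested per-sample
assignments along each transplant edge, which is stricter than the data can
guarantee under censoring and may be infeasible (reported with the binding
constraints).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from .genotype import CloneGenotype, EventConstraints, explain_sample
from .harmonize import Harmonization, Resolution, build_observation_matrix
from .phylogeny import CloneTree, check_phylogeny
from .types import Call, ObservationMatrix, ValidationError

__all__ = [
    "Options",
    "InfeasibleError",
    "CapExceededError",
    "CloneSetSolution",
    "MinimalCloneSets",
    "CloneRange",
    "enumerate_resolutions",
    "lower_bound",
    "minimal_clone_set",
    "exhaustive_minimal",
    "minimal_clone_range",
]


class InfeasibleError(ValidationError):
    """No clone set explains the observations; carries binding constraints."""

    def __init__(self, message: str, binding: Sequence[str] = ()):
        self.binding = tuple(binding)
        detail = ("; binding constraints: " + "; ".join(binding)) if binding else ""
        super().__init__(message + detail)


class CapExceededError(ValidationError):
    def __init__(self, what: str, count: int, cap: int):
        self.count, self.cap = count, cap
        super().__init__(f"{what}: {count} exceeds configured cap {cap}")


@dataclass(frozen=True)
class Options:
    """Search options.

    strict_lineage
        Also require assignment[child] ⊆ assignment[parent] along transplant
        edges (off by default; see module docstring).
    clone_cap / resolution_cap
        Hard limits; exceeding either fails loudly.
    max_free_events
        Per-sample cap on unconstrained events when generating candidate
        genotypes (guards the 2^free lattice).
    """

    strict_lineage: bool = False
    clone_cap: int = 64
    resolution_cap: int = 10_000
    max_solutions: int = 5_000
    max_free_events: int = 16


@dataclass(frozen=True)
class _SampleCons:
    """Effective per-sample constraint masks over the event index."""

    sample_id: str
    cl: int  # every assigned clone carries these
    ab: int  # no assigned clone carries these
    sub: int  # each needs a carrier and a non-carrier among assigned clones


@dataclass
class CloneSetSolution:
    """A diagnostic clone set with per-sample assignments and its phylogeny."""

    clones: tuple[CloneGenotype, ...]
    assignment: dict[str, tuple[CloneGenotype, ...]]
    tree: CloneTree
    resolution: Resolution = Resolution()


@dataclass
class MinimalCloneSets:
    minimum: int
    solutions: list[CloneSetSolution]
    truncated: bool = False


@dataclass
class ResolutionOutcome:
    resolution: Resolution
    minimum: Optional[int]  # None when this reading is contradicted by the data
    representative: Optional[CloneSetSolution]
    n_cominimal: int = 0
    infeasible_reason: str = ""


@dataclass
class CloneRange:
    """Range of minimal diagnostic clone counts over all observation
    resolutions, with the per-resolution table."""

    minimum: int
    maximum: int
    table: list[ResolutionOutcome]


# -- setup --------------------------------------------------------------------


def _event_index(matrix: ObservationMatrix) -> dict[str, int]:
    return {eid: i for i, eid in enumerate(matrix.event_ids)}


def _sample_constraints(matrix: ObservationMatrix, options: Options) -> list[_SampleCons]:
    idx = _event_index(matrix)
    raw: dict[str, tuple[int, int, int]] = {}
    for s in matrix.samples:
        if not s.assayed:
            continue
        cl = ab = sub = 0
        for eid, call in matrix.row(s.sample_id).items():
            bit = 1 << idx[eid]
            if call is Call.CLONAL:
                cl |= bit
            elif call is Call.ABSENT:
                ab |= bit
            elif call is Call.SUBCLONAL:
                sub |= bit
        raw[s.sample_id] = (cl, ab, sub)

    by_id = {s.sample_id: s for s in matrix.samples}
    out = []
    for sid, (cl, ab, sub) in raw.items():
        ecl, eab = cl, ab
        if options.strict_lineage:
            cur = by_id[sid]
            while cur.parent_sample is not None:
                cur = by_id[cur.parent_sample]
                if cur.sample_id in raw:
                    acl, aab, _ = raw[cur.sample_id]
                    ecl |= acl
                    eab |= aab
        out.append(_SampleCons(sample_id=sid, cl=ecl, ab=eab, sub=sub))
    return out


def _closure(mask: int, parent_bits: dict[int, int]) -> int:
    """Add first-hit parents required by any second hit in the mask."""
    changed = True
    while changed:
        changed = False
        for child, par in parent_bits.items():
            if mask & child and not mask & par:
                mask |= par
                changed = True
    return mask


def _structure(matrix: ObservationMatrix) -> tuple[EventConstraints, dict[int, int], list[tuple[int, int]]]:
    idx = _event_index(matrix)
    cons = EventConstraints(matrix.events)
    parent_bits = {1 << idx[c]: 1 << idx[p] for c, p in cons.parent.items()}
    excl_bits = [(1 << idx[a], 1 << idx[b]) for a, b in cons.exclusive]
    return cons, parent_bits, excl_bits


def _check_sample_feasibility(
    samples: list[_SampleCons],
    parent_bits: dict[int, int],
    excl_bits: list[tuple[int, int]],
    matrix: ObservationMatrix,
    options: Options,
) -> None:
    """Raise InfeasibleError for constraints no clone set of any size can meet."""
    binding = []
    eids = matrix.event_ids
    for sc in samples:
        names = lambda m: [eids[i] for i in range(len(eids)) if m >> i & 1]
        if sc.cl & sc.ab:
            binding.append(
                f"sample {sc.sample_id}: events {names(sc.cl & sc.ab)} required "
                "CLONAL and ABSENT at once"
                + (" along its transplant lineage" if options.strict_lineage else "")
            )
            continue
        if sc.sub & sc.cl or sc.sub & sc.ab:
            binding.append(
                f"sample {sc.sample_id}: SUBCLONAL events {names(sc.sub & (sc.cl | sc.ab))} "
                "also pinned CLONAL/ABSENT along its transplant lineage"
            )
            continue
        base = _closure(sc.cl, parent_bits)
        if base & sc.ab:
            binding.append(
                f"sample {sc.sample_id}: CLONAL second hit requires first-hit "
                f"parent {names(base & sc.ab)} called ABSENT"
            )
        for a, b in excl_bits:
            if base & a and base & b:
                binding.append(
                    f"sample {sc.sample_id}: mutually exclusive second hits "
                    f"{names(a | b)} both CLONAL"
                )
        for i in range(len(eids)):
            bit = 1 << i
            if sc.sub & bit:
                carrier = _closure(base | bit, parent_bits)
                if carrier & sc.ab:
                    binding.append(
                        f"sample {sc.sample_id}: no admissible carrier for "
                        f"subclonal event {eids[i]} (requires {names(carrier & sc.ab)})"
                    )
    if binding:
        raise InfeasibleError("observations admit no clone set", binding)


def _candidate_pool(
    samples: list[_SampleCons],
    n_events: int,
    parent_bits: dict[int, int],
    excl_bits: list[tuple[int, int]],
    options: Options,
) -> list[int]:
    full = (1 << n_events) - 1
    pool: set[int] = set()
    for sc in samples:
        if not (sc.cl | sc.ab | sc.sub):
            continue  # uninformative; explained by any non-empty set
        free = full & ~sc.cl & ~sc.ab
        free_bits = [1 << i for i in range(n_events) if free >> i & 1]
        if len(free_bits) > options.max_free_events:
            raise CapExceededError(
                f"candidate lattice for sample {sc.sample_id}",
                2 ** len(free_bits),
                2 ** options.max_free_events,
            )
        for r in range(len(free_bits) + 1):
            for combo in itertools.combinations(free_bits, r):
                g = sc.cl
                for b in combo:
                    g |= b
                if _valid_mask(g, parent_bits, excl_bits):
                    pool.add(g)
    return sorted(pool, key=lambda g: (g.bit_count(), g))


def _valid_mask(g: int, parent_bits: dict[int, int], excl_bits: list[tuple[int, int]]) -> bool:
    for child, par in parent_bits.items():
        if g & child and not g & par:
            return False
    for a, b in excl_bits:
        if g & a and g & b:
            return False
    return True


def _eligible(g: int, sc: _SampleCons) -> bool:
    return (g & sc.cl) == sc.cl and not g & sc.ab


def _sample_satisfied(clones: Sequence[int], sc: _SampleCons) -> bool:
    elig = [g for g in clones if _eligible(g, sc)]
    if not elig:
        return False
    sub = sc.sub
    i = 0
    while sub >> i:
        bit = 1 << i
        if sub & bit:
            if not any(g & bit for g in elig):
                return False
            if all(g & bit for g in elig):
                return False
        i += 1
    return True


def _is_laminar(clones: Sequence[int], n_events: int) -> bool:
    present = 0
    for g in clones:
        present |= g
    bits = [1 << i for i in range(n_events) if present >> i & 1]
    for a, b in itertools.combinations(bits, 2):
        both = only_a = only_b = False
        for g in clones:
            ha, hb = bool(g & a), bool(g & b)
            if ha and hb:
                both = True
            elif ha:
                only_a = True
            elif hb:
                only_b = True
            if both and only_a and only_b:
                return False
    return True


# -- bounds -------------------------------------------------------------------


def _deficit(clones: Sequence[int], sc: _SampleCons) -> int:
    """Admissible count of additional clones sample ``sc`` still needs."""
    if not (sc.cl | sc.ab | sc.sub):
        return 0
    elig = [g for g in clones if _eligible(g, sc)]
    if not elig:
        return 2 if sc.sub else 1
    return 0 if _sample_satisfied(clones, sc) else 1


def _incompatible(a: _SampleCons, b: _SampleCons) -> bool:
    """No single genotype can be assigned to both samples."""
    return bool((a.cl | b.cl) & (b.ab | a.ab))


def _clique_bound(deficits: dict[str, int], samples: list[_SampleCons]) -> int:
    active = [sc for sc in samples if deficits.get(sc.sample_id, 0) > 0]
    if not active:
        return 0
    g = nx.Graph()
    g.add_nodes_from(sc.sample_id for sc in active)
    for a, b in itertools.combinations(active, 2):
        if _incompatible(a, b):
            g.add_edge(a.sample_id, b.sample_id)
    best = 0
    for clique in nx.find_cliques(g):
        best = max(best, sum(deficits[s] for s in clique))
    return best


def lower_bound(matrix: ObservationMatrix, options: Options = Options()) -> int:
    """Admissible lower bound on the minimal diagnostic clone count.

    At least 2 for any sample with a SUBCLONAL (mosaic) call, and at least
    the total demand of a set of samples whose clonal signatures are
    pairwise incompatible (each needs its own clones).
    """
    samples = _sample_constraints(matrix, options)
    deficits = {sc.sample_id: (2 if sc.sub else 1) for sc in samples
                if sc.cl | sc.ab | sc.sub}
    if not deficits:
        return 1
    return max(1, max(deficits.values()), _clique_bound(deficits, samples))


# -- search -------------------------------------------------------------------


def _search_all_minimal(
    pool: list[int],
    samples: list[_SampleCons],
    n_events: int,
    k_start: int,
    options: Options,
) -> tuple[int, list[tuple[int, ...]], bool]:
    informative = [sc for sc in samples if sc.cl | sc.ab | sc.sub]
    elig_pool = {
        sc.sample_id: [i for i, g in enumerate(pool) if _eligible(g, sc)]
        for sc in informative
    }
    n = len(pool)

    for k in range(max(1, k_start), options.clone_cap + 1):
        found: list[tuple[int, ...]] = []
        truncated = False

        def rec(start: int, chosen: list[int]) -> None:
            nonlocal truncated
            if len(found) >= options.max_solutions:
                truncated = True
                return
            if len(chosen) == k:
                if all(_sample_satisfied(chosen, sc) for sc in informative):
                    found.append(tuple(chosen))
                return
            deficits = {
                sc.sample_id: _deficit(chosen, sc) for sc in informative
            }
            need = max([0] + list(deficits.values()))
            need = max(need, _clique_bound(deficits, informative))
            if len(chosen) + need > k:
                return
            # every still-unserved sample must have an eligible clone ahead
            for sc in informative:
                if deficits[sc.sample_id] > 0 and not any(
                    i >= start for i in elig_pool[sc.sample_id]
                ) and not any(_eligible(g, sc) for g in chosen):
                    return
            for i in range(start, n):
                if n - i < k - len(chosen):
                    break
                cand = chosen + [pool[i]]
                if _is_laminar(cand, n_events):
                    rec(i + 1, cand)

        rec(0, [])
        if found:
            return k, found, truncated
    raise InfeasibleError(
        f"no clone set of size <= {options.clone_cap} explains the observations"
    )


def _to_solution(
    clone_masks: tuple[int, ...],
    matrix: ObservationMatrix,
    samples: list[_SampleCons],
    resolution: Resolution,
) -> CloneSetSolution:
    eids = matrix.event_ids
    genos = tuple(
        CloneGenotype(frozenset(eids[i] for i in range(len(eids)) if g >> i & 1))
        for g in sorted(clone_masks, key=lambda g: (g.bit_count(), g))
    )
    mask_of = {
        geno: mask
        for geno, mask in zip(genos, sorted(clone_masks, key=lambda g: (g.bit_count(), g)))
    }
    cons_by_id = {sc.sample_id: sc for sc in samples}
    assignment: dict[str, tuple[CloneGenotype, ...]] = {}
    for s in matrix.samples:
        sc = cons_by_id.get(s.sample_id)
        if sc is None:  # unassayed: canonical full-set assignment
            assignment[s.sample_id] = genos
        else:
            assignment[s.sample_id] = tuple(
                g for g in genos if _eligible(mask_of[g], sc)
            )
    labels = {g.events: [f"C{i + 1}"] for i, g in enumerate(genos)}
    tree = check_phylogeny([g.events for g in genos], clone_labels=labels)
    return CloneSetSolution(
        clones=genos, assignment=assignment, tree=tree, resolution=resolution
    )


def minimal_clone_set(
    matrix: ObservationMatrix,
    resolution: Optional[Resolution] = None,
    options: Options = Options(),
    harmonization: Optional[Harmonization] = None,
) -> MinimalCloneSets:
    """Smallest diagnostic clone set explaining every assayed sample, plus
    all co-minimal clone sets (deduplicated, deterministic order).

    If ``resolution`` is given, it is applied first (requires the
    harmonization it came from).
    """
    if resolution is not None and (resolution.merge_choices or resolution.link_choices):
        if harmonization is None:
            raise ValidationError("applying a non-trivial resolution requires the harmonization")
        matrix = build_observation_matrix(harmonization, matrix.samples, resolution)
    resolution = resolution or Resolution()

    samples = _sample_constraints(matrix, options)
    cons, parent_bits, excl_bits = _structure(matrix)
    _check_sample_feasibility(samples, parent_bits, excl_bits, matrix, options)
    n_events = len(matrix.events)
    pool = _candidate_pool(samples, n_events, parent_bits, excl_bits, options)
    if not pool:
        # no informative observations: one unaltered clone explains everything
        sol = _to_solution((0,), matrix, samples, resolution)
        return MinimalCloneSets(minimum=1, solutions=[sol])

    k0 = lower_bound(matrix, options)
    k, found, truncated = _search_all_minimal(pool, samples, n_events, k0, options)
    seen = set()
    solutions = []
    for masks in sorted(found, key=lambda ms: tuple(sorted(ms))):
        key = tuple(sorted(masks))
        if key in seen:
            continue
        seen.add(key)
        solutions.append(_to_solution(masks, matrix, samples, resolution))
    return MinimalCloneSets(minimum=k, solutions=solutions, truncated=truncated)


def exhaustive_minimal(
    matrix: ObservationMatrix,
    options: Options = Options(),
    max_events: int = 14,
) -> MinimalCloneSets:
    """Reference search over *all* valid genotypes (2^E), no candidate
    lattice, no bounds.  Exponential; for cross-checks on small instances."""
    n_events = len(matrix.events)
    if n_events > max_events:
        raise CapExceededError("exhaustive search events", n_events, max_events)
    samples = _sample_constraints(matrix, options)
    cons, parent_bits, excl_bits = _structure(matrix)
    _check_sample_feasibility(samples, parent_bits, excl_bits, matrix, options)
    informative = [sc for sc in samples if sc.cl | sc.ab | sc.sub]
    all_genos = [
        g for g in range(1 << n_events) if _valid_mask(g, parent_bits, excl_bits)
    ]
    for k in range(1, min(options.clone_cap, len(all_genos)) + 1):
        found = [
            combo
            for combo in itertools.combinations(all_genos, k)
            if _is_laminar(combo, n_events)
            and all(_sample_satisfied(combo, sc) for sc in informative)
        ]
        if found:
            return MinimalCloneSets(
                minimum=k,
                solutions=[
                    _to_solution(m, matrix, samples, Resolution())
                    for m in sorted(found, key=lambda ms: tuple(sorted(ms)))
                ],
            )
    raise InfeasibleError("no clone set explains the observations")


# -- resolutions --------------------------------------------------------------


def enumerate_resolutions(
    harmonization: Harmonization, cap: int = Options.resolution_cap
) -> list[Resolution]:
    """Every combination of merge-partition and second-hit-link choices, in
    deterministic lexicographic order."""
    merge_axes = [amb.choices for amb in harmonization.merge_ambiguities]
    link_axes = [
        [(amb.second_hit_id, parent) for parent in amb.candidates]
        for amb in harmonization.link_ambiguities
    ]
    count = 1
    for axis in merge_axes + link_axes:
        count *= len(axis)
    if count > cap:
        raise CapExceededError("resolution count", count, cap)
    out = []
    for merges in itertools.product(*merge_axes):
        for links in itertools.product(*link_axes):
            out.append(Resolution(merge_choices=tuple(merges), link_choices=tuple(links)))
    return out


def minimal_clone_range(
    matrix: ObservationMatrix,
    harmonization: Optional[Harmonization] = None,
    options: Options = Options(),
) -> CloneRange:
    """Minimal clone count under every resolution of the ambiguity report;
    returns the (min, max) range and the per-resolution table.

    This is the model's headline quantity: the number of diagnostic clones
    needed to explain the xenograft read-out, as a range over all readings
    of the SNP data that the breakpoint resolution and zygosity linking
    leave open.
    """
    if harmonization is None:
        resolutions = [Resolution()]
    else:
        resolutions = enumerate_resolutions(harmonization, options.resolution_cap)
    table = []
    for res in resolutions:
        try:
            if harmonization is not None:
                m = build_observation_matrix(harmonization, matrix.samples, res)
            else:
                m = matrix
            result = minimal_clone_set(m, options=options)
        except CapExceededError:
            raise
        except (InfeasibleError, ValidationError) as exc:
            # this reading of the data is self-contradictory; it contributes
            # no theoretically possible clone combination
            table.append(
                ResolutionOutcome(
                    resolution=res,
                    minimum=None,
                    representative=None,
                    infeasible_reason=str(exc),
                )
            )
            continue
        rep = result.solutions[0]
        rep.resolution = res
        table.append(
            ResolutionOutcome(
                resolution=res,
                minimum=result.minimum,
                representative=rep,
                n_cominimal=len(result.solutions),
            )
        )
    minima = [t.minimum for t in table if t.minimum is not None]
    if not minima:
        raise InfeasibleError(
            "every resolution of the ambiguity report is contradicted by the "
            "observations",
            [t.infeasible_reason for t in table][:5],
        )
    return CloneRange(minimum=min(minima), maximum=max(minima), table=table)
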