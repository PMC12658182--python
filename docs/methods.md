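# Methods

## Data model

A **CNA event** is a breakpoint-specific alteration: a genomic segment
(0-based, half-open; a reader dialect converts 1-based inclusive
SNP-array exports), an alteration class (DEL / AMP / CNLOH) and a
zygosity tier. Heterozygous deletions and amplifications are FIRST_HIT
events; a homozygous deletion or a cnLOH is a SECOND_HIT that completes
an overlapping heterozygous FIRST_HIT deletion
(`WT → HET_DEL → {HOM_DEL | CNLOH}`). cnLOH can instead be configured as
an independent FIRST_HIT (`cnloh_independent=True`); the default treats
it as the extreme of the zygosity progression. All second hits completing
the same first hit are mutually exclusive within one clone — a lineage
resolves a locus one way.

The **observation matrix** holds one call per (sample, event):
ABSENT / SUBCLONAL / CLONAL / UNKNOWN. Supplementary-style tables report
detected CNAs only, so an unreported event defaults to ABSENT in an
assayed sample and to UNKNOWN in a sample without array data. A reported
second hit implies its first hit is carried by at least the same cells:
an unreported first hit under a CLONAL second hit is promoted to CLONAL,
and to UNKNOWN under a SUBCLONAL one (SUBCLONAL would wrongly assert a
non-carrier; UNKNOWN is the conservative choice).

## Harmonization and resolutions

Segments from different samples are merged into one event iff they share
chromosome, class and tier and both endpoints agree within `tolerance`
(single-linkage union-find; the consensus segment is the member span).
The default tolerance is 0: the analysis distinguishes clones by deletion
size, so aggressive merging would erase exactly the signal of interest.
Single-linkage is transitively closed, so a chain of near-matches can
merge segments whose pairwise distance exceeds the tolerance; this drift
is intentional and tested.

Two sources of ambiguity are recorded rather than decided:

* **Merge ambiguity** — clusters that agree only within a wider
  `ambiguity_tolerance` (default: equal to `tolerance`, i.e. off) may
  alternatively be one event. Choices are the partitions of the clusters
  whose blocks are pairwise within the window; two segments co-reported
  in one sample are provably distinct and never offered for merging.
  Partitions per ambiguity are capped (64) and fail loudly.
* **Link ambiguity** — a second hit overlapping ≥ 2 candidate het
  deletions may descend from any of them.

A **resolution** is one choice per ambiguity. Resolutions are enumerated
in deterministic lexicographic order; the count (product of per-ambiguity
choices) is capped (default 10,000) and exceeding the cap is an error,
not a hang. Each resolution is minimized separately. A resolution whose
implied matrix or clone-set problem is self-contradictory (e.g. a cnLOH
linked to a deletion that is absent wherever the cnLOH is seen) describes
a reading the data rule out; it is recorded in the per-resolution table
as infeasible and contributes no clone count. The reported range
[min, max] is taken over the surviving readings.

## The minimization

A clone set `C` is feasible when every assayed sample has a non-empty
subset of `C` meeting the CLONAL / ABSENT / SUBCLONAL semantics and the
event-carrier sets over `C` form a laminar family (perfect phylogeny:
each event arises once, is never lost). Because all per-sample demands
are existential, the maximal assignment — every clone compatible with the
sample's CLONAL/ABSENT constraints — is optimal, making the feasibility
check polynomial in `|C|`; reported assignments are these maximal sets
(samples without array data canonically receive the full clone set so
outputs are total).

**Candidate lattice.** Any clone in a minimal solution is assigned to at
least one assayed sample (unassigned clones can be dropped), hence it
carries all of that sample's CLONAL events, none of its ABSENT events,
and an arbitrary subset of the rest. The candidate pool is exactly the
union over samples of these sublattices, filtered for zygosity validity,
so restricting the search to it loses no optimum. Samples with more than
`max_free_events` (default 16) unconstrained events make the lattice
explode and fail loudly.

**Search.** Iterative deepening on the clone count `k`, starting from an
admissible lower bound, with depth-first enumeration over the ordered
pool. Pruning: incremental laminarity; a per-sample deficit (2 if the
sample has unmet mosaicism, else 1, else 0) aggregated over a clique of
samples with pairwise-incompatible clonal signatures (their clone needs
are disjoint, so deficits add — admissible); and a reachability check
that every unserved sample still has an eligible candidate ahead. At the
first feasible `k`, *all* feasible k-subsets are collected, deduplicated
by canonical genotype-set ordering, and returned (capped at
`max_solutions`, with a truncation flag). `lower_bound` exposes the
root bound: at least 2 for any sample with a SUBCLONAL call, and at least
the summed demand of a maximum clique of pairwise-incompatible samples
(exact clique search on these small graphs via networkx).

An **exhaustive reference search** over all valid genotypes (no lattice,
no bounds, no pruning beyond laminarity) provides an independent oracle;
branch-and-bound equals it on every tested instance (random cohorts are
drawn feasible-by-construction from random laminar clone families, since
fully random call matrices can be incompatible with any perfect
phylogeny).

**Transplant lineage.** The no-new-mutation assumption is operationalized
as the single shared diagnostic clone set: every sample, wherever it sits
in the patient → primary → secondary forest, must be explained by subsets
of one `C`. The stricter reading — detected assignments nested along
every transplant edge, `A(child) ⊆ A(parent)` — is available as
`Options(strict_lineage=True)` but is **off** by default: detection
censoring means a clone can expand from sub-threshold to detectable
across a passage, so strict nesting of detected assignments declares
genuinely observed disappear/re-appear patterns impossible. In strict
mode, constraints are folded down the lineage and contradictions are
reported as infeasibility certificates naming the binding sample and
events.

## Phylogenies and hierarchies

`check_phylogeny` builds the rooted clone tree from a laminar family:
events with identical carrier sets are gained on one edge (their relative
order is not identifiable), ancestors are materialized only where
branches diverge, the root carries no events, and crossing carrier sets
raise a certificate naming the two events. `order_events` orders events
by carrier containment (A before B iff every carrier of B carries A,
strictly somewhere); UNKNOWN cells are excluded from both sides so
missing data cannot fabricate order, and the relation is transitively
closed. `build_hierarchy` joins per-timepoint clone sets (diagnosis /
remission / relapse) over the shared catalog: shared events become common
ancestors, private events branches. Newick output annotates gained events
in `[&gained=...]` comment blocks and is parseable by standard readers
(round-tripped against dendropy in tests); DOT export serves figures.

## Synthetic cohorts

The generator emulates the study design: a random clone tree whose
branches each gain one FIRST_HIT at a fresh locus (fresh breakpoints;
distinct loci live on distinct chromosomes) and, with probability
`p_second_hit` (default 0.3), complete an ancestral het deletion as
HOM_DEL or CNLOH (equiprobable) with breakpoints nested in the parent
segment. Diagnostic clone frequencies are Dirichlet(concentration = 1);
each transplant is a single multinomial bottleneck of `bottleneck_cells`
cells from its inoculum — 2 × 10⁵ by default, the injected dose in the
emulated design — with `n_primary = 3` primaries and `n_secondary = 2`
secondaries per primary. No within-mouse growth dynamics are modelled:
one multinomial per passage is the minimal mechanism producing mosaicism,
clone dropout and sub-threshold clones expanding into detectability.
Detection censors the summed carrier fraction `f` per (sample, event):
ABSENT if `f ≤ θ_a`, CLONAL if `f ≥ θ_c`, else SUBCLONAL, with defaults
`θ_a = 0.05`, `θ_c = 0.95` as a stand-in for SNP-array sensitivity (no
quantitative limit is published for the arrays; thresholds are config,
never hard-coded). Randomness flows from one seed through per-stage
`SeedSequence` sub-streams; identical config gives bit-identical files.

What the generator does **not** emulate: within-mouse selection and
growth, immunophenotype sorting, chemotherapy, array noise beyond
thresholding, and genotype–phenotype segregation (a phenotype label would
be inert metadata). Passing recovery tests therefore show correctness of
the inference under the stated sampling model, not robustness to
real-array artefacts.

## Recovery, identifiability and the censoring bias

The true clone set always explains its own censored read-out, so the
inferred minimum never exceeds the truth on feasible cohorts; exact
recovery additionally needs every clone to be *pinned* — reaching
fraction ≥ θ_c in some sample in which every event it lacks stays
≤ θ_a — because otherwise distinct mixtures are observationally
equivalent (a root clone plus two sibling clones whose events are
subclonal everywhere is explained by two clones). `truth_identifiable`
implements this predicate; recovery tests condition on it and use 1-cell
bottlenecks (near-monoclonal mice) so that pinning occurs at a useful
rate. On pinned cohorts the reported interval always contains the truth,
and collapses onto it under perfect detection.

Raising θ_a (worse sensitivity) biases the count **downward overall** — a
clone kept sub-threshold everywhere can never be demanded — but is *not*
pointwise monotone: hardening one sample's SUBCLONAL call into ABSENT
while the event stays detected elsewhere adds a no-carrier constraint
that can split clone-sharing and raise the minimum (verified against the
exhaustive oracle; in the observed cases the raised minimum moved toward,
never past, the true count). The test suite asserts the downward
tendency mechanisms and records the pointwise non-monotonicity as a known
property of the call semantics.

## Numerical and degenerate-input choices

Threshold comparisons are inclusive (`f ≤ θ_a`, `f ≥ θ_c`); frequencies
are exact multiples of 1/bottleneck in mice, so boundary behaviour is
deterministic. A matrix with no informative calls yields the trivial
one-clone (unaltered ancestor) solution. Ties everywhere — pool order,
co-minimal solutions, resolution order, child order in trees, Newick and
JSON output — are broken lexicographically for reproducible artifacts.
Caps (clone count 64, resolutions 10,000, per-ambiguity partitions 64,
per-sample free events 16, solution list 5,000) are configuration, and
exceeding any of them raises a distinct, loud error.

## Problem sizes used in the shipped analyses

Built-in cohorts: 3–11 samples, 1–8 events (the complex stand-in: 11
samples, 8 events, 80 resolutions). Oracle cross-checks: 200 random
cohorts with ≤ 6 events and ≤ 5 samples. Recovery: 100 pinned cohorts of
4 true clones over 17 samples each, plus 30 under perfect detection.
Threshold sweeps: 20 default-condition cohorts × 5 thresholds. These
sizes keep the full analysis within about a minute on one CPU while
exercising every code path; all scale knobs are public configuration.
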