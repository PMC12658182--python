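"""Minimal-clone *range* over ambiguous readings of a complex cohort.

The synthetic stand-in cohort carries three breakpoint-nested chromosome 9
heterozygous deletions, a homozygous loss and a cnLOH whose parentage is
ambiguous, plus a breakpoint-wobbled deletion that may or may not be a
distinct event.  Every consistent reading (resolution) of these ambiguities
is enumerated and minimized separately; the spread of minima is the
headline range.
"""

from mosaiclone import minimal_clone_range
from mosaiclone.datasets import patient2_like_cohort

harm, manifest, matrix = patient2_like_cohort()
print(f"samples: {len(matrix.samples)}, events: {len(matrix.events)}")
print(f"merge ambiguities: {len(harm.merge_ambiguities)}, "
      f"link ambiguities: {len(harm.link_ambiguities)}")

result = minimal_clone_range(matrix, harmonization=harm)
feasible = [t for t in result.table if t.minimum is not None]
print(f"resolutions: {len(result.table)} enumerated, {len(feasible)} supported by the data")
print(f"minimal diagnostic clones: {result.minimum}-{result.maximum}")
for t in feasible:
    links = {s: p for s, p in t.resolution.link_choices}
    merged = [b for ch in t.resolution.merge_choices for b in ch if len(b) > 1]
    merge_note = f", merging {merged}" if merged else ", no merges"
    print(f"  second-hit parents {links}{merge_note}: minimum {t.minimum} "
          f"({t.n_cominimal} co-minimal sets)")

# Each feasible reading assigns the homozygous-deletion and cnLOH second
# hits to one of the nested het deletions and decides whether the wobbled
# breakpoints are one event or two; readings contradicted by the perfect-
# phylogeny model are discarded.  The printed range is the number of clones
# that must have coexisted at diagnosis under the most parsimonious and the
# least parsimonious supported reading.
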