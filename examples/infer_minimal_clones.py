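"""Minimal diagnostic clone counts on two small cohorts.

Builds a stable single-clone cohort and a mosaic three-sample toy, runs the
exact minimal clone-set search on each and prints the resulting counts,
clone genotypes and phylogeny.
"""

from mosaiclone import minimal_clone_set, newick_string
from mosaiclone.datasets import monoclonal_cohort, mosaic_toy_matrix

for name, matrix in [
    ("stable single-clone cohort", monoclonal_cohort()),
    ("mosaic three-sample toy", mosaic_toy_matrix()),
]:
    result = minimal_clone_set(matrix)
    print(f"== {name} ==")
    print(f"samples: {len(matrix.samples)}, events: {matrix.event_ids}")
    print(f"minimal diagnostic clones: {result.minimum} "
          f"({len(result.solutions)} co-minimal clone set(s))")
    best = result.solutions[0]
    for i, clone in enumerate(best.clones, 1):
        print(f"  C{i}: {sorted(clone.events) or '(unaltered ancestor)'}")
    print(f"phylogeny: {newick_string(best.tree)}")
    print()

# The minimum is the smallest number of clones that must already have
# coexisted in the diagnostic sample to explain every transplant read-out
# under a no-new-mutation, perfect-phylogeny model: mosaicism (a SUBCLONAL
# call) forces carrier and non-carrier clones to coexist, which is why the
# toy needs two clones while the stable cohort needs one.
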