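# mosaiclone

Clonal deconvolution from copy-number-alteration (CNA) mosaicism across
serially xenotransplanted leukaemia samples.

## The problem

SNP arrays on a patient's diagnostic bone-marrow sample and on the bone
marrow of serially transplanted immunodeficient mice report, per sample,
which CNAs (deletions, amplifications, copy-neutral LOH) are **clonal**
(in essentially all cells), **subclonal** (mosaic: carriers and
non-carriers coexist) or **absent**. Transplantation acts as a bottleneck
that re-samples the clonal mix, so alterations disappear and re-appear
across recipients, and a heterozygous deletion may surface with different
degrees of homozygous involvement — up to cnLOH — in different animals.

Assuming **no new mutations arise during transplantation**, every clone
read out in any xenograft must already have existed in the diagnostic
sample. `mosaiclone` answers: *what is the smallest set of diagnostic
clones that can explain every sample's read-out?* — exactly, for every
consistent reading of the SNP data, together with the clone phylogeny and
the pre-leukemic hierarchy implied by event containment. It is written for
cancer-genomics groups analysing multi-sample CNA calls from serial
transplantation or longitudinal (diagnosis / remission / relapse) designs.

## The model

Let `E` be the harmonized catalog of breakpoint-specific events and let a
clone be a subset `g ⊆ E`, subject to zygosity chains
`WT → HET_DEL → {HOM_DEL | CNLOH}`: a second hit is carried only together
with its first-hit het deletion, and the two completions of one locus are
mutually exclusive within a clone. A clone set `C` **explains** sample `s`
if some non-empty `A(s) ⊆ C` satisfies, for every event `e`:

    call(s,e) = CLONAL    ⇒  ∀ c ∈ A(s):  e ∈ c
    call(s,e) = ABSENT    ⇒  ∀ c ∈ A(s):  e ∉ c
    call(s,e) = SUBCLONAL ⇒  ∃ c,c' ∈ A(s):  e ∈ c, e ∉ c'
    call(s,e) = UNKNOWN   ⇒  no constraint

and `C` admits a perfect phylogeny — each event arises once and is never
lost, i.e. event-carrier sets over `C` are nested or disjoint (laminar).
The package minimizes `|C|` by branch-and-bound with an admissible lower
bound over a candidate-genotype lattice generated from the per-sample
constraints (provably lossless), keeping **all** co-minimal clone sets.

Because SNP arrays cannot decide whether two similar deletions in
different samples are one event or two, nor which het deletion a
homozygous/cnLOH segment completes, every such **resolution** of the
ambiguity report is enumerated and minimized separately; readings
contradicted by the model are discarded, and the spread of minima over the
surviving readings is the headline *minimal clone range*.

## Worked example

```
$ python examples/complex_cohort_range.py
samples: 11, events: 8
merge ambiguities: 1, link ambiguities: 2
resolutions: 80 enumerated, 9 supported by the data
minimal diagnostic clones: 6-7
```

The cohort (a built-in synthetic stand-in) has a clonal chr14 deletion, a
drifting chrX amplification and three breakpoint-nested chr9 het deletions
with a homozygous loss and a cnLOH of ambiguous parentage. Nine readings
of the data survive the perfect-phylogeny model; the most parsimonious
needs 6 diagnostic clones, the least parsimonious 7 — at least six clones
must already have coexisted at diagnosis.

The same analysis is available from the shell:

```
mosaiclone simulate --seed 42 --out case/          # synthetic cohort + truth
mosaiclone infer --segments case/segments.tsv \
                 --manifest case/manifest.tsv --out results/
```

`infer` writes the observation matrix (TSV/JSON), the per-resolution
table (`clone_range.json`), the representative clone × event matrix
(`clones.tsv`), the clone tree (`tree.nwk`, `tree.dot`) and a markdown
report. Exit codes: 0 ok, 2 parse error, 3 infeasible, 4 cap exceeded.

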