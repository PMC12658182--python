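"""Synthetic cohorts with the statistical structure the inference assumes.

A case is: (1) a branching clone tree whose edges gain breakpoint-specific
CNA events, including het-deletion -> {hom-deletion | cnLOH} zygosity
progressions at a locus; (2) diagnostic clone frequencies drawn from a
Dirichlet; (3) serial-transplant bottlenecks — each mouse's clone mix is a
single multinomial draw of ``bottleneck_cells`` cells from its inoculum,
which is the minimal mechanism producing mosaicism, clone dropout and
sub-threshold clones expanding into detectability; (4) detection censoring
of per-event carrier fractions into {ABSENT, SUBCLONAL, CLONAL} at the
array thresholds.

Ground truth (tree, genotypes, per-sample frequencies) is retained so that
recovery of the clone count by the enumeration module can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .genotype import CloneGenotype
from .harmonize import build_observation_matrix, harmonize_events
from .io import SegmentRecord, write_manifest, write_segments
from .phylogeny import CloneTree, check_phylogeny
from .types import (
    AlterationClass,
    Call,
    CNAEvent,
    Compartment,
    GenomicSegment,
    Host,
    ObservationMatrix,
    SampleMeta,
    Tier,
    Timepoint,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "GeneratedCase",
    "simulate_tree",
    "simulate_cohort",
    "observe",
    "generate_case",
    "truth_identifiable",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults follow the serial-transplant design: a diagnostic bulk sample,
    ``n_primary`` primary recipients each seeding ``n_secondary`` secondary
    recipients, 2e5 cells injected per transplant, and array detection
    thresholds theta_a / theta_c bracketing the mosaic (SUBCLONAL) band.
    """

    n_clones: int = 4
    n_loci: int = 8
    p_second_hit: float = 0.3
    frequency_concentration: float = 1.0
    n_primary: int = 3
    n_secondary: int = 2  # per primary mouse
    bottleneck_cells: int = 200_000
    detect_absent: float = 0.05  # theta_a: carrier fraction <= this -> ABSENT
    detect_clonal: float = 0.95  # theta_c: carrier fraction >= this -> CLONAL
    p_amplification: float = 0.2
    patient: str = "P1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValidationError("n_clones must be >= 1")
        if self.bottleneck_cells < 1:
            raise ValidationError("bottleneck_cells must be >= 1")
        if not (0 <= self.detect_absent < self.detect_clonal <= 1):
            raise ValidationError("require 0 <= detect_absent < detect_clonal <= 1")
        if self.n_loci < self.n_clones - 1:
            raise ValidationError(
                "need n_loci >= n_clones - 1 (one fresh locus per branch)"
            )
        if not (0 <= self.p_second_hit <= 1 and 0 <= self.p_amplification <= 1):
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.frequency_concentration <= 0:
            raise ValidationError("frequency_concentration must be > 0")
        if self.n_primary < 1:
            raise ValidationError("n_primary must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated cohort."""

    tree: CloneTree
    genotypes: list[CloneGenotype]
    events: list[CNAEvent]
    frequencies: dict[str, np.ndarray]  # sample_id -> clone-frequency vector
    manifest: list[SampleMeta]
    config: SimulationConfig

    @property
    def n_clones(self) -> int:
        return len(self.genotypes)


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    """Deterministic sub-streams per simulation stage (and per mouse)."""
    root = np.random.SeedSequence(config.seed)
    tree_ss, cohort_ss = root.spawn(2)
    return {"tree": np.random.default_rng(tree_ss), "cohort": np.random.default_rng(cohort_ss)}


def simulate_tree(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[CloneTree, list[CloneGenotype], list[CNAEvent]]:
    """Random clone tree: each branch gains one FIRST_HIT event at a fresh
    locus with its own breakpoints, and — if its ancestry carries a het
    deletion not yet completed — a matching SECOND_HIT (hom deletion or
    cnLOH, equiprobable) with probability ``p_second_hit``."""
    rng = rng if rng is not None else _streams(config)["tree"]
    events: list[CNAEvent] = []
    by_id: dict[str, CNAEvent] = {}
    genotypes: list[frozenset[str]] = [frozenset()]
    parents: list[int] = [-1]
    loci = list(rng.permutation(config.n_loci))
    used_breakpoints: set[tuple[str, str, int, int]] = set()

    for i in range(1, config.n_clones):
        attach = int(rng.integers(0, i))
        locus = int(loci[i - 1])
        chrom = f"chr{locus + 1}"
        is_amp = rng.random() < config.p_amplification
        start = 10_000_000 + int(rng.integers(0, 20_000_000))
        end = start + 2_000_000 + int(rng.integers(0, 13_000_000))
        tag = "amp" if is_amp else "del"
        eid = f"{tag}_{chrom}"
        ev = CNAEvent(
            event_id=eid,
            segment=GenomicSegment(chrom, start, end, genome_build="sim"),
            alteration_class=AlterationClass.AMP if is_amp else AlterationClass.DEL,
            tier=Tier.FIRST_HIT,
        )
        events.append(ev)
        by_id[eid] = ev
        used_breakpoints.add((chrom, tag, start, end))
        genotype = genotypes[attach] | {eid}

        # optional zygosity progression on an ancestral (or the fresh) het del
        open_dels = [
            e
            for e in events
            if e.event_id in genotype
            and e.tier is Tier.FIRST_HIT
            and e.alteration_class is AlterationClass.DEL
            and not any(
                x.parent_event_id == e.event_id and x.event_id in genotype
                for x in events
            )
        ]
        if open_dels and rng.random() < config.p_second_hit:
            target = open_dels[int(rng.integers(0, len(open_dels)))]
            is_cnloh = rng.random() < 0.5
            tseg = target.segment
            span = tseg.end - tseg.start
            for _ in range(100):
                s2 = tseg.start + int(rng.integers(0, max(1, span // 4)))
                e2 = tseg.end - int(rng.integers(0, max(1, span // 4)))
                tag2 = "cnloh" if is_cnloh else "homdel"
                if (tseg.chromosome, tag2, s2, e2) not in used_breakpoints:
                    break
            used_breakpoints.add((tseg.chromosome, tag2, s2, e2))
            n_prior = sum(1 for e in events if e.parent_event_id == target.event_id)
            sid = f"{tag2}_{tseg.chromosome}_{n_prior + 1}"
            sev = CNAEvent(
                event_id=sid,
                segment=GenomicSegment(tseg.chromosome, s2, e2, genome_build="sim"),
                alteration_class=AlterationClass.CNLOH if is_cnloh else AlterationClass.DEL,
                tier=Tier.SECOND_HIT,
                parent_event_id=target.event_id,
            )
            events.append(sev)
            by_id[sid] = sev
            genotype = genotype | {sid}

        genotypes.append(genotype)
        parents.append(attach)

    genos = [CloneGenotype(g) for g in genotypes]
    labels = {g: [f"T{i + 1}"] for i, g in enumerate(genotypes)}
    tree = check_phylogeny(genotypes, clone_labels=labels)
    return tree, genos, events


def simulate_cohort(
    config: SimulationConfig,
    n_clones: int,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, np.ndarray], list[SampleMeta]]:
    """Clone frequencies per sample under the serial-transplant design.

    Diagnostic frequencies ~ Dirichlet(concentration); every transplant is a
    single multinomial bottleneck of ``bottleneck_cells`` cells from its
    inoculum's frequencies.  Clones absent from a mouse stay absent in all
    its secondaries (lineage containment by construction)."""
    rng = rng if rng is not None else _streams(config)["cohort"]
    freqs: dict[str, np.ndarray] = {}
    manifest: list[SampleMeta] = []

    diag = rng.dirichlet(np.full(n_clones, config.frequency_concentration))
    freqs["DX"] = diag
    manifest.append(
        SampleMeta(
            sample_id="DX",
            patient=config.patient,
            timepoint=Timepoint.DIAGNOSIS,
            compartment=Compartment.BULK,
            host=Host.PATIENT,
        )
    )
    for i in range(1, config.n_primary + 1):
        mid = f"M{i}"
        counts = rng.multinomial(config.bottleneck_cells, diag)
        freqs[mid] = counts / config.bottleneck_cells
        manifest.append(
            SampleMeta(
                sample_id=mid,
                patient=config.patient,
                timepoint=Timepoint.DIAGNOSIS,
                compartment=Compartment.BULK,
                host=Host.PRIMARY_XENO,
                parent_sample="DX",
            )
        )
        for j in range(1, config.n_secondary + 1):
            sid = f"M{i}S{j}"
            counts2 = rng.multinomial(config.bottleneck_cells, freqs[mid])
            freqs[sid] = counts2 / config.bottleneck_cells
            manifest.append(
                SampleMeta(
                    sample_id=sid,
                    patient=config.patient,
                    timepoint=Timepoint.DIAGNOSIS,
                    compartment=Compartment.BULK,
                    host=Host.SECONDARY_XENO,
                    parent_sample=mid,
                )
            )
    return freqs, manifest


def observe(
    frequencies: dict[str, np.ndarray],
    genotypes: list[CloneGenotype],
    events: list[CNAEvent],
    manifest: list[SampleMeta],
    config: SimulationConfig,
) -> ObservationMatrix:
    """Censor carrier fractions into calls: per sample and event, the summed
    frequency f of carrier clones gives ABSENT if f <= theta_a, CLONAL if
    f >= theta_c, SUBCLONAL otherwise."""
    rows: dict[str, dict[str, Call]] = {}
    for s in manifest:
        f = frequencies[s.sample_id]
        if abs(float(np.sum(f)) - 1.0) > 1e-9:
            raise ValidationError(f"sample {s.sample_id}: frequencies do not sum to 1")
        row = {}
        for e in events:
            carrier = sum(
                float(f[k]) for k, g in enumerate(genotypes) if g.carries(e.event_id)
            )
            if carrier <= config.detect_absent:
                row[e.event_id] = Call.ABSENT
            elif carrier >= config.detect_clonal:
                row[e.event_id] = Call.CLONAL
            else:
                row[e.event_id] = Call.SUBCLONAL
        rows[s.sample_id] = row
    return ObservationMatrix.from_rows(list(manifest), list(events), rows)


@dataclass
class GeneratedCase:
    segments_path: Path
    manifest_path: Path
    truth_path: Path
    matrix: ObservationMatrix
    truth: SyntheticTruth


def _truth_json(truth: SyntheticTruth) -> dict:
    return {
        "config": dataclasses.asdict(truth.config),
        "n_clones": truth.n_clones,
        "genotypes": [sorted(g.events) for g in truth.genotypes],
        "events": [
            {
                "event_id": e.event_id,
                "chromosome": e.segment.chromosome,
                "start": e.segment.start,
                "end": e.segment.end,
                "class": e.alteration_class.value,
                "tier": e.tier.value,
                "parent": e.parent_event_id,
            }
            for e in truth.events
        ],
        "frequencies": {s: [float(x) for x in v] for s, v in truth.frequencies.items()},
        "tree": truth.tree.to_json(),
    }


def simulate_case(config: SimulationConfig) -> tuple[ObservationMatrix, SyntheticTruth]:
    """In-memory end of :func:`generate_case` (no files written)."""
    streams = _streams(config)
    tree, genotypes, events = simulate_tree(config, rng=streams["tree"])
    frequencies, manifest = simulate_cohort(config, len(genotypes), rng=streams["cohort"])
    matrix = observe(frequencies, genotypes, events, manifest, config)
    truth = SyntheticTruth(
        tree=tree,
        genotypes=genotypes,
        events=events,
        frequencies=frequencies,
        manifest=manifest,
        config=config,
    )
    return matrix, truth


def _segment_records(matrix: ObservationMatrix) -> list[SegmentRecord]:
    """Detected-only segment rows in the reader's input format."""
    records = []
    by_id = {e.event_id: e for e in matrix.events}
    for s in matrix.samples:
        for eid in matrix.event_ids:
            call = matrix.calls.at[s.sample_id, eid]
            if call in (Call.ABSENT, Call.UNKNOWN):
                continue
            e = by_id[eid]
            if e.alteration_class is AlterationClass.DEL:
                zyg = "hom" if e.tier is Tier.SECOND_HIT else "het"
            else:
                zyg = "na"
            records.append(
                SegmentRecord(
                    sample_id=s.sample_id,
                    segment=e.segment,
                    alteration_class=e.alteration_class,
                    zygosity=zyg,
                    status=call,
                )
            )
    return records


def generate_case(
    config: SimulationConfig, out_dir: Union[str, Path]
) -> GeneratedCase:
    """Simulate one cohort and write it in the package's input formats:
    segments.tsv + manifest.tsv (pipeline inputs) and truth.json
    (ground truth for scoring)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_case(config)
    seg_path, man_path, truth_path = (
        out / "segments.tsv",
        out / "manifest.tsv",
        out / "truth.json",
    )
    write_segments(_segment_records(matrix), seg_path)
    write_manifest(truth.manifest, man_path)
    truth_path.write_text(json.dumps(_truth_json(truth), indent=1) + "\n")
    return GeneratedCase(
        segments_path=seg_path,
        manifest_path=man_path,
        truth_path=truth_path,
        matrix=matrix,
        truth=truth,
    )


def truth_identifiable(truth: SyntheticTruth) -> bool:
    """True when every clone's genotype is pinned by some sample: the clone
    reaches clonal dominance (fraction >= theta_c) in a sample where every
    event it lacks falls below the absence threshold.  On such cohorts the
    minimal clone count recovers the true count exactly."""
    cfg = truth.config
    for k, g in enumerate(truth.genotypes):
        pinned = False
        for sid, f in truth.frequencies.items():
            if float(f[k]) < cfg.detect_clonal:
                continue
            other = [
                sum(float(f[j]) for j, h in enumerate(truth.genotypes) if h.carries(e.event_id))
                for e in truth.events
                if not g.carries(e.event_id)
            ]
            if all(x <= cfg.detect_absent for x in other):
                pinned = True
                break
        if not pinned:
            return False
    return True
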