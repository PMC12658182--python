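"""Readers and writers for segment tables, manifests and observation matrices.

Input tables are plain TSV with a header row; lines starting with ``#`` are
ignored.  Internally all coordinates are 0-based half-open; SNP-array exports
are commonly 1-based inclusive, which the reader accepts via a dialect flag.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

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
    validate_lineage,
)

__all__ = [
    "SegmentRecord",
    "Dialect",
    "ParseError",
    "read_segments",
    "write_segments",
    "read_manifest",
    "write_manifest",
    "write_matrix_tsv",
    "write_matrix_json",
    "read_matrix_json",
    "load_config",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass(frozen=True)
class Dialect:
    """Table conventions.

    one_based_inclusive
        If True, input coordinates are 1-based inclusive (common for
        SNP-array exports) and are converted to 0-based half-open on read;
        writers convert back symmetrically.
    """

    one_based_inclusive: bool = False
    genome_build: str = "unspecified"


@dataclass(frozen=True)
class SegmentRecord:
    """One row of a segment-call table."""

    sample_id: str
    segment: GenomicSegment
    alteration_class: AlterationClass
    zygosity: str  # "het" | "hom" | "na"
    status: Call


_STATUS_TOKENS = {
    "absent": Call.ABSENT,
    "subclonal": Call.SUBCLONAL,
    "mosaic": Call.SUBCLONAL,
    "clonal": Call.CLONAL,
    "unknown": Call.UNKNOWN,
    "na": Call.UNKNOWN,
}

_ZYGOSITY_TOKENS = {"het", "hom", "na", "-", ""}

_SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "class", "zygosity", "status"]


def _rows(path: Union[str, Path]):
    """Yield (line_number, fields) for non-comment, non-blank TSV lines."""
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            if all(not f.strip() for f in row):
                continue
            yield lineno, [f.strip() for f in row]


def read_segments(
    path: Union[str, Path], dialect: Dialect = Dialect()
) -> list[SegmentRecord]:
    """Read a per-sample CNA segment-call table.

    Required header columns: sample, chrom, start, end, class, zygosity,
    status (order free, extra columns ignored).
    """
    rows = _rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise ParseError(f"{path}: empty file")
    cols = [c.lower() for c in header]
    missing = [c for c in _SEGMENT_COLUMNS if c not in cols]
    if missing:
        raise ParseError(f"{path}:{header_lineno}: missing columns {missing}")
    idx = {c: cols.index(c) for c in _SEGMENT_COLUMNS}

    records = []
    for lineno, row in rows:
        if len(row) < len(cols):
            raise ParseError(f"{path}:{lineno}: expected {len(cols)} fields, got {len(row)}")
        try:
            start = int(row[idx["start"]])
            end = int(row[idx["end"]])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates")
        if dialect.one_based_inclusive:
            start -= 1
        cls_token = row[idx["class"]].upper()
        try:
            alteration = AlterationClass(cls_token)
        except ValueError:
            raise ValidationError(f"{path}:{lineno}: unknown alteration class {cls_token!r}")
        status_token = row[idx["status"]].lower()
        if status_token not in _STATUS_TOKENS:
            raise ValidationError(f"{path}:{lineno}: unknown status token {row[idx['status']]!r}")
        zygosity = row[idx["zygosity"]].lower()
        if zygosity not in _ZYGOSITY_TOKENS:
            raise ValidationError(f"{path}:{lineno}: unknown zygosity {row[idx['zygosity']]!r}")
        try:
            segment = GenomicSegment(
                chromosome=row[idx["chrom"]],
                start=start,
                end=end,
                genome_build=dialect.genome_build,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}")
        records.append(
            SegmentRecord(
                sample_id=row[idx["sample"]],
                segment=segment,
                alteration_class=alteration,
                zygosity=zygosity if zygosity in {"het", "hom"} else "na",
                status=_STATUS_TOKENS[status_token],
            )
        )
    return records


def write_segments(
    records: list[SegmentRecord],
    path: Union[str, Path],
    dialect: Dialect = Dialect(),
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_SEGMENT_COLUMNS)
        for r in records:
            start = r.segment.start + (1 if dialect.one_based_inclusive else 0)
            w.writerow(
                [
                    r.sample_id,
                    r.segment.chromosome,
                    start,
                    r.segment.end,
                    r.alteration_class.value,
                    r.zygosity,
                    r.status.value.lower(),
                ]
            )


_MANIFEST_COLUMNS = ["sample_id", "patient", "timepoint", "compartment", "host", "parent_sample"]


def read_manifest(path: Union[str, Path]) -> list[SampleMeta]:
    """Read the sample manifest encoding patient, timepoint, compartment and
    transplant lineage.  Optional column ``assayed`` (true/false) marks
    samples lacking SNP-array data."""
    rows = _rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise ParseError(f"{path}: empty file")
    cols = [c.lower() for c in header]
    missing = [c for c in _MANIFEST_COLUMNS if c not in cols]
    if missing:
        raise ParseError(f"{path}:{header_lineno}: missing columns {missing}")
    idx = {c: cols.index(c) for c in cols}

    samples = []
    for lineno, row in rows:
        if len(row) < len(cols):
            raise ParseError(f"{path}:{lineno}: expected {len(cols)} fields, got {len(row)}")
        parent = row[idx["parent_sample"]]
        parent = None if parent in {"", "-", "NA", "na", "none"} else parent
        assayed = True
        if "assayed" in idx:
            assayed = row[idx["assayed"]].lower() not in {"false", "0", "no"}
        try:
            samples.append(
                SampleMeta(
                    sample_id=row[idx["sample_id"]],
                    patient=row[idx["patient"]],
                    timepoint=Timepoint(row[idx["timepoint"]].upper()),
                    compartment=Compartment(row[idx["compartment"]].upper()),
                    host=Host(row[idx["host"]].upper()),
                    parent_sample=parent,
                    assayed=assayed,
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}")
    validate_lineage(samples)
    return samples


def write_manifest(samples: list[SampleMeta], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_MANIFEST_COLUMNS + ["assayed"])
        for s in samples:
            w.writerow(
                [
                    s.sample_id,
                    s.patient,
                    s.timepoint.value,
                    s.compartment.value,
                    s.host.value,
                    s.parent_sample or "-",
                    "true" if s.assayed else "false",
                ]
            )


# -- observation-matrix serialization -----------------------------------------


def write_matrix_tsv(matrix: ObservationMatrix, path: Union[str, Path]) -> None:
    """Samples x events call table (human-readable; metadata goes to JSON)."""
    out = matrix.calls.map(lambda c: c.value)
    out.to_csv(path, sep="\t", index_label="sample_id")


def _segment_to_json(seg: GenomicSegment) -> dict:
    return {
        "chromosome": seg.chromosome,
        "start": seg.start,
        "end": seg.end,
        "genome_build": seg.genome_build,
    }


def write_matrix_json(matrix: ObservationMatrix, path: Union[str, Path]) -> None:
    payload = {
        "samples": [
            {
                "sample_id": s.sample_id,
                "patient": s.patient,
                "timepoint": s.timepoint.value,
                "compartment": s.compartment.value,
                "host": s.host.value,
                "parent_sample": s.parent_sample,
                "assayed": s.assayed,
            }
            for s in matrix.samples
        ],
        "events": [
            {
                "event_id": e.event_id,
                "segment": _segment_to_json(e.segment),
                "alteration_class": e.alteration_class.value,
                "tier": e.tier.value,
                "parent_event_id": e.parent_event_id,
            }
            for e in matrix.events
        ],
        "calls": {
            s: {e: matrix.calls.at[s, e].value for e in matrix.event_ids}
            for s in matrix.sample_ids
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=False)
        fh.write("\n")


def read_matrix_json(path: Union[str, Path]) -> ObservationMatrix:
    with open(path) as fh:
        payload = json.load(fh)
    samples = [
        SampleMeta(
            sample_id=s["sample_id"],
            patient=s["patient"],
            timepoint=Timepoint(s["timepoint"]),
            compartment=Compartment(s["compartment"]),
            host=Host(s["host"]),
            parent_sample=s["parent_sample"],
            assayed=s["assayed"],
        )
        for s in payload["samples"]
    ]
    events = [
        CNAEvent(
            event_id=e["event_id"],
            segment=GenomicSegment(**e["segment"]),
            alteration_class=AlterationClass(e["alteration_class"]),
            tier=Tier(e["tier"]),
            parent_event_id=e["parent_event_id"],
        )
        for e in payload["events"]
    ]
    rows = {
        s: {e: Call(v) for e, v in row.items()} for s, row in payload["calls"].items()
    }
    return ObservationMatrix.from_rows(samples, events, rows)


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML run configuration (tolerances, dialect, caps, thresholds)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return cfg
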