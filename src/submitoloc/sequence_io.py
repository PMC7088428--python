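"""FASTA/label-table I/O, dataset-curation filters and redundancy reduction.

The curation chain mirrors the screening applied to localization-annotated
database exports: drop records whose free-text annotation is hedged
("probable", "by similarity", ...), records annotated with more than one
compartment, short sequences, and sequences containing non-standard
residues; finally cap pairwise sequence identity with a greedy,
longest-first clustering so no two retained sequences exceed the identity
threshold (CD-HIT-style, but self-contained via global alignment).

Taxonomic screening (e.g. restricting to non-plant eukaryotes) is out of
scope here: plain FASTA carries no taxonomy, so that filter is the caller's
responsibility upstream of this module.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .constants import AMINO_ACIDS, CLASSES, CLASS_KEYWORDS

DEFAULT_MIN_LENGTH = 80
DEFAULT_AMBIGUITY_KEYWORDS = ("possible", "probable", "by similarity", "potential")
DEFAULT_IDENTITY_THRESHOLD = 0.70

# Filter names, in application order; each removed record is charged to the
# first filter it fails.
FILTER_ORDER = (
    "ambiguous_annotation",
    "multiple_locations",
    "short_sequence",
    "nonstandard_residue",
)


@dataclass
class ProteinRecord:
    """One protein sequence with optional annotation text and class label."""

    id: str
    sequence: str
    annotation: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(
                f"record {self.id!r}: unknown class label {self.label!r}; "
                f"expected one of {', '.join(CLASSES)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CurationReport:
    """Outcome of the curation filter chain, with per-filter removal counts."""

    input_count: int
    removed_by_filter: dict[str, int]
    retained: list[ProteinRecord] = field(repr=False)

    def __post_init__(self) -> None:
        total = len(self.retained) + sum(self.removed_by_filter.values())
        if total != self.input_count:
            raise ValueError(
                f"curation counts do not conserve input: {self.input_count} in, "
                f"{total} accounted for"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_count": self.input_count,
                "removed_by_filter": self.removed_by_filter,
                "retained_count": len(self.retained),
                "retained_ids": [r.id for r in self.retained],
            },
            indent=2,
        )


def _parse_header_label(description: str) -> str | None:
    """Extract a ``loc=<class>`` token from a FASTA description line."""
    for token in description.split():
        if token.startswith("loc="):
            value = token[len("loc="):]
            if value not in CLASSES:
                raise ValueError(
                    f"unknown label {value!r} in FASTA header; "
                    f"expected one of {', '.join(CLASSES)}"
                )
            return value
    return None


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, class) TSV into a mapping, validating classes."""
    labels: dict[str, str] = {}
    with open(path, newline="") as handle:
        for row_num, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: line {row_num}: expected 2 columns")
            rec_id, label = row[0].strip(), row[1].strip()
            if label not in CLASSES:
                raise ValueError(
                    f"{path}: line {row_num}: unknown label {label!r}; "
                    f"expected one of {', '.join(CLASSES)}"
                )
            labels[rec_id] = label
    return labels


def write_label_table(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for rec in records:
            if rec.label is not None:
                writer.writerow([rec.id, rec.label])


def read_fasta(
    path: str | Path,
    label_table: str | Path | None = None,
) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved.

    Labels are attached from ``label_table`` (two-column TSV) when given,
    otherwise from a ``loc=<class>`` token in the header description; records
    without a resolvable label stay unlabelled.

    Raises ``ValueError`` on text before the first header (with the line
    number), duplicate ids, or unrecognized label strings.
    """
    path = Path(path)
    with open(path) as handle:
        for line_num, line in enumerate(handle, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {line_num}: expected FASTA header '>', "
                    f"got {line.strip()[:30]!r}"
                )
            break
        else:
            return []

    labels = read_label_table(label_table) if label_table is not None else {}

    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        seen[seq_rec.id] = seen.get(seq_rec.id, 0) + 1
        label = labels.get(seq_rec.id)
        if label is None:
            label = _parse_header_label(seq_rec.description)
        annotation = seq_rec.description[len(seq_rec.id):].strip()
        records.append(
            ProteinRecord(
                id=seq_rec.id,
                sequence=str(seq_rec.seq).upper(),
                annotation=annotation,
                label=label,
            )
        )
    duplicates = sorted(rec_id for rec_id, n in seen.items() if n > 1)
    if duplicates:
        raise ValueError(f"{path}: duplicate record ids: {', '.join(duplicates)}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.id}"
            if rec.label is not None:
                header += f" loc={rec.label}"
            handle.write(header + "\n")
            for start in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[start:start + width] + "\n")


def _mentions_multiple_locations(annotation: str) -> bool:
    text = annotation.lower()
    hits = 0
    for keywords in CLASS_KEYWORDS.values():
        if any(kw in text for kw in keywords):
            hits += 1
    return hits > 1


def curate(
    records: Sequence[ProteinRecord],
    min_length: int = DEFAULT_MIN_LENGTH,
    annotation_keywords: Sequence[str] = DEFAULT_AMBIGUITY_KEYWORDS,
    allowed_alphabet: str = AMINO_ACIDS,
) -> CurationReport:
    """Apply the curation filter chain; total (never raises on records).

    Filters, in order: ambiguous-annotation keywords (case-insensitive
    substring), multiple-location annotation, minimum length, standard
    alphabet. Each removed record counts against the first filter it fails.
    """
    keywords = tuple(kw.lower() for kw in annotation_keywords)
    allowed = frozenset(allowed_alphabet)
    removed = {name: 0 for name in FILTER_ORDER}
    retained: list[ProteinRecord] = []
    for rec in records:
        annotation = rec.annotation.lower()
        if any(kw in annotation for kw in keywords):
            removed["ambiguous_annotation"] += 1
        elif _mentions_multiple_locations(rec.annotation):
            removed["multiple_locations"] += 1
        elif len(rec.sequence) < min_length:
            removed["short_sequence"] += 1
        elif not set(rec.sequence) <= allowed:
            removed["nonstandard_residue"] += 1
        else:
            retained.append(rec)
    return CurationReport(
        input_count=len(records),
        removed_by_filter=removed,
        retained=retained,
    )


def _make_aligner() -> PairwiseAligner:
    # Global alignment scoring fixed by convention: match 1, mismatch 0,
    # linear gap -1; identity = matches / alignment columns.
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def alignment_identity(seq_a: str, seq_b: str, aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment identity: identical columns / alignment length."""
    if aligner is None:
        aligner = _make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def reduce_redundancy(
    records: Sequence[ProteinRecord],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> list[ProteinRecord]:
    """Greedy longest-first identity clustering; returns representatives.

    Records are visited longest first (length ties broken by id); a record
    joins the first existing representative it exceeds ``identity_threshold``
    global-alignment identity with, else becomes a new representative.
    Deterministic for a given input set.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}"
        )
    aligner = _make_aligner()
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    representatives: list[ProteinRecord] = []
    for rec in ordered:
        for rep in representatives:
            if alignment_identity(rec.sequence, rep.sequence, aligner) > identity_threshold:
                break
        else:
            representatives.append(rec)
    return representatives
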