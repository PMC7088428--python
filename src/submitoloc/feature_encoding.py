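"""The 239-dimensional sequence feature vector, in four named blocks.

Block layout (order fixed, residue order alphabetical A..Y throughout):

``ccd`` (60)
    Per amino acid: Composition (frequency n_a/L), Centroid (mean 1-based
    occurrence position / L; 0 when absent) and Distribution (population
    standard deviation of the normalized positions; 0 when the residue
    occurs at most once). 20 + 20 + 20 values.

``saac`` (60)
    Split amino-acid composition: the sequence is cut into three
    near-equal parts at floor(L/3) and floor(2L/3); each part contributes
    its own 20-residue composition, concatenated N- to C-terminal.

``fg_sse`` (88)
    Functional-group, short-peptide and secondary-structure features:
    17 global group frequencies (10 functional + 7 physico-chemical);
    5 short-peptide class frequencies from sliding length-10 windows
    classified by strict-majority residue class (ties -> unclassified);
    3 H/E/C content fractions; 51 per-state group frequencies (17 groups
    x 3 states, normalized within each state, 0 when a state is absent);
    12 per-state short-peptide frequencies (hydrophobic / hydrophilic /
    polar / non-polar x 3 states, a window carrying the state of its
    central residue). 17 + 5 + 3 + 51 + 12 = 88. The decomposition is this
    package's fixed convention for the published sub-counts.

``physchem`` (31)
    Sequence means of 31 per-residue physico-chemical scales.

Group memberships and scales live in TSV resources (``groups.tsv``,
``physchem_scales.tsv``) and can be overridden, never hard-coded here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .constants import AMINO_ACIDS, AA_INDEX
from .secondary_structure import SSEAssignment, assign_sse
from .sequence_io import ProteinRecord

BLOCK_LAYOUT = {"ccd": 60, "saac": 60, "fg_sse": 88, "physchem": 31}
N_FEATURES = sum(BLOCK_LAYOUT.values())  # 239

DEFAULT_PEPTIDE_WINDOW = 10
# Window classes used by the per-state short-peptide sub-block (the global
# sub-block uses all five classes including 'neutral').
PER_STATE_PEPTIDE_CLASSES = ("hydrophobic", "hydrophilic", "polar", "nonpolar")
SSE_STATES = ("H", "E", "C")


@dataclass(frozen=True)
class GroupingScheme:
    """Named residue groupings: 10 functional, 7 physico-chemical, 5 peptide."""

    functional_groups: dict[str, frozenset[str]]
    physchem_groups: dict[str, frozenset[str]]
    peptide_classes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if len(self.functional_groups) != 10:
            raise ValueError(
                f"expected 10 functional groups, got {len(self.functional_groups)}"
            )
        if len(self.physchem_groups) != 7:
            raise ValueError(
                f"expected 7 physico-chemical groups, got {len(self.physchem_groups)}"
            )
        for category, groups in (
            ("functional", self.functional_groups),
            ("physchem", self.physchem_groups),
        ):
            covered = frozenset().union(*groups.values())
            missing = set(AMINO_ACIDS) - covered
            if missing:
                raise ValueError(
                    f"{category} groups do not cover residues {sorted(missing)}"
                )

    @property
    def all_groups(self) -> dict[str, frozenset[str]]:
        """The 17 group sets in feature order (functional then physchem)."""
        merged = {f"fg.{k}": v for k, v in self.functional_groups.items()}
        merged.update({f"pc.{k}": v for k, v in self.physchem_groups.items()})
        return merged


@dataclass(frozen=True)
class PhyschemScales:
    """Ordered per-residue numeric scales (AAindex-style), 31 by default."""

    scales: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for name, mapping in self.scales.items():
            missing = set(AMINO_ACIDS) - set(mapping)
            if missing:
                raise ValueError(
                    f"scale {name!r} missing residues {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.scales)

    @property
    def names(self) -> list[str]:
        return list(self.scales)


@dataclass(frozen=True)
class FeatureVector:
    """A 239-float encoding of one sequence, addressable by block name."""

    values: np.ndarray = field(repr=False)
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != (N_FEATURES,):
            raise ValueError(
                f"expected {N_FEATURES} features, got {self.values.shape}"
            )

    def block(self, name: str) -> np.ndarray:
        start = 0
        for block_name, size in BLOCK_LAYOUT.items():
            if block_name == name:
                return self.values[start:start + size]
            start += size
        raise KeyError(f"unknown block {name!r}; known: {list(BLOCK_LAYOUT)}")


def _read_resource(name: str, path: str | Path | None) -> list[list[str]]:
    if path is None:
        text = resources.files("submitoloc.data").joinpath(name).read_text()
    else:
        text = Path(path).read_text()
    return [
        row
        for row in csv.reader(text.splitlines(), delimiter="\t")
        if row and not row[0].startswith("#")
    ]


def load_grouping_scheme(path: str | Path | None = None) -> GroupingScheme:
    rows = _read_resource("groups.tsv", path)
    header, *body = rows
    categories: dict[str, dict[str, frozenset[str]]] = {
        "functional": {},
        "physchem": {},
        "peptide": {},
    }
    for category, name, members in body:
        categories[category][name] = frozenset(members)
    return GroupingScheme(
        functional_groups=categories["functional"],
        physchem_groups=categories["physchem"],
        peptide_classes=categories["peptide"],
    )


def load_physchem_scales(path: str | Path | None = None) -> PhyschemScales:
    rows = _read_resource("physchem_scales.tsv", path)
    header, *body = rows
    residues = header[1:]
    scales = {
        row[0]: dict(zip(residues, map(float, row[1:])))
        for row in body
    }
    return PhyschemScales(scales=scales)


_DEFAULT_SCHEME: GroupingScheme | None = None
_DEFAULT_SCALES: PhyschemScales | None = None


def default_grouping_scheme() -> GroupingScheme:
    global _DEFAULT_SCHEME
    if _DEFAULT_SCHEME is None:
        _DEFAULT_SCHEME = load_grouping_scheme()
    return _DEFAULT_SCHEME


def default_physchem_scales() -> PhyschemScales:
    global _DEFAULT_SCALES
    if _DEFAULT_SCALES is None:
        _DEFAULT_SCALES = load_physchem_scales()
    return _DEFAULT_SCALES


def _check_alphabet(sequence: str) -> None:
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"nonstandard residues in sequence: {sorted(bad)}")


def _composition(sequence: str) -> np.ndarray:
    counts = np.zeros(20)
    for aa in sequence:
        counts[AA_INDEX[aa]] += 1
    return counts / len(sequence)


def encode_ccd(sequence: str) -> np.ndarray:
    """Composition, centroid and distribution of each residue type (60)."""
    if len(sequence) < 1:
        raise ValueError("sequence must be non-empty")
    _check_alphabet(sequence)
    length = len(sequence)
    composition = _composition(sequence)
    centroid = np.zeros(20)
    distribution = np.zeros(20)
    positions: dict[str, list[int]] = {aa: [] for aa in AMINO_ACIDS}
    for pos, aa in enumerate(sequence, start=1):
        positions[aa].append(pos)
    for aa, occ in positions.items():
        idx = AA_INDEX[aa]
        if occ:
            centroid[idx] = float(np.mean(occ)) / length
        if len(occ) > 1:
            distribution[idx] = float(np.std(np.asarray(occ) / length))
    return np.concatenate([composition, centroid, distribution])


def encode_saac(sequence: str) -> np.ndarray:
    """Split amino-acid composition over three near-equal parts (60)."""
    if len(sequence) < 3:
        raise ValueError("sequence must have length >= 3 for a three-way split")
    _check_alphabet(sequence)
    length = len(sequence)
    cut1, cut2 = length // 3, (2 * length) // 3
    parts = (sequence[:cut1], sequence[cut1:cut2], sequence[cut2:])
    return np.concatenate([_composition(part) for part in parts])


def _window_class(
    window: str,
    peptide_classes: Mapping[str, frozenset[str]],
) -> str | None:
    """Classify a window by strict-majority residue class; ties -> None."""
    width = len(window)
    counts = {
        name: sum(aa in members for aa in window)
        for name, members in peptide_classes.items()
    }
    best = max(counts.values())
    if best * 2 <= width:
        return None
    winners = [name for name, n in counts.items() if n == best]
    return winners[0] if len(winners) == 1 else None


def encode_fg_sse(
    sequence: str,
    sse: SSEAssignment,
    scheme: GroupingScheme | None = None,
    peptide_window: int = DEFAULT_PEPTIDE_WINDOW,
) -> np.ndarray:
    """Functional-group, short-peptide and secondary-structure features (88)."""
    if scheme is None:
        scheme = default_grouping_scheme()
    if len(sse.states) != len(sequence):
        raise ValueError(
            f"SSE states length {len(sse.states)} != sequence length {len(sequence)}"
        )
    if len(sequence) < peptide_window:
        raise ValueError(
            f"sequence length {len(sequence)} < peptide window {peptide_window}"
        )
    _check_alphabet(sequence)
    length = len(sequence)
    groups = scheme.all_groups  # 17 ordered group sets

    # (a) 17 global group frequencies
    global_freqs = np.array(
        [sum(aa in members for aa in sequence) / length for members in groups.values()]
    )

    # (b) 5 short-peptide class frequencies over sliding length-10 windows
    n_windows = length - peptide_window + 1
    center_offset = (peptide_window - 1) // 2
    window_labels: list[str | None] = []
    window_states: list[str] = []
    for start in range(n_windows):
        window = sequence[start:start + peptide_window]
        window_labels.append(_window_class(window, scheme.peptide_classes))
        window_states.append(sse.states[start + center_offset])
    peptide_freqs = np.array(
        [
            sum(lbl == name for lbl in window_labels) / n_windows
            for name in scheme.peptide_classes
        ]
    )

    # (c) 3 SSE content fractions
    content = np.asarray(sse.content)

    # (d) 51 per-state group frequencies, normalized within each state
    state_counts = {s: sse.states.count(s) for s in SSE_STATES}
    per_state_group = np.zeros((len(groups), len(SSE_STATES)))
    for gi, members in enumerate(groups.values()):
        for si, state in enumerate(SSE_STATES):
            if state_counts[state] == 0:
                continue
            hits = sum(
                aa in members
                for aa, st in zip(sequence, sse.states)
                if st == state
            )
            per_state_group[gi, si] = hits / state_counts[state]

    # (e) 12 per-state short-peptide frequencies, normalized per state
    state_window_counts = {s: window_states.count(s) for s in SSE_STATES}
    per_state_peptide = np.zeros((len(PER_STATE_PEPTIDE_CLASSES), len(SSE_STATES)))
    for ci, cls in enumerate(PER_STATE_PEPTIDE_CLASSES):
        for si, state in enumerate(SSE_STATES):
            if state_window_counts[state] == 0:
                continue
            hits = sum(
                lbl == cls and st == state
                for lbl, st in zip(window_labels, window_states)
            )
            per_state_peptide[ci, si] = hits / state_window_counts[state]

    return np.concatenate(
        [
            global_freqs,
            peptide_freqs,
            content,
            per_state_group.ravel(),
            per_state_peptide.ravel(),
        ]
    )


def encode_physchem(sequence: str, scales: PhyschemScales | None = None) -> np.ndarray:
    """Mean of each per-residue physico-chemical scale over the sequence (31)."""
    if scales is None:
        scales = default_physchem_scales()
    if len(sequence) < 1:
        raise ValueError("sequence must be non-empty")
    _check_alphabet(sequence)
    return np.array(
        [
            float(np.mean([mapping[aa] for aa in sequence]))
            for mapping in scales.scales.values()
        ]
    )


def encode(
    record: ProteinRecord | str,
    scheme: GroupingScheme | None = None,
    scales: PhyschemScales | None = None,
    peptide_window: int = DEFAULT_PEPTIDE_WINDOW,
    sse_window: int = 5,
) -> FeatureVector:
    """Encode one sequence as the full 239-feature vector."""
    if isinstance(record, ProteinRecord):
        sequence, rec_id = record.sequence, record.id
    else:
        sequence, rec_id = record, ""
    sse = assign_sse(sequence, window=sse_window)
    values = np.concatenate(
        [
            encode_ccd(sequence),
            encode_saac(sequence),
            encode_fg_sse(sequence, sse, scheme, peptide_window),
            encode_physchem(sequence, scales),
        ]
    )
    return FeatureVector(values=values, record_id=rec_id)


def feature_names(
    scheme: GroupingScheme | None = None,
    scales: PhyschemScales | None = None,
) -> list[str]:
    """The 239 column names, in vector order."""
    if scheme is None:
        scheme = default_grouping_scheme()
    if scales is None:
        scales = default_physchem_scales()
    names: list[str] = []
    names += [f"ccd.comp.{aa}" for aa in AMINO_ACIDS]
    names += [f"ccd.centroid.{aa}" for aa in AMINO_ACIDS]
    names += [f"ccd.dist.{aa}" for aa in AMINO_ACIDS]
    for part in ("n", "m", "c"):
        names += [f"saac.{part}.{aa}" for aa in AMINO_ACIDS]
    names += [f"group.{g}" for g in scheme.all_groups]
    names += [f"peptide.{c}" for c in scheme.peptide_classes]
    names += [f"sse.content.{s}" for s in SSE_STATES]
    for g in scheme.all_groups:
        names += [f"group.{g}.{s}" for s in SSE_STATES]
    for c in PER_STATE_PEPTIDE_CLASSES:
        names += [f"peptide.{c}.{s}" for s in SSE_STATES]
    names += [f"physchem.{name}" for name in scales.names]
    if len(names) != N_FEATURES:
        raise AssertionError(f"feature naming out of sync: {len(names)}")
    return names


def encode_dataset(
    records: Sequence[ProteinRecord],
    scheme: GroupingScheme | None = None,
    scales: PhyschemScales | None = None,
    peptide_window: int = DEFAULT_PEPTIDE_WINDOW,
    sse_window: int = 5,
):
    """Encode many records into a (records x 239) pandas DataFrame.

    Row index carries record ids; a ``label`` column is appended when every
    record is labelled.
    """
    import pandas as pd

    vectors = [
        encode(rec, scheme, scales, peptide_window, sse_window) for rec in records
    ]
    frame = pd.DataFrame(
        np.vstack([v.values for v in vectors]) if vectors else np.empty((0, N_FEATURES)),
        index=[rec.id for rec in records],
        columns=feature_names(scheme, scales),
    )
    if records and all(rec.label is not None for rec in records):
        frame["label"] = [rec.label for rec in records]
    return frame
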