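"""Three-state secondary-structure assignment from Chou-Fasman propensities.

Each residue receives a helix (H), sheet (E) or coil (C) state from
window-averaged conformational propensities: a residue is helical when the
local mean helix propensity reaches the classical former threshold (1.03)
and beats the sheet average, strand when the sheet average reaches 1.05 and
beats the helix average, coil otherwise. The window mean is truncated at
the termini rather than padded, so no fictitious residues are introduced.

This is a deliberately self-contained propensity assignment -- not a
PSSM/neural predictor -- fixing the structural context the fg_sse feature
block needs without any external tool. The propensity table ships as a TSV
resource and an alternative scale (or a precomputed per-residue H/E/C
string) can be supplied instead.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import AMINO_ACIDS

DEFAULT_HELIX_THRESHOLD = 1.03
DEFAULT_SHEET_THRESHOLD = 1.05


@dataclass(frozen=True)
class SSEAssignment:
    """Per-residue H/E/C states plus the overall state fractions."""

    states: str
    content: tuple[float, float, float]  # helix, sheet, coil fractions

    def __post_init__(self) -> None:
        if set(self.states) - set("HEC"):
            raise ValueError("states must be over {H, E, C}")
        if abs(sum(self.content) - 1.0) > 1e-9:
            raise ValueError("content fractions must sum to 1")


def load_propensities(path: str | Path | None = None) -> dict[str, dict[str, float]]:
    """Load a propensity table (columns aa/helix/sheet[/turn]) from TSV."""
    if path is None:
        source = resources.files("submitoloc.data").joinpath("chou_fasman.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    rows = [
        row
        for row in csv.reader(text.splitlines(), delimiter="\t")
        if row and not row[0].startswith("#")
    ]
    header, *body = rows
    table: dict[str, dict[str, float]] = {"helix": {}, "sheet": {}}
    for row in body:
        entry = dict(zip(header, row))
        aa = entry["aa"]
        table["helix"][aa] = float(entry["helix"])
        table["sheet"][aa] = float(entry["sheet"])
    missing = set(AMINO_ACIDS) - set(table["helix"])
    if missing:
        raise ValueError(f"propensity table missing residues: {sorted(missing)}")
    return table


_DEFAULT_TABLE = load_propensities()


def _window_means(values: np.ndarray, window: int) -> np.ndarray:
    """Mean over a centred window of width ``window``, truncated at termini."""
    half = window // 2
    length = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    starts = np.maximum(np.arange(length) - half, 0)
    stops = np.minimum(np.arange(length) + half + 1, length)
    return (csum[stops] - csum[starts]) / (stops - starts)


def assign_sse(
    sequence: str,
    window: int = 5,
    helix_threshold: float = DEFAULT_HELIX_THRESHOLD,
    sheet_threshold: float = DEFAULT_SHEET_THRESHOLD,
    propensities: dict[str, dict[str, float]] | None = None,
) -> SSEAssignment:
    """Assign H/E/C states to every residue of ``sequence``."""
    if len(sequence) < 1:
        raise ValueError("sequence must be non-empty")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    table = propensities if propensities is not None else _DEFAULT_TABLE
    for pos, aa in enumerate(sequence):
        if aa not in table["helix"]:
            raise ValueError(f"nonstandard residue {aa!r} at position {pos + 1}")

    helix = np.array([table["helix"][aa] for aa in sequence])
    sheet = np.array([table["sheet"][aa] for aa in sequence])
    helix_avg = _window_means(helix, window)
    sheet_avg = _window_means(sheet, window)

    states = np.full(len(sequence), "C")
    states[(helix_avg >= helix_threshold) & (helix_avg > sheet_avg)] = "H"
    states[(sheet_avg >= sheet_threshold) & (sheet_avg > helix_avg)] = "E"
    state_string = "".join(states)
    length = len(sequence)
    content = (
        state_string.count("H") / length,
        state_string.count("E") / length,
        state_string.count("C") / length,
    )
    return SSEAssignment(states=state_string, content=content)
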