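"""Average-mass calculation for heparin/heparan-sulfate oligosaccharide standards.

The standards panel consists of synthetic oligosaccharides built from repeating
uronic acid / glucosamine disaccharide units, written in a compact dash-separated
notation such as ``GlcNS6S-(GlcA-GlcNS6S)_5_-GlcA-pNP``: an optional parenthesised
block carries a subscript repeat count, and a trailing ``-pNP`` marks the
para-nitrophenyl aglycone tag at the reducing end.

Masses are free-acid average masses computed from standard average atomic
weights (C 12.011, H 1.008, N 14.007, O 15.999, S 32.06).  Residue masses are
the dehydrated (in-chain) monosaccharide masses; one terminal water is added
per chain, and the pNP tag replaces the anomeric hydroxyl hydrogen
(net +121.10 Da).  Sodium-salt and monoisotopic variants are out of scope.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

__all__ = [
    "ResidueMassTable",
    "OligoComposition",
    "StandardRecord",
    "StructureParseError",
    "DEFAULT_MASS_TABLE",
    "parse_structure_notation",
    "composition_to_notation",
    "compute_average_mw",
    "build_standard_panel",
    "round_to_dalton",
]

AVERAGE_ATOMIC_WEIGHTS = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str) -> float:
    """Average mass of a molecular formula like ``C6H8O6``."""
    mass = 0.0
    consumed = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        element, count = m.group(1), m.group(2)
        if element not in AVERAGE_ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        mass += AVERAGE_ATOMIC_WEIGHTS[element] * (int(count) if count else 1)
        consumed += len(m.group(0))
    if consumed != len(formula):
        raise ValueError(f"malformed formula {formula!r}")
    return mass


# In-chain (dehydrated) residue formulas.  Sulfation replaces an -OH or -NH
# hydrogen with -SO3H: each sulfo group adds SO3 (+80.06 Da).  The unsaturated
# uronate dHexA formed by beta-elimination is the saturated residue minus H2O.
RESIDUE_FORMULAS = {
    "GlcA": "C6H8O6",
    "IdoA": "C6H8O6",
    "IdoA2S": "C6H8O9S",
    "GlcNAc": "C8H13NO5",
    "GlcNS": "C6H11NO7S",
    "GlcNS6S": "C6H11NO10S2",
    "dHexA": "C6H6O5",
    "dHexA2S": "C6H6O8S",
}

# p-nitrophenyl glycoside: C6H4NO2 replaces the anomeric hydroxyl hydrogen.
_PNP_INCREMENT = formula_mass("C6H4NO2") - formula_mass("H")


@dataclass(frozen=True)
class ResidueMassTable:
    """Average residue masses (Da) plus aglycone increments and terminal water."""

    entries: dict[str, float]
    aglycone_increments: dict[str, float]
    water: float

    def residue_mass(self, code: str) -> float:
        try:
            return self.entries[code]
        except KeyError:
            raise KeyError(f"no residue mass for code {code!r}") from None


DEFAULT_MASS_TABLE = ResidueMassTable(
    entries={code: formula_mass(f) for code, f in RESIDUE_FORMULAS.items()},
    aglycone_increments={"pNP": _PNP_INCREMENT},
    water=formula_mass("H2O"),
)


class StructureParseError(ValueError):
    """Raised when a repeating-unit notation string cannot be parsed."""


@dataclass
class OligoComposition:
    """Residue multiset (plus optional aglycone) describing one oligosaccharide.

    ``unsaturated`` marks a 4,5-unsaturated uronate at the non-reducing end,
    the UV-232-active chromophore produced by lyase or beta-eliminative
    cleavage.
    """

    residues: dict[str, int] = field(default_factory=dict)
    aglycone: Optional[str] = None
    unsaturated: bool = False
    label: str = ""
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.residues.values()):
            raise ValueError("residue counts must be non-negative")
        if self.dp < 1:
            raise ValueError("composition must contain at least one residue")

    @property
    def dp(self) -> int:
        """Degree of polymerisation (total residue count)."""
        return sum(self.residues.values())


# Unicode variants of the unsaturated-uronate prefix seen in the literature
# (increment symbol vs. capital delta), with or without a comma before the
# sulfation locant.
_DELTA_NORMALISE = [
    ("∆HexA,2S", "dHexA2S"),
    ("ΔHexA,2S", "dHexA2S"),
    ("∆HexA2S", "dHexA2S"),
    ("ΔHexA2S", "dHexA2S"),
    ("∆HexA", "dHexA"),
    ("ΔHexA", "dHexA"),
    ("∆UA2S", "dHexA2S"),
    ("ΔUA2S", "dHexA2S"),
    ("∆UA", "dHexA"),
    ("ΔUA", "dHexA"),
]

_REPEAT_RE = re.compile(r"\(([^()]*)\)_(\d+)_")


def _normalise(notation: str) -> str:
    out = notation.strip()
    for src, dst in _DELTA_NORMALISE:
        out = out.replace(src, dst)
    return out


def parse_structure_notation(notation: str, label: str = "", group: str | None = None) -> OligoComposition:
    """Parse a repeating-unit notation string into an :class:`OligoComposition`.

    Accepts a dash-separated residue sequence with at most one parenthesised
    repeat block (subscript count written ``_n_``) and an optional trailing
    ``-pNP`` aglycone, e.g. ``GlcNS-GlcA-(GlcNS-IdoA2S)_7_-GlcNS-GlcA-pNP``.
    """
    text = _normalise(notation)
    if not text:
        raise StructureParseError("empty notation")
    if text.count("(") != text.count(")"):
        raise StructureParseError(f"unbalanced parentheses in {notation!r}")

    def expand(m: re.Match) -> str:
        block, count = m.group(1), int(m.group(2))
        return "-".join([block] * count) if count > 0 else ""

    expanded = _REPEAT_RE.sub(expand, text)
    if "(" in expanded or ")" in expanded:
        pos = text.index("(")
        raise StructureParseError(
            f"malformed repeat syntax at position {pos} in {notation!r}"
        )
    tokens = [t for t in expanded.split("-") if t]
    if not tokens:
        raise StructureParseError(f"no residues in {notation!r}")

    aglycone = None
    if tokens[-1] == "pNP":
        aglycone = "pNP"
        tokens = tokens[:-1]
    if not tokens:
        raise StructureParseError(f"aglycone with no residues in {notation!r}")

    counts: dict[str, int] = {}
    for tok in tokens:
        if tok not in RESIDUE_FORMULAS:
            raise StructureParseError(f"unknown residue code {tok!r} in {notation!r}")
        counts[tok] = counts.get(tok, 0) + 1

    unsaturated = tokens[0].startswith("dHexA")
    return OligoComposition(
        residues=counts,
        aglycone=aglycone,
        unsaturated=unsaturated,
        label=label or notation,
        group=group,
    )


def composition_to_notation(comp: OligoComposition) -> str:
    """Serialise a composition back to a (fully expanded) notation string.

    The residue *order* of the original sequence is not stored in the
    composition, so this emits a canonical ordering: any unsaturated uronate
    first, the remaining codes alphabetically, each repeated by its count.
    Re-parsing the result recovers identical residue counts, aglycone and
    unsaturation flag.
    """
    codes = sorted(comp.residues)
    ordered: list[str] = []
    for code in codes:
        if code.startswith("dHexA"):
            ordered = [code] * comp.residues[code] + ordered
        else:
            ordered.extend([code] * comp.residues[code])
    if comp.aglycone:
        ordered.append(comp.aglycone)
    return "-".join(ordered)


def compute_average_mw(
    comp: OligoComposition, masses: ResidueMassTable = DEFAULT_MASS_TABLE
) -> float:
    """Free-acid average molecular mass (Da) of an oligosaccharide.

    Sum of in-chain residue masses, one terminal water, and the aglycone
    increment when a tag is present.
    """
    total = masses.water
    for code, count in comp.residues.items():
        total += count * masses.residue_mass(code)
    if comp.aglycone is not None:
        try:
            total += masses.aglycone_increments[comp.aglycone]
        except KeyError:
            raise KeyError(f"no aglycone increment for {comp.aglycone!r}") from None
    return total


def round_to_dalton(mass: float) -> int:
    """Round half away from zero to the nearest dalton (display convention)."""
    return int(math.floor(mass + 0.5)) if mass >= 0 else -round_to_dalton(-mass)


@dataclass(frozen=True)
class StandardRecord:
    """One row of the standards panel.

    ``composition`` is ``None`` for the pharmacopeial calibrant peaks, whose
    underlying oligosaccharides are heterogeneous mixtures without a defined
    structure.  ``approximate`` marks standards whose reported mass is only a
    nominal value (the commercial dp4/dp6 heparin oligosaccharides).
    """

    compound_id: int | str
    group: str
    name: str
    notation: Optional[str]
    reported_mw: float
    composition: Optional[OligoComposition] = None
    approximate: bool = False

    @property
    def computed_mw(self) -> Optional[float]:
        if self.composition is None:
            return None
        return compute_average_mw(self.composition)


def _load_panel_frame() -> pd.DataFrame:
    with resources.files("glycocal").joinpath("data/panel.csv").open("r") as fh:
        return pd.read_csv(fh, dtype={"id": str})


def build_standard_panel() -> list[StandardRecord]:
    """Build the full 36-record standards panel.

    27 synthetic oligosaccharides (groups A-E, pNP-tagged), the two commercial
    dp4/dp6 heparin oligosaccharides (group F, nominal masses), and the seven
    pharmacopeial calibrant peaks (group G, assigned peak masses 11000, 7750,
    5200, 3350, 2250, 1800 and 1400 Da).
    """
    frame = _load_panel_frame()
    records: list[StandardRecord] = []
    for row in frame.itertuples(index=False):
        cid: int | str = int(row.id) if str(row.id).isdigit() else str(row.id)
        notation = None if pd.isna(row.notation) else str(row.notation)
        comp = None
        if notation:
            comp = parse_structure_notation(notation, label=str(row.name), group=str(row.group))
        records.append(
            StandardRecord(
                compound_id=cid,
                group=str(row.group),
                name=str(row.name),
                notation=notation,
                reported_mw=float(row.reported_mw),
                composition=comp,
                approximate=bool(row.approx),
            )
        )
    return records
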