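"""Elemental constants and molecular-formula arithmetic.

This module is the mass calculus underneath everything else: monoisotopic
and nominal masses, a small immutable :class:`Formula` container with
element algebra, a parser that accepts both the compact ``C20H43O5P`` and
the underscore-subscript ``C_20_H_43_O_5_P`` notations, ppm error, and the
amino-acid residue calculus that turns a peptide *composition* (an
unordered multiset of residues, optionally N-acetylated and/or
C-amidated) into a neutral molecular formula.

Atomic constants are shipped as a versioned TSV (``data/elements.tsv``)
holding IUPAC monoisotopic masses to >= 8 decimals so that golden-mass
tests are bit-stable.  Neutral masses carry no electron-mass correction;
adduct handling uses the proton mass constant directly.
"""

from __future__ import annotations

import csv
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "PROTON_MASS",
    "C13_SHIFT",
    "C13_ABUNDANCE",
    "C12_ABUNDANCE",
    "Element",
    "ELEMENTS",
    "Formula",
    "FormulaError",
    "FormulaParseError",
    "parse_formula",
    "monoisotopic_mass",
    "nominal_mass",
    "ppm_error",
    "Residue",
    "RESIDUES",
    "resolve_residue",
    "peptide_formula",
    "WATER",
]

#: Mass of a proton in Da; the +/-H adduct shift for singly charged ions.
PROTON_MASS = 1.007276466

#: Mass difference 13C - 12C in Da.
C13_SHIFT = 1.0033548378
C13_ABUNDANCE = 0.0107
C12_ABUNDANCE = 0.9893


class FormulaError(ValueError):
    """Invalid element symbol or negative count in a formula."""


class FormulaParseError(FormulaError):
    """Malformed formula string; message names the offending token."""


@dataclass(frozen=True)
class Element:
    symbol: str
    monoisotopic_mass: float
    nominal_mass: int
    isotope_shift: float      # mass of the M+1 isotope minus monoisotopic
    isotope_abundance: float  # natural abundance of the M+1 isotope


def _load_elements() -> dict[str, Element]:
    path = resources.files(__package__) / "data" / "elements.tsv"
    table: dict[str, Element] = {}
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            el = Element(
                symbol=row["symbol"],
                monoisotopic_mass=float(row["monoisotopic_mass"]),
                nominal_mass=int(row["nominal_mass"]),
                isotope_shift=float(row["isotope_shift"]),
                isotope_abundance=float(row["isotope_abundance"]),
            )
            if el.monoisotopic_mass <= 0:
                raise FormulaError(f"non-positive mass for element {el.symbol}")
            table[el.symbol] = el
    return table


ELEMENTS: dict[str, Element] = _load_elements()


class Formula(Mapping):
    """Immutable element -> count map with algebra.

    Zero counts are dropped on construction (so ``C0H2O`` is water);
    negative counts raise :class:`FormulaError`.  Supports ``+``, ``-``
    (underflow raises) and ``*`` by a non-negative integer.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **extra: int):
        merged: dict[str, int] = {}
        for src in (counts or {}, extra):
            for sym, n in src.items():
                merged[sym] = merged.get(sym, 0) + int(n)
        for sym, n in merged.items():
            if sym not in ELEMENTS:
                raise FormulaError(f"unknown element symbol {sym!r}")
            if n < 0:
                raise FormulaError(f"negative count for {sym}: {n}")
        self._counts = {s: n for s, n in sorted(merged.items()) if n > 0}

    # -- Mapping interface; missing elements read as 0 ------------------
    def __getitem__(self, sym: str) -> int:
        return self._counts.get(sym, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __eq__(self, other) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {s: n for s, n in other.items() if n}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(sorted(self._counts.items())))

    def __add__(self, other: "Formula") -> "Formula":
        out = dict(self._counts)
        for sym, n in other.items():
            out[sym] = out.get(sym, 0) + n
        return Formula(out)

    def __sub__(self, other: "Formula") -> "Formula":
        out = dict(self._counts)
        for sym, n in other.items():
            out[sym] = out.get(sym, 0) - n
        return Formula(out)  # negative counts rejected by the constructor

    def __mul__(self, k: int) -> "Formula":
        return Formula({s: n * k for s, n in self._counts.items()})

    __rmul__ = __mul__

    def hill(self) -> str:
        """Formula string in Hill order (C, H, then alphabetical)."""
        syms = list(self._counts)
        if "C" in self._counts:
            head = ["C"] + (["H"] if "H" in self._counts else [])
            syms = head + sorted(s for s in syms if s not in ("C", "H"))
        else:
            syms = sorted(syms)
        return "".join(
            f"{s}{self._counts[s]}" if self._counts[s] != 1 else s for s in syms
        )

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"


WATER = Formula(H=2, O=1)

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(?:_(\d+)_?|(\d+))?")


def parse_formula(text: str) -> Formula:
    """Parse ``C20H43O5P`` or the underscore notation ``C_20_H_43_O_5_P``.

    Unknown element symbols and stray characters raise
    :class:`FormulaParseError` naming the offending token.  Zero counts
    are tolerated and dropped.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaParseError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise FormulaParseError(
                f"unrecognized token {text[pos:pos + 4]!r} at position {pos} "
                f"in {text!r}"
            )
        sym = m.group(1)
        if sym not in ELEMENTS:
            raise FormulaParseError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(m.group(2) or m.group(3) or 1)
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return Formula(counts)


def monoisotopic_mass(f: Mapping[str, int]) -> float:
    """Neutral monoisotopic mass in Da (no electron correction)."""
    return sum(ELEMENTS[s].monoisotopic_mass * n for s, n in f.items())


def nominal_mass(f: Mapping[str, int]) -> int:
    """Integer mass using the mass number of each most abundant isotope."""
    return sum(ELEMENTS[s].nominal_mass * n for s, n in f.items())


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error, 1e6 * (obs - theo) / theo."""
    if theoretical <= 0:
        raise ValueError(f"theoretical mass must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


# -- residue calculus ---------------------------------------------------

@dataclass(frozen=True)
class Residue:
    code: str        # one-letter code (J = norleucine)
    name: str        # short name, e.g. Gly
    formula: Formula  # residue formula = amino acid minus water


def _load_residues() -> dict[str, Residue]:
    path = resources.files(__package__) / "data" / "residues.tsv"
    table: dict[str, Residue] = {}
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            res = Residue(row["code"], row["name"], parse_formula(row["formula"]))
            table[res.code] = res
            table[res.name.lower()] = res
    return table


_RESIDUE_LOOKUP = _load_residues()

#: One-letter code -> Residue (the canonical view of the residue table).
RESIDUES: dict[str, Residue] = {
    r.code: r for r in _RESIDUE_LOOKUP.values()
}

#: Terminal modifications as (add, subtract) formula pairs.
NTERM_MODS: dict[str, tuple[Formula, Formula]] = {
    "acetyl": (Formula(C=2, H=2, O=1), Formula()),
}
CTERM_MODS: dict[str, tuple[Formula, Formula]] = {
    "amide": (Formula(N=1, H=1), Formula(O=1)),
}


def resolve_residue(key: str) -> Residue:
    """Look up a residue by one-letter code or by name (case-insensitive)."""
    if len(key) == 1:
        res = _RESIDUE_LOOKUP.get(key.upper())
    else:
        res = _RESIDUE_LOOKUP.get(key.lower())
    if res is None:
        raise KeyError(f"unknown residue {key!r}")
    return res


def peptide_formula(
    residues: Iterable[str] | str,
    nterm_mod: str | None = None,
    cterm_mod: str | None = None,
) -> Formula:
    """Neutral formula of a linear peptide from its residue composition.

    ``residues`` may be a string of one-letter codes or any iterable of
    codes/names; order never matters (direct-infusion accurate mass cannot
    resolve sequence, only composition).  The peptide is the residue sum
    plus one water; ``nterm_mod='acetyl'`` adds C2H2O and
    ``cterm_mod='amide'`` swaps the C-terminal OH for NH2.
    """
    keys = list(residues) if not isinstance(residues, str) else list(residues)
    if not keys:
        raise ValueError("empty residue composition")
    f = WATER
    for key in keys:
        f = f + resolve_residue(key).formula
    for mod, table, where in (
        (nterm_mod, NTERM_MODS, "N-terminal"),
        (cterm_mod, CTERM_MODS, "C-terminal"),
    ):
        if mod is not None:
            if mod not in table:
                raise KeyError(f"unknown {where} modification {mod!r}")
            add, sub = table[mod]
            f = f + add - sub
    return f
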