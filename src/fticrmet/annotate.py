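"""Putative identification of accurate masses.

Accurate-mass annotation for singly charged, even-electron neutral
masses: exhaustive molecular-formula enumeration over a bounded CHNOPS
lattice inside a ppm window, filtered by the nitrogen rule, a ring-plus-
double-bond-equivalents (RDBE) range and element-ratio plausibility
heuristics, and ranked by absolute ppm error (ties toward lower RDBE).
Also: verification of an amino-acid composition against a mass, de novo
search over 4-8-residue compositions, and matching against a
user-supplied compound library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import (
    ELEMENTS,
    Formula,
    monoisotopic_mass,
    nominal_mass,
    parse_formula,
    peptide_formula,
    ppm_error,
    RESIDUES,
)

__all__ = [
    "FormulaCandidate",
    "CompositionMatch",
    "rdbe",
    "nitrogen_rule",
    "ratio_rules",
    "default_bounds",
    "enumerate_formulas",
    "verify_composition",
    "search_peptide_compositions",
    "load_library",
    "match_library",
]

#: Ring-plus-double-bond valence contributions (P trivalent by convention).
_RDBE_WEIGHTS = {"C": 1.0, "H": -0.5, "N": 0.5, "O": 0.0, "P": 0.5, "S": 0.0}

RDBE_MIN = -0.5
RDBE_MAX = 40.0

#: Element-ratio plausibility bounds (applied when C > 0).
RATIO_LIMITS = {"H/C": (0.1, 3.1), "N/C": 1.3, "O/C": 1.2, "P/C": 0.3, "S/C": 0.8}

#: Heavy-atom cap for carbon-free candidates (small inorganics only).
_CARBON_FREE_HEAVY_MAX = 5


def rdbe(f: Mapping[str, int]) -> float:
    """Ring-plus-double-bond equivalents: 1 + C - H/2 + N/2 + P/2."""
    return 1.0 + sum(_RDBE_WEIGHTS.get(s, 0.0) * n for s, n in f.items())


def nitrogen_rule(f: Mapping[str, int]) -> bool:
    """Even-electron parity check: nominal mass parity == N-count parity."""
    return nominal_mass(f) % 2 == f.get("N", 0) % 2


def ratio_rules(f: Mapping[str, int]) -> bool:
    """Element-ratio plausibility; passes trivially without carbon."""
    c = f.get("C", 0)
    if c == 0:
        heavy = sum(n for s, n in f.items() if s != "H")
        return heavy <= _CARBON_FREE_HEAVY_MAX
    h = f.get("H", 0)
    lo, hi = RATIO_LIMITS["H/C"]
    if h and not (lo <= h / c <= hi):
        return False
    for sym, key in (("N", "N/C"), ("O", "O/C"), ("P", "P/C"), ("S", "S/C")):
        if f.get(sym, 0) / c > RATIO_LIMITS[key]:
            return False
    return True


@dataclass(frozen=True)
class FormulaCandidate:
    formula: Formula
    theoretical_mass: float
    ppm: float
    rdbe: float
    nitrogen_rule_ok: bool
    ratio_rules_ok: bool


def default_bounds(mass: float) -> dict[str, int]:
    """Mass-scaled CHNOPS count caps in the spirit of common heuristic
    limits for small-molecule formula assignment."""
    return {
        "C": int(mass / 12) + 1,
        "H": int(mass / 1.0078) + 1,
        "N": int(mass / 14) + 1,
        "O": int(mass / 15.99) + 1,
        "P": 3,
        "S": 3,
    }


def enumerate_formulas(
    mass: float,
    window_ppm: float = 5.0,
    bounds: Mapping[str, int] | None = None,
    apply_filters: bool = True,
) -> list[FormulaCandidate]:
    """Exhaustive formula search within ``window_ppm`` of a neutral mass.

    ``bounds`` maps element symbols to maximum counts and defines the
    allowed element set (default: mass-scaled CHNOPS).  Candidates are
    filtered by the nitrogen rule, RDBE in [-0.5, 40] and element-ratio
    heuristics unless ``apply_filters=False``, and ranked by |ppm| with
    ties broken toward lower RDBE.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if window_ppm <= 0:
        raise ValueError("window_ppm must be positive")
    if bounds is None:
        bounds = default_bounds(mass)
    if not bounds:
        raise ValueError("empty element set")
    unknown = set(bounds) - set(ELEMENTS)
    if unknown:
        raise ValueError(f"unknown elements in bounds: {sorted(unknown)}")

    mC = ELEMENTS["C"].monoisotopic_mass
    mH = ELEMENTS["H"].monoisotopic_mass
    mN = ELEMENTS["N"].monoisotopic_mass
    mO = ELEMENTS["O"].monoisotopic_mass
    mP = ELEMENTS["P"].monoisotopic_mass
    mS = ELEMENTS["S"].monoisotopic_mass
    bC = bounds.get("C", 0)
    bH = bounds.get("H", 0)
    bN = bounds.get("N", 0)
    bO = bounds.get("O", 0)
    bP = bounds.get("P", 0)
    bS = bounds.get("S", 0)

    lo = mass * (1 - window_ppm * 1e-6)
    hi = mass * (1 + window_ppm * 1e-6)

    out: list[FormulaCandidate] = []
    for s in range(bS + 1):
        base_s = s * mS
        if base_s > hi:
            break
        for p in range(bP + 1):
            base_p = base_s + p * mP
            if base_p > hi:
                break
            for c in range(bC + 1):
                base_c = base_p + c * mC
                if base_c > hi:
                    break
                n_cap = bN if c == 0 else min(bN, int(RATIO_LIMITS["N/C"] * c))
                o_cap = bO if c == 0 else min(bO, int(RATIO_LIMITS["O/C"] * c))
                if not apply_filters:
                    n_cap, o_cap = bN, bO
                for n in range(n_cap + 1):
                    base_n = base_c + n * mN
                    if base_n > hi:
                        break
                    for o in range(o_cap + 1):
                        base = base_n + o * mO
                        if base > hi:
                            break
                        h_lo = int(np.ceil((lo - base) / mH))
                        h_hi = int(np.floor((hi - base) / mH))
                        for h in range(max(h_lo, 0), min(h_hi, bH) + 1):
                            theo = base + h * mH
                            if not (lo <= theo <= hi):
                                continue
                            f = Formula(C=c, H=h, N=n, O=o, P=p, S=s)
                            if not f:
                                continue
                            cand = FormulaCandidate(
                                formula=f,
                                theoretical_mass=theo,
                                ppm=ppm_error(mass, theo),
                                rdbe=rdbe(f),
                                nitrogen_rule_ok=nitrogen_rule(f),
                                ratio_rules_ok=ratio_rules(f),
                            )
                            if apply_filters and not (
                                cand.nitrogen_rule_ok
                                and cand.ratio_rules_ok
                                and RDBE_MIN <= cand.rdbe <= RDBE_MAX
                            ):
                                continue
                            out.append(cand)
    out.sort(key=lambda x: (abs(x.ppm), x.rdbe))
    return out


@dataclass(frozen=True)
class CompositionMatch:
    formula: Formula
    theoretical_mass: float
    ppm: float
    ok: bool


def verify_composition(
    mass: float,
    residues: Iterable[str] | str,
    nterm_mod: str | None = None,
    cterm_mod: str | None = None,
    window_ppm: float = 5.0,
) -> CompositionMatch:
    """Check an amino-acid composition (order-free) against a neutral mass."""
    f = peptide_formula(residues, nterm_mod=nterm_mod, cterm_mod=cterm_mod)
    theo = monoisotopic_mass(f)
    err = ppm_error(mass, theo)
    return CompositionMatch(f, theo, err, abs(err) <= window_ppm)


def _residue_classes() -> list[tuple[str, float]]:
    """Distinct residue composition classes (Leu/Ile/Nle collapse to one)."""
    seen: dict[Formula, str] = {}
    for code in sorted(RESIDUES):
        res = RESIDUES[code]
        if res.formula in seen:
            seen[res.formula] = seen[res.formula] + "/" + res.name
        else:
            seen[res.formula] = res.name
    return sorted(
        ((name, monoisotopic_mass(f)) for f, name in seen.items()),
        key=lambda x: x[1],
    )


def search_peptide_compositions(
    mass: float,
    window_ppm: float = 5.0,
    min_len: int = 4,
    max_len: int = 8,
    nterm_mod: str | None = None,
    cterm_mod: str | None = None,
) -> list[tuple[tuple[str, ...], float, float]]:
    """De novo search over residue multisets whose peptide mass fits.

    Returns (composition names, theoretical mass, ppm) sorted by |ppm|.
    Residue order is never reported: accurate mass alone cannot
    determine sequence, only composition.  Leu/Ile/Nle count as a single
    composition class.
    """
    from .chem import WATER, NTERM_MODS, CTERM_MODS

    offset = monoisotopic_mass(WATER)
    for mod, table in ((nterm_mod, NTERM_MODS), (cterm_mod, CTERM_MODS)):
        if mod is not None:
            add, sub = table[mod]
            offset += monoisotopic_mass(add) - monoisotopic_mass(sub)
    target = mass - offset
    lo = mass * (1 - window_ppm * 1e-6) - offset
    hi = mass * (1 + window_ppm * 1e-6) - offset

    classes = _residue_classes()
    min_res = classes[0][1]
    results: list[tuple[tuple[str, ...], float, float]] = []

    def dfs(idx: int, length: int, acc_mass: float, picked: list[str]) -> None:
        if lo <= acc_mass <= hi and min_len <= length <= max_len:
            theo = acc_mass + offset
            results.append((tuple(picked), theo, ppm_error(mass, theo)))
        if length >= max_len or idx >= len(classes):
            return
        remaining = max_len - length
        if acc_mass + min_res > hi:
            return
        for j in range(idx, len(classes)):
            name, m = classes[j]
            if acc_mass + m > hi:
                break
            # largest still-reachable mass from here must cover lo
            if acc_mass + remaining * classes[-1][1] < lo:
                return
            picked.append(name)
            dfs(j, length + 1, acc_mass + m, picked)
            picked.pop()

    dfs(0, 0, 0.0, [])
    results.sort(key=lambda r: abs(r[2]))
    return results


def load_library(path) -> pd.DataFrame:
    """Read a compound library TSV with columns name, formula, class."""
    lib = pd.read_csv(path, sep="\t")
    missing = {"name", "formula"} - set(lib.columns)
    if missing:
        raise ValueError(f"library missing columns {sorted(missing)}")
    if "class" not in lib.columns:
        lib["class"] = ""
    lib["theoretical_mass"] = [
        monoisotopic_mass(parse_formula(f)) for f in lib["formula"]
    ]
    return lib


def match_library(
    masses: Sequence[float],
    library: pd.DataFrame,
    window_ppm: float = 5.0,
) -> pd.DataFrame:
    """All (mass, compound) pairs within the ppm window.

    Returns a hit table (possibly empty — the absence of hits is itself a
    result) with columns mass, name, formula, class, theoretical_mass, ppm.
    """
    if library.empty:
        raise ValueError("compound library is empty")
    lib = library.copy()
    if "theoretical_mass" not in lib.columns:
        lib["theoretical_mass"] = [
            monoisotopic_mass(parse_formula(f)) for f in lib["formula"]
        ]
    hits = []
    for m in masses:
        for _, row in lib.iterrows():
            err = ppm_error(m, row["theoretical_mass"])
            if abs(err) <= window_ppm:
                hits.append(
                    {
                        "mass": m,
                        "name": row["name"],
                        "formula": row["formula"],
                        "class": row.get("class", ""),
                        "theoretical_mass": row["theoretical_mass"],
                        "ppm": err,
                    }
                )
    return pd.DataFrame(
        hits, columns=["mass", "name", "formula", "class", "theoretical_mass", "ppm"]
    )
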