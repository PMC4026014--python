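"""Peak-list container and plain-text I/O.

A :class:`PeakList` is one injection's worth of (mass, S/N) pairs for a
single (sample, mode), kept sorted by mass, with flags recording whether
the masses have been recalibrated, whether they are in neutral-mass
space, and which peaks have been recognized as 13C isotopologue
partners.  Peak lists round-trip through a 5-column TSV
(mz, sn, mode_code, sample_id, replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import PROTON_MASS

__all__ = [
    "PeakList",
    "mz_from_neutral",
    "neutral_from_mz",
    "write_peaklist_tsv",
    "read_peaklist_tsv",
    "read_peaklist_dir",
]


def mz_from_neutral(neutral_mass: float, polarity: str) -> float:
    """Singly protonated/deprotonated m/z for a neutral mass."""
    if polarity == "positive":
        return neutral_mass + PROTON_MASS
    if polarity == "negative":
        return neutral_mass - PROTON_MASS
    raise ValueError(f"unknown polarity {polarity!r}")


def neutral_from_mz(mz, polarity: str):
    """Neutral mass under the default [M+H]+ / [M-H]- assumption."""
    if polarity == "positive":
        return mz - PROTON_MASS
    if polarity == "negative":
        return mz + PROTON_MASS
    raise ValueError(f"unknown polarity {polarity!r}")


@dataclass
class PeakList:
    sample_id: str
    mode: int
    mass: np.ndarray                 # Da; m/z or neutral depending on `neutral`
    sn: np.ndarray                   # signal-to-noise ratio, >= 0
    calibrated: bool = False
    neutral: bool = False
    replicate: int = 0
    is_isotope: np.ndarray | None = None  # set by alignment.pair_isotopes

    def __post_init__(self):
        self.mass = np.asarray(self.mass, dtype=float)
        self.sn = np.asarray(self.sn, dtype=float)
        if self.mass.shape != self.sn.shape:
            raise ValueError("mass and sn must have identical shape")
        if np.any(self.sn < 0):
            raise ValueError("S/N values must be >= 0")
        order = np.argsort(self.mass, kind="stable")
        self.mass = self.mass[order]
        self.sn = self.sn[order]
        if self.is_isotope is not None:
            self.is_isotope = np.asarray(self.is_isotope, dtype=bool)[order]

    def __len__(self) -> int:
        return self.mass.size

    def with_masses(self, mass: np.ndarray, **flags) -> "PeakList":
        """Copy with transformed masses (and updated flags)."""
        return replace(self, mass=np.asarray(mass, dtype=float), **flags)


def write_peaklist_tsv(pl: PeakList, path) -> None:
    df = pd.DataFrame(
        {
            "mz": pl.mass,
            "sn": pl.sn,
            "mode_code": pl.mode,
            "sample_id": pl.sample_id,
            "replicate": pl.replicate,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8f")


def read_peaklist_tsv(path) -> list[PeakList]:
    """Read a TSV with mz/sn/mode_code/sample_id[/replicate] columns.

    A single file may hold several runs; one PeakList is returned per
    (sample_id, mode_code, replicate) present.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"mz", "sn", "mode_code", "sample_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    out = []
    for (sid, code, rep), grp in df.groupby(["sample_id", "mode_code", "replicate"], sort=True):
        out.append(
            PeakList(
                sample_id=str(sid),
                mode=int(code),
                mass=grp["mz"].to_numpy(),
                sn=grp["sn"].to_numpy(),
                replicate=int(rep),
            )
        )
    return out


def read_peaklist_dir(directory) -> list[PeakList]:
    directory = Path(directory)
    out: list[PeakList] = []
    for path in sorted(directory.glob("*.tsv")):
        out.extend(read_peaklist_tsv(path))
    if not out:
        raise FileNotFoundError(f"no peak-list TSV files under {directory}")
    return out
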