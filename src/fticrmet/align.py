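"""From recalibrated peak lists to the two-dimensional metabolite array.

Pipeline order per mode: flag 13C isotopologue partners, convert m/z to
neutral mass (default [M+H]+/[M-H]- assumption), single-linkage cluster
masses across samples at a ppm link threshold, then merge the per-mode
tables into one array whose rows are unique neutral masses and whose
columns are samples, cells holding S/N.  Missing cells are filled with
S/N = 1 (log2 = 0), the noise floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import C12_ABUNDANCE, C13_ABUNDANCE, C13_SHIFT
from .peaklist import PeakList, neutral_from_mz
from .simulate import MODES

__all__ = [
    "DEFAULT_TOL_PPM",
    "FILL_SN",
    "MetaboliteArray",
    "pair_isotopes",
    "to_neutral_mass",
    "strip_standards",
    "align_across_samples",
    "merge_modes",
]

logger = logging.getLogger(__name__)

DEFAULT_TOL_PPM = 2.0   # link threshold; calibration guarantees < 1 ppm
FILL_SN = 1.0           # S/N assigned to absent cells (log2 = 0)


@dataclass
class MetaboliteArray:
    """Rows = unique neutral masses, columns = samples, cells = S/N."""

    intensities: pd.DataFrame     # index: neutral mass; absent cells filled
    provenance: pd.DataFrame      # per row: modes, n_peaks
    groups: dict[str, str] = field(default_factory=dict)
    fill_value: float = FILL_SN

    @property
    def masses(self) -> np.ndarray:
        return self.intensities.index.to_numpy()

    @property
    def n_rows(self) -> int:
        return len(self.intensities)

    def per_mode_counts(self) -> dict[str, int]:
        """Row counts per mode provenance (multi-mode rows count once per mode)."""
        counts: dict[str, int] = {}
        for modes in self.provenance["modes"]:
            for code in str(modes).split("+"):
                counts[code] = counts.get(code, 0) + 1
        return dict(sorted(counts.items()))

    def to_csv(self, path) -> None:
        out = self.intensities.copy()
        out.insert(0, "mass", out.index)
        out.to_csv(path, index=False, float_format="%.8f")


def pair_isotopes(
    pl: PeakList,
    tol_ppm: float = DEFAULT_TOL_PPM,
    ratio_window: float = 0.5,
) -> PeakList:
    """Flag peaks that are 13C partners of a peak 1.003355 Da below.

    A peak j is flagged when it sits at mass_i + 1.003355 within
    ``tol_ppm`` of some unflagged peak i and the intensity ratio
    sn_j/sn_i is within ``ratio_window`` (relative) of nC * 0.0107/0.9893
    for a plausible carbon count 1 <= nC <= mass_i/12.  Flagged peaks are
    retained but excluded from unique-metabolite rows downstream.
    """
    if not pl.calibrated:
        raise ValueError("pair_isotopes requires a calibrated peak list")
    n = len(pl)
    flags = np.zeros(n, dtype=bool)
    r1 = C13_ABUNDANCE / C12_ABUNDANCE
    for i in range(n):
        if flags[i]:
            continue  # isotope peaks are not parents
        target = pl.mass[i] + C13_SHIFT
        tol = tol_ppm * 1e-6 * target
        lo = np.searchsorted(pl.mass, target - tol, side="left")
        hi = np.searchsorted(pl.mass, target + tol, side="right")
        if lo == hi:
            continue
        cand = lo + int(np.argmin(np.abs(pl.mass[lo:hi] - target)))
        if flags[cand] or pl.sn[i] <= 0:
            continue
        ratio = pl.sn[cand] / pl.sn[i]
        nc = int(round(ratio / r1))
        nc_max = int(pl.mass[i] // 12)
        if nc < 1 or nc > nc_max:
            continue
        expected = nc * r1
        if abs(ratio - expected) <= ratio_window * expected:
            flags[cand] = True
    out = pl.with_masses(pl.mass)
    out.is_isotope = flags
    return out


def to_neutral_mass(pl: PeakList) -> PeakList:
    """Convert m/z to neutral mass using the mode's polarity."""
    if pl.mode not in MODES:
        raise ValueError(f"unknown mode code {pl.mode}; polarity unknown")
    if pl.neutral:
        return pl
    polarity = MODES[pl.mode].polarity
    return pl.with_masses(neutral_from_mz(pl.mass, polarity), neutral=True)


def strip_standards(pl: PeakList, standards, window_ppm: float = 5.0) -> PeakList:
    """Drop internal-standard peaks (matched in m/z space) before alignment."""
    if pl.neutral:
        raise ValueError("strip standards before neutral-mass conversion")
    keep = np.ones(len(pl), dtype=bool)
    for std in standards:
        tol = window_ppm * 1e-6 * std
        lo = np.searchsorted(pl.mass, std - tol, side="left")
        hi = np.searchsorted(pl.mass, std + tol, side="right")
        keep[lo:hi] = False
    from dataclasses import replace

    return replace(
        pl,
        mass=pl.mass[keep],
        sn=pl.sn[keep],
        is_isotope=None if pl.is_isotope is None else pl.is_isotope[keep],
    )


def _cluster_masses(masses: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Single-linkage clusters in 1-D: break where the gap exceeds tol."""
    labels = np.zeros(masses.size, dtype=int)
    if masses.size == 0:
        return labels
    gaps = np.diff(masses)
    brk = gaps > tol_ppm * 1e-6 * masses[1:]
    labels[1:] = np.cumsum(brk)
    return labels


def align_across_samples(
    pls: Sequence[PeakList],
    tol_ppm: float = DEFAULT_TOL_PPM,
    drop_isotopes: bool = True,
    by_replicate: bool = False,
) -> pd.DataFrame:
    """Merge one mode's peak lists into a mass x sample table.

    Single-linkage clustering of neutral masses at ``tol_ppm``; each
    cluster becomes one row with an intensity-weighted representative
    mass.  Each sample contributes at most one peak per row (nearest to
    the representative mass wins; ties break toward higher S/N).  Absent
    cells are NaN here; the fill policy is applied at the merge step.
    """
    if not pls:
        raise ValueError("no peak lists to align")
    modes = {pl.mode for pl in pls}
    if len(modes) != 1:
        raise ValueError(f"align_across_samples takes one mode at a time, got {modes}")
    if any(not pl.calibrated for pl in pls):
        raise ValueError("all peak lists must be calibrated before alignment")
    if len({pl.neutral for pl in pls}) != 1:
        raise ValueError("peak lists mix neutral and m/z mass spaces")

    def column(pl: PeakList) -> str:
        return f"{pl.sample_id}:rep{pl.replicate}" if by_replicate else pl.sample_id

    mass_all, sn_all, col_all = [], [], []
    for pl in pls:
        keep = np.ones(len(pl), dtype=bool)
        if drop_isotopes and pl.is_isotope is not None:
            keep &= ~pl.is_isotope
        mass_all.append(pl.mass[keep])
        sn_all.append(pl.sn[keep])
        col_all.extend([column(pl)] * int(keep.sum()))
    masses = np.concatenate(mass_all)
    sns = np.concatenate(sn_all)
    cols = np.asarray(col_all)
    order = np.argsort(masses, kind="stable")
    masses, sns, cols = masses[order], sns[order], cols[order]

    labels = _cluster_masses(masses, tol_ppm)
    columns = sorted({column(pl) for pl in pls})
    rows: list[dict] = []
    index: list[float] = []
    mode_code = next(iter(modes))
    for lab in np.unique(labels):
        sel = labels == lab
        m, s, c = masses[sel], sns[sel], cols[sel]
        rep = float(np.sum(m * s) / np.sum(s)) if np.sum(s) > 0 else float(np.mean(m))
        span = float(m.max() - m.min())
        if span > 3 * tol_ppm * 1e-6 * rep:
            logger.warning(
                "mode %s: cluster at %.5f Da spans %.2f ppm (> 3x link threshold)",
                mode_code, rep, 1e6 * span / rep,
            )
        cell: dict[str, float] = {}
        for col in np.unique(c):
            members = np.flatnonzero(c == col)
            # nearest to representative mass; tie -> higher S/N
            best = min(members, key=lambda j: (abs(m[j] - rep), -s[j]))
            cell[col] = float(s[best])
        rows.append(cell)
        index.append(rep)
    table = pd.DataFrame(rows, index=index, columns=columns)
    table = table.sort_index()
    table.attrs["mode"] = mode_code
    return table


def merge_modes(
    tables: Mapping[int, pd.DataFrame],
    tol_ppm: float = DEFAULT_TOL_PPM,
    merge_shared: bool = True,
    fill_value: float = FILL_SN,
    groups: Mapping[str, str] | None = None,
) -> MetaboliteArray:
    """Pool per-mode tables into one MetaboliteArray.

    With ``merge_shared`` (default), masses equal within ``tol_ppm``
    across modes collapse into a single row listing every contributing
    mode code; per-cell conflicts resolve to the higher S/N.  With
    ``merge_shared=False`` each mode keeps its own rows (the pooled-count
    convention).
    """
    if not tables:
        raise ValueError("no mode tables to merge")
    frames = []
    for code in sorted(tables):
        t = tables[code]
        f = t.copy()
        f["__mode"] = str(code)
        f["__mass"] = f.index.to_numpy(dtype=float)
        frames.append(f)
    stacked = pd.concat(frames, ignore_index=True)
    sample_cols = [c for c in stacked.columns if not c.startswith("__")]

    stacked = stacked.sort_values("__mass", kind="stable").reset_index(drop=True)
    masses = stacked["__mass"].to_numpy()
    if merge_shared:
        labels = _cluster_masses(masses, tol_ppm)
    else:
        labels = np.arange(len(stacked))

    out_rows, prov_rows, index = [], [], []
    for lab in np.unique(labels):
        sub = stacked.loc[labels == lab]
        weights = sub[sample_cols].sum(axis=1).to_numpy()
        w = np.where(weights > 0, weights, 1.0)
        rep = float(np.sum(sub["__mass"].to_numpy() * w) / np.sum(w))
        cells = sub[sample_cols].max(axis=0)  # conflict -> higher S/N
        out_rows.append(cells)
        prov_rows.append(
            {
                "modes": "+".join(sorted(set(sub["__mode"]))),
                "n_peaks": int(sub[sample_cols].notna().sum().sum()),
            }
        )
        index.append(rep)

    intensities = pd.DataFrame(out_rows, index=index)[sample_cols]
    intensities = intensities.fillna(fill_value).sort_index()
    provenance = pd.DataFrame(prov_rows, index=index).sort_index()
    return MetaboliteArray(
        intensities=intensities,
        provenance=provenance,
        groups=dict(groups or {}),
        fill_value=fill_value,
    )
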