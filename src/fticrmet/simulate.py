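"""Synthetic ground-truth metabolomes and per-sample, per-mode peak lists.

The generator emulates a direct-infusion FTICR-MS cerebrospinal-fluid
study: six analytical modes (codes 1101-1204 combining ion source,
polarity and extract), metabolites of 100-1500 Da drawn as valid CHNOPS
formulas, signal-to-noise intensities with multiplicative (log2-Gaussian)
replicate noise tuned so that the replicate coefficient of variation sits
in the 10-15 % band, a linear per-run mass miscalibration, natural-
abundance 13C partner peaks, internal calibration standards spanning
m/z 100-1000, and planted group-effect patterns following four
time-course trend clusters relative to untreated controls:

* cluster 1: suppressed at weeks 4, 8 and 12;
* cluster 2: suppressed at week 12 only;
* cluster 3: elevated at week 8, suppressed at week 12;
* cluster 4: elevated at week 12 only.

Everything is a pure function of its configuration plus a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chem import (
    C12_ABUNDANCE,
    C13_ABUNDANCE,
    C13_SHIFT,
    PROTON_MASS,
    Formula,
    monoisotopic_mass,
)
from .peaklist import PeakList, mz_from_neutral

__all__ = [
    "ModeDescriptor",
    "MODES",
    "GroundTruthMetabolite",
    "StudyDesign",
    "DEFAULT_STANDARDS",
    "generate_panel",
    "emit_peaklists",
    "emit_pooled_replicates",
    "truth_intensity_array",
    "write_peaklists",
    "write_truth",
]


@dataclass(frozen=True)
class ModeDescriptor:
    """One analytical mode: ion source, polarity and extract phase."""

    code: int
    ionization: str  # ESI | APCI
    polarity: str    # positive | negative
    extract: str     # aqueous | organic1 | organic2


#: The six analysis modes. Polarity and extract follow the study's mode
#: table; the source assignment (ESI for aqueous/organic1, APCI for
#: organic2) is a labelling convention — only polarity enters the math.
MODES: dict[int, ModeDescriptor] = {
    1101: ModeDescriptor(1101, "ESI", "positive", "aqueous"),
    1102: ModeDescriptor(1102, "ESI", "negative", "aqueous"),
    1201: ModeDescriptor(1201, "ESI", "positive", "organic1"),
    1202: ModeDescriptor(1202, "ESI", "negative", "organic1"),
    1203: ModeDescriptor(1203, "APCI", "positive", "organic2"),
    1204: ModeDescriptor(1204, "APCI", "negative", "organic2"),
}

GROUPS = ("control", "week4", "week8", "week12")

#: Trend-cluster group-mean offsets in units of the effect size delta,
#: keyed by cluster, ordered (week4, week8, week12); controls are 0.
CLUSTER_OFFSETS: dict[int, tuple[float, float, float]] = {
    1: (-1.0, -1.0, -1.0),
    2: (0.0, 0.0, -1.0),
    3: (0.0, 1.0, -1.0),
    4: (0.0, 0.0, 1.0),
}

#: Synthetic internal-standard m/z values spanning the 100-1000
#: calibration range (arbitrary accurate masses, not real compounds).
DEFAULT_STANDARDS: tuple[float, ...] = (
    110.071154,
    223.063928,
    341.108743,
    454.292156,
    568.424871,
    692.187505,
    815.640332,
    990.713266,
)

STANDARD_LOG2_SN = 9.0  # baseline log2 S/N of internal-standard peaks
SN_FLOOR = 1.0          # peaks below S/N 1 are not detected


@dataclass(frozen=True)
class GroundTruthMetabolite:
    formula: Formula
    neutral_mass: float
    baseline_log2_sn: float
    trend_cluster: int            # 1..4, or 0 for a null metabolite
    effect_size: float            # log2 units; 0 iff trend_cluster == 0
    modes_detected: tuple[int, ...]

    def group_offset(self, group: str) -> float:
        """Planted log2 offset of this metabolite in the given group."""
        if self.trend_cluster == 0 or group == "control":
            return 0.0
        w = GROUPS.index(group) - 1
        return CLUSTER_OFFSETS[self.trend_cluster][w] * self.effect_size


@dataclass(frozen=True)
class StudyDesign:
    """Sample groups and replicate counts.

    Defaults to the realized design of the emulated study: 2 controls and
    3/2/3 treated animals at weeks 4/8/12 (after exclusions).
    """

    replicates: tuple[int, int, int, int] = (2, 3, 2, 3)
    seed: int = 0

    def samples(self) -> list[tuple[str, str]]:
        out = []
        for group, n in zip(GROUPS, self.replicates):
            for i in range(1, n + 1):
                out.append((f"{group}_{i}", group))
        return out

    @property
    def groups(self) -> dict[str, str]:
        return dict(self.samples())


# -- panel generation ---------------------------------------------------

_RATIO_BOUNDS = {  # element-ratio plausibility bounds for sampled formulas
    "H/C": (0.3, 3.0),
    "N/C": 1.3,
    "O/C": 1.2,
    "P/C": 0.3,
    "S/C": 0.8,
}


def _sample_formula(rng: np.random.Generator, mass_range: tuple[float, float]) -> Formula:
    """Rejection-sample a plausible even-electron CHNOPS formula."""
    lo, hi = mass_range
    while True:
        c = int(rng.integers(5, 80))
        n = int(rng.integers(0, int(0.35 * c) + 2))
        o = int(rng.integers(0, int(0.7 * c) + 2))
        p = int(rng.integers(0, 3)) if rng.random() < 0.25 else 0
        s = int(rng.integers(0, 3)) if rng.random() < 0.15 else 0
        h = int(rng.integers(max(1, int(0.5 * c)), 2 * c + n + 3))
        if (h + n + p) % 2:  # enforce integer RDBE (even-electron neutral)
            h += 1
        rdbe = 1 + c - h / 2 + (n + p) / 2
        if not (0 <= rdbe <= 25):
            continue
        hc = h / c
        if not (_RATIO_BOUNDS["H/C"][0] <= hc <= _RATIO_BOUNDS["H/C"][1]):
            continue
        if n / c > _RATIO_BOUNDS["N/C"] or o / c > _RATIO_BOUNDS["O/C"]:
            continue
        if p / c > _RATIO_BOUNDS["P/C"] or s / c > _RATIO_BOUNDS["S/C"]:
            continue
        f = Formula(C=c, H=h, N=n, O=o, P=p, S=s)
        if lo <= monoisotopic_mass(f) <= hi:
            return f


def generate_panel(
    n_metabolites: int = 300,
    cluster_fractions: Sequence[float] = (0.05, 0.05, 0.05, 0.05),
    effect_size: float = 1.5,
    seed: int | None = 0,
    mass_range: tuple[float, float] = (100.0, 1500.0),
    baseline_range: tuple[float, float] = (2.0, 10.0),
    rng: np.random.Generator | None = None,
    avoid_mz: Sequence[float] = DEFAULT_STANDARDS,
) -> list[GroundTruthMetabolite]:
    """Draw a ground-truth metabolite panel with planted trend clusters.

    ``cluster_fractions`` gives the fraction of metabolites assigned to
    each of the four trend clusters (the remainder are nulls with zero
    effect).  Metabolite adduct m/z positions are kept >= 20 ppm away
    from ``avoid_mz`` (the spiked calibration standards are chosen to be
    interference-free).  The same seed always yields the identical panel.
    """
    if n_metabolites < 1:
        raise ValueError("n_metabolites must be >= 1")
    fractions = tuple(float(x) for x in cluster_fractions)
    if len(fractions) != 4 or any(x < 0 or x > 1 for x in fractions):
        raise ValueError(f"cluster_fractions must be 4 values in [0,1]: {fractions}")
    if sum(fractions) > 1 + 1e-9:
        raise ValueError(f"cluster_fractions sum to {sum(fractions)} > 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    counts = [int(round(n_metabolites * f)) for f in fractions]
    labels = [c for c, k in zip((1, 2, 3, 4), counts) for _ in range(k)]
    labels += [0] * (n_metabolites - len(labels))
    rng.shuffle(labels)

    panel: list[GroundTruthMetabolite] = []
    seen_masses: list[float] = []
    for lab in labels:
        while True:
            f = _sample_formula(rng, mass_range)
            m = monoisotopic_mass(f)
            # keep planted masses >= 20 ppm apart so truth rows are unambiguous
            if any(abs(m - x) <= 20e-6 * m for x in seen_masses):
                continue
            if any(
                abs(m + sign * PROTON_MASS + iso - std) <= 20e-6 * std
                for std in avoid_mz
                for sign in (1.0, -1.0)
                for iso in (0.0, C13_SHIFT)
            ):
                continue
            break
        seen_masses.append(m)
        polarity = "positive" if rng.random() < 0.5 else "negative"
        compatible = [c for c, d in MODES.items() if d.polarity == polarity]
        k = 1 + int(rng.random() < 0.3)
        modes = tuple(sorted(rng.choice(compatible, size=k, replace=False).tolist()))
        panel.append(
            GroundTruthMetabolite(
                formula=f,
                neutral_mass=m,
                baseline_log2_sn=float(rng.uniform(*baseline_range)),
                trend_cluster=lab,
                effect_size=effect_size if lab else 0.0,
                modes_detected=modes,
            )
        )
    return panel


# -- peak-list emission -------------------------------------------------

def _draw_distortion(
    miscalibration,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Per-run linear mass distortion (slope, intercept in Da)."""
    if miscalibration is None:
        return 1.0, 0.0
    if miscalibration == "random":
        return 1.0 + float(rng.normal(0.0, 2e-6)), float(rng.normal(0.0, 2e-4))
    slope, intercept = miscalibration
    return float(slope), float(intercept)


def _emit_one_run(
    panel: Sequence[GroundTruthMetabolite],
    group: str,
    mode: ModeDescriptor,
    rng: np.random.Generator,
    noise_sd: float,
    mass_jitter_ppm: float,
    miscalibration,
    isotope: bool,
    standards: Sequence[float],
    sample_id: str,
    replicate: int = 0,
) -> PeakList:
    slope, intercept = _draw_distortion(miscalibration, rng)

    masses: list[float] = []
    sns: list[float] = []
    for met in panel:
        if mode.code not in met.modes_detected:
            continue
        log2_sn = met.baseline_log2_sn + met.group_offset(group)
        if noise_sd > 0:
            log2_sn += float(rng.normal(0.0, noise_sd))
        sn = 2.0 ** log2_sn
        mz = mz_from_neutral(met.neutral_mass, mode.polarity)
        masses.append(mz)
        sns.append(sn)
        if isotope:
            n_c = met.formula["C"]
            ratio = n_c * C13_ABUNDANCE / C12_ABUNDANCE
            iso_sn = sn * ratio
            if iso_sn >= SN_FLOOR:
                masses.append(mz + C13_SHIFT)
                sns.append(iso_sn)
    for std in standards:
        sn = 2.0 ** (STANDARD_LOG2_SN + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
        masses.append(float(std))
        sns.append(sn)

    obs = np.asarray(masses, dtype=float) * slope + intercept
    if mass_jitter_ppm > 0:
        obs = obs * (1.0 + rng.normal(0.0, mass_jitter_ppm * 1e-6, size=obs.size))
    return PeakList(
        sample_id=sample_id,
        mode=mode.code,
        mass=obs,
        sn=np.asarray(sns, dtype=float),
        calibrated=False,
        replicate=replicate,
    )


def emit_peaklists(
    panel: Sequence[GroundTruthMetabolite],
    design: StudyDesign,
    noise_sd: float = 0.2,
    mass_jitter_ppm: float = 0.3,
    miscalibration="random",
    isotope: bool = True,
    standards: Sequence[float] = DEFAULT_STANDARDS,
    seed: int | None = None,
) -> dict[tuple[str, int], PeakList]:
    """Emit one observed peak list per (sample, detected mode).

    Observed m/z = per-run linear distortion of the adduct m/z plus
    Gaussian ppm jitter; S/N = 2**(baseline + group offset + noise).
    13C partner peaks carry the expected natural-abundance intensity
    ratio nC * 0.0107 / 0.9893.  Internal standards are appended
    (undistorted in truth, distorted in observation).
    """
    if not panel:
        raise ValueError("panel is empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    out: dict[tuple[str, int], PeakList] = {}
    for sample_id, group in design.samples():
        for code, mode in MODES.items():
            if not any(code in met.modes_detected for met in panel):
                continue
            out[(sample_id, code)] = _emit_one_run(
                panel, group, mode, rng, noise_sd, mass_jitter_ppm,
                miscalibration, isotope, standards, sample_id,
            )
    return out


def emit_pooled_replicates(
    panel: Sequence[GroundTruthMetabolite],
    n_replicates: int = 6,
    noise_sd: float = 0.2,
    mass_jitter_ppm: float = 0.3,
    miscalibration="random",
    isotope: bool = True,
    standards: Sequence[float] = DEFAULT_STANDARDS,
    seed: int | None = 0,
) -> dict[int, list[PeakList]]:
    """Replicate injections of one pooled extract, per mode (QC design)."""
    rng = np.random.default_rng(seed)
    out: dict[int, list[PeakList]] = {}
    for code, mode in MODES.items():
        if not any(code in met.modes_detected for met in panel):
            continue
        out[code] = [
            _emit_one_run(
                panel, "control", mode, rng, noise_sd, mass_jitter_ppm,
                miscalibration, isotope, standards,
                sample_id="pooled", replicate=r,
            )
            for r in range(n_replicates)
        ]
    return out


def truth_intensity_array(
    panel: Sequence[GroundTruthMetabolite],
    design: StudyDesign,
    noise_sd: float = 0.2,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
):
    """Log2 S/N matrix (metabolites x samples) straight from the truth.

    Bypasses peak emission and alignment; used to exercise the statistics
    stage at scale.  Returns ``(DataFrame, groups)`` with rows indexed by
    neutral mass in panel order.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(design.seed if seed is None else seed)
    samples = design.samples()
    data = np.empty((len(panel), len(samples)))
    for j, (_, group) in enumerate(samples):
        for i, met in enumerate(panel):
            data[i, j] = met.baseline_log2_sn + met.group_offset(group)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    df = pd.DataFrame(
        data,
        index=[met.neutral_mass for met in panel],
        columns=[sid for sid, _ in samples],
    )
    return df, design.groups


# -- serialization ------------------------------------------------------

def write_peaklists(peaklists: Mapping, directory) -> list[Path]:
    """Write each peak list as a TSV (mz, sn, mode_code, sample_id, replicate)."""
    from .peaklist import write_peaklist_tsv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for key in sorted(peaklists):
        pl = peaklists[key]
        if isinstance(pl, PeakList):
            runs = [pl]
        else:
            runs = list(pl)
        for run in runs:
            name = f"{run.sample_id}_{run.mode}"
            if run.replicate:
                name += f"_rep{run.replicate}"
            path = directory / f"{name}.tsv"
            write_peaklist_tsv(run, path)
            paths.append(path)
    return paths


def write_truth(panel: Sequence[GroundTruthMetabolite], design: StudyDesign, path) -> None:
    """Ground-truth sidecar JSON for a simulated study."""
    payload = {
        "design": {"replicates": list(design.replicates), "seed": design.seed},
        "metabolites": [
            {
                "formula": met.formula.hill(),
                "neutral_mass": met.neutral_mass,
                "baseline_log2_sn": met.baseline_log2_sn,
                "trend_cluster": met.trend_cluster,
                "effect_size": met.effect_size,
                "modes_detected": list(met.modes_detected),
            }
            for met in panel
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
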