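"""Internal-standard linear mass recalibration.

Each injection carries a set of internal-standard peaks of known
theoretical mass spanning m/z 100-1000.  Standards are matched to
observed peaks within a ppm window (one-to-one, nearest wins, ties
broken toward higher S/N), and an ordinary least-squares line of
theoretical on observed mass is fitted and applied to every peak.  The
fit is accepted when every post-fit standard residual is below 1 ppm;
larger residuals raise a flag but do not abort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chem import ppm_error
from .peaklist import PeakList

__all__ = [
    "CalibrationError",
    "MatchedStandard",
    "CalibrationFit",
    "match_standards",
    "fit_and_apply",
    "calibrate_peaklist",
]

logger = logging.getLogger(__name__)

CALIBRATION_RANGE = (100.0, 1000.0)  # m/z range the standards span
RESIDUAL_TOLERANCE_PPM = 1.0


class CalibrationError(RuntimeError):
    """Too few matched standards, or a degenerate fit."""


@dataclass(frozen=True)
class MatchedStandard:
    theoretical: float
    observed: float
    sn: float
    ppm: float  # pre-fit error of the observed peak


@dataclass(frozen=True)
class CalibrationFit:
    slope: float
    intercept: float                # Da
    residuals_ppm: np.ndarray       # post-fit, one per matched standard
    n_standards: int
    unmatched: tuple[float, ...]    # theoretical masses with no peak in window

    @property
    def max_abs_residual_ppm(self) -> float:
        return float(np.max(np.abs(self.residuals_ppm)))

    @property
    def within_tolerance(self) -> bool:
        return self.max_abs_residual_ppm < RESIDUAL_TOLERANCE_PPM


def match_standards(
    pl: PeakList,
    standards,
    window_ppm: float = 10.0,
) -> tuple[list[MatchedStandard], list[float]]:
    """Match each standard to its nearest peak within ``window_ppm``.

    Matching is one-to-one: candidate (standard, peak) pairs are taken in
    order of increasing |ppm| distance (ties toward higher S/N), skipping
    standards or peaks already claimed.  Returns (matches, unmatched
    theoretical masses).  Raises :class:`CalibrationError` if fewer than
    two standards match.
    """
    if window_ppm <= 0:
        raise ValueError("window_ppm must be positive")
    candidates = []
    for theo in standards:
        tol = window_ppm * 1e-6 * theo
        lo = np.searchsorted(pl.mass, theo - tol, side="left")
        hi = np.searchsorted(pl.mass, theo + tol, side="right")
        for j in range(lo, hi):
            candidates.append((abs(ppm_error(pl.mass[j], theo)), -pl.sn[j], theo, j))
    candidates.sort()
    used_std: set[float] = set()
    used_peak: set[int] = set()
    matches: list[MatchedStandard] = []
    for _, _, theo, j in candidates:
        if theo in used_std or j in used_peak:
            continue
        used_std.add(theo)
        used_peak.add(j)
        matches.append(
            MatchedStandard(
                theoretical=theo,
                observed=float(pl.mass[j]),
                sn=float(pl.sn[j]),
                ppm=ppm_error(pl.mass[j], theo),
            )
        )
    unmatched = [s for s in standards if s not in used_std]
    if len(matches) < 2:
        raise CalibrationError(
            f"{pl.sample_id}/{pl.mode}: only {len(matches)} standard(s) matched "
            f"within {window_ppm} ppm; >= 2 required"
        )
    matches.sort(key=lambda m: m.theoretical)
    return matches, unmatched


def fit_and_apply(
    pl: PeakList,
    matches: list[MatchedStandard],
) -> tuple[PeakList, CalibrationFit]:
    """Linear least squares of theoretical on observed standard mass.

    The fit is inverse-variance weighted with weights 1/m**2 because the
    mass error of an FTICR peak is multiplicative (ppm-scale): an
    unweighted fit in Da lets the high-mass standards dominate and
    leaves ppm-scale residuals at the low-mass end.  The correction is
    applied to every peak mass.
    """
    if len(matches) < 2:
        raise CalibrationError("need >= 2 matched standards to fit")
    obs = np.array([m.observed for m in matches])
    theo = np.array([m.theoretical for m in matches])
    if np.ptp(obs) == 0:
        raise CalibrationError("singular fit: all observed standard masses identical")
    w = 1.0 / obs  # row scaling: residuals become relative (ppm-scale)
    A = np.column_stack([obs * w, w])
    slope, intercept = np.linalg.lstsq(A, theo * w, rcond=None)[0]
    corrected = slope * obs + intercept
    residuals = np.array([ppm_error(c, t) for c, t in zip(corrected, theo)])
    fit = CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        residuals_ppm=residuals,
        n_standards=len(matches),
        unmatched=(),
    )
    if not fit.within_tolerance:
        logger.warning(
            "%s/%s: max standard residual %.3f ppm exceeds %.1f ppm",
            pl.sample_id, pl.mode, fit.max_abs_residual_ppm, RESIDUAL_TOLERANCE_PPM,
        )
    n_outside = int(np.sum((pl.mass < CALIBRATION_RANGE[0]) | (pl.mass > CALIBRATION_RANGE[1])))
    if n_outside:
        logger.debug(
            "%s/%s: %d peak(s) outside the %.0f-%.0f calibration range "
            "recalibrated by extrapolation",
            pl.sample_id, pl.mode, n_outside, *CALIBRATION_RANGE,
        )
    calibrated = pl.with_masses(slope * pl.mass + intercept, calibrated=True)
    return calibrated, fit


def calibrate_peaklist(
    pl: PeakList,
    standards,
    window_ppm: float = 10.0,
) -> tuple[PeakList, CalibrationFit]:
    """Convenience: match standards, fit, and apply in one call."""
    matches, unmatched = match_standards(pl, standards, window_ppm)
    calibrated, fit = fit_and_apply(pl, matches)
    from dataclasses import replace as _replace

    return calibrated, _replace(fit, unmatched=tuple(unmatched))
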