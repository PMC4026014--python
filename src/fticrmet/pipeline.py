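"""End-to-end orchestration: simulate -> calibrate -> align -> stats -> annotate.

A single JSON-serializable :class:`PipelineConfig` drives every stage;
all randomness flows from one root seed through named substreams, so an
identical config + seed yields byte-identical output files.  Each stage
writes its interface files into the run directory and a manifest records
the parameter echo plus SHA-256 hashes of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .align import (
    DEFAULT_TOL_PPM,
    align_across_samples,
    merge_modes,
    pair_isotopes,
    strip_standards,
    to_neutral_mass,
)
from .annotate import enumerate_formulas
from .calibrate import calibrate_peaklist
from .peaklist import read_peaklist_dir
from .simulate import (
    DEFAULT_STANDARDS,
    StudyDesign,
    emit_peaklists,
    emit_pooled_replicates,
    generate_panel,
    write_peaklists,
    write_truth,
)
from .stats import (
    classify_trends,
    group_tests,
    hca,
    log_transform,
    pca,
    qc_report,
    trend_profiles,
)

__all__ = ["PipelineConfig", "PipelineError", "run_all"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None          # used when simulate is False
    # synthetic study
    n_metabolites: int = 300
    cluster_fractions: tuple[float, float, float, float] = (0.05, 0.05, 0.05, 0.05)
    effect_size: float = 1.5
    noise_sd: float = 0.2
    mass_jitter_ppm: float = 0.3
    replicates: tuple[int, int, int, int] = (2, 3, 2, 3)
    n_pooled_replicates: int = 6
    # tolerances and thresholds
    calibration_window_ppm: float = 10.0
    alignment_ppm: float = DEFAULT_TOL_PPM
    annotation_ppm: float = 5.0
    fc_threshold: float = 0.5
    alpha: float = 0.05
    alpha_strict: float = 0.01
    annotate_top: int = 10

    def __post_init__(self):
        for name in ("calibration_window_ppm", "alignment_ppm", "annotation_ppm", "fc_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.cluster_fractions = tuple(self.cluster_fractions)
        self.replicates = tuple(self.replicates)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_all(config: PipelineConfig, outdir) -> Path:
    """Execute every stage and return the artifact directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    design = StudyDesign(replicates=config.replicates, seed=config.seed)

    # ---- simulate (or load) --------------------------------------------
    @_stage("simulate")
    def stage_simulate():
        rng = np.random.default_rng(seeds[0])
        panel = generate_panel(
            n_metabolites=config.n_metabolites,
            cluster_fractions=config.cluster_fractions,
            effect_size=config.effect_size,
            rng=rng,
        )
        peaklists = emit_peaklists(
            panel,
            design,
            noise_sd=config.noise_sd,
            mass_jitter_ppm=config.mass_jitter_ppm,
            seed=seeds[1].generate_state(1)[0] % (2**31),
        )
        write_peaklists(peaklists, outdir / "peaklists")
        write_truth(panel, design, outdir / "truth.json")
        pooled = emit_pooled_replicates(
            panel,
            n_replicates=config.n_pooled_replicates,
            noise_sd=config.noise_sd,
            mass_jitter_ppm=config.mass_jitter_ppm,
            seed=seeds[2].generate_state(1)[0] % (2**31),
        )
        return list(peaklists.values()), pooled

    @_stage("load")
    def stage_load():
        if config.input_dir is None:
            raise FileNotFoundError("simulate is False and no input_dir given")
        path = Path(config.input_dir)
        if not path.exists():
            raise FileNotFoundError(f"input path does not exist: {path}")
        return read_peaklist_dir(path), None

    runs, pooled = stage_simulate() if config.simulate else stage_load()

    # ---- calibrate -----------------------------------------------------
    @_stage("calibrate")
    def stage_calibrate():
        fits = {}
        calibrated = []
        for pl in runs:
            cal, fit = calibrate_peaklist(pl, DEFAULT_STANDARDS, config.calibration_window_ppm)
            calibrated.append(cal)
            fits[f"{pl.sample_id}:{pl.mode}"] = {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "max_abs_residual_ppm": fit.max_abs_residual_ppm,
                "within_tolerance": fit.within_tolerance,
                "n_standards": fit.n_standards,
            }
        (outdir / "calibration.json").write_text(json.dumps(fits, indent=1, sort_keys=True))
        return calibrated

    calibrated = stage_calibrate()

    # ---- align ---------------------------------------------------------
    @_stage("align")
    def stage_align():
        by_mode: dict[int, list] = {}
        for pl in calibrated:
            clean = strip_standards(pl, DEFAULT_STANDARDS, config.calibration_window_ppm)
            flagged = pair_isotopes(clean, tol_ppm=config.alignment_ppm)
            by_mode.setdefault(pl.mode, []).append(to_neutral_mass(flagged))
        tables = {
            code: align_across_samples(pls, tol_ppm=config.alignment_ppm)
            for code, pls in by_mode.items()
        }
        arr = merge_modes(tables, tol_ppm=config.alignment_ppm, groups=design.groups)
        arr.to_csv(outdir / "array.csv")
        prov = arr.provenance.copy()
        prov.insert(0, "mass", prov.index)
        prov.to_csv(outdir / "provenance.csv", index=False, float_format="%.8f")
        return arr

    arr = stage_align()

    # ---- stats ---------------------------------------------------------
    @_stage("stats")
    def stage_stats():
        log_df = log_transform(arr)
        gs = group_tests(log_df, arr.groups, alpha=config.alpha)
        tp = trend_profiles(log_df, gs, arr.groups, alpha=config.alpha)
        labels = classify_trends(tp, fc_threshold=config.fc_threshold)
        stats_table = pd.concat([gs.frame, tp, labels], axis=1)
        stats_table.insert(0, "mass", stats_table.index)
        stats_table.to_csv(outdir / "stats.csv", index=False, float_format="%.8g")

        sig = gs.frame["f_p"] < config.alpha
        if sig.sum() >= 2:
            res = pca(log_df, row_filter=sig)
            res.scores.to_csv(outdir / "pca_scores.csv", float_format="%.8g")
            res.loadings.to_csv(outdir / "pca_loadings.csv", float_format="%.8g")
            pd.Series(res.variance_fractions, name="variance_fraction").to_csv(
                outdir / "pca_variance.csv", float_format="%.8g"
            )
        strict = gs.frame["f_p"] < config.alpha_strict
        if strict.sum() >= 2:
            h = hca(log_df.loc[strict])
            payload = {
                "row_order": h.row_order.tolist(),
                "col_order": h.col_order.tolist(),
                "row_masses": [float(x) for x in h.index],
                "columns": list(h.columns),
                "k4_labels": h.cut_rows(4).tolist(),
            }
            (outdir / "hca.json").write_text(json.dumps(payload, indent=1))
        if pooled is not None:
            pooled_cal = {
                code: [
                    calibrate_peaklist(pl, DEFAULT_STANDARDS, config.calibration_window_ppm)[0]
                    for pl in pls
                ]
                for code, pls in pooled.items()
            }
            qc = qc_report(pooled_cal, DEFAULT_STANDARDS, window_ppm=config.calibration_window_ppm)
            (outdir / "qc.json").write_text(json.dumps(qc.to_dict(), indent=1, sort_keys=True))
        return gs

    gs = stage_stats()

    # ---- annotate ------------------------------------------------------
    @_stage("annotate")
    def stage_annotate():
        order = gs.frame["f_p"].sort_values()
        targets = [m for m in order.index[: config.annotate_top]]
        rows = []
        for m in targets:
            for rank, cand in enumerate(
                enumerate_formulas(float(m), window_ppm=config.annotation_ppm)[:5], start=1
            ):
                rows.append(
                    {
                        "mass": float(m),
                        "rank": rank,
                        "formula": cand.formula.hill(),
                        "theoretical_mass": cand.theoretical_mass,
                        "ppm": cand.ppm,
                        "rdbe": cand.rdbe,
                    }
                )
        pd.DataFrame(
            rows, columns=["mass", "rank", "formula", "theoretical_mass", "ppm", "rdbe"]
        ).to_csv(outdir / "candidates.csv", index=False, float_format="%.8g")

    stage_annotate()

    # ---- manifest ------------------------------------------------------
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package": "fticrmet",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config.to_json()),
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir
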