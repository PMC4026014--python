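"""Group statistics, multivariate views, QC and trend classification.

Works on the log2-scaled metabolite array (rows = masses, columns =
samples).  The per-row F statistic is a one-way ANOVA across the four
collection groups (control, week 4, 8, 12); pairwise comparisons are
independent two-sample Student t-tests (the animals differ between
groups, so no pairing is defined).  P-values are reported raw, matching
the 0.05 / 0.01 thresholds of the emulated workflow; Benjamini-Hochberg
adjustment is available behind a flag.

Trend classification assigns each mass to one of four time-course
patterns relative to control (tau = fold-change threshold in log2
units, default 0.5; a/b/c = significance vs control / week 4 / week 8):

1. below -tau with flag a at weeks 4, 8 and 12;
2. flat at weeks 4 and 8, below -tau at week 12 with flags a, b, c;
3. above +tau at week 8 (flags a, b), below -tau at week 12 (flags a, c);
4. flat at weeks 4 and 8, above +tau at week 12 with flags a, b, c.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .align import MetaboliteArray
from .calibrate import match_standards
from .peaklist import PeakList

__all__ = [
    "GROUPS",
    "GROUP_PAIRS",
    "GroupStats",
    "PCAResult",
    "HCAResult",
    "QCReport",
    "log_transform",
    "group_tests",
    "significant_pair_counts",
    "pca",
    "hca",
    "trend_profiles",
    "classify_trend",
    "classify_trends",
    "qc_report",
    "UNCLASSIFIED",
]

logger = logging.getLogger(__name__)

GROUPS = ("control", "week4", "week8", "week12")
GROUP_PAIRS = tuple(itertools.combinations(GROUPS, 2))
WEEKS = ("week4", "week8", "week12")
UNCLASSIFIED = 0
DEFAULT_FC_THRESHOLD = 0.5  # log2 units


def log_transform(arr: MetaboliteArray | pd.DataFrame) -> pd.DataFrame:
    """log2 the S/N cells; the fill value S/N = 1 maps to 0."""
    df = arr.intensities if isinstance(arr, MetaboliteArray) else arr
    if (df.to_numpy() < 0).any():
        raise ValueError("negative S/N cell encountered")
    with np.errstate(divide="ignore"):
        return np.log2(df)


@dataclass
class GroupStats:
    """Per-row F statistic, pairwise t p-values and group means."""

    frame: pd.DataFrame
    alpha: float = 0.05

    @staticmethod
    def pair_col(g1: str, g2: str) -> str:
        if (g1, g2) not in GROUP_PAIRS:
            g1, g2 = g2, g1
        return f"p_{g1}_vs_{g2}"

    def pairwise_p(self, g1: str, g2: str) -> pd.Series:
        return self.frame[self.pair_col(g1, g2)]


def _group_columns(columns, groups: Mapping[str, str]) -> dict[str, list]:
    by_group: dict[str, list] = {g: [] for g in GROUPS}
    for col in columns:
        g = groups.get(col)
        if g is None:
            raise KeyError(f"sample {col!r} has no group assignment")
        by_group[g].append(col)
    return by_group


def group_tests(
    log_df: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 0.05,
    bh_adjust: bool = False,
) -> GroupStats:
    """One-way ANOVA across groups plus the six pairwise Student t-tests.

    Constant rows yield NaN p-values (no variance to test).  Pairs where
    a group has < 2 samples get NaN with a warning.
    """
    by_group = _group_columns(log_df.columns, groups)
    present = [g for g in GROUPS if by_group[g]]
    if sum(len(by_group[g]) >= 2 for g in present) < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each for the F-test")

    out = pd.DataFrame(index=log_df.index)
    arrays = {g: log_df[by_group[g]].to_numpy() for g in present}
    for g in present:
        out[f"mean_{g}"] = arrays[g].mean(axis=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, f_p = sps.f_oneway(*[arrays[g] for g in present if len(by_group[g]) >= 1], axis=1)
    out["f_stat"] = f_stat
    out["f_p"] = f_p

    for g1, g2 in GROUP_PAIRS:
        col = GroupStats.pair_col(g1, g2)
        if g1 not in arrays or g2 not in arrays:
            out[col] = np.nan
            continue
        if len(by_group[g1]) < 2 or len(by_group[g2]) < 2:
            logger.warning("pair %s vs %s: a group has < 2 samples; p undefined", g1, g2)
            out[col] = np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = sps.ttest_ind(arrays[g1], arrays[g2], axis=1, equal_var=True)
        out[col] = p

    if bh_adjust:
        from statsmodels.stats.multitest import multipletests  # lazy; optional path

        for col in ["f_p"] + [GroupStats.pair_col(*p) for p in GROUP_PAIRS]:
            mask = out[col].notna()
            if mask.any():
                out.loc[mask, col] = multipletests(out.loc[mask, col], method="fdr_bh")[1]
    return GroupStats(frame=out, alpha=alpha)


def significant_pair_counts(gs: GroupStats, alpha: float | None = None) -> pd.DataFrame:
    """Count of rows below alpha for each group pair (upper triangle)."""
    a = gs.alpha if alpha is None else alpha
    mat = pd.DataFrame(index=list(GROUPS), columns=list(GROUPS), dtype="Int64")
    for g1, g2 in GROUP_PAIRS:
        mat.loc[g1, g2] = int((gs.pairwise_p(g1, g2) < a).sum())
    return mat


@dataclass
class PCAResult:
    scores: pd.DataFrame             # samples x components
    loadings: pd.DataFrame           # masses x components
    variance_fractions: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(log_df: pd.DataFrame, row_filter: pd.Series | None = None) -> PCAResult:
    """Column-centered PCA with samples as observations, masses as variables."""
    df = log_df.loc[row_filter] if row_filter is not None else log_df
    if len(df) < 2:
        raise ValueError("need >= 2 rows (masses) for PCA")
    if df.shape[1] < 2:
        raise ValueError("need >= 2 samples for PCA")
    X = df.T.to_numpy(dtype=float)           # samples x masses
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(X.shape[0] - 1, X.shape[1])
    k = max(k, 1)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    total = float(np.sum(s**2))
    frac = s**2 / total if total > 0 else np.full(k, np.nan)
    comps = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(U * s, index=df.columns, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=df.index, columns=comps),
        variance_fractions=frac,
    )


@dataclass
class HCAResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: np.ndarray   # leaf order over masses
    col_order: np.ndarray   # leaf order over samples
    index: pd.Index
    columns: pd.Index

    def cut_rows(self, k: int) -> pd.Series:
        labels = fcluster(self.row_linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.index, name="hca_cluster")


def hca(log_df: pd.DataFrame) -> HCAResult:
    """Average-linkage clustering: masses by 1 - Pearson r, samples by Euclidean."""
    if len(log_df) < 2 or log_df.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns for HCA")
    X = log_df.to_numpy(dtype=float)
    constant = X.std(axis=1) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d_rows = pdist(X, metric="correlation")
    if np.isnan(d_rows).any():
        logger.warning(
            "%d constant row(s): correlation undefined, assigned max distance",
            int(constant.sum()),
        )
        d_rows = np.nan_to_num(d_rows, nan=2.0)
    row_link = linkage(d_rows, method="average")
    col_link = linkage(pdist(X.T, metric="euclidean"), method="average")
    return HCAResult(
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=leaves_list(row_link),
        col_order=leaves_list(col_link),
        index=log_df.index,
        columns=log_df.columns,
    )


def trend_profiles(
    log_df: pd.DataFrame,
    gs: GroupStats,
    groups: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Control-normalized log2 fold changes plus a/b/c significance flags.

    fc_weekW = mean(week W) - mean(control) in log2 units.  Flags:
    a_W = p < alpha vs control, b_W = vs week 4, c_W = vs week 8.
    """
    by_group = _group_columns(log_df.columns, groups)
    if not by_group["control"]:
        raise ValueError("control group absent; cannot normalize")
    tp = pd.DataFrame(index=log_df.index)
    for w in WEEKS:
        tp[f"fc_{w}"] = gs.frame[f"mean_{w}"] - gs.frame["mean_control"]
    for w in WEEKS:
        tp[f"a_{w}"] = gs.pairwise_p("control", w) < alpha
    for w in ("week8", "week12"):
        tp[f"b_{w}"] = gs.pairwise_p("week4", w) < alpha
    tp["c_week12"] = gs.pairwise_p("week8", "week12") < alpha
    return tp


def classify_trend(row: Mapping[str, float], fc_threshold: float = DEFAULT_FC_THRESHOLD) -> int:
    """Assign one trend-profile row to cluster 1-4, or 0 (unclassified)."""
    t = fc_threshold
    fc4, fc8, fc12 = row["fc_week4"], row["fc_week8"], row["fc_week12"]
    if fc4 < -t and row["a_week4"] and fc8 < -t and row["a_week8"] and fc12 < -t and row["a_week12"]:
        return 1
    if abs(fc4) <= t and abs(fc8) <= t and fc12 < -t and row["a_week12"] and row["b_week12"] and row["c_week12"]:
        return 2
    if fc8 > t and row["a_week8"] and row["b_week8"] and fc12 < -t and row["a_week12"] and row["c_week12"]:
        return 3
    if abs(fc4) <= t and abs(fc8) <= t and fc12 > t and row["a_week12"] and row["b_week12"] and row["c_week12"]:
        return 4
    return UNCLASSIFIED


def classify_trends(tp: pd.DataFrame, fc_threshold: float = DEFAULT_FC_THRESHOLD) -> pd.Series:
    return pd.Series(
        [classify_trend(row, fc_threshold) for _, row in tp.iterrows()],
        index=tp.index,
        name="trend_cluster",
    )


# -- quality control ----------------------------------------------------

@dataclass
class ModeQC:
    mean_cv_percent: float
    mean_r2: float | None
    n_replicates: int


@dataclass
class QCReport:
    per_mode: dict[int, ModeQC]

    @property
    def overall_mean_cv_percent(self) -> float:
        return float(np.mean([m.mean_cv_percent for m in self.per_mode.values()]))

    @property
    def overall_mean_r2(self) -> float:
        vals = [m.mean_r2 for m in self.per_mode.values() if m.mean_r2 is not None]
        return float(np.mean(vals)) if vals else float("nan")

    def to_dict(self) -> dict:
        return {
            str(code): {
                "mean_cv_percent": m.mean_cv_percent,
                "mean_r2": m.mean_r2,
                "n_replicates": m.n_replicates,
            }
            for code, m in self.per_mode.items()
        }


def qc_report(
    replicates_by_mode: Mapping[int, Sequence[PeakList]],
    standards,
    window_ppm: float = 5.0,
    tol_ppm: float = 2.0,
    log_scale: bool = True,
) -> QCReport:
    """Reproducibility QC from replicate injections of one pooled extract.

    CV: for each internal standard, sd/mean of its matched S/N across a
    mode's replicates, averaged over standards (percent).  R2: replicate
    peak lists are aligned into a profile table; every replicate pair is
    regressed (log2 intensities by default, absences filled at the noise
    floor) and the squared correlation is averaged.
    """
    from .align import align_across_samples  # local to avoid cycle at import

    per_mode: dict[int, ModeQC] = {}
    for code, runs in replicates_by_mode.items():
        runs = list(runs)
        # -- CV of internal standards
        sn_by_std: dict[float, list[float]] = {s: [] for s in standards}
        for pl in runs:
            matches, _ = match_standards(pl, standards, window_ppm)
            for m in matches:
                sn_by_std[m.theoretical].append(m.sn)
        cvs = []
        for vals in sn_by_std.values():
            if len(vals) >= 2:
                arr = np.asarray(vals)
                cvs.append(float(arr.std(ddof=1) / arr.mean()))
        mean_cv = 100.0 * float(np.mean(cvs)) if cvs else float("nan")

        # -- pairwise replicate R2 over full profiles
        if len(runs) < 2:
            logger.warning("mode %s: < 2 replicates, R2 omitted", code)
            per_mode[code] = ModeQC(mean_cv, None, len(runs))
            continue
        table = align_across_samples(runs, tol_ppm=tol_ppm, by_replicate=True)
        prof = table.fillna(1.0)
        if log_scale:
            prof = np.log2(prof)
        r2s = []
        cols = list(prof.columns)
        for i, j in itertools.combinations(range(len(cols)), 2):
            x, y = prof[cols[i]].to_numpy(), prof[cols[j]].to_numpy()
            if x.std() == 0 or y.std() == 0:
                r2s.append(1.0 if np.allclose(x, y) else 0.0)
            else:
                r2s.append(float(np.corrcoef(x, y)[0, 1] ** 2))
        per_mode[code] = ModeQC(mean_cv, float(np.mean(r2s)), len(runs))
    return QCReport(per_mode=per_mode)
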