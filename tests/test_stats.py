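"""Group tests, PCA, HCA, trend classification and QC."""

import numpy as np
import pandas as pd
import pytest

from fticrmet.simulate import StudyDesign, generate_panel, truth_intensity_array
from fticrmet.stats import (
    UNCLASSIFIED,
    classify_trend,
    classify_trends,
    group_tests,
    hca,
    log_transform,
    pca,
    qc_report,
    significant_pair_counts,
    trend_profiles,
)


def toy_log_array(design, rows):
    samples = design.samples()
    df = pd.DataFrame(
        {sid: [row[g] for row in rows] for sid, g in samples},
        index=[100.0 + i for i in range(len(rows))],
    )
    return df, dict(samples)


class TestLogTransform:
    def test_exact_powers(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 8.0], "b": [1.0, 1.0, 1.0]})
        out = log_transform(df)
        assert out["a"].tolist() == [1.0, 2.0, 3.0]
        assert out["b"].tolist() == [0.0, 0.0, 0.0]

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            log_transform(pd.DataFrame({"a": [-1.0]}))


class TestGroupTests:
    def test_constant_row_has_undefined_p(self, design):
        df, groups = toy_log_array(
            design, [{g: 5.0 for g in ("control", "week4", "week8", "week12")}]
        )
        gs = group_tests(df, groups)
        assert np.isnan(gs.frame["f_p"].iloc[0])

    def test_planted_difference_detected(self, design):
        df, groups = toy_log_array(
            design, [{"control": 5.0, "week4": 5.0, "week8": 5.0, "week12": 1.0}]
        )
        df += np.random.default_rng(0).normal(0, 0.05, df.shape)
        gs = group_tests(df, groups)
        assert gs.frame["f_p"].iloc[0] < 0.01
        assert gs.pairwise_p("week8", "week12").iloc[0] < 0.01
        assert gs.pairwise_p("control", "week4").iloc[0] > 0.05

    def test_type_i_error_matches_alpha(self, design):
        panel = generate_panel(1000, cluster_fractions=(0, 0, 0, 0), seed=13)
        df, groups = truth_intensity_array(panel, design, noise_sd=0.2, seed=14)
        gs = group_tests(df, groups)
        rate = (gs.frame["f_p"] < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_pair_counts_table(self, design):
        df, groups = toy_log_array(
            design, [{"control": 5.0, "week4": 5.0, "week8": 5.0, "week12": 1.0}] * 3
        )
        df += np.random.default_rng(1).normal(0, 0.05, df.shape)
        counts = significant_pair_counts(group_tests(df, groups))
        assert counts.loc["week8", "week12"] == 3
        assert counts.loc["control", "week4"] == 0

    def test_row_and_column_order_invariance(self, design):
        panel = generate_panel(50, seed=17)
        df, groups = truth_intensity_array(panel, design, noise_sd=0.2, seed=18)
        gs1 = group_tests(df, groups).frame
        shuffled = df.sample(frac=1, axis=0, random_state=0).sample(frac=1, axis=1, random_state=1)
        gs2 = group_tests(shuffled, groups).frame
        pd.testing.assert_frame_equal(gs1.sort_index(), gs2.sort_index())


class TestPCA:
    def test_rank_one_data_loads_on_pc1(self, design):
        samples = [s for s, _ in design.samples()]
        direction = np.linspace(-1, 1, len(samples))
        df = pd.DataFrame(
            np.outer([1.0, 2.0, 3.0], direction), columns=samples,
            index=[100.0, 200.0, 300.0],
        )
        res = pca(df)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_matches_brute_force_eigendecomposition(self, rng):
        X = rng.normal(size=(4, 5))  # 5 masses x 4 samples
        df = pd.DataFrame(X.T, columns=list("abcd"))
        res = pca(df)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        evals = evals[::-1]
        assert np.allclose(res.variance_fractions, evals[: res.n_components] / evals.sum(), atol=1e-9)
        scores_norms = np.sort((res.scores.to_numpy() ** 2).sum(axis=0))[::-1]
        assert np.allclose(scores_norms, evals[: res.n_components], atol=1e-8)

    def test_variance_fractions_sum_to_one_and_scores_orthogonal(self, design):
        panel = generate_panel(40, seed=19)
        df, _ = truth_intensity_array(panel, design, noise_sd=0.3, seed=20)
        res = pca(df)
        assert res.variance_fractions.sum() == pytest.approx(1.0)
        G = res.scores.to_numpy().T @ res.scores.to_numpy()
        assert np.allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_week12_separates_along_pc1(self, design):
        """Late-time-point samples split from the rest (the global view)."""
        from sklearn.metrics import silhouette_score

        panel = generate_panel(200, (0.1, 0.1, 0.1, 0.1), effect_size=1.5, seed=23)
        df, groups = truth_intensity_array(panel, design, noise_sd=0.2, seed=24)
        gs = group_tests(df, groups)
        res = pca(df, row_filter=gs.frame["f_p"] < 0.05)
        labels = [1 if groups[s] == "week12" else 0 for s in res.scores.index]
        assert silhouette_score(res.scores[["PC1"]].to_numpy(), labels) > 0


class TestHCA:
    def test_correlation_distances(self, design):
        samples = [s for s, _ in design.samples()]
        base = np.linspace(0, 1, len(samples))
        df = pd.DataFrame(
            [base, 2 * base + 1, -base], columns=samples, index=[1.0, 2.0, 3.0]
        )
        res = hca(df)
        from scipy.spatial.distance import squareform

        d = squareform(
            np.asarray([[0, 0, 2], [0, 0, 2], [2, 2, 0]], float), checks=False
        )
        from scipy.spatial.distance import pdist

        got = pdist(df.to_numpy(), metric="correlation")
        assert np.allclose(got, d, atol=1e-12)

    def test_constant_row_gets_max_distance_with_warning(self, design, caplog):
        samples = [s for s, _ in design.samples()]
        df = pd.DataFrame(
            [np.linspace(0, 1, len(samples)), np.full(len(samples), 3.0)],
            columns=samples, index=[1.0, 2.0],
        )
        with caplog.at_level("WARNING", logger="fticrmet.stats"):
            res = hca(df)
        assert res.row_linkage[0, 2] == pytest.approx(2.0)

    def test_planted_clusters_recovered_at_k4(self, design):
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(20):
            panel = generate_panel(120, (0.25, 0.25, 0.25, 0.25), effect_size=1.5, seed=seed)
            df, _ = truth_intensity_array(panel, design, noise_sd=0.2, seed=seed + 500)
            truth = np.array([m.trend_cluster for m in panel])
            pred = hca(df).cut_rows(4).to_numpy()
            aris.append(adjusted_rand_score(truth, pred))
        assert np.median(aris) >= 0.9


class TestTrendClassification:
    def _stats(self, design, rows, noise=0.05, seed=0):
        df, groups = toy_log_array(design, rows)
        df += np.random.default_rng(seed).normal(0, noise, df.shape)
        gs = group_tests(df, groups)
        return trend_profiles(df, gs, groups)

    def test_flat_row_unclassified(self, design):
        tp = self._stats(design, [{"control": 5, "week4": 5, "week8": 5, "week12": 5}])
        assert tp["fc_week4"].iloc[0] == pytest.approx(0, abs=0.2)
        assert classify_trends(tp).iloc[0] == UNCLASSIFIED

    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ({"control": 5, "week4": 4, "week8": 4, "week12": 4}, 1),
            ({"control": 5, "week4": 5, "week8": 5, "week12": 4}, 2),
            ({"control": 5, "week4": 5, "week8": 6, "week12": 4}, 3),
            ({"control": 5, "week4": 5, "week8": 5, "week12": 6}, 4),
        ],
    )
    def test_four_patterns(self, design, pattern, expected):
        tp = self._stats(design, [pattern])
        assert classify_trends(tp).iloc[0] == expected

    def test_control_normalization_identity(self, design):
        tp = self._stats(design, [{"control": 7, "week4": 7, "week8": 7, "week12": 7}], noise=0)
        assert tp[["fc_week4", "fc_week8", "fc_week12"]].iloc[0].tolist() == [0, 0, 0]

    def test_planted_labels_recovered(self, design):
        accs = []
        for seed in range(20):
            panel = generate_panel(100, (0.1, 0.1, 0.1, 0.1), effect_size=1.5, seed=seed)
            df, groups = truth_intensity_array(panel, design, noise_sd=0.2, seed=seed + 900)
            gs = group_tests(df, groups)
            labels = classify_trends(trend_profiles(df, gs, groups))
            truth = np.array([m.trend_cluster for m in panel])
            mask = truth != 0
            accs.append((labels.to_numpy()[mask] == truth[mask]).mean())
        assert np.median(accs) >= 0.95


class TestQC:
    def test_constant_replicates_perfect(self):
        from fticrmet.peaklist import PeakList

        masses = np.array([150.0, 250.0, 350.0])
        sns = np.array([50.0, 60.0, 70.0])
        runs = [
            PeakList("pooled", 1101, masses, sns, calibrated=True, replicate=r)
            for r in range(3)
        ]
        qc = qc_report({1101: runs}, standards=[150.0, 250.0])
        assert qc.per_mode[1101].mean_cv_percent == pytest.approx(0.0)
        assert qc.per_mode[1101].mean_r2 == pytest.approx(1.0)

    def test_single_replicate_omits_r2(self):
        from fticrmet.peaklist import PeakList

        runs = [PeakList("pooled", 1101, np.array([150.0, 250.0]),
                         np.array([5.0, 6.0]), calibrated=True)]
        qc = qc_report({1101: runs}, standards=[150.0, 250.0])
        assert qc.per_mode[1101].mean_r2 is None

    def test_default_noise_meets_stated_bounds(self):
        """log2 sd 0.2 -> CV ~ 14 %, below the 20 % bound; R2 > 0.95."""
        from fticrmet.calibrate import calibrate_peaklist
        from fticrmet.simulate import DEFAULT_STANDARDS, emit_pooled_replicates

        panel = generate_panel(300, cluster_fractions=(0, 0, 0, 0), seed=31)
        pooled = emit_pooled_replicates(panel, n_replicates=6, seed=32)
        cal = {
            c: [calibrate_peaklist(p, DEFAULT_STANDARDS)[0] for p in runs]
            for c, runs in pooled.items()
        }
        qc = qc_report(cal, DEFAULT_STANDARDS)
        for mode_qc in qc.per_mode.values():
            assert mode_qc.mean_cv_percent < 20.0
            assert mode_qc.mean_r2 > 0.95
        assert 8.0 < qc.overall_mean_cv_percent < 18.0
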