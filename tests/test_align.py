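"""Isotope pairing, neutral-mass conversion and array assembly."""

import numpy as np
import pytest

from fticrmet.align import (
    align_across_samples,
    merge_modes,
    pair_isotopes,
    strip_standards,
    to_neutral_mass,
)
from fticrmet.calibrate import calibrate_peaklist
from fticrmet.chem import C13_SHIFT, PROTON_MASS
from fticrmet.peaklist import PeakList
from fticrmet.simulate import DEFAULT_STANDARDS, MODES, emit_peaklists, generate_panel


def make_peaklist(masses, sns, mode=1102, sample="s1", **kw):
    kw.setdefault("calibrated", True)
    return PeakList(sample, mode, np.asarray(masses, float), np.asarray(sns, float), **kw)


class TestIsotopePairing:
    def test_carbon20_partner_flagged(self):
        # S/N ratio 0.21 matches the C20 expectation 20*0.0107/0.9893 = 0.216
        pl = make_peaklist([394.2848, 394.2848 + C13_SHIFT], [100.0, 21.0])
        out = pair_isotopes(pl, tol_ppm=2)
        assert out.is_isotope.tolist() == [False, True]

    def test_lone_peak_unflagged(self):
        out = pair_isotopes(make_peaklist([394.2848], [100.0]))
        assert out.is_isotope.tolist() == [False]

    def test_implausible_ratio_unflagged(self):
        # ratio 1.5 would need ~139 carbons; a 394 Da ion holds at most 32
        pl = make_peaklist([394.2848, 394.2848 + C13_SHIFT], [100.0, 150.0])
        out = pair_isotopes(pl, tol_ppm=2)
        assert out.is_isotope.tolist() == [False, False]

    def test_uncalibrated_rejected(self):
        with pytest.raises(ValueError):
            pair_isotopes(make_peaklist([100.0], [1.0], calibrated=False))


class TestNeutralMass:
    def test_negative_mode_adds_proton(self):
        pl = make_peaklist([393.2773], [10.0], mode=1102)
        out = to_neutral_mass(pl)
        assert out.mass[0] == pytest.approx(394.2846, abs=1e-4)
        assert out.neutral

    def test_positive_mode_subtracts_proton(self):
        pl = make_peaklist([395.2921], [10.0], mode=1101)
        assert to_neutral_mass(pl).mass[0] == pytest.approx(394.2848, abs=1e-4)

    def test_round_trip_identity(self):
        from fticrmet.peaklist import mz_from_neutral, neutral_from_mz

        for pol in ("positive", "negative"):
            assert neutral_from_mz(mz_from_neutral(500.123, pol), pol) == pytest.approx(500.123)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            to_neutral_mass(make_peaklist([100.0], [1.0], mode=9999))


class TestAlignment:
    def test_close_masses_form_one_row(self):
        pls = [
            make_peaklist([500.0000], [10.0], sample="a", neutral=True),
            make_peaklist([500.0005], [20.0], sample="b", neutral=True),
            make_peaklist([500.0008], [30.0], sample="c", neutral=True),
        ]
        table = align_across_samples(pls, tol_ppm=2)
        assert len(table) == 1
        assert table.notna().sum().sum() == 3
        # representative mass is the intensity-weighted mean
        rep = table.index[0]
        assert rep == pytest.approx((500.0 * 10 + 500.0005 * 20 + 500.0008 * 30) / 60)

    def test_distant_masses_stay_separate(self):
        pls = [
            make_peaklist([500.000], [10.0], sample="a", neutral=True),
            make_peaklist([500.010], [10.0], sample="b", neutral=True),
        ]
        assert len(align_across_samples(pls, tol_ppm=2)) == 2

    def test_single_peak_single_row(self):
        table = align_across_samples([make_peaklist([300.0], [5.0], neutral=True)])
        assert len(table) == 1 and table.iloc[0, 0] == 5.0

    def test_one_peak_per_sample_per_row(self):
        # two same-sample peaks 0.5 ppm apart: nearest to the representative wins
        pls = [
            make_peaklist([500.0000, 500.00025], [10.0, 40.0], sample="a", neutral=True),
            make_peaklist([500.0001], [20.0], sample="b", neutral=True),
        ]
        table = align_across_samples(pls, tol_ppm=2)
        assert len(table) == 1
        assert table.loc[table.index[0], "a"] in (10.0, 40.0)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        base = [
            make_peaklist(np.sort(rng.uniform(100, 900, 50)), rng.uniform(1, 100, 50),
                          sample=f"s{i}", neutral=True)
            for i in range(4)
        ]
        t1 = align_across_samples(base, tol_ppm=2)
        t2 = align_across_samples(base[::-1], tol_ppm=2)
        assert np.allclose(t1.index, t2.index)
        assert t1.equals(t2)


class TestMergeModes:
    def test_disjoint_modes_concatenate(self):
        t1 = align_across_samples([make_peaklist([300.0], [5.0], mode=1101, neutral=True)])
        t2 = align_across_samples([make_peaklist([400.0], [6.0], mode=1102, neutral=True)])
        arr = merge_modes({1101: t1, 1102: t2})
        assert arr.n_rows == 2
        assert arr.per_mode_counts() == {"1101": 1, "1102": 1}

    def test_shared_mass_merges_with_joint_provenance(self):
        t1 = align_across_samples([make_peaklist([400.0000], [5.0], mode=1101, neutral=True)])
        t2 = align_across_samples([make_peaklist([400.0004], [9.0], mode=1102, neutral=True)])
        arr = merge_modes({1101: t1, 1102: t2}, tol_ppm=2)
        assert arr.n_rows == 1
        assert arr.provenance["modes"].iloc[0] == "1101+1102"
        assert arr.intensities.iloc[0, 0] == 9.0  # conflict -> higher S/N
        # separate-count convention keeps both rows
        assert merge_modes({1101: t1, 1102: t2}, merge_shared=False).n_rows == 2

    def test_missing_cells_filled_at_noise_floor(self):
        t1 = align_across_samples(
            [
                make_peaklist([300.0], [5.0], sample="a", mode=1101, neutral=True),
                make_peaklist([310.0], [7.0], sample="b", mode=1101, neutral=True),
            ]
        )
        arr = merge_modes({1101: t1})
        assert (arr.intensities.to_numpy() >= 1.0).all()
        assert arr.intensities.loc[arr.masses[0], "b"] == 1.0


class TestGeneratorClosure:
    def test_noiseless_pipeline_recovers_planted_panel(self, design):
        """Zero noise, zero jitter: the array equals the ground truth."""
        panel = generate_panel(80, cluster_fractions=(0.1, 0.1, 0.1, 0.1),
                               effect_size=1.5, seed=21)
        pls = emit_peaklists(panel, design, noise_sd=0, mass_jitter_ppm=0,
                             miscalibration=(1 + 3e-6, 5e-4), seed=2)
        by_mode = {}
        for (sid, code), pl in pls.items():
            cal, _ = calibrate_peaklist(pl, DEFAULT_STANDARDS)
            clean = strip_standards(cal, DEFAULT_STANDARDS)
            by_mode.setdefault(code, []).append(to_neutral_mass(pair_isotopes(clean)))
        tables = {c: align_across_samples(v) for c, v in by_mode.items()}
        arr = merge_modes(tables, groups=design.groups)

        assert arr.n_rows == len(panel)
        truth = np.sort([m.neutral_mass for m in panel])
        got = np.sort(arr.masses)
        assert np.max(np.abs(got - truth) / truth) * 1e6 < 0.1
        # noiseless S/N cells match the planted baselines exactly
        truth_by_mass = {m.neutral_mass: m for m in panel}
        for mass in arr.masses:
            met = truth_by_mass[min(truth_by_mass, key=lambda t: abs(t - mass))]
            ctrl = arr.intensities.loc[mass, "control_1"]
            if 2.0 ** met.baseline_log2_sn >= 1.0 and ctrl != arr.fill_value:
                assert np.log2(ctrl) == pytest.approx(met.baseline_log2_sn, abs=1e-6)
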