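"""Critical velocity, trajectory classification and the kinetics summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nephroscreen import (
    TrajSimConfig,
    VesselSegment,
    adhesion_by_shear,
    classify_cells,
    critical_velocity,
    estimate_centerline_velocity,
    generate_trajectories,
    segment_geometry,
    transmigration_summary,
)


def track(cell_id, t, x, y, segment_id="S1", region="vascular"):
    n = len(t)
    return pd.DataFrame(
        {
            "cell_id": cell_id,
            "t_s": t,
            "x_um": np.broadcast_to(x, (n,)),
            "y_um": np.broadcast_to(y, (n,)),
            "segment_id": segment_id,
            "region": np.broadcast_to(region, (n,)),
        }
    )


SEG = [VesselSegment("S1", diameter=30.0, v_cc=200.0, shear_rate=26.7)]


class TestCriticalVelocity:
    def test_formula_and_boundaries(self):
        assert critical_velocity(100.0, 10.0, 20.0) == pytest.approx(75.0)
        assert critical_velocity(200.0, 7.5, 30.0) == pytest.approx(87.5)
        # eps = 1: a cell as wide as the vessel rides the centerline
        assert critical_velocity(123.0, 5.0, 5.0) == pytest.approx(123.0)
        assert critical_velocity(100.0, 1e-9, 50.0) == pytest.approx(0.0, abs=1e-8)

    def test_oversized_cell_rejected(self):
        with pytest.raises(ValueError, match="eps"):
            critical_velocity(100.0, 30.0, 20.0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        v_cc=st.floats(0.0, 1e4),
        eps=st.floats(1e-6, 1.0),
    )
    def test_algebraic_identity_and_bounds(self, v_cc, eps):
        v = critical_velocity(v_cc, eps, 1.0)
        # v_crit = v_cc * (1 - (1 - eps)^2), never above v_cc
        assert v == pytest.approx(v_cc * (1.0 - (1.0 - eps) ** 2), rel=1e-12, abs=1e-12)
        assert v <= v_cc + 1e-9


class TestEstimateCenterlineVelocity:
    def test_constant_speed_single_cell(self):
        t = np.arange(0, 31.0, 0.5)
        traj = track("c1", t, 120.0 * t, 0.0)
        assert estimate_centerline_velocity(traj, "S1") == pytest.approx(120.0)

    def test_max_over_cells(self):
        t = np.arange(0, 31.0, 0.5)
        traj = pd.concat(
            [track(f"c{i}", t, v * t, 0.0) for i, v in enumerate([50.0, 80.0, 120.0])]
        )
        assert estimate_centerline_velocity(traj, "S1") == pytest.approx(120.0)
        assert estimate_centerline_velocity(traj, "S1", q=50) == pytest.approx(80.0)

    def test_empty_segment_rejected(self):
        t = np.arange(0, 31.0, 0.5)
        with pytest.raises(ValueError, match="S9"):
            estimate_centerline_velocity(track("c1", t, t, 0.0), "S9")

    def test_poiseuille_cohort_within_ten_percent(self):
        # ten free cells per segment so one flows near the centerline
        cfg = TrajSimConfig(
            seed=21,
            n_cells_per_class={"free": 40, "rolling": 4, "adherent": 4, "transmigrating": 4},
        )
        traj, segments, _ = generate_trajectories(cfg)
        for seg in segments:
            est = estimate_centerline_velocity(traj, seg.segment_id)
            assert est <= seg.v_cc + 1e-9
            assert est >= 0.9 * seg.v_cc


class TestClassifyCells:
    def test_stationary_cell_is_adherent(self):
        t = np.arange(0, 40.0, 0.5)
        cls = classify_cells(track("c1", t, 5.0, 10.0), SEG)
        assert cls.loc["c1", "cls"] == "adherent"

    def test_slow_moving_cell_is_rolling(self):
        t = np.arange(0, 40.0, 0.5)
        v = 0.5 * critical_velocity(200.0, 7.5, 30.0)
        cls = classify_cells(track("c1", t, v * t, 11.0), SEG)
        assert cls.loc["c1", "cls"] == "rolling"
        assert cls.loc["c1", "v_crit_used"] == pytest.approx(87.5)

    def test_fast_cell_is_free(self):
        t = np.arange(0, 40.0, 0.5)
        cls = classify_cells(track("c1", t, 150.0 * t, 0.0), SEG)
        assert cls.loc["c1", "cls"] == "free"

    def test_tissue_region_takes_precedence(self):
        t = np.arange(0, 40.0, 0.5)
        tr = track("c1", t, 5.0, 10.0)  # would be adherent
        tr.loc[tr.index[-5:], "region"] = "tissue"
        cls = classify_cells(tr, SEG)
        assert cls.loc["c1", "cls"] == "transmigrated"
        assert cls.loc["c1", "t_cross"] == pytest.approx(t[-5])

    def test_short_window_rejected(self):
        t = np.arange(0, 10.0, 0.5)
        with pytest.raises(ValueError, match="30"):
            classify_cells(track("c1", t, 5.0, 10.0), SEG)

    def test_time_shift_and_translation_invariance(self):
        cfg = TrajSimConfig(seed=3, n_cells_per_class={"free": 3, "rolling": 3, "adherent": 3, "transmigrating": 3})
        traj, segments, _ = generate_trajectories(cfg)
        base = classify_cells(traj, segments)
        moved = traj.assign(
            t_s=traj["t_s"] + 17.0, x_um=traj["x_um"] - 250.0, y_um=traj["y_um"] + 40.0
        )
        shifted = classify_cells(moved, segments)
        assert (base["cls"] == shifted["cls"]).all()

    def test_monotone_in_delta_and_v_crit(self):
        cfg = TrajSimConfig(seed=8)
        traj, segments, _ = generate_trajectories(cfg)
        tight = classify_cells(traj, segments, delta_um=0.1)
        loose = classify_cells(traj, segments, delta_um=10.0)
        assert (loose["cls"] == "adherent").sum() >= (tight["cls"] == "adherent").sum()
        # doubling every centerline velocity can only add rolling cells
        doubled = [
            VesselSegment(s.segment_id, s.diameter, 2.0 * s.v_cc, s.shear_rate)
            for s in segments
        ]
        more = classify_cells(traj, doubled)
        roll_or_slower = {"rolling", "adherent", "transmigrated"}
        assert (more["cls"].isin(roll_or_slower)).sum() >= (
            classify_cells(traj, segments)["cls"].isin(roll_or_slower)
        ).sum()

    def test_estimated_v_cc_used_when_geometry_lacks_it(self):
        t = np.arange(0, 40.0, 0.5)
        fast = track("c1", t, 200.0 * t, 0.0)
        slow = track("c2", t, 50.0 * t, 11.0)
        segments = [VesselSegment("S1", diameter=30.0)]  # no v_cc supplied
        cls = classify_cells(pd.concat([fast, slow]), segments)
        assert cls.loc["c1", "cls"] == "free"
        assert cls.loc["c2", "cls"] == "rolling"
        assert cls.loc["c2", "v_crit_used"] == pytest.approx(
            critical_velocity(200.0, 7.5, 30.0)
        )


class TestAdhesionByShear:
    def test_no_adherent_cells_all_bins_zero(self):
        cls = pd.DataFrame({"cls": ["free"], "segment_id": ["S1"]}, index=["c1"])
        out = adhesion_by_shear(cls, SEG, bins=[0, 50, 100])
        assert (out == 0).all()

    def test_single_adherent_cell_binned(self):
        seg = [VesselSegment("S1", 30.0, v_cc=200.0, shear_rate=40.0)]
        cls = pd.DataFrame({"cls": ["adherent"], "segment_id": ["S1"]}, index=["c1"])
        out = adhesion_by_shear(cls, seg, bins=[0, 50, 100])
        assert out.iloc[0] == 1 and out.iloc[1] == 0

    def test_uniform_adhesion_tracks_segment_occupancy(self):
        cfg = TrajSimConfig(seed=13, n_cells_per_class={"free": 0, "rolling": 0, "adherent": 8, "transmigrating": 0})
        traj, segments, _ = generate_trajectories(cfg)
        cls = classify_cells(traj, segments)
        shear_rates = sorted(s.shear_rate for s in segments)
        edges = [0] + [r + 0.5 for r in shear_rates]
        out = adhesion_by_shear(cls, segments, bins=edges)
        # 8 adherent cells round-robined over 4 segments -> 2 per shear bin
        assert list(out) == [2, 2, 2, 2]


class TestTransmigrationSummary:
    @staticmethod
    def fake_classification(n_trans, n_roll, n_free, t_cross=20.0):
        n = n_trans + n_roll + n_free
        return pd.DataFrame(
            {
                "cls": ["transmigrated"] * n_trans + ["rolling"] * n_roll + ["free"] * n_free,
                "t_cross": [t_cross] * n_trans + [np.nan] * (n_roll + n_free),
            },
            index=[f"c{i}" for i in range(n)],
        )

    def test_treated_equals_untreated_gives_ratio_one(self):
        cls = self.fake_classification(5, 3, 2)
        out = transmigration_summary({0.0: cls, 5.0: cls.copy()}, [1.0])
        assert out.loc[5.0, "rel_transmigration_1min"] == pytest.approx(1.0)
        assert out.loc[0.0, "pct_rolling"] == pytest.approx(30.0)

    def test_zero_untreated_count_reported_missing(self):
        untreated = self.fake_classification(1, 0, 4, t_cross=50.0)
        treated = self.fake_classification(2, 0, 3, t_cross=10.0)
        out = transmigration_summary({0.0: untreated, 5.0: treated}, [0.5, 1.0])
        assert np.isnan(out.loc[5.0, "rel_transmigration_0.5min"])
        assert out.loc[5.0, "rel_transmigration_1min"] == pytest.approx(2.0)

    def test_untreated_condition_required(self):
        with pytest.raises(ValueError, match="untreated"):
            transmigration_summary({5.0: self.fake_classification(1, 1, 1)}, [1.0])


class TestGenerator:
    def test_single_adherent_cell_zero_jitter(self):
        cfg = TrajSimConfig(
            seed=1,
            n_cells_per_class={"free": 0, "rolling": 0, "adherent": 1, "transmigrating": 0},
            adherent_jitter=0.0,
        )
        traj, _, truth = generate_trajectories(cfg)
        assert truth.cell_labels.iloc[0] == "adherent"
        assert traj["x_um"].nunique() == 1 and traj["y_um"].nunique() == 1

    def test_rolling_below_and_free_above_v_crit(self):
        cfg = TrajSimConfig(seed=17)
        traj, segments, truth = generate_trajectories(cfg)
        vcrit = {
            s.segment_id: critical_velocity(s.v_cc, cfg.cell_diameter, s.diameter)
            for s in segments
        }
        for cell_id, label in truth.cell_labels.items():
            g = traj[traj["cell_id"] == cell_id].sort_values("t_s")
            seg = g["segment_id"].iloc[0]
            dt = g["t_s"].iloc[-1] - g["t_s"].iloc[0]
            dist = np.linalg.norm(
                np.diff(g[["x_um", "y_um"]].to_numpy(), axis=0), axis=1
            ).sum()
            speed = dist / dt
            if label == "rolling":
                assert speed < vcrit[seg]
            elif label == "free":
                assert speed > vcrit[seg]

    def test_generator_v_crit_formula_example(self):
        # v_max 200, vessel 30, cell 7.5 -> v_crit = 200 * 0.25 * 1.75 = 87.5
        cfg = TrajSimConfig(
            seed=2,
            n_segments=1,
            segment_diameters=(30.0,),
            v_max_per_segment=(200.0,),
            n_cells_per_class={"free": 0, "rolling": 5, "adherent": 0, "transmigrating": 0},
        )
        traj, segments, truth = generate_trajectories(cfg)
        assert critical_velocity(segments[0].v_cc, cfg.cell_diameter, 30.0) == pytest.approx(87.5)
        speeds = traj.groupby("cell_id").apply(
            lambda g: np.linalg.norm(
                np.diff(g[["x_um", "y_um"]].to_numpy(), axis=0), axis=1
            ).sum()
            / (g["t_s"].max() - g["t_s"].min()),
            include_groups=False,
        )
        assert (speeds < 87.5).all()

    def test_shear_rate_convention(self):
        cfg = TrajSimConfig(seed=1)
        for seg, d, v in zip(
            segment_geometry(cfg), cfg.segment_diameters, cfg.v_max_per_segment
        ):
            assert seg.shear_rate == pytest.approx(4.0 * v / d)

    def test_determinism(self):
        a, _, _ = generate_trajectories(TrajSimConfig(seed=33))
        b, _, _ = generate_trajectories(TrajSimConfig(seed=33))
        pd.testing.assert_frame_equal(a, b)

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError, match="30"):
            TrajSimConfig(seed=1, duration=20.0)

    def test_truth_keys_match_cells(self):
        traj, _, truth = generate_trajectories(TrajSimConfig(seed=5))
        assert set(truth.cell_labels.index) == set(traj["cell_id"].unique())
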