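import numpy as np
import pytest

from nodulekit.errors import (
    DegenerateInputError,
    EmptyWellError,
    MissingControlError,
    OutOfRangeError,
)
from nodulekit.pipeline import score_well, simulate_well
from nodulekit.synthetic import NoiseModel
from nodulekit.viability import (
    WellRecord,
    estimate_background,
    estimate_ld50,
    normalize_viability,
    student_t_test,
    summarize_irradiance_series,
    well_viability,
)

from oracles import pooled_t_test


class TestEstimateBackground:
    def test_constant_image(self):
        assert estimate_background(np.full((50, 50), 100.0)) == 100.0

    def test_dominant_mode(self):
        img = np.full(1000, 50.0)
        img[:100] = 4000.0
        assert estimate_background(img.reshape(20, 50)) == pytest.approx(50.0, abs=1e-9)

    def test_synthetic_background_recovery(self, rng):
        # background 200 + N(0, 5) with a bright 10% tail, as the renderer makes
        img = 200.0 + rng.normal(0, 5.0, size=(400, 400))
        img[:40] += 4000.0
        assert estimate_background(img) == pytest.approx(200.0, abs=5.0)


class TestWellViability:
    def test_dead_channel_pure_background(self, rng):
        live = np.zeros((200, 200))
        live[50:100, 50:100] = 3000.0
        dead = np.full((200, 200), 150.0)  # constant background, no signal
        _, dead_total, viability = well_viability(live, dead)
        assert dead_total == 0.0
        assert viability == 1.0

    def test_symmetric_channels(self):
        live = np.zeros((100, 100))
        dead = np.zeros((100, 100))
        live[10:20, 10:20] = 500.0
        dead[60:70, 60:70] = 500.0
        _, _, viability = well_viability(live, dead)
        assert viability == pytest.approx(0.5)

    def test_empty_well_raises(self):
        blank = np.full((50, 50), 7.0)
        with pytest.raises(EmptyWellError):
            well_viability(blank, blank.copy())

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            well_viability(np.zeros((5, 5)), np.zeros((6, 6)))

    def test_synthetic_nt_well(self, small_cfg):
        well = simulate_well(small_cfg, well_id="nt", condition="NT", seed=14)
        record = score_well(well)
        assert record.viability >= 0.98

    def test_gain_invariance(self, small_cfg):
        well = simulate_well(
            small_cfg, well_id="w", condition="treated", dose=15.0, seed=21
        )
        live = well.render.image["live"]
        dead = well.render.image["dead"]
        _, _, v1 = well_viability(live, dead)
        _, _, v2 = well_viability(3.7 * live, 3.7 * dead)
        assert v2 == pytest.approx(v1, abs=1e-6)

    def test_offset_invariance(self, small_cfg):
        well = simulate_well(
            small_cfg, well_id="w", condition="treated", dose=15.0, seed=22
        )
        live = well.render.image["live"]
        dead = well.render.image["dead"]
        _, _, v1 = well_viability(live, dead)
        _, _, v2 = well_viability(live + 500.0, dead + 500.0)
        assert v2 == pytest.approx(v1, abs=0.01)


class TestNormalizeViability:
    def _records(self, viabilities, conditions):
        return [
            WellRecord(well_id=str(i), condition=c, viability=v)
            for i, (v, c) in enumerate(zip(viabilities, conditions))
        ]

    def test_simple_arithmetic(self):
        wells = self._records([0.9, 1.0, 0.95, 0.475], ["NT", "NT", "NT", "treated"])
        normalize_viability(wells)
        assert wells[-1].normalized_viability == pytest.approx(0.5)

    def test_identical_wells_normalize_to_one(self):
        wells = self._records([0.8] * 4, ["NT", "NT", "treated", "treated"])
        normalize_viability(wells)
        assert all(w.normalized_viability == pytest.approx(1.0) for w in wells)

    def test_nt_mean_is_exactly_one(self, rng):
        v = rng.uniform(0.5, 1.0, size=12)
        conds = ["NT"] * 5 + ["treated"] * 7
        wells = self._records(v, conds)
        normalize_viability(wells)
        nt_mean = np.mean([w.normalized_viability for w in wells if w.condition == "NT"])
        assert nt_mean == pytest.approx(1.0, abs=1e-12)

    def test_missing_control(self):
        wells = self._records([0.5], ["treated"])
        with pytest.raises(MissingControlError):
            normalize_viability(wells)


class TestStudentTTest:
    def test_identical_groups(self):
        res = student_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_order_symmetry(self):
        a, b = [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]
        assert student_t_test(a, b).p_value == pytest.approx(
            student_t_test(b, a).p_value
        )

    def test_matches_textbook_computation(self):
        a = [0.1, 0.12, 0.11, 0.09]
        b = [0.9, 0.88, 0.91, 0.93]
        res = student_t_test(a, b)
        t_ref, p_ref = pooled_t_test(a, b)
        assert res.t_statistic == pytest.approx(t_ref, abs=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-10)
        assert res.degrees_of_freedom == 6

    def test_degenerate_input(self):
        with pytest.raises(DegenerateInputError):
            student_t_test([1.0, 1.0, 1.0], [1.0, 1.0])
        with pytest.raises(DegenerateInputError):
            student_t_test([1.0], [1.0, 2.0])

    def test_welch_flag(self):
        a = [0.1, 0.12, 0.11, 0.09]
        b = [0.9, 0.7, 1.1, 0.5, 0.8]
        res = student_t_test(a, b, welch=True)
        assert res.degrees_of_freedom != len(a) + len(b) - 2


class TestEstimateLd50:
    def test_linear_interpolation(self):
        assert estimate_ld50([10.0, 30.0], [0.6, 0.4]) == pytest.approx(20.0)

    def test_no_crossing(self):
        with pytest.raises(OutOfRangeError):
            estimate_ld50([0.0, 10.0, 20.0], [1.0, 0.9, 0.8])

    def test_lowest_crossing_wins(self):
        doses = [0.0, 10.0, 20.0, 30.0, 40.0]
        vals = [1.0, 0.4, 0.6, 0.4, 0.3]  # crosses at 5-ish, again later
        first = estimate_ld50(doses, vals)
        assert first < 10.0

    def test_replicates_averaged_first(self):
        doses = [10.0, 10.0, 30.0, 30.0]
        vals = [0.7, 0.5, 0.5, 0.3]  # per-dose means 0.6 and 0.4
        assert estimate_ld50(doses, vals) == pytest.approx(20.0)


class TestIrradianceSummary:
    def _wells(self, irradiances, values):
        return [
            WellRecord(
                well_id=str(i),
                condition="treated",
                irradiance=e,
                normalized_viability=v,
            )
            for i, (e, v) in enumerate(zip(irradiances, values))
        ]

    def test_increasing_series(self):
        wells = self._wells([25, 50, 100, 200], [0.4, 0.6, 0.7, 0.72])
        table, argmin_irr, plateau = summarize_irradiance_series(wells)
        assert argmin_irr == 25
        assert plateau == 200

    def test_flat_series_plateaus_immediately(self):
        wells = self._wells([25, 50, 100], [0.7, 0.7, 0.7])
        _, _, plateau = summarize_irradiance_series(wells)
        assert plateau == 25

    def test_needs_three_levels(self):
        with pytest.raises(ValueError):
            summarize_irradiance_series(self._wells([25, 50], [0.1, 0.2]))


def test_type_i_error_rate(rng):
    # both groups from one normal law: rejection at alpha=0.05 should be ~5%
    n_reps = 1000
    rejections = 0
    for _ in range(n_reps):
        a = rng.normal(0.5, 0.1, size=4)
        b = rng.normal(0.5, 0.1, size=4)
        if student_t_test(a, b).p_value < 0.05:
            rejections += 1
    assert abs(rejections / n_reps - 0.05) <= 0.015


def test_dark_toxicity_equivalence(small_cfg):
    # identical EO generator settings under both atmospheres: the pairwise
    # test should not reject in the vast majority of seeded replicates
    non_significant = 0
    n_reps = 40
    for rep in range(n_reps):
        base = 1000 + 8 * rep
        normo = [
            score_well(
                simulate_well(
                    small_cfg, well_id="n", condition="EO", atmosphere="normoxic",
                    seed=base + i,
                )
            ).viability
            for i in range(4)
        ]
        hypo = [
            score_well(
                simulate_well(
                    small_cfg, well_id="h", condition="EO", atmosphere="hypoxic",
                    seed=base + 4 + i,
                )
            ).viability
            for i in range(4)
        ]
        if student_t_test(normo, hypo).p_value > 0.05:
            non_significant += 1
    assert non_significant >= 0.9 * n_reps
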