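import numpy as np
import pytest

from nodulekit.errors import UnthresholdableError
from nodulekit.morphometry import (
    fit_powerlaw,
    nodule_metrics,
    otsu_threshold,
    penetration_depth,
    segment_nodules,
)
from nodulekit.synthetic import (
    CultureField,
    DoseResponseModel,
    NoduleSpec,
    NoiseModel,
    render_livedead,
    render_uptake,
    sample_nodule_field,
)

from oracles import brute_force_otsu

MODEL = DoseResponseModel(d50=14.5)
NOISE = NoiseModel()


class TestOtsuThreshold:
    def test_perfectly_bimodal(self):
        values = np.concatenate([np.zeros(100), np.full(100, 10.0)])
        thr = otsu_threshold(values)
        assert 0.0 <= thr < 10.0
        low = values[values <= thr]
        high = values[values > thr]
        assert low.var() == 0.0 and high.var() == 0.0

    def test_constant_raises(self):
        with pytest.raises(UnthresholdableError):
            otsu_threshold(np.full((10, 10), 3.0))

    def test_matches_brute_force_on_random_histograms(self, rng):
        for _ in range(25):
            centers = np.arange(64, dtype=float)
            counts = rng.integers(0, 50, size=64).astype(float)
            if np.count_nonzero(counts) < 2:
                continue
            assert otsu_threshold((counts, centers)) == brute_force_otsu(
                counts, centers
            )

    def test_accepts_grid_or_histogram(self, rng):
        grid = rng.normal(100, 10, size=(64, 64))
        grid[:20] += 300
        thr = otsu_threshold(grid)
        assert 100 < thr < 400


class TestSegmentNodules:
    def test_blank_image_yields_empty_map(self, rng):
        live = 200.0 + rng.normal(0, 5, size=(256, 256))
        dead = 200.0 + rng.normal(0, 5, size=(256, 256))
        labels = segment_nodules(live, dead, pixel_size=2.0, min_diameter=30.0)
        assert labels.max() == 0

    def test_recovers_generator_field(self):
        nodules = sample_nodule_field(20, (60, 250), (3000, 3000), seed=31)
        field = CultureField(nodules=nodules, condition="NT")
        render = render_livedead(
            field, MODEL, NOISE, pixel_size=2.0, seed=31, field_size=(3000, 3000)
        )
        labels = segment_nodules(
            render.image["live"], render.image["dead"], 2.0, min_diameter=30.0
        )
        assert labels.max() == 20
        # each generator center must fall within one pixel of a centroid
        from scipy import ndimage

        centroids = ndimage.center_of_mass(
            np.ones_like(labels), labels, index=np.arange(1, 21)
        )
        centroids_um = np.array(centroids)[:, ::-1] * 2.0 + 1.0  # (x, y)
        for spec in nodules:
            d = np.min(np.hypot(*(centroids_um - np.array(spec.center_xy)).T))
            assert d <= 2.0  # one pixel

    def test_count_matches_generator_across_seeds(self):
        for seed in range(40, 50):
            nodules = sample_nodule_field(8, (60, 200), (1600, 1600), seed=seed)
            field = CultureField(nodules=nodules, condition="NT")
            render = render_livedead(
                field, MODEL, NOISE, pixel_size=2.0, seed=seed, field_size=(1600, 1600)
            )
            labels = segment_nodules(
                render.image["live"], render.image["dead"], 2.0, 30.0
            )
            assert labels.max() == 8

    def test_tangent_nodules_stay_separate(self):
        live = np.zeros((100, 100))
        live[20:40, 20:40] = 1000.0
        live[20:40, 44:64] = 1000.0  # 4 px gap
        dead = np.zeros((100, 100))
        labels = segment_nodules(live, dead, pixel_size=4.0, min_diameter=30.0)
        assert labels.max() == 2


class TestNoduleMetrics:
    def test_equivalent_diameter_formula(self):
        # circular component of known area: 100 um^2 at 1 um/px
        labels = np.zeros((60, 60), dtype=np.int32)
        yy, xx = np.indices(labels.shape)
        disk = np.hypot(yy - 30, xx - 30) <= 5.6
        labels[disk] = 1
        live = np.where(disk, 100.0, 0.0)
        records, _ = nodule_metrics(labels, live, np.zeros_like(live), pixel_size=1.0)
        area = float(disk.sum())  # um^2
        assert records[0].equivalent_diameter == pytest.approx(
            2 * np.sqrt(area / np.pi)
        )

    def test_volume_formula(self):
        labels = np.zeros((300, 300), dtype=np.int32)
        yy, xx = np.indices(labels.shape)
        disk = np.hypot(yy - 150, xx - 150) <= 100
        labels[disk] = 1
        live = np.where(disk, 100.0, 0.0)
        records, _ = nodule_metrics(labels, live, np.zeros_like(live), pixel_size=1.0)
        rec = records[0]
        assert rec.volume == pytest.approx(np.pi / 6 * rec.equivalent_diameter**3)
        assert rec.ratio_clipped  # dead_sum == 0 flagged

    def test_reference_volume_value(self):
        # equivalent diameter 200 um -> (pi/6) * 200^3
        assert np.pi / 6 * 200.0**3 == pytest.approx(4.18879e6, rel=1e-5)

    def test_ground_truth_viability_recovery(self):
        # survival 0.30 in both regions, noise-free
        dose = 14.5 * np.sqrt(7.0 / 3.0)
        model = DoseResponseModel(d50=14.5, core_efficiency=1.0, irr_scale=1e9)
        nodules = sample_nodule_field(4, (150, 250), (1600, 1600), seed=8)
        field = CultureField(
            nodules=nodules, condition="treated", dose=dose, irradiance=1.0
        )
        render = render_livedead(
            field, model, None, pixel_size=2.0, seed=8, field_size=(1600, 1600)
        )
        records, _ = nodule_metrics(
            render.labels, render.image["live"], render.image["dead"], 2.0
        )
        truth = {t.id: t.true_viability for t in render.truth}
        assert truth and all(abs(v - 0.30) < 0.08 for v in truth.values())
        for rec in records:
            assert rec.viability == pytest.approx(truth[rec.label], abs=0.02)

    def test_border_nodules_excluded(self):
        labels = np.zeros((50, 50), dtype=np.int32)
        labels[0:10, 0:10] = 1  # touches border
        labels[20:30, 20:30] = 2
        live = np.where(labels > 0, 100.0, 0.0)
        records, border = nodule_metrics(labels, live, np.zeros_like(live), 1.0)
        assert [r.label for r in records] == [2]
        assert border == [1]


class TestFitPowerlaw:
    def test_exact_recovery(self, rng):
        v = rng.uniform(1e4, 1e8, size=50)
        r = 2.0 * v**0.5
        fit = fit_powerlaw(v, r)
        assert fit.prefactor == pytest.approx(2.0, abs=1e-10)
        assert fit.exponent == pytest.approx(0.5, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_ratios(self, rng):
        v = rng.uniform(1e4, 1e8, size=30)
        fit = fit_powerlaw(v, np.full(30, 5.0))
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_noisy_exponent_recovery(self, rng):
        v = 10 ** rng.uniform(4, 9, size=1000)
        r = 0.5 * v**0.7 * np.exp(rng.normal(0, 0.1, size=1000))
        fit = fit_powerlaw(v, r)
        assert fit.exponent == pytest.approx(0.7, abs=0.05)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_powerlaw([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_powerlaw([1.0, 2.0, -3.0], [1.0, 2.0, 3.0])


class TestPenetrationDepth:
    SPEC = NoduleSpec(id=1, center_xy=(0, 0), diameter=600, core_fraction=0.5)

    def _uptake(self, decay_length):
        render = render_uptake(
            self.SPEC,
            "peripheral_decay",
            {"decay_length": decay_length},
            noise=None,
            pixel_size=2.0,
        )
        return render.image["uptake"], render.mask

    def test_exponential_125(self):
        img, mask = self._uptake(125.0)
        res = penetration_depth(img, mask, 2.0)
        assert not res.full_penetration
        assert res.depth == pytest.approx(125.0, abs=3.0)

    def test_exponential_40(self):
        img, mask = self._uptake(40.0)
        res = penetration_depth(img, mask, 2.0)
        assert res.depth == pytest.approx(40.0, abs=3.0)

    def test_uniform_uptake_flags_full_penetration(self):
        _, mask = self._uptake(125.0)
        img = np.where(mask, 1000.0, 0.0)
        res = penetration_depth(img, mask, 2.0)
        assert res.full_penetration
        assert res.depth == pytest.approx(300.0, abs=5.0)  # ~ the radius

    def test_mask_must_be_single_nodule(self):
        img = np.zeros((50, 50))
        mask = np.zeros((50, 50), dtype=bool)
        mask[5:10, 5:10] = True
        mask[30:35, 30:35] = True
        with pytest.raises(ValueError):
            penetration_depth(img, mask, 2.0)


def test_live_sums_bounded_by_image_total():
    nodules = sample_nodule_field(6, (80, 250), (1600, 1600), seed=77)
    field = CultureField(nodules=nodules, condition="treated", dose=10.0, irradiance=50.0)
    render = render_livedead(
        field, MODEL, NOISE, pixel_size=2.0, seed=77, field_size=(1600, 1600)
    )
    live = render.image["live"]
    labels = segment_nodules(live, render.image["dead"], 2.0, 30.0)
    records, _ = nodule_metrics(labels, live, render.image["dead"], 2.0)
    from nodulekit.viability import subtract_background

    total = subtract_background(live).sum()
    assert sum(r.live_sum for r in records) <= total + 1e-6


def test_kill_pattern_discrimination():
    # matched geometry, 10 J/cm^2: periphery-kill agent loses efficacy with
    # size (positive ratio-vs-volume exponent); core-kill agent gains
    # (negative exponent)
    core_model = DoseResponseModel(d50=14.5, pattern="core_kill")
    peri_model = DoseResponseModel(d50=14.5, pattern="periphery_kill")
    exponents = {}
    for name, model in (("core", core_model), ("periphery", peri_model)):
        ratios, volumes = [], []
        for seed in range(6):
            nodules = sample_nodule_field(8, (220, 580), (4000, 4000), seed=seed)
            field = CultureField(
                nodules=nodules, condition="treated", dose=10.0, irradiance=50.0
            )
            render = render_livedead(
                field, model, NOISE, pixel_size=4.0, seed=seed, field_size=(4000, 4000)
            )
            labels = segment_nodules(
                render.image["live"], render.image["dead"], 4.0, 30.0
            )
            records, _ = nodule_metrics(
                labels, render.image["live"], render.image["dead"], 4.0
            )
            for rec in records:
                if rec.live_dead_ratio > 0 and rec.volume > 0:
                    ratios.append(rec.live_dead_ratio)
                    volumes.append(rec.volume)
        exponents[name] = fit_powerlaw(np.array(volumes), np.array(ratios)).exponent
    assert exponents["periphery"] > exponents["core"]
    assert exponents["core"] < 0 < exponents["periphery"]
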