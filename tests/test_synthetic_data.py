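"""Synthetic landscape and driver generators: ground truth, determinism,
and change-regime post-conditions."""

import numpy as np
import pytest

from wetscape.change_dynamics import transition_matrix, wetland_flows
from wetscape.landscape_metrics import class_metrics
from wetscape.patch_engine import label_patches, size_frequency
from wetscape.raster_core import landscape_area
from wetscape.synthetic_data import (
    GRASSLAND_CODE,
    WETLAND_CODE,
    ChangeScenario,
    LandscapeScenario,
    evolve_landscape,
    generate_driver_system,
    generate_landscape,
)
from wetscape.drivers import grey_relational_analysis


@pytest.fixture(scope="module")
def base_raster():
    return generate_landscape(LandscapeScenario(shape=(200, 200), seed=7))


class TestGenerateLandscape:
    def test_single_class_uniform(self):
        sc = LandscapeScenario(
            shape=(20, 20), proportions={1: 1.0}, legend={1: "grassland"}, seed=0
        )
        r = generate_landscape(sc)
        assert (r.grid == 1).all()

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            LandscapeScenario(proportions={1: 0.5, 3: 0.4})

    @pytest.mark.parametrize("target", [0.05, 0.1, 0.2])
    def test_wetland_proportion_recovered(self, target):
        sc = LandscapeScenario(
            shape=(200, 200),
            proportions={1: 1.0 - target, 3: target},
            seed=7,
        )
        r = generate_landscape(sc)
        wp = class_metrics(r, WETLAND_CODE).wp
        assert abs(wp / 100 - target) < 0.005

    def test_measured_wp_near_target(self):
        sc = LandscapeScenario(shape=(300, 300), seed=7)
        wp = class_metrics(generate_landscape(sc), WETLAND_CODE).wp
        assert 9.0 <= wp <= 11.0

    def test_deterministic_bitwise(self):
        sc = LandscapeScenario(shape=(100, 100), seed=3)
        assert np.array_equal(generate_landscape(sc).grid, generate_landscape(sc).grid)

    def test_all_proportions_within_tolerance(self, base_raster):
        props = base_raster.class_proportions()
        for code, target in LandscapeScenario().proportions.items():
            assert abs(props[code] - target) < 0.01

    def test_wetland_size_spectrum_spans_bins(self, base_raster):
        table = size_frequency(label_patches(base_raster, WETLAND_CODE))
        assert np.count_nonzero(table.bin_counts) >= 3

    def test_generator_output_is_valid_raster(self, base_raster):
        assert landscape_area(base_raster) == pytest.approx(200 * 200 * 1.0)


class TestEvolveLandscape:
    def test_stationary_identity(self, base_raster):
        out = evolve_landscape(base_raster, ChangeScenario(regime="stationary"))
        assert np.array_equal(out.grid, base_raster.grid)

    def test_fragmentation_raises_pn_keeps_wa(self, base_raster):
        out = evolve_landscape(
            base_raster, ChangeScenario(regime="fragmentation", intensity=0.3, seed=1)
        )
        before = class_metrics(base_raster, WETLAND_CODE)
        after = class_metrics(out, WETLAND_CODE)
        assert after.pn > before.pn
        assert after.wa <= before.wa
        assert after.wa >= 0.9 * before.wa  # corridors remove little area

    def test_erosion_shrinks_area_outflow_only(self, base_raster):
        out = evolve_landscape(
            base_raster, ChangeScenario(regime="edge-erosion", steps=2, seed=2)
        )
        before = class_metrics(base_raster, WETLAND_CODE)
        after = class_metrics(out, WETLAND_CODE)
        assert after.wa < before.wa
        tab_before = size_frequency(label_patches(base_raster, WETLAND_CODE))
        tab_after = size_frequency(label_patches(out, WETLAND_CODE))
        assert tab_after.level_areas[2] <= tab_before.level_areas[2]
        flows = wetland_flows(
            transition_matrix(base_raster, out), WETLAND_CODE, GRASSLAND_CODE
        )
        assert flows.grassland_to_wetland == 0.0
        assert flows.wetland_to_others > 0.0

    def test_recovery_grows_area_and_small_patches(self, base_raster):
        out = evolve_landscape(
            base_raster,
            ChangeScenario(regime="recovery", intensity=0.4, n_new_patches=30, seed=3),
        )
        before = class_metrics(base_raster, WETLAND_CODE)
        after = class_metrics(out, WETLAND_CODE)
        assert after.wa > before.wa
        small_before = size_frequency(label_patches(base_raster, WETLAND_CODE)).bin_counts[0]
        small_after = size_frequency(label_patches(out, WETLAND_CODE)).bin_counts[0]
        assert small_after > small_before

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError, match="regime"):
            ChangeScenario(regime="melt")

    def test_three_date_narrative(self, base_raster):
        """Fragmentation then erosion then recovery reproduces the
        degradation-and-rebound pattern: PN up then down, WA down then up."""
        frag = evolve_landscape(
            base_raster, ChangeScenario(regime="fragmentation", intensity=0.5, seed=11)
        )
        erod = evolve_landscape(frag, ChangeScenario(regime="edge-erosion", steps=2, seed=12))
        reco = evolve_landscape(
            erod, ChangeScenario(regime="recovery", intensity=0.5, n_new_patches=40, seed=13)
        )
        pn = [class_metrics(r, WETLAND_CODE).pn for r in (base_raster, frag, erod, reco)]
        wa = [class_metrics(r, WETLAND_CODE).wa for r in (base_raster, frag, erod, reco)]
        assert pn[1] > pn[0]
        assert wa[2] < wa[1] <= wa[0]
        assert wa[3] > wa[2]


class TestDriverSystem:
    def test_zero_noise_copy_ranks_first(self):
        table, target = generate_driver_system(
            12, {"exact": 0.0, "noisy": 0.5}, seed=0
        )
        result = grey_relational_analysis(target, table.factors)
        assert result.ranking["exact"] == 1

    def test_deterministic(self):
        a, ta = generate_driver_system(10, {"f1": 0.1, "f2": 1.0}, seed=5)
        b, tb = generate_driver_system(10, {"f1": 0.1, "f2": 1.0}, seed=5)
        assert np.array_equal(ta, tb)
        for name in a.factors:
            assert np.array_equal(a.factors[name], b.factors[name])

    def test_noise_ordering_recovered_mostly(self):
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            table, target = generate_driver_system(
                26, {"low": 0.02, "mid": 0.2, "high": 1.0}, seed=seed
            )
            result = grey_relational_analysis(target, table.factors)
            hits += list(result.ranking.sort_values().index) == ["low", "mid", "high"]
        assert hits >= 0.9 * n_rep

    def test_years_aligned(self):
        table, _ = generate_driver_system(6, {"f": 0.1}, seed=1, start_year=1995)
        assert table.years == (1995, 1996, 1997, 1998, 1999, 2000)
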