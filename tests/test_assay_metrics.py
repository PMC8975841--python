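"""Assay calculators: CFU arithmetic, viability, rheology, recipe volumes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mucogel import assay_metrics as am


def table(rows):
    exps, vols, counts = zip(*rows)
    return am.SpotCountTable(np.array(exps), np.array(vols), np.array(counts))


class TestCfuPerMl:
    def test_single_countable_row(self):
        # 30 colonies from 20 ul of the 10^-5 dilution: 30/0.02 * 1e5
        result = am.cfu_per_ml(table([(5, 0.02, 30)]))
        assert result.cfu_per_ml == pytest.approx(1.5e8)
        assert not result.censored

    def test_countable_range_filter(self):
        # 400 too crowded, 4 too sparse: only the 45-count row is usable
        result = am.cfu_per_ml(table([(3, 0.02, 400), (4, 0.02, 45), (5, 0.02, 4)]))
        assert list(result.usable_rows) == [1]
        assert result.cfu_per_ml == pytest.approx(2.25e7)

    def test_sterile_sample_censored_with_detection_limit(self):
        result = am.cfu_per_ml(table([(2, 0.02, 0), (3, 0.02, 0)]))
        assert result.censored
        assert result.cfu_per_ml == 0.0
        assert result.detection_limit == pytest.approx(6 / (0.02 * 1e-3))

    def test_multiple_usable_rows_averaged(self):
        result = am.cfu_per_ml(table([(4, 0.02, 40), (5, 0.02, 6)]))
        expected = np.mean([40 / 0.02 * 1e4, 6 / 0.02 * 1e5])
        assert result.cfu_per_ml == pytest.approx(expected)

    def test_most_dilute_mode(self):
        result = am.cfu_per_ml(table([(4, 0.02, 40), (5, 0.02, 6)]), mode="most_dilute")
        assert result.cfu_per_ml == pytest.approx(6 / 0.02 * 1e5)

    def test_malformed_row_named(self):
        with pytest.raises(ValueError, match="row 1"):
            table([(4, 0.02, 10), (5, -0.02, 10)])

    @given(k=st.integers(1, 50))
    @settings(max_examples=20, deadline=None)
    def test_scale_consistency(self, k):
        # scaling counts and the countable range by k scales the estimate by k
        base = am.cfu_per_ml(table([(5, 0.02, 30)]))
        scaled = am.cfu_per_ml(
            table([(5, 0.02, 30 * k)]), countable_min=6 * k, countable_max=60 * k
        )
        assert scaled.cfu_per_ml == pytest.approx(k * base.cfu_per_ml)


class TestViability:
    @pytest.mark.parametrize(
        "total,dead,expected", [(100, 0, 100.0), (100, 100, 0.0), (250, 50, 80.0)]
    )
    def test_formula(self, total, dead, expected):
        assert am.viability(total, dead) == pytest.approx(expected)

    @pytest.mark.parametrize("total,dead", [(0, 0), (10, 11), (10, -1)])
    def test_invalid_counts_rejected(self, total, dead):
        with pytest.raises(ValueError):
            am.viability(total, dead)

    @given(total=st.integers(1, 10_000), frac=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_bounded_percentage(self, total, frac):
        dead = int(frac * total)
        assert 0.0 <= am.viability(total, dead) <= 100.0


class TestCountCells:
    def test_recovers_spot_count(self, spot_field):
        img, centers = spot_field(50)
        total, dead = am.count_cells(img, np.zeros_like(img))
        assert total == 50
        assert dead == 0

    def test_blank_images_zero(self):
        assert am.count_cells(np.zeros((128, 128)), np.zeros((128, 128))) == (0, 0)

    def test_coincident_dead_spots_give_75pct_viability(self, spot_field):
        img, centers = spot_field(100, shape=(1024, 1024), seed=2)
        yy, xx = np.mgrid[0:1024, 0:1024]
        dead = np.zeros_like(img)
        for r, c in centers[:25]:
            dead += np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * 3.0**2))
        total, n_dead = am.count_cells(img, dead)
        assert am.viability(total, n_dead) == pytest.approx(75.0, abs=1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            am.count_cells(np.zeros((10, 10)), np.zeros((10, 12)))


class TestLossTangent:
    def test_ideal_elastic_zero(self):
        sweep = am.FrequencySweep(np.logspace(0, 2, 5), np.full(5, 50.0), np.zeros(5))
        assert np.allclose(am.loss_tangent(sweep)["tan_delta"], 0.0)

    def test_crossover_unity(self):
        sweep = am.FrequencySweep(np.array([1.0, 2.0]), np.array([10.0, 20.0]), np.array([10.0, 5.0]))
        assert am.loss_tangent(sweep)["tan_delta"].iloc[0] == pytest.approx(1.0)

    def test_maxwell_closed_form(self):
        from mucogel.synthetic_data import simulate_frequency_sweep

        tau = 0.3
        omega = np.logspace(-1, 2, 40)
        sweep = simulate_frequency_sweep(100.0, tau, omega)
        tan_delta = am.loss_tangent(sweep)["tan_delta"].to_numpy()
        assert np.allclose(tan_delta, 1.0 / (omega * tau), rtol=1e-10)

    def test_zero_storage_modulus_rejected(self):
        sweep = am.FrequencySweep(np.array([1.0, 2.0]), np.array([0.0, 5.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="undefined"):
            am.loss_tangent(sweep)

    def test_rescaling_invariance(self):
        sweep = am.FrequencySweep(np.array([1.0, 10.0]), np.array([40.0, 50.0]), np.array([4.0, 10.0]))
        scaled = am.FrequencySweep(sweep.omega, 7.0 * sweep.g_prime, 7.0 * sweep.g_double_prime)
        assert np.allclose(
            am.loss_tangent(sweep)["tan_delta"], am.loss_tangent(scaled)["tan_delta"]
        )

    def test_query_nearest_within_5pct(self):
        sweep = am.FrequencySweep(
            np.array([0.98, 5.0, 10.2]), np.array([50.0, 50.0, 50.0]), np.array([5.0, 10.0, 20.0])
        )
        out = am.loss_tangent(sweep, query_omega=[1.0, 10.0])
        assert out["tan_delta"].tolist() == pytest.approx([0.1, 0.4])
        assert (out["method"] == "nearest").all()
        with pytest.raises(ValueError, match="no grid point"):
            am.loss_tangent(sweep, query_omega=[2.0])
        interp = am.loss_tangent(sweep, query_omega=[2.0], interpolate=True)
        assert interp["method"].iloc[0] == "interpolated"


class TestLveRegion:
    def test_flat_sweep_full_range(self):
        strain = np.logspace(-1, 3, 20)
        lo, hi = am.lve_region(strain, np.full(20, 100.0))
        assert (lo, hi) == (pytest.approx(strain[0]), pytest.approx(strain[-1]))

    def test_plateau_then_decay_crossing_located(self):
        strain = np.logspace(-1, 3, 60)
        g = np.where(strain <= 10.0, 100.0, 100.0 * (strain / 10.0) ** -0.5)
        lo, hi = am.lve_region(strain, g, tolerance=0.05)
        # upper bound within one grid point of the 5%-deviation crossing
        crossing = 10.0 * (1 / 0.95) ** 2  # G' = 0.95 plateau
        idx_cross = np.searchsorted(strain, crossing)
        assert abs(np.searchsorted(strain, hi) - idx_cross) <= 1

    def test_monotonic_decay_no_plateau(self):
        strain = np.logspace(-1, 2, 30)
        with pytest.raises(ValueError, match="plateau"):
            am.lve_region(strain, 100.0 * strain**-0.8)


class TestRecipe:
    @pytest.mark.parametrize(
        "muc,expected_pbs,expected_muc",
        [(0.0, 150, 0), (0.5, 105, 45), (1.0, 60, 90)],
    )
    def test_hydrogel_volume_table(self, muc, expected_pbs, expected_muc):
        vols = am.recipe(am.RecipeSpec(mucin_target_pct=muc))
        assert vols["alginate_stock_ul"] == 300
        assert vols["pbs_ul"] == expected_pbs
        assert vols["mucin_stock_ul"] == expected_muc
        assert vols["cacl2_solution_ul"] == 450
        assert vols["total_ul"] == 900

    def test_final_crosslinker_concentration(self):
        vols = am.recipe(am.RecipeSpec())
        assert vols["final_cacl2_mM"] == pytest.approx(5.5)

    def test_overconstrained_reports_max_mucin(self):
        with pytest.raises(ValueError, match="maximum feasible mucin"):
            am.recipe(am.RecipeSpec(mucin_target_pct=9.0))

    @given(
        total=st.integers(100, 5000),
        alg=st.floats(0.1, 2.0),
        muc=st.floats(0.0, 1.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_volumes_always_sum_to_total(self, total, alg, muc):
        try:
            vols = am.recipe(
                am.RecipeSpec(total_volume_ul=total, alginate_target_pct=alg, mucin_target_pct=muc)
            )
        except ValueError:
            return  # over-constrained combinations are rejected, not mis-summed
        parts = (
            vols["alginate_stock_ul"] + vols["pbs_ul"]
            + vols["mucin_stock_ul"] + vols["cacl2_solution_ul"]
        )
        assert parts == total


class TestMolarHelper:
    def test_hoechst_conversion(self):
        # 5 ug/ml of a 616 g/mol stain is 8.1e-3 mM
        assert am.ug_per_ml_to_mM(5.0, 616.0) == pytest.approx(8.1e-3, abs=5e-5)

    def test_invalid_molar_mass(self):
        with pytest.raises(ValueError):
            am.ug_per_ml_to_mM(5.0, 0.0)
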