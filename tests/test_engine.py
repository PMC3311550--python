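"""Unit and property tests for the growth engine."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from serasim import (SimConfig, Tree, annual_growth, apply_mortality,
                     init_stand, light_exposure, recruit, run, step,
                     update_height)
from serasim.sera_engine import _partition_mass


# ----------------------------------------------------------------------
# init_stand
# ----------------------------------------------------------------------
class TestInitStand:
    def test_exact_seedling_count_and_bounds(self):
        st = init_stand(SimConfig(planting_density=10_000, area_ha=1.0,
                                  rng_seed=1))
        assert st.n_trees == 10_000
        assert st.x.min() >= 0 and st.x.max() < 100
        assert st.y.min() >= 0 and st.y.max() < 100

    def test_single_seedling(self):
        st = init_stand(SimConfig(planting_density=1, area_ha=1.0, rng_seed=1))
        assert st.n_trees == 1

    def test_quarter_hectare_count(self):
        st = init_stand(SimConfig(planting_density=10_000, area_ha=0.25,
                                  rng_seed=1))
        assert st.n_trees == 2500
        assert st.width == pytest.approx(50.0)

    def test_mix_proportions_exact(self):
        cfg = SimConfig(species={"abies_alba": 0.5, "generic_angiosperm": 0.5},
                        planting_density=1000, rng_seed=3)
        st = init_stand(cfg)
        counts = np.bincount(st.sidx, minlength=2)
        assert counts.tolist() == [500, 500]

    @pytest.mark.parametrize("kwargs", [
        {"planting_density": 0.0},
        {"area_ha": 0.0},
        {"planting_density": 0.4, "area_ha": 1.0},  # rounds to zero seedlings
        {"light_intensity": 0.0},
        {"light_intensity": 1.5},
        {"years": -1},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs).validate()

    def test_deterministic_given_seed(self):
        a = init_stand(SimConfig(planting_density=500, rng_seed=9))
        b = init_stand(SimConfig(planting_density=500, rng_seed=9))
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.stem_mass, b.stem_mass)


# ----------------------------------------------------------------------
# update_height
# ----------------------------------------------------------------------
class TestUpdateHeight:
    def test_negative_dbh_rejected(self, abies):
        with pytest.raises(ValueError):
            update_height(-0.1, "juvenile", abies)

    def test_curves_meet_at_switch_diameter(self, abies):
        d_star = abies.switch_diameter()
        h_juv = abies.c_juv * d_star ** abies.gamma_juv
        h_mat = abies.h_asym * -math.expm1(-abies.k_mature * d_star)
        assert h_juv == pytest.approx(h_mat, abs=1e-8)

    def test_mature_height_approaches_asymptote_from_below(self, abies):
        h, phase = update_height(5.0, "mature", abies)
        assert phase == "mature"
        assert h < abies.h_asym
        assert h == pytest.approx(abies.h_asym, rel=1e-4)

    @pytest.mark.parametrize("name", ["abies_alba", "cryptomeria",
                                      "generic_gymnosperm",
                                      "generic_angiosperm"])
    def test_grid_scan_monotone_single_switch(self, species, name):
        """Brute-force diameter scan: nondecreasing height, one swap."""
        p = species[name]
        phase = "juvenile"
        heights, phases = [], []
        for d in np.linspace(1e-4, 2.0, 4000):
            h, phase = update_height(float(d), phase, p)
            heights.append(h)
            phases.append(phase)
        heights = np.array(heights)
        assert (np.diff(heights) >= -1e-12).all()
        assert heights.max() <= p.h_asym
        swaps = sum(a != b for a, b in zip(phases, phases[1:]))
        assert swaps == 1
        assert phases[0] == "juvenile" and phases[-1] == "mature"

    def test_switch_is_irrevocable(self, abies):
        # once mature, even a (hypothetically) small diameter uses Eq. 2b
        h, phase = update_height(0.01, "mature", abies)
        assert phase == "mature"
        assert h == pytest.approx(abies.h_asym
                                  * -math.expm1(-abies.k_mature * 0.01))


# ----------------------------------------------------------------------
# light_exposure
# ----------------------------------------------------------------------
def _two_tree_stand(dist, r_low=1.0, r_high=1.0, light=1.0):
    cfg = SimConfig(planting_density=2, area_ha=1.0, light_intensity=light,
                    rng_seed=0)
    st = init_stand(cfg)
    st.x[:] = [50.0, 50.0 + dist]
    st.y[:] = [50.0, 50.0]
    st.height[:] = [30.0, 10.0]          # first is taller
    st.canopy_area[:] = [math.pi * r_high ** 2, math.pi * r_low ** 2]
    return st


class TestLightExposure:
    def test_single_tree_full_light(self):
        st = init_stand(SimConfig(planting_density=1, rng_seed=0))
        assert light_exposure(st)[0] == pytest.approx(1.0)

    def test_full_occlusion(self):
        st = _two_tree_stand(dist=0.0, r_low=0.5, r_high=2.0)
        exp = light_exposure(st, method="exact")
        assert exp[0] == pytest.approx(1.0)
        assert exp[1] == pytest.approx(0.0, abs=1e-6)

    def test_half_lens_overlap_exact_geometry(self):
        """Equal discs one radius apart: shaded lens = 2r^2 cos^-1(1/2)
        - (1/2)sqrt(3) r^2; unshaded fraction of the shorter tree 0.609."""
        st = _two_tree_stand(dist=1.0)
        lens = 2 * math.acos(0.5) - 0.5 * math.sqrt(3.0)
        expected = 1.0 - lens / math.pi
        exp = light_exposure(st, method="exact")
        assert exp[1] == pytest.approx(expected, abs=1e-3)
        assert expected == pytest.approx(0.609, abs=5e-4)

    def test_half_lens_overlap_monte_carlo_oracle(self):
        """The same case against a 10^6-point Monte Carlo disc sampler."""
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1, 1, (2_000_000, 2))
        pts = pts[(pts ** 2).sum(axis=1) <= 1.0][:1_000_000]
        shaded = ((pts[:, 0] - 1.0) ** 2 + pts[:, 1] ** 2) <= 1.0
        mc = 1.0 - shaded.mean()
        st = _two_tree_stand(dist=1.0)
        assert light_exposure(st, method="exact")[1] == pytest.approx(mc, abs=3e-3)

    def test_equal_heights_do_not_shade(self):
        st = _two_tree_stand(dist=0.5)
        st.height[:] = [20.0, 20.0]
        for method in ("exact", "raster"):
            exp = light_exposure(st, method=method)
            assert exp == pytest.approx([1.0, 1.0])

    def test_light_intensity_scales_exposure(self):
        st = _two_tree_stand(dist=1.0, light=0.5)
        st.light_intensity = 0.5
        exp = light_exposure(st, method="exact")
        assert exp[0] == pytest.approx(0.5)
        assert exp[1] == pytest.approx(0.5 * 0.609, abs=2e-3)

    def test_raster_agrees_with_exact_on_random_stand(self):
        cfg = SimConfig(planting_density=60, rng_seed=4, light_cell=0.25)
        st = init_stand(cfg)
        rng = np.random.default_rng(1)
        st.height[:] = rng.uniform(2, 30, st.n_trees)
        st.canopy_area[:] = rng.uniform(1, 30, st.n_trees)
        exact = light_exposure(st, method="exact")
        raster = light_exposure(st, method="raster")
        assert np.mean(np.abs(exact - raster)) < 0.02
        assert np.max(np.abs(exact - raster)) < 0.12

    def test_empty_stand(self):
        cfg = SimConfig(planting_density=1, rng_seed=0)
        st = init_stand(cfg)
        st._remove(np.array([True]))
        assert light_exposure(st).size == 0


# ----------------------------------------------------------------------
# annual_growth and the mass partition
# ----------------------------------------------------------------------
class TestAnnualGrowth:
    def _seedling(self, p):
        ml = p.canopy_mass(p.seedling_mass)
        return Tree(id=0, x=0, y=0, age=0, dbh=p.seedling_dbh,
                    height=p.seedling_height, stem_mass=p.seedling_mass,
                    canopy_mass=ml, canopy_area=p.canopy_area(ml),
                    phase="juvenile", species=p.name)

    def test_zero_exposure_only_ages(self, abies):
        t0 = self._seedling(abies)
        t1 = annual_growth(t0, 0.0, abies)
        assert t1.age == t0.age + 1
        assert t1.last_growth == 0.0
        assert t1.stem_mass == pytest.approx(t0.stem_mass)
        assert t1.height == pytest.approx(t0.height)

    def test_mass_conservation_and_allometry(self, abies):
        t0 = self._seedling(abies)
        t1 = annual_growth(t0, 0.8, abies)
        total0 = t0.stem_mass + t0.canopy_mass
        total1 = t1.stem_mass + t1.canopy_mass
        assert total1 - total0 == pytest.approx(t1.last_growth, rel=1e-12)
        assert t1.canopy_mass == pytest.approx(
            abies.c_lm * t1.stem_mass ** abies.e_lm, rel=1e-9)
        assert t1.dbh == pytest.approx(
            abies.c_dm * t1.stem_mass ** abies.e_dm, rel=1e-12)

    def test_century_of_growth_is_reproducible_and_monotone(self, abies):
        def grow():
            t = self._seedling(abies)
            track = []
            for _ in range(100):
                t = annual_growth(t, 1.0, abies)
                track.append((t.stem_mass, t.height, t.dbh, t.phase))
            return track
        a, b = grow(), grow()
        assert a == b  # bit-identical
        heights = [h for _, h, _, _ in a]
        assert all(h2 >= h1 for h1, h2 in zip(heights, heights[1:]))
        assert {ph for _, _, _, ph in a} == {"juvenile", "mature"}

    def test_partition_solver_matches_brentq(self, abies):
        rng = np.random.default_rng(0)
        for total in rng.uniform(0.1, 5000, 20):
            ms = float(_partition_mass(np.array([total]), abies.c_lm,
                                       abies.e_lm, np.array([1e-6]))[0])
            f = lambda m: m + abies.c_lm * m ** abies.e_lm - total
            ref = brentq(f, 1e-12, total)
            assert ms == pytest.approx(ref, rel=1e-9)

    def test_invalid_exposure_rejected(self, abies):
        with pytest.raises(ValueError):
            annual_growth(self._seedling(abies), 1.5, abies)


# ----------------------------------------------------------------------
# mortality / recruitment / step
# ----------------------------------------------------------------------
class TestDemography:
    def test_fully_lit_growing_stand_has_no_deaths(self):
        cfg = SimConfig(planting_density=5, years=1, rng_seed=2)
        st = init_stand(cfg)
        step(st)
        assert st.n_trees == 5
        assert st.dead_log == []

    def test_fully_shaded_tree_dies_within_persistence_window(self, species):
        p = species["abies_alba"]
        cfg = SimConfig(planting_density=2, rng_seed=0,
                        recruitment_enabled=False)
        st = init_stand(cfg)
        st.x[:] = [50, 50]
        st.y[:] = [50, 50]
        st.height[:] = [30.0, 5.0]
        st.canopy_area[:] = [50.0, 1.0]
        st.stem_mass[:] = [500.0, 5.0]
        st.canopy_mass[:] = [p.canopy_mass(500.0), p.canopy_mass(5.0)]
        for _ in range(p.persist_years + 1):
            step(st)
        assert st.n_trees == 1
        assert st.height[0] > 20  # the dominant survived

    def test_mortality_never_increases_stems(self, tiny_config):
        st = init_stand(tiny_config)
        before = st.n_trees
        apply_mortality(st)
        assert st.n_trees <= before

    def test_no_reproductive_trees_no_recruits(self, tiny_config):
        st = init_stand(tiny_config)
        n = st.n_trees
        recruit(st)
        assert st.n_trees == n

    def test_recruit_count_bounded_and_inside_plot(self, species):
        p = species["abies_alba"]
        cfg = SimConfig(planting_density=1, rng_seed=8)
        st = init_stand(cfg)
        st.x[:] = 50.0
        st.y[:] = 50.0
        st.height[:] = p.h_asym  # far above the reproductive threshold
        st.last_exposure[:] = 1.0
        recruit(st)
        n_new = st.n_trees - 1
        assert 0 <= n_new <= p.seeds_per_year
        assert (st.x >= 0).all() and (st.x < st.width).all()
        d = np.hypot(st.x[1:] - 50.0, st.y[1:] - 50.0)
        assert (d <= p.dispersal_radius).all()

    def test_recruits_outside_plot_are_discarded(self, species):
        p = species["abies_alba"]
        cfg = SimConfig(planting_density=1, rng_seed=8)
        st = init_stand(cfg)
        st.x[:] = 0.1          # corner parent; much of the dispersal disc
        st.y[:] = 0.1          # falls outside the plot
        st.height[:] = p.h_asym
        st.last_exposure[:] = 1.0
        recruit(st)
        assert (st.x >= 0).all() and (st.y >= 0).all()

    def test_step_on_empty_stand(self):
        cfg = SimConfig(planting_density=1, rng_seed=0)
        st = init_stand(cfg)
        st._remove(np.array([True]))
        step(st)
        assert st.year == 1 and st.n_trees == 0

    def test_year_increments_by_one(self, tiny_config):
        st = init_stand(tiny_config)
        step(st)
        step(st)
        assert st.year == 2


# ----------------------------------------------------------------------
# run-level invariants
# ----------------------------------------------------------------------
class TestRun:
    def test_zero_years_returns_initial_state_only(self):
        res = run(SimConfig(planting_density=100, years=0, rng_seed=1))
        assert len(res.summaries) == 1
        assert res.summaries.year.iloc[0] == 0
        assert res.summaries.stems_per_ha.iloc[0] == 100

    def test_seeded_runs_are_identical(self):
        cfg = SimConfig(planting_density=300, years=15, rng_seed=13)
        a = run(cfg, record_stems=True)
        b = run(cfg, record_stems=True)
        pd.testing.assert_frame_equal(a.summaries, b.summaries)
        pd.testing.assert_frame_equal(a.stems, b.stems)

    def test_run_invariants_over_a_short_dense_run(self, species):
        """Phase irreversibility, height cap, mass conservation per step."""
        cfg = SimConfig(planting_density=2000, years=25, rng_seed=21)
        res = run(cfg, record_stems=True)
        stems = res.stems
        h_cap = species["abies_alba"].h_asym
        assert stems.height_m.max() <= h_cap + 1e-9
        # per-tree phase sequences never go mature -> juvenile
        phase_num = stems.phase.map({"juvenile": 0, "mature": 1})
        regressions = (stems.assign(p=phase_num)
                       .sort_values(["tree_id", "year"])
                       .groupby("tree_id")["p"].apply(
                           lambda s: (s.diff() < 0).any()))
        assert not regressions.any()
        # heights nondecreasing while alive
        dec = (stems.sort_values(["tree_id", "year"])
               .groupby("tree_id")["height_m"]
               .apply(lambda s: (s.diff() < -1e-9).any()))
        assert not dec.any()

    def test_volume_equals_mass_over_density(self, species):
        res = run(SimConfig(planting_density=50, years=5, rng_seed=2),
                  record_stems=True)
        rho = species["abies_alba"].wood_density
        np.testing.assert_allclose(res.stems.stem_volume_m3,
                                   res.stems.stem_mass_kg / rho)
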