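"""Field model: grid construction, solver physics (linearity, antisymmetry,
current conservation, analytic oracle), coverage metrics, conductivity
perturbation and the sweep/heterogeneity experiments."""

import numpy as np
import pytest

from snfsim import field_model as fm

# A compact homogeneous domain with central contacts for solver physics
# tests; the hippocampal slab parameters are irrelevant here.
ORACLE_GEO = dict(brain_semiaxes=(13.0, 13.0, 11.0),
                  brain_center=(0.0, 0.0, 0.0),
                  hpc_ap_range=(-3.0, 3.0), homogeneous=True)


@pytest.fixture(scope="module")
def oracle_setup():
    geo = fm.GeometryConfig(resolution=0.3, **ORACLE_GEO)
    grid = fm.build_grid(geo)

    def snap(p):
        i = grid.index_of(p)
        return tuple(grid.origin[d] + i[d] * grid.resolution for d in range(3))

    src, snk = snap((0.0, 1.0, 0.0)), snap((0.0, -1.0, 0.0))
    montage = fm.ElectrodeMontage([fm.Contact(src, "anode", "P"),
                                   fm.Contact(snk, "cathode", "P")])
    fmap = fm.solve_quasistatic(grid, montage, "P", 1000.0)
    return grid, montage, fmap, src, snk


class TestGrid:
    def test_hippocampus_fraction_plausible(self, coarse_geometry):
        grid = fm.build_grid(coarse_geometry)
        hpc = grid.masks["hippocampus"].sum()
        brain = hpc + grid.masks["brain"].sum()
        assert 0.03 <= hpc / brain <= 0.10

    def test_masks_disjoint_and_cover(self, coarse_geometry):
        grid = fm.build_grid(coarse_geometry)
        total = (grid.masks["air"].astype(int)
                 + grid.masks["brain"].astype(int)
                 + grid.masks["hippocampus"].astype(int))
        assert np.all(total == 1)

    def test_air_has_zero_sigma(self, coarse_geometry):
        grid = fm.build_grid(coarse_geometry)
        assert np.all(grid.sigma[grid.masks["air"]] == 0.0)

    def test_tissue_conductivities_assigned(self, coarse_geometry):
        grid = fm.build_grid(coarse_geometry)
        assert np.all(grid.sigma[grid.masks["brain"]] == fm.SIGMA_BRAIN)
        assert np.all(grid.sigma[grid.masks["hippocampus"]]
                      == fm.SIGMA_HIPPOCAMPUS)

    def test_refinement_changes_masks_little(self):
        vols = {}
        for res in (0.5, 0.25):
            grid = fm.build_grid(fm.GeometryConfig(resolution=res))
            vols[res] = {
                name: grid.masks[name].sum() * res**3
                for name in ("brain", "hippocampus")
            }
        for name in vols[0.5]:
            assert vols[0.25][name] == pytest.approx(vols[0.5][name],
                                                     rel=0.05)

    def test_bad_resolution_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            fm.GeometryConfig(resolution=0.05)

    def test_electrode_tracks_marked_insulating(self, snf_setup):
        grid, montage, _ = snf_setup
        ins = grid.masks["electrode_insulation"]
        assert ins.any()
        assert np.all(grid.sigma[ins] == fm.SIGMA_INSULATION)


class TestSolverPhysics:
    def test_oracle_matches_monopole_superposition(self, oracle_setup):
        grid, _, fmap, src, snk = oracle_setup
        AP, ML, DV = np.meshgrid(*grid.coords(), indexing="ij")

        def mono(p, sign):
            r = np.sqrt((AP - p[0])**2 + (ML - p[1])**2
                        + (DV - p[2])**2) * 1e-3
            return sign * 1e-3 / (4 * np.pi * 0.7 * np.maximum(r, 1e-6)) * 1e3

        ana = mono(src, 1) + mono(snk, -1)
        rs = np.sqrt((AP - src[0])**2 + (ML - src[1])**2 + (DV - src[2])**2)
        rk = np.sqrt((AP - snk[0])**2 + (ML - snk[1])**2 + (DV - snk[2])**2)
        scale = np.maximum(np.abs(mono(src, 1)), np.abs(mono(snk, -1)))
        r_min = 5 * grid.resolution
        sel = ((grid.sigma > 0) & (rs > r_min) & (rk > r_min)
               & (rs < 4.0) & (rk < 4.0) & (np.abs(ana) >= 0.3 * scale))
        offset = np.median(fmap.potential[sel] - ana[sel])
        err = np.abs(fmap.potential[sel] - ana[sel] - offset) \
            / np.abs(ana[sel])
        assert err.max() < 0.05

    def test_linearity_in_current(self, oracle_setup):
        grid, montage, fmap, *_ = oracle_setup
        double = fm.solve_quasistatic(grid, montage, "P", 2000.0)
        np.testing.assert_allclose(double.potential, 2 * fmap.potential,
                                   rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(double.e_mag, 2 * fmap.e_mag,
                                   rtol=1e-5, atol=1e-8)

    def test_anode_cathode_swap_antisymmetry(self, oracle_setup):
        grid, montage, fmap, src, snk = oracle_setup
        swapped = fm.ElectrodeMontage([fm.Contact(src, "cathode", "P"),
                                       fm.Contact(snk, "anode", "P")])
        neg = fm.solve_quasistatic(grid, swapped, "P", 1000.0)
        np.testing.assert_allclose(neg.potential, -fmap.potential,
                                   rtol=1e-5, atol=1e-6)
        np.testing.assert_allclose(neg.e_mag, fmap.e_mag,
                                   rtol=1e-5, atol=1e-6)

    def test_current_conservation_around_empty_box(self, oracle_setup):
        # net flux through a closed voxel box enclosing no source ~ 0
        grid, _, fmap, src, _ = oracle_setup
        i0 = np.array(grid.index_of(src)) + np.array([10, 10, 0])
        lo, hi = i0 - 3, i0 + 3
        h = grid.resolution * 1e-3
        V = fmap.potential * 1e-3
        net = 0.0
        inj = 1000.0 * 1e-6
        for ax in range(3):
            for face, sgn in ((lo[ax], -1), (hi[ax], +1)):
                sl_in = [slice(lo[d], hi[d] + 1) for d in range(3)]
                sl_out = list(sl_in)
                sl_in[ax] = face
                sl_out[ax] = face + sgn
                v_in = V[tuple(sl_in)]
                v_out = V[tuple(sl_out)]
                s_in = grid.sigma[tuple(sl_in)]
                s_out = grid.sigma[tuple(sl_out)]
                g = np.where((s_in > 0) & (s_out > 0),
                             2 * s_in * s_out / (s_in + s_out + 1e-300) * h,
                             0.0)
                net += np.sum(g * (v_in - v_out))
        assert abs(net) < 1e-3 * inj

    def test_nonpositive_current_rejected(self, oracle_setup):
        grid, montage, *_ = oracle_setup
        with pytest.raises(ValueError, match="positive"):
            fm.solve_quasistatic(grid, montage, "P", 0.0)

    def test_unknown_configuration_rejected(self, snf_setup):
        grid, montage, _ = snf_setup
        with pytest.raises(ValueError, match="unknown"):
            fm.solve_quasistatic(grid, montage, "X9", 100.0)


class TestSequentialSet:
    def test_one_map_per_subconfiguration(self, snf_setup):
        grid, montage, _ = snf_setup
        maps = fm.sequential_field_set(grid, montage, fm.SNF_ORDER, 650.0)
        assert len(maps) == 8
        assert [m.config_label for m in maps] == list(fm.SNF_ORDER)

    def test_repeated_label_rejected(self, snf_setup):
        grid, montage, _ = snf_setup
        with pytest.raises(ValueError, match="repeat"):
            fm.sequential_field_set(grid, montage, ("L1", "L1"), 650.0)

    def test_union_covers_at_least_any_member(self, snf_setup):
        grid, montage, _ = snf_setup
        maps = fm.sequential_field_set(grid, montage, fm.SNF_ORDER, 650.0)
        hpc = grid.masks["hippocampus"]
        union = np.zeros(grid.shape, dtype=bool)
        for m in maps:
            union |= m.e_mag >= fm.THRESH_TARGET
        for m in maps:
            member = (m.e_mag >= fm.THRESH_TARGET) & hpc
            assert union[member].all()


class TestCoverage:
    def test_zero_field_zero_fractions(self, snf_setup):
        grid, _, fmap = snf_setup
        zero = fm.FieldMap(np.zeros(grid.shape),
                           np.zeros((3,) + grid.shape),
                           np.zeros(grid.shape), grid, "Z", 1.0, 0.0)
        out = fm.coverage_and_spread([zero], grid.masks["hippocampus"],
                                     grid.masks["brain"])
        assert out == {"target_coverage_fraction": 0.0,
                       "off_target_fraction@10": 0.0,
                       "off_target_fraction@50": 0.0}

    def test_zero_thresholds_saturate(self, snf_setup):
        grid, _, fmap = snf_setup
        out = fm.coverage_and_spread([fmap], grid.masks["hippocampus"],
                                     grid.masks["brain"],
                                     thresholds=(0.0, 0.0, 0.0))
        off = grid.masks["brain"]
        assert out["off_target_fraction@10"] == pytest.approx(
            (fmap.e_mag[off] > 0).mean(), abs=1e-6)

    def test_empty_mask_rejected(self, snf_setup):
        grid, _, fmap = snf_setup
        with pytest.raises(ValueError, match="empty"):
            fm.coverage_and_spread([fmap], np.zeros(grid.shape, bool),
                                   grid.masks["brain"])

    def test_scaled_map_scales_coverage_monotonically(self, snf_setup):
        grid, _, fmap = snf_setup
        hpc = grid.masks["hippocampus"]
        covs = [fm.coverage_and_spread([fmap.scaled(c)], hpc,
                                       grid.masks["brain"])
                ["target_coverage_fraction"] for c in (100.0, 650.0, 5000.0)]
        assert covs[0] <= covs[1] <= covs[2]


class TestPerturbation:
    def test_zero_perturbation_identity(self, snf_setup):
        grid, *_ = snf_setup
        out = fm.perturb_conductivity(grid, 0.0, seed=1)
        np.testing.assert_array_equal(out.sigma, grid.sigma)

    def test_factors_within_bounds(self, snf_setup):
        grid, *_ = snf_setup
        out = fm.perturb_conductivity(grid, 0.10, seed=2)
        tissue = (grid.sigma > 0) & ~grid.masks["electrode_insulation"]
        f = out.sigma[tissue] / grid.sigma[tissue]
        assert f.min() >= 0.9 and f.max() <= 1.1

    def test_insulation_and_air_untouched(self, snf_setup):
        grid, *_ = snf_setup
        out = fm.perturb_conductivity(grid, 0.10, seed=3)
        ins = grid.masks["electrode_insulation"]
        np.testing.assert_array_equal(out.sigma[ins], grid.sigma[ins])
        np.testing.assert_array_equal(out.sigma[grid.masks["air"]],
                                      grid.sigma[grid.masks["air"]])

    def test_mean_factor_unbiased(self):
        grid = fm.build_grid(fm.GeometryConfig(resolution=0.25))
        out = fm.perturb_conductivity(grid, 0.10, seed=4)
        tissue = grid.sigma > 0
        assert tissue.sum() >= 1e5
        f = out.sigma[tissue] / grid.sigma[tissue]
        assert abs(f.mean() - 1.0) < 0.005


class TestHeterogeneity:
    def test_uniform_scaling_gives_analytic_deviation(self):
        # scaling sigma globally by 1.1 at fixed current scales |E| by 1/1.1
        geo = fm.GeometryConfig(resolution=0.5, homogeneous=True)
        grid = fm.build_grid(geo)
        montage = fm.snf_montage()
        fm.add_electrode_tracks(grid, montage)
        base = fm.solve_quasistatic(grid, montage, "L2", 650.0)
        scaled_grid = fm.ConductivityGrid(
            np.where(grid.sigma > 0, grid.sigma * 1.1, 0.0),
            grid.resolution, grid.origin, grid.masks)
        scaled = fm.solve_quasistatic(scaled_grid, montage, "L2", 650.0)
        hpc = grid.masks["hippocampus"] & (base.e_mag > 0.01)
        dev = np.abs(scaled.e_mag[hpc] - base.e_mag[hpc]) / base.e_mag[hpc]
        assert np.median(dev) == pytest.approx(abs(1 / 1.1 - 1), rel=0.02)

    def test_zero_perturbation_zero_deviation(self):
        geo = fm.GeometryConfig(resolution=0.5, homogeneous=True)
        out = fm.heterogeneity_experiment(geo, n_seeds=1, max_rel=0.0, seed=0)
        assert out["max_deviation"] == pytest.approx(0.0, abs=1e-9)


class TestSweep:
    def test_sweep_montage_places_pairs_in_target(self, coarse_geometry):
        grid = fm.build_grid(coarse_geometry)
        for n in (1, 3, 5):
            montage = fm.sweep_montage(n, coarse_geometry, side="R")
            assert len(montage.contacts) == 2 * n
            for c in montage.contacts:
                if c.role == "cathode":
                    i = grid.index_of(c.position)
                    assert grid.masks["hippocampus_R"][i]

    def test_required_current_and_spread_decrease(self, coarse_geometry):
        out = fm.electrode_count_sweep(coarse_geometry,
                                       pair_counts=(1, 2, 4))
        cur = out["required_current_uA"]
        off = out["off_target_fraction"]
        assert cur[0] > cur[1] > cur[2]
        assert off[0] > off[1] > off[2]
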