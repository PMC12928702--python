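"""Membrane fields: gridding, curvature, PMF, energies, observables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scstrain import fields as F, synthetic as S
from scstrain.constants import KB_KCAL
from scstrain.particles import ParticleFrame


def strip_leaflets(fr):
    blank = np.array([""] * len(fr), dtype=object)
    return ParticleFrame(fr.positions, fr.category, blank, fr.lipid_id,
                        fr.chain_label, fr.box)


class TestAssignLeaflets:
    def test_matches_generator_ground_truth(self, flat_bilayer_frames):
        fr = flat_bilayer_frames[0]
        lab = F.assign_leaflets(strip_leaflets(fr))
        heads = fr.select("lipid-head")
        assert (lab.leaflet[heads] == fr.leaflet[heads]).all()

    def test_single_leaflet_rejected(self):
        n = 50
        rng = np.random.default_rng(0)
        pos = np.column_stack([rng.uniform(0, 10, (n, 2)), np.full(n, 2.0)])
        fr = ParticleFrame(pos, np.array(["lipid-head"] * n, dtype=object),
                           np.array([""] * n, dtype=object), np.arange(n),
                           np.array([""] * n, dtype=object), box=[10, 10, 10])
        with pytest.raises(ValueError, match="single-leaflet|one leaflet"):
            F.assign_leaflets(fr)

    def test_invariant_to_global_z_translation(self, flat_bilayer_frames):
        fr = flat_bilayer_frames[0]
        shifted = ParticleFrame(fr.positions + [0, 0, 7.5], fr.category,
                                np.array([""] * len(fr), dtype=object),
                                fr.lipid_id, fr.chain_label, fr.box)
        lab0 = F.assign_leaflets(strip_leaflets(fr))
        lab1 = F.assign_leaflets(shifted)
        assert (lab0.leaflet == lab1.leaflet).all()


class TestGridSurfaces:
    def test_flat_bilayer_thickness_map(self, flat_bilayer_frames):
        g = F.grid_surfaces(flat_bilayer_frames, resolution=1.0)
        assert np.nanmean(g.thickness) == pytest.approx(4.05, abs=0.02)
        assert np.nanstd(g.thickness) < 0.1

    def test_weights_follow_median_rule(self):
        # construct a grid where one cell holds a quarter of the median count
        spec = S.DeformationSpec(box_x=12, box_y=12, n_lipids_per_leaflet=360,
                                 noise_sd=0.0, seed=3)
        frames = S.make_membrane_frames(spec, 8)
        g = F.grid_surfaces(frames, resolution=2.0)
        med = np.median(g.count[g.count > 0])
        cell = np.unravel_index(np.argmax(g.count), g.count.shape)
        assert g.weight[cell] == min(1.0, g.count[cell] / (0.5 * med))

    def test_filled_cells_have_zero_weight(self):
        spec = S.DeformationSpec(box_x=20, box_y=20, n_lipids_per_leaflet=300,
                                 inclusion=(10, 10, 4.0, 1.0), noise_sd=0.0,
                                 seed=4)
        g = F.grid_surfaces(S.make_membrane_frames(spec, 2), resolution=0.5)
        assert g.filled.any()
        assert (g.weight[g.filled] == 0).all()
        assert np.isfinite(g.thickness).all()  # interpolation left no holes

    def test_bad_resolution_rejected(self, flat_bilayer_frames):
        with pytest.raises(ValueError):
            F.grid_surfaces(flat_bilayer_frames, resolution=0.0)


class TestShiftMap:
    def test_flat_membrane_shift_is_zero(self, flat_bilayer_frames):
        g = F.grid_surfaces(flat_bilayer_frames, resolution=1.0)
        assert np.abs(F.shift_map(g)).max() < 0.05

    def test_bump_peak_recovered(self):
        spec = S.DeformationSpec(box_x=40, box_y=40, n_lipids_per_leaflet=2400,
                                 height_bumps=((1.0, 3.0, 20, 20),),
                                 noise_sd=0.05, seed=5)
        g = F.grid_surfaces(S.make_membrane_frames(spec, 10), resolution=1.0)
        assert F.shift_map(g).max() == pytest.approx(1.0, abs=0.1)

    def test_invariant_to_constant_height_offset(self, flat_bilayer_frames):
        g = F.grid_surfaces(flat_bilayer_frames, resolution=1.0)
        s0 = F.shift_map(g)
        g.midplane = g.midplane + 3.0
        assert np.allclose(F.shift_map(g), s0, atol=1e-12)


class TestMeanCurvature:
    @given(a=st.floats(-2, 2), b=st.floats(-0.5, 0.5), c=st.floats(-0.5, 0.5))
    @settings(max_examples=25, deadline=None)
    def test_affine_surface_has_zero_curvature(self, a, b, c):
        x = np.arange(0, 20, 0.5)
        X, Y = np.meshgrid(x, x, indexing="ij")
        h = F.mean_curvature(a + b * X + c * Y, 0.5)
        assert np.nanmax(np.abs(h)) < 1e-10

    def test_hemisphere_curvature_is_inverse_radius(self):
        res, R = 0.5, 10.0
        x = np.arange(0, 40, res)
        X, Y = np.meshgrid(x, x, indexing="ij")
        r2 = (X - 20) ** 2 + (Y - 20) ** 2
        Z = np.sqrt(np.maximum(R**2 - r2, 0.0))
        h = F.mean_curvature(Z, res)
        inner = r2 < (0.5 * R) ** 2
        assert np.nanmean(np.abs(h[inner])) == pytest.approx(1 / R, rel=0.05)

    def test_sinusoid_crest_curvature(self):
        res, A = 0.5, 0.5
        k = 2 * np.pi / 10.0
        x = np.arange(0, 40, res)
        X, _ = np.meshgrid(x, x, indexing="ij")
        h = F.mean_curvature(A * np.sin(k * X), res)
        crest = np.isclose(np.sin(k * X), 1.0, atol=1e-3) & np.isfinite(h)
        assert np.nanmean(np.abs(h[crest])) == pytest.approx(A * k**2 / 2, rel=0.05)

    def test_paper_formula_differs_only_on_tilted_saddles(self):
        x = np.arange(0, 20, 0.5)
        X, Y = np.meshgrid(x, x, indexing="ij")
        flat_bump = np.exp(-((X - 10) ** 2 + (Y - 10) ** 2) / 8.0)
        h_std = F.mean_curvature(flat_bump, 0.5, formula="standard")
        h_pap = F.mean_curvature(flat_bump, 0.5, formula="paper")
        # radially symmetric bump: difference confined to off-axis cells
        on_axis = np.isclose(X, 10.0) | np.isclose(Y, 10.0)
        assert np.allclose(h_std[on_axis & np.isfinite(h_std)],
                           h_pap[on_axis & np.isfinite(h_pap)], atol=1e-9)
        assert not np.allclose(np.nan_to_num(h_std), np.nan_to_num(h_pap))

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError, match="5x5"):
            F.mean_curvature(np.zeros((4, 8)), 0.5)


class TestThicknessPMF:
    def test_gaussian_curvature_recovery(self):
        rng = np.random.default_rng(6)
        sigma = 0.12
        pmf = F.thickness_pmf(rng.normal(4.05, sigma, 100_000), temperature=310.0)
        v = np.isfinite(pmf.free_energy)
        coef = np.polyfit(pmf.bin_centers[v] - 4.05, pmf.free_energy[v], 2)
        expected = KB_KCAL * 310.0 / sigma**2
        assert 2 * coef[0] == pytest.approx(expected, rel=0.1)

    def test_minimum_shifted_to_zero(self):
        rng = np.random.default_rng(7)
        pmf = F.thickness_pmf(rng.normal(4.0, 0.1, 5000))
        assert np.nanmin(pmf.free_energy) == 0.0

    def test_invariant_to_sample_duplication(self):
        rng = np.random.default_rng(8)
        s = rng.normal(4.0, 0.1, 2000)
        p1 = F.thickness_pmf(s)
        p2 = F.thickness_pmf(np.concatenate([s, s]), bin_edges=p1.bin_edges)
        assert np.allclose(p1.free_energy, p2.free_energy, equal_nan=True)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            F.thickness_pmf(np.ones(10))


class TestStrainEnergy:
    def make_pmf(self):
        rng = np.random.default_rng(9)
        return F.thickness_pmf(rng.normal(4.0, 0.1, 200_000), temperature=310.0)

    def test_reference_distribution_gives_bulk_baseline(self):
        pmf = self.make_pmf()
        rng = np.random.default_rng(10)
        sample = rng.normal(4.0, 0.1, 100_000)
        g = F.strain_energy(sample, pmf)
        dz = pmf.bin_width
        v = np.isfinite(pmf.free_energy)
        baseline = float(np.sum(pmf.density[v] * pmf.free_energy[v]) * dz)
        assert g == pytest.approx(baseline, rel=0.05)

    def test_distribution_at_minimum_gives_zero(self):
        pmf = self.make_pmf()
        at_min = np.full(5000, pmf.bin_centers[np.nanargmin(pmf.free_energy)])
        assert F.strain_energy(at_min, pmf) == pytest.approx(0.0, abs=0.02)

    def test_thinning_shift_raises_strain_monotonically(self):
        pmf = self.make_pmf()
        rng = np.random.default_rng(11)
        base = rng.normal(4.0, 0.05, 50_000)
        gs = [F.strain_energy(base - shift, pmf) for shift in (0.0, 0.1, 0.2)]
        assert gs[0] < gs[1] < gs[2]

    def test_mass_outside_support_rejected(self):
        pmf = self.make_pmf()
        with pytest.raises(ValueError, match="outside"):
            F.strain_energy(np.full(1000, 10.0), pmf)


class TestDeformationEnergies:
    def test_flat_membrane_has_zero_bending_energy(self, flat_bilayer_frames):
        grids = [F.grid_surfaces(flat_bilayer_frames[i:i + 5], resolution=1.0)
                 for i in (0, 5)]
        dec = F.deformation_energies(grids, mask_radius=8.0, bootstrap=20,
                                     smooth_sigma=1.0)
        assert dec.g_curv < 0.5  # residual noise floor only
        assert dec.g_thick is None

    def test_bump_matches_analytic_helfrich_integral(self):
        A, w = 0.8, 4.0
        spec = S.DeformationSpec(box_x=40, box_y=40, n_lipids_per_leaflet=2400,
                                 noise_sd=0.0, height_bumps=((A, w, 20, 20),),
                                 seed=12)
        frames = S.make_membrane_frames(spec, 180)
        grids = [F.grid_surfaces(frames[i * 60:(i + 1) * 60], resolution=0.5)
                 for i in range(3)]
        dec = F.deformation_energies(grids, mask_radius=15.0, bootstrap=50,
                                     seed=0)
        # oracle: analytic field of the generator on a fine grid
        res_f = 0.1
        x = np.arange(res_f / 2, 40, res_f)
        X, Y = np.meshgrid(x, x, indexing="ij")
        Z = A * np.exp(-((X - 20) ** 2 + (Y - 20) ** 2) / (2 * w**2))
        Hf = F.mean_curvature(Z, res_f)
        m = ((X - 20) ** 2 + (Y - 20) ** 2 <= 15.0**2) & np.isfinite(Hf)
        oracle = (0.5 * 11.85 * np.nansum((2 * Hf[m]) ** 2) * res_f**2
                  * 1000.0 / (m.sum() * res_f**2))
        assert dec.g_curv == pytest.approx(oracle, rel=0.10)

    def test_g_curv_linear_in_kappa(self):
        spec = S.DeformationSpec(box_x=30, box_y=30, n_lipids_per_leaflet=1300,
                                 noise_sd=0.0, height_bumps=((0.5, 3.0, 15, 15),),
                                 seed=13)
        frames = S.make_membrane_frames(spec, 40)
        grids = [F.grid_surfaces(frames[i * 20:(i + 1) * 20], resolution=0.5)
                 for i in range(2)]
        d1 = F.deformation_energies(grids, kappa=11.85, mask_radius=10,
                                    bootstrap=0)
        d2 = F.deformation_energies(grids, kappa=23.70, mask_radius=10,
                                    bootstrap=0)
        assert d2.g_curv == pytest.approx(2 * d1.g_curv, rel=1e-9)

    def test_merged_inclusion_costs_less_than_separated(self):
        def g_curv(bumps):
            spec = S.DeformationSpec(box_x=60, box_y=40,
                                     n_lipids_per_leaflet=5000, noise_sd=0.0,
                                     height_bumps=bumps, seed=14)
            frames = S.make_membrane_frames(spec, 40)
            grids = [F.grid_surfaces(frames[i * 20:(i + 1) * 20],
                                     resolution=0.5) for i in range(2)]
            return F.deformation_energies(grids, mask_radius=28,
                                          center=(30, 20), bootstrap=0).g_curv

        separated = g_curv(((0.8, 3.0, 18, 20), (0.8, 3.0, 42, 20)))
        merged = g_curv(((0.8, 4.0, 30, 20),))
        assert merged < separated

    def test_bootstrap_sd_vanishes_for_identical_frames(self, flat_bilayer_frames):
        g = F.grid_surfaces(flat_bilayer_frames, resolution=1.0)
        dec = F.deformation_energies([g, g, g], mask_radius=8, bootstrap=50)
        assert dec.g_curv_sd == pytest.approx(0.0, abs=1e-12)

    def test_thickness_energy_uses_pmf(self, flat_bilayer_frames):
        rng = np.random.default_rng(15)
        pmf = F.thickness_pmf(rng.normal(4.05, 0.1, 100_000))
        grids = [F.grid_surfaces(flat_bilayer_frames[i:i + 5], resolution=1.0)
                 for i in (0, 5)]
        dec = F.deformation_energies(grids, pmf=pmf, mask_radius=8,
                                     bootstrap=20)
        assert dec.g_thick is not None and dec.g_thick >= 0


class TestEndToEnd:
    def make_chain_frame(self):
        # straight 18-bead chain at 0.1 nm spacing along z
        n = 18
        pos = np.column_stack([np.zeros(n), np.zeros(n),
                               np.arange(n) * 0.1])
        labels = np.array([f"CA{i + 1}" for i in range(n)], dtype=object)
        return ParticleFrame(pos, np.array(["lipid-chain"] * n, dtype=object),
                             np.array([""] * n, dtype=object), np.zeros(n, int),
                             labels, box=[5, 5, 5])

    def test_straight_chain_length(self):
        out = F.end_to_end(self.make_chain_frame())
        assert out["lengths_nm"] == pytest.approx([1.7])

    def test_coincident_ends_give_zero(self):
        fr = self.make_chain_frame()
        fr.positions[-1] = fr.positions[0]
        assert F.end_to_end(fr)["lengths_nm"] == pytest.approx([0.0])

    def test_invariant_under_rigid_rotation(self):
        fr = self.make_chain_frame()
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        fr2 = self.make_chain_frame()
        fr2.positions = fr.positions @ rot.T
        assert F.end_to_end(fr2)["lengths_nm"] == pytest.approx(
            F.end_to_end(fr)["lengths_nm"]
        )

    def test_missing_label_skipped_with_count(self):
        fr = self.make_chain_frame()
        fr.chain_label[-1] = "CAX"
        out = F.end_to_end(fr)
        assert out["n_skipped"] == 1
        assert len(out["lengths_nm"]) == 0


class TestFlipFlop:
    def test_telegraph_mean_recovered_within_printed_band(self):
        traj = S.make_q_trajectory(S.TelegraphSpec(n_molecules=200,
                                                   total_time_ns=10_000,
                                                   mean_flip_time_ns=125.0,
                                                   seed=16))
        out = F.flipflop_times(traj)
        assert 100.0 <= out["mean_ns"] <= 150.0
        assert out["ci_ns"][0] < out["mean_ns"] < out["ci_ns"][1]

    def test_alternating_series_gives_timestep(self):
        labels = np.tile([0, 1], 50)[None, :]
        out = F.flipflop_times(labels, timestep_ns=2.0)
        assert out["mean_ns"] == pytest.approx(2.0)

    def test_invariant_to_molecule_order(self):
        traj = S.make_q_trajectory(S.TelegraphSpec(n_molecules=50,
                                                   total_time_ns=2000, seed=17))
        a = F.flipflop_times(traj.labels, timestep_ns=1.0)
        b = F.flipflop_times(traj.labels[::-1], timestep_ns=1.0)
        assert a["mean_ns"] == pytest.approx(b["mean_ns"])

    def test_no_transitions_reports_censored(self):
        out = F.flipflop_times(np.zeros((3, 100), dtype=int), timestep_ns=1.0)
        assert out["censored"] is True


class TestDensityEnrichment:
    def test_uniform_distribution_reads_unity(self):
        spec = S.DeformationSpec(box_x=30, box_y=30, n_lipids_per_leaflet=1500,
                                 n_quinones=2000, noise_sd=0.02, seed=18)
        frames = S.make_membrane_frames(spec, 5)
        out = F.density_enrichment(frames, "quinone-head",
                                   bulk_zone=lambda x, y: x < 15.0,
                                   resolution=3.0)
        assert np.abs(out["map"] - 1.0).max() < 3 / math.sqrt(
            out["bulk_count"] / out["bulk_mask"].sum()
        )

    def test_ring_enrichment_recovered(self):
        spec = S.DeformationSpec(box_x=40, box_y=40, n_lipids_per_leaflet=2000,
                                 inclusion=(20, 20, 4.0, 2.0), n_quinones=3000,
                                 enrichment_ring=(4.0, 8.0, 1.3),
                                 noise_sd=0.02, seed=19)
        frames = S.make_membrane_frames(spec, 20)
        out = F.density_enrichment(
            frames, "quinone-head",
            bulk_zone=lambda x, y: np.hypot(x - 20, y - 20) > 12.0,
            resolution=1.0,
        )
        gx, gy = np.meshgrid(out["x_centers"], out["y_centers"], indexing="ij")
        r = np.hypot(gx - 20, gy - 20)
        ring = (r > 4.5) & (r < 7.5)
        assert out["map"][ring].mean() == pytest.approx(1.3, abs=0.1)

    def test_doubling_counts_leaves_map_unchanged(self):
        spec = S.DeformationSpec(box_x=30, box_y=30, n_lipids_per_leaflet=800,
                                 n_quinones=1000, noise_sd=0.02, seed=20)
        frames = S.make_membrane_frames(spec, 4)
        zone = lambda x, y: x < 15.0
        m1 = F.density_enrichment(frames, "quinone-head", zone, resolution=3.0)
        m2 = F.density_enrichment(frames + frames, "quinone-head", zone,
                                  resolution=3.0)
        assert np.allclose(m1["map"], m2["map"])

    def test_empty_bulk_zone_rejected(self, flat_bilayer_frames):
        with pytest.raises(ValueError):
            F.density_enrichment(flat_bilayer_frames, "lipid-head",
                                 bulk_zone=lambda x, y: x > 1e9)


class TestDielectric:
    def test_zero_variance_gives_unity(self):
        d = S.make_dipole_snapshots(np.zeros(5), 200, seed=21)
        prof = F.dielectric_profile(d)
        assert np.allclose(prof.epsilon, 1.0)

    def test_closed_form_gaussian_recovery(self):
        sigma2 = 0.01
        d = S.make_dipole_snapshots(np.full(8, sigma2), 10_000, seed=22)
        prof = F.dielectric_profile(d, temperature=310.0)
        from scstrain.constants import E_CHARGE, EPS0_SI, KB_SI

        v = 4.0 / 3.0 * math.pi * (0.2e-9) ** 3
        expected = 1.0 + 3 * sigma2 * (E_CHARGE * 1e-9) ** 2 / (
            3 * EPS0_SI * KB_SI * 310.0 * v
        )
        assert np.allclose(prof.epsilon, expected, rtol=0.05)

    def test_step_profile_located_within_one_bin(self):
        var = np.r_[np.full(10, 0.001), np.full(10, 0.02)]
        d = S.make_dipole_snapshots(var, 2000, seed=23)
        prof = F.dielectric_profile(d)
        jump = np.argmax(np.diff(prof.epsilon))
        assert abs(jump - 9) <= 1

    def test_zero_charges_give_exactly_unity(self):
        # M = sum q r with all charges zero -> identically 1
        probes = np.array([[0.0, 0.0, z] for z in np.linspace(-2, 2, 5)])
        rng = np.random.default_rng(24)
        pos = rng.uniform(-3, 3, size=(500, 3))
        m = F.local_dipole_moments(pos, np.zeros(500), probes)
        samples = np.repeat(m[None, :, :], 150, axis=0)
        prof = F.dielectric_profile(
            S.DipoleSampleSet(samples, probes[:, 2])
        )
        assert (prof.epsilon == 1.0).all()

    def test_underpopulated_bins_masked(self):
        d = S.make_dipole_snapshots(np.full(3, 0.01), 50, seed=25)
        prof = F.dielectric_profile(d)
        assert np.isnan(prof.epsilon).all()
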