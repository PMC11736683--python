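"""Boltzmann inversion: profiles, block errors, ΔG_m."""

import numpy as np
import pytest

import permeant as pm
from permeant.errors import ReferenceRegionError, ValidationError

KT = pm.kBT(310.0)


def _traj_from_z(z, box_z=40.0, dt=1.0):
    z = np.asarray(z, dtype=float)
    pos = np.zeros((len(z), 1, 3))
    pos[:, 0, 2] = z
    return pm.Trajectory(
        times=dt * np.arange(len(z)),
        positions=pos,
        box=np.array([1.0, 1.0, box_z]),
        labels=["permeant"],
    )


class TestFreeEnergyProfile:
    def test_uniform_positions_give_flat_profile(self):
        # exactly uniform: one sample per bin center
        centers = np.arange(-19.75, 20.0, 0.5)
        traj = _traj_from_z(centers)
        prof = pm.free_energy_profile(traj, bins=0.5, water_region=(15, 20), T=310.0)
        assert np.allclose(prof.F[np.isfinite(prof.F)], 0.0, atol=1e-9)

    def test_single_boltzmann_factor(self):
        # two equal-width bins with counts (n·e, n); the sparse bin is the
        # water reference, so the dense bin sits exactly -kBT below it
        n = 1000
        n_e = int(round(n * np.e))
        z = np.concatenate([np.full(n_e, 4.0), np.full(n, 12.0)])
        traj = _traj_from_z(z)
        prof = pm.free_energy_profile(
            traj, bins=np.array([0.0, 8.0, 16.0]), water_region=(10, 14), T=310.0
        )
        assert prof.F[1] == pytest.approx(0.0, abs=1e-12)
        assert prof.F[0] == pytest.approx(-KT * np.log(n_e / n), abs=1e-9)
        assert prof.F[0] == pytest.approx(-KT, abs=1e-3)

    def test_empty_bins_are_nan_not_inf(self):
        z = np.full(100, 5.0)
        traj = _traj_from_z(z)
        prof = pm.free_energy_profile(traj, bins=0.5, water_region=(4, 6), T=310.0)
        assert not np.any(np.isinf(prof.F))
        assert np.isnan(prof.F[0])

    def test_empty_water_region_raises(self):
        traj = _traj_from_z(np.zeros(50))
        with pytest.raises(ReferenceRegionError):
            pm.free_energy_profile(traj, bins=1.0, water_region=(10, 19), T=310.0)

    def test_histogram_conserves_counts(self, well_traj):
        _, traj = well_traj
        prof = pm.free_energy_profile(
            traj, bins=1.0, water_region=(25, 38), T=310.0
        )
        assert prof.counts.sum() == traj.n_frames * traj.n_particles

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0.0, 6.0, size=5000)
        z = z[np.abs(z) < 19.9]
        traj = _traj_from_z(np.concatenate([z, rng.uniform(-20, 20, 2000)]))
        prof = pm.free_energy_profile(traj, bins=2.0, water_region=(15, 20), T=310.0)
        # water-region mean of F is pinned to zero regardless of normalization
        centers = prof.bin_centers
        mask = (np.abs(centers) >= 15) & (np.abs(centers) <= 20) & (prof.counts > 0)
        assert np.nanmean(prof.F[mask]) == pytest.approx(0.0, abs=1e-9)

    def test_input_profile_recovered(self, well_traj):
        spec, traj = well_traj
        prof = pm.free_energy_profile(traj, bins=1.0, water_region=(25, 38), T=310.0)
        err = pm.block_errors(traj, bins=1.0, water_region=(25, 38), T=310.0)
        centers = prof.bin_centers
        f_true = spec._F(centers)
        wmask = (np.abs(centers) >= 25) & (np.abs(centers) <= 38) & (prof.counts > 0)
        f_true = f_true - f_true[wmask].mean()
        sampled = prof.counts >= 100
        within = np.abs(prof.F - f_true)[sampled] <= 2 * err[sampled]
        assert within.mean() >= 0.95


class TestBlockErrors:
    def test_identical_blocks_have_zero_error(self):
        segment = np.concatenate([np.full(30, -10.0), np.full(70, 10.0)])
        traj = _traj_from_z(np.tile(segment, 10))
        err = pm.block_errors(
            traj, bins=np.array([-20.0, 0.0, 20.0]), water_region=(5, 15),
            T=310.0, n_blocks=10,
        )
        assert np.allclose(err, 0.0, atol=1e-12)

    def test_error_shrinks_with_run_length(self, well_traj):
        spec, traj = well_traj
        half = pm.Trajectory(
            times=traj.times[: traj.n_frames // 2],
            positions=traj.positions[: traj.n_frames // 2],
            box=traj.box[: traj.n_frames // 2],
            labels=traj.labels,
        )
        e_full = pm.block_errors(traj, bins=2.0, water_region=(25, 38), T=310.0)
        e_half = pm.block_errors(half, bins=2.0, water_region=(25, 38), T=310.0)
        ok = np.isfinite(e_full) & np.isfinite(e_half) & (e_half > 0)
        ratio = np.median(e_full[ok] / e_half[ok])
        assert 0.5 < ratio < 0.95  # ~1/sqrt(2) with block-noise scatter

    def test_too_few_blocks_rejected(self, well_traj):
        _, traj = well_traj
        with pytest.raises(ValidationError):
            pm.block_errors(traj, bins=1.0, water_region=(25, 38), n_blocks=1)

    def test_independent_seeds_agree_within_combined_errors(self):
        kt = KT
        F, dF = pm.gaussian_profile([-1.5 * kt], [0.0], [5.0])
        profs = []
        for seed in (61, 62):
            spec = pm.PermeationSystemSpec(
                F=F, dF=dF, D=0.5, box_z=60.0, dt=0.25, n_steps=400_000,
                n_particles=4, seed=seed,
            )
            traj = pm.simulate_permeation_1d(spec)
            prof = pm.free_energy_profile(traj, bins=1.5, water_region=(20, 28), T=310.0)
            prof.F_err = pm.block_errors(traj, bins=1.5, water_region=(20, 28), T=310.0)
            profs.append(prof)
        a, b = profs
        ok = (a.counts >= 100) & (b.counts >= 100)
        diff = np.abs(a.F - b.F)[ok]
        comb = np.sqrt(a.F_err**2 + b.F_err**2)[ok]
        assert (diff <= 2 * comb).mean() >= 0.95


class TestDeltaGm:
    def test_flat_profile_gives_zero(self):
        centers = np.arange(-19.75, 20.0, 0.5)
        traj = _traj_from_z(centers)
        prof = pm.free_energy_profile(traj, bins=0.5, water_region=(15, 20), T=310.0)
        assert pm.delta_g_membrane(prof) == pytest.approx(0.0, abs=1e-9)

    def test_sign_convention_on_handmade_profile(self):
        """A well of 3.22 kBT at the center reads out as ΔG_m = +3.22."""
        prof = pm.FreeEnergyProfile(
            bin_centers=np.array([-10.0, 0.0, 10.0]),
            F=np.array([0.0, -3.22 * KT, 0.0]),
            counts=np.array([10, 10, 10]),
            water_region=(5, 15),
            T=310.0,
        )
        assert pm.delta_g_membrane(prof) == pytest.approx(3.22, abs=1e-12)

    def test_synthetic_well_depth_recovered(self, well_traj):
        _, traj = well_traj
        res = pm.BoltzmannProfileModel(
            traj, bins=1.0, water_region=(25, 38), T=310.0
        ).fit()
        assert res.delta_g_m == pytest.approx(2.0, abs=0.2)
        assert res.delta_g_m_err < 0.15

    def test_empty_center_bin_raises(self):
        z = np.full(100, 15.0)
        traj = _traj_from_z(z)
        prof = pm.free_energy_profile(traj, bins=1.0, water_region=(14, 16), T=310.0)
        with pytest.raises(ReferenceRegionError):
            pm.delta_g_membrane(prof)


class TestModelFacade:
    def test_summary_mentions_key_quantities(self, well_traj):
        _, traj = well_traj
        res = pm.BoltzmannProfileModel(
            traj, bins=1.0, water_region=(25, 38), T=310.0
        ).fit()
        text = res.summary()
        assert "dG_m" in text
        assert "water region" in text
        frame = res.to_frame()
        assert {"z", "counts"} <= set(frame.columns)
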