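"""Dynamics: Metropolis rules, hop proposals, contention, height moves,
diffusion statistics, translocation drift, and reproducibility."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import intercells as ic
from intercells.core import CompiledSpecies, InterfaceGrid
from intercells.engine import ProposalBatch, resolve_contention

from conftest import free_simulation, small_config


class TestMetropolis:
    @pytest.mark.parametrize("dE,expect", [
        (-1.0, 1.0), (0.0, 1.0), (math.log(2), 0.5), (700.0, 0.0)])
    def test_probability(self, dE, expect):
        assert ic.metropolis_probability(dE) == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("dEl,dEe,expect", [
        (-1.0, -1.0, 1.0),
        (0.0, math.log(2), 0.5),
        (math.log(2), math.log(2), 0.25),
    ])
    def test_two_stage_product(self, dEl, dEe, expect):
        assert ic.hop_acceptance(dEl, dEe) == pytest.approx(expect)


class TestProposals:
    def test_immobile_species_never_proposes(self):
        sim = free_simulation(n=16, n_mol=5, D=0.0, n_steps=10)
        for _ in range(10):
            r = sim.step()
            assert r.hop_attempts.sum() == 0

    def test_unit_attempt_probability(self):
        # D = a^2 / (4 dt) makes every molecule propose every iteration
        D = 10.0 ** 2 / (4 * 0.01)
        sim = free_simulation(n=32, n_mol=10, D=D, n_steps=20)
        for _ in range(20):
            assert sim.step().hop_attempts.sum() == 10

    def test_excessive_diffusion_rejected(self):
        with pytest.raises(ic.ConfigurationError):
            ic.hop_attempt_probability(5e4, 0.01, 10.0)

    def test_occupied_targets_dropped(self):
        # full grid: every proposal hits an occupied pixel and is dropped
        n = 8
        rows, cols = np.divmod(np.arange(n * n), n)
        sim = free_simulation(n=n, placements=(rows, cols), D=2500.0, n_steps=5)
        for _ in range(5):
            assert sim.step().hop_accepted.sum() == 0
        sim.grid.check_consistency()


class TestContention:
    def _batch(self, gains):
        n = len(gains)
        z = np.zeros(n)
        return ProposalBatch(
            mol=np.arange(n), surface=np.zeros(n, int),
            src_r=np.arange(n), src_c=np.zeros(n, int),
            dst_r=np.full(n, 5), dst_c=np.full(n, 5),
            dE_leave=np.zeros(n), dE_enter=-np.asarray(gains, float),
        )

    def test_highest_energy_gain_wins(self):
        batch = self._batch([1.0, 2.0])  # gains +1 and +2 kT, same target
        rng = np.random.default_rng(0)
        winners = resolve_contention(batch, np.array([True, True]), (10, 10), rng)
        assert list(winners) == [1]

    def test_uncontested_proposal_unchanged(self):
        batch = self._batch([1.0])
        winners = resolve_contention(batch, np.array([True]), (10, 10),
                                     np.random.default_rng(0))
        assert list(winners) == [0]

    def test_exact_tie_reproducible(self):
        batch = self._batch([1.5, 1.5, 1.5])
        acc = np.array([True, True, True])
        w1 = resolve_contention(batch, acc, (10, 10), np.random.default_rng(42))
        w2 = resolve_contention(batch, acc, (10, 10), np.random.default_rng(42))
        assert list(w1) == list(w2) and len(w1) == 1

    def test_rejected_proposals_do_not_compete(self):
        batch = self._batch([1.0, 5.0])
        winners = resolve_contention(batch, np.array([True, False]), (10, 10),
                                     np.random.default_rng(0))
        assert list(winners) == [0]


class TestHeightMoves:
    def test_sigma_zero_leaves_field_unchanged(self):
        sim = free_simulation(n=16, n_mol=3, sigma_z=0.0, n_steps=5)
        z0 = sim.grid.z.copy()
        for _ in range(5):
            sim.step()
        assert np.array_equal(sim.grid.z, z0)

    def test_pinned_pixels_never_move(self):
        cfg = small_config(n=16, n_steps=30)
        sim = ic.build_scenario(cfg).build()
        for _ in range(30):
            sim.step()
        pinned = sim.grid.pinned_mask(sim.table)
        sp = sim.grid.mol_species
        ph = sim.table.pinned_h[sp]
        keep = ~np.isnan(ph)
        assert np.all(sim.grid.z[sim.grid.mol_row[keep],
                                 sim.grid.mol_col[keep]] == ph[keep])
        assert pinned.sum() == keep.sum()

    def test_downhill_moves_always_accepted(self):
        # strongly curved single-pixel spike relaxes deterministically
        table = CompiledSpecies.compile([ic.SpeciesSpec("X", k_mol=0.0)])
        grid = InterfaceGrid(8, 8)
        grid.z[4, 4] += 30.0
        e0 = ic.elastic_energy(grid.z, 300.0, 10.0)
        rng = np.random.default_rng(3)
        for _ in range(50):
            ic.update_heights(grid, table, 300.0, 1.0, rng)
        assert ic.elastic_energy(grid.z, 300.0, 10.0) < e0 / 5


class TestEquipartition:
    def test_free_membrane_mean_elastic_energy(self):
        """Long-run mean elastic energy of a free membrane matches the
        Boltzmann expectation kT/2 per non-zero mode of the discrete
        biharmonic quadratic form (independent eigenvalue oracle)."""
        n, kappa, a = 6, 30.0, 10.0
        # oracle: assemble A with H = 1/2 z^T A z by finite differences
        npix = n * n
        A = np.zeros((npix, npix))
        for i in range(npix):
            e = np.zeros(npix)
            e[i] = 1.0
            z = e.reshape(n, n)
            lap = (np.roll(z, 1, 0) + np.roll(z, -1, 0) + np.roll(z, 1, 1)
                   + np.roll(z, -1, 1) - 4 * z)
            A[:, i] = (kappa / (a * a)) * (
                np.roll(lap, 1, 0) + np.roll(lap, -1, 0) + np.roll(lap, 1, 1)
                + np.roll(lap, -1, 1) - 4 * lap).ravel()
        eigs = np.linalg.eigvalsh(A)
        expected = 0.5 * np.sum(eigs > 1e-9 * eigs.max())  # kT/2 per mode

        table = CompiledSpecies.compile([ic.SpeciesSpec("X", k_mol=0.0)])
        grid = InterfaceGrid(n, n, z_init=70.0)
        rng = np.random.default_rng(11)
        energies = []
        for sweep in range(12_000):
            ic.update_heights(grid, table, kappa, 1.0, rng)
            if sweep >= 2_000:
                energies.append(ic.elastic_energy(grid.z, kappa, grid.a))
        assert np.mean(energies) == pytest.approx(expected, rel=0.05)


class TestDiffusionStatistics:
    def test_spatial_distribution_stays_uniform(self):
        """With interactions off and dilute occupancy, quadrat counts are
        consistent with complete spatial randomness (chi^2, alpha = 0.01)."""
        sim = free_simulation(n=64, n_mol=256, D=1250.0, seed=5, n_steps=400)
        for _ in range(400):
            sim.step()
        q = 16  # 16 x 16 quadrats of 4x4 pixels
        counts = np.zeros((q, q))
        np.add.at(counts, (sim.grid.mol_row // 4, sim.grid.mol_col // 4), 1)
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = sps.chi2.sf(chi2, q * q - 1)
        assert p > 0.01


class TestTranslocation:
    def test_zero_speed_gives_uniform_weights(self):
        w = ic.apply_translocation_bias(np.array([[3, 3]]), (10, 10), 0.0,
                                        0.01, 10.0, 0.5, (32, 32))
        assert np.allclose(w, 0.25)

    def test_expected_drift_per_iteration(self):
        # v = 19 nm/s, dt = 0.01 s -> 0.19 nm expected centripetal step
        speed, dt, a, p = 19.0, 0.01, 10.0, 0.5
        pos = np.array([[16, 4]])  # straight west of the target
        w = ic.apply_translocation_bias(pos, (16, 16), speed, dt, a, p, (32, 32))
        drift = p * a * (w[0, 3] - w[0, 2])  # +x minus -x weight
        assert drift == pytest.approx(speed * dt)
        assert w[0, 0] == pytest.approx(w[0, 1])  # no transverse bias

    def test_excessive_bias_rejected(self):
        with pytest.raises(ic.ConfigurationError):
            ic.apply_translocation_bias(np.array([[0, 0]]), (16, 16), 500.0,
                                        0.01, 10.0, 0.2, (32, 32))


class TestScenarioDynamics:
    def test_apc_cross_gap_binding_flags(self):
        """A TCR sharing its pixel column with a cognate pMHC at the engaged
        separation is bound, and so is its partner; a non-cognate pMHC is
        not engaged."""
        table = CompiledSpecies.compile(ic.default_species_table("APC"))
        grid = InterfaceGrid(8, 8)
        grid.add_molecules(table.index("TCR"), [2], [2], 0)
        grid.add_molecules(table.index("pMHC"), [2], [2], 1)
        grid.add_molecules(table.index("TCR"), [5], [5], 0)
        grid.add_molecules(table.index("pMHC_nc"), [5], [5], 1)
        grid.apply_pins(table)  # both TCR pixels at 13 nm
        from intercells.energetics import update_bound_flags
        update_bound_flags(grid, table)
        assert grid.mol_bound[0] and grid.mol_bound[1]
        assert not grid.mol_bound[2] and not grid.mol_bound[3]

    @pytest.mark.parametrize("scenario", ["PLL", "APC"])
    def test_non_default_scenarios_run_conserving(self, scenario):
        cfg = small_config(scenario=scenario, n=24, n_steps=120,
                           save_every=60, pll_U=-2.0)
        sim = ic.build_scenario(cfg).build()
        counts0 = sim.grid.species_counts(sim.table)
        sim.run(check_invariants=True)
        assert sim.grid.species_counts(sim.table) == counts0


class TestReproducibility:
    def test_same_seed_bit_identical(self):
        cfg = small_config(n=24, n_steps=60, seed=99)
        runs = []
        for _ in range(2):
            sim = ic.build_scenario(cfg).build()
            traj = sim.run()
            runs.append((sim.grid.z.copy(), sim.grid.mol_row.copy(),
                         sim.grid.mol_col.copy(),
                         traj.reports[-1].height_accepted))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])
        assert np.array_equal(runs[0][2], runs[1][2])
        assert runs[0][3] == runs[1][3]

    def test_acceptance_bookkeeping(self):
        sim = ic.build_scenario(small_config(n=16, n_steps=10)).build()
        for _ in range(10):
            r = sim.step()
            assert (r.hop_accepted <= r.hop_attempts).all()
            assert r.height_accepted <= r.height_attempts
            assert r.height_attempts <= sim.grid.n_rows * sim.grid.n_cols
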