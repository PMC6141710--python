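"""Potentials, Hamiltonian terms, and locality of incremental energies.

The brute-force oracle here recomputes the full Hamiltonian with its own
independent (loop-based) implementation and compares complete-state energy
differences against the localized kernel evaluations.
"""

import numpy as np
import pytest

import intercells as ic
from intercells.core import CompiledSpecies, InterfaceGrid, T_CELL, APC_SURF
from intercells.energetics import (elastic_energy, interaction_energy,
                                   ligand_potential, repulsion_potential,
                                   total_energy)


# ---------------------------------------------------------------------------
# independent brute-force Hamiltonian (test-local oracle)
# ---------------------------------------------------------------------------

def brute_force_energy(grid, table, kappa):
    """Loop-based H = H_int + H_el, independent of the package kernels."""
    R, C, a = grid.n_rows, grid.n_cols, grid.a
    z = grid.z
    e_el = 0.0
    for r in range(R):
        for c in range(C):
            lap = (z[(r - 1) % R, c] + z[(r + 1) % R, c]
                   + z[r, (c - 1) % C] + z[r, (c + 1) % C] - 4 * z[r, c])
            e_el += kappa / (2 * a * a) * lap * lap
    e_int = 0.0
    sp_at = {}
    for surf in (T_CELL, APC_SURF):
        for r in range(R):
            for c in range(C):
                m = grid.occ[surf, r, c]
                if m >= 0:
                    sp_at[(surf, r, c)] = int(grid.mol_species[m])
    for (surf, r, c), s in sp_at.items():
        zi = z[r, c]
        if zi < table.l_mol[s]:
            e_int += table.k_mol[s] * (zi - table.l_mol[s]) ** 2
        if surf == T_CELL:
            if table.coat_w[s] > 0 and abs(zi - table.coat_l[s]) < table.coat_w[s]:
                e_int += table.coat_U[s]
            if table.pll_w[s] > 0 and abs(zi - table.pll_l[s]) < table.pll_w[s]:
                e_int += table.pll_U[s]
            lg = table.pair_lig[s]
            if lg >= 0 and sp_at.get((APC_SURF, r, c)) == lg \
                    and abs(zi - table.pair_l[s]) < table.pair_w[s]:
                e_int += table.pair_U[s]
        # self-clustering: count right/down neighbours once per pair
        for dr, dc in ((1, 0), (0, 1)):
            if sp_at.get((surf, (r + dr) % R, (c + dc) % C)) == s:
                e_int += table.J_self[s]
    return e_int + e_el


def random_state(rng, scenario="aCD3", n=12):
    """Small randomized interface with all interaction classes active."""
    specs = ic.default_species_table(scenario)
    table = CompiledSpecies.compile(
        specs, coating="aCD3" if scenario == "aCD3" else None,
        pll_U=-2.0 if scenario == "PLL" else 0.0)
    grid = InterfaceGrid(n, n)
    for s, count in zip(range(table.n_species), (6, 8, 5, 5, 4, 4)):
        if s >= table.n_species:
            break
        surf = 0 if table.surface[s] == T_CELL else 1
        free = np.nonzero(grid.occ[surf].ravel() < 0)[0]
        pick = rng.choice(free, size=min(count, free.size), replace=False)
        grid.add_molecules(s, pick // n, pick % n, surf)
    grid.z += rng.normal(0, 8, grid.z.shape)
    grid.z = np.clip(grid.z, 1.0, None)
    grid.apply_pins(table)
    return grid, table


# ---------------------------------------------------------------------------
# single-pixel potentials
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("z,U,l,w,expect", [
    (13.0, -3.0, 13.0, 2.0, -3.0),   # inside the well
    (70.0, -3.0, 13.0, 2.0, 0.0),    # far outside
    (15.0, -3.0, 13.0, 2.0, 0.0),    # boundary excluded (strict <)
    (13.9, -3.0, 13.0, 1.0, 0.1 * 0 - 3.0),
])
def test_ligand_potential(z, U, l, w, expect):
    assert ligand_potential(z, U, l, w) == expect


@pytest.mark.parametrize("z,k,l,expect", [
    (40.0, 1.0, 40.0, 0.0),    # exactly at rest length: continuous 0
    (45.0, 1.0, 40.0, 0.0),    # taller gap: no compression
    (39.0, 1.0, 40.0, 1.0),
    (30.0, 0.5, 40.0, 50.0),
])
def test_repulsion_potential(z, k, l, expect):
    assert repulsion_potential(z, k, l) == pytest.approx(expect)


# ---------------------------------------------------------------------------
# full-grid terms
# ---------------------------------------------------------------------------

class TestElasticEnergy:
    def test_flat_field_vanishes(self):
        z = np.full((8, 8), 70.0)
        assert elastic_energy(z, 30.0, 10.0) == 0.0

    def test_single_pixel_bump(self):
        # bump of height h: center Laplacian 16 h^2, four neighbours h^2 each
        # -> kappa/(2 a^2) * 20 h^2 = 10 kappa h^2 / a^2
        kappa, a, h = 25.0, 10.0, 3.0
        z = np.full((8, 8), 70.0)
        z[4, 4] += h
        assert elastic_energy(z, kappa, a) == pytest.approx(10 * kappa * h * h / a ** 2)

    def test_matches_brute_force_on_sinusoid(self, rng):
        n = 8
        x = np.arange(n)
        z = 70 + 5 * np.sin(2 * np.pi * x[:, None] / n) * np.cos(2 * np.pi * x[None, :] / n)
        grid = InterfaceGrid(n, n)
        grid.z = z
        table = CompiledSpecies.compile([ic.SpeciesSpec("X", k_mol=0.0)])
        assert elastic_energy(z, 17.0, 10.0) == pytest.approx(
            brute_force_energy(grid, table, 17.0), abs=1e-9)

    def test_zero_mode_and_translation_invariance(self, rng):
        z = 70 + rng.normal(0, 3, (9, 7))
        e = elastic_energy(z, 30.0, 10.0)
        assert elastic_energy(z + 11.3, 30.0, 10.0) == pytest.approx(e)
        assert elastic_energy(np.roll(z, (2, 3), (0, 1)), 30.0, 10.0) == pytest.approx(e)


class TestInteractionEnergy:
    def test_empty_grid(self):
        grid = InterfaceGrid(6, 6)
        table = CompiledSpecies.compile(ic.default_species_table("aCD3"),
                                        coating="aCD3")
        assert interaction_energy(grid, table) == 0.0

    def test_uncompressed_unbound_molecule(self):
        table = CompiledSpecies.compile(ic.default_species_table("aCD3"),
                                        coating="aCD3")
        grid = InterfaceGrid(6, 6, z_init=41.0)  # CD45 length + 1
        grid.add_molecules(table.index("CD45"), [2], [2], 0)
        assert interaction_energy(grid, table) == 0.0

    def test_sum_of_single_pixel_terms(self):
        # one bound TCR (-3 kT) plus one CD45 compressed by 2 kT -> -1 kT
        specs = [
            ic.SpeciesSpec("TCR", ligand="aCD3", U_bind=-3.0, l_complex=13.0,
                           w_bind=2.0, l_mol=10.0, k_mol=2.0, D=0.0,
                           mobile=False, pinned_height=13.0),
            ic.SpeciesSpec("CD45", l_mol=40.0, k_mol=0.5, D=0.0, mobile=False),
        ]
        table = CompiledSpecies.compile(specs, coating="aCD3")
        grid = InterfaceGrid(6, 6, z_init=70.0)
        grid.add_molecules(0, [1], [1], 0)
        grid.add_molecules(1, [4], [4], 0)
        grid.z[1, 1] = 13.0
        grid.z[4, 4] = 38.0  # 0.5 * 2^2 = +2 kT
        assert interaction_energy(grid, table) == pytest.approx(-1.0)

    def test_additive_over_molecules(self, rng):
        grid, table = random_state(rng)
        total = interaction_energy(grid, table)
        assert total == pytest.approx(
            brute_force_energy(grid, table, 0.0), abs=1e-9)


class TestEnergyBreakdown:
    def test_total_is_exact_sum(self, rng):
        grid, table = random_state(rng)
        e = total_energy(grid, table, 30.0)
        assert e.H_total == e.H_int + e.H_el
        assert e.H_el >= 0.0


# ---------------------------------------------------------------------------
# locality of incremental energies
# ---------------------------------------------------------------------------

class TestHopLocality:
    def test_isolated_free_molecule_zero_delta(self):
        table = CompiledSpecies.compile([ic.SpeciesSpec("X", k_mol=0.0, D=100.0)])
        grid = InterfaceGrid(8, 8)
        grid.add_molecules(0, [4], [4], 0)
        dEl, dEe = ic.delta_energy_for_hop(grid, table, 30.0, 0, (4, 5))
        assert dEl == 0.0 and dEe == 0.0

    def test_contract_violations(self):
        table = CompiledSpecies.compile([ic.SpeciesSpec("X", k_mol=0.0, D=100.0)])
        grid = InterfaceGrid(8, 8)
        grid.add_molecules(0, [4, 4], [4, 5], 0)
        with pytest.raises(ValueError):
            ic.delta_energy_for_hop(grid, table, 30.0, 0, (4, 5))  # occupied
        with pytest.raises(ValueError):
            ic.delta_energy_for_hop(grid, table, 30.0, 0, (6, 6))  # not adjacent

    @pytest.mark.parametrize("scenario", ["aCD3", "PLL", "APC"])
    def test_localized_equals_full_recomputation(self, scenario, rng):
        """Incremental dE of any hop equals the brute-force full-grid
        difference, including the elastic change moved pins cause."""
        checked = 0
        while checked < 25:
            grid, table = random_state(rng, scenario=scenario)
            kappa = 22.0
            m = int(rng.integers(grid.n_molecules))
            r0, c0 = int(grid.mol_row[m]), int(grid.mol_col[m])
            surf = int(grid.mol_surface[m])
            dr, dc = [(-1, 0), (1, 0), (0, -1), (0, 1)][int(rng.integers(4))]
            r1, c1 = (r0 + dr) % grid.n_rows, (c0 + dc) % grid.n_cols
            if grid.occ[surf, r1, c1] >= 0:
                continue
            e0 = brute_force_energy(grid, table, kappa)
            dEl, dEe = ic.delta_energy_for_hop(grid, table, kappa, m, (r1, c1))
            grid.occ[surf, r0, c0] = -1
            grid.occ[surf, r1, c1] = m
            grid.mol_row[m], grid.mol_col[m] = r1, c1
            ph = table.pinned_h[grid.mol_species[m]]
            if not np.isnan(ph):
                grid.z[r1, c1] = ph  # vacated pixel keeps its last height
            e1 = brute_force_energy(grid, table, kappa)
            assert dEl + dEe == pytest.approx(e1 - e0, abs=1e-9)
            checked += 1
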