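"""Hamiltonian of the interface: H = H_int + H_el.

``H_int`` sums, over occupied pixels, the square ligand well of each
engaged molecule and its compressional repulsion against the opposing
surface, plus the nearest-neighbour self-clustering pair energies.
``H_el`` is the discrete bending energy of the separation field,
``sum_i kappa/(2 a^2) (Delta_d z_i)^2`` with the 5-point periodic
Laplacian ``Delta_d z_i = z_i1 + z_i2 + z_i3 + z_i4 - 4 z_i``.

All energies are in kT.  The full-grid evaluations here are vectorized
numpy; localized evaluations for proposed moves live in ``_kernels`` and
must agree with these to machine tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core import APC_SURF, CompiledSpecies, InterfaceGrid, T_CELL

__all__ = [
    "EnergyBreakdown",
    "ligand_potential",
    "repulsion_potential",
    "interaction_energy",
    "elastic_energy",
    "total_energy",
    "delta_energy_for_hop",
]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Interaction and elastic parts of the Hamiltonian, kT."""

    H_int: float
    H_el: float

    @property
    def H_total(self) -> float:
        return self.H_int + self.H_el


def ligand_potential(z_i, U_bind, l_complex, w_bind):
    """Square binding well: ``U_bind`` when ``|z_i - l_complex| < w_bind``
    (strict inequality; the boundary is outside the well), else 0."""
    z_i = np.asarray(z_i, dtype=float)
    out = np.where(np.abs(z_i - l_complex) < w_bind, float(U_bind), 0.0)
    return out if out.ndim else float(out)


def repulsion_potential(z_i, k_mol, l_mol):
    """Compressional spring: ``k_mol (z_i - l_mol)^2`` for ``z_i < l_mol``,
    else 0 (continuous at ``z_i = l_mol``)."""
    z_i = np.asarray(z_i, dtype=float)
    out = np.where(z_i < l_mol, k_mol * (z_i - l_mol) ** 2, 0.0)
    return out if out.ndim else float(out)


def _species_at_pixels(grid: InterfaceGrid, surf: int) -> np.ndarray:
    occ = grid.occ[surf]
    sp = np.full(occ.shape, -1, dtype=np.int64)
    occupied = occ >= 0
    if occupied.any():
        sp[occupied] = grid.mol_species[occ[occupied]]
    return sp

def interaction_energy(grid: InterfaceGrid, table: CompiledSpecies) -> float:
    """Full-grid H_int: wells + repulsion + self-clustering pairs (kT)."""
    z = grid.z
    sp_t = _species_at_pixels(grid, T_CELL)
    sp_a = _species_at_pixels(grid, APC_SURF)
    e = 0.0
    for s in range(table.n_species):
        on_t = table.surface[s] == T_CELL
        mask = (sp_t if on_t else sp_a) == s
        if not mask.any():
            continue
        zm = z[mask]
        e += float(np.sum(repulsion_potential(zm, table.k_mol[s], table.l_mol[s])))
        if on_t:
            if table.coat_w[s] > 0:
                e += float(np.sum(ligand_potential(
                    zm, table.coat_U[s], table.coat_l[s], table.coat_w[s])))
            if table.pll_w[s] > 0:
                e += float(np.sum(ligand_potential(
                    zm, table.pll_U[s], table.pll_l[s], table.pll_w[s])))
            lg = table.pair_lig[s]
            if lg >= 0:
                pair_mask = mask & (sp_a == lg)
                if pair_mask.any():
                    e += float(np.sum(ligand_potential(
                        z[pair_mask], table.pair_U[s], table.pair_l[s],
                        table.pair_w[s])))
        if table.J_self[s] != 0.0:
            # each unordered nearest-neighbour pair counted once (periodic)
            pairs = (np.sum(mask & np.roll(mask, 1, axis=0))
                     + np.sum(mask & np.roll(mask, 1, axis=1)))
            e += table.J_self[s] * float(pairs)
    return e


def elastic_energy(z: np.ndarray, kappa: float, a: float) -> float:
    """Discrete bending energy sum_i kappa/(2 a^2) (Delta_d z_i)^2 (kT)."""
    lap = (np.roll(z, 1, 0) + np.roll(z, -1, 0)
           + np.roll(z, 1, 1) + np.roll(z, -1, 1) - 4.0 * z)
    return float(kappa / (2.0 * a * a) * np.sum(lap * lap))


def total_energy(grid: InterfaceGrid, table: CompiledSpecies,
                 kappa: float) -> EnergyBreakdown:
    return EnergyBreakdown(
        H_int=interaction_energy(grid, table),
        H_el=elastic_energy(grid.z, kappa, grid.a),
    )


def delta_energy_for_hop(grid: InterfaceGrid, table: CompiledSpecies,
                         kappa: float, mol: int,
                         target_pixel: tuple[int, int]) -> tuple[float, float]:
    """Two-stage (dE_leave, dE_enter) for hopping molecule ``mol`` to one of
    the 4 neighbouring pixels.  Only terms touching the two pixels and their
    stencils are recomputed; equals the full-grid difference to machine
    tolerance (the vacated pixel retains its height, the target pixel of a
    pinned species jumps to the pinned height)."""
    r0, c0 = int(grid.mol_row[mol]), int(grid.mol_col[mol])
    r1, c1 = int(target_pixel[0]) % grid.n_rows, int(target_pixel[1]) % grid.n_cols
    dr = min((r1 - r0) % grid.n_rows, (r0 - r1) % grid.n_rows)
    dc = min((c1 - c0) % grid.n_cols, (c0 - c1) % grid.n_cols)
    if dr + dc != 1:
        raise ValueError("target must be one of the 4 nearest neighbours")
    surf = int(grid.mol_surface[mol])
    if grid.occ[surf, r1, c1] >= 0:
        raise ValueError("target pixel is occupied")
    if grid.n_rows < 3 or grid.n_cols < 3:
        raise ValueError("localized evaluation needs at least a 3x3 grid")
    dEl, dEe = _kernels.hop_delta(
        grid.z, grid.occ[T_CELL], grid.occ[APC_SURF], grid.mol_species,
        int(grid.mol_species[mol]), surf, r0, c0, r1, c1,
        table.l_mol, table.k_mol, table.coat_U, table.coat_l, table.coat_w,
        table.pll_U, table.pll_l, table.pll_w,
        table.pair_lig, table.pair_U, table.pair_l, table.pair_w,
        table.J_self, table.pinned_h, kappa, grid.a)
    return float(dEl), float(dEe)


def delta_energy_for_height_move(grid: InterfaceGrid, table: CompiledSpecies,
                                 kappa: float, pixel: tuple[int, int],
                                 dz: float) -> float:
    """Localized energy change of one height proposal ``z_i -> z_i + dz``:
    the elastic stencil of the pixel plus the z-dependent interaction terms
    of its occupants.  Equals the full-grid difference to machine tolerance."""
    r, c = int(pixel[0]) % grid.n_rows, int(pixel[1]) % grid.n_cols
    if grid.n_rows < 3 or grid.n_cols < 3:
        raise ValueError("localized evaluation needs at least a 3x3 grid")
    z0 = float(grid.z[r, c])
    z1 = z0 + dz
    dE = float(_kernels._elastic_delta(grid.z, r, c, z1, kappa, grid.a))
    st = sa = -1
    m = grid.occ[T_CELL, r, c]
    if m >= 0:
        st = int(grid.mol_species[m])
    m = grid.occ[APC_SURF, r, c]
    if m >= 0:
        sa = int(grid.mol_species[m])
    for zz, sign in ((z1, 1.0), (z0, -1.0)):
        dE += sign * _kernels._pix_energy(
            zz, st, sa, table.l_mol, table.k_mol,
            table.coat_U, table.coat_l, table.coat_w,
            table.pll_U, table.pll_l, table.pll_w,
            table.pair_lig, table.pair_U, table.pair_l, table.pair_w)
    return dE


def update_bound_flags(grid: InterfaceGrid, table: CompiledSpecies) -> None:
    """Recompute each molecule's bound flag from the current state.

    A molecule is bound when a compatible ligand exists at its pixel
    (uniform coat, non-specific PLL well, or a cross-gap partner at the
    same pixel column) and the separation lies inside the binding well.
    """
    z = grid.z[grid.mol_row, grid.mol_col]
    sp = grid.mol_species
    bound = np.zeros(grid.n_molecules, dtype=bool)
    coat_ok = table.coat_w[sp] > 0
    bound |= coat_ok & (np.abs(z - table.coat_l[sp]) < table.coat_w[sp])
    pll_ok = table.pll_w[sp] > 0
    bound |= pll_ok & (np.abs(z - table.pll_l[sp]) < table.pll_w[sp])
    # cross-gap pairs: T-cell molecule stores the well; both partners are bound
    sp_a = _species_at_pixels(grid, APC_SURF)
    on_t = grid.mol_surface == T_CELL
    lg = table.pair_lig[sp]
    has_pair = on_t & (lg >= 0)
    if has_pair.any():
        idx = np.nonzero(has_pair)[0]
        partner = sp_a[grid.mol_row[idx], grid.mol_col[idx]]
        engaged = (partner == lg[idx]) & (
            np.abs(z[idx] - table.pair_l[sp[idx]]) < table.pair_w[sp[idx]])
        bound[idx] |= engaged
        # mirror onto the APC partner molecules
        eng_idx = idx[engaged]
        if eng_idx.size:
            partners = grid.occ[APC_SURF][grid.mol_row[eng_idx], grid.mol_col[eng_idx]]
            bound[partners] = True
    grid.mol_bound = bound
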