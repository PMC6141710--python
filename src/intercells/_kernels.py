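"""Numba kernels for localized energy evaluation and the height sweep.

Everything here operates on the flat arrays held by ``InterfaceGrid`` and
``CompiledSpecies``.  The localized energy differences computed here must
agree with a full-grid recomputation to machine tolerance; that contract
is enforced by the test suite against an independent brute-force oracle.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _repulsion(z, l_mol, k_mol):
    if z < l_mol:
        d = z - l_mol
        return k_mol * d * d
    return 0.0


@njit(cache=True)
def _pix_energy(z, st, sa,
                l_mol, k_mol, coat_U, coat_l, coat_w,
                pll_U, pll_l, pll_w,
                pair_lig, pair_U, pair_l, pair_w):
    """Interaction energy contributed by the occupants of one pixel.

    st / sa: species index on the T-cell / APC surface (-1 = empty).
    Cross-gap pair wells are attributed to the T-cell occupant.
    """
    e = 0.0
    if st >= 0:
        e += _repulsion(z, l_mol[st], k_mol[st])
        if coat_w[st] > 0.0 and abs(z - coat_l[st]) < coat_w[st]:
            e += coat_U[st]
        if pll_w[st] > 0.0 and abs(z - pll_l[st]) < pll_w[st]:
            e += pll_U[st]
        lg = pair_lig[st]
        if lg >= 0 and sa == lg and abs(z - pair_l[st]) < pair_w[st]:
            e += pair_U[st]
    if sa >= 0:
        e += _repulsion(z, l_mol[sa], k_mol[sa])
    return e


@njit(cache=True)
def _sp_at(occ, mol_species, r, c):
    m = occ[r, c]
    if m >= 0:
        return mol_species[m]
    return -1


@njit(cache=True)
def _laplacian(z, r, c):
    R, C = z.shape
    return (z[(r - 1) % R, c] + z[(r + 1) % R, c]
            + z[r, (c - 1) % C] + z[r, (c + 1) % C] - 4.0 * z[r, c])


@njit(cache=True, inline="always")
def _elastic_delta(z, r, c, z_new, kappa, a):
    """Elastic energy change from setting z[r, c] = z_new.

    Only the Laplacians of (r, c) and its 4 nearest neighbours change;
    with grids of at least 3x3 (enforced by the engine) the five stencil
    pixels are distinct and (r, c) enters each neighbour's Laplacian
    exactly once.
    """
    R, C = z.shape
    d = z_new - z[r, c]
    rm, rp = (r - 1) % R, (r + 1) % R
    cm, cp = (c - 1) % C, (c + 1) % C
    lc = z[rm, c] + z[rp, c] + z[r, cm] + z[r, cp] - 4.0 * z[r, c]
    tot = d * (16.0 * d - 8.0 * lc)  # (lc - 4d)^2 - lc^2
    ln = _laplacian(z, rm, c)
    tot += d * (2.0 * ln + d)
    ln = _laplacian(z, rp, c)
    tot += d * (2.0 * ln + d)
    ln = _laplacian(z, r, cm)
    tot += d * (2.0 * ln + d)
    ln = _laplacian(z, r, cp)
    tot += d * (2.0 * ln + d)
    return kappa / (2.0 * a * a) * tot


@njit(cache=True)
def _same_species_neighbours(occ, mol_species, r, c, sp, skip_r, skip_c):
    """Count same-species nearest neighbours of (r, c) on one surface,
    skipping pixel (skip_r, skip_c) (pass -1, -1 to skip none)."""
    R, C = occ.shape
    n = 0
    for k in range(4):
        if k == 0:
            rr, cc = (r - 1) % R, c
        elif k == 1:
            rr, cc = (r + 1) % R, c
        elif k == 2:
            rr, cc = r, (c - 1) % C
        else:
            rr, cc = r, (c + 1) % C
        if rr == skip_r and cc == skip_c:
            continue
        m = occ[rr, cc]
        if m >= 0 and mol_species[m] == sp:
            n += 1
    return n


@njit(cache=True)
def hop_delta(z, occ_t, occ_a, mol_species, sp, surf, r0, c0, r1, c1,
              l_mol, k_mol, coat_U, coat_l, coat_w,
              pll_U, pll_l, pll_w,
              pair_lig, pair_U, pair_l, pair_w,
              J_self, pinned_h, kappa, a):
    """Two-stage energy difference for hopping one molecule.

    Returns (dE_leave, dE_enter):
      dE_leave = E(after vacating the old pixel) - E(before); the vacated
                 pixel retains its height, so only interaction and
                 self-clustering terms appear.
      dE_enter = E(after occupying the target) - E(vacated state); for
                 pinned species the target pixel's height jumps to the
                 pinned height, which also changes the elastic energy.
    """
    occ = occ_t if surf == 0 else occ_a
    # --- leave ---
    z0 = z[r0, c0]
    st = _sp_at(occ_t, mol_species, r0, c0)
    sa = _sp_at(occ_a, mol_species, r0, c0)
    e_with = _pix_energy(z0, st, sa, l_mol, k_mol, coat_U, coat_l, coat_w,
                         pll_U, pll_l, pll_w, pair_lig, pair_U, pair_l, pair_w)
    if surf == 0:
        st_n, sa_n = -1, sa
    else:
        st_n, sa_n = st, -1
    e_without = _pix_energy(z0, st_n, sa_n, l_mol, k_mol, coat_U, coat_l, coat_w,
                            pll_U, pll_l, pll_w, pair_lig, pair_U, pair_l, pair_w)
    nJ0 = _same_species_neighbours(occ, mol_species, r0, c0, sp, -1, -1)
    dE_leave = e_without - e_with - J_self[sp] * nJ0

    # --- enter ---
    z1_old = z[r1, c1]
    ph = pinned_h[sp]
    z1_new = ph if not np.isnan(ph) else z1_old
    st1 = _sp_at(occ_t, mol_species, r1, c1)
    sa1 = _sp_at(occ_a, mol_species, r1, c1)
    e_before = _pix_energy(z1_old, st1, sa1, l_mol, k_mol, coat_U, coat_l, coat_w,
                           pll_U, pll_l, pll_w, pair_lig, pair_U, pair_l, pair_w)
    if surf == 0:
        st1_n, sa1_n = sp, sa1
    else:
        st1_n, sa1_n = st1, sp
    e_after = _pix_energy(z1_new, st1_n, sa1_n, l_mol, k_mol, coat_U, coat_l, coat_w,
                          pll_U, pll_l, pll_w, pair_lig, pair_U, pair_l, pair_w)
    nJ1 = _same_species_neighbours(occ, mol_species, r1, c1, sp, r0, c0)
    dE_enter = e_after - e_before + J_self[sp] * nJ1
    if z1_new != z1_old:
        dE_enter += _elastic_delta(z, r1, c1, z1_new, kappa, a)
    return dE_leave, dE_enter


@njit(cache=True)
def hop_delta_batch(z, occ_t, occ_a, mol_species, sps, surfs, r0s, c0s, r1s, c1s,
                    l_mol, k_mol, coat_U, coat_l, coat_w,
                    pll_U, pll_l, pll_w,
                    pair_lig, pair_U, pair_l, pair_w,
                    J_self, pinned_h, kappa, a):
    n = sps.size
    dEl = np.empty(n, np.float64)
    dEe = np.empty(n, np.float64)
    for i in range(n):
        dEl[i], dEe[i] = hop_delta(
            z, occ_t, occ_a, mol_species, sps[i], surfs[i],
            r0s[i], c0s[i], r1s[i], c1s[i],
            l_mol, k_mol, coat_U, coat_l, coat_w,
            pll_U, pll_l, pll_w, pair_lig, pair_U, pair_l, pair_w,
            J_self, pinned_h, kappa, a)
    return dEl, dEe


@njit(cache=True)
def height_sweep(z, occ_t, occ_a, mol_species, pinned_sp,
                 l_mol, k_mol, coat_U, coat_l, coat_w,
                 pll_U, pll_l, pll_w,
                 pair_lig, pair_U, pair_l, pair_w,
                 kappa, a, order, dz, u):
    """One Metropolis sweep of height moves, sequential in the given order.

    ``order`` is a permutation of flat pixel indices; ``dz`` the proposed
    Gaussian displacements; ``u`` uniform accept draws.  Pinned pixels are
    skipped entirely (not counted as attempts); proposals that would make
    the separation non-positive are attempts that are always rejected.
    Returns (attempts, accepts); mutates z in place.
    """
    R, C = z.shape
    attempts = 0
    accepts = 0
    for k in range(order.size):
        idx = order[k]
        r = idx // C
        c = idx % C
        st = _sp_at(occ_t, mol_species, r, c)
        sa = _sp_at(occ_a, mol_species, r, c)
        if (st >= 0 and pinned_sp[st]) or (sa >= 0 and pinned_sp[sa]):
            continue
        attempts += 1
        z0 = z[r, c]
        z1 = z0 + dz[k]
        if z1 <= 0.0:
            continue
        dE = _elastic_delta(z, r, c, z1, kappa, a)
        if st >= 0 or sa >= 0:
            dE += (_pix_energy(z1, st, sa, l_mol, k_mol, coat_U, coat_l, coat_w,
                               pll_U, pll_l, pll_w, pair_lig, pair_U, pair_l, pair_w)
                   - _pix_energy(z0, st, sa, l_mol, k_mol, coat_U, coat_l, coat_w,
                                 pll_U, pll_l, pll_w, pair_lig, pair_U, pair_l, pair_w))
        if dE <= 0.0 or u[k] < np.exp(-dE):
            z[r, c] = z1
            accepts += 1
    return attempts, accepts
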