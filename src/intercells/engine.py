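"""Monte-Carlo propagation of the interface.

One iteration (0.01 s of cell time at defaults):

1. every mobile molecule attempts, with probability ``4 D dt / a^2``, a
   hop to one of its 4 nearest neighbours (uniformly chosen, or with a
   centripetal bias when translocation is active);
2. attempts onto occupied pixels are rejected outright; the rest are
   accepted with the two-stage Metropolis product
   ``P(old -> free) * P(free -> new)``;
3. among accepted attempts colliding on one target pixel, the molecule
   with the highest energy gain moves (seeded tie-break);
4. moves are applied synchronously and the separation field is re-pinned
   at the new pixels of pinned-height species (vacated pixels retain
   their last height and resume fluctuating);
5. every unpinned pixel receives one Gaussian height proposal
   ``dz ~ N(0, sigma_z^2)``, accepted by the Metropolis criterion on the
   local energy change, evaluated sequentially in random order.

All randomness flows from a single ``numpy.random.Generator``, so a run
is bit-reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .core import (APC_SURF, CompiledSpecies, ConfigurationError, InterfaceGrid,
                   MembraneSpec, SimConfig, T_CELL, TranslocationSpec)
from .energetics import EnergyBreakdown, total_energy, update_bound_flags

__all__ = [
    "metropolis_probability",
    "hop_acceptance",
    "hop_attempt_probability",
    "apply_translocation_bias",
    "ProposalBatch",
    "propose_hops",
    "resolve_contention",
    "update_heights",
    "StepReport",
    "Snapshot",
    "Trajectory",
    "Simulation",
]

# neighbour order: row-1, row+1, col-1, col+1
_DIR_DR = np.array([-1, 1, 0, 0])
_DIR_DC = np.array([0, 0, -1, 1])
# unit displacement of each direction in (x, y); y grows with row index
_DIR_XY = np.array([[0.0, -1.0], [0.0, 1.0], [-1.0, 0.0], [1.0, 0.0]])


def metropolis_probability(dE):
    """Metropolis acceptance: 1 for dE <= 0, exp(-dE) otherwise (dE in kT)."""
    dE = np.asarray(dE, dtype=float)
    out = np.where(dE <= 0.0, 1.0, np.exp(-np.clip(dE, 0.0, 700.0)))
    return out if out.ndim else float(out)


def hop_acceptance(dE_leave, dE_enter):
    """Two-stage acceptance P(old->free) * P(free->new)."""
    return metropolis_probability(dE_leave) * metropolis_probability(dE_enter)


def hop_attempt_probability(D: float, dt: float, a: float) -> float:
    """Per-iteration attempt probability 4 D dt / a^2, so accepted free hops
    reproduce the 2D diffusion law MSD = 4 D t."""
    p = 4.0 * D * dt / (a * a)
    if p > 1.0:
        raise ConfigurationError(
            f"hop attempt probability 4*D*dt/a^2 = {p:.3g} > 1; "
            "reduce dt or the diffusion coefficient")
    return p


def apply_translocation_bias(pos_rc: np.ndarray, target_rc: tuple[int, int],
                             speed: float, dt: float, a: float,
                             p_attempt: float, shape: tuple[int, int]) -> np.ndarray:
    """Neighbour-choice weights giving a mean centripetal drift of speed*dt.

    For each molecule the four weights are ``1/4 + b/2 * (e_k . u)`` with
    ``u`` the unit vector toward the target (shortest periodic displacement)
    and ``b = speed*dt / (p_attempt * a)``; the expected displacement per
    iteration is then ``p_attempt * a * b * u = speed*dt * u``, superposed
    on unbiased diffusion.  Molecules within one pixel of the target get
    uniform weights.
    """
    R, C = shape
    n = pos_rc.shape[0]
    w = np.full((n, 4), 0.25)
    if speed == 0.0 or n == 0:
        return w
    if p_attempt <= 0.0:
        raise ConfigurationError("translocation requires a mobile species")
    b = speed * dt / (p_attempt * a)
    if b > 0.5:
        raise ConfigurationError(
            f"translocation bias {b:.3g} > 0.5 makes neighbour weights "
            "negative; reduce speed or dt, or increase D")
    dy = ((target_rc[0] - pos_rc[:, 0] + R / 2) % R - R / 2) * a
    dx = ((target_rc[1] - pos_rc[:, 1] + C / 2) % C - C / 2) * a
    dist = np.hypot(dx, dy)
    far = dist > a
    ux = np.where(far, dx / np.where(dist == 0, 1.0, dist), 0.0)
    uy = np.where(far, dy / np.where(dist == 0, 1.0, dist), 0.0)
    w += 0.5 * b * (ux[:, None] * _DIR_XY[None, :, 0]
                    + uy[:, None] * _DIR_XY[None, :, 1])
    return w


@dataclass
class ProposalBatch:
    """Synchronous hop proposals of one iteration (array-of-columns)."""

    mol: np.ndarray        # molecule ids
    surface: np.ndarray
    src_r: np.ndarray
    src_c: np.ndarray
    dst_r: np.ndarray
    dst_c: np.ndarray
    dE_leave: np.ndarray
    dE_enter: np.ndarray
    n_attempted: int = 0   # attempts incl. rule-1 rejections
    attempts_by_species: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return self.mol.size

    @property
    def gain(self) -> np.ndarray:
        """Total energy decrease of each proposal (positive = downhill)."""
        return -(self.dE_leave + self.dE_enter)


def propose_hops(grid: InterfaceGrid, table: CompiledSpecies, kappa: float,
                 dt: float, rng: np.random.Generator,
                 translocation: Optional[TranslocationSpec] = None) -> ProposalBatch:
    """Draw this iteration's hop attempts and their energy differences.

    Each mobile molecule independently attempts with probability
    ``4 D dt / a^2``; attempts whose target pixel is occupied (on the
    molecule's own surface) are dropped here (rule 1) but still counted
    as attempts.
    """
    a = grid.a
    p_sp = np.array([hop_attempt_probability(d, dt, a) if m else 0.0
                     for d, m in zip(table.D, table.mobile)])
    p_mol = p_sp[grid.mol_species]
    attempt = rng.random(grid.n_molecules) < p_mol
    idx = np.nonzero(attempt)[0]
    attempts_by_species = np.bincount(grid.mol_species[idx],
                                      minlength=table.n_species)
    n_att = idx.size
    if n_att == 0:
        e = np.empty(0)
        ei = np.empty(0, np.int64)
        return ProposalBatch(ei, ei, ei, ei, ei, ei, e, e, 0, attempts_by_species)

    # neighbour choice
    if translocation is not None and translocation.speed != 0.0:
        target = translocation.target or (grid.n_rows // 2, grid.n_cols // 2)
        weights = np.full((n_att, 4), 0.25)
        for name in translocation.species:
            s = table.index(name)
            biased = grid.mol_species[idx] == s
            if biased.any():
                bi = idx[biased]
                pos = np.column_stack([grid.mol_row[bi], grid.mol_col[bi]])
                weights[biased] = apply_translocation_bias(
                    pos, target, translocation.speed, dt, a, float(p_sp[s]),
                    (grid.n_rows, grid.n_cols))
        u = rng.random(n_att)
        dirs = (u[:, None] > np.cumsum(weights, axis=1)).sum(axis=1)
        dirs = np.clip(dirs, 0, 3)
    else:
        dirs = rng.integers(0, 4, size=n_att)

    dst_r = (grid.mol_row[idx] + _DIR_DR[dirs]) % grid.n_rows
    dst_c = (grid.mol_col[idx] + _DIR_DC[dirs]) % grid.n_cols
    surf = grid.mol_surface[idx]
    free = grid.occ[surf, dst_r, dst_c] < 0  # rule 1
    idx, dst_r, dst_c, surf = idx[free], dst_r[free], dst_c[free], surf[free]

    dEl, dEe = _kernels.hop_delta_batch(
        grid.z, grid.occ[T_CELL], grid.occ[APC_SURF], grid.mol_species,
        grid.mol_species[idx], surf.astype(np.int64),
        grid.mol_row[idx].astype(np.int64), grid.mol_col[idx].astype(np.int64),
        dst_r.astype(np.int64), dst_c.astype(np.int64),
        table.l_mol, table.k_mol, table.coat_U, table.coat_l, table.coat_w,
        table.pll_U, table.pll_l, table.pll_w,
        table.pair_lig, table.pair_U, table.pair_l, table.pair_w,
        table.J_self, table.pinned_h, kappa, a)
    return ProposalBatch(idx, surf, grid.mol_row[idx].copy(),
                         grid.mol_col[idx].copy(), dst_r, dst_c, dEl, dEe,
                         n_att, attempts_by_species)


def resolve_contention(batch: ProposalBatch, accepted: np.ndarray,
                       grid_shape: tuple[int, int],
                       rng: np.random.Generator) -> np.ndarray:
    """Indices (into the batch) of the proposals that actually move.

    Among individually accepted proposals colliding on one target pixel,
    the one with the largest total energy decrease wins; exact ties are
    broken by the seeded RNG.
    """
    sel = np.nonzero(accepted)[0]
    if sel.size == 0:
        return sel
    R, C = grid_shape
    key = (batch.surface[sel].astype(np.int64) * R * C
           + batch.dst_r[sel].astype(np.int64) * C + batch.dst_c[sel])
    gain = batch.gain[sel]
    tie = rng.random(sel.size)
    order = np.lexsort((tie, -gain, key))
    key_sorted = key[order]
    first = np.ones(sel.size, dtype=bool)
    first[1:] = key_sorted[1:] != key_sorted[:-1]
    return sel[order[first]]


def update_heights(grid: InterfaceGrid, table: CompiledSpecies, kappa: float,
                   sigma_z: float, rng: np.random.Generator) -> tuple[int, int]:
    """One sweep of Gaussian height proposals; returns (attempts, accepts).

    Every unpinned pixel receives one proposal ``dz ~ N(0, sigma_z^2)``,
    evaluated sequentially in random order against the current field and
    accepted by the Metropolis criterion; moves to non-positive separation
    are rejected.  Pinned pixels are skipped.
    """
    if sigma_z == 0.0:
        return 0, 0
    n_pix = grid.n_rows * grid.n_cols
    order = rng.permutation(n_pix)
    dz = rng.normal(0.0, sigma_z, n_pix)
    u = rng.random(n_pix)
    pinned_sp = ~np.isnan(table.pinned_h)
    att, acc = _kernels.height_sweep(
        grid.z, grid.occ[T_CELL], grid.occ[APC_SURF], grid.mol_species,
        pinned_sp, table.l_mol, table.k_mol,
        table.coat_U, table.coat_l, table.coat_w,
        table.pll_U, table.pll_l, table.pll_w,
        table.pair_lig, table.pair_U, table.pair_l, table.pair_w,
        kappa, grid.a, order, dz, u)
    return int(att), int(acc)


@dataclass
class StepReport:
    """Per-iteration acceptance statistics (and energies at snapshot steps)."""

    iteration: int
    hop_attempts: np.ndarray      # per species
    hop_accepted: np.ndarray      # per species (moves actually applied)
    height_attempts: int
    height_accepted: int
    energy: Optional[EnergyBreakdown] = None

    @property
    def height_acceptance(self) -> float:
        return self.height_accepted / self.height_attempts if self.height_attempts else math.nan


@dataclass
class Snapshot:
    iteration: int
    time_s: float
    z: np.ndarray
    molecules: pd.DataFrame  # id, species, surface, x_nm, y_nm, bound


@dataclass
class Trajectory:
    """Time-ordered snapshots plus the per-iteration acceptance log."""

    snapshots: list[Snapshot] = field(default_factory=list)
    reports: list[StepReport] = field(default_factory=list)

    @property
    def total_time(self) -> float:
        return self.snapshots[-1].time_s if self.snapshots else 0.0

    def height_acceptance(self, start: int = 0, stop: Optional[int] = None) -> float:
        """Fraction of accepted membrane height moves over iterations
        [start, stop) of the log."""
        reps = self.reports[start:stop]
        att = sum(r.height_attempts for r in reps)
        acc = sum(r.height_accepted for r in reps)
        return acc / att if att else math.nan


class Simulation:
    """Bound state of one run: grid + species table + membrane + config."""

    def __init__(self, grid: InterfaceGrid, table: CompiledSpecies,
                 membrane: MembraneSpec, config: SimConfig,
                 rng: Optional[np.random.Generator] = None):
        self.grid = grid
        self.table = table
        self.membrane = membrane
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.iteration = 0
        if grid.n_rows < 3 or grid.n_cols < 3:
            raise ConfigurationError(
                "dynamics needs at least a 3x3 grid (distinct Laplacian stencil)")
        # validate attempt probabilities up front
        for D, m in zip(table.D, table.mobile):
            if m:
                hop_attempt_probability(D, config.dt, grid.a)
        if config.translocation is not None:
            for name in config.translocation.species:
                table.index(name)  # raises if unknown
        grid.apply_pins(table)
        update_bound_flags(grid, table)

    @property
    def kappa(self) -> float:
        return self.membrane.kappa

    def step(self, with_energy: bool = False) -> StepReport:
        """Advance one iteration; returns the acceptance report."""
        grid, table, cfg = self.grid, self.table, self.config
        batch = propose_hops(grid, table, self.kappa, cfg.dt, self.rng,
                             cfg.translocation)
        if len(batch):
            p_acc = hop_acceptance(batch.dE_leave, batch.dE_enter)
            accepted = self.rng.random(len(batch)) < p_acc
            winners = resolve_contention(batch, accepted,
                                         (grid.n_rows, grid.n_cols), self.rng)
        else:
            winners = np.empty(0, np.int64)
        acc_by_species = np.zeros(table.n_species, dtype=np.int64)
        if winners.size:
            mols = batch.mol[winners]
            acc_by_species = np.bincount(grid.mol_species[mols],
                                         minlength=table.n_species)
            # synchronous application: clear all sources, then set targets
            grid.occ[batch.surface[winners], batch.src_r[winners],
                     batch.src_c[winners]] = -1
            grid.occ[batch.surface[winners], batch.dst_r[winners],
                     batch.dst_c[winners]] = mols
            grid.mol_row[mols] = batch.dst_r[winners]
            grid.mol_col[mols] = batch.dst_c[winners]
            # re-pin heights at the new pixels of pinned species
            ph = table.pinned_h[grid.mol_species[mols]]
            pin = ~np.isnan(ph)
            if pin.any():
                grid.z[batch.dst_r[winners][pin], batch.dst_c[winners][pin]] = ph[pin]
        h_att, h_acc = update_heights(grid, table, self.kappa,
                                      self.membrane.sigma_z, self.rng)
        update_bound_flags(grid, table)
        self.iteration += 1
        report = StepReport(
            iteration=self.iteration,
            hop_attempts=batch.attempts_by_species,
            hop_accepted=acc_by_species,
            height_attempts=h_att,
            height_accepted=h_acc,
            energy=total_energy(grid, table, self.kappa) if with_energy else None,
        )
        return report

    def snapshot(self) -> Snapshot:
        surf_names = np.array(["t_cell", "apc"])
        df = pd.DataFrame({
            "id": np.arange(self.grid.n_molecules),
            "species": [self.table.names[s] for s in self.grid.mol_species],
            "surface": surf_names[self.grid.mol_surface],
            "x_nm": (self.grid.mol_col + 0.5) * self.grid.a,
            "y_nm": (self.grid.mol_row + 0.5) * self.grid.a,
            "bound": self.grid.mol_bound,
        })
        return Snapshot(self.iteration, self.iteration * self.config.dt,
                        self.grid.z.copy(), df)

    def run(self, check_invariants: bool = False) -> Trajectory:
        """Execute ``config.n_steps`` iterations, snapshotting every
        ``config.save_every`` (plus the initial state)."""
        cfg = self.config
        traj = Trajectory()
        counts0 = self.grid.species_counts(self.table)
        traj.snapshots.append(self.snapshot())
        for _ in range(cfg.n_steps):
            save = ((self.iteration + 1) % cfg.save_every == 0
                    or self.iteration + 1 == cfg.n_steps)
            report = self.step(with_energy=save)
            traj.reports.append(report)
            if save:
                traj.snapshots.append(self.snapshot())
                if check_invariants:
                    self.grid.check_consistency()
                    if self.grid.species_counts(self.table) != counts0:
                        raise AssertionError("species counts not conserved")
        return traj
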