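"""Domain types and the lattice/occupancy data model.

The interface between two cells (or a cell and a functionalized coverslip)
is discretized on a periodic square lattice of 10 nm pixels.  Each pixel
carries the local inter-surface separation ``z_i`` (nm) and, per surface,
at most one membrane molecule.  Molecular species are described by a small
set of physical parameters: an uncompressed length and a compressional
stiffness (the molecule acts as a repulsive spring when the gap closes
below its length), an optional ligand with a square binding well, a
diffusion coefficient, and an optional nearest-neighbour self-clustering
energy.  All energies are expressed in units of kT, so Metropolis
acceptance uses ``exp(-dE)`` with no explicit temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SpeciesSpec",
    "MembraneSpec",
    "SimConfig",
    "TranslocationSpec",
    "MoleculeState",
    "InterfaceGrid",
    "CompiledSpecies",
    "ConfigurationError",
    "CapacityError",
    "kappa_eff",
    "default_species_table",
    "max_capacity",
    "SCENARIOS",
]

SCENARIOS = ("PLL", "aCD3", "APC")

#: surface codes
T_CELL = 0
APC_SURF = 1
SUBSTRATE = 2

_SURFACE_CODES = {"t_cell": T_CELL, "apc": APC_SURF, "substrate": SUBSTRATE}


class ConfigurationError(ValueError):
    """Raised for physically or structurally invalid configuration."""


class CapacityError(ConfigurationError):
    """Raised when a placement would exceed the single-occupancy capacity."""


@dataclass
class SpeciesSpec:
    """Physical parameters of one molecular species.

    Parameters
    ----------
    name:
        Text label, e.g. ``"TCR"``.
    surface:
        ``"t_cell"``, ``"apc"`` or ``"substrate"``.
    l_mol:
        Uncompressed molecular length, nm.  When the local separation drops
        below ``l_mol`` the molecule is compressed and pays
        ``k_mol * (z - l_mol)**2`` kT.
    k_mol:
        Compressional stiffness, kT/nm^2.
    ligand:
        Name of the partner species (on the opposite surface) or of a
        substrate coating (``"aCD3"``); ``None`` for purely repulsive
        species such as CD45.
    U_bind:
        Depth of the ligand binding well, kT (negative = attractive).
    l_complex:
        Length of the engaged molecule--ligand complex, nm (the centre of
        the binding well on the separation axis).
    w_bind:
        Half-width of the binding well ("interaction range"), nm.  The well
        is active when ``|z - l_complex| < w_bind`` (strict inequality).
    D:
        Diffusion coefficient, nm^2/s.  Immobile species have ``D = 0``.
    J_self:
        Nearest-neighbour same-species pair energy, kT (0 disables
        self-clustering; negative favours it).
    mobile:
        Whether the species attempts diffusive hops at all.
    pinned_height:
        If set, pixels occupied by this species hold the separation field
        at exactly this value (nm) -- the engaged heights of TCR (13 nm)
        and CD11 (35 nm).
    """

    name: str
    surface: str = "t_cell"
    l_mol: float = 10.0
    k_mol: float = 1.0
    ligand: Optional[str] = None
    U_bind: float = 0.0
    l_complex: float = 0.0
    w_bind: float = 2.0
    D: float = 0.0
    J_self: float = 0.0
    mobile: bool = True
    pinned_height: Optional[float] = None

    def __post_init__(self) -> None:
        if self.l_mol <= 0:
            raise ConfigurationError(f"{self.name}: l_mol must be > 0")
        if self.ligand is not None and self.w_bind <= 0:
            raise ConfigurationError(f"{self.name}: w_bind must be > 0 when a ligand is set")
        if self.D < 0:
            raise ConfigurationError(f"{self.name}: D must be >= 0")
        if not self.mobile and self.D != 0:
            raise ConfigurationError(f"{self.name}: immobile species must have D = 0")
        if self.surface not in _SURFACE_CODES:
            raise ConfigurationError(f"{self.name}: unknown surface {self.surface!r}")

    @property
    def surface_code(self) -> int:
        return _SURFACE_CODES[self.surface]


def kappa_eff(kappa1: float, kappa2: float) -> float:
    """Effective bending rigidity kappa1*kappa2/(kappa1+kappa2) of two stacked
    membranes (series combination); a rigid substrate (kappa2 = inf) leaves
    kappa1 unchanged."""
    if kappa1 <= 0 or kappa2 <= 0:
        raise ConfigurationError("bending rigidities must be positive")
    if math.isinf(kappa1) and math.isinf(kappa2):
        raise ConfigurationError("at least one surface must have finite rigidity")
    if math.isinf(kappa1):
        return kappa2
    if math.isinf(kappa2):
        return kappa1
    return kappa1 * kappa2 / (kappa1 + kappa2)


@dataclass
class MembraneSpec:
    """Mechanical parameters of the separation field.

    ``kappa1`` is the T-cell membrane rigidity; ``kappa2`` the opposing
    surface (infinite for a coverslip).  The field is propagated with the
    effective rigidity ``kappa1*kappa2/(kappa1+kappa2)``.
    """

    kappa1: float = 30.0
    kappa2: float = math.inf
    z_init: float = 70.0
    sigma_z: float = 1.0

    @property
    def kappa(self) -> float:
        return kappa_eff(self.kappa1, self.kappa2)


@dataclass
class TranslocationSpec:
    """Centripetal translocation of selected species at constant speed."""

    species: Sequence[str] = ("TCR",)
    speed: float = 19.0  # nm/s
    target: Optional[tuple[int, int]] = None  # (row, col); grid centre if None


@dataclass
class SimConfig:
    """Run-level parameters.

    ``n_steps * dt`` is the total simulated cell time; the defaults
    (10,000 iterations of 0.01 s) give 100 s.
    """

    n_steps: int = 10_000
    dt: float = 0.01
    seed: int = 0
    save_every: int = 1000
    scenario: str = "aCD3"
    pll_U: float = 0.0
    pll_w: float = 5.0
    cognate_fraction: float = 1.0
    translocation: Optional[TranslocationSpec] = None
    pin_mode: str = "always"  # or "when_bound"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; valid: {SCENARIOS}")
        if self.n_steps <= 0 or self.dt <= 0:
            raise ConfigurationError("n_steps and dt must be positive")
        if not (0.0 <= self.cognate_fraction <= 1.0):
            raise ConfigurationError("cognate_fraction must lie in [0, 1]")
        if self.pin_mode not in ("always", "when_bound"):
            raise ConfigurationError("pin_mode must be 'always' or 'when_bound'")

    @property
    def total_time(self) -> float:
        return self.n_steps * self.dt


@dataclass
class MoleculeState:
    """Read-only view of one molecule's state at an instant."""

    id: int
    species: str
    pixel: tuple[int, int]
    surface: str
    bound: bool


# ---------------------------------------------------------------------------
# default parameter table
# ---------------------------------------------------------------------------

#: Documented, implementation-chosen defaults.  Engaged complex lengths
#: (TCR 13 nm, CD11/ICAM 35 nm) and the 10 nm lattice are fixed by the
#: model; well depths, stiffnesses and diffusion coefficients are defaults
#: chosen to be physically plausible and are overridable from configuration.
#: D is capped by the hop rule 4*D*dt/a^2 <= 1 (D <= 2500 nm^2/s at the
#: default dt = 0.01 s, a = 10 nm).
_DEFAULTS = dict(
    TCR=dict(l_mol=10.0, k_mol=2.0, U_bind=-8.0, l_complex=13.0, w_bind=2.0,
             D=1250.0, J_self=-2.0, pinned_height=13.0),
    CD45=dict(l_mol=40.0, k_mol=0.5, D=1250.0, J_self=0.0),
    CD11=dict(l_mol=20.0, k_mol=2.0, U_bind=-6.0, l_complex=35.0, w_bind=2.0,
              D=1250.0, J_self=-2.0, pinned_height=35.0),
    pMHC=dict(l_mol=7.0, k_mol=2.0, D=1250.0),
    ICAM=dict(l_mol=19.0, k_mol=2.0, D=1250.0),
)


def default_species_table(scenario: str) -> list[SpeciesSpec]:
    """Documented default species for a scenario.

    * ``PLL``  -- TCR, CD45, CD11 on the T-cell membrane; no specific
      ligand layer (the non-specific PLL well is configured separately
      via ``SimConfig.pll_U``).
    * ``aCD3`` -- as PLL, but TCR binds the uniform immobile aCD3 coat.
    * ``APC``  -- adds mobile pMHC and ICAM on the second surface; TCR
      binds (cognate) pMHC and CD11 binds ICAM across the gap.
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}; valid: {SCENARIOS}")
    tcr = SpeciesSpec("TCR", "t_cell", **_DEFAULTS["TCR"])
    cd45 = SpeciesSpec("CD45", "t_cell", **_DEFAULTS["CD45"])
    cd11 = SpeciesSpec("CD11", "t_cell", **_DEFAULTS["CD11"])
    if scenario == "PLL":
        return [tcr, cd45, cd11]
    if scenario == "aCD3":
        return [replace(tcr, ligand="aCD3"), cd45, cd11]
    # APC
    return [
        replace(tcr, ligand="pMHC"),
        cd45,
        replace(cd11, ligand="ICAM"),
        SpeciesSpec("pMHC", "apc", **_DEFAULTS["pMHC"]),
        # non-cognate pMHC: physically identical but not a TCR ligand
        SpeciesSpec("pMHC_nc", "apc", **_DEFAULTS["pMHC"]),
        SpeciesSpec("ICAM", "apc", **_DEFAULTS["ICAM"]),
    ]


# ---------------------------------------------------------------------------
# compiled species table (flat arrays for the kernels)
# ---------------------------------------------------------------------------

@dataclass
class CompiledSpecies:
    """Flat-array view of a species table, resolved against a scenario.

    ``coat_*`` describe a uniform immobile substrate well (e.g. aCD3);
    ``pll_*`` the non-specific PLL well (centred on each species' own
    length); ``pair_*`` a cross-gap well keyed by the partner species
    index on the opposite surface.  Pair wells are stored on the T-cell
    species only so each pair is counted once.
    """

    names: list[str]
    surface: np.ndarray      # int8
    l_mol: np.ndarray
    k_mol: np.ndarray
    coat_U: np.ndarray
    coat_l: np.ndarray
    coat_w: np.ndarray
    pll_U: np.ndarray
    pll_l: np.ndarray
    pll_w: np.ndarray
    pair_lig: np.ndarray     # int32, -1 = none
    pair_U: np.ndarray
    pair_l: np.ndarray
    pair_w: np.ndarray
    D: np.ndarray
    J_self: np.ndarray
    mobile: np.ndarray       # bool
    pinned_h: np.ndarray     # nan = unpinned
    specs: list[SpeciesSpec] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @classmethod
    def compile(cls, specs: Sequence[SpeciesSpec], *, coating: Optional[str] = None,
                pll_U: float = 0.0, pll_w: float = 5.0,
                pin_mode: str = "always") -> "CompiledSpecies":
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate species names")
        n = len(specs)
        t = cls(
            names=names,
            surface=np.array([s.surface_code for s in specs], dtype=np.int8),
            l_mol=np.array([s.l_mol for s in specs], dtype=np.float64),
            k_mol=np.array([s.k_mol for s in specs], dtype=np.float64),
            coat_U=np.zeros(n), coat_l=np.zeros(n), coat_w=np.zeros(n),
            pll_U=np.zeros(n), pll_l=np.zeros(n), pll_w=np.zeros(n),
            pair_lig=np.full(n, -1, dtype=np.int32),
            pair_U=np.zeros(n), pair_l=np.zeros(n), pair_w=np.zeros(n),
            D=np.array([s.D for s in specs], dtype=np.float64),
            J_self=np.array([s.J_self for s in specs], dtype=np.float64),
            mobile=np.array([s.mobile for s in specs], dtype=bool),
            pinned_h=np.array(
                [np.nan if (s.pinned_height is None or pin_mode == "when_bound")
                 else s.pinned_height for s in specs], dtype=np.float64),
            specs=list(specs),
        )
        for i, s in enumerate(specs):
            if s.surface_code == T_CELL and pll_U != 0.0:
                t.pll_U[i], t.pll_l[i], t.pll_w[i] = pll_U, s.l_mol, pll_w
            if s.ligand is None:
                continue
            if coating is not None and s.ligand == coating:
                t.coat_U[i], t.coat_l[i], t.coat_w[i] = s.U_bind, s.l_complex, s.w_bind
            elif s.ligand in names:
                j = names.index(s.ligand)
                if specs[j].surface_code == s.surface_code:
                    raise ConfigurationError(
                        f"{s.name}: ligand {s.ligand} is on the same surface")
                t.pair_lig[i], t.pair_U[i] = j, s.U_bind
                t.pair_l[i], t.pair_w[i] = s.l_complex, s.w_bind
            else:
                raise ConfigurationError(
                    f"{s.name}: ligand {s.ligand!r} is neither the coating "
                    f"({coating!r}) nor a configured species")
        return t


# ---------------------------------------------------------------------------
# lattice
# ---------------------------------------------------------------------------

class InterfaceGrid:
    """Periodic square lattice of the separation field and occupancy.

    Each pixel has exactly 4 nearest neighbours under wrap-around and can
    accommodate at most one molecule per surface.  ``z`` is the local
    membrane--surface (or membrane--membrane) separation in nm and is
    strictly positive everywhere.
    """

    def __init__(self, n_rows: int, n_cols: int, a: float = 10.0,
                 z_init: float = 70.0):
        if n_rows < 1 or n_cols < 1:
            raise ConfigurationError("grid must have at least one pixel")
        if a <= 0 or z_init <= 0:
            raise ConfigurationError("lattice constant and z_init must be positive")
        self.n_rows = int(n_rows)
        self.n_cols = int(n_cols)
        self.a = float(a)
        self.z = np.full((n_rows, n_cols), float(z_init), dtype=np.float64)
        # occ[surface, r, c] = molecule id or -1
        self.occ = np.full((2, n_rows, n_cols), -1, dtype=np.int32)
        self.mol_species = np.empty(0, dtype=np.int32)
        self.mol_row = np.empty(0, dtype=np.int32)
        self.mol_col = np.empty(0, dtype=np.int32)
        self.mol_surface = np.empty(0, dtype=np.int8)
        self.mol_bound = np.empty(0, dtype=bool)

    # -- registry ----------------------------------------------------------

    @property
    def n_molecules(self) -> int:
        return self.mol_species.size

    def add_molecules(self, species_idx: int, rows: np.ndarray, cols: np.ndarray,
                      surface: int = T_CELL) -> np.ndarray:
        """Register molecules of one species at given pixels; returns ids."""
        rows = np.asarray(rows, dtype=np.int32)
        cols = np.asarray(cols, dtype=np.int32)
        if rows.size != cols.size:
            raise ValueError("rows and cols must have equal length")
        occ = self.occ[surface]
        if np.any(occ[rows, cols] >= 0):
            raise CapacityError("placement collides with an occupied pixel")
        flat = rows.astype(np.int64) * self.n_cols + cols
        if np.unique(flat).size != flat.size:
            raise CapacityError("duplicate pixels in one placement batch")
        start = self.n_molecules
        ids = np.arange(start, start + rows.size, dtype=np.int32)
        occ[rows, cols] = ids
        self.mol_species = np.concatenate([self.mol_species,
                                           np.full(rows.size, species_idx, np.int32)])
        self.mol_row = np.concatenate([self.mol_row, rows])
        self.mol_col = np.concatenate([self.mol_col, cols])
        self.mol_surface = np.concatenate([self.mol_surface,
                                           np.full(rows.size, surface, np.int8)])
        self.mol_bound = np.concatenate([self.mol_bound,
                                         np.zeros(rows.size, dtype=bool)])
        return ids

    def species_counts(self, table: CompiledSpecies) -> dict[str, int]:
        counts = np.bincount(self.mol_species, minlength=table.n_species)
        return {name: int(counts[i]) for i, name in enumerate(table.names)}

    def molecule_states(self, table: CompiledSpecies) -> list[MoleculeState]:
        surf_names = {T_CELL: "t_cell", APC_SURF: "apc"}
        return [
            MoleculeState(int(i), table.names[self.mol_species[i]],
                          (int(self.mol_row[i]), int(self.mol_col[i])),
                          surf_names[int(self.mol_surface[i])],
                          bool(self.mol_bound[i]))
            for i in range(self.n_molecules)
        ]

    def positions_nm(self, table: CompiledSpecies, species: Optional[str] = None,
                     surface: Optional[int] = None) -> np.ndarray:
        """(n, 2) array of x, y pixel-centre coordinates in nm."""
        mask = np.ones(self.n_molecules, dtype=bool)
        if species is not None:
            mask &= self.mol_species == table.index(species)
        if surface is not None:
            mask &= self.mol_surface == surface
        x = (self.mol_col[mask] + 0.5) * self.a
        y = (self.mol_row[mask] + 0.5) * self.a
        return np.column_stack([x, y])

    # -- invariants --------------------------------------------------------

    def pinned_mask(self, table: CompiledSpecies) -> np.ndarray:
        """Boolean (n_rows, n_cols): pixel holds a pinned-height molecule."""
        mask = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        pinned_sp = np.isnan(table.pinned_h) == False  # noqa: E712
        for surf in (T_CELL, APC_SURF):
            occ = self.occ[surf]
            occupied = occ >= 0
            sp = np.where(occupied, self.mol_species[np.clip(occ, 0, None)], -1)
            mask |= occupied & np.isin(sp, np.nonzero(pinned_sp)[0])
        return mask

    def apply_pins(self, table: CompiledSpecies) -> None:
        """Force the separation field to the pinned heights at occupied pixels."""
        for surf in (T_CELL, APC_SURF):
            occ = self.occ[surf]
            occupied = occ >= 0
            if not occupied.any():
                continue
            sp = self.mol_species[np.clip(occ, 0, None)]
            ph = table.pinned_h[sp]
            sel = occupied & ~np.isnan(ph)
            self.z[sel] = ph[sel]

    def check_consistency(self) -> None:
        """Assert mutual consistency of occupancy map and registry."""
        if np.any(self.z <= 0):
            raise AssertionError("separation field must be strictly positive")
        for surf in (T_CELL, APC_SURF):
            occ = self.occ[surf]
            ids = occ[occ >= 0]
            if ids.size != np.unique(ids).size:
                raise AssertionError("molecule registered at two pixels")
        for i in range(self.n_molecules):
            s, r, c = int(self.mol_surface[i]), int(self.mol_row[i]), int(self.mol_col[i])
            if self.occ[s, r, c] != i:
                raise AssertionError(f"registry/occupancy mismatch for molecule {i}")


def max_capacity(grid: InterfaceGrid) -> int:
    """Molecule capacity per surface under single occupancy (rows x cols)."""
    return grid.n_rows * grid.n_cols
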