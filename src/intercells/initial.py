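"""Starting molecular placements: SMLM localization tables and synthetic
point-pattern recipes, and their rasterization onto the lattice.

Localization tables are ThunderSTORM-style delimited text with x/y
coordinates in nm (columns ``"x [nm]"``/``"y [nm]"`` are recognized out of
the box).  Synthetic recipes emulate the point patterns used as initial
conditions in the experiments: microvilli-like tight Gaussian clusters
(TCR), uniform (CSR) placement (CD11, CD45), and ring patterns.

Pixel indexing is 0-based and row-major with the origin at the lower-left
of the window; x maps to columns, so a point at (x, y) nm lands in pixel
(floor(y/a), floor(x/a)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import CapacityError, ConfigurationError, InterfaceGrid, max_capacity

__all__ = [
    "LocalizationTable",
    "FormatError",
    "read_localizations",
    "rasterize",
    "synthetic_pattern",
]


class FormatError(ValueError):
    """Raised when a localization file lacks usable x/y columns."""


@dataclass
class LocalizationTable:
    """Point records with coordinates in nm and optional extra columns."""

    data: pd.DataFrame  # at least columns x, y (nm)
    species: Optional[str] = None
    n_skipped: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)


_X_ALIASES = ("x [nm]", "x[nm]", "x_nm", "x")
_Y_ALIASES = ("y [nm]", "y[nm]", "y_nm", "y")


def _find_column(columns, aliases, mapped):
    if mapped is not None:
        if mapped not in columns:
            raise FormatError(f"mapped column {mapped!r} not in file")
        return mapped
    lower = {c.strip().lower(): c for c in columns}
    for alias in aliases:
        if alias in lower:
            return lower[alias]
    raise FormatError(f"no coordinate column among {aliases}; found {list(columns)}")


def read_localizations(path, column_map: Optional[dict] = None,
                       crop: Optional[tuple[float, float, float, float]] = None,
                       species: Optional[str] = None,
                       merge_radius: Optional[float] = None,
                       sep: str = ",") -> LocalizationTable:
    """Read a delimited localization table.

    Parameters
    ----------
    column_map:
        Optional ``{"x": name, "y": name}`` override of the automatic
        ThunderSTORM-style column detection.
    crop:
        ``(x0, y0, x1, y1)`` nm window; records outside are dropped and the
        remaining coordinates are shifted so the window origin is (0, 0).
    merge_radius:
        Optional distance (nm) below which localizations are collapsed into
        one molecule (single-linkage union of all pairs closer than the
        radius, replaced by their centroid).  By default every record is
        treated as one molecule.
    """
    df = pd.read_csv(path, sep=sep)
    column_map = column_map or {}
    xc = _find_column(df.columns, _X_ALIASES, column_map.get("x"))
    yc = _find_column(df.columns, _Y_ALIASES, column_map.get("y"))
    x = pd.to_numeric(df[xc], errors="coerce")
    y = pd.to_numeric(df[yc], errors="coerce")
    ok = x.notna() & y.notna() & np.isfinite(x) & np.isfinite(y)
    n_skipped = int((~ok).sum())
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-numeric localization rows")
    out = df.loc[ok].copy()
    out["x"] = x[ok]
    out["y"] = y[ok]
    if crop is not None:
        x0, y0, x1, y1 = crop
        inside = (out["x"] >= x0) & (out["x"] < x1) & (out["y"] >= y0) & (out["y"] < y1)
        out = out.loc[inside].copy()
        out["x"] -= x0
        out["y"] -= y0
    if (out["x"] < 0).any() or (out["y"] < 0).any():
        raise FormatError("negative coordinates; supply a crop window")
    if merge_radius is not None and merge_radius > 0 and len(out) > 1:
        out = _merge_localizations(out, merge_radius)
    out = out.reset_index(drop=True)
    return LocalizationTable(out, species=species, n_skipped=n_skipped)


def _merge_localizations(df: pd.DataFrame, radius: float) -> pd.DataFrame:
    from scipy.spatial import cKDTree

    xy = df[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    parent = np.arange(len(df))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in tree.query_pairs(radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    roots = np.array([find(i) for i in range(len(df))])
    g = pd.DataFrame({"x": df["x"].to_numpy(), "y": df["y"].to_numpy(),
                      "root": roots})
    merged = g.groupby("root", as_index=False)[["x", "y"]].mean()
    return merged[["x", "y"]]


def synthetic_pattern(kind: str, params: dict, seed) -> LocalizationTable:
    """Reproducible synthetic point pattern (coordinates in nm).

    Kinds
    -----
    ``gaussian_clusters``: ``n_clusters`` isotropic Gaussian clusters of
        ``pts_per_cluster`` points with standard deviation ``cluster_sd``
        (nm), centres uniform in ``window`` (points wrapped periodically).
        Emulates microvilli-like TCR clusters.
    ``uniform``: ``n`` points, complete spatial randomness in ``window``.
    ``ring``: ``n`` points at radius ``N(r_mean, r_sd)`` around ``center``
        (window centre by default), uniform in angle, wrapped.
    ``halo``: ``n`` points on annuli of radius ``N(r_mean, r_sd)`` around
        the given ``centers`` (e.g. the TCR cluster centres), each point
        assigned to a uniformly chosen centre.  Emulates the interstitial
        CD11 and ring-like CD45 placements around microvilli contacts.

    ``window`` is ``(width, height)`` in nm.  Cluster patterns record their
    centres in ``table.meta["centers"]``.
    """
    rng = np.random.default_rng(seed)
    params = dict(params)
    window = params.pop("window", None)
    if window is None:
        raise ConfigurationError("synthetic_pattern requires a window (w, h) in nm")
    w, h = float(window[0]), float(window[1])
    if w <= 0 or h <= 0:
        raise ConfigurationError("window extents must be positive")

    meta = {}
    if kind == "gaussian_clusters":
        nc = int(params.pop("n_clusters"))
        npc = int(params.pop("pts_per_cluster"))
        sd = float(params.pop("cluster_sd"))
        if nc <= 0 or npc <= 0 or sd < 0:
            raise ConfigurationError("cluster parameters must be positive")
        centers = rng.uniform([0, 0], [w, h], size=(nc, 2))
        pts = np.repeat(centers, npc, axis=0) + rng.normal(0, sd, size=(nc * npc, 2))
        meta["centers"] = centers
    elif kind == "halo":
        n = int(params.pop("n"))
        r_mean = float(params.pop("r_mean"))
        r_sd = float(params.pop("r_sd", 0.0))
        centers = np.asarray(params.pop("centers"), dtype=float)
        if n < 0 or r_mean <= 0 or r_sd < 0 or centers.ndim != 2:
            raise ConfigurationError("halo needs centers (m, 2), r_mean > 0, r_sd >= 0")
        which = rng.integers(centers.shape[0], size=n)
        r = np.abs(rng.normal(r_mean, r_sd, n))
        theta = rng.uniform(0, 2 * np.pi, n)
        pts = centers[which] + np.column_stack([r * np.cos(theta),
                                                r * np.sin(theta)])
    elif kind == "uniform":
        n = int(params.pop("n"))
        if n < 0:
            raise ConfigurationError("n must be non-negative")
        pts = rng.uniform([0, 0], [w, h], size=(n, 2))
    elif kind == "ring":
        n = int(params.pop("n"))
        r_mean = float(params.pop("r_mean"))
        r_sd = float(params.pop("r_sd", 0.0))
        center = params.pop("center", (w / 2, h / 2))
        if n < 0 or r_mean <= 0 or r_sd < 0:
            raise ConfigurationError("ring parameters must be positive")
        r = rng.normal(r_mean, r_sd, n)
        theta = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack([center[0] + r * np.cos(theta),
                               center[1] + r * np.sin(theta)])
    else:
        raise ConfigurationError(
            f"unknown pattern kind {kind!r}; valid: gaussian_clusters, uniform, "
            "ring, halo")
    if params:
        raise ConfigurationError(f"unknown pattern parameters {sorted(params)}")
    pts[:, 0] %= w
    pts[:, 1] %= h
    return LocalizationTable(pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1]}),
                             meta=meta)


def rasterize(table: LocalizationTable, grid: InterfaceGrid,
              rng: np.random.Generator, species_idx: int,
              surface: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Map localization records to lattice pixels and register the molecules.

    Each record maps to pixel ``(floor(y/a), floor(x/a))``.  When a pixel is
    already taken, the later record is displaced to the nearest free pixel
    (breadth-first ring search in Chebyshev rings, nearest Euclidean within
    the ring, RNG tie-break), so counts are preserved unless the grid is
    full.  Returns the (rows, cols) actually used.
    """
    xy = table.xy
    n = xy.shape[0]
    occ = grid.occ[surface]
    free_slots = int(np.sum(occ < 0))
    if n > free_slots:
        raise CapacityError(
            f"{n} records exceed the {free_slots} free pixels of this surface "
            f"(capacity {max_capacity(grid)} under single occupancy)")
    a = grid.a
    R, C = grid.n_rows, grid.n_cols
    rows_out = np.empty(n, dtype=np.int32)
    cols_out = np.empty(n, dtype=np.int32)
    taken = occ >= 0
    for i in range(n):
        c0 = int(xy[i, 0] // a) % C
        r0 = int(xy[i, 1] // a) % R
        if not taken[r0, c0]:
            r, c = r0, c0
        else:
            r, c = _nearest_free(taken, r0, c0, rng)
        taken[r, c] = True
        rows_out[i], cols_out[i] = r, c
    grid.add_molecules(species_idx, rows_out, cols_out, surface)
    return rows_out, cols_out


def _nearest_free(taken: np.ndarray, r0: int, c0: int,
                  rng: np.random.Generator) -> tuple[int, int]:
    """Nearest free pixel in growing Chebyshev rings around (r0, c0)."""
    R, C = taken.shape
    max_k = max(R, C)
    for k in range(1, max_k + 1):
        cand = []
        for dr in range(-k, k + 1):
            for dc in range(-k, k + 1):
                if max(abs(dr), abs(dc)) != k:
                    continue
                r, c = (r0 + dr) % R, (c0 + dc) % C
                if not taken[r, c]:
                    cand.append((dr * dr + dc * dc, r, c))
        if cand:
            d2min = min(c[0] for c in cand)
            best = [(r, c) for d2, r, c in cand if d2 == d2min]
            return best[int(rng.integers(len(best)))] if len(best) > 1 else best[0]
    raise CapacityError("no free pixel found")  # pragma: no cover
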