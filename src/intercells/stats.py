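"""Spatial statistics: topology (Minkowski-perimeter) conditional densities,
pair-correlation functions, and peak-shift summaries.

The topology analysis grows disks of increasing radius around a reference
point set (e.g. TCR localizations); the band between consecutive dilations
of the union defines a perimeter region, and the conditional density of
every other species at that radius is its point count in the band divided
by the band area.  Densities of a CSR (uniform random) species converge to
its global density at large radii, while enrichment or exclusion around
the reference clusters shows up as peaks or valleys.  The reference set
itself is summarized by its univariate pair-correlation function g(r).

Distances are Euclidean, computed on the pixel raster by an exact distance
transform; the window is treated as periodic for simulated data, while
imported SMLM crops use clipped bands with area normalization by the
clipped band area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "AnalysisError",
    "TopologyCurves",
    "topology_analysis",
    "pcf_univariate",
    "pcf_bivariate",
    "peak_shift",
]


class AnalysisError(ValueError):
    """Raised for unusable analysis inputs (empty reference, <2 points...)."""


@dataclass
class TopologyCurves:
    """Conditional densities vs. dilation radius around a reference set.

    ``radii`` are the outer radii of the bands (nm); band k covers
    distances in (radii[k-1], radii[k]] with band 0 covering [0, radii[0]]
    (distance 0 = on a reference pixel).  ``density_by_species`` maps each
    non-reference species to its per-band density; the units are points
    per nm^2 of band area (or per nm of estimated band perimeter when
    ``normalization="perimeter"``).
    """

    radii: np.ndarray
    density_by_species: dict[str, np.ndarray]
    counts_by_species: dict[str, np.ndarray]
    band_area: np.ndarray            # nm^2
    ref_pcf: Optional[np.ndarray] = None
    normalization: str = "area"
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (radius_nm, species, density) table."""
        rows = []
        for name, dens in self.density_by_species.items():
            for r, d in zip(self.radii, dens):
                rows.append((float(r), name, float(d)))
        return pd.DataFrame(rows, columns=["radius_nm", "species", "density"])


def _ref_distance_map(ref_points: np.ndarray, shape: tuple[int, int],
                      pixel_size: float, periodic: bool) -> np.ndarray:
    """Per-pixel Euclidean distance (nm) to the nearest reference pixel."""
    R, C = shape
    mask = np.ones(shape, dtype=bool)  # True = background (not reference)
    rows = (ref_points[:, 1] // pixel_size).astype(int) % R
    cols = (ref_points[:, 0] // pixel_size).astype(int) % C
    mask[rows, cols] = False
    if periodic:
        tiled = np.tile(mask, (3, 3))
        d = ndimage.distance_transform_edt(tiled, sampling=pixel_size)
        d = d[R:2 * R, C:2 * C]
    else:
        d = ndimage.distance_transform_edt(mask, sampling=pixel_size)
    return d


def topology_analysis(ref_points: np.ndarray,
                      other_points_by_species: dict[str, np.ndarray],
                      radii: np.ndarray, pixel_size: float,
                      window: tuple[float, float],
                      periodic: bool = True,
                      normalization: str = "area",
                      compute_ref_pcf: bool = True) -> TopologyCurves:
    """Conditional density of each species vs. dilation radius.

    Parameters
    ----------
    ref_points, other_points_by_species:
        (n, 2) arrays of x, y in nm.
    radii:
        Increasing outer band radii in nm (band width defaults to the
        radius step; one pixel is the natural choice).
    pixel_size:
        Raster resolution, nm (the simulation lattice constant).
    window:
        (width, height) of the analysis window in nm.
    normalization:
        ``"area"``: points per nm^2 of band area (default);
        ``"perimeter"``: points per nm of estimated band perimeter
        (band area / band width).
    """
    ref_points = np.asarray(ref_points, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if ref_points.size == 0:
        raise AnalysisError("empty reference point set")
    if radii.size == 0 or np.any(np.diff(radii) <= 0):
        raise AnalysisError("radii must be non-empty and strictly increasing")
    if normalization not in ("area", "perimeter"):
        raise AnalysisError("normalization must be 'area' or 'perimeter'")
    w, h = window
    shape = (int(round(h / pixel_size)), int(round(w / pixel_size)))
    dmap = _ref_distance_map(ref_points, shape, pixel_size, periodic)

    edges = np.concatenate([[-1.0], radii])  # band 0 includes distance 0
    pix_band = np.digitize(dmap.ravel(), edges[1:], right=True)
    in_range = pix_band < radii.size
    band_pixels = np.bincount(pix_band[in_range], minlength=radii.size)
    band_area = band_pixels.astype(float) * pixel_size ** 2
    widths = np.diff(np.concatenate([[0.0], radii]))

    counts = {}
    densities = {}
    R, C = shape
    for name, pts in other_points_by_species.items():
        pts = np.asarray(pts, dtype=float)
        if pts.size == 0:
            counts[name] = np.zeros(radii.size, dtype=int)
            densities[name] = np.zeros(radii.size)
            continue
        rows = (pts[:, 1] // pixel_size).astype(int) % R
        cols = (pts[:, 0] // pixel_size).astype(int) % C
        d = dmap[rows, cols]
        b = np.digitize(d, edges[1:], right=True)
        ok = b < radii.size
        cnt = np.bincount(b[ok], minlength=radii.size)
        counts[name] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            if normalization == "area":
                dens = np.where(band_area > 0, cnt / band_area, 0.0)
            else:
                dens = np.where(band_area > 0, cnt / (band_area / widths), 0.0)
        densities[name] = dens

    ref_pcf = None
    if compute_ref_pcf and ref_points.shape[0] >= 2:
        ref_pcf = pcf_univariate(ref_points, radii, window, periodic=periodic)
    return TopologyCurves(radii=radii, density_by_species=densities,
                          counts_by_species=counts, band_area=band_area,
                          ref_pcf=ref_pcf, normalization=normalization,
                          meta={"pixel_size": pixel_size, "window": window,
                                "periodic": periodic,
                                "n_ref": int(ref_points.shape[0])})


def _ring_areas(radii: np.ndarray) -> np.ndarray:
    inner = np.concatenate([[0.0], radii[:-1]])
    return np.pi * (radii ** 2 - inner ** 2)


def pcf_univariate(points: np.ndarray, radii: np.ndarray,
                   window: tuple[float, float], periodic: bool = True) -> np.ndarray:
    """Pair-correlation function g(r) with ring binning.

    g(r) -> 1 at large r for complete spatial randomness.  With a periodic
    window no edge correction is needed; for a bounded window no edge
    correction is applied (documented; bands near the border are biased
    low, so prefer generous crops).
    """
    points = np.asarray(points, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise AnalysisError("pair correlation requires at least 2 points")
    w, h = window
    area = w * h
    if periodic:
        pts = np.mod(points, [w, h])
        tree = cKDTree(pts, boxsize=[w, h])
    else:
        tree = cKDTree(points)
    cum = tree.count_neighbors(tree, radii)  # ordered pairs incl. self
    cum = cum.astype(float) - n  # drop self-pairs
    pairs = np.diff(np.concatenate([[0.0], cum]))
    expected = n * (n - 1) * _ring_areas(radii) / area
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(expected > 0, pairs / expected, np.nan)


def pcf_bivariate(points_a: np.ndarray, points_b: np.ndarray,
                  radii: np.ndarray, window: tuple[float, float],
                  periodic: bool = True) -> np.ndarray:
    """Bivariate (cross) pair-correlation g_ab(r) between two species."""
    points_a = np.asarray(points_a, dtype=float)
    points_b = np.asarray(points_b, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if points_a.shape[0] < 1 or points_b.shape[0] < 1 or \
            points_a.shape[0] + points_b.shape[0] < 2:
        raise AnalysisError("cross pair correlation requires points in both sets")
    w, h = window
    area = w * h
    if periodic:
        ta = cKDTree(np.mod(points_a, [w, h]), boxsize=[w, h])
        tb = cKDTree(np.mod(points_b, [w, h]), boxsize=[w, h])
    else:
        ta, tb = cKDTree(points_a), cKDTree(points_b)
    cum = ta.count_neighbors(tb, radii).astype(float)
    pairs = np.diff(np.concatenate([[0.0], cum]))
    expected = (points_a.shape[0] * points_b.shape[0]
                * _ring_areas(radii) / area)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(expected > 0, pairs / expected, np.nan)


@dataclass
class PeakSummary:
    species: str
    peak_radius: Optional[float]  # None for a flat curve
    peak_density: float


def peak_shift(curves: TopologyCurves) -> dict[str, PeakSummary]:
    """Radius of each species' maximum conditional density.

    Ties across bands report the smaller radius; a flat curve reports
    no peak together with its plateau value.
    """
    out = {}
    for name, dens in curves.density_by_species.items():
        if np.allclose(dens, dens[0]):
            out[name] = PeakSummary(name, None, float(dens[0]))
            continue
        k = int(np.argmax(dens))  # argmax takes the first (smallest) band on ties
        out[name] = PeakSummary(name, float(curves.radii[k]), float(dens[k]))
    return out
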