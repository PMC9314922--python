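"""Kernel utilization distribution (UD) from telemetry fixes.

Satellite-telemetry fixes are pooled across animals, projected onto a local
azimuthal equal-area plane (so the kernel bandwidth is metric), smoothed with a
bivariate normal kernel, and the highest-density region enclosing a chosen
probability mass (default the 95% isopleth) is extracted as the habitat
polygon used to mask regional ocean diagnostics.

The default bandwidth is 250 km, the smoothing used for wide-ranging Barents
Sea harp seals; the evaluation grid is bandwidth/10 with >= 3 bandwidths of
padding so essentially all kernel mass lies on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely.geometry
import shapely.ops

__all__ = [
    "EARTH_RADIUS_KM",
    "project_locations",
    "unproject_locations",
    "KernelUD",
    "UDResults",
    "ContourRegion",
]

EARTH_RADIUS_KM = 6371.0088


def _check_lonlat(lon, lat):
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude outside [-90, 90]")
    # normalize longitudes to [-180, 180)
    lon = (lon + 180.0) % 360.0 - 180.0
    return lon, lat


def project_locations(lon, lat, lon0: float, lat0: float):
    """Lambert azimuthal equal-area projection to planar km about (lon0, lat0).

    Spherical formulas; exact for the equal-area property, sub-metre round
    trip.  Raises if any point is antipodal-hemisphere distant from the
    centre (the projection is not usable there).
    """
    lon, lat = _check_lonlat(lon, lat)
    lam = np.radians(lon)
    phi = np.radians(lat)
    lam0 = np.radians(((lon0 + 180.0) % 360.0) - 180.0)
    phi0 = np.radians(lat0)
    cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    if np.any(cosc <= -1.0 + 1e-12):
        raise ValueError("fixes span more than a hemisphere from the centre")
    k = np.sqrt(2.0 / (1.0 + cosc))
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


def unproject_locations(x, y, lon0: float, lat0: float):
    """Inverse of :func:`project_locations` (planar km -> lon/lat degrees)."""
    x = np.atleast_1d(np.asarray(x, dtype=float)) / EARTH_RADIUS_KM
    y = np.atleast_1d(np.asarray(y, dtype=float)) / EARTH_RADIUS_KM
    lam0 = np.radians(lon0)
    phi0 = np.radians(lat0)
    rho = np.hypot(x, y)
    c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(
            rho == 0,
            phi0,
            np.arcsin(np.clip(
                np.cos(c) * np.sin(phi0) + y * np.sin(c) * np.cos(phi0) / np.where(rho == 0, 1, rho),
                -1.0, 1.0,
            )),
        )
        lam = np.where(
            rho == 0,
            lam0,
            lam0 + np.arctan2(
                x * np.sin(c),
                rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c),
            ),
        )
    lon = (np.degrees(lam) + 180.0) % 360.0 - 180.0
    return lon, np.degrees(phi)


@dataclass
class ContourRegion:
    """A highest-density region: polygons (projected km and geographic)."""

    polygons_km: list
    polygons_lonlat: list
    area_km2: float
    threshold: float
    isopleth: float
    lon0: float
    lat0: float

    @property
    def n_polygons(self) -> int:
        return len(self.polygons_km)

    def contains(self, lon, lat) -> np.ndarray:
        """Point-in-region test in geographic coordinates; boundary is inside."""
        x, y = project_locations(lon, lat, self.lon0, self.lat0)
        union = shapely.ops.unary_union(self.polygons_km)
        pts = [shapely.geometry.Point(xi, yi) for xi, yi in zip(np.atleast_1d(x), np.atleast_1d(y))]
        out = np.array([union.covers(p) for p in pts])
        return out if out.size > 1 else bool(out[0])

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"isopleth": self.isopleth, "area_km2": self.area_km2},
                    "geometry": shapely.geometry.mapping(poly),
                }
                for poly in self.polygons_lonlat
            ],
        }


class UDResults:
    """Fitted kernel utilization distribution on an equal-area grid."""

    def __init__(self, density: np.ndarray, x_edges: np.ndarray, y_edges: np.ndarray,
                 bandwidth_km: float, lon0: float, lat0: float):
        self.density = density  # (ny, nx), integrates to 1 over the grid
        self.x_edges = x_edges
        self.y_edges = y_edges
        self.bandwidth_km = bandwidth_km
        self.lon0 = lon0
        self.lat0 = lat0
        self.cell_km = float(x_edges[1] - x_edges[0])

    @property
    def cell_area_km2(self) -> float:
        return self.cell_km * float(self.y_edges[1] - self.y_edges[0])

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area_km2)

    def iso_level(self, p: float) -> float:
        """Density threshold whose super-level set encloses mass >= p."""
        if not 0.0 < p < 1.0:
            raise ValueError("isopleth probability must lie in (0, 1)")
        dens = np.sort(self.density.ravel())[::-1]
        mass = np.cumsum(dens) * self.cell_area_km2
        idx = int(np.searchsorted(mass, p))
        idx = min(idx, len(dens) - 1)
        return float(dens[idx])

    def contour_region(self, p: float = 0.95) -> ContourRegion:
        """Highest-density region enclosing mass p, as merged cell polygons."""
        thr = self.iso_level(p)
        inside = self.density >= thr
        boxes = []
        ys, xs = np.nonzero(inside)
        xe, ye = self.x_edges, self.y_edges
        for iy, ix in zip(ys, xs):
            boxes.append(shapely.geometry.box(xe[ix], ye[iy], xe[ix + 1], ye[iy + 1]))
        union = shapely.ops.unary_union(boxes)
        if union.geom_type == "Polygon":
            polys = [union]
        else:
            polys = list(union.geoms)
        polys_ll = []
        for poly in polys:
            bx, by = poly.exterior.xy
            lon, lat = unproject_locations(np.asarray(bx), np.asarray(by), self.lon0, self.lat0)
            polys_ll.append(shapely.geometry.Polygon(zip(lon, lat)))
        return ContourRegion(
            polygons_km=polys,
            polygons_lonlat=polys_ll,
            area_km2=float(inside.sum() * self.cell_area_km2),
            threshold=thr,
            isopleth=p,
            lon0=self.lon0,
            lat0=self.lat0,
        )

    def mass_in_region(self, region: ContourRegion, density_fn=None) -> float:
        """Grid integral over the region of this UD or of an external density.

        ``density_fn(x, y)`` is evaluated at projected-km cell centres; used to
        measure how much of a reference distribution the region captures.
        """
        thr = region.threshold
        inside = self.density >= thr
        if density_fn is None:
            vals = self.density
        else:
            xx, yy = np.meshgrid(self.x_centers, self.y_centers)
            vals = density_fn(xx, yy)
        return float(np.where(inside, vals, 0.0).sum() * self.cell_area_km2)

    def mask_on_grid(self, lon_grid, lat_grid, p: float = 0.95) -> np.ndarray:
        """Boolean region mask evaluated on an arbitrary lon/lat grid."""
        region = self.contour_region(p)
        lon = np.asarray(lon_grid, dtype=float)
        lat = np.asarray(lat_grid, dtype=float)
        flat = region.contains(lon.ravel(), lat.ravel())
        return np.asarray(flat).reshape(lon.shape)


class KernelUD:
    """Bivariate-normal kernel UD estimator for pooled telemetry fixes.

    Parameters
    ----------
    fixes : DataFrame with columns animal_id, lon, lat (timestamp optional)
    bandwidth_km : kernel standard deviation, km
    grid_km : evaluation grid cell size, km (default bandwidth / 10)
    pad_bandwidths : grid padding beyond the fix bounding box
    weighting : "fix" pools all fixes equally; "animal" gives each animal
        equal total weight regardless of its number of fixes.
    """

    def __init__(self, fixes: pd.DataFrame, bandwidth_km: float = 250.0,
                 grid_km: float | None = None, pad_bandwidths: float = 3.0,
                 weighting: str = "fix"):
        if bandwidth_km <= 0:
            raise ValueError("bandwidth must be positive")
        if len(fixes) < 5:
            raise ValueError("kernel UD needs at least 5 fixes")
        if weighting not in ("fix", "animal"):
            raise ValueError("weighting must be 'fix' or 'animal'")
        self.fixes = fixes.reset_index(drop=True)
        self.bandwidth_km = float(bandwidth_km)
        self.grid_km = float(grid_km) if grid_km is not None else bandwidth_km / 10.0
        self.pad_bandwidths = float(pad_bandwidths)
        self.weighting = weighting

    def fit(self) -> UDResults:
        lon, lat = _check_lonlat(self.fixes["lon"], self.fixes["lat"])
        lon0 = float(np.mean(lon))
        lat0 = float(np.mean(lat))
        x, y = project_locations(lon, lat, lon0, lat0)
        h = self.bandwidth_km
        pad = self.pad_bandwidths * h
        res = self.grid_km
        x_edges = np.arange(x.min() - pad, x.max() + pad + res, res)
        y_edges = np.arange(y.min() - pad, y.max() + pad + res, res)
        xc = 0.5 * (x_edges[:-1] + x_edges[1:])
        yc = 0.5 * (y_edges[:-1] + y_edges[1:])
        if self.weighting == "fix":
            w = np.full(len(x), 1.0 / len(x))
        else:
            ids = self.fixes["animal_id"].to_numpy()
            counts = pd.Series(ids).value_counts()
            w = np.array([1.0 / (len(counts) * counts[i]) for i in ids])
        # separable Gaussian kernel: density = sum_i w_i N(x; x_i, h) N(y; y_i, h)
        gx = np.exp(-0.5 * ((xc[None, :] - x[:, None]) / h) ** 2)  # (n, nx)
        gy = np.exp(-0.5 * ((yc[None, :] - y[:, None]) / h) ** 2)  # (n, ny)
        dens = (gy * w[:, None]).T @ gx  # (ny, nx)
        dens /= 2.0 * np.pi * h * h
        # normalise residual off-grid mass so the grid sums to exactly 1
        dens /= dens.sum() * res * res
        return UDResults(dens, x_edges, y_edges, h, lon0, lat0)
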