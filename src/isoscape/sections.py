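"""Diagnostics on gridded ocean sections and regional cubes.

The section diagnostics operate on annual depth x latitude fields at an inflow
section (zonal velocity, potential temperature, salinity, nitrate and its
delta15N): Atlantic Water masking, volume transport and its decomposition into
velocity-driven and water-mass-volume-driven trends, nitrate flux, and masked
property averages.  The regional diagnostics operate on depth x lat x lon
cubes inside a habitat mask: upper-100 m means, vertically integrated primary
production, per-cell decadal trend maps and paired-run attribution
percentages.

Atlantic Water is defined by strict thresholds: potential temperature > 2 degC
AND salinity > 34.5 psu; boundary cells are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

__all__ = [
    "SectionSeries",
    "TrendResult",
    "DecompositionResult",
    "aw_mask",
    "transport",
    "transport_decomposition",
    "nitrate_flux",
    "masked_mean",
    "regional_upper_mean",
    "integrate_npp",
    "decadal_trend",
    "trend_map",
    "attribution_pct",
]

SV = 1.0e6  # m3 s-1 per Sverdrup
AW_THETA_MIN = 2.0  # degC, strict
AW_SALINITY_MIN = 34.5  # psu, strict
SECONDS_PER_YEAR = 3.15576e7


@dataclass
class SectionSeries:
    """Annual section fields with cell geometry.

    All field arrays have shape (year, depth, lat); ``cell_area`` has shape
    (depth, lat) in m2 (level thickness x along-section cell width).
    """

    years: np.ndarray
    u: np.ndarray  # zonal velocity, m s-1, positive eastward
    theta: np.ndarray  # potential temperature, degC
    salinity: np.ndarray  # psu
    no3: np.ndarray  # mmol m-3
    d15n_no3: np.ndarray  # permil
    cell_area: np.ndarray

    def __post_init__(self) -> None:
        shape = self.u.shape
        for name in ("theta", "salinity", "no3", "d15n_no3"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != u shape {shape}")
        if self.cell_area.shape != shape[1:]:
            raise ValueError("cell_area must have shape (depth, lat)")
        if np.any(self.cell_area <= 0):
            raise ValueError("cell areas must be positive")
        if len(self.years) != shape[0]:
            raise ValueError("years length must match leading field dimension")

    def to_dataset(self) -> xr.Dataset:
        dims = ("year", "depth", "lat")
        return xr.Dataset(
            {
                "uo": (dims, self.u),
                "thetao": (dims, self.theta),
                "so": (dims, self.salinity),
                "no3": (dims, self.no3),
                "d15n_no3": (dims, self.d15n_no3),
                "cell_area": (dims[1:], self.cell_area),
            },
            coords={"year": self.years},
        )

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "SectionSeries":
        dims = ("year", "depth", "lat")
        ds = ds.transpose(*dims, missing_dims="ignore")
        return cls(
            years=ds["year"].values,
            u=ds["uo"].values,
            theta=ds["thetao"].values,
            salinity=ds["so"].values,
            no3=ds["no3"].values,
            d15n_no3=ds["d15n_no3"].values,
            cell_area=ds["cell_area"].values,
        )


@dataclass(frozen=True)
class TrendResult:
    """OLS linear trend expressed per decade."""

    slope_per_decade: float
    se_per_decade: float
    intercept: float
    n: int


@dataclass(frozen=True)
class DecompositionResult:
    """Velocity vs water-mass-volume contributions to a transport trend.

    ``trend_velocity + trend_volume == trend_total`` exactly by construction:
    the volume contribution is defined as the residual of the total trend after
    removing the trend of the volume-normalised transport.
    """

    trend_total: float  # Sv decade-1
    trend_velocity: float
    trend_volume: float
    mean_aw_area: float  # m2
    years_used: np.ndarray


def aw_mask(theta: np.ndarray, salinity: np.ndarray) -> np.ndarray:
    """Boolean Atlantic Water mask: theta > 2 degC and S > 34.5 psu (strict)."""
    theta = np.asarray(theta)
    salinity = np.asarray(salinity)
    if theta.shape != salinity.shape:
        raise ValueError("theta and salinity shapes differ")
    return (theta > AW_THETA_MIN) & (salinity > AW_SALINITY_MIN)


def _per_year_mask(section: SectionSeries, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        mask = aw_mask(section.theta, section.salinity)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape == section.u.shape[1:]:
        mask = np.broadcast_to(mask, section.u.shape)
    if mask.shape != section.u.shape:
        raise ValueError("mask shape incompatible with section fields")
    return mask


def transport(section: SectionSeries, mask: np.ndarray | None = None) -> np.ndarray:
    """Volume transport (Sv) through the masked section cells, per year."""
    m = _per_year_mask(section, mask)
    return np.where(m, section.u * section.cell_area, 0.0).sum(axis=(1, 2)) / SV


def nitrate_flux(section: SectionSeries, mask: np.ndarray | None = None):
    """Nitrate flux through the masked cells.

    Returns ``(flux, cumulative)``: flux in mol s-1 per year and the running
    annual integral in mol (flux x seconds per year, cumulatively summed).
    """
    m = _per_year_mask(section, mask)
    conc_mol = section.no3 * 1.0e-3  # mmol m-3 -> mol m-3
    flux = np.where(m, conc_mol * section.u * section.cell_area, 0.0).sum(axis=(1, 2))
    cumulative = np.cumsum(flux * SECONDS_PER_YEAR)
    return flux, cumulative


def masked_mean(
    field: np.ndarray,
    mask: np.ndarray,
    cell_area: np.ndarray,
    velocity: np.ndarray | None = None,
    flux_weighted: bool = False,
) -> np.ndarray:
    """Weighted mean of a (year, depth, lat) field over masked cells, per year.

    Area-weighted by default; with ``flux_weighted=True`` the weights are
    velocity x area (the value carried by the transport).  Years with an empty
    mask (or zero total weight) return NaN.
    """
    field = np.asarray(field, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape == field.shape[1:]:
        mask = np.broadcast_to(mask, field.shape)
    weights = np.broadcast_to(cell_area, field.shape).astype(float).copy()
    if flux_weighted:
        if velocity is None:
            raise ValueError("flux_weighted mean requires the velocity field")
        weights = weights * velocity
    weights = np.where(mask, weights, 0.0)
    wsum = weights.sum(axis=(1, 2))
    out = np.full(field.shape[0], np.nan)
    ok = wsum != 0
    out[ok] = (weights * field).sum(axis=(1, 2))[ok] / wsum[ok]
    return out


def transport_decomposition(
    section: SectionSeries,
    mask: np.ndarray | None = None,
    min_coverage: float = 0.8,
) -> DecompositionResult:
    """Split the transport trend into velocity and water-mass-volume parts.

    The volume-normalised transport Tn(t) = [T(t)/A(t)] * mean(A) carries only
    velocity changes; its trend is the velocity contribution and the remainder
    of the total trend is the volume contribution.  Years with no Atlantic
    Water are excluded (transport per unit area is undefined there).
    """
    if len(section.years) < 10:
        raise ValueError("decomposition needs at least 10 years")
    m = _per_year_mask(section, mask)
    t_sv = np.where(m, section.u * section.cell_area, 0.0).sum(axis=(1, 2)) / SV
    area = np.where(m, np.broadcast_to(section.cell_area, m.shape), 0.0).sum(axis=(1, 2))
    keep = area > 0
    if keep.mean() < min_coverage:
        raise ValueError(
            f"Atlantic Water present in only {keep.mean():.0%} of years "
            f"(need >= {min_coverage:.0%})"
        )
    years = np.asarray(section.years, dtype=float)[keep]
    t_sv = t_sv[keep]
    area = area[keep]
    mean_area = area.mean()
    tn = t_sv / area * mean_area
    trend_total = decadal_trend(years, t_sv).slope_per_decade
    trend_velocity = decadal_trend(years, tn).slope_per_decade
    return DecompositionResult(
        trend_total=trend_total,
        trend_velocity=trend_velocity,
        trend_volume=trend_total - trend_velocity,
        mean_aw_area=float(mean_area),
        years_used=years,
    )


def decadal_trend(years, values) -> TrendResult:
    """OLS linear trend of an annual series, expressed per decade."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(years) < 3:
        raise ValueError("need at least 3 years for a trend")
    if np.ptp(years) == 0:
        raise ValueError("singular design: all years identical")
    tc = years - years.mean()
    sxx = np.dot(tc, tc)
    slope = np.dot(tc, values - values.mean()) / sxx
    fitted = values.mean() + slope * tc
    dof = len(years) - 2
    if dof > 0:
        sigma2 = np.sum((values - fitted) ** 2) / dof
        se = np.sqrt(sigma2 / sxx)
    else:
        se = np.nan
    return TrendResult(
        slope_per_decade=float(slope * 10.0),
        se_per_decade=float(se * 10.0),
        intercept=float(values.mean() - slope * years.mean()),
        n=len(years),
    )


def trend_map(years, cube: np.ndarray, cell_area: np.ndarray | None = None):
    """Per-cell decadal trends of a (year, ...) cube, with summaries.

    Cells containing any non-finite year are flagged (NaN trend) and excluded
    from the summaries.  Returns ``(trends, summary)`` where ``summary`` has
    the minimum, maximum and area-weighted mean trend -- the "range" and
    "mean" statistics quoted for spatial trend maps.
    """
    years = np.asarray(years, dtype=float)
    cube = np.asarray(cube, dtype=float)
    if cube.shape[0] != len(years):
        raise ValueError("cube leading dimension must match years")
    if len(years) < 3:
        raise ValueError("need at least 3 years for a trend")
    tc = years - years.mean()
    sxx = np.dot(tc, tc)
    valid = np.isfinite(cube).all(axis=0)
    anom = cube - np.nanmean(cube, axis=0)
    trends = 10.0 * np.tensordot(tc, np.nan_to_num(anom), axes=(0, 0)) / sxx
    trends = np.where(valid, trends, np.nan)
    if cell_area is None:
        weights = np.ones_like(trends)
    else:
        weights = np.broadcast_to(np.asarray(cell_area, float), trends.shape)
    w = np.where(valid, weights, 0.0)
    if w.sum() == 0:
        summary = {"min": np.nan, "max": np.nan, "mean": np.nan, "n_cells": 0}
    else:
        summary = {
            "min": float(np.nanmin(trends)),
            "max": float(np.nanmax(trends)),
            "mean": float(np.nansum(w * trends) / w.sum()),
            "n_cells": int(valid.sum()),
        }
    return trends, summary


def _upper_levels(thickness: np.ndarray, n_levels_total: int) -> np.ndarray:
    """Indices of the levels over which 'upper 100 m' means are taken.

    On a 31-level grid the first 10 levels are used literally; otherwise all
    levels whose bottom depth is <= 100 m.
    """
    thickness = np.asarray(thickness, dtype=float)
    if n_levels_total == 31:
        return np.arange(10)
    bottoms = np.cumsum(thickness)
    idx = np.nonzero(bottoms <= 100.0 + 1e-9)[0]
    if len(idx) == 0:
        idx = np.array([0])
    return idx


def regional_upper_mean(
    cube: np.ndarray,
    thickness: np.ndarray,
    region_mask: np.ndarray,
    cell_area: np.ndarray | None = None,
):
    """Upper-100 m, volume-weighted regional mean of a (year, depth, lat, lon) cube.

    Returns ``(mean_per_year, per_cell_series)`` where ``per_cell_series`` is
    the upper-100 m mean at each horizontal cell (year, lat, lon), the input
    to per-cell trend mapping.
    """
    cube = np.asarray(cube, dtype=float)
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != cube.shape[2:]:
        raise ValueError("region mask must match the horizontal grid")
    if not region_mask.any():
        raise ValueError("region mask selects no cells")
    lev = _upper_levels(thickness, cube.shape[1])
    th = np.asarray(thickness, dtype=float)[lev]
    sub = cube[:, lev]  # (year, lev, lat, lon)
    per_cell = np.tensordot(th, sub, axes=(0, 1)) / th.sum()  # (year, lat, lon)
    if cell_area is None:
        area = np.ones(cube.shape[2:])
    else:
        area = np.broadcast_to(np.asarray(cell_area, float), cube.shape[2:])
    w = np.where(region_mask, area, 0.0)
    mean = np.tensordot(per_cell, w, axes=((1, 2), (0, 1))) / w.sum()
    return mean, per_cell


def integrate_npp(
    npp_cube: np.ndarray,
    thickness: np.ndarray,
    region_mask: np.ndarray,
    cell_area: np.ndarray | None = None,
) -> np.ndarray:
    """Vertically integrated, regionally averaged primary production.

    ``npp_cube`` is volumetric production (g C m-3 yr-1) with shape
    (year, depth, lat, lon); columns are integrated over all levels with the
    layer thicknesses, then area-averaged inside the region.  Result is
    g C m-2 yr-1 per year.
    """
    npp_cube = np.asarray(npp_cube, dtype=float)
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region mask selects no cells")
    th = np.asarray(thickness, dtype=float)
    column = np.tensordot(th, npp_cube, axes=(0, 1))  # (year, lat, lon)
    if cell_area is None:
        area = np.ones(npp_cube.shape[2:])
    else:
        area = np.broadcast_to(np.asarray(cell_area, float), npp_cube.shape[2:])
    w = np.where(region_mask, area, 0.0)
    return np.tensordot(column, w, axes=((1, 2), (0, 1))) / w.sum()


def attribution_pct(
    with_series, without_series, cumulative: bool = True
) -> np.ndarray:
    """Percent increase of one run over another: 100 (with - without) / without.

    With ``cumulative=True`` the series are cumulatively summed first (the
    convention for "cumulative nitrate delivered").  Zero denominators yield
    NaN.
    """
    w = np.asarray(with_series, dtype=float)
    wo = np.asarray(without_series, dtype=float)
    if w.shape != wo.shape:
        raise ValueError("series must share a year axis")
    if cumulative:
        w = np.cumsum(w)
        wo = np.cumsum(wo)
    out = np.full(w.shape, np.nan)
    ok = wo != 0
    out[ok] = 100.0 * (w[ok] - wo[ok]) / wo[ok]
    return out
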