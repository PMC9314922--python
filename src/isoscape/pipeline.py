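"""End-to-end pipeline runner: synthetic inputs -> analyses -> manifest.

Stages run in dependency order (generators first, then the seal trend,
habitat region, forcing, box model and section diagnostics), writing their
artifacts under the configured output directory.  A manifest records the
configuration, seeds and SHA-256 hashes of every output so identical configs
reproduce byte-identical runs.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np

from . import __version__, io
from .boxmodel import BoxParams, NitrogenBoxModel
from .config import RunConfig
from .forcing import DepositionForcing, InflowScenario, deposition_timeseries
from .seal import SealTrendModel, build_records, records_to_frame
from .sections import (
    aw_mask,
    decadal_trend,
    masked_mean,
    nitrate_flux,
    transport,
    transport_decomposition,
)
from .synthetic import (
    AWCore,
    SealTruth,
    SectionSpec,
    gen_seal_dataset,
    gen_section_series,
    gen_telemetry,
)
from .telemetry import KernelUD

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    results: dict[str, dict] = {}

    dep = DepositionForcing(
        preindustrial_rate=config.forcing.preindustrial_rate,
        modern_multiple=config.forcing.modern_multiple,
        post1950_fraction=config.forcing.post1950_fraction,
        delta_dep=config.forcing.delta_dep,
    )

    if "seal" in config.stages:
        c = config.seal
        table, truth = gen_seal_dataset(
            SealTruth(
                baseline_delta=c.baseline_delta,
                slope_per_year=c.slope_per_year,
                noise_sd=c.noise_sd,
                year_range=(c.year_start, c.year_end),
                n_seals=c.n_seals,
                seed=config.seed,
            )
        )
        mpath = out / "measurements.csv"
        table.to_csv(mpath, index=False)
        records = build_records(table, qc_tolerance=c.qc_tolerance)
        rpath = out / "records.csv"
        io.write_records(records_to_frame(records), rpath)
        fit = SealTrendModel.from_records(records).fit()
        report = fit.to_dict()
        report["truth_slope_per_decade"] = truth["slope_per_decade"]
        report["n_qc_excluded"] = len(records) - fit.n
        tpath = out / "seal_trend.json"
        io.write_report(report, tpath)
        logger.info("seal stage: %d records, %d excluded by QC",
                    len(records), report["n_qc_excluded"])
        artifacts.update(measurements=mpath, records=rpath, seal_trend=tpath)
        results["seal"] = report

    if "telemetry" in config.stages:
        c = config.telemetry
        fixes, _ = gen_telemetry(
            c.n_animals, c.n_fixes, components=((1.0, 0.0, 0.0, c.sigma_km),),
            seed=config.seed + 1,
        )
        fpath = out / "fixes.csv"
        fixes.to_csv(fpath, index=False)
        ud = KernelUD(fixes, bandwidth_km=c.bandwidth_km).fit()
        region = ud.contour_region(c.isopleth)
        gpath = out / "region.geojson"
        io.write_geojson(region, gpath)
        logger.info("telemetry stage: %d fixes, region %.0f km2 in %d polygon(s)",
                    len(fixes), region.area_km2, region.n_polygons)
        artifacts.update(fixes=fpath, region=gpath)
        results["telemetry"] = {
            "area_km2": region.area_km2, "n_polygons": region.n_polygons,
        }

    if "forcing" in config.stages:
        years = np.arange(config.forcing.year_from, config.forcing.year_to + 1)
        r_a, c_a = deposition_timeseries(years, dep, anthropogenic=True)
        r_c, c_c = deposition_timeseries(years, dep, anthropogenic=False)
        import pandas as pd

        fpath = out / "forcing.csv"
        pd.DataFrame({
            "year": years,
            "deposition_anthropogenic_tg": r_a,
            "deposition_control_tg": r_c,
            "cumulative_anthropogenic_tg": c_a,
            "cumulative_control_tg": c_c,
        }).to_csv(fpath, index=False)
        artifacts["forcing"] = fpath
        results["forcing"] = {
            "rate_1850": r_a[years <= 1850][-1] if (years <= 1850).any() else None,
            "rate_final": float(r_a[-1]),
        }

    if "boxmodel" in config.stages:
        c = config.boxmodel
        model = NitrogenBoxModel(
            BoxParams(), dep, InflowScenario(),
            np.arange(c.year_from, c.year_to + 1),
        )
        paired = model.paired(window=(c.window_from, c.window_to))
        wpath = out / "boxmodel_with_deposition.csv"
        wopath = out / "boxmodel_without_deposition.csv"
        paired.with_run.to_csv(wpath)
        paired.without_run.to_csv(wopath)
        report = {
            "window": list(paired.window),
            "delta_in_trend_with": paired.delta_in_trend_with,
            "delta_in_trend_without": paired.delta_in_trend_without,
            "delta_pom_trend_with": paired.delta_pom_trend_with,
            "delta_pom_trend_without": paired.delta_pom_trend_without,
            "npp_trend_with": paired.npp_trend_with,
            "npp_trend_without": paired.npp_trend_without,
            "nitrate_attribution_pct": paired.nitrate_attribution_pct,
            "npp_attribution_pct": paired.npp_attribution_pct,
        }
        apath = out / "attribution.json"
        io.write_report(report, apath)
        artifacts.update(boxmodel_with=wpath, boxmodel_without=wopath,
                         attribution=apath)
        results["boxmodel"] = report

    if "section" in config.stages:
        c = config.section
        section, truth = gen_section_series(
            SectionSpec(
                n_depth=c.n_depth, n_lat=c.n_lat, n_years=c.n_years,
                aw_core=AWCore(u0=c.u0, u_trend=c.u_trend,
                               area_trend=c.area_trend, d15n_trend=c.d15n_trend),
            ),
            seed=config.seed + 2,
        )
        spath = out / "section.nc"
        io.write_section(section, spath)
        t_sv = transport(section)
        decomp = transport_decomposition(section)
        flux, cum = nitrate_flux(section)
        mask = aw_mask(section.theta, section.salinity)
        d15n_aw = masked_mean(section.d15n_no3, mask, section.cell_area)
        report = {
            "transport_trend_sv_per_decade": decomp.trend_total,
            "transport_trend_velocity": decomp.trend_velocity,
            "transport_trend_volume": decomp.trend_volume,
            "mean_transport_sv": float(t_sv.mean()),
            "d15n_no3_aw_trend_per_decade": decadal_trend(
                section.years, d15n_aw).slope_per_decade,
            "nitrate_flux_final_mol_s": float(flux[-1]),
            "truth_trend_total": truth["trend_total"],
            "truth_trend_velocity": truth["trend_velocity"],
            "truth_trend_volume": truth["trend_volume"],
        }
        rpath = out / "section_report.json"
        io.write_report(report, rpath)
        artifacts.update(section=spath, section_report=rpath)
        results["section"] = report

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "config": config.to_dict(),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
        "hashes": {k: _sha256(v) for k, v in artifacts.items()},
        "results": results,
    }
    io.write_report(manifest, out / "manifest.json")
    return manifest
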