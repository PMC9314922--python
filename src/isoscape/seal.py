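"""Seal-tooth delta15N_Phe records: correction, QC, chronology and trend fitting.

Compound-specific delta15N of phenylalanine in dentine growth layer groups
(GLGs) records the isotope baseline of the food web in the years the layer was
deposited.  The pipeline here turns raw replicate GC-IRMS measurements into a
year-anchored record and fits its multi-decadal linear trend:

1. *standard correction* -- each sample's replicate mean is shifted by the
   offset between the nearest bracketing mixed amino-acid standard's measured
   and certified values;
2. *replicate QC* -- duplicates agreeing within 1.0 permil pass; disagreeing
   duplicates require a third replicate (flag ``triplicated``) or are excluded
   (flag ``fail``);
3. *chronology* -- the combined second+third GLGs of an animal caught in year
   c at age a span calendar years [c - a + 1, c - a + 2]; the window midpoint
   is the regression abscissa;
4. *trend* -- ordinary least squares of delta15N_Phe on midpoint year, with
   residual diagnostics (normality, homoscedasticity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "SealRecord",
    "SealTrendModel",
    "SealTrendResults",
    "ResidualDiagnostics",
    "correct_delta",
    "qc_replicates",
    "assign_glg_years",
    "assign_nearest_standards",
    "build_records",
]

QC_PASS = "pass"
QC_TRIPLICATED = "triplicated"
QC_FAIL = "fail"

MIN_AGE_YEARS = 5


def correct_delta(sample_replicates, standard_measured: float,
                  standard_known: float) -> float:
    """Standard-offset correction of a sample's replicate delta15N values.

    reported = mean(replicates) - (standard_measured - standard_known),
    i.e. the instrument drift estimated from the nearest mixed standard is
    removed from the replicate mean.
    """
    reps = np.asarray(sample_replicates, dtype=float)
    if reps.size == 0:
        raise ValueError("at least one replicate value is required")
    if not np.all(np.isfinite(reps)) or not np.isfinite(standard_measured) \
            or not np.isfinite(standard_known):
        raise ValueError("all delta values must be finite")
    return float(reps.mean() - (standard_measured - standard_known))


def assign_nearest_standards(sample_positions, standard_positions) -> np.ndarray:
    """Index of the nearest standard injection for each sample injection.

    Positions are injection sequence numbers (standards run every few
    injections bracket the samples).  Ties go to the earlier standard.
    """
    samples = np.asarray(sample_positions, dtype=float)
    standards = np.asarray(standard_positions, dtype=float)
    if standards.size == 0:
        raise ValueError("no standard injections supplied")
    dist = np.abs(samples[:, None] - standards[None, :])
    return np.argmin(dist, axis=1)


def qc_replicates(replicates, tolerance: float = 1.0):
    """Replicate-agreement QC.

    Duplicates whose range is within ``tolerance`` pass with the mean as the
    final value.  A wider spread requires a third replicate, in which case the
    mean of all replicates is reported with flag ``triplicated``; without one
    the sample fails QC (it is excluded from trend fitting by default).
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 2:
        raise ValueError("QC requires at least two replicates")
    if not np.all(np.isfinite(reps)):
        raise ValueError("replicate values must be finite")
    spread = float(np.ptp(reps))
    if spread <= tolerance:
        return float(reps.mean()), QC_PASS
    if reps.size >= 3:
        return float(reps.mean()), QC_TRIPLICATED
    return float(reps.mean()), QC_FAIL


def assign_glg_years(catch_year: int, age_years: int, min_age: int = MIN_AGE_YEARS):
    """Calendar years covered by the combined 2nd+3rd growth layer groups.

    Each GLG records one year of life, so an animal born in year
    ``catch_year - age_years`` laid down its second and third GLGs in
    ``[birth + 1, birth + 2]``.  Animals younger than ``min_age`` are rejected
    (their outermost layers are incomplete).
    Returns ``((year_start, year_end), midpoint)``.
    """
    if age_years < min_age:
        raise ValueError(
            f"age {age_years} below the minimum of {min_age} years; record excluded"
        )
    if catch_year < age_years:
        raise ValueError("catch year inconsistent with age")
    birth = catch_year - age_years
    window = (birth + 1, birth + 2)
    return window, (window[0] + window[1]) / 2.0


@dataclass
class SealRecord:
    """One animal's corrected, QC'd delta15N_Phe value anchored in time."""

    seal_id: str
    catch_year: int
    age_years: int
    glg_window: tuple[int, int]
    midpoint_year: float
    reported_d15n_phe: float
    qc_flag: str

    @property
    def passes_qc(self) -> bool:
        return self.qc_flag in (QC_PASS, QC_TRIPLICATED)


def build_records(
    measurements: pd.DataFrame,
    qc_tolerance: float = 1.0,
    min_age: int = MIN_AGE_YEARS,
    amino_acid: str = "phenylalanine",
) -> list[SealRecord]:
    """Assemble per-seal records from a tidy replicate measurement table.

    Expected columns: seal_id, amino_acid, replicate_index, d15n_measured,
    standard_measured, standard_known, catch_year, age_years.  Each replicate
    is corrected against its own nearest standard, then replicate QC is
    applied to the corrected values.  Underage animals are dropped.
    """
    required = {
        "seal_id", "amino_acid", "replicate_index", "d15n_measured",
        "standard_measured", "standard_known", "catch_year", "age_years",
    }
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    rows = measurements[measurements["amino_acid"] == amino_acid]
    records: list[SealRecord] = []
    for seal_id, grp in rows.groupby("seal_id", sort=True):
        corrected = [
            correct_delta([r.d15n_measured], r.standard_measured, r.standard_known)
            for r in grp.itertuples()
        ]
        final, flag = qc_replicates(corrected, tolerance=qc_tolerance)
        catch_year = int(grp["catch_year"].iloc[0])
        age_years = int(grp["age_years"].iloc[0])
        try:
            window, midpoint = assign_glg_years(catch_year, age_years, min_age)
        except ValueError:
            continue
        records.append(
            SealRecord(
                seal_id=str(seal_id),
                catch_year=catch_year,
                age_years=age_years,
                glg_window=window,
                midpoint_year=midpoint,
                reported_d15n_phe=final,
                qc_flag=flag,
            )
        )
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seal_id": [r.seal_id for r in records],
            "catch_year": [r.catch_year for r in records],
            "age_years": [r.age_years for r in records],
            "glg_start": [r.glg_window[0] for r in records],
            "glg_end": [r.glg_window[1] for r in records],
            "midpoint_year": [r.midpoint_year for r in records],
            "d15n_phe": [r.reported_d15n_phe for r in records],
            "qc_flag": [r.qc_flag for r in records],
        }
    )


@dataclass
class ResidualDiagnostics:
    """Numeric residual diagnostics plus the data series behind the plots."""

    shapiro_stat: float
    shapiro_p: float
    normality_flag: str
    bp_stat: float
    bp_p: float
    heteroscedasticity_flag: str
    reliable: bool
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)
    years: np.ndarray = field(repr=False, default=None)
    qq_theoretical: np.ndarray = field(repr=False, default=None)
    qq_sample: np.ndarray = field(repr=False, default=None)


class SealTrendResults:
    """OLS results for the delta15N_Phe-on-year model."""

    def __init__(self, sm_results, years: np.ndarray, values: np.ndarray):
        self._res = sm_results
        self.years = years
        self.values = values

    @property
    def slope_per_year(self) -> float:
        return float(self._res.params[1])

    @property
    def slope_per_decade(self) -> float:
        return 10.0 * self.slope_per_year

    @property
    def slope_se(self) -> float:
        return float(self._res.bse[1])

    @property
    def slope_se_per_decade(self) -> float:
        return 10.0 * self.slope_se

    @property
    def intercept(self) -> float:
        return float(self._res.params[0])

    @property
    def _centered_tss(self) -> float:
        return float(np.sum((self.values - self.values.mean()) ** 2))

    @property
    def r_squared(self) -> float:
        # a constant response carries no variance to explain
        if self._centered_tss == 0.0:
            return 0.0
        return float(self._res.rsquared)

    @property
    def r_squared_pct(self) -> float:
        return 100.0 * self.r_squared

    @property
    def f_statistic(self) -> float:
        if self._centered_tss == 0.0:
            return 0.0
        return float(self._res.fvalue)

    @property
    def p_value(self) -> float:
        if self._centered_tss == 0.0:
            return 1.0
        return float(self._res.pvalues[1])

    @property
    def df_resid(self) -> int:
        return int(self._res.df_resid)

    @property
    def n(self) -> int:
        return int(self._res.nobs)

    @property
    def residuals(self) -> np.ndarray:
        return np.asarray(self._res.resid)

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self._res.fittedvalues)

    def slope_conf_int(self, alpha: float = 0.05):
        lo, hi = self._res.conf_int(alpha)[1]
        return float(lo), float(hi)

    def predict(self, years) -> np.ndarray:
        years = np.asarray(years, dtype=float)
        return self.intercept + self.slope_per_year * years

    def diagnostics(self, alpha: float = 0.01) -> ResidualDiagnostics:
        """Normality (Shapiro-Wilk) and heteroscedasticity (Breusch-Pagan) checks.

        Flags are ``pass`` when the null (normal / homoscedastic residuals) is
        not rejected at ``alpha``, ``warn`` otherwise.  With fewer than 8
        observations the diagnostics are marked unreliable.
        """
        resid = self.residuals
        if np.allclose(resid, 0.0):
            qq_t, qq_s = scipy.stats.probplot(resid, dist="norm")[0]
            return ResidualDiagnostics(
                shapiro_stat=1.0, shapiro_p=1.0, normality_flag="pass",
                bp_stat=0.0, bp_p=1.0, heteroscedasticity_flag="pass",
                reliable=self.n >= 8, fitted=self.fittedvalues, residuals=resid,
                years=self.years, qq_theoretical=qq_t, qq_sample=qq_s,
            )
        sw_stat, sw_p = scipy.stats.shapiro(resid)
        exog = sm.add_constant(self.years)
        bp_stat, bp_p, _, _ = het_breuschpagan(resid, exog)
        (qq_t, qq_s), _ = scipy.stats.probplot(resid, dist="norm")
        return ResidualDiagnostics(
            shapiro_stat=float(sw_stat),
            shapiro_p=float(sw_p),
            normality_flag="pass" if sw_p > alpha else "warn",
            bp_stat=float(bp_stat),
            bp_p=float(bp_p),
            heteroscedasticity_flag="pass" if bp_p > alpha else "warn",
            reliable=self.n >= 8,
            fitted=self.fittedvalues,
            residuals=resid,
            years=self.years,
            qq_theoretical=qq_t,
            qq_sample=qq_s,
        )

    def plot_diagnostics(self, path=None):
        """Three-panel residual plot (vs fitted, vs year, QQ); convenience only."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        d = self.diagnostics()
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        axes[0].scatter(d.fitted, d.residuals, s=12)
        axes[0].axhline(0, color="grey", lw=0.8)
        axes[0].set(xlabel="fitted", ylabel="residual")
        axes[1].scatter(d.years, d.residuals, s=12)
        axes[1].axhline(0, color="grey", lw=0.8)
        axes[1].set(xlabel="year", ylabel="residual")
        axes[2].scatter(d.qq_theoretical, d.qq_sample, s=12)
        axes[2].set(xlabel="theoretical quantile", ylabel="sample quantile")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def summary(self) -> str:
        lines = [
            "delta15N_Phe linear trend (OLS on GLG midpoint year)",
            f"  n              : {self.n}",
            f"  slope          : {self.slope_per_year:+.4f} permil/yr "
            f"({self.slope_per_decade:+.3f} permil/decade, "
            f"se {self.slope_se_per_decade:.3f})",
            f"  intercept      : {self.intercept:.3f} permil",
            f"  R-squared      : {self.r_squared:.3f} ({self.r_squared_pct:.1f}%)",
            f"  F-statistic    : {self.f_statistic:.1f} on 1 and {self.df_resid} df",
            f"  p-value        : {self.p_value:.2e}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "slope_per_year": self.slope_per_year,
            "slope_per_decade": self.slope_per_decade,
            "slope_se_per_decade": self.slope_se_per_decade,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "r_squared_pct": self.r_squared_pct,
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
            "df_resid": self.df_resid,
        }


class SealTrendModel:
    """Linear model of delta15N_Phe as a function of (midpoint) year.

    Gaussian errors, identity link, no transformation of the data.  Construct
    from explicit arrays, from QC'd :class:`SealRecord` objects, or from a raw
    replicate measurement table.
    """

    def __init__(self, years, values):
        years = np.asarray(years, dtype=float)
        values = np.asarray(values, dtype=float)
        if len(years) != len(values):
            raise ValueError("years and values must have equal length")
        if len(years) < 3:
            raise ValueError("trend fitting needs at least 3 records")
        if np.ptp(years) == 0:
            raise ValueError("singular design: all years identical")
        self.years = years
        self.values = values

    @classmethod
    def from_records(cls, records, include_failed: bool = False,
                     abscissa: str = "midpoint") -> "SealTrendModel":
        """Build from SealRecords; QC failures excluded unless requested.

        ``abscissa`` selects the regression year: ``midpoint`` (default),
        ``start`` (first GLG year) or ``catch`` (catch year).
        """
        kept = [r for r in records if include_failed or r.passes_qc]
        if abscissa == "midpoint":
            years = [r.midpoint_year for r in kept]
        elif abscissa == "start":
            years = [r.glg_window[0] for r in kept]
        elif abscissa == "catch":
            years = [r.catch_year for r in kept]
        else:
            raise ValueError(f"unknown abscissa {abscissa!r}")
        return cls(years, [r.reported_d15n_phe for r in kept])

    @classmethod
    def from_measurements(cls, measurements: pd.DataFrame,
                          qc_tolerance: float = 1.0, **kwargs) -> "SealTrendModel":
        return cls.from_records(
            build_records(measurements, qc_tolerance=qc_tolerance), **kwargs
        )

    def fit(self) -> SealTrendResults:
        exog = sm.add_constant(self.years)
        res = sm.OLS(self.values, exog).fit()
        return SealTrendResults(res, self.years, self.values)
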