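"""Atmospheric reactive-nitrogen deposition forcing and Atlantic-inflow scenarios.

Historical deposition of reactive nitrogen (Nr) to the ocean is represented as a
piecewise-linear ramp: a constant preindustrial rate up to 1850, then linear
segments through anchor years 1850, 1950, 2000 and 2030, constructed so that 60%
of the 1850-2000 increase occurs after 1950 (the post-war acceleration of fossil
fuel burning and fertilizer use).  The control (non-anthropogenic) series holds
the preindustrial rate throughout.  Deposited nitrogen carries a fixed, light
isotope signature (default -4 permil vs air N2).

The inflow scenario describes Atlantic Water entering the Barents Sea: volume
transport Q(t), its nitrate concentration, and the subpolar/subtropical
endmember mix that sets the inflow delta15N_NO3 before deposition acts on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "DepositionForcing",
    "InflowScenario",
    "deposition_rate",
    "deposition_timeseries",
    "endmember_delta",
]

#: grams of N per teragram divided by molar mass of N -> mol N per Tg N
MOL_PER_TG_N = 1.0e12 / 14.007

YEAR_MIN = 1648
YEAR_MAX = 2030


@dataclass(frozen=True)
class DepositionForcing:
    """Global Nr deposition ramp and its isotopic signature.

    Parameters
    ----------
    preindustrial_rate : float
        Global deposition for all years <= 1850, Tg N yr-1.
    modern_multiple : float
        Ratio of the year-2000 rate to the preindustrial rate.  The year-2000
        and year-2030 magnitudes are not constrained by the printed record and
        are configuration defaults, not literature values.
    rate_2030_factor : float
        Year-2030 rate as a multiple of the year-2000 rate.
    post1950_fraction : float
        Fraction of the 1850-2000 rate increase occurring after 1950.
    delta_dep : float
        delta15N of deposited nitrogen, permil.
    regional_scaling_atlantic, regional_scaling_barents : float
        Fractions of the *global* Tg flux deposited on the Atlantic source box
        and directly on the Barents surface box of the box model.  Demonstration
        values; see docs/methods.md for the calibration rationale.
    """

    preindustrial_rate: float = 11.0
    modern_multiple: float = 2.5
    rate_2030_factor: float = 1.08
    post1950_fraction: float = 0.60
    delta_dep: float = -4.0
    regional_scaling_atlantic: float = 0.08
    regional_scaling_barents: float = 0.02

    def __post_init__(self) -> None:
        if self.preindustrial_rate <= 0:
            raise ValueError("preindustrial_rate must be positive")
        if not 0.0 <= self.post1950_fraction <= 1.0:
            raise ValueError("post1950_fraction must lie in [0, 1]")
        if self.modern_multiple < 1.0:
            raise ValueError("modern_multiple must be >= 1 (rate non-decreasing)")

    @property
    def rate_2000(self) -> float:
        return self.modern_multiple * self.preindustrial_rate

    @property
    def rate_1950(self) -> float:
        # 60% of the 1850-2000 increase after 1950 <=> 40% accrued by 1950.
        return self.preindustrial_rate + (1.0 - self.post1950_fraction) * (
            self.rate_2000 - self.preindustrial_rate
        )

    @property
    def rate_2030(self) -> float:
        return self.rate_2030_factor * self.rate_2000


def deposition_rate(
    year: float, forcing: DepositionForcing, anthropogenic: bool
) -> float:
    """Global Nr deposition rate (Tg N yr-1) at ``year``.

    The control series (``anthropogenic=False``) is the constant preindustrial
    rate.  The anthropogenic series is piecewise linear with kinks at 1850,
    1950 and 2000 only.
    """
    year = float(year)
    if not YEAR_MIN <= year <= YEAR_MAX:
        raise ValueError(f"year {year} outside supported range [{YEAR_MIN}, {YEAR_MAX}]")
    if not anthropogenic or year <= 1850.0:
        return forcing.preindustrial_rate
    xp = [1850.0, 1950.0, 2000.0, 2030.0]
    fp = [
        forcing.preindustrial_rate,
        forcing.rate_1950,
        forcing.rate_2000,
        forcing.rate_2030,
    ]
    return float(np.interp(year, xp, fp))


def deposition_timeseries(
    years, forcing: DepositionForcing, anthropogenic: bool
):
    """Vectorised deposition rates plus cumulative deposited mass.

    Returns
    -------
    rates : ndarray, Tg N yr-1
    cumulative : ndarray, Tg N
        Trapezoidal integral of the rate from the first year; ``cumulative[0]``
        is zero.
    """
    years = np.asarray(years, dtype=float)
    if years.ndim != 1 or len(years) == 0:
        raise ValueError("years must be a non-empty 1-D sequence")
    if np.any(np.diff(years) <= 0):
        raise ValueError("years must be strictly increasing")
    rates = np.array(
        [deposition_rate(y, forcing, anthropogenic) for y in years]
    )
    cumulative = np.concatenate(
        [[0.0], cumulative_trapezoid(rates, years)]
    ) if len(years) > 1 else np.zeros(1)
    return rates, cumulative


@dataclass(frozen=True)
class InflowScenario:
    """Atlantic Water inflow to the Barents Sea and its endmember mix.

    Transport and the subtropical fraction evolve linearly about ``ref_year``;
    the transport trend default (+0.009 Sv yr-1, i.e. +0.09 Sv decade-1)
    matches the simulated multi-decadal strengthening of the inflow.
    Endmember delta15N_NO3 defaults (subpolar 5.0, subtropical 3.5 permil) are
    literature-style values, exposed as configuration.
    """

    q0_sv: float = 2.0
    q_trend_sv_per_year: float = 0.009
    no3_in: float = 6.0  # mmol m-3, inflow nitrate concentration
    f_subtropical0: float = 0.30
    f_subtropical_trend: float = 0.002  # fraction yr-1
    delta_subpolar: float = 5.0
    delta_subtropical: float = 3.5
    ref_year: float = 1970.0

    def __post_init__(self) -> None:
        if self.delta_subtropical >= self.delta_subpolar:
            raise ValueError("subtropical endmember must be lighter than subpolar")
        if not 0.0 <= self.f_subtropical0 <= 1.0:
            raise ValueError("f_subtropical0 must lie in [0, 1]")

    def transport_sv(self, year: float) -> float:
        q = self.q0_sv + self.q_trend_sv_per_year * (year - self.ref_year)
        if q <= 0:
            raise ValueError(f"scenario transport non-positive at year {year}")
        return q

    def f_subtropical(self, year: float) -> float:
        f = self.f_subtropical0 + self.f_subtropical_trend * (year - self.ref_year)
        return float(np.clip(f, 0.0, 1.0))


def endmember_delta(
    year: float,
    scenario: InflowScenario,
    no3_subpolar: float | None = None,
    no3_subtropical: float | None = None,
) -> float:
    """delta15N_NO3 of the inflow as a two-endmember mixture.

    Equal nitrate concentrations in both endmembers by default, in which case
    the mixture is linear in the volume fraction.  If concentrations are
    supplied the mixture is nitrate-weighted.
    """
    f = scenario.f_subtropical(year)
    if no3_subpolar is None and no3_subtropical is None:
        return (1.0 - f) * scenario.delta_subpolar + f * scenario.delta_subtropical
    c_sp = scenario.no3_in if no3_subpolar is None else no3_subpolar
    c_st = scenario.no3_in if no3_subtropical is None else no3_subtropical
    w_sp = (1.0 - f) * c_sp
    w_st = f * c_st
    return (w_sp * scenario.delta_subpolar + w_st * scenario.delta_subtropical) / (
        w_sp + w_st
    )
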