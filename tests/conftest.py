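import numpy as np
import pytest

from isoscape.boxmodel import demo_model
from isoscape.synthetic import SealTruth, gen_seal_dataset, gen_telemetry
from isoscape.telemetry import KernelUD


@pytest.fixture(scope="session")
def paired_demo():
    """Paired with/without-deposition run of the documented demo scenario."""
    return demo_model().paired()


@pytest.fixture(scope="session")
def study_condition_table():
    """Synthetic measurement table at the archived-record conditions."""
    return gen_seal_dataset(SealTruth(seed=0))


@pytest.fixture(scope="session")
def single_gaussian_ud():
    """Fitted 250-km kernel UD on 2000 fixes from one isotropic Gaussian.

    Returns (ud_results, truth, sigma_km).
    """
    sigma = 100.0
    fixes, truth = gen_telemetry(
        15, 2000, components=((1.0, 0.0, 0.0, sigma),), seed=7
    )
    ud = KernelUD(fixes, bandwidth_km=250.0).fit()
    return ud, truth, sigma


def smoothed_mass_in_region(ud, truth, bandwidth_km, p=0.95):
    """Grid integral of the analytic smoothed mixture over the p-region."""
    from isoscape.telemetry import unproject_locations

    region = ud.contour_region(p)
    xx, yy = np.meshgrid(ud.x_centers, ud.y_centers)
    lon, lat = unproject_locations(xx.ravel(), yy.ravel(), ud.lon0, ud.lat0)
    dens = truth.smoothed_density_lonlat(bandwidth_km)(lon, lat).reshape(xx.shape)
    inside = ud.density >= region.threshold
    return float(np.where(inside, dens, 0.0).sum() * ud.cell_area_km2), region
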