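import numpy as np
import pytest

from seasurv.prep import MonthlySeries
from seasurv.synthetic import SiteSpec, simulate_site


@pytest.fixture
def make_series():
    """Factory for a MonthlySeries from a plain count list."""

    def _make(counts, start=(2000, 1), site_id="s1", latitude=40.0):
        return MonthlySeries(site_id, latitude, start[0], start[1], np.asarray(counts, float))

    return _make


@pytest.fixture
def seasonal_site():
    """Factory for a flat-trend seasonal Poisson site."""

    def _make(amplitude, peak=2, c0=50.0, n_months=240, seed=0, site_id="sim", ramp=0):
        spec = SiteSpec(
            site_id=site_id,
            latitude=40.0,
            start_year=2000,
            start_month=1,
            n_months=n_months,
            trend_coeffs=(c0, 0.0, 0.0),
            amplitude=amplitude,
            peak_month=peak,
            ramp_months=ramp,
            seed=seed,
        )
        return simulate_site(spec)

    return _make
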