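import math

import pytest

from csbench import default_profiles, literature_bands, mnhr_site_summaries


@pytest.fixture(scope="session")
def site_summaries():
    """The seven bundled MNHR site summaries."""
    return mnhr_site_summaries()


@pytest.fixture(scope="session")
def summaries_by_id(site_summaries):
    return {s.site_id: s for s in site_summaries}


@pytest.fixture(scope="session")
def bands():
    """The bundled literature-review reference bands."""
    return literature_bands()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


def percentile_oracle(values, level):
    """Independent sort-and-interpolate percentile: k-th of n at (k-1)/(n-1)."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return xs[0]
    pos = level * (n - 1)
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return xs[lo] * (1.0 - frac) + xs[hi] * frac
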