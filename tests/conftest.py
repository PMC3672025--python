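import numpy as np
import pytest

from nextpeak.model import GlobalShape
from nextpeak.simulate import SimulationSpec, simulate_region


@pytest.fixture
def shape():
    return GlobalShape(sigma=40.0, beta=60.0)


def make_region(seed, mu=250.0, nu=200.0, rho=0.1, width=500, sigma=40.0, beta=60.0, **kw):
    spec = SimulationSpec(
        mu=mu, nu=nu, sigma=sigma, beta=beta, rho=rho, width=width, seed=seed, **kw
    )
    return simulate_region(spec)[0]


def brute_force_regions(positions, window, min_count, chrom="chr1"):
    """Independent region-selection oracle: enumerate every tiling window,
    mark qualifying ones on a boolean coverage array, read off connected
    runs."""
    positions = np.sort(np.asarray(positions))
    if positions.size == 0:
        return []
    hi = int(positions.max()) + window
    covered = np.zeros(hi + window + 2, dtype=bool)  # index = 1-based position
    for start in range(1, hi + 1, window):
        count = int(np.sum((positions >= start) & (positions <= start + window - 1)))
        if count >= min_count:
            covered[start : start + window] = True
    regions = []
    in_run = False
    for i in range(1, covered.size):
        if covered[i] and not in_run:
            start, in_run = i, True
        elif not covered[i] and in_run:
            end, in_run = i - 1, False
            total = int(np.sum((positions >= start) & (positions <= end)))
            regions.append((chrom, start, end, total))
    return regions
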