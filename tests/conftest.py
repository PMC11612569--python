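import numpy as np
import pytest

from habiquant import (
    Grid,
    HQConfig,
    LandUseLegend,
    ThreatSpec,
    default_parameter_tables,
)
from habiquant.raster_io import LegendEntry


@pytest.fixture(scope="session")
def default_tables():
    return default_parameter_tables()


@pytest.fixture
def mini_legend():
    """Two-threat toy legend: forest (code 1) and urban (code 2)."""
    return LandUseLegend(
        {
            1: LegendEntry(1, "forest", 0.9, {"urban": 0.5, "farm": 0.3}),
            2: LegendEntry(2, "urban", 0.0, {"urban": 0.0, "farm": 0.0}),
            3: LegendEntry(3, "farm", 0.4, {"urban": 0.4, "farm": 0.6}),
        }
    )


@pytest.fixture
def mini_threats():
    return [
        ThreatSpec("urban", frozenset({2}), d_rmax=2.0, weight=0.9, decay="exponential"),
        ThreatSpec("farm", frozenset({3}), d_rmax=3.0, weight=0.6, decay="linear"),
    ]


def brute_force_degradation(lu, threats, legend, config=None):
    """Reference quadruple loop over (cell x, source y, threat r) — Eq.-level oracle."""
    config = config or HQConfig()
    total_w = sum(t.weight for t in threats)
    beta = config.beta_array(lu)
    nrows, ncols = lu.values.shape
    valid = lu.valid_mask
    out = np.zeros((nrows, ncols))
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                out[r, c] = lu.nodata
                continue
            code = int(lu.values[r, c])
            acc = 0.0
            for threat in threats:
                s = legend.sensitivity(code, threat.name)
                for rr in range(nrows):
                    for cc in range(ncols):
                        if not valid[rr, cc]:
                            continue
                        if int(lu.values[rr, cc]) not in threat.source_codes:
                            continue
                        d = np.hypot(r - rr, c - cc) * lu.cell_size
                        if d > threat.d_rmax:
                            continue
                        if threat.decay == "linear":
                            i = max(0.0, 1.0 - d / threat.d_rmax)
                        else:
                            i = np.exp(-2.99 * d / threat.d_rmax)
                        acc += (threat.weight / total_w) * i * beta[r, c] * s
            out[r, c] = acc
    return Grid(out, cell_size=lu.cell_size, nodata=lu.nodata)


def brute_force_morans_i(values, mask, scheme="queen", row_standardized=True):
    """Reference double sum over all cell pairs."""
    cells = [(r, c) for r in range(mask.shape[0]) for c in range(mask.shape[1]) if mask[r, c]]
    n = len(cells)
    x = np.array([values[r, c] for r, c in cells])
    z = x - x.mean()

    def adjacent(a, b):
        dr, dc = abs(a[0] - b[0]), abs(a[1] - b[1])
        if scheme == "rook":
            return dr + dc == 1
        return max(dr, dc) == 1

    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and adjacent(cells[i], cells[j]):
                w[i, j] = 1.0
    if row_standardized:
        deg = w.sum(axis=1)
        deg[deg == 0] = 1.0
        w = w / deg[:, None]
    s0 = w.sum()
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / s0) * num / (z @ z)
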