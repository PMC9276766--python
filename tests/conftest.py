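"""Shared fixtures: expensive simulations and synthetic assays built once."""

import numpy as np
import pytest

import tissellate as tl


@pytest.fixture(scope="session")
def unequal_circles():
    """Size-mismatched circle pair run to a full tessellation.

    Boundary oracle: arrival-time equality d1 - R1 = d2 - R2 puts the fused
    boundary on the hyperbola branch d1 - d2 = R1 - R2 curving away from
    the larger circle.
    """
    scene = tl.Scene(
        tissues=[
            tl.TissueSeed(1, tl.Circle((600, 1200), 500)),
            tl.TissueSeed(2, tl.Circle((2600, 1200), 250)),
        ],
        world_extent=(3400, 2400),
    )
    movie = tl.simulate(scene, t_end=60, dt=1 / 3, spacing=10)
    return scene, movie


@pytest.fixture(scope="session")
def engulfment_movie():
    """Fast strip vs 6x-slower circle: the fast tissue engulfs the slow one."""
    scene = tl.Scene(
        tissues=[
            tl.TissueSeed(1, tl.Rectangle((300, 1000), 400, 1900), speed=29.5),
            tl.TissueSeed(2, tl.Circle((1100, 1000), 200), speed=29.5 / 6),
        ],
        world_extent=(2000, 2000),
    )
    return tl.simulate(scene, t_end=50, dt=0.5, spacing=20)


@pytest.fixture(scope="session")
def free_circle_movie():
    """Freely expanding circle at the default normal speed (calibration)."""
    scene = tl.Scene(
        tissues=[tl.TissueSeed(1, tl.Circle((850, 850), 500))],
        world_extent=(1700, 1700),
    )
    return tl.simulate(scene, t_end=10, dt=1 / 3, spacing=10)


@pytest.fixture(scope="session")
def synth_default():
    """Default noisy density-mismatch assay (2600 vs 1800 cells/mm^2)."""
    return tl.synth_collision(tl.SynthSpec.density_mismatch(seed=1234))


@pytest.fixture(scope="session")
def synth_assays():
    """Three noisy assays spanning a range of density mismatches."""
    mismatches = [(2600.0, 1800.0), (3000.0, 1500.0), (2400.0, 2000.0)]
    out = []
    for i, (ra, rb) in enumerate(mismatches):
        spec = tl.SynthSpec.density_mismatch(rho_a=ra, rho_b=rb, seed=11 + i)
        out.append(tl.synth_collision(spec))
    return out


def assay_pair(result, window=(20.0, 36.0)):
    """(mean density gradient, boundary velocity) of one synthetic assay."""
    trace = tl.boundary_trace_from_labels(result.movie, 1, 2)
    v_b = tl.boundary_velocity(trace, window=window)
    grads = tl.density_gradient_series(result.density, trace)
    sel = (result.density.t_h >= window[0]) & (result.density.t_h <= window[1])
    return float(np.nanmean(grads[sel])), v_b
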