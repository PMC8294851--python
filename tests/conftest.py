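import numpy as np
import pytest

from fusepore import synthdata as sd


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def default_params():
    return sd.GeneratorParams(seed=11)


@pytest.fixture(scope="session")
def short_patch_params():
    """2-minute patches at elevated nucleation for fast round trips."""
    return sd.GeneratorParams(patch_duration=2.0, nucleation_rate=2.0, seed=11)


@pytest.fixture(scope="session")
def burst_ensemble(default_params, rng):
    """10^4 simulated bursts for distributional checks."""
    law = sd.HillLaw()
    return [
        sd.simulate_burst(default_params, law, calcium=100.0, rng=rng)
        for _ in range(10_000)
    ]


@pytest.fixture(scope="session")
def catenoid_solution():
    """Minimal-surface limit: vanishing tension, hinged edge placed at the
    catenoid mouth, solver started from the analytic catenoid.

    Returns ``(shape, tight_bend_energy)`` where the second value is the
    bending energy of the competing tight-bend profile family, for scale.
    """
    from fusepore.lever.membrane import (
        MembraneParams,
        ScaffoldParams,
        _ShapeProblem,
        solve_shape,
    )

    c, h = 3.0, 6.0
    z0 = h / 2
    x_mouth = float(c * np.cosh(h / (2 * c)))
    mem = MembraneParams(kappa=1.0, gamma=1e-6)
    scaf = ScaffoldParams(
        disc_radius=x_mouth, edge_condition="elastic_ring", ring_stretch_modulus=0.0
    )
    prob = _ShapeProblem(c, h, mem, scaf, m=6, nq=61)
    tt = prob.tt
    # upper catenoid branch: mouth (z = h) down to the waist
    uu = np.linspace(h / (2 * c), 0, 500)
    x1, z1 = c * np.cosh(uu), z0 + c * uu
    dx, dz = np.gradient(x1), np.gradient(z1)
    ds = np.hypot(dx, dz)
    s = np.cumsum(ds) - ds[0]
    phi1 = np.arctan2(-dz / ds, -dx / ds)
    L1 = s[-1]
    phi1_t = np.interp(tt * L1, s, phi1)
    # lower branch to z = 0.8, then a smooth cosine blend onto the plane
    uu2 = np.linspace(0, (z0 - 0.8) / c, 400)
    x2, z2 = c * np.cosh(uu2), z0 - c * uu2
    xb = np.linspace(x2[-1], x2[-1] + 5.0, 300)
    zb = 0.8 * 0.5 * (1 + np.cos(np.pi * (xb - xb[0]) / 5.0))
    x2 = np.r_[x2, xb[1:], np.linspace(xb[-1], 14.0, 100)[1:]]
    z2 = np.r_[z2, zb[1:], np.zeros(99)]
    dx2, dz2 = np.gradient(x2), np.gradient(z2)
    ds2 = np.hypot(dx2, dz2)
    s2 = np.cumsum(ds2) - ds2[0]
    phi2 = np.arctan2(-dz2 / ds2, -dx2 / ds2) % (2 * np.pi)
    L2 = s2[-1]
    phi2_t = np.interp(tt * L2, s2, phi2)
    m = prob.m
    u0 = np.zeros(2 * m + 3)
    base1 = phi1_t[0] + (np.pi / 2 - phi1_t[0]) * tt
    u0[:m], *_ = np.linalg.lstsq(prob.sinbasis, phi1_t - base1, rcond=None)
    u0[m : 2 * m], *_ = np.linalg.lstsq(
        prob.sinbasis, phi2_t - (np.pi / 2 + (np.pi / 2) * tt), rcond=None
    )
    u0[2 * m], u0[2 * m + 1] = L1, L2
    u0[2 * m + 2] = phi1_t[0]
    shape = solve_shape(c, h, mem, scaf, m=6, nq=61, x0=u0, maxiter=600)
    tight = solve_shape(c, h, mem, scaf, m=6, nq=61, maxiter=600)
    return shape, tight.bending_energy


@pytest.fixture(scope="session")
def lever_model():
    """The calibrated lever model with its landscape computed once.

    Uses a slightly coarsened grid (0.1 nm radius, 0.5 nm height) so the
    whole suite stays fast; acceptance-level checks on the default grid
    live in the acceptance script.
    """
    from fusepore.lever import default_model

    model = default_model(
        r_grid=np.round(np.arange(0.3, 4.001, 0.1), 3),
        h_grid=np.round(np.arange(5.0, 16.01, 0.5), 3),
    )
    model.landscape  # force the scan here so failures surface early
    return model
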