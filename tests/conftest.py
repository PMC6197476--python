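"""Shared fixtures: the toy world, generated once per session."""

import numpy as np
import pandas as pd
import pytest

import absaxs as ax
from absaxs.tamc import Ensemble


@pytest.fixture(scope="session")
def toy_cfg():
    return ax.ToyBuildConfig()


@pytest.fixture(scope="session")
def antibody(toy_cfg):
    return ax.make_toy_antibody(toy_cfg)


@pytest.fixture(scope="session")
def antigen(toy_cfg):
    return ax.make_toy_tetramer(toy_cfg)


@pytest.fixture(scope="session")
def fab(toy_cfg):
    return ax.make_toy_fab(toy_cfg)


@pytest.fixture(scope="session")
def filters():
    return ax.AssemblyFilters()


@pytest.fixture(scope="session")
def pose(fab, antigen):
    return ax.make_docked_pose(fab, antigen, "sub1", gap=4.0, seed=7)


@pytest.fixture(scope="session")
def antibody_ensemble(antibody):
    cfg = ax.TamcConfig(
        pivots=antibody.meta["default_pivots"], n_accept=8, max_step=30.0, seed=1
    )
    return ax.tamc_sample(antibody, cfg)


@pytest.fixture(scope="session")
def pose_ensemble(fab, antigen):
    members = [
        ax.make_docked_pose(fab, antigen, f"sub{(i % 4) + 1}", gap=4.0, seed=100 + i)
        for i in range(32)
    ]
    return Ensemble(members, pd.DataFrame({"member": range(len(members))}), {})


@pytest.fixture(scope="session")
def block_ensemble(pose_ensemble, filters):
    members = []
    for p in pose_ensemble.members:
        for axis in (0, 1):
            try:
                members.append(ax.symmetrize_pose(p, axis_index=axis, filters=filters))
            except ax.ClashRejection:
                pass
    assert members, "toy world must yield at least one symmetrized block"
    return Ensemble(members, pd.DataFrame({"member": range(len(members))}), {})


@pytest.fixture(scope="session")
def fc_ensemble(toy_cfg):
    return Ensemble([ax.make_toy_fc(toy_cfg)], pd.DataFrame({"member": [0]}), {})


@pytest.fixture(scope="session")
def ball_structure():
    """~10^4 uniformly spaced points filling a 30 A ball.

    A cubic lattice filling, not a random cloud: the deterministic quadrature
    approximates the continuous sphere to well below the acceptance
    tolerances, whereas a random cloud of this size carries ~10% Monte-Carlo
    noise in the intensity tail near QR = 4.
    """
    radius = 30.0
    spacing = (4.0 / 3.0 * np.pi * radius**3 / 10_000) ** (1.0 / 3.0)
    k = int(np.ceil(radius / spacing))
    axis = np.arange(-k, k + 1) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    xyz = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    xyz = xyz[np.linalg.norm(xyz, axis=1) <= radius]
    n = len(xyz)
    return ax.Structure(
        serial=np.arange(1, n + 1),
        chain_id=np.full(n, "A"),
        res_id=np.arange(1, n + 1),
        res_name=np.full(n, "ALA"),
        atom_name=np.full(n, "CA"),
        element=np.full(n, "C"),
        coord=xyz,
    )


@pytest.fixture(scope="session")
def ball_profile(ball_structure):
    """Noiseless Debye profile of the lattice ball on a 120-point low-Q grid
    (computed once; it is the costly input shared by the Guinier checks)."""
    q = np.linspace(0.002, 0.2, 120)
    return ax.debye_profile(ball_structure, q)


@pytest.fixture(scope="session")
def random_ball():
    """3000 random uniform points in a 30 A ball, for distance-histogram
    oracles (a random cloud has no lattice combing in its P(r))."""
    rng = np.random.default_rng(2024)
    n, radius = 3000, 30.0
    xyz = rng.normal(size=(n, 3))
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    xyz *= radius * rng.uniform(0.0, 1.0, size=(n, 1)) ** (1.0 / 3.0)
    return ax.Structure(
        serial=np.arange(1, n + 1),
        chain_id=np.full(n, "A"),
        res_id=np.arange(1, n + 1),
        res_name=np.full(n, "ALA"),
        atom_name=np.full(n, "CA"),
        element=np.full(n, "C"),
        coord=xyz,
    )


def sphere_form_factor(q, radius):
    """Analytic normalised sphere intensity [3 (sin x - x cos x) / x^3]^2."""
    x = np.asarray(q) * radius
    amp = np.ones_like(x, dtype=float)
    nz = x != 0
    amp[nz] = 3.0 * (np.sin(x[nz]) - x[nz] * np.cos(x[nz])) / x[nz] ** 3
    return amp**2
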