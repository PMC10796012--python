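"""Shared fixtures and finite-difference oracles.

The FD helpers implement surface and volume differential operators directly
in Cartesian coordinates, independent of the spectral-multiplier reductions
used by the package; they are the arbiters for every convention choice
(harmonic normalisation, s_l, tensor-divergence identities).
"""

import math
import warnings

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

# property tests must be reproducible across runs
_hyp_settings.register_profile("derandomised", derandomize=True)
_hyp_settings.load_profile("derandomised")

from bulbvib.parameters import (
    ShellSpec, FillingSpec, VITREOUS, WATER, moduli_from_rigidity,
    pressure_mmHg_to_Pa, lame_from_young_poisson,
)


@pytest.fixture(scope="session")
def eye_shell():
    """Eye-baseline shell: Table-style parameters at 15 mmHg, constant K."""
    p = pressure_mmHg_to_Pa(15.0)
    mu, lam, _ = moduli_from_rigidity(11.2e-3, 0.5e-3, 2.1e7, p, 0.5)
    return ShellSpec(R=11.2e-3, h=0.5e-3, rho_s=1077.0, mu=mu,
                     lam_tilde=lam, p=p)


@pytest.fixture(scope="session")
def ball_shell():
    """Water-filled rubber ball of the validation study at 13.7 kPa."""
    mu, lam = lame_from_young_poisson(4.8e6, 0.45)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # h/R = 0.16 triggers the thin-shell
        return ShellSpec(R=25e-3, h=4e-3, rho_s=1200.0, mu=mu,
                         lam_tilde=lam, p=13.7e3)


@pytest.fixture(scope="session")
def vitreous():
    return VITREOUS


@pytest.fixture(scope="session")
def water():
    return WATER


# ---------------------------------------------------------------------------
# Cartesian finite-difference machinery
# ---------------------------------------------------------------------------

#: 4th-order central first-derivative stencil
_C1 = ((-2, 1 / 12), (-1, -8 / 12), (1, 8 / 12), (2, -1 / 12))
#: 4th-order central second-derivative stencil
_C2 = ((-2, -1 / 12), (-1, 16 / 12), (0, -30 / 12), (1, 16 / 12),
       (2, -1 / 12))


def fd_gradient(f, x, h):
    """4th-order gradient of a (possibly vector-valued) field: d f / d x_j."""
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(f(x))
    out = np.zeros(f0.shape + (3,), dtype=complex)
    for j in range(3):
        e = np.zeros(3)
        e[j] = h
        acc = 0
        for k, w in _C1:
            acc = acc + w * np.asarray(f(x + k * e))
        out[..., j] = acc / h
    return out


def fd_second(f, x, i, j, h):
    """4th-order mixed second derivative d^2 f / dx_i dx_j (scalar/vector)."""
    x = np.asarray(x, dtype=float)
    ei, ej = np.zeros(3), np.zeros(3)
    ei[i] = h
    ej[j] = h
    if i == j:
        acc = 0
        for k, w in _C2:
            acc = acc + w * np.asarray(f(x + k * ei))
        return acc / h**2
    acc = 0
    for ki, wi in _C1:
        for kj, wj in _C1:
            acc = acc + wi * wj * np.asarray(f(x + ki * ei + kj * ej))
    return acc / h**2


def sphere_point(theta, phi, r=1.0):
    return r * np.array([math.sin(theta) * math.cos(phi),
                         math.sin(theta) * math.sin(phi),
                         math.cos(theta)])


def tangent_projector(x):
    n = np.asarray(x) / np.linalg.norm(x)
    return np.eye(3) - np.outer(n, n), n


def surface_divergence_tensor(T, x, h=1e-5):
    """Euclidean surface divergence (div_s T)_i = P_jk d_k T_ij at |x| = R.

    ``T(y)`` must be defined in a neighbourhood of the sphere (the tests use
    radially constant extensions T(y) = T(R y/|y|)).
    """
    P, _ = tangent_projector(x)
    gradT = fd_gradient(T, x, h)          # (3, 3, 3): d_k T_ij -> [i, j, k]
    return np.einsum("jk,ijk->i", P, gradT)


def surface_divergence_vector(v, x, h=1e-5):
    """Euclidean surface divergence P_jk d_k v_j of a vector field."""
    P, _ = tangent_projector(x)
    grad = fd_gradient(v, x, h)           # (3, 3): d_j v_i
    return np.einsum("jk,jk->", P, grad)


def gauss_sphere_quadrature(n_theta=48, n_phi=None):
    """Gauss-Legendre x trapezoid quadrature nodes/weights on the unit sphere.

    Returns (theta, phi, w) flattened arrays with sum(w) = 4 pi.
    """
    xs, ws = np.polynomial.legendre.leggauss(n_theta)
    thetas = np.arccos(xs)
    if n_phi is None:
        n_phi = 2 * n_theta
    phis = 2 * np.pi * np.arange(n_phi) / n_phi
    TH, PH = np.meshgrid(thetas, phis, indexing="ij")
    W = np.repeat(ws[:, None], n_phi, axis=1) * (2 * np.pi / n_phi)
    return TH.ravel(), PH.ravel(), W.ravel()
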