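"""Scalar and vector spherical harmonics, surface-operator spectral
multipliers, and spherical Bessel functions of complex argument.

Conventions
-----------
Harmonics are fully normalised (orthonormal on the unit sphere) with the
Condon--Shortley phase.  The vector harmonics attached to Y_lm are

    p = Y rhat,     b = grad_1 Y / s_l,     c = rhat x b,

with grad_1 the unit-sphere surface gradient and s_l = sqrt(l (l + 1)), so
that p, b, c are orthonormal on the unit sphere.  Only m = 0 enters the
eigenproblem (the characteristic equations are m-independent); general m is
accepted for mode rendering.

Because all shell and interior fields of a given degree are built from Y and
its surface derivatives, the surface differential operators reduce to scalar
multipliers ("spectral multipliers") on a small algebra of tensor atoms; the
table lives in :func:`surface_operators` and is verified against
finite-difference surface calculus in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import jv, jve, sph_harm_y

_MAX_BESSEL_IM = 650.0  # exp overflow guard for unscaled evaluation


# ---------------------------------------------------------------------------
# scalar and vector spherical harmonics
# ---------------------------------------------------------------------------

def _check_index(ell: int, m: int) -> None:
    if ell < 0 or not float(ell).is_integer():
        raise ValueError(f"degree must be a non-negative integer, got {ell!r}")
    if abs(m) > ell:
        raise ValueError(f"order |m| <= ell required, got ell={ell}, m={m}")


def scalar_harmonic(ell: int, m: int, theta, phi):
    """Orthonormal spherical harmonic Y_lm(theta, phi), theta = colatitude."""
    _check_index(ell, m)
    return sph_harm_y(ell, m, theta, phi)


def scalar_harmonic_dtheta(ell: int, m: int, theta, phi):
    """d/dtheta of Y_lm via the standard ladder relation.

    dY/dtheta = m cot(theta) Y_lm + sqrt((l-m)(l+m+1)) e^{-i phi} Y_{l,m+1}.
    """
    _check_index(ell, m)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = np.zeros(np.broadcast(theta, phi).shape, dtype=complex)
    if m != 0:
        out = out + m / np.tan(theta) * sph_harm_y(ell, m, theta, phi)
    if m < ell:
        out = out + (math.sqrt((ell - m) * (ell + m + 1))
                     * np.exp(-1j * phi) * sph_harm_y(ell, m + 1, theta, phi))
    return out


def _unit_vectors(theta, phi):
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    rhat = np.stack([st * cp, st * sp, ct], axis=-1)
    that = np.stack([ct * cp, ct * sp, -st], axis=-1)
    phat = np.stack([-sp, cp, np.zeros_like(sp)], axis=-1)
    return rhat, that, phat


def vector_harmonics(ell: int, m: int, theta, phi):
    """Vector spherical harmonics (p, b, c) as Cartesian 3-vectors.

    p = Y rhat is radial; b (proportional to the surface gradient of Y) and
    c = rhat x b are tangential and mutually orthogonal.  Orthonormal on the
    unit sphere.  b and c require ell >= 1 (they vanish identically for
    ell = 0 and are not defined here).
    """
    _check_index(ell, m)
    if ell < 1:
        raise ValueError("tangential harmonics b, c require ell >= 1")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    rhat, that, phat = _unit_vectors(theta, phi)
    Y = sph_harm_y(ell, m, theta, phi)
    dY = scalar_harmonic_dtheta(ell, m, theta, phi)
    s = math.sqrt(ell * (ell + 1))
    p_vec = Y[..., None] * rhat
    if m != 0:
        mY_over_sin = 1j * m * Y / np.sin(theta)
    else:
        mY_over_sin = np.zeros_like(Y)
    b_vec = (dY[..., None] * that + mY_over_sin[..., None] * phat) / s
    c_vec = (dY[..., None] * phat - mY_over_sin[..., None] * that) / s
    return p_vec, b_vec, c_vec


# ---------------------------------------------------------------------------
# surface-operator spectral multipliers
# ---------------------------------------------------------------------------

def surface_operators(ell: int, R: float = 1.0) -> dict:
    """Spectral multipliers of surface differential operators at degree ell.

    On a sphere of radius R, fields of degree ell are spanned by the scalar
    harmonic Y, the tangential vectors b and c, and four tangential 2-tensor
    atoms:

    ==========  ====================================================
    ``T1``      Y P                  (P the tangent projector)
    ``T2``      projected surface Hessian of Y (= covariant Hessian)
    ``T4``      symmetric covariant gradient of c
    ``T5``      Y eps                (eps = antisymmetric rotation, n x .)
    ==========  ====================================================

    Returned multipliers (s2 = ell (ell + 1), s = sqrt(s2)):

    - ``laplacian``: Delta_s Y = laplacian * Y
    - ``div_b``, ``div_c``: surface divergence of the tangential harmonics
    - ``pdiv``: {atom: (coef_b, coef_c)} tangential part of div_s T
    - ``divpdiv``: {atom: coef_Y} of div_s(P div_s T)
    - ``trace``: {atom: coef_Y} of tr T
    - ``grad_b``: |grad_s Y| coefficient: grad_s Y = grad_b * b

    The tangential part of div_s equals the intrinsic covariant divergence;
    the normal part is n (-tr T / R).  These reductions are pinned by a
    finite-difference oracle in the tests.
    """
    _check_index(ell, 0)
    s2 = ell * (ell + 1)
    s = math.sqrt(s2)
    return {
        "s": s,
        "s2": s2,
        "laplacian": -s2 / R**2,
        "grad_b": s / R,
        "div_b": -s / R,
        "div_c": 0.0,
        "pdiv": {
            "T1": (s / R, 0.0),
            "T2": (s * (1 - s2) / R, 0.0),
            "T4": (0.0, (1 - s2 / 2) / R),
            "T5": (0.0, s / R),
        },
        "divpdiv": {
            "T1": -s2 / R**2,
            "T2": s2 * (s2 - 1) / R**2,
            "T4": 0.0,
            "T5": 0.0,
        },
        "trace": {"T1": 2.0, "T2": -s2, "T4": 0.0, "T5": 0.0},
    }


# ---------------------------------------------------------------------------
# spherical Bessel functions of complex argument
# ---------------------------------------------------------------------------

def _dfact(n: int) -> float:
    """Double factorial n!! (n odd)."""
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def _jl_series_ratio(ell: int, z: complex, kmax: int = 24) -> complex:
    """j_l(z) / z^l by the ascending series (entire, even in z)."""
    z2 = z * z
    term = 1.0 / _dfact(2 * ell + 1)
    total = term
    for k in range(1, kmax + 1):
        term *= -z2 / (2.0 * k * (2 * ell + 2 * k + 1))
        total += term
        if abs(term) < 1e-18 * abs(total):
            break
    return total


def spherical_bessel_j(ell: int, z: complex) -> complex:
    """Spherical Bessel function j_l(z) for complex z.

    Uses j_l(z) = sqrt(pi / (2 z)) J_{l+1/2}(z); the origin is handled by the
    series limit (j_0(0) = 1, j_l(0) = 0 for l >= 1) and small arguments by
    the ascending series.  Raises OverflowError when |Im z| is large enough
    that the result would overflow double precision (use
    :func:`bessel_uv` with ``scaled=True`` in that regime).
    """
    if ell < 0:
        raise ValueError(f"ell must be >= 0, got {ell}")
    z = complex(z)
    if z == 0:
        return 1.0 + 0.0j if ell == 0 else 0.0 + 0.0j
    if abs(z.imag) > _MAX_BESSEL_IM:
        raise OverflowError(
            f"j_{ell}({z!r}) would overflow double precision; use the "
            "exponentially scaled evaluation instead")
    # parity: j_l(-z) = (-1)^l j_l(z); evaluate away from the jv branch cut
    sign = 1.0
    if z.real < 0 or (z.real == 0 and z.imag < 0):
        z = -z
        sign = (-1.0) ** ell
    if abs(z) < 1e-3:
        return sign * _jl_series_ratio(ell, z) * z**ell
    return sign * complex(np.sqrt(np.pi / (2 * z)) * jv(ell + 0.5, z))


def spherical_bessel_j_derivative(ell: int, z: complex) -> complex:
    """d/dz j_l(z), via j_l' = j_{l-1} - (l+1)/z j_l (and j_0' = -j_1)."""
    z = complex(z)
    if ell == 0:
        return -spherical_bessel_j(1, z)
    if z == 0:
        return 1.0 / 3.0 + 0j if ell == 1 else 0.0 + 0.0j
    return (spherical_bessel_j(ell - 1, z)
            - (ell + 1) / z * spherical_bessel_j(ell, z))


def bessel_uv(ell: int, z: complex, scaled: bool = True
              ) -> tuple[complex, complex]:
    """The entire even functions u = j_l(z)/z^l and v = j_{l-1}(z)/z^{l-1}.

    These are the natural building blocks of the characteristic matrices: the
    interior-solution column depends on the wavenumber a only through u(a),
    v(a) and polynomials in a^2, which makes the characteristic functions
    single-valued in zeta (the square-root branch of a cancels) and regular
    at a = 0.

    With ``scaled=True`` both values carry a common factor exp(-|Im z|),
    which prevents overflow for strongly viscous interiors; the factor is
    positive, so zeros and phases of any homogeneous expression are
    unaffected.  Requires ell >= 1.
    """
    if ell < 1:
        raise ValueError("bessel_uv requires ell >= 1")
    z = complex(z)
    # u, v are even in z; move z to the right half-plane so the half-integer
    # Bessel routine never sees its branch cut (negative real axis), keeping
    # the evaluation continuous in z^2.
    if z.real < 0 or (z.real == 0 and z.imag < 0):
        z = -z
    if abs(z) < 1e-3:
        u = _jl_series_ratio(ell, z)
        v = _jl_series_ratio(ell - 1, z)
        if scaled:
            fac = math.exp(-abs(z.imag))
            u, v = u * fac, v * fac
        return u, v
    front = np.sqrt(np.pi / (2 * z))
    if scaled:
        ju = complex(front * jve(ell + 0.5, z))
        jm = complex(front * jve(ell - 0.5, z))
    else:
        if abs(z.imag) > _MAX_BESSEL_IM:
            raise OverflowError(
                f"unscaled Bessel at {z!r} would overflow; pass scaled=True")
        ju = complex(front * jv(ell + 0.5, z))
        jm = complex(front * jv(ell - 0.5, z))
    return ju / z**ell, jm / z**(ell - 1)
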