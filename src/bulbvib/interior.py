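"""General bounded solution of the viscoelastic interior problem.

For motions exp(zeta t) the interior displacement u and pressure increment q
of an incompressible linear viscoelastic medium satisfy

    rho_v zeta^2 u = -grad q + G(zeta) lap u,      div u = 0,

(the pre-stress part p (grad u)^T of the nominal stress is divergence-free for
a solenoidal field and drops out of the momentum balance, but it does
contribute to the traction transmitted to the shell).  At harmonic degree
ell >= 1 the bounded general solution has three amplitudes:

- ``C1``: potential flow driven by a harmonic pressure field,
- ``C2``: divergence-free poloidal shear wave with radial dependence
  j_ell(a r / R), a the dimensionless interior wavenumber,
- ``C3``: toroidal shear wave (purely tangential, pressure-free).

For ell = 1 the first family (C1, C2) does not correspond to admissible
vibration modes and is excluded at construction time; the ell = 1 toroidal
solution is a rigid oscillatory rotation of each concentric sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import FillingSpec
from .rheology import kelvin_voigt_modulus, interior_wavenumber
from .harmonics import (
    vector_harmonics,
    scalar_harmonic,
    spherical_bessel_j,
    spherical_bessel_j_derivative,
)


@dataclass(frozen=True)
class InteriorSolution:
    """Interior solution of degree ``ell`` at complex frequency ``zeta``.

    Amplitudes C1, C2 (spheroidal family) and C3 (torsional family) have
    units of displacement [m].  ``R`` is the shell radius bounding the
    domain, ``filling`` the interior medium.
    """

    ell: int
    zeta: complex
    C1: complex
    C2: complex
    C3: complex
    R: float
    filling: FillingSpec

    def __post_init__(self):
        if self.ell < 1:
            raise ValueError("interior solutions require ell >= 1 (the "
                             "ell = 0 problem only has the trivial solution)")
        if self.ell == 1 and (self.C1 != 0 or self.C2 != 0):
            raise ValueError(
                "ell = 1 spheroidal amplitudes are inadmissible (no such "
                "vibration mode exists); set C1 = C2 = 0")
        if not (self.R > 0):
            raise ValueError(f"R must be positive, got {self.R!r}")

    @property
    def modulus(self) -> complex:
        """Complex shear modulus of the filling at this frequency."""
        return kelvin_voigt_modulus(self.zeta, self.filling.gamma,
                                    self.filling.eta)

    @property
    def wavenumber(self) -> complex:
        """Dimensionless interior wavenumber a(zeta)."""
        return interior_wavenumber(self.zeta, self.R, self.filling.rho_v,
                                   self.modulus)


@dataclass(frozen=True)
class RadialProfiles:
    """Radial coefficient functions at one radius.

    q = Q Y, u = P (Y rhat) + B b + C c, with Y, b, c the degree-ell scalar
    and vector harmonics.
    """

    Q: complex
    P: complex
    B: complex
    C: complex


def _profiles(sol: InteriorSolution, r: float, derivative: bool = False):
    ell, a, R = sol.ell, sol.wavenumber, sol.R
    s = math.sqrt(ell * (ell + 1))
    x = r / R
    jl = spherical_bessel_j
    djl = spherical_bessel_j_derivative

    if x == 0.0:
        pow_lm1 = 1.0 if ell == 1 else 0.0
        Q = 0.0
        P = sol.C1 * pow_lm1
        B = sol.C1 * (s / ell) * pow_lm1
        C = 0.0  # j_l(0) = 0 for ell >= 1
    else:
        ax = a * x
        pow_l = x**ell
        pow_lm1 = x**(ell - 1)
        Q = -sol.C1 * sol.filling.rho_v * R * sol.zeta**2 / ell * pow_l
        P = sol.C1 * pow_lm1 + sol.C2 * jl(ell, ax) / x
        B = (sol.C1 * (s / ell) * pow_lm1
             + sol.C2 / s * (a * jl(ell - 1, ax) - ell * jl(ell, ax) / x))
        C = sol.C3 * jl(ell, ax)
    if not derivative:
        return RadialProfiles(Q=Q, P=P, B=B, C=C)

    # d/dr of the displacement profiles (used for the shell traction)
    if x == 0.0:
        raise ValueError("profile derivatives at the origin are not needed "
                         "and not implemented")
    ax = a * x
    dP = (sol.C1 * (ell - 1) * x**(ell - 2)
          + sol.C2 * (a * djl(ell, ax) / x - jl(ell, ax) / x**2)) / R
    dB = (sol.C1 * s * (ell - 1) / ell * x**(ell - 2)
          + sol.C2 / s * (a**2 * djl(ell - 1, ax)
                          + ell * jl(ell, ax) / x**2
                          - ell * a * djl(ell, ax) / x)) / R
    dC = sol.C3 * a * djl(ell, ax) / R
    return RadialProfiles(Q=Q, P=P, B=B, C=C), (dP, dB, dC)


def radial_profiles(sol: InteriorSolution, r: float) -> RadialProfiles:
    """Evaluate the radial coefficient functions Q, P, B, C at radius r."""
    if r < 0 or r > sol.R * (1 + 1e-12):
        raise ValueError(f"radius {r!r} outside the ball [0, R]")
    return _profiles(sol, r)


def displacement_field(sol: InteriorSolution, r: float, theta, phi,
                       m: int = 0):
    """Displacement u(r, theta, phi) as a Cartesian complex 3-vector.

    The angular structure is carried by the degree-(ell, m) vector harmonics;
    the eigenproblem itself is m-independent and solved at m = 0, but any
    |m| <= ell is accepted for rendering.
    """
    prof = _profiles(sol, min(r, sol.R))
    p_vec, b_vec, c_vec = vector_harmonics(sol.ell, m, theta, phi)
    return prof.P * p_vec + prof.B * b_vec + prof.C * c_vec


def pressure_increment(sol: InteriorSolution, r: float, theta, phi,
                       m: int = 0):
    """Pressure-increment field q at a point."""
    prof = _profiles(sol, r)
    return prof.Q * scalar_harmonic(sol.ell, m, theta, phi)


def _displacement_cartesian(sol: InteriorSolution, xyz: np.ndarray,
                            m: int = 0) -> np.ndarray:
    x, y, z = xyz
    r = math.sqrt(x * x + y * y + z * z)
    theta = math.acos(max(-1.0, min(1.0, z / r))) if r > 0 else 0.0
    phi = math.atan2(y, x)
    return np.asarray(_field_any_radius(sol, r, theta, phi, m))


def _field_any_radius(sol, r, theta, phi, m):
    # The analytic formulas extend smoothly past r = R; finite-difference
    # stencils centred on the surface rely on this.
    prof = _profiles(sol, r)
    p_vec, b_vec, c_vec = vector_harmonics(sol.ell, m, theta, phi)
    return prof.P * p_vec + prof.B * b_vec + prof.C * c_vec


def displacement_gradient(sol: InteriorSolution, r: float, theta: float,
                          phi: float, m: int = 0,
                          step: float = 1e-3) -> np.ndarray:
    """Cartesian gradient (du_i/dx_j) at a point, 4th-order central FD.

    ``step`` is relative to R.  The displacement components are analytic in
    position, so the stencil achieves ~1e-10 relative accuracy at the default
    step; this keeps the stress evaluation independent of any hand-derived
    gradient formulas (the closed-form route is used only for the surface
    traction, and the two are cross-checked in the tests).
    """
    st, ct = math.sin(theta), math.cos(theta)
    x0 = np.array([r * st * math.cos(phi), r * st * math.sin(phi), r * ct])
    hstep = step * sol.R
    grad = np.empty((3, 3), dtype=complex)
    for j in range(3):
        e = np.zeros(3)
        e[j] = hstep
        fp1 = _displacement_cartesian(sol, x0 + e, m)
        fm1 = _displacement_cartesian(sol, x0 - e, m)
        fp2 = _displacement_cartesian(sol, x0 + 2 * e, m)
        fm2 = _displacement_cartesian(sol, x0 - 2 * e, m)
        grad[:, j] = (8 * (fp1 - fm1) - (fp2 - fm2)) / (12 * hstep)
    return grad


def incremental_stress(sol: InteriorSolution, r: float, theta: float,
                       phi: float, m: int = 0, p: float = 0.0,
                       include_prestress: bool = True) -> np.ndarray:
    """Incremental nominal (Piola) stress S at a point, complex 3x3 [Pa].

    S = p (grad u)^T + Sigma with Sigma = -q I + 2 G(zeta) sym(grad u); the
    symmetric part is automatically deviatoric because div u = 0.  ``p`` is
    the equilibrium reference pressure shared with the shell.  The pre-stress
    transport term p (grad u)^T belongs to the nominal stress and is included
    by default; ``include_prestress=False`` exists only for sensitivity
    studies, never as a production path.
    """
    G = sol.modulus
    grad = displacement_gradient(sol, r, theta, phi, m)
    q = pressure_increment(sol, r, theta, phi, m)
    S = G * (grad + grad.T) - q * np.eye(3)
    if include_prestress and p != 0.0:
        S = S + p * grad.T
    return S


def shell_traction(sol: InteriorSolution, p: float = 0.0
                   ) -> tuple[complex, complex, complex]:
    """Harmonic coefficients of the traction S n exerted on the shell.

    Returns ``(normal_coeff, tangential_b_coeff, tangential_c_coeff)``: the
    coefficients of Y, b and c in the surface traction at r = R, for
    reference pressure p.  These are the fluid-loading terms entering the
    shell equations (with the minus signs placed there).  Linear in
    (C1, C2, C3); a vacuum filling exerts no traction.

    Closed forms (independent of the finite-difference stress route, which
    cross-checks them):

        T_n = (p + 2 G) P'(R) - Q(R)
        T_b = p (s P - B)/R + G (B' - B/R + s P / R)
        T_c = -p C / R + G (C' - C / R)
    """
    if sol.filling.is_vacuum:
        return (0.0 + 0.0j, 0.0 + 0.0j, 0.0 + 0.0j)
    ell = sol.ell
    s = math.sqrt(ell * (ell + 1))
    G = sol.modulus
    prof, (dP, dB, dC) = _profiles(sol, sol.R, derivative=True)
    R = sol.R
    T_n = (p + 2 * G) * dP - prof.Q
    T_b = (p * (s * prof.P - prof.B) / R
           + G * (dB - prof.B / R + s * prof.P / R))
    T_c = -p * prof.C / R + G * (dC - prof.C / R)
    return (T_n, T_b, T_c)
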