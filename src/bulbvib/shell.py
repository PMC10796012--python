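"""Harmonic reduction of the pre-stressed thin-shell equations and assembly
of the characteristic system.

The shell mid-surface displacement is u = w n + v with v = v_b b + v_c c at
harmonic degree ell.  Linearised about the pressurised equilibrium (membrane
pre-tension p R / 2), the normal and tangential momentum balances are

    rho_s h w_tt = div_s(P div_s M) - (1/R) P:N + (pR/2) Lap_s w
                   - (p/2) div_s v - n . S n,
    rho_s h v_tt = P div_s N + (1/R) P div_s M - P S n,

with constitutive laws

    N = (pR/2) grad_s u + h (2 mu eps + lam_tilde tr(eps) P) + M / R,
    M = (h^3/12) (2 mu kappa + lam_tilde tr(kappa) P),

where eps is the in-plane stretch, kappa the bending tensor.  Every tensor of
degree ell is a combination of four atoms (Y P, the surface Hessian of Y, the
symmetric gradient of c, and Y times the tangential rotation), so the PDE
system collapses to a 2x2 algebraic system in (w, v_b) (spheroidal, first
family) plus a scalar equation in v_c (torsional, second family).  Coupling
to the interior uses no-slip (w, v_b, v_c) = interior displacement at r = R
and the interior traction S n.

The explicit pre-stress terms (pR/2) Lap_s w - (p/2) div_s v in the normal
equation are exactly the normal component of div_s of the pre-stress block
(pR/2) n (x) (grad_s w - v / R) of N; the implementation keeps that block in
N and recovers the printed terms, which fixes all signs consistently.  Four
independent anchors validate the reduction: the interior PDE residual, the
static inflation balance dp/dR = 4 h (mu + lam_tilde) / R^2, the classical
toroidal thin-shell limit omega^2 = mu (ell-1)(ell+2) / (rho_s R^2), and the
water-filled-ball validation table.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np

from .parameters import ShellSpec, FillingSpec
from .rheology import kelvin_voigt_modulus, interior_wavenumber
from .harmonics import surface_operators, bessel_uv


@dataclass(frozen=True)
class ShellKinematics:
    """Harmonic coefficients of the shell mid-surface displacement.

    w on the scalar harmonic Y (normal), v_b and v_c on the tangential
    harmonics b and c.  First-family motion has v_c = 0; second-family
    (torsional) motion has w = v_b = 0.
    """

    w: complex = 0.0
    v_b: complex = 0.0
    v_c: complex = 0.0


def strain_tensors(kin: ShellKinematics, ell: int, R: float
                   ) -> tuple[dict, dict]:
    """Atom coefficients of the stretch eps and bending kappa tensors.

    Tensors are returned as ``{"T1": ..., "T2": ..., "T4": ...}`` in the atom
    basis of :func:`bulbvib.harmonics.surface_operators` (both are symmetric:
    no T5 part).  Works for ell >= 0; tangential atoms vanish at ell = 0.

        eps   = (w/R) T1 + (v_b/(s R)) T2 + (v_c/R) T4
        kappa = (w/R^2) T1 + ((2 v_b/s - w)/R^2) T2 + (2 v_c/R^2) T4
    """
    s = math.sqrt(ell * (ell + 1))
    w, v_b, v_c = kin.w, kin.v_b, kin.v_c
    if ell == 0 and (v_b != 0 or v_c != 0):
        raise ValueError("tangential displacement requires ell >= 1")
    vb_s = v_b / s if ell > 0 else 0.0
    eps = {"T1": w / R, "T2": vb_s / R, "T4": v_c / R}
    kappa = {"T1": w / R**2, "T2": (2 * vb_s - w) / R**2,
             "T4": 2 * v_c / R**2}
    return eps, kappa


def _trace(coeffs: dict, ops: dict) -> complex:
    return sum(coeffs.get(k, 0.0) * tr for k, tr in ops["trace"].items())


def stress_resultants(eps: dict, kappa: dict, shell: ShellSpec,
                      kin: ShellKinematics, ell: int) -> tuple[dict, dict]:
    """Membrane-force and bending-moment increments in the atom basis.

    Returns ``(N_coeffs, M_coeffs)``.  M is symmetric-tangential
    ({T1, T2, T4}); N additionally carries an antisymmetric tangential part
    ("T5", from the pre-stress term (pR/2) grad_s u acting on toroidal
    motion) and a normal block n (x) t recorded as {"nb", "nc"}: the b and c
    coefficients of t = (pR/2)(grad_s w - v/R).
    """
    ops = surface_operators(ell, shell.R)
    s = ops["s"]
    mu, lam, h, p, R = (shell.mu, shell.lam_tilde, shell.h, shell.p, shell.R)

    tr_eps = _trace(eps, ops)
    tr_kap = _trace(kappa, ops)
    beta = h**3 / 12.0

    M = {k: beta * 2 * mu * kappa.get(k, 0.0) for k in ("T1", "T2", "T4")}
    M["T1"] += beta * lam * tr_kap

    N = {k: h * 2 * mu * eps.get(k, 0.0) + M.get(k, 0.0) / R
         for k in ("T1", "T2", "T4")}
    N["T1"] += h * lam * tr_eps
    # pre-stress block (pR/2) grad_s u:
    #   tangential-tangential: (w/R) T1 + (v_b/(sR)) T2 + (v_c/R) T4
    #                          - (s v_c / (2R)) T5
    #   normal block:          n (x) (grad_s w - v/R)
    N["T1"] += (p * R / 2) * kin.w / R
    if ell > 0:
        N["T2"] += (p * R / 2) * kin.v_b / (s * R)
    N["T4"] += (p * R / 2) * kin.v_c / R
    N["T5"] = -(p * R / 2) * s * kin.v_c / (2 * R)
    N["nb"] = (p * R / 2) * (s * kin.w - kin.v_b) / R
    N["nc"] = -(p * R / 2) * kin.v_c / R
    return N, M


def shell_rhs(kin: ShellKinematics, ell: int, shell: ShellSpec
              ) -> tuple[complex, complex, complex]:
    """Elastic + pre-stress right-hand sides of the three shell equations.

    Returns the coefficients (on Y, b, c) of

        RHS_n = div_s(P div_s M) - (1/R) P:N + n . div_s(N_normal-block)
        RHS_b,c = [P div_s N + (1/R) P div_s M] . (b, c)

    i.e. everything except inertia and the interior traction.  The explicit
    pressure terms of the normal equation, (pR/2) Lap_s w - (p/2) div_s v,
    are recovered identically as n . div_s of the pre-stress normal block.
    """
    ops = surface_operators(ell, shell.R)
    R = shell.R
    s = ops["s"]
    eps, kappa = strain_tensors(kin, ell, R)
    N, M = stress_resultants(eps, kappa, shell, kin, ell)

    def pdiv(coeffs):
        cb = sum(coeffs.get(k, 0.0) * ops["pdiv"][k][0]
                 for k in ("T1", "T2", "T4", "T5"))
        cc = sum(coeffs.get(k, 0.0) * ops["pdiv"][k][1]
                 for k in ("T1", "T2", "T4", "T5"))
        return cb, cc

    def divpdiv(coeffs):
        return sum(coeffs.get(k, 0.0) * ops["divpdiv"][k]
                   for k in ("T1", "T2", "T4", "T5"))

    nb, nc = N.get("nb", 0.0), N.get("nc", 0.0)
    # normal equation
    rhs_n = (divpdiv(M) - _trace(N, ops) / R
             # n . div_s(n (x) t) = div_s t = -(s/R) t_b
             - (s / R) * nb)
    # tangential equations; P div_s(n (x) t) = t / R
    Nb, Nc = pdiv(N)
    Mb, Mc = pdiv(M)
    rhs_b = Nb + nb / R + Mb / R
    rhs_c = Nc + nc / R + Mc / R
    return rhs_n, rhs_b, rhs_c


def _stiffness_spheroidal(ell: int, shell: ShellSpec) -> np.ndarray:
    """2x2 map (w, v_b) -> (RHS_n, RHS_b) of the empty-shell equations."""
    s = math.sqrt(ell * (ell + 1))
    cols = []
    for kin in (ShellKinematics(w=1.0), ShellKinematics(v_b=1.0)):
        rn, rb, _ = shell_rhs(kin, ell, shell)
        cols.append([rn, rb])
    return np.array(cols, dtype=complex).T


def _stiffness_torsional(ell: int, shell: ShellSpec) -> complex:
    """Scalar map v_c -> RHS_c of the empty-shell torsional equation."""
    _, _, rc = shell_rhs(ShellKinematics(v_c=1.0), ell, shell)
    return rc


def empty_shell_spheroidal_roots(ell: int, shell: ShellSpec) -> list[complex]:
    """Exact eigenvalues zeta of the empty (in vacuo) spheroidal problem.

    The empty-shell system is rho_s h zeta^2 x = K x with a constant 2x2
    stiffness K, i.e. a polynomial eigenproblem; roots are returned as the
    canonical representatives (Im zeta >= 0), sorted by frequency.  For a
    purely elastic shell K is real symmetric negative definite and the roots
    are purely imaginary.
    """
    if ell < 2:
        raise ValueError("spheroidal modes require ell >= 2")
    K = _stiffness_spheroidal(ell, shell)
    lam = np.linalg.eigvals(K) / (shell.rho_s * shell.h)
    roots = [cmath.sqrt(l) for l in lam]  # zeta^2 = lam, take Im >= 0 branch
    out = []
    for r in roots:
        zeta = r if r.imag >= 0 else -r
        out.append(zeta)
    return sorted(out, key=lambda z: z.imag)


def empty_shell_torsional_root(ell: int, shell: ShellSpec) -> complex:
    """Exact torsional eigenvalue of the empty shell (Im zeta >= 0)."""
    if ell < 1:
        raise ValueError("torsional modes require ell >= 1")
    lam = _stiffness_torsional(ell, shell) / (shell.rho_s * shell.h)
    zeta = cmath.sqrt(lam)
    return zeta if zeta.imag >= 0 else -zeta


def _interior_quantities(ell: int, zeta: complex, shell: ShellSpec,
                         filling: FillingSpec):
    """Wavenumber, modulus and scaled Bessel blocks for the filled problem."""
    G = kelvin_voigt_modulus(zeta, filling.gamma, filling.eta)
    a = interior_wavenumber(zeta, shell.R, filling.rho_v, G)
    u, v = bessel_uv(ell, a, scaled=True)
    return G, a, u, v


def assemble_first_family(ell: int, zeta: complex, shell: ShellSpec,
                          filling: FillingSpec
                          ) -> tuple[complex, complex, complex, complex]:
    """Entries (m11, m12, m21, m22) of the spheroidal characteristic system.

    Column 1 multiplies the interior potential amplitude C1, column 2 the
    poloidal shear amplitude C2 (rescaled by a^ell and an exponential factor
    for numerical stability: zeros of the determinant are unchanged).  Row 1
    is the normal shell equation, row 2 the tangential (b) equation, each
    written as m = inertia - elastic RHS + traction so that m . C = 0.

    Requires ell >= 2; the interior index m never enters (the characteristic
    equations are azimuth-independent).
    """
    if ell < 2:
        raise ValueError("first-family modes require ell >= 2")
    if filling.is_vacuum:
        raise ValueError("the vacuum case is a polynomial eigenproblem; use "
                         "empty_shell_spheroidal_roots")
    R, p = shell.R, shell.p
    s = math.sqrt(ell * (ell + 1))
    S = ell * (ell + 1)
    G, a, u, v = _interior_quantities(ell, zeta, shell, filling)
    rho_v = filling.rho_v
    inert = shell.rho_s * shell.h * zeta**2

    # column 1: no-slip values and traction per unit C1
    w1, vb1 = 1.0, s / ell
    Tn1 = (p + 2 * G) * (ell - 1) / R + rho_v * R * zeta**2 / ell
    Tb1 = (s * (ell - 1) / (ell * R)) * (p + 2 * G)
    # column 2 (scaled): per unit C2 * a^ell * exp(-|Im a|)
    w2 = u
    vb2 = (v - ell * u) / s
    Tn2 = (p + 2 * G) * (v - (ell + 2) * u) / R
    Tb2 = (p * ((S + ell) * u - v) + G * ((2 * ell + 2 * S - a * a) * u
                                          - 2 * v)) / (s * R)

    rn1, rb1, _ = shell_rhs(ShellKinematics(w=w1, v_b=vb1), ell, shell)
    rn2, rb2, _ = shell_rhs(ShellKinematics(w=w2, v_b=vb2), ell, shell)

    m11 = inert * w1 - rn1 + Tn1
    m21 = inert * vb1 - rb1 + Tb1
    m12 = inert * w2 - rn2 + Tn2
    m22 = inert * vb2 - rb2 + Tb2
    return m11, m12, m21, m22


def _torsional_parts(ell: int, zeta: complex, shell: ShellSpec,
                     filling: FillingSpec) -> tuple[complex, complex, complex]:
    """(inertia, elastic RHS, traction) contributions to m33."""
    if ell < 1:
        raise ValueError("torsional modes require ell >= 1")
    R, p = shell.R, shell.p
    if filling.is_vacuum:
        vc = 1.0
        Tc = 0.0
    else:
        G, a, u, v = _interior_quantities(ell, zeta, shell, filling)
        vc = u
        Tc = (-p * u + G * (v - (ell + 2) * u)) / R
    inert = shell.rho_s * shell.h * zeta**2 * vc
    _, _, rc = shell_rhs(ShellKinematics(v_c=vc), ell, shell)
    return inert, rc, Tc


def assemble_torsional(ell: int, zeta: complex, shell: ShellSpec,
                       filling: FillingSpec) -> complex:
    """Coefficient m33 of the torsional characteristic equation m33 C3 = 0.

    The torsional equation is decoupled from (C1, C2); the empty-shell limit
    reduces to the classical toroidal balance
    zeta^2 -> -mu (ell-1)(ell+2) / (rho_s R^2) as h/R -> 0 and p -> 0.
    """
    inert, rc, Tc = _torsional_parts(ell, zeta, shell, filling)
    return inert - rc + Tc


def torsional_scale(ell: int, zeta: complex, shell: ShellSpec,
                    filling: FillingSpec) -> float:
    """Magnitude scale of m33 (sum of its contributions' magnitudes).

    Guards against pseudo-roots: at zeros of j_ell(a) every term proportional
    to the interior surface amplitude vanishes and m33 is legitimately small
    without being a root; measuring the residual against this scale rejects
    such points.
    """
    inert, rc, Tc = _torsional_parts(ell, zeta, shell, filling)
    return abs(inert) + abs(rc) + abs(Tc)


def characteristic_first(ell: int, zeta: complex, shell: ShellSpec,
                         filling: FillingSpec) -> complex:
    """Determinant of the spheroidal 2x2 system; zeros are eigenvalues."""
    m11, m12, m21, m22 = assemble_first_family(ell, zeta, shell, filling)
    return m11 * m22 - m21 * m12


def first_family_scale(ell: int, zeta: complex, shell: ShellSpec,
                       filling: FillingSpec) -> float:
    """Natural magnitude of the spheroidal determinant (residual scale).

    The determinant is the difference m11 m22 - m12 m21; the sum of the two
    product magnitudes is the scale against which its cancellation (and hence
    a root residual) is meaningful.  Comparable to, and sharper than, the
    product of row norms when the two interior columns differ wildly in
    magnitude (thin viscous boundary layers).
    """
    m11, m12, m21, m22 = assemble_first_family(ell, zeta, shell, filling)
    return abs(m11 * m22) + abs(m12 * m21)


def characteristic_torsional(ell: int, zeta: complex, shell: ShellSpec,
                             filling: FillingSpec) -> complex:
    """Torsional characteristic function m33; zeros are eigenvalues."""
    return assemble_torsional(ell, zeta, shell, filling)


def first_family_amplitudes(ell: int, zeta: complex, shell: ShellSpec,
                            filling: FillingSpec) -> tuple[complex, complex]:
    """(C1, C2) nullspace direction of the 2x2 system at a root.

    The returned C2 is in physical units (the internal column scaling is
    undone), normalised so that max(|C1|, |C2 j_ell-scale|) is O(1).
    """
    m11, m12, m21, m22 = assemble_first_family(ell, zeta, shell, filling)
    # nullspace of [[m11, m12], [m21, m22]]: pick the larger row
    if abs(m11) + abs(m12) >= abs(m21) + abs(m22):
        c1, c2s = m12, -m11
    else:
        c1, c2s = m22, -m21
    # undo the column-2 scaling: C2_phys = C2_scaled exp(-|Im a|) / a^ell
    G = kelvin_voigt_modulus(zeta, filling.gamma, filling.eta)
    a = interior_wavenumber(zeta, shell.R, filling.rho_v, G)
    if a != 0:
        c2 = c2s * cmath.exp(-abs(a.imag)) / a**ell
    else:
        c2 = c2s
    norm = max(abs(c1), abs(c2s))
    return c1 / norm, c2 / norm


def surface_kinematics_at_root(ell: int, zeta: complex, shell: ShellSpec,
                               filling: FillingSpec) -> ShellKinematics:
    """Shell displacement coefficients (w, v_b) of the spheroidal nullspace.

    Computed in the scaled column space, so it is overflow-safe for any
    viscosity; normalised to unit Euclidean length of (w, v_b).
    """
    m11, m12, m21, m22 = assemble_first_family(ell, zeta, shell, filling)
    if abs(m11) + abs(m12) >= abs(m21) + abs(m22):
        c1, c2s = m12, -m11
    else:
        c1, c2s = m22, -m21
    s = math.sqrt(ell * (ell + 1))
    _, _, u, v = _interior_quantities(ell, zeta, shell, filling)
    w = c1 * 1.0 + c2s * u
    vb = c1 * (s / ell) + c2s * (v - ell * u) / s
    norm = math.hypot(abs(w), abs(vb))
    if norm == 0:
        raise ValueError("degenerate nullspace: zeta is not a simple root")
    return ShellKinematics(w=w / norm, v_b=vb / norm)
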