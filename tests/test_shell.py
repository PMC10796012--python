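"""Shell reduction: static-inflation anchor, classical toroidal limit,
energy-method stiffness oracle, scaling laws, symmetry of the characteristic
functions.
"""

import cmath
import math
import warnings

import numpy as np
import pytest

from bulbvib.parameters import (
    ShellSpec, FillingSpec, lame_from_young_poisson, moduli_from_rigidity,
    pressure_mmHg_to_Pa, VITREOUS, WATER,
)
from bulbvib.harmonics import scalar_harmonic, vector_harmonics
from bulbvib.shell import (
    ShellKinematics, strain_tensors, stress_resultants, shell_rhs,
    assemble_first_family, assemble_torsional, characteristic_first,
    characteristic_torsional, empty_shell_spheroidal_roots,
    empty_shell_torsional_root, _stiffness_spheroidal, _stiffness_torsional,
)
from conftest import fd_gradient, sphere_point, tangent_projector


def _shell(R=1.0, h=1e-3, rho=1000.0, mu=1e6, lam=2e6, p=0.0):
    return ShellSpec(R=R, h=h, rho_s=rho, mu=mu, lam_tilde=lam, p=p)


# ---------------------------------------------------------------------------
# strain measures
# ---------------------------------------------------------------------------

def test_uniform_inflation_strains():
    """w = dR, v = 0: eps = (dR/R) P and kappa = (dR/R^2) P."""
    R, dR = 0.0112, 1e-5
    eps, kappa = strain_tensors(ShellKinematics(w=dR), 0, R)
    assert eps["T1"] == pytest.approx(dR / R)
    assert kappa["T1"] == pytest.approx(dR / R**2)
    # T2/T4 atoms are identically zero tensors at ell = 0


def test_zero_displacement_zero_strain():
    eps, kappa = strain_tensors(ShellKinematics(), 3, 1.0)
    assert all(v == 0 for v in eps.values())
    assert all(v == 0 for v in kappa.values())


def test_toroidal_twist_is_area_preserving():
    """Pure c-harmonic motion: tr eps = 0 (atoms T4 is traceless)."""
    from bulbvib.harmonics import surface_operators
    ops = surface_operators(3, 1.0)
    eps, _ = strain_tensors(ShellKinematics(v_c=1.0), 3, 1.0)
    tr = sum(eps.get(k, 0.0) * t for k, t in ops["trace"].items())
    assert tr == 0.0


def test_uniform_inflation_membrane_force():
    """N = (pR/2 + 2h(mu+lam)) (dR/R) P for uniform inflation, no bending."""
    R, h, mu, lam, p = 0.0112, 5e-4, 1.4e6, 2.8e6, 2000.0
    sh = _shell(R=R, h=h, mu=mu, lam=lam, p=p)
    kin = ShellKinematics(w=1.0)
    eps, kappa = strain_tensors(kin, 0, R)
    kappa = {k: 0.0 for k in kappa}  # bending neglected in this identity
    N, M = stress_resultants(eps, kappa, sh, kin, 0)
    assert N["T1"] == pytest.approx((p * R / 2 + 2 * h * (mu + lam)) / R)


def test_membrane_law_at_zero_pressure():
    """p = 0, kappa = 0: N = h (2 mu eps + lam tr(eps) P), classical law."""
    R = 1.0
    sh = _shell(R=R, p=0.0)
    kin = ShellKinematics(w=0.3, v_b=-0.4)
    eps, _ = strain_tensors(kin, 2, R)
    N, _ = stress_resultants(eps, {"T1": 0, "T2": 0, "T4": 0}, sh, kin, 2)
    from bulbvib.harmonics import surface_operators
    tre = sum(eps.get(k, 0.0) * t
              for k, t in surface_operators(2, R)["trace"].items())
    assert N["T1"] == pytest.approx(sh.h * (2 * sh.mu * eps["T1"]
                                            + sh.lam_tilde * tre))
    assert N["T2"] == pytest.approx(sh.h * 2 * sh.mu * eps["T2"])


def test_bending_moment_scales_as_h_cubed():
    kin = ShellKinematics(w=1.0, v_b=0.2)
    eps, kappa = strain_tensors(kin, 2, 1.0)
    M_h = stress_resultants(eps, kappa, _shell(h=1e-3), kin, 2)[1]
    M_h2 = stress_resultants(eps, kappa, _shell(h=5e-4), kin, 2)[1]
    for k in ("T1", "T2", "T4"):
        if M_h[k] != 0:
            assert M_h[k] / M_h2[k] == pytest.approx(8.0)


# ---------------------------------------------------------------------------
# static inflation anchor (pins signs/factors of the pre-stress terms)
# ---------------------------------------------------------------------------

def test_static_inflation_identity():
    """Normal equation for the uniform mode: dp/dR = 4h(mu+lam)/R^2.

    The shell RHS for w = dR must equal -(p + 4h(mu+lam)/R) dR/R so that the
    balance with applied traction dp + p dR/R reproduces the inflation
    relation.  A very thin wall is used so the (neglected-in-the-identity)
    bending correction, O((h/R)^2), is below the tolerance.
    """
    R, h = 0.0112, 1e-6
    mu, lam, p = 1.4e6, 2.8e6, 2000.0
    sh = _shell(R=R, h=h, mu=mu, lam=lam, p=p)
    rhs_n, rhs_b, rhs_c = shell_rhs(ShellKinematics(w=1.0), 0, sh)
    expect = -(p + 4 * h / R * (mu + lam)) / R
    assert rhs_n == pytest.approx(expect, rel=1e-9)


def test_static_inflation_bending_correction_vanishes_cubically():
    """The deviation from the inflation identity scales like h^3."""
    R, mu, lam, p = 0.0112, 1.4e6, 2.8e6, 2000.0

    def deviation(h):
        sh = _shell(R=R, h=h, mu=mu, lam=lam, p=p)
        rhs_n = shell_rhs(ShellKinematics(w=1.0), 0, sh)[0]
        return rhs_n + (p + 4 * h / R * (mu + lam)) / R

    d1, d2 = deviation(1e-4), deviation(2e-4)
    assert abs(d2 / d1) == pytest.approx(8.0, rel=1e-3)


# ---------------------------------------------------------------------------
# energy-method stiffness oracle (independent of the spectral reduction)
# ---------------------------------------------------------------------------

def _energy_stiffness(ell, sh):
    """Empty-shell stiffness quadratic form via strain energy + Cartesian FD.

    U = 1/2 ∮ [h (2 mu eps:eps + lam tr(eps)^2)
                + h^3/12 (2 mu kap:kap + lam tr(kap)^2)] dA with eps, kappa
    evaluated from their tensor definitions by finite differences of the
    displacement field on the sphere; modal mass is rho_s h R^2 per unit
    coefficient (orthonormal harmonics).  Returns the 3x3 stiffness on
    (w, v_b, v_c) divided by rho_s h R^2, whose eigenvalues are omega^2.
    """
    R, h, mu, lam = sh.R, sh.h, sh.mu, sh.lam_tilde
    s = math.sqrt(ell * (ell + 1))

    def disp(y, q):
        w, vb, vc = q
        r = np.linalg.norm(y)
        yn = y / r
        th = math.acos(max(-1.0, min(1.0, yn[2])))
        ph = math.atan2(yn[1], yn[0])
        pv, bv, cv = vector_harmonics(ell, 0, th, ph)
        return (w * pv + vb * bv + vc * cv).real

    def tang(y, q):
        w, vb, vc = q
        return disp(y, (0.0, vb, vc))

    def normal_scalar(y, q):
        r = np.linalg.norm(y)
        yn = y / r
        th = math.acos(max(-1.0, min(1.0, yn[2])))
        return q[0] * scalar_harmonic(ell, 0, th, 0.0).real

    def eps_kappa(x, q):
        P, n = tangent_projector(x)
        gv = fd_gradient(lambda y: tang(y, q), x, 1e-5 * R).real / 1.0
        gv = gv @ P
        wY = float(np.dot(disp(x, q), n))
        eps = 0.5 * (P @ gv + gv.T @ P) + (wY / R) * P

        def grad_w(y):
            g = fd_gradient(lambda z: normal_scalar(z, q), y, 1e-5 * R).real
            Py, _ = tangent_projector(y)
            return Py @ g

        Hw = fd_gradient(grad_w, x, 1e-4 * R).real
        Hw = P @ Hw @ P
        kap = -Hw + (1 / R) * (P @ gv) + (1 / R) * (gv.T @ P) \
            + (wY / R**2) * P
        return eps, kap

    xs, ws = np.polynomial.legendre.leggauss(40)

    def U(q):
        tot = 0.0
        for xg, wq in zip(xs, ws):
            th = math.acos(xg)
            x = R * np.array([math.sin(th), 0.0, math.cos(th)])
            eps, kap = eps_kappa(x, q)
            dens = h * (2 * mu * np.sum(eps * eps) + lam * np.trace(eps)**2)
            dens += h**3 / 12 * (2 * mu * np.sum(kap * kap)
                                 + lam * np.trace(kap)**2)
            tot += wq * dens * 2 * math.pi * R**2
        return 0.5 * tot

    e = np.eye(3)
    K = np.zeros((3, 3))
    for i in range(3):
        K[i, i] = 2 * U(e[i])
    for i in range(3):
        for j in range(i + 1, 3):
            K[i, j] = K[j, i] = U(e[i] + e[j]) - U(e[i]) - U(e[j])
    return K / (sh.rho_s * h * R**2)


@pytest.mark.parametrize("ell", [2, 3])
def test_energy_oracle_matches_spectral_stiffness(ell):
    """Energy-method (FD) empty-shell stiffness == spectral assembly, p = 0.

    Checks membrane AND bending blocks of both families at once; this is the
    strongest guard on the reduction of the elastic operators.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sh = _shell(R=0.025, h=4e-3, rho=1200.0, mu=1.655e6, lam=2.979e6,
                    p=0.0)
    K_energy = _energy_stiffness(ell, sh)
    K_sph = -_stiffness_spheroidal(ell, sh).real / (sh.rho_s * sh.h)
    K_tor = -_stiffness_torsional(ell, sh).real / (sh.rho_s * sh.h)
    assert np.allclose(K_energy[:2, :2], K_sph, rtol=1e-6)
    assert K_energy[2, 2] == pytest.approx(K_tor, rel=1e-6)
    # families decouple
    assert abs(K_energy[0, 2]) < 1e-6 * abs(K_energy[2, 2])
    assert abs(K_energy[1, 2]) < 1e-6 * abs(K_energy[2, 2])


# ---------------------------------------------------------------------------
# empty-shell eigenvalues
# ---------------------------------------------------------------------------

def test_empty_elastic_shell_roots_purely_imaginary(eye_shell):
    for z in empty_shell_spheroidal_roots(2, eye_shell):
        assert abs(z.real) < 1e-8 * abs(z)
    z = empty_shell_torsional_root(2, eye_shell)
    assert abs(z.real) < 1e-8 * abs(z)


def test_classical_toroidal_limit():
    """h/R -> 0, p -> 0: zeta^2 -> -mu (l-1)(l+2) / (rho_s R^2)."""
    R, mu, rho = 0.0112, 1.4e6, 1077.0
    for ell in (2, 3, 4):
        omega_classical = math.sqrt(mu * (ell - 1) * (ell + 2) / (rho * R**2))
        sh = _shell(R=R, h=1e-3 * R, rho=rho, mu=mu, lam=2 * mu, p=0.0)
        z = empty_shell_torsional_root(ell, sh)
        assert abs(z.imag - omega_classical) < 1e-2 * omega_classical
        # and convergence: smaller h/R gets closer
        sh2 = _shell(R=R, h=1e-4 * R, rho=rho, mu=mu, lam=2 * mu, p=0.0)
        z2 = empty_shell_torsional_root(ell, sh2)
        assert abs(z2.imag - omega_classical) < abs(z.imag - omega_classical)


def test_sqrt_pressure_scaling_of_empty_shell():
    """Moduli ~ p (constant rigidity): every frequency scales exactly as
    sqrt(p)."""
    R, h, K = 11.2e-3, 0.5e-3, 2.1e7
    freqs = {}
    for fac in (1.0, 4.0):
        p = fac * pressure_mmHg_to_Pa(15.0)
        mu, lam, _ = moduli_from_rigidity(R, h, K, p, 0.5)
        sh = _shell(R=R, h=h, rho=1077.0, mu=mu, lam=lam, p=p)
        freqs[fac] = ([z.imag for z in empty_shell_spheroidal_roots(2, sh)]
                      + [empty_shell_torsional_root(2, sh).imag])
    for f1, f4 in zip(freqs[1.0], freqs[4.0]):
        assert f4 / f1 == pytest.approx(2.0, rel=1e-12)


# ---------------------------------------------------------------------------
# characteristic functions: symmetry and consistency
# ---------------------------------------------------------------------------

def test_characteristic_conjugation_symmetry(eye_shell, vitreous):
    """det(conj zeta) = conj det(zeta): eigenvalues form conjugate pairs."""
    for z in (-20 + 1300j, -5 + 400j, -300 + 2500j):
        d = characteristic_first(2, z, eye_shell, vitreous)
        dc = characteristic_first(2, z.conjugate(), eye_shell, vitreous)
        assert dc == pytest.approx(d.conjugate(), rel=1e-10)
        m = characteristic_torsional(2, z, eye_shell, vitreous)
        mc = characteristic_torsional(2, z.conjugate(), eye_shell, vitreous)
        assert mc == pytest.approx(m.conjugate(), rel=1e-10)


def test_characteristic_nonzero_on_positive_real_axis(eye_shell, vitreous):
    """No unstable growing modes: det has no zeros for real zeta > 0."""
    from bulbvib.shell import first_family_scale
    for zr in np.geomspace(1.0, 5e3, 40):
        d = characteristic_first(2, complex(zr, 0.0), eye_shell, vitreous)
        scale = first_family_scale(2, complex(zr, 0.0), eye_shell, vitreous)
        assert abs(d) > 1e-6 * scale


def test_assembly_rejects_invalid_degree_and_vacuum(eye_shell, vitreous):
    from bulbvib.parameters import VACUUM
    with pytest.raises(ValueError):
        assemble_first_family(1, 1j, eye_shell, vitreous)
    with pytest.raises(ValueError):
        assemble_first_family(2, 1j, eye_shell, VACUUM)
    with pytest.raises(ValueError):
        assemble_torsional(0, 1j, eye_shell, vitreous)


def test_characteristic_vanishes_at_converged_root(eye_shell, vitreous):
    from bulbvib.shell import first_family_scale
    from bulbvib.eigensolver import solve_modes
    modes = solve_modes(2, eye_shell, vitreous, band=(50, 400),
                        family="spheroidal", certify=False)
    z = modes[0].zeta
    d = characteristic_first(2, z, eye_shell, vitreous)
    assert abs(d) < 1e-8 * first_family_scale(2, z, eye_shell, vitreous)


def test_no_code_path_receives_azimuthal_order():
    """The characteristic assembly is structurally m-independent."""
    import inspect
    for fn in (assemble_first_family, assemble_torsional,
               characteristic_first, characteristic_torsional):
        assert "m" not in inspect.signature(fn).parameters


def test_filled_equations_reduce_to_empty_as_density_vanishes(eye_shell):
    """rho_v -> 0 with tiny moduli and p = 0: filled roots -> empty roots.

    (At p > 0 the two problems differ by design: the nominal-stress transport
    term p (grad u)^T n survives the massless limit of a pressurised interior
    medium, whereas the in-vacuo idealisation carries no surface traction.)
    """
    from bulbvib.eigensolver import find_root
    sh = eye_shell.at_pressure(0.0)
    thin_air = FillingSpec(rho_v=1e-6, gamma=0.0, eta=1e-9, label="air-ish")
    z_empty = empty_shell_spheroidal_roots(2, sh)[0]

    def f(z):
        return characteristic_first(2, z, sh, thin_air)

    z = find_root(f, z_empty * (1 + 1e-4), tol=1e-9)
    assert abs(z - z_empty) < 1e-5 * abs(z_empty)
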