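"""Complex shear modulus of the interior medium and the interior wavenumber.

For motions proportional to exp(zeta t) the hereditary (convolution)
constitutive law of linear viscoelasticity collapses to multiplication by the
complex modulus

    G(zeta) = zeta * Laplace[G_relax](zeta),

the zeta-weighted Laplace transform of the stress-relaxation function.  A
Kelvin--Voigt solid (spring and dashpot in parallel) has
G(zeta) = gamma + zeta * eta, which contains the purely elastic (eta = 0) and
Newtonian (gamma = 0) media as special cases.

The interior shear field depends on position through the dimensionless
wavenumber a(zeta) = i R zeta sqrt(rho_v / G(zeta)); the characteristic
functions downstream depend on a only through even combinations of spherical
Bessel functions, so the square-root branch is immaterial (asserted in the
test suite).
"""

from __future__ import annotations

import cmath

import numpy as np
from scipy.integrate import quad


def kelvin_voigt_modulus(zeta: complex, gamma: float, eta: float) -> complex:
    """Complex modulus of a Kelvin--Voigt medium: G(zeta) = gamma + zeta*eta."""
    return gamma + zeta * eta


def modulus_from_relaxation(zeta: complex, G_of_t, t_max: float = 50.0,
                            rtol: float = 1e-8) -> complex:
    """Complex modulus from a sampled stress-relaxation function.

    Evaluates G(zeta) = zeta * int_0^inf exp(-zeta tau) G_relax(tau) dtau by
    adaptive quadrature.  Provided for rheological models beyond Kelvin--Voigt
    (which has a closed form); the integral must converge, i.e. Re(zeta) must
    exceed the growth rate of ``G_of_t``.

    Parameters
    ----------
    zeta : complex
        Complex frequency [1/s].
    G_of_t : callable
        Relaxation modulus G(t) [Pa] for t >= 0.  Distributional parts
        (a Dirac mass at 0, as for a Newtonian fluid) cannot be sampled and
        must be handled analytically by the caller.
    t_max : float
        Truncation time of the Laplace integral, in units of 1/|zeta|.
    """
    if zeta == 0:
        raise ValueError("complex modulus undefined at zeta = 0")
    # the exp(-zeta tau) factor decays at rate Re(zeta); truncate there when
    # possible, otherwise rely on the decay of G itself (checked below)
    scale = zeta.real if zeta.real > 0 else abs(zeta)
    upper = t_max / scale

    def integrand_re(tau):
        return (cmath.exp(-zeta * tau) * G_of_t(tau)).real

    def integrand_im(tau):
        return (cmath.exp(-zeta * tau) * G_of_t(tau)).imag

    if zeta.real < 0:
        # exp(-zeta tau) grows; demand decay of G(t) fast enough that the
        # truncated integrand is negligible at the cutoff, else refuse.
        tail = abs(cmath.exp(-zeta * upper) * G_of_t(upper))
        head = max(abs(G_of_t(0.0)), abs(G_of_t(1.0 / scale)))
        if tail > rtol * max(head, 1e-300):
            raise ValueError(
                "Laplace integral for the complex modulus does not converge "
                f"at zeta = {zeta!r} for this relaxation function")
    re, re_err = quad(integrand_re, 0.0, upper, epsabs=0.0, epsrel=rtol,
                      limit=4000)
    im, im_err = quad(integrand_im, 0.0, upper, epsabs=0.0, epsrel=rtol,
                      limit=4000)
    val = zeta * complex(re, im)
    err = abs(zeta) * (re_err + im_err)
    if abs(val) > 0 and err > 100 * rtol * abs(val):
        raise ValueError(
            f"quadrature for the complex modulus failed to reach rtol={rtol}")
    return val


def interior_wavenumber(zeta: complex, R: float, rho_v: float,
                        G: complex) -> complex:
    """Dimensionless interior wavenumber a(zeta) = i R zeta sqrt(rho_v/G).

    Principal square-root branch.  a = 0 iff zeta = 0 or rho_v = 0; the
    downstream characteristic functions are even under a -> -a, so the branch
    choice does not affect eigenvalues.
    """
    if rho_v == 0.0:
        return 0.0 + 0.0j
    if G == 0:
        raise ValueError("interior wavenumber undefined for G = 0 with "
                         "rho_v > 0")
    return 1j * R * zeta * np.sqrt(complex(rho_v) / G)
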