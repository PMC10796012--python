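"""Complex root finding, certification and classification of vibration modes.

Eigenvalues zeta are zeros of the characteristic functions (the spheroidal
determinant or the torsional coefficient).  The solver locates them with a
damped Newton iteration started from (i) the exact empty-shell roots,
(ii) minima of the characteristic magnitude along the imaginary axis, and
(iii) continuation seeds supplied by sweep drivers; completeness inside the
search window is certified independently via the argument principle (winding
number of the characteristic function around the window), which guards
against missed or spurious roots.  Roots come in conjugate pairs; the
canonical representative has Im zeta >= 0, so frequency = Im(zeta)/(2 pi) and
damping rate = -Re(zeta) are both reported non-negative.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import ShellSpec, FillingSpec
from .shell import (
    characteristic_first,
    characteristic_torsional,
    torsional_scale,
    assemble_first_family,
    empty_shell_spheroidal_roots,
    empty_shell_torsional_root,
    first_family_amplitudes,
    surface_kinematics_at_root,
    _stiffness_spheroidal,
)
from .interior import InteriorSolution, displacement_field
from .harmonics import vector_harmonics


class ConvergenceError(RuntimeError):
    """Newton iteration failed to reach the residual tolerance."""


class RootCountError(RuntimeError):
    """Solver root count disagrees with the argument-principle certificate."""


@dataclass(frozen=True)
class ModeResult:
    """A converged vibration mode.

    ``zeta`` is the canonical eigenvalue (Im >= 0); ``freq_hz`` its
    oscillation frequency Im(zeta)/(2 pi) and ``damping_rate`` the decay rate
    -Re(zeta).  ``amplitudes`` holds the normalised interior amplitudes
    (C1, C2, C3); ``label`` is "bending" or "stretching" for the spheroidal
    family (by the normal kinetic-energy fraction of the shell motion) and
    "torsional" for the second family.  ``detectable`` is False only for the
    ell = 1 torsional mode, which deforms nothing and cannot be observed on
    the shell surface.
    """

    ell: int
    family: str
    zeta: complex
    amplitudes: tuple[complex, complex, complex]
    label: str
    residual: float
    shell: ShellSpec = field(repr=False, default=None)
    filling: FillingSpec = field(repr=False, default=None)
    detectable: bool = True

    @property
    def freq_hz(self) -> float:
        return self.zeta.imag / (2 * math.pi)

    @property
    def damping_rate(self) -> float:
        return -self.zeta.real


def find_root(f, z0: complex, tol: float = 1e-10, max_iter: int = 100,
              scale=None) -> complex:
    """Damped Newton iteration for a zero of the analytic function ``f``.

    The derivative is taken by central finite differences with relative step
    1e-6; steps are halved until the residual decreases (simple line search,
    which gives dog-leg-like robustness for seeds inside the basin).
    Convergence means |f(z)| < tol * scale(z) (``scale`` defaults to the
    running magnitude of f near the seed, which makes ``tol`` relative).
    Raises :class:`ConvergenceError` if the tolerance is not met.
    """
    z = complex(z0)
    fz = f(z)
    if scale is None:
        f_ref = abs(fz) if fz != 0 else 1.0
        scale = lambda _z: f_ref  # noqa: E731
    best_z, best_r = z, abs(fz) / max(scale(z), 1e-300)
    for _ in range(max_iter):
        sc = max(scale(z), 1e-300)
        if abs(fz) <= tol * sc:
            return z
        h = 1e-6 * max(abs(z), 1e-12)
        df = (f(z + h) - f(z - h)) / (2 * h)
        if df == 0:
            h *= 97.0
            df = (f(z + h) - f(z - h)) / (2 * h)
            if df == 0:
                raise ConvergenceError(
                    f"vanishing derivative at z = {z!r}")
        step = -fz / df
        alpha = 1.0
        for _ in range(30):
            z_new = z + alpha * step
            f_new = f(z_new)
            if abs(f_new) < abs(fz) or abs(z_new - z) < 1e-16 * max(abs(z), 1):
                break
            alpha *= 0.5
        else:
            raise ConvergenceError(f"line search stalled at z = {z!r}")
        z, fz = z_new, f_new
        r = abs(fz) / max(scale(z), 1e-300)
        if r < best_r:
            best_z, best_r = z, r
    if best_r <= tol:
        return best_z
    raise ConvergenceError(
        f"no convergence from seed {z0!r} after {max_iter} iterations "
        f"(best relative residual {best_r:.3g})")


def count_roots_rectangle(f, corners: tuple[complex, complex],
                          max_points: int = 400_000,
                          sample_hint=None) -> int:
    """Number of zeros of analytic ``f`` inside a rectangle.

    ``corners`` is (lower-left, upper-right).  The winding number of f along
    the boundary is accumulated with adaptive refinement: segments whose
    phase increment exceeds ~1 radian are bisected, so zeros are never
    stepped over.  ``sample_hint(p, q)`` may supply a minimum number of
    initial samples for the edge p -> q; characteristic functions oscillate
    on the scale of the interior wavenumber, and adaptive bisection alone can
    alias phase wraps if the initial stride is too coarse.  A zero (or
    near-zero) on the contour triggers an automatic small outward
    perturbation of the rectangle; if that fails repeatedly a RuntimeError is
    raised.
    """
    z_ll, z_ur = complex(corners[0]), complex(corners[1])
    for attempt in range(4):
        grow = 1e-3 * attempt
        dx = (z_ur.real - z_ll.real) * grow
        dy = (z_ur.imag - z_ll.imag) * grow
        a = complex(z_ll.real - dx, z_ll.imag - dy)
        b = complex(z_ur.real + dx, z_ur.imag + dy)
        verts = [a, complex(b.real, a.imag), b, complex(a.real, b.imag), a]
        try:
            # escalate the sampling density until two consecutive densities
            # agree: adaptive bisection alone cannot detect a full phase wrap
            # between samples (aliasing), but it cannot stay aliased at two
            # different densities with the same integer answer spuriously
            # except with vanishing probability.
            prev = None
            for factor in (1, 2, 4, 8, 16):
                total = 0.0
                for p, q in zip(verts[:-1], verts[1:]):
                    n0 = 8
                    if sample_hint is not None:
                        n0 = max(n0, int(sample_hint(p, q)))
                    total += _phase_change(f, p, q, max_points, factor * n0)
                n = total / (2 * math.pi)
                n_int = round(n)
                if abs(n - n_int) > 1e-3:
                    raise _ContourProblem(
                        f"winding number {n:.6f} is not an integer")
                if prev is not None and n_int == prev:
                    return int(n_int)
                prev = n_int
            raise _ContourProblem("winding number did not stabilise under "
                                  "sampling refinement")
        except _ContourProblem:
            continue
    raise RuntimeError("could not certify root count: characteristic "
                       "function vanishes too close to the contour")


class _ContourProblem(Exception):
    pass


def _phase_change(f, p: complex, q: complex, max_points: int,
                  n_init: int = 8) -> float:
    """Total phase change of f along segment p -> q, adaptively refined."""
    ts = np.linspace(0.0, 1.0, n_init + 1)
    pts = [p + t * (q - p) for t in ts]
    vals = [f(z) for z in pts]
    stack = list(zip(pts[:-1], vals[:-1], pts[1:], vals[1:]))
    total = 0.0
    evals = len(pts)
    while stack:
        a, fa, b, fb = stack.pop()
        if fa == 0 or fb == 0:
            raise _ContourProblem("zero on contour")
        dphi = cmath.phase(fb / fa)
        if abs(dphi) <= 1.0:
            total += dphi
            continue
        if evals > max_points:
            raise _ContourProblem("contour refinement budget exhausted")
        mid = 0.5 * (a + b)
        fm = f(mid)
        evals += 1
        stack.append((a, fa, mid, fm))
        stack.append((mid, fm, b, fb))
    return total


def _contour_sample_hint(shell: ShellSpec, filling: FillingSpec):
    """Initial contour sampling density for the argument-principle count.

    The characteristic functions inherit oscillations exp(+-i a) from the
    interior solution, so the phase along a contour edge can wind roughly as
    fast as the interior wavenumber a(zeta) varies; sampling with ~1 point
    per radian of that variation prevents phase aliasing.
    """
    from .rheology import kelvin_voigt_modulus, interior_wavenumber

    def hint(p: complex, q: complex) -> int:
        ts = np.linspace(0.0, 1.0, 65)
        prev = None
        tot = 0.0
        for t in ts:
            z = p + t * (q - p)
            G = kelvin_voigt_modulus(z, filling.gamma, filling.eta)
            if G == 0:
                continue
            a = interior_wavenumber(z, shell.R, filling.rho_v, G)
            if a.real < 0 or (a.real == 0 and a.imag < 0):
                a = -a  # canonical branch, as used by the Bessel layer
            if prev is not None:
                tot += abs(a - prev)
            prev = a
        return int(16 + 1.3 * tot)

    return hint


def _characteristic(ell: int, shell: ShellSpec, filling: FillingSpec,
                    family: str):
    """(f, scale) pair for one family; scale is the row-norm normalisation."""
    if family == "spheroidal":
        def f(z):
            return characteristic_first(ell, z, shell, filling)

        def scale(z):
            m11, m12, m21, m22 = assemble_first_family(ell, z, shell, filling)
            return abs(m11 * m22) + abs(m12 * m21)
    elif family == "torsional":
        def f(z):
            return characteristic_torsional(ell, z, shell, filling)

        def scale(z):
            return torsional_scale(ell, z, shell, filling)
    else:
        raise ValueError(f"unknown family {family!r}")
    return f, scale


def seed_guesses(ell: int, shell: ShellSpec, filling: FillingSpec,
                 band_hz: tuple[float, float] = (1.0, 5000.0),
                 family: str = "spheroidal", n_grid: int = 240,
                 previous: list[complex] | None = None) -> list[complex]:
    """Seed candidates for the root search in one family.

    Combines (i) exact empty-shell eigenvalues, (ii) local minima of the
    normalised characteristic magnitude on an imaginary-axis grid over the
    band, and (iii) optional continuation seeds from a neighbouring sweep
    point.
    """
    seeds: list[complex] = []
    if previous:
        seeds.extend(previous)
    try:
        if family == "spheroidal":
            seeds.extend(empty_shell_spheroidal_roots(ell, shell))
        else:
            seeds.append(empty_shell_torsional_root(ell, shell))
    except ValueError:
        pass
    if filling.is_vacuum:
        return seeds
    f, scale = _characteristic(ell, shell, filling, family)

    def g(wi):
        return abs(f(1j * wi)) / max(scale(1j * wi), 1e-300)

    w = 2 * math.pi * np.geomspace(band_hz[0], band_hz[1], n_grid)
    vals = np.array([g(wi) for wi in w])
    for i in range(1, len(w) - 1):
        if vals[i] < vals[i - 1] and vals[i] < vals[i + 1]:
            seeds.append(1j * _refine_axis_minimum(g, w[i - 1], w[i],
                                                   w[i + 1]))
    return seeds


def _refine_axis_minimum(g, a: float, b: float, c: float,
                         iters: int = 40) -> float:
    """Golden-section refinement of a bracketed minimum of g on [a, c].

    Newton basins can be narrow when the characteristic function oscillates
    (thin viscous boundary layers), so grid minima are sharpened on the
    imaginary axis before seeding the complex iteration.
    """
    invphi = (math.sqrt(5) - 1) / 2
    lo, hi = a, c
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    g1, g2 = g(x1), g(x2)
    for _ in range(iters):
        if (hi - lo) < 1e-10 * hi:
            break
        if g1 < g2:
            hi, x2, g2 = x2, x1, g1
            x1 = hi - invphi * (hi - lo)
            g1 = g(x1)
        else:
            lo, x1, g1 = x1, x2, g2
            x2 = lo + invphi * (hi - lo)
            g2 = g(x2)
    return 0.5 * (lo + hi)


def _roots_in(roots: list[complex], rect: tuple[complex, complex]
              ) -> list[complex]:
    a, b = rect
    return [z for z in roots if a.real <= z.real <= b.real
            and a.imag <= z.imag <= b.imag]


def _hunt_missing_roots(f, scale, rect: tuple[complex, complex], hint,
                        known: list[complex], tol: float,
                        depth: int = 0) -> list[complex]:
    """Locate roots the seeded Newton pass missed, by winding-guided bisection.

    The rectangle is subdivided until each region holding an unaccounted root
    is small enough for Newton to converge from its centre.  Returns the new
    roots found inside ``rect``.
    """
    n = count_roots_rectangle(f, rect, sample_hint=hint)
    have = _roots_in(known, rect)
    if n == len(have):
        return []
    if n < len(have):
        raise RootCountError(
            f"contour count {n} below the {len(have)} converged roots in "
            f"window {rect}; residual tolerance or contour sampling is "
            "inconsistent")
    a, b = rect
    diag = abs(b - a)
    if depth >= 40:
        raise RootCountError(f"bisection stalled at window {rect}")
    # try Newton from the centre once the window is reasonably tight
    if diag < 0.05 * max(abs(a), abs(b)) or depth > 20:
        centre = 0.5 * (a + b)
        try:
            z = find_root(f, centre, tol=tol, scale=scale)
            if (a.real <= z.real <= b.real and a.imag <= z.imag <= b.imag
                    and all(abs(z - k) > 1e-6 * max(abs(z), abs(k))
                            for k in known)):
                new = [z]
                rest = _hunt_missing_roots(f, scale, rect, hint,
                                           known + new, tol, depth + 1)
                return new + rest
        except ConvergenceError:
            pass
    # split along the longer side
    if (b.real - a.real) >= (b.imag - a.imag):
        mid = 0.5 * (a.real + b.real)
        halves = [(a, complex(mid, b.imag)), (complex(mid, a.imag), b)]
    else:
        mid = 0.5 * (a.imag + b.imag)
        halves = [(a, complex(b.real, mid)), (complex(a.real, mid), b)]
    found: list[complex] = []
    for half in halves:
        found += _hunt_missing_roots(f, scale, half, hint,
                                     known + found, tol, depth + 1)
    return found


def _dedup(roots: list[complex], rtol: float = 1e-6) -> list[complex]:
    out: list[complex] = []
    for r in sorted(roots, key=lambda z: z.imag):
        if all(abs(r - o) > rtol * max(abs(r), abs(o)) for o in out):
            out.append(r)
    return out


def _empty_modes(ell: int, shell: ShellSpec, band, family_filter):
    modes = []
    if ell >= 2 and family_filter in ("both", "spheroidal"):
        K = _stiffness_spheroidal(ell, shell) / (shell.rho_s * shell.h)
        lam, vecs = np.linalg.eig(K)
        for i, l in enumerate(lam):
            zeta = cmath.sqrt(l)
            if zeta.imag < 0:
                zeta = -zeta
            w, vb = vecs[0, i], vecs[1, i]
            nrm = math.hypot(abs(w), abs(vb))
            label = ("bending" if abs(w)**2 / nrm**2 > 0.5 else "stretching")
            modes.append(ModeResult(
                ell=ell, family="spheroidal", zeta=zeta,
                amplitudes=(w / nrm, vb / nrm, 0.0), label=label,
                residual=0.0, shell=shell, filling=None))
    if family_filter in ("both", "torsional"):
        zeta = empty_shell_torsional_root(ell, shell)
        modes.append(ModeResult(
            ell=ell, family="torsional", zeta=zeta,
            amplitudes=(0.0, 0.0, 1.0), label="torsional", residual=0.0,
            shell=shell, filling=None, detectable=(ell >= 2)))
    lo, hi = band
    return sorted([m for m in modes if lo <= m.freq_hz <= hi],
                  key=lambda m: m.freq_hz)


def solve_modes(ell: int, shell: ShellSpec, filling: FillingSpec,
                band: tuple[float, float] = (1.0, 5000.0),
                damping_max: float = 1e4, family: str = "both",
                certify: bool = True, tol: float = 1e-10,
                extra_seeds: list[complex] | None = None) -> list["ModeResult"]:
    """All vibration modes of degree ``ell`` with frequency inside ``band``.

    Roots are found per family, deduplicated (relative 1e-6), canonicalised
    to Im zeta >= 0 and sorted by frequency.  With ``certify=True`` the
    number of converged roots in the window [-damping_max, ~0] x band is
    checked against the argument-principle count; a mismatch raises
    :class:`RootCountError` rather than returning a possibly incomplete
    spectrum.  Spheroidal modes require ell >= 2; the ell = 1 torsional mode
    is computed but marked not detectable.
    """
    if ell < 1:
        raise ValueError("modes require ell >= 1")
    if filling.is_vacuum:
        return _empty_modes(ell, shell, band, family)

    families = [family] if family != "both" else ["spheroidal", "torsional"]
    modes: list[ModeResult] = []
    lo, hi = band
    for fam in families:
        if fam == "spheroidal" and ell < 2:
            continue
        f, scale = _characteristic(ell, shell, filling, fam)
        seeds = seed_guesses(ell, shell, filling, band, fam,
                             previous=extra_seeds)
        roots = []
        for z0 in seeds:
            try:
                z = find_root(f, z0, tol=tol, scale=scale)
            except ConvergenceError:
                continue
            if z.imag < 0:
                z = z.conjugate()  # conjugate-pair symmetry
            freq = z.imag / (2 * math.pi)
            if not (lo <= freq <= hi) or not (-1e-9 * abs(z) - damping_max
                                              <= z.real <= 1e-6 * abs(z)):
                continue
            roots.append(z)
        roots = _dedup(roots)
        if certify:
            eps = 1e-3 * 2 * math.pi * hi
            window = (complex(-damping_max, 2 * math.pi * lo),
                      complex(eps, 2 * math.pi * hi))
            hint = _contour_sample_hint(shell, filling)
            n_expected = count_roots_rectangle(f, window, sample_hint=hint)
            if n_expected < len(roots):
                raise RootCountError(
                    f"{fam} family, ell={ell}: found {len(roots)} roots but "
                    f"the contour certificate counts {n_expected} in the "
                    "window")
            if n_expected > len(roots):
                # strongly damped roots sit far from the imaginary-axis
                # seeds; corner them by winding-guided bisection
                roots = _dedup(roots + _hunt_missing_roots(
                    f, scale, window, hint, roots, tol))
                if n_expected != len(roots):
                    raise RootCountError(
                        f"{fam} family, ell={ell}: {len(roots)} roots "
                        f"converged but the certificate counts {n_expected}")
        for z in roots:
            resid = abs(f(z)) / max(scale(z), 1e-300)
            if fam == "spheroidal":
                c1, c2 = first_family_amplitudes(ell, z, shell, filling)
                kin = surface_kinematics_at_root(ell, z, shell, filling)
                frac = abs(kin.w)**2 / (abs(kin.w)**2 + abs(kin.v_b)**2)
                label = "bending" if frac > 0.5 else "stretching"
                amps = (c1, c2, 0.0)
            else:
                label = "torsional"
                amps = (0.0, 0.0, 1.0)
            modes.append(ModeResult(
                ell=ell, family=fam, zeta=z, amplitudes=amps, label=label,
                residual=resid, shell=shell, filling=filling,
                detectable=not (fam == "torsional" and ell == 1)))
    return sorted(modes, key=lambda m: m.freq_hz)


def slowest_decaying_mode(modes: list[ModeResult]) -> ModeResult:
    """The detectable mode that survives longest after excitation.

    Smallest damping rate among detectable modes; exact ties (e.g. the
    undamped empty elastic shell) break towards the lowest frequency.
    """
    cand = [m for m in modes if m.detectable]
    if not cand:
        raise ValueError("no detectable modes given")
    return min(cand, key=lambda m: (m.damping_rate, m.freq_hz))


def mode_field(mode: ModeResult, grid=None, m: int = 0):
    """Velocity field zeta * u of a mode, sampled on a meridian section.

    ``grid``: optional (r_values, theta_values) in metres/radians; defaults
    to 12 radii x 49 colatitudes covering the meridian phi = 0.  Returns
    (points, velocities): Cartesian sample points (N, 3) and complex
    velocity vectors (N, 3) normalised to unit maximum speed.  For an empty
    shell only the surface r = R is sampled (there is no interior field).
    """
    R = mode.shell.R
    if grid is None:
        thetas = np.linspace(1e-3, math.pi - 1e-3, 49)
        if mode.filling is None or mode.filling.is_vacuum:
            radii = np.array([R])
        else:
            radii = np.linspace(R / 12, R, 12)
    else:
        radii, thetas = np.asarray(grid[0]), np.asarray(grid[1])

    pts, vels = [], []
    if mode.filling is None or mode.filling.is_vacuum:
        w, vb, vc = _empty_surface_amplitudes(mode)
        for th in thetas:
            p_vec, b_vec, c_vec = vector_harmonics(mode.ell, m, th, 0.0)
            u = w * p_vec + vb * b_vec + vc * c_vec
            x = R * np.array([math.sin(th), 0.0, math.cos(th)])
            pts.append(x)
            vels.append(mode.zeta * u)
    else:
        c1, c2, c3 = mode.amplitudes
        sol = InteriorSolution(ell=mode.ell, zeta=mode.zeta, C1=c1, C2=c2,
                               C3=c3, R=R, filling=mode.filling)
        for r in radii:
            for th in thetas:
                u = displacement_field(sol, r, th, 0.0, m)
                x = r * np.array([math.sin(th), 0.0, math.cos(th)])
                pts.append(x)
                vels.append(mode.zeta * u)
    pts = np.array(pts)
    vels = np.array(vels)
    vmax = np.max(np.linalg.norm(np.abs(vels), axis=1))
    if vmax > 0:
        vels = vels / vmax
    return pts, vels


def _empty_surface_amplitudes(mode: ModeResult):
    if mode.family == "torsional":
        return 0.0, 0.0, 1.0
    w, vb, _ = mode.amplitudes
    return w, vb, 0.0
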