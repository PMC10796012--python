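"""Deterministic study pipelines: validation against the water-filled-ball
experiment, IOP sweeps, rigidity grids, viscosity-damping curves and
filling-material comparisons.

Every driver returns a tidy :class:`pandas.DataFrame` with one row per
tracked mode per parameter point, each row carrying the root residual; CSV
output is deterministic for a fixed configuration (run metadata, including
the timestamp, goes to a separate run log).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .parameters import (
    ShellSpec, FillingSpec, RigidityModel, VACUUM, WATER, VITREOUS,
    SILICONE_OIL, pressure_mmHg_to_Pa, pressure_kPa_to_Pa,
    rigidity_per_microliter_to_SI, lame_from_young_poisson,
    effective_young,
)
from .eigensolver import (
    solve_modes, slowest_decaying_mode, find_root, ConvergenceError,
    _characteristic, ModeResult,
)

#: Default solver tolerance used by the study drivers.
TOL = 1e-10

#: Baseline ocular rigidity [1/m^3] and physiological IOP [Pa].
K_BASELINE = rigidity_per_microliter_to_SI(0.021)
P_PHYS = pressure_mmHg_to_Pa(15.0)


def _eye_shell(p: float, K: float = K_BASELINE,
               mode: str = "constant-rigidity") -> ShellSpec:
    """Eye-baseline shell at pressure p under the given rigidity mode."""
    rig = RigidityModel(K=K, p0=P_PHYS, poisson=0.5, mode=mode,
                        p_freeze=P_PHYS)
    E = effective_young(rig, (11.2e-3, 0.5e-3), p)
    mu, lam = lame_from_young_poisson(E, 0.5)
    return ShellSpec(R=11.2e-3, h=0.5e-3, rho_s=1077.0, mu=mu,
                     lam_tilde=lam, p=p)


def _mode_row(m: ModeResult, **extra) -> dict:
    row = dict(ell=m.ell, family=m.family, label=m.label,
               freq_hz=m.freq_hz, damping_per_s=m.damping_rate,
               re_zeta=m.zeta.real, im_zeta=m.zeta.imag,
               residual=m.residual)
    row.update(extra)
    return row


def _track(ell: int, shells, fillings, family: str, z0: complex,
           labels=None) -> list[dict]:
    """Continuation of a single root across a parameter sweep.

    ``shells`` and ``fillings`` are parallel sequences; the roots found at
    previous points seed the next one (linear extrapolation, falling back to
    the last root and then to a local imaginary-axis search).  A failed point
    is reported explicitly (NaN row with its parameter label) rather than
    silently dropped.
    """
    from .eigensolver import _refine_axis_minimum

    rows = []
    z_prev, z_prev2 = z0, None
    for i, (sh, fl) in enumerate(zip(shells, fillings)):
        f, scale = _characteristic(ell, sh, fl, family)
        tag = labels[i] if labels is not None else i
        seeds = []
        if z_prev2 is not None:
            seeds.append(2 * z_prev - z_prev2)  # extrapolate along the sweep
        seeds.append(z_prev)
        z = None
        for seed in seeds:
            try:
                z = find_root(f, seed, tol=TOL, scale=scale)
                break
            except ConvergenceError:
                continue
        if z is None:
            # local search on the imaginary axis around the previous root
            def g(w):
                return abs(f(complex(z_prev.real, w))) / max(
                    scale(complex(z_prev.real, w)), 1e-300)
            ws = abs(z_prev.imag) * np.linspace(0.7, 1.4, 57)
            vals = [g(w) for w in ws]
            j = int(np.argmin(vals))
            if 0 < j < len(ws) - 1:
                wj = _refine_axis_minimum(g, ws[j - 1], ws[j], ws[j + 1])
            else:
                wj = ws[j]
            try:
                z = find_root(f, complex(z_prev.real, wj), tol=TOL,
                              scale=scale)
            except ConvergenceError:
                z = None
        if z is not None:
            if z.imag < 0:
                z = z.conjugate()
            rows.append(dict(point=tag, freq_hz=z.imag / (2 * math.pi),
                             damping_per_s=-z.real, re_zeta=z.real,
                             im_zeta=z.imag,
                             residual=abs(f(z)) / max(scale(z), 1e-300),
                             failed=False))
            z_prev2, z_prev = z_prev, z
        else:
            rows.append(dict(point=tag, freq_hz=np.nan,
                             damping_per_s=np.nan, re_zeta=np.nan,
                             im_zeta=np.nan, residual=np.nan, failed=True))
            z_prev2 = None  # restart extrapolation after a gap
    return rows


# ---------------------------------------------------------------------------
# validation against the water-filled rubber ball
# ---------------------------------------------------------------------------

#: Experimental lowest ell=2 frequencies [Hz] of the water-filled rubber
#: ball at the three internal pressures [kPa].
SALIMI_PRESSURES_KPA = (13.7, 34.5, 62.0)
SALIMI_EXPERIMENTAL_HZ = (187.0, 195.0, 206.0)


def validate_salimi() -> pd.DataFrame:
    """Lowest ell = 2 spheroidal frequency of the water-filled rubber ball.

    Ball parameters: radius 25 mm, wall 4 mm, E = 4.8 MPa, nu = 0.45, shell
    density 1200 kg/m^3, filled with water (1000 kg/m^3, 1e-3 Pa s), at
    internal pressures 13.7, 34.5 and 62.0 kPa.  Also reports the relative
    error against the measured frequencies.
    """
    mu, lam = lame_from_young_poisson(4.8e6, 0.45)
    rows = []
    for p_kpa, f_exp in zip(SALIMI_PRESSURES_KPA, SALIMI_EXPERIMENTAL_HZ):
        shell = ShellSpec(R=25e-3, h=4e-3, rho_s=1200.0, mu=mu,
                          lam_tilde=lam, p=pressure_kPa_to_Pa(p_kpa))
        modes = solve_modes(2, shell, WATER, band=(20.0, 1200.0),
                            family="spheroidal", tol=TOL)
        if not modes:
            raise RuntimeError(f"no ell=2 spheroidal mode found at "
                               f"{p_kpa} kPa")
        m = modes[0]
        rows.append(dict(pressure_kPa=p_kpa, freq_hz=m.freq_hz,
                         damping_per_s=m.damping_rate,
                         experimental_hz=f_exp,
                         rel_error=(f_exp - m.freq_hz) / f_exp,
                         residual=m.residual))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IOP sweeps
# ---------------------------------------------------------------------------

def iop_sweep(K_values=None, p_mmHg=None, mode: str = "constant-rigidity",
              filling: FillingSpec = VITREOUS) -> pd.DataFrame:
    """Frequency/damping of the slowest-decaying ell = 2 mode vs IOP.

    The mode is located in full at the first pressure (with certification)
    and tracked by continuation across the grid.  ``mode`` selects between
    constant ocular rigidity (moduli grow linearly with p) and constant
    compliance (moduli frozen at the physiological point).
    """
    if K_values is None:
        K_values = [K_BASELINE]
    if p_mmHg is None:
        p_mmHg = np.geomspace(2.0, 80.0, 40)
    p_mmHg = np.asarray(p_mmHg, dtype=float)
    out = []
    for K in K_values:
        shells = [_eye_shell(pressure_mmHg_to_Pa(p), K, mode) for p in p_mmHg]
        base = solve_modes(2, shells[0], filling, band=(1.0, 5000.0),
                           tol=TOL)
        m0 = slowest_decaying_mode(base)
        rows = _track(2, shells, [filling] * len(shells), m0.family,
                      m0.zeta, labels=p_mmHg)
        for r in rows:
            r["p_mmHg"] = r.pop("point")
            r["K_per_m3"] = K
            r["rigidity_mode"] = mode
            r["family"] = m0.family
            r["label"] = m0.label
        out.extend(rows)
    cols = ["p_mmHg", "K_per_m3", "rigidity_mode", "family", "label",
            "freq_hz", "damping_per_s", "re_zeta", "im_zeta", "residual",
            "failed"]
    return pd.DataFrame(out)[cols]


def loglog_slope(df: pd.DataFrame, p_col: str = "p_mmHg",
                 f_col: str = "freq_hz") -> float:
    """Least-squares slope of log(frequency) vs log(pressure)."""
    ok = df[~df["failed"]] if "failed" in df else df
    x = np.log(ok[p_col].to_numpy(dtype=float))
    y = np.log(ok[f_col].to_numpy(dtype=float))
    return float(np.polyfit(x, y, 1)[0])


# ---------------------------------------------------------------------------
# rigidity grid
# ---------------------------------------------------------------------------

def rigidity_grid(p_mmHg=None, K_values=None,
                  filling: FillingSpec = VITREOUS) -> pd.DataFrame:
    """Slowest-decaying-mode frequency and damping on an (IOP, K) grid.

    K defaults to +/-50% around the baseline rigidity.  Adds the relative
    sensitivity (dlog f / dlog K) per grid point, computed along the K axis.
    """
    if p_mmHg is None:
        p_mmHg = np.geomspace(2.0, 80.0, 10)
    if K_values is None:
        K_values = np.linspace(0.5, 1.5, 7) * K_BASELINE
    p_mmHg = np.asarray(p_mmHg, dtype=float)
    K_values = np.asarray(K_values, dtype=float)

    rows = []
    for K in K_values:
        shells = [_eye_shell(pressure_mmHg_to_Pa(p), K) for p in p_mmHg]
        base = solve_modes(2, shells[0], filling, band=(1.0, 5000.0), tol=TOL)
        m0 = slowest_decaying_mode(base)
        tr = _track(2, shells, [filling] * len(shells), m0.family, m0.zeta,
                    labels=p_mmHg)
        for r in tr:
            r["p_mmHg"] = r.pop("point")
            r["K_per_m3"] = K
        rows.extend(tr)
    df = pd.DataFrame(rows)

    # relative sensitivity d log f / d log K at fixed p
    df["dlogf_dlogK"] = np.nan
    for p in p_mmHg:
        sel = df["p_mmHg"] == p
        sub = df[sel].sort_values("K_per_m3")
        logK = np.log(sub["K_per_m3"].to_numpy())
        logf = np.log(sub["freq_hz"].to_numpy())
        df.loc[sub.index, "dlogf_dlogK"] = np.gradient(logf, logK)
    cols = ["p_mmHg", "K_per_m3", "freq_hz", "damping_per_s", "re_zeta",
            "im_zeta", "dlogf_dlogK", "residual", "failed"]
    return df[cols]


# ---------------------------------------------------------------------------
# viscosity-damping curve
# ---------------------------------------------------------------------------

def viscosity_damping_curve(nu_range=None) -> pd.DataFrame:
    """Damping of the slowest-decaying ell = 2 mode vs fluid viscosity.

    The eye-baseline shell (15 mmHg) is filled with a Newtonian fluid of
    density 1000 kg/m^3 and kinematic viscosity swept over ``nu_range``
    [m^2/s] (default: log grid from 1e-6, water, to 1e-3, tamponade silicone
    oil).
    """
    if nu_range is None:
        nu_range = np.geomspace(1e-6, 1e-3, 13)
    nu_range = np.asarray(nu_range, dtype=float)
    shell = _eye_shell(P_PHYS)
    rho = 1000.0
    fillings = [FillingSpec(rho_v=rho, gamma=0.0, eta=rho * nu,
                            label="newtonian") for nu in nu_range]
    base = solve_modes(2, shell, fillings[0], band=(1.0, 5000.0), tol=TOL)
    m0 = slowest_decaying_mode(base)
    rows = _track(2, [shell] * len(nu_range), fillings, m0.family, m0.zeta,
                  labels=nu_range)
    for r in rows:
        r["nu_m2_s"] = r.pop("point")
        r["ell"] = 2
        r["family"] = m0.family
        r["label"] = m0.label
    cols = ["nu_m2_s", "ell", "family", "label", "freq_hz", "damping_per_s",
            "re_zeta", "im_zeta", "residual", "failed"]
    return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# filling comparison
# ---------------------------------------------------------------------------

def filling_comparison() -> pd.DataFrame:
    """The three lowest ell = 2 eigenvalues for different interior media.

    Empty shell, water, vitreous humor and silicone oil inside the
    eye-baseline shell at 15 mmHg: two spheroidal modes (bending and
    stretching) plus the torsional mode for each case.
    """
    shell = _eye_shell(P_PHYS)
    rows = []
    for filling in (VACUUM, WATER, VITREOUS, SILICONE_OIL):
        modes = solve_modes(2, shell, filling, band=(1.0, 5000.0), tol=TOL)
        for m in modes:
            rows.append(_mode_row(m, filling=filling.label, failed=False))
    cols = ["filling", "ell", "family", "label", "freq_hz", "damping_per_s",
            "re_zeta", "im_zeta", "residual", "failed"]
    return pd.DataFrame(rows)[cols]
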