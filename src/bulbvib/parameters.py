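"""Material and geometric parameters, unit conversions, and the ocular-rigidity
route to effective shell moduli.

The eye's outer shell is characterised mechanically not by a directly measured
Young's modulus (scleral data are scattered and the tissue is inhomogeneous)
but through inflation tests summarised by Friedenwald's empirical law

    ln(p / p0) = K (V - V0),

with ``K`` the *ocular rigidity* (natural logarithm: the law is used through
its differential form dp/dV = K p).  For a thin spherical shell of radius R
and wall thickness h this fixes the ocular compliance C = dV/dp = 1/(K p) and,
via the static inflation balance of the pre-stressed shell,

    mu + lam_tilde = pi R^4 K p / h,      C = pi R^4 / (h (mu + lam_tilde)).

With an incompressible wall (nu = 0.5, so lam_tilde = 2 mu and
E = mu + lam_tilde) the effective Young's modulus is E = pi R^4 K p / h: the
modulus grows linearly with the inflating pressure, which is the "material
stiffening" encoded by a constant ocular rigidity.

All computation is in SI units; conversions happen only at the I/O boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

#: Conversion constant, millimetres of mercury to pascal.
MMHG_TO_PA = 133.322

#: One microlitre^-1 expressed in m^-3 (1 ul = 1e-9 m^3).
PER_UL_TO_PER_M3 = 1.0e9


def pressure_mmHg_to_Pa(p_mmHg: float) -> float:
    """Convert a pressure from mmHg to Pa (1 mmHg = 133.322 Pa)."""
    if not math.isfinite(p_mmHg):
        raise ValueError(f"pressure must be finite, got {p_mmHg!r}")
    return p_mmHg * MMHG_TO_PA


def pressure_kPa_to_Pa(p_kPa: float) -> float:
    """Convert a pressure from kPa to Pa."""
    if not math.isfinite(p_kPa):
        raise ValueError(f"pressure must be finite, got {p_kPa!r}")
    return p_kPa * 1.0e3


def rigidity_per_microliter_to_SI(K_ul: float) -> float:
    """Convert an ocular rigidity from 1/microlitre to 1/m^3.

    Friedenwald's rigidity is conventionally quoted per microlitre of ocular
    volume; the SI value is larger by 1e9.
    """
    if not (K_ul > 0):
        raise ValueError(f"ocular rigidity must be positive, got {K_ul!r}")
    return K_ul * PER_UL_TO_PER_M3


def lame_from_young_poisson(E: float, nu: float) -> tuple[float, float]:
    """Shear modulus and plane-stress-corrected Lame parameter from (E, nu).

    Returns ``(mu, lam_tilde)`` with mu = E / (2 (1 + nu)) and
    lam_tilde = 2 E nu / (1 + nu).  ``lam_tilde`` replaces the classical Lame
    lambda because a thin shell is in a plane-stress state; for an
    incompressible wall (nu = 0.5) this gives lam_tilde = 2 mu and mu = E/3.
    """
    if not (E > 0):
        raise ValueError(f"Young's modulus must be positive, got {E!r}")
    if not (-1.0 < nu <= 0.5):
        raise ValueError(f"Poisson ratio outside (-1, 0.5], got {nu!r}")
    mu = E / (2.0 * (1.0 + nu))
    lam_tilde = 2.0 * E * nu / (1.0 + nu)
    return mu, lam_tilde


def young_from_lame(mu: float, lam_tilde: float) -> tuple[float, float]:
    """Invert :func:`lame_from_young_poisson`: returns (E, nu)."""
    # lam_tilde/mu = 4 nu  =>  nu = lam_tilde / (4 mu)
    nu = lam_tilde / (4.0 * mu)
    E = 2.0 * mu * (1.0 + nu)
    return E, nu


def moduli_from_rigidity(R: float, h: float, K: float, p: float,
                         nu: float = 0.5) -> tuple[float, float, float]:
    """Effective shell moduli from ocular rigidity.

    E = pi R^4 K p / h, then (mu, lam_tilde) from ``lame_from_young_poisson``.
    Returns ``(mu, lam_tilde, E)``.  Degenerate at p = 0: under constant
    rigidity the modulus is proportional to the inflating pressure, so an
    unpressurised globe has no defined stiffness and is rejected.
    """
    for name, val in (("R", R), ("h", h), ("K", K)):
        if not (val > 0):
            raise ValueError(f"{name} must be positive, got {val!r}")
    if not (p > 0):
        raise ValueError(
            "moduli_from_rigidity requires p > 0: with constant ocular "
            "rigidity the effective modulus E = pi R^4 K p / h vanishes at "
            "zero pressure and the model is degenerate there")
    E = math.pi * R**4 * K * p / h
    mu, lam_tilde = lame_from_young_poisson(E, nu)
    return mu, lam_tilde, E


def ocular_compliance(K: float, p: float) -> float:
    """Ocular compliance C = dV/dp = 1/(K p) [m^3/Pa]."""
    if not (K > 0):
        raise ValueError(f"K must be positive, got {K!r}")
    if not (p > 0):
        raise ValueError(f"p must be positive, got {p!r}")
    return 1.0 / (K * p)


@dataclass(frozen=True)
class ShellSpec:
    """Geometry, density, effective moduli and pre-stress of the thin shell.

    Attributes
    ----------
    R : float
        Mid-surface reference radius [m].
    h : float
        Wall thickness [m].
    rho_s : float
        Shell density [kg/m^3].
    mu : float
        Shear modulus [Pa].
    lam_tilde : float
        Plane-stress-corrected Lame parameter [Pa].
    p : float
        Internal reference pressure (IOP / inflation pressure) [Pa].
    """

    R: float
    h: float
    rho_s: float
    mu: float
    lam_tilde: float
    p: float

    def __post_init__(self):
        if not (self.R > 0):
            raise ValueError(f"R must be positive, got {self.R!r}")
        if not (self.h > 0):
            raise ValueError(f"h must be positive, got {self.h!r}")
        if not (self.rho_s > 0):
            raise ValueError(f"rho_s must be positive, got {self.rho_s!r}")
        if not (self.mu > 0):
            raise ValueError(f"mu must be positive, got {self.mu!r}")
        if self.p < 0:
            raise ValueError(f"p must be non-negative, got {self.p!r}")
        if self.h / self.R >= 0.2:
            warnings.warn(
                f"h/R = {self.h / self.R:.3g} is outside the thin-shell "
                "regime (h/R < 0.2); results may be unreliable",
                stacklevel=2)

    @property
    def young(self) -> float:
        """Effective Young's modulus implied by (mu, lam_tilde)."""
        return young_from_lame(self.mu, self.lam_tilde)[0]

    @property
    def poisson(self) -> float:
        return young_from_lame(self.mu, self.lam_tilde)[1]

    @classmethod
    def from_young(cls, R: float, h: float, rho_s: float, E: float,
                   nu: float, p: float) -> "ShellSpec":
        mu, lam_tilde = lame_from_young_poisson(E, nu)
        return cls(R=R, h=h, rho_s=rho_s, mu=mu, lam_tilde=lam_tilde, p=p)

    @classmethod
    def from_rigidity(cls, R: float, h: float, rho_s: float, K: float,
                      p: float, nu: float = 0.5) -> "ShellSpec":
        mu, lam_tilde, _ = moduli_from_rigidity(R, h, K, p, nu)
        return cls(R=R, h=h, rho_s=rho_s, mu=mu, lam_tilde=lam_tilde, p=p)

    def at_pressure(self, p: float, rigidity: "RigidityModel | None" = None
                    ) -> "ShellSpec":
        """Shell at a different pressure.

        Without a rigidity model the moduli are kept frozen; with one, the
        moduli follow :func:`effective_young` (constant-rigidity moduli grow
        linearly with p, constant-compliance moduli stay frozen at the
        model's reference pressure).
        """
        if rigidity is None:
            return ShellSpec(R=self.R, h=self.h, rho_s=self.rho_s,
                             mu=self.mu, lam_tilde=self.lam_tilde, p=p)
        E = effective_young(rigidity, (self.R, self.h), p)
        mu, lam_tilde = lame_from_young_poisson(E, rigidity.poisson)
        return ShellSpec(R=self.R, h=self.h, rho_s=self.rho_s,
                         mu=mu, lam_tilde=lam_tilde, p=p)


@dataclass(frozen=True)
class RigidityModel:
    """How shell moduli respond to pressure changes.

    ``constant-rigidity`` keeps Friedenwald's K fixed, so E(p) grows linearly
    with p (material stiffening).  ``constant-compliance`` freezes the moduli
    at their value for ``p_freeze`` (ocular compliance C = 1/(K p_freeze)
    held constant), which isolates the purely geometric effect of pre-stress.
    """

    K: float
    p0: float
    poisson: float = 0.5
    mode: str = "constant-rigidity"
    p_freeze: float | None = None

    def __post_init__(self):
        if not (self.K > 0):
            raise ValueError(f"K must be positive, got {self.K!r}")
        if not (0.0 < self.poisson <= 0.5):
            raise ValueError(
                f"poisson must be in (0, 0.5], got {self.poisson!r}")
        if self.mode not in ("constant-rigidity", "constant-compliance"):
            raise ValueError(f"unknown rigidity mode {self.mode!r}")
        if self.mode == "constant-compliance" and self.p_freeze is None:
            object.__setattr__(self, "p_freeze", self.p0)


def effective_young(rigidity_model: RigidityModel,
                    geometry: tuple[float, float] | ShellSpec,
                    p: float) -> float:
    """Young's modulus at pressure p under the given rigidity model.

    ``geometry`` is (R, h) or a :class:`ShellSpec`.  Constant-rigidity mode:
    E(p) = pi R^4 K p / h.  Constant-compliance mode: E frozen at its value
    for the model's reference (freeze) pressure.
    """
    if isinstance(geometry, ShellSpec):
        R, h = geometry.R, geometry.h
    else:
        R, h = geometry
    if rigidity_model.mode == "constant-rigidity":
        p_eval = p
    else:
        p_eval = rigidity_model.p_freeze
    return moduli_from_rigidity(R, h, rigidity_model.K, p_eval,
                                rigidity_model.poisson)[2]


@dataclass(frozen=True)
class FillingSpec:
    """Density and Kelvin--Voigt parameters of the interior medium.

    gamma is the shear elastic modulus [Pa], eta the shear viscosity [Pa s].
    gamma = 0 is a Newtonian fluid; rho_v = 0 encodes a vacuum (the shell is
    then solved empty).
    """

    rho_v: float
    gamma: float
    eta: float
    label: str = "custom"

    def __post_init__(self):
        if self.rho_v < 0:
            raise ValueError(f"rho_v must be >= 0, got {self.rho_v!r}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma!r}")
        if self.eta < 0:
            raise ValueError(f"eta must be >= 0, got {self.eta!r}")

    @property
    def is_vacuum(self) -> bool:
        return self.rho_v == 0.0


#: Empty interior: the shell vibrates in vacuo.
VACUUM = FillingSpec(rho_v=0.0, gamma=0.0, eta=0.0, label="vacuum")

#: Healthy vitreous humor (Kelvin--Voigt fit of rheometric data).
VITREOUS = FillingSpec(rho_v=1000.0, gamma=10.0, eta=0.39, label="vitreous")

#: Water / fully liquefied vitreous.
WATER = FillingSpec(rho_v=1000.0, gamma=0.0, eta=1.0e-3, label="water")

#: Silicone oil used as a tamponade fluid after vitrectomy.
SILICONE_OIL = FillingSpec(rho_v=970.0, gamma=0.0, eta=0.5,
                           label="silicone-oil")

_FILLING_BY_LABEL = {
    "vacuum": VACUUM,
    "vitreous": VITREOUS,
    "water": WATER,
    "silicone-oil": SILICONE_OIL,
}


@dataclass
class Configuration:
    """A fully resolved model configuration."""

    shell: ShellSpec
    filling: FillingSpec
    rigidity: RigidityModel | None = None
    name: str = "custom"


def _resolve_pressure(section: dict) -> float:
    value = float(section["value"])
    unit = str(section.get("unit", "Pa")).lower()
    if unit == "mmhg":
        return pressure_mmHg_to_Pa(value)
    if unit == "kpa":
        return pressure_kPa_to_Pa(value)
    if unit == "pa":
        return value
    raise ValueError(f"unknown pressure unit {unit!r}")


def load_config(source: dict | str | Path) -> Configuration:
    """Build a :class:`Configuration` from a YAML file or a parsed dict.

    Expected sections::

        shell:    {R_mm, h_mm, rho, nu, E_MPa | rigidity_per_ul}
        filling:  {label} or {label, rho, gamma, eta}
        pressure: {value, unit: mmHg|kPa|Pa}
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
        name = Path(source).stem
    else:
        data = dict(source)
        name = data.get("name", "custom")

    sh = data["shell"]
    p = _resolve_pressure(data["pressure"])
    R = float(sh["R_mm"]) * 1e-3
    h = float(sh["h_mm"]) * 1e-3
    rho_s = float(sh["rho"])
    nu = float(sh.get("nu", 0.5))

    rigidity = None
    if "rigidity_per_ul" in sh:
        K = rigidity_per_microliter_to_SI(float(sh["rigidity_per_ul"]))
        rigidity = RigidityModel(K=K, p0=p, poisson=nu)
        shell = ShellSpec.from_rigidity(R=R, h=h, rho_s=rho_s, K=K, p=p, nu=nu)
    elif "E_MPa" in sh:
        E = float(sh["E_MPa"]) * 1e6
        shell = ShellSpec.from_young(R=R, h=h, rho_s=rho_s, E=E, nu=nu, p=p)
    else:
        raise ValueError("shell section needs either E_MPa or rigidity_per_ul")

    fl = data.get("filling", {"label": "vacuum"})
    label = fl.get("label", "custom")
    if set(fl) == {"label"}:
        try:
            filling = _FILLING_BY_LABEL[label]
        except KeyError:
            raise ValueError(f"unknown filling label {label!r}; provide "
                             "rho/gamma/eta explicitly") from None
    else:
        filling = FillingSpec(rho_v=float(fl["rho"]),
                              gamma=float(fl.get("gamma", 0.0)),
                              eta=float(fl.get("eta", 0.0)),
                              label=label)

    return Configuration(shell=shell, filling=filling, rigidity=rigidity,
                         name=name)


def load_preset(name: str) -> Configuration:
    """Load one of the bundled named presets.

    ``eye-table1``: human eye baseline (R = 11.2 mm, h = 0.5 mm, sclera
    density 1077 kg/m^3, ocular rigidity 0.021 per microlitre, IOP 15 mmHg,
    vitreous filling).  ``salimi-ball``: water-filled rubber ball used for
    validation (R = 25 mm, h = 4 mm, E = 4.8 MPa, nu = 0.45, shell density
    1200 kg/m^3, internal pressure 13.7 kPa).
    """
    ref = resources.files("bulbvib").joinpath("presets", f"{name}.yaml")
    if not ref.is_file():
        raise ValueError(f"unknown preset {name!r}")
    with resources.as_file(ref) as path:
        cfg = load_config(path)
    cfg.name = name
    return cfg
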