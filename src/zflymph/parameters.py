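"""Dimensional parameters, characteristic scales and dimensionless groups.

The model couples interstitial (Darcy/Brinkman) flow, reactive transport of
VEGFC and the MMP2 activation network, and collagen-I remodelling in a 2D
slice of a zebrafish trunk between 36 and 48 hours post-fertilisation.  All
solvers in this package operate on *nondimensional* quantities; this module
is the only place where physical units appear.  Units are carried explicitly
as documented floats and stripped exactly once, when :func:`compute_scales`
and :func:`compute_groups` turn a :class:`ParameterSet` into a
:class:`ScaleSet` and :class:`DimensionlessGroups`.

Species naming
--------------
``VC``     VEGFC (secreted tetramer, mobile, interstitial space only)
``M2P``    proMMP2   (mobile, both domains)
``M2``     MMP2      (mobile, both domains)
``T2``     TIMP2     (mobile, both domains)
``M2T2``   MMP2·TIMP2 complex (mobile, interstitial space only)
``C1``     collagen I (immobile, interstitial space)
``VCC1``   VEGFC·collagen-I complex (immobile, interstitial space)
``MT1``    MT1-MMP (immobile, LEC)
``MT1T2``  MT1-MMP·TIMP2 (immobile, LEC)
``MT1T2M2P``  MT1-MMP·TIMP2·proMMP2 ternary complex (immobile, LEC)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping

import yaml

__all__ = [
    "MOBILE_SPECIES",
    "ALL_SPECIES",
    "ParameterSet",
    "ScaleSet",
    "DimensionlessGroups",
    "InvalidParameterError",
    "average_da_pressure",
    "molecules_per_cell_to_molar",
    "stokes_einstein_radius",
    "initial_time_step",
    "compute_scales",
    "compute_groups",
]

# ---------------------------------------------------------------------------
# unit conversion constants (stripped exactly once, in this module)
# ---------------------------------------------------------------------------

MMHG_TO_PA = 133.322          # 1 mmHg in Pa
MMHG_TO_DYN_CM2 = 1333.22     # 1 mmHg in dyn cm^-2
MMHG_TO_CMH2O = 1.35951       # 1 mmHg in cmH2O
CMH2O_TO_DYN_CM2 = MMHG_TO_DYN_CM2 / MMHG_TO_CMH2O   # ~980.66
CP_TO_POISE = 1e-2            # 1 cP in P (dyn s cm^-2)
AVOGADRO = 6.02214076e23      # mol^-1
K_BOLTZMANN = 1.380649e-23    # J K^-1

MOBILE_SPECIES = ("VC", "M2", "M2P", "M2T2", "T2")
IMMOBILE_IS_SPECIES = ("C1", "VCC1")
IMMOBILE_LEC_SPECIES = ("MT1", "MT1T2", "MT1T2M2P")
ALL_SPECIES = MOBILE_SPECIES + IMMOBILE_IS_SPECIES + IMMOBILE_LEC_SPECIES


class InvalidParameterError(ValueError):
    """A physical parameter is missing, non-positive or dimensionally absurd."""


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------


def _default_D_inf() -> Dict[str, float]:
    # free-fluid diffusivities, cm^2 s^-1
    return {
        "VC": 5.01e-7,
        "M2": 0.85e-6,
        "M2P": 0.80e-6,
        "M2T2": 0.75e-6,
        "T2": 1.10e-6,
    }


def _default_k_deg() -> Dict[str, float]:
    # first-order enzymatic attack in the interstitial space, s^-1
    return {s: 1e-4 for s in MOBILE_SPECIES}


@dataclass(frozen=True)
class ParameterSet:
    """All dimensional parameters of the model, in the units stated.

    Defaults are the study's literature-derived values: vessel pressures and
    permeabilities plus interstitial-fluid properties; free-fluid
    diffusivities, collagen fibril geometry and partial specific volumes; and
    the kinetic constants of the VEGFC-collagen and MMP2 activation networks.
    """

    # -- interstitial flow -------------------------------------------------
    P_DA: float = 0.1844       # dorsal aorta pressure, mmHg
    P_PCV: float = 0.0         # posterior cardinal vein pressure, mmHg
    P_DLAV: float = 0.0        # DLAV pressure, mmHg
    L_DA: float = 7.20e6       # vascular permeability, cm s^-1 cmH2O^-1
    L_PCV: float = 7.20e6
    L_DLAV: float = 7.20e6
    mu: float = 1.200          # interstitial fluid dynamic viscosity, cP
    rho: float = 1025.0        # interstitial fluid density, kg m^-3
    M_C1: float = 300.0        # collagen-I molar mass, kg mol^-1

    # -- transport ---------------------------------------------------------
    D_inf: Dict[str, float] = field(default_factory=_default_D_inf)
    r_f: float = 2e-9          # collagen fibril radius, m
    v_C1: float = 0.75         # partial specific volume, dry collagen, cm^3 g^-1
    v_C1h: float = 1.89        # partial specific volume, hydrated collagen, cm^3 g^-1
    T: float = 298.0           # temperature, K

    # -- kinetics ----------------------------------------------------------
    k_on_VC_C1: float = 3.60e4     # M^-1 s^-1
    k_off_VC_C1: float = 3.60e-3   # s^-1
    k_on_M2_T2: float = 5.90e6     # M^-1 s^-1
    k_off_M2_T2: float = 6.30      # s^-1
    k_on_MT1_T2: float = 3.54e6    # M^-1 s^-1
    k_off_MT1_T2: float = 2e-4     # s^-1
    k_on_MT1T2_M2P: float = 0.14e6  # M^-1 s^-1
    k_off_MT1T2_M2P: float = 4.70e-3  # s^-1
    k_eff_act: float = 2.80e3      # M^-1 s^-1, MMP2 activation
    k_cat_M2_C1: float = 4.50e-3   # s^-1, collagenolysis turnover
    K_M_M2_C1: float = 8.50e-6     # M, Michaelis constant of collagenolysis
    k_deg: Dict[str, float] = field(default_factory=_default_k_deg)
    P_M2P: float = 2.64e-8         # LEC production rate, M s^-1
    P_T2: float = 1.54e-10         # LEC production rate, M s^-1
    R_DA_VC: float = 1.65e-17      # VEGFC surface release, mol dm^-2 s^-1

    # -- initial concentrations -------------------------------------------
    C_MT1_0: float = 5.71e-7       # M, MT1-MMP in the LEC
    C_C1_0: float = 3.50e-4        # M, collagen I (adult midpoint)
    C_C1_0_embryonic: float = 1.59e-6  # M, alternative embryonic/larval value

    # -- scale choices -----------------------------------------------------
    L: float = 434.0               # length scale, um (largest dimension)
    tau: float = 43200.0           # time scale, s (12 h)

    def __post_init__(self) -> None:
        positive = {
            "P_DA": self.P_DA, "L_DA": self.L_DA, "L_PCV": self.L_PCV,
            "L_DLAV": self.L_DLAV, "mu": self.mu, "rho": self.rho,
            "M_C1": self.M_C1, "r_f": self.r_f, "v_C1": self.v_C1,
            "v_C1h": self.v_C1h, "T": self.T,
            "k_on_VC_C1": self.k_on_VC_C1, "k_off_VC_C1": self.k_off_VC_C1,
            "k_on_M2_T2": self.k_on_M2_T2, "k_off_M2_T2": self.k_off_M2_T2,
            "k_on_MT1_T2": self.k_on_MT1_T2, "k_off_MT1_T2": self.k_off_MT1_T2,
            "k_on_MT1T2_M2P": self.k_on_MT1T2_M2P,
            "k_off_MT1T2_M2P": self.k_off_MT1T2_M2P,
            "k_eff_act": self.k_eff_act, "k_cat_M2_C1": self.k_cat_M2_C1,
            "K_M_M2_C1": self.K_M_M2_C1, "P_M2P": self.P_M2P,
            "P_T2": self.P_T2, "R_DA_VC": self.R_DA_VC,
            "C_MT1_0": self.C_MT1_0, "C_C1_0": self.C_C1_0,
            "L": self.L, "tau": self.tau,
        }
        for name, value in positive.items():
            if not (value > 0.0 and math.isfinite(value)):
                raise InvalidParameterError(f"{name} must be strictly positive, got {value!r}")
        for s in MOBILE_SPECIES:
            if self.D_inf.get(s, 0.0) <= 0.0:
                raise InvalidParameterError(f"D_inf[{s}] must be strictly positive")
            if self.k_deg.get(s, 0.0) <= 0.0:
                raise InvalidParameterError(f"k_deg[{s}] must be strictly positive")

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> Dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["D_inf"] = dict(self.D_inf)
        d["k_deg"] = dict(self.k_deg)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def with_overrides(self, **kw) -> "ParameterSet":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# elementary derivations
# ---------------------------------------------------------------------------


def average_da_pressure(peak: float, diastolic: float) -> float:
    """Arithmetic mean of peak-systolic and end-diastolic DA pressures (mmHg).

    The dorsal aorta pressure entering the model ignores pulsatility and is
    the mean of the two measured extremes.
    """
    if not (peak > 0.0 and diastolic > 0.0):
        raise InvalidParameterError("pressures must be strictly positive")
    return 0.5 * (peak + diastolic)


def molecules_per_cell_to_molar(n: float, cell_diameter_um: float) -> float:
    """Convert a per-cell molecule count to molar concentration.

    The cell is treated as a sphere of the given diameter; the count is
    divided by Avogadro's number and the sphere volume in litres.
    """
    if n < 0:
        raise InvalidParameterError("molecule count must be nonnegative")
    if cell_diameter_um <= 0:
        raise InvalidParameterError("cell diameter must be strictly positive")
    r_dm = cell_diameter_um * 1e-5 / 2.0          # um -> dm
    volume_litre = 4.0 / 3.0 * math.pi * r_dm**3  # dm^3 == L
    return n / (AVOGADRO * volume_litre)


def stokes_einstein_radius(D_inf_cm2_s: float, mu_cP: float, T_K: float) -> float:
    """Stokes-Einstein radius r_s = k_B T / (6 pi mu D), returned in metres."""
    if D_inf_cm2_s <= 0 or mu_cP <= 0 or T_K < 0:
        raise InvalidParameterError("need D > 0, mu > 0, T >= 0")
    D = D_inf_cm2_s * 1e-4          # cm^2/s -> m^2/s
    mu = mu_cP * 1e-3               # cP -> Pa s
    return K_BOLTZMANN * T_K / (6.0 * math.pi * mu * D)


def initial_time_step(p: ParameterSet) -> float:
    """Nondimensional diffusive time to traverse 1 um for the fastest species.

    The mobile species are absent initially and permeate the geometry on the
    diffusive time scale of the most diffusive species (TIMP2 by default);
    t = (1 um)^2 / max_i D_inf_i, nondimensionalised by tau.  This sets the
    magnitude of the integrator's first step (rounded down to 1e-7 in the
    default solver configuration).
    """
    d_max = max(p.D_inf[s] for s in MOBILE_SPECIES)   # cm^2/s
    t_seconds = (1e-4) ** 2 / d_max                   # (1 um in cm)^2 / D
    return t_seconds / p.tau


# ---------------------------------------------------------------------------
# scales
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaleSet:
    """Characteristic scales used for nondimensionalisation.

    ``L`` (um), ``tau`` (s), ``U`` (um/s), ``P_scale`` (mmHg) and one molar
    concentration scale per species.  The velocity scale solves eta_1 = 1
    (drag balances the driving pressure at full collagen); the concentration
    scales set the corresponding dimensionless production/binding terms to
    unity, so the groups lambda_8, lambda_12, lambda_16, lambda_22, lambda_31
    and the DA influx lambda_DA_VC are 1 by construction.
    """

    L: float
    tau: float
    U: float
    P_scale: float
    C_s: Dict[str, float]

    def concentration(self, species: str) -> float:
        return self.C_s[species]


def _kappa_at_full_collagen(p: ParameterSet, beta_cm2: float, alpha: float) -> float:
    """Specific hydraulic conductivity (cm^2) at the collagen-I scale."""
    mass_fraction = p.M_C1 * p.C_C1_0  # (kg/mol)(mol/dm^3) / (1 kg/dm^3)
    return beta_cm2 * mass_fraction**alpha


def conductivity_constants() -> tuple[float, float]:
    """(alpha, beta): the log-log conductivity regression, slope and intercept.

    log10 kappa' = alpha * log10[collagen mass fraction] - 14.18 with kappa'
    in cm^4 s^-1 dyn^-1 for a 1 cP reference fluid; the specific conductivity
    is kappa = kappa' * 1e-2 dyn s cm^-2, hence beta = 1e-2 * 10^-14.18 cm^2.
    """
    alpha = -2.70
    beta = 1e-2 * 10.0 ** (-14.18)
    return alpha, beta


def compute_scales(p: ParameterSet) -> ScaleSet:
    """Derive the velocity and concentration scales from a parameter set."""
    alpha, beta = conductivity_constants()
    kappa = _kappa_at_full_collagen(p, beta, alpha)          # cm^2
    P_dyn = p.P_DA * MMHG_TO_DYN_CM2                          # dyn cm^-2
    mu_P = p.mu * CP_TO_POISE                                 # poise
    L_cm = p.L * 1e-4
    U_cm_s = kappa * P_dyn / (mu_P * L_cm)                    # eta_1 = 1
    U = U_cm_s * 1e4                                          # um/s

    tau = p.tau
    C_s: Dict[str, float] = {}
    C_s["C1"] = p.C_C1_0
    C_s["MT1"] = C_s["MT1T2"] = C_s["MT1T2M2P"] = p.C_MT1_0
    # lambda_DA_VC = R_DA_VC * tau / (C_VC_s * L) = 1
    R_mol_cm2_s = p.R_DA_VC / 100.0                           # mol dm^-2 -> mol cm^-2
    C_s["VC"] = R_mol_cm2_s * tau / L_cm * 1000.0             # mol/cm^3 -> M
    C_s["M2P"] = p.P_M2P * tau                                # lambda_8 = 1
    C_s["T2"] = p.P_T2 * tau                                  # lambda_16 = 1
    C_s["M2"] = p.k_eff_act * tau * p.C_MT1_0**2              # lambda_12 = 1
    C_s["M2T2"] = p.k_on_M2_T2 * tau * C_s["M2"] * C_s["T2"]  # lambda_22 = 1
    C_s["VCC1"] = p.k_on_VC_C1 * tau * C_s["VC"] * C_s["C1"]  # lambda_31 = 1
    return ScaleSet(L=p.L, tau=tau, U=U, P_scale=p.P_DA, C_s=C_s)


# ---------------------------------------------------------------------------
# dimensionless groups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DimensionlessGroups:
    """Every dimensionless group of the nondimensionalised model.

    ``eta`` groups parametrise the flow problem, ``lam`` the transport and
    kinetics.  ``lam['28']`` is kept in molar units together with ``K_M`` and
    ``C_C1_s`` because the Michaelis-Menten denominator K_M + C_C1_s*C~_C1 is
    dimensional; the ratio entering the equations is dimensionless.
    """

    alpha: float
    beta: float                 # cm^2
    eta_1: float
    eta_2: float
    eta_3: float
    eta_DA: float
    eta_PCV: float
    eta_DLAV: float
    lam_1: Dict[str, float]     # per mobile species: D_inf tau / L^2
    lam_2: Dict[str, float]     # per mobile species: r_s / r_f
    lam: Dict[str, float]       # lambda_3..lambda_42 plus 'DA_VC', keyed by number
    K_M: float                  # M
    C_C1_s: float               # M

    def __getitem__(self, key: str) -> float:
        return self.lam[key]


def compute_groups(p: ParameterSet, s: ScaleSet) -> DimensionlessGroups:
    """Evaluate every eta and lambda group from the parameters and scales."""
    alpha, beta = conductivity_constants()
    mu_P = p.mu * CP_TO_POISE
    L_cm = s.L * 1e-4
    U_cm = s.U * 1e-4
    P_dyn = s.P_scale * MMHG_TO_DYN_CM2
    tau = s.tau
    C = s.C_s

    eta_1 = mu_P * U_cm * L_cm / (P_dyn * beta * (p.M_C1 * C["C1"]) ** alpha)
    eta_2 = C["VCC1"] / C["C1"]
    eta_3 = mu_P * U_cm / (L_cm * P_dyn)
    # vascular permeabilities are per cmH2O of transvascular pressure
    lperm = {k: v / CMH2O_TO_DYN_CM2 for k, v in
             dict(DA=p.L_DA, PCV=p.L_PCV, DLAV=p.L_DLAV).items()}
    eta_DA = lperm["DA"] * P_dyn / U_cm
    eta_PCV = lperm["PCV"] * P_dyn / U_cm
    eta_DLAV = 2.0 * lperm["DLAV"] * P_dyn / U_cm

    lam_1 = {i: p.D_inf[i] * tau / L_cm**2 for i in MOBILE_SPECIES}
    lam_2 = {i: stokes_einstein_radius(p.D_inf[i], p.mu, p.T) / p.r_f
             for i in MOBILE_SPECIES}

    lam: Dict[str, float] = {}
    # v is cm^3/g == dm^3/kg; times M (kg/mol) times C (mol/dm^3) -> dimensionless
    lam["3"] = p.v_C1 * p.M_C1 * C["C1"]
    lam["4"] = p.v_C1 * p.M_C1 * C["VCC1"]
    lam["5"] = p.v_C1h * p.M_C1 * C["C1"]
    lam["6"] = p.v_C1h * p.M_C1 * C["VCC1"]
    lam["7"] = (s.U * tau) / s.L                     # um/s * s / um
    lam["8"] = p.P_M2P * tau / C["M2P"]
    lam["9"] = p.k_on_MT1T2_M2P * tau * C["MT1T2"]
    lam["10"] = p.k_off_MT1T2_M2P * tau * C["MT1T2M2P"] / C["M2P"]
    lam["11"] = p.k_deg["M2P"] * tau
    lam["12"] = p.k_eff_act * tau * C["MT1T2M2P"] * C["MT1"] / C["M2"]
    lam["13"] = p.k_on_M2_T2 * tau * C["T2"]
    lam["14"] = p.k_off_M2_T2 * tau * C["M2T2"] / C["M2"]
    lam["15"] = p.k_deg["M2"] * tau
    lam["16"] = p.P_T2 * tau / C["T2"]
    lam["17"] = p.k_on_MT1_T2 * tau * C["MT1"]
    lam["18"] = p.k_off_MT1_T2 * tau * C["MT1T2"] / C["T2"]
    lam["19"] = p.k_on_M2_T2 * tau * C["M2"]
    lam["20"] = p.k_off_M2_T2 * tau * C["M2T2"] / C["T2"]
    lam["21"] = p.k_deg["T2"] * tau
    lam["22"] = p.k_on_M2_T2 * tau * C["M2"] * C["T2"] / C["M2T2"]
    lam["23"] = p.k_off_M2_T2 * tau
    lam["24"] = p.k_deg["M2T2"] * tau
    lam["25"] = p.k_on_VC_C1 * tau * C["C1"]
    lam["26"] = p.k_off_VC_C1 * tau * C["VCC1"] / C["VC"]
    lam["27"] = p.k_deg["VC"] * tau
    lam["DA_VC"] = (p.R_DA_VC / 100.0) * tau / (C["VC"] / 1000.0 * L_cm)
    lam["28"] = p.k_cat_M2_C1 * tau * C["M2"]        # in M (spec: not truly dimensionless)
    lam["29"] = p.k_on_VC_C1 * tau * C["VC"]
    lam["30"] = p.k_off_VC_C1 * tau * C["VCC1"] / C["C1"]
    lam["31"] = p.k_on_VC_C1 * tau * C["VC"] * C["C1"] / C["VCC1"]
    lam["32"] = p.k_off_VC_C1 * tau
    lam["33"] = p.k_on_MT1_T2 * tau * C["T2"]
    lam["34"] = p.k_off_MT1_T2 * tau * C["MT1T2"] / C["MT1"]
    lam["35"] = p.k_on_MT1_T2 * tau * C["MT1"] * C["T2"] / C["MT1T2"]
    lam["36"] = p.k_off_MT1_T2 * tau
    lam["37"] = p.k_on_MT1T2_M2P * tau * C["M2P"]
    lam["38"] = p.k_off_MT1T2_M2P * tau * C["MT1T2M2P"] / C["MT1T2"]
    lam["39"] = p.k_eff_act * tau * C["MT1T2M2P"] * C["MT1"] / C["MT1T2"]
    lam["40"] = p.k_on_MT1T2_M2P * tau * C["MT1T2"] * C["M2P"] / C["MT1T2M2P"]
    lam["41"] = p.k_off_MT1T2_M2P * tau
    lam["42"] = p.k_eff_act * tau * C["MT1"]

    return DimensionlessGroups(
        alpha=alpha, beta=beta,
        eta_1=eta_1, eta_2=eta_2, eta_3=eta_3,
        eta_DA=eta_DA, eta_PCV=eta_PCV, eta_DLAV=eta_DLAV,
        lam_1=lam_1, lam_2=lam_2, lam=lam,
        K_M=p.K_M_M2_C1, C_C1_s=C["C1"],
    )
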