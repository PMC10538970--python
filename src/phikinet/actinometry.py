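"""Photon flux from lamp irradiance, kinactinometry, and actinometer calibration.

The incident photon flux entering the reactor,

    P0 = [E_sp lambda / (Na h c)] * S_irr / V_irr   (einstein s^-1 dm^-3),

converts a measured spectral irradiance (J s^-1 cm^-2 at the single
irradiation wavelength) into moles of photons per second, per irradiated
area and volume. "Kinactinometry" inverts the initial-rate law of a
standardized photoreaction to measure P0 from a kinetic trace alone.

Note: P0 multiplies by the actually irradiated sample area S_irr, so it
differs from the IUPAC spectral photon flux per volume (q_n,p/V) unless
S_irr = 1 cm^2; both conventions are reported side by side.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import linregress

from .phiorder import CoupledFit, eval_model, model_initial_rate

__all__ = [
    "PLANCK_H",
    "SPEED_OF_LIGHT",
    "AVOGADRO",
    "LampSpec",
    "molar_photon_energy",
    "photon_flux",
    "kinactinometry",
    "CalibrationLine",
    "CalibrationReport",
    "calibrate_actinometer",
]

# Physical constants at the precision used throughout the numeric examples.
PLANCK_H = 6.62608e-34  # J s
SPEED_OF_LIGHT = 299792458.0  # m s^-1
AVOGADRO = 6.02214e23  # einstein^-1


@dataclass(frozen=True)
class LampSpec:
    """Monochromatic lamp and reactor geometry.

    ``e_sp_irr`` is the spectral irradiance at the irradiation wavelength
    in J s^-1 cm^-2 (the per-nm dimension is dropped for a monochromatic
    beam); ``s_irr`` the irradiated area in cm^2; ``v_irr`` the irradiated
    volume in dm^3.
    """

    e_sp_irr: float
    lambda_irr: float
    s_irr: float
    v_irr: float

    def __post_init__(self) -> None:
        for name in ("e_sp_irr", "lambda_irr", "s_irr", "v_irr"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def check_geometry(self, l_irr: float) -> None:
        if self.v_irr / self.s_irr * 1000.0 < l_irr:  # dm^3/cm^2 -> cm
            warnings.warn(
                "V_irr/S_irr is smaller than the optical path l_irr; "
                "check the reactor geometry", stacklevel=2,
            )


def molar_photon_energy(lambda_nm: float) -> float:
    """Energy of one einstein of photons at the given wavelength, J einstein^-1."""
    return AVOGADRO * PLANCK_H * SPEED_OF_LIGHT / (lambda_nm * 1e-9)


def photon_flux(ls: LampSpec, l_irr: float | None = None) -> float:
    """Incident photon flux P0 entering the reactor, einstein s^-1 dm^-3.

    ``P0 = [E_sp / E_mol(lambda)] * S_irr / V_irr``; the IUPAC-style
    ``q_n,p/V`` equals ``P0 / S_irr`` (they coincide for S_irr = 1 cm^2).
    """
    if l_irr is not None:
        ls.check_geometry(l_irr)
    flx = ls.e_sp_irr / molar_photon_energy(ls.lambda_irr)  # einstein s^-1 cm^-2
    return flx * ls.s_irr / ls.v_irr


def kinactinometry(r0x: float, phi_sum: float, ax0: float) -> float:
    """Incident photon flux from the initial rate of a standardized reaction.

    ``P0 = -r0X / [Phi_sum (1 - 10^-AX0)]`` -- the initial-rate law solved
    for P0. ``r0x`` must be negative (the reactant is consumed) and
    ``phi_sum`` is the summed quantum yield of the steps leaving the
    reactant, known for a standardized actinometer.
    """
    if not phi_sum > 0:
        raise ValueError("phi_sum must be > 0")
    if not ax0 > 0:
        raise ValueError("ax0 must be > 0")
    if r0x >= 0:
        raise ValueError("the reactant initial rate must be negative")
    return -r0x / (phi_sum * -np.expm1(-ax0 * np.log(10.0)))


@dataclass(frozen=True)
class CalibrationLine:
    """Ordinary least-squares line of one observable versus P0."""

    quantity: str
    slope: float
    intercept: float
    r2: float


@dataclass(frozen=True)
class CalibrationReport:
    lines: tuple[CalibrationLine, ...]
    c_inf_spread: dict[str, float]  # relative spread of C_inf across runs
    half_lives: tuple[float, ...]  # model-implied reactant half-lives per run

    def line(self, quantity: str) -> CalibrationLine:
        for ln in self.lines:
            if ln.quantity == quantity:
                return ln
        raise KeyError(quantity)


def _model_half_life(cf: CoupledFit) -> float:
    """Reactant half-life implied by the fitted model (bisection on the model)."""
    name = cf.species[0]
    pm = cf.models[name]
    c0 = eval_model(pm, 0.0)
    target = 0.5 * (c0 + pm.c_inf)
    kmin = min((k for _, k in pm.terms), default=1.0)
    t_hi = 1.0
    while eval_model(pm, t_hi) > target and t_hi < 1e6 / kmin:
        t_hi *= 2.0
    return float(brentq(lambda t: eval_model(pm, t) - target, 0.0, t_hi, xtol=1e-9))


def calibrate_actinometer(runs: list[tuple[float, CoupledFit]]) -> CalibrationReport:
    """Least-squares calibration lines of rate constants and initial rates vs P0.

    ``runs`` are (P0, coupled fit) pairs for the same reactive system
    differing only in the incident flux. Each shared rate constant and
    each species' initial rate (plus the total-absorbance model's, when
    fitted) is regressed against P0 with an intercept, so a nonzero
    intercept remains visible as a diagnostic. Also reports the relative
    spread of the final concentrations across runs (they must be invariant
    with P0) and the model-implied reactant half-lives (they must shrink
    as P0 grows).
    """
    if len(runs) < 3:
        raise ValueError("need at least 3 runs at different P0 for a calibration")
    p0s = np.array([p for p, _ in runs])
    if len(np.unique(p0s)) < len(p0s):
        raise ValueError("P0 values must be distinct (rank-deficient input)")
    fits = [cf for _, cf in runs]
    n_k = min(len(cf.k_values) for cf in fits)
    lines: list[CalibrationLine] = []
    for i in range(n_k):
        ks = np.array([sorted(cf.k_values, reverse=True)[i] for cf in fits])
        res = linregress(p0s, ks)
        lines.append(CalibrationLine(f"k{i + 1}", res.slope, res.intercept, res.rvalue**2))
    for name in fits[0].species:
        r0 = np.array([model_initial_rate(cf.models[name]) for cf in fits])
        res = linregress(p0s, r0)
        lines.append(CalibrationLine(f"r0_{name}", res.slope, res.intercept, res.rvalue**2))
    if all(cf.atot_model is not None for cf in fits):
        r0a = np.array([model_initial_rate(cf.atot_model) for cf in fits])
        res = linregress(p0s, r0a)
        lines.append(CalibrationLine("r0_Atot", res.slope, res.intercept, res.rvalue**2))
    c_inf_spread = {}
    for name in fits[0].species:
        vals = np.array([cf.models[name].c_inf for cf in fits])
        scale = max(float(np.max(np.abs(vals))), 1e-300)
        c_inf_spread[name] = float(np.ptp(vals) / scale)
    half_lives = tuple(_model_half_life(cf) for cf in fits)
    return CalibrationReport(lines=tuple(lines), c_inf_spread=c_inf_spread, half_lives=half_lives)
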