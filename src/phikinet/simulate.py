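"""Photokinetic rate law and fixed-step Runge-Kutta simulation.

The rate of each species j under monochromatic irradiation is

    r_j(t) = sum over steps  [ -phi_{j->j'} Pa_j(t) + phi_{j'->j} Pa_j'(t) ]

where the light absorbed by species j,

    Pa_j(t) = A_j(t) P0 PKF(Atot(t)),      PKF(a) = (1 - 10^-a) / a,

is its share of the total absorbed photon flux. The total absorbance
includes every absorber present -- reactive species and inert spectators
alike -- which makes the rate law nonlinear and couples species that do not
share any reaction step.

Traces are integrated with a classic fixed-step fourth-order Runge-Kutta
scheme (default step 0.1 s), which keeps results bit-reproducible.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .mechanism import IrradiationSetup, Mechanism

__all__ = [
    "LN10",
    "KineticTrace",
    "SimulationError",
    "ConvergenceError",
    "photokinetic_factor",
    "absorbed_light",
    "rate_law",
    "simulate",
    "simulate_to_steady",
    "total_absorbance_trace",
    "photostationary_state",
    "half_life",
]

LN10 = math.log(10.0)

#: Total absorbance above which the Beer-Lambert linearity of typical
#: calibration graphs becomes doubtful; the simulator only warns.
ATOT_LINEARITY_GUIDELINE = 0.5

_NEG_CLAMP = -1e-12


class SimulationError(RuntimeError):
    """Raised when the integrator produces unphysical concentrations."""


class ConvergenceError(RuntimeError):
    """Raised when no photostationary/steady state is reached in time."""


def photokinetic_factor(atot):
    """Dimensionless photokinetic factor ``(1 - 10^-a) / a``.

    Continuous at ``a = 0`` (limit ``ln 10``) and strictly decreasing.
    Accepts scalars or arrays; negative absorbances raise ``ValueError``.
    """
    a = np.asarray(atot, dtype=float)
    if np.any(a < 0):
        raise ValueError("total absorbance must be >= 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(a > 0, -np.expm1(-a * LN10) / np.where(a > 0, a, 1.0), LN10)
    return float(out) if np.isscalar(atot) or np.ndim(atot) == 0 else out


def absorbed_light(a_species, atot, p0: float):
    """Photon flux absorbed by one absorber, einstein s^-1 dm^-3.

    ``Pa = A_j * P0 * PKF(Atot)``. Summed over every absorber (spectators
    included) this equals ``P0 (1 - 10^-Atot)``.
    """
    a_species = np.asarray(a_species, dtype=float)
    if np.any(a_species < 0):
        raise ValueError("species absorbance must be >= 0")
    if np.any(a_species > np.asarray(atot) * (1 + 1e-12) + 1e-15):
        raise ValueError("species absorbance cannot exceed the total absorbance")
    out = a_species * p0 * photokinetic_factor(atot)
    return float(out) if out.ndim == 0 else out


class _RateEvaluator:
    """Precompiled rate-law structure for one (mechanism, setup) pair."""

    def __init__(self, m: Mechanism, s: IrradiationSetup):
        self.m, self.s = m, s
        self.eps_l = np.array([sp.epsilon for sp in m.species]) * s.l_irr
        self.a_spm = m.spectator_absorbance
        self.p0 = s.p0
        self.src = np.array([m.index(st.source) for st in m.steps], dtype=int)
        self.tgt = np.array([m.index(st.target) for st in m.steps], dtype=int)
        self.phi = np.array([st.phi for st in m.steps])
        # incidence matrix: column per step, -1 at source, +1 at target
        B = np.zeros((m.nsp, m.n_phi))
        for q in range(m.n_phi):
            B[self.src[q], q] -= 1.0
            B[self.tgt[q], q] += 1.0
        self.B = B

    def atot(self, c: np.ndarray) -> float:
        return float(self.eps_l @ c) + self.a_spm

    def __call__(self, c: np.ndarray) -> np.ndarray:
        a = self.eps_l * c
        # clamp: intermediate RK stages may transiently dip below zero
        at = max(float(a.sum()) + self.a_spm, 0.0)
        pa = a * (self.p0 * photokinetic_factor(at))
        return self.B @ (self.phi * pa[self.src])


def rate_law(m: Mechanism, s: IrradiationSetup, c) -> np.ndarray:
    """Instantaneous rate vector (M s^-1) at concentration vector ``c``.

    Spectator absorbances enter the total absorbance (slowing every
    species) but spectators themselves have no rate. The rates sum to
    zero: the mechanism only interconverts species.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (m.nsp,):
        raise ValueError(f"expected concentration vector of length {m.nsp}, got shape {c.shape}")
    return _RateEvaluator(m, s)(c)


@dataclass(frozen=True)
class KineticTrace:
    """Simulated or measured kinetic traces on a common time grid.

    ``conc`` has one column per species in mechanism order; ``atot`` is
    the total absorbance of the medium at lambda_irr (spectators included).
    """

    times: np.ndarray
    conc: np.ndarray
    species: tuple[str, ...]
    atot: np.ndarray | None = None

    @property
    def c_total(self) -> np.ndarray:
        return self.conc.sum(axis=1)

    def column(self, name: str) -> np.ndarray:
        return self.conc[:, self.species.index(name)]

    def at(self, t) -> np.ndarray:
        """Concentration vector(s) at time(s) ``t`` by linear interpolation."""
        t = np.asarray(t, dtype=float)
        out = np.stack([np.interp(t, self.times, self.conc[:, j]) for j in range(self.conc.shape[1])], axis=-1)
        return out

    def atot_at(self, t):
        if self.atot is None:
            raise ValueError("trace has no total-absorbance series")
        return np.interp(t, self.times, self.atot)

    def subsample(self, max_points: int) -> "KineticTrace":
        """Uniformly thinned copy keeping the first and last grid points."""
        n = len(self.times)
        if n <= max_points:
            return self
        idx = np.unique(np.linspace(0, n - 1, max_points).round().astype(int))
        return KineticTrace(
            times=self.times[idx],
            conc=self.conc[idx],
            species=self.species,
            atot=None if self.atot is None else self.atot[idx],
        )


def _rk4(ev: _RateEvaluator, c0: np.ndarray, n_steps: int, dt: float) -> np.ndarray:
    out = np.empty((n_steps + 1, c0.size))
    out[0] = c = c0.copy()
    for i in range(n_steps):
        k1 = ev(c)
        k2 = ev(c + 0.5 * dt * k1)
        k3 = ev(c + 0.5 * dt * k2)
        k4 = ev(c + dt * k3)
        c = c + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if np.any(c < _NEG_CLAMP):
            raise SimulationError(
                f"negative concentration at t={(i + 1) * dt:g} s; use a smaller dt"
            )
        np.clip(c, 0.0, None, out=c)
        out[i + 1] = c
    return out


def simulate(
    m: Mechanism,
    s: IrradiationSetup,
    t_end: float,
    dt: float = 0.1,
    warn_linearity: bool = True,
) -> KineticTrace:
    """Integrate the rate law with fixed-step RK4 from the declared c0.

    The returned trace includes the t=0 row and the total-absorbance
    series recomputed from the concentrations. Deterministic.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    if not 0 < dt <= 5:
        raise ValueError("dt must be in (0, 5] s")
    ev = _RateEvaluator(m, s)
    n_steps = int(round(t_end / dt))
    c0 = np.array([sp.c0 for sp in m.species], dtype=float)
    conc = _rk4(ev, c0, n_steps, dt)
    times = np.arange(n_steps + 1) * dt
    atot = conc @ ev.eps_l + ev.a_spm
    if warn_linearity and float(atot.max(initial=0.0)) > ATOT_LINEARITY_GUIDELINE:
        warnings.warn(
            f"Atot exceeds {ATOT_LINEARITY_GUIDELINE} during the run; "
            "concentrations may leave the Beer-Lambert linearity range",
            stacklevel=2,
        )
    return KineticTrace(times=times, conc=conc, species=m.names, atot=atot)


def _k_scale(m: Mechanism, s: IrradiationSetup) -> float:
    """Crude upper-bound rate-constant scale, s^-1 (primary-photoprocess formula)."""
    ks = [
        st.phi * m.species[m.index(st.source)].epsilon * s.p0 * s.l_irr * LN10
        for st in m.steps
    ]
    return max(ks) if ks else 1.0


def simulate_to_steady(
    m: Mechanism,
    s: IrradiationSetup,
    dt: float | None = None,
    rate_frac: float = 1e-3,
    t_max: float | None = None,
    max_points: int | None = None,
) -> KineticTrace:
    """Simulate until every rate has decayed to ``rate_frac`` of its initial scale.

    Convenience wrapper used to produce traces that span several
    half-lives (the regime the trace-fitting protocol requires).
    """
    k = _k_scale(m, s)
    if dt is None:
        dt = min(5.0, max(0.1, 0.02 / k))
    t_half = math.log(2) / k
    if t_max is None:
        t_max = max(200.0 * t_half, 100 * dt)
    ev = _RateEvaluator(m, s)
    c0 = np.array([sp.c0 for sp in m.species], dtype=float)
    r0 = float(np.max(np.abs(ev(c0))))
    block = max(64, int(round(10 * t_half / dt)))
    chunks = [c0[None, :]]
    c = c0
    t = 0.0
    while True:
        seg = _rk4(ev, c, block, dt)
        chunks.append(seg[1:])
        c = seg[-1]
        t += block * dt
        if float(np.max(np.abs(ev(c)))) <= rate_frac * r0 or t >= t_max:
            break
    conc = np.concatenate(chunks, axis=0)
    times = np.arange(conc.shape[0]) * dt
    atot = conc @ ev.eps_l + ev.a_spm
    tr = KineticTrace(times=times, conc=conc, species=m.names, atot=atot)
    if max_points is not None:
        tr = tr.subsample(max_points)
    return tr


def total_absorbance_trace(
    tr: KineticTrace, m: Mechanism, s: IrradiationSetup, observed: bool = False
) -> np.ndarray:
    """Total absorbance series recomputed from the concentrations.

    ``Atot(t) = sum_r A_SPM,r + sum_j eps_j * l_irr * C_j(t)``. With
    ``observed=True`` the series is rescaled by ``l_obs / l_irr`` (the
    inverse rescaling, multiplying by ``l_irr / l_obs``, restores it).
    """
    if tr.species != m.names:
        raise ValueError("trace columns do not match the mechanism's species")
    eps_l = np.array([sp.epsilon for sp in m.species]) * s.l_irr
    atot = tr.conc @ eps_l + m.spectator_absorbance
    if observed:
        atot = atot * (s.path_obs / s.l_irr)
    return atot


def photostationary_state(
    m: Mechanism,
    s: IrradiationSetup,
    rate_tol: float = 1e-15,
    t_max: float | None = None,
    dt: float | None = None,
) -> np.ndarray:
    """Final concentration vector under continuous irradiation.

    For the two-species photoreversible system ``X <-> Y1`` the closed
    form ``C_Y1_inf / C_X_inf = (phi_f eps_X) / (phi_r eps_Y1)`` is used;
    otherwise the long-time RK limit is returned (steady state detected
    when ``max |rate| < rate_tol`` M/s).
    """
    c_tot = sum(sp.c0 for sp in m.species)
    if m.nsp == 2 and m.n_phi <= 2:
        x, y = m.names
        fwd = next((st for st in m.steps if st.source == x), None)
        rev = next((st for st in m.steps if st.source == y), None)
        if fwd is not None and rev is None:
            return np.array([0.0, c_tot])  # irreversible: full conversion
        if fwd is not None and rev is not None:
            num = fwd.phi * m.species[0].epsilon
            den = rev.phi * m.species[1].epsilon
            if den > 0:
                ratio = num / den  # C_Y_inf / C_X_inf
                cx = c_tot / (1.0 + ratio)
                return np.array([cx, c_tot - cx])
            return np.array([0.0, c_tot])  # transparent product: full conversion
    ev = _RateEvaluator(m, s)
    k = _k_scale(m, s)
    if dt is None:
        dt = min(5.0, max(0.1, 0.02 / k))
    t_half = math.log(2) / k
    if t_max is None:
        t_max = max(100.0 * t_half, 100 * dt)
    c = np.array([sp.c0 for sp in m.species], dtype=float)
    t = 0.0
    block = max(64, int(round(5 * t_half / dt)))
    while t < t_max:
        c = _rk4(ev, c, block, dt)[-1]
        t += block * dt
        if float(np.max(np.abs(ev(c)))) < rate_tol:
            return c
    if float(np.max(np.abs(ev(c)))) < rate_tol:
        return c
    raise ConvergenceError(f"no steady state within t_max={t_max:g} s (max|rate|={np.max(np.abs(ev(c))):.3g})")


def half_life(tr: KineticTrace, cx_inf: float | None = None) -> float:
    """Operational reactant half-life.

    First time the reactant trace crosses ``(C_X(0) + C_X_inf) / 2``, by
    linear interpolation on the grid; ``cx_inf`` defaults to the last
    trace value.
    """
    cx = tr.conc[:, 0]
    if cx_inf is None:
        cx_inf = float(cx[-1])
    target = 0.5 * (cx[0] + cx_inf)
    below = np.nonzero(cx <= target)[0]
    if below.size == 0:
        raise ValueError("trace never reaches the half-conversion level")
    i = int(below[0])
    if i == 0:
        return 0.0
    t0, t1 = tr.times[i - 1], tr.times[i]
    c0, c1 = cx[i - 1], cx[i]
    return float(t0 + (target - c0) * (t1 - t0) / (c1 - c0))
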