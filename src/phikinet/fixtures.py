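"""Canonical example systems and the synthetic-condition generator.

Every input the test battery needs is generated here: the photoreversible
worked example (with the extrinsic values of its published illustration),
the primary photoprocess, divergent and cyclic sub-mechanisms of the
canonical template, spectator and flux-grid conditions, and seeded random
sub-mechanisms. Defaults reproduce the standard study conditions:
CX0 = 1.58e-5 M, P0 = 1.25e-5 einstein s^-1 dm^-3, l_irr = 1.65 cm,
quantum yields of a few percent and absorption coefficients of order 1e4
M^-1 cm^-1, typical of organic photoswitches and photolabile drugs.
"""
from __future__ import annotations

import numpy as np

from .mechanism import (
    IrradiationSetup,
    Mechanism,
    ReactionStep,
    SCHEME1_STEPS,
    Species,
    Spectator,
    scheme1_template,
)

__all__ = [
    "DEFAULT_SETUP",
    "table1_system",
    "primary_photoprocess",
    "branch_system",
    "cyclic3_system",
    "consecutive_system",
    "isosbestic_system",
    "p0_grid",
    "random_submechanism",
    "FIXTURE_CASES",
]

DEFAULT_SETUP = IrradiationSetup(lambda_irr=370.0, p0=1.25e-5, l_irr=1.65)


def table1_system() -> tuple[Mechanism, IrradiationSetup]:
    """The photoreversible reference system ``X <-> Y1``.

    CX0 = 1.58e-5 M, eps_X = 12004, eps_Y1 = 23123 M^-1 cm^-1,
    Phi_f = 0.062, Phi_r = 0.034, P0 = 1.25e-5 einstein s^-1 dm^-3,
    l = 1.65 cm.
    """
    m = Mechanism(
        species=(
            Species("X", epsilon=12004.0, c0=1.58e-5),
            Species("Y1", epsilon=23123.0, c0=0.0),
        ),
        steps=(
            ReactionStep("X", "Y1", phi=0.062),
            ReactionStep("Y1", "X", phi=0.034),
        ),
    )
    return m, DEFAULT_SETUP


def primary_photoprocess(
    phi: float = 0.05,
    eps_x: float = 12004.0,
    eps_y: float = 0.0,
    c0: float = 1.58e-5,
) -> tuple[Mechanism, IrradiationSetup]:
    """``X -> Y1``; with the default transparent product it has an exact solution."""
    m = Mechanism(
        species=(Species("X", epsilon=eps_x, c0=c0), Species("Y1", epsilon=eps_y, c0=0.0)),
        steps=(ReactionStep("X", "Y1", phi=phi),),
    )
    return m, DEFAULT_SETUP


def branch_system(
    phi1: float = 0.03,
    phi3: float = 0.05,
    eps: tuple[float, float, float] = (12004.0, 8000.0, 15000.0),
    c0: float = 1.58e-5,
) -> tuple[Mechanism, IrradiationSetup]:
    """Divergent ``Y1 <- X -> Y3`` (the branch quantum-yield benchmark)."""
    m = Mechanism(
        species=(
            Species("X", epsilon=eps[0], c0=c0),
            Species("Y1", epsilon=eps[1], c0=0.0),
            Species("Y3", epsilon=eps[2], c0=0.0),
        ),
        steps=(ReactionStep("X", "Y1", phi=phi1), ReactionStep("X", "Y3", phi=phi3)),
    )
    return m, DEFAULT_SETUP


def cyclic3_system(c0: float = 1.58e-5) -> tuple[Mechanism, IrradiationSetup]:
    """Cyclic three-species system ``X <-> Y1 <-> Y2 <-> X`` (six steps)."""
    m = Mechanism(
        species=(
            Species("X", epsilon=12004.0, c0=c0),
            Species("Y1", epsilon=18000.0, c0=0.0),
            Species("Y2", epsilon=9000.0, c0=0.0),
        ),
        steps=(
            ReactionStep("X", "Y1", phi=0.062),
            ReactionStep("Y1", "X", phi=0.034),
            ReactionStep("Y1", "Y2", phi=0.045),
            ReactionStep("Y2", "Y1", phi=0.020),
            ReactionStep("Y2", "X", phi=0.030),
            ReactionStep("X", "Y2", phi=0.015),
        ),
    )
    return m, DEFAULT_SETUP


def consecutive_system(
    n_products: int = 4,
    a_spm: float = 0.0,
    c0: float = 1.58e-5,
) -> tuple[Mechanism, IrradiationSetup]:
    """Multi-consecutive chain ``X -> Y1 -> ... -> Yn`` with optional spectator."""
    if not 1 <= n_products <= 7:
        raise ValueError("n_products must be in 1..7")
    names = ["X"] + [f"Y{i}" for i in range(1, n_products + 1)]
    eps = [12004.0, 16000.0, 9500.0, 20000.0, 7000.0, 14000.0, 11000.0, 18500.0]
    phis = [0.062, 0.048, 0.035, 0.055, 0.028, 0.040, 0.033]
    species = tuple(
        Species(n, epsilon=eps[i], c0=c0 if i == 0 else 0.0) for i, n in enumerate(names)
    )
    steps = tuple(
        ReactionStep(names[i], names[i + 1], phi=phis[i]) for i in range(n_products)
    )
    spect = (Spectator("SPM1", absorbance=a_spm),) if a_spm > 0 else ()
    m = Mechanism(species=species, steps=steps, spectators=spect)
    return m, DEFAULT_SETUP


def isosbestic_system(eps: float = 15000.0, c0: float = 1.58e-5) -> tuple[Mechanism, IrradiationSetup]:
    """Photoreversible system irradiated at an isosbestic wavelength.

    All species share one absorption coefficient, so the total absorbance
    is constant and the kinetics collapse to first order.
    """
    m = Mechanism(
        species=(Species("X", epsilon=eps, c0=c0), Species("Y1", epsilon=eps, c0=0.0)),
        steps=(ReactionStep("X", "Y1", phi=0.062), ReactionStep("Y1", "X", phi=0.034)),
    )
    return m, DEFAULT_SETUP


def p0_grid(factors=(0.25, 0.5, 1.0, 2.0, 4.0), p0_ref: float = 1.25e-5) -> list[IrradiationSetup]:
    """Setups differing only in incident flux, for actinometer calibration lines."""
    return [
        IrradiationSetup(lambda_irr=DEFAULT_SETUP.lambda_irr, p0=f * p0_ref, l_irr=DEFAULT_SETUP.l_irr)
        for f in factors
    ]


_FORWARD_TREE = ["X->Y1", "X->Y3", "Y1->Y2", "Y3->Y4", "Y2->Y5", "Y4->Y6", "Y5->Y7"]


def random_submechanism(
    rng: np.random.Generator,
    n_products: int | None = None,
    a0_target: float = 0.31294,
) -> tuple[Mechanism, IrradiationSetup]:
    """A random connected sub-mechanism of the canonical template.

    Grows a random forward tree from X (1-4 photoproducts), includes each
    reverse step with probability 1/2, and draws quantum yields uniformly
    from [0.01, 0.5] and absorption coefficients from [1e3, 5e4] M^-1 cm^-1.
    CX0 is set so the initial absorbance matches ``a0_target`` but is
    capped so the total absorbance can never leave the window in which the
    unifying trace model is established (Atot <= 0.6 at all times, cf. the
    Beer-Lambert linearity guideline).
    """
    if n_products is None:
        n_products = int(rng.integers(1, 5))
    present = {"X"}
    labels: list[str] = []
    cands = list(_FORWARD_TREE)
    while len(present) - 1 < n_products:
        viable = [lb for lb in cands if SCHEME1_STEPS[lb][0] in present and SCHEME1_STEPS[lb][1] not in present]
        lb = viable[int(rng.integers(len(viable)))]
        labels.append(lb)
        present.add(SCHEME1_STEPS[lb][1])
    for lb in list(labels):
        rev = "->".join(reversed(lb.split("->")))
        if rng.random() < 0.5:
            labels.append(rev)
    names = sorted(present - {"X"}, key=lambda n: int(n[1:]))
    eps = {"X": float(rng.uniform(1e3, 5e4))}
    eps.update({n: float(rng.uniform(1e3, 5e4)) for n in names})
    phis = {lb: float(rng.uniform(0.01, 0.5)) for lb in labels}
    eps_max = max(eps.values())
    c0 = min(
        a0_target / (eps["X"] * DEFAULT_SETUP.l_irr),
        0.6 / (eps_max * DEFAULT_SETUP.l_irr),
    )
    m = scheme1_template(labels, c0=c0, epsilons=eps, phis=phis)
    return m, DEFAULT_SETUP


#: Named fixture cases for the command-line ``fixtures`` subcommand.
FIXTURE_CASES = {
    "table1": table1_system,
    "primary": primary_photoprocess,
    "branch": branch_system,
    "cyclic3": cyclic3_system,
    "consecutive4": consecutive_system,
    "isosbestic": isosbestic_system,
}
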