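"""Data model, parser and validator for unimolecular photomechanisms.

A mechanism is a set of species interconverted by light-driven unimolecular
steps ``source -> target``, each characterised by a quantum yield ``phi`` at
the (single) irradiation wavelength. Every species carries its molar
absorption coefficient ``epsilon`` at that wavelength and its initial
concentration. Photochemically inert absorbers ("spectators") are modelled
by a constant absorbance: they compete for photons but never react.

All quantities refer to one irradiation wavelength; a mechanism instance is
always "at one lambda_irr".
"""
from __future__ import annotations

import tomllib
from collections import deque
from dataclasses import dataclass, field, replace

__all__ = [
    "Species",
    "ReactionStep",
    "Spectator",
    "Mechanism",
    "IrradiationSetup",
    "MechanismError",
    "Issue",
    "parse_mechanism",
    "load_config",
    "serialize_mechanism",
    "validate_mechanism",
    "scheme1_template",
    "SCHEME1_STEPS",
]


class MechanismError(ValueError):
    """Raised for structurally invalid mechanisms or configs."""


@dataclass(frozen=True)
class Species:
    """A reactive species at the irradiation wavelength.

    Parameters
    ----------
    name : str
        Unique identifier within the mechanism.
    epsilon : float
        Molar absorption coefficient at lambda_irr, M^-1 cm^-1 (>= 0).
    c0 : float
        Initial concentration, M (>= 0).
    """

    name: str
    epsilon: float
    c0: float = 0.0

    def __post_init__(self) -> None:
        if not self.name:
            raise MechanismError("species name must be non-empty")
        if self.epsilon < 0:
            raise MechanismError(f"species {self.name!r}: epsilon must be >= 0")
        if self.c0 < 0:
            raise MechanismError(f"species {self.name!r}: c0 must be >= 0")


@dataclass(frozen=True)
class ReactionStep:
    """A unimolecular photoreaction step ``source -> target`` with quantum yield ``phi``."""

    source: str
    target: str
    phi: float

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise MechanismError(f"step {self.source}->{self.target}: source equals target")
        if not self.phi > 0:
            raise MechanismError(
                f"step {self.source}->{self.target}: quantum yield must be > 0, got {self.phi}"
            )

    @property
    def label(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass(frozen=True)
class Spectator:
    """A photochemically and thermally inert absorber with constant absorbance."""

    name: str
    absorbance: float

    def __post_init__(self) -> None:
        if self.absorbance < 0:
            raise MechanismError(f"spectator {self.name!r}: absorbance must be >= 0")


@dataclass(frozen=True)
class IrradiationSetup:
    """Irradiation geometry and incident photon flux.

    Parameters
    ----------
    lambda_irr : float
        Irradiation wavelength, nm.
    p0 : float
        Incident photon flux entering the reactor, einstein s^-1 dm^-3.
        May be computed from a lamp spectral irradiance (see
        :mod:`phikinet.actinometry`).
    l_irr : float
        Optical path length of the irradiation beam, cm.
    l_obs : float or None
        Observation path length, cm; defaults to ``l_irr``.
    lambda_obs : float or None
        Observation wavelength, nm; defaults to ``lambda_irr``.
    """

    lambda_irr: float
    p0: float
    l_irr: float
    l_obs: float | None = None
    lambda_obs: float | None = None

    def __post_init__(self) -> None:
        if not self.p0 > 0:
            raise MechanismError("p0 must be > 0")
        if not self.l_irr > 0:
            raise MechanismError("l_irr must be > 0")
        if self.l_obs is not None and not self.l_obs > 0:
            raise MechanismError("l_obs must be > 0")

    @property
    def path_obs(self) -> float:
        return self.l_irr if self.l_obs is None else self.l_obs


@dataclass(frozen=True)
class Issue:
    """A validation finding; ``severity`` is ``"error"`` or ``"warning"``."""

    severity: str
    message: str

    @property
    def is_error(self) -> bool:
        return self.severity == "error"


@dataclass(frozen=True)
class Mechanism:
    """An ordered collection of species, photoreaction steps and spectators.

    The first species is the reactant X. Stoichiometry is implicitly 1:1
    (all steps are isomerizations/interconversions), so the total
    concentration is conserved along any trajectory.
    """

    species: tuple[Species, ...]
    steps: tuple[ReactionStep, ...]
    spectators: tuple[Spectator, ...] = ()

    def __post_init__(self) -> None:
        hard = [i for i in self._structural_issues() if i.is_error]
        if hard:
            raise MechanismError("; ".join(i.message for i in hard))

    # -- structure -----------------------------------------------------
    @property
    def nsp(self) -> int:
        return len(self.species)

    @property
    def n_phi(self) -> int:
        return len(self.steps)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(sp.name for sp in self.species)

    @property
    def reactant(self) -> Species:
        return self.species[0]

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def spectator_absorbance(self) -> float:
        return sum(sp.absorbance for sp in self.spectators)

    def steps_touching(self, name: str) -> tuple[ReactionStep, ...]:
        return tuple(st for st in self.steps if name in (st.source, st.target))

    def steps_leaving(self, name: str) -> tuple[ReactionStep, ...]:
        return tuple(st for st in self.steps if st.source == name)

    def bfs_order(self) -> tuple[str, ...]:
        """Species names ordered by graph distance from the reactant.

        This is the order in which the coupled fitting protocol visits the
        traces (reactant first, then its nearest neighbours, and so on).
        """
        adj: dict[str, set[str]] = {n: set() for n in self.names}
        for st in self.steps:
            adj[st.source].add(st.target)
            adj[st.target].add(st.source)
        seen = [self.reactant.name]
        queue = deque(seen)
        while queue:
            cur = queue.popleft()
            for nxt in sorted(adj[cur], key=self.index):
                if nxt not in seen:
                    seen.append(nxt)
                    queue.append(nxt)
        # unreachable species last, in declaration order
        seen.extend(n for n in self.names if n not in seen)
        return tuple(seen)

    # -- validation ----------------------------------------------------
    def _structural_issues(self) -> list[Issue]:
        issues: list[Issue] = []
        names = [sp.name for sp in self.species]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            issues.append(Issue("error", f"duplicate species name(s): {sorted(dup)}"))
        if not self.steps:
            issues.append(Issue("error", "mechanism must declare at least one step"))
        declared = set(names)
        spect_names = {sp.name for sp in self.spectators}
        if spect_names & declared:
            issues.append(
                Issue("error", f"spectator(s) also declared as species: {sorted(spect_names & declared)}")
            )
        seen_steps: set[tuple[str, str]] = set()
        for st in self.steps:
            for end in (st.source, st.target):
                if end in spect_names:
                    issues.append(Issue("error", f"spectator {end!r} appears in step {st.label}"))
                elif end not in declared:
                    issues.append(Issue("error", f"unknown species {end!r} in step {st.label}"))
            if (st.source, st.target) in seen_steps:
                issues.append(Issue("error", f"duplicate step {st.label}"))
            seen_steps.add((st.source, st.target))
        return issues

    def issues(self) -> list[Issue]:
        """All validation findings, hard errors first."""
        issues = self._structural_issues()
        for st in self.steps:
            if st.phi > 1:
                issues.append(
                    Issue("warning", f"step {st.label}: quantum yield {st.phi} > 1 (chain process?)")
                )
        reachable = set(self.bfs_order()[: self._n_reachable()])
        for name in self.names:
            if name not in reachable:
                issues.append(Issue("warning", f"species {name!r} not connected to the reactant"))
        return issues

    def _n_reachable(self) -> int:
        adj: dict[str, set[str]] = {n: set() for n in self.names}
        for st in self.steps:
            if st.source in adj and st.target in adj:
                adj[st.source].add(st.target)
                adj[st.target].add(st.source)
        seen = {self.reactant.name}
        queue = deque(seen)
        while queue:
            cur = queue.popleft()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append(nxt)
        return len(seen)


def validate_mechanism(m: Mechanism) -> list[Issue]:
    """Report all invariant violations without raising.

    Returns an empty list iff the mechanism is fully valid. Warnings
    (quantum yield > 1, species unreachable from the reactant) are
    distinguished from errors by :attr:`Issue.severity`.
    """
    issues = list(m.issues())
    for st in m.steps:
        if not st.phi > 0:  # pragma: no cover - unconstructible via dataclass
            issues.append(Issue("error", f"step {st.label}: non-positive phi"))
    return issues


# ---------------------------------------------------------------------------
# Config parsing / serialization (TOML dialect)
# ---------------------------------------------------------------------------

def _parse_tables(data: dict) -> tuple[Mechanism, IrradiationSetup | None]:
    species = []
    for name, tbl in data.get("species", {}).items():
        try:
            species.append(Species(name=name, epsilon=float(tbl["epsilon_M_cm"]), c0=float(tbl.get("c0_M", 0.0))))
        except KeyError as exc:
            raise MechanismError(f"species {name!r}: missing key {exc}") from None
    steps = []
    for tbl in data.get("step", []):
        try:
            steps.append(ReactionStep(source=str(tbl["from"]), target=str(tbl["to"]), phi=float(tbl["phi"])))
        except KeyError as exc:
            raise MechanismError(f"step table missing key {exc}") from None
    spectators = [
        Spectator(name=name, absorbance=float(tbl["absorbance"]))
        for name, tbl in data.get("spectator", {}).items()
    ]
    mech = Mechanism(species=tuple(species), steps=tuple(steps), spectators=tuple(spectators))
    setup = None
    if "setup" in data:
        st = data["setup"]
        setup = IrradiationSetup(
            lambda_irr=float(st["lambda_irr_nm"]),
            p0=float(st["p0_einstein_s_dm3"]),
            l_irr=float(st["l_irr_cm"]),
            l_obs=float(st["l_obs_cm"]) if "l_obs_cm" in st else None,
            lambda_obs=float(st["lambda_obs_nm"]) if "lambda_obs_nm" in st else None,
        )
    return mech, setup


def load_config(text: str) -> tuple[Mechanism, IrradiationSetup | None]:
    """Parse a mechanism config (TOML), returning mechanism and optional setup."""
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise MechanismError(f"invalid config: {exc}") from None
    return _parse_tables(data)


def parse_mechanism(config_text: str) -> Mechanism:
    """Parse and validate a mechanism from its TOML config text.

    Species order follows declaration order; the first declared species is
    the reactant.
    """
    return load_config(config_text)[0]


def _fmt(x: float) -> str:
    return repr(float(x))


def serialize_mechanism(m: Mechanism, setup: IrradiationSetup | None = None) -> str:
    """Render a mechanism (and optional setup) back to its TOML config form.

    Round-trips exactly: ``parse_mechanism(serialize_mechanism(m)) == m``.
    """
    lines: list[str] = []
    for sp in m.species:
        lines += [f"[species.{sp.name}]", f"epsilon_M_cm = {_fmt(sp.epsilon)}", f"c0_M = {_fmt(sp.c0)}", ""]
    for st in m.steps:
        lines += ["[[step]]", f'from = "{st.source}"', f'to = "{st.target}"', f"phi = {_fmt(st.phi)}", ""]
    for sp in m.spectators:
        lines += [f"[spectator.{sp.name}]", f"absorbance = {_fmt(sp.absorbance)}", ""]
    if setup is not None:
        lines += [
            "[setup]",
            f"lambda_irr_nm = {_fmt(setup.lambda_irr)}",
            f"p0_einstein_s_dm3 = {_fmt(setup.p0)}",
            f"l_irr_cm = {_fmt(setup.l_irr)}",
        ]
        if setup.l_obs is not None:
            lines.append(f"l_obs_cm = {_fmt(setup.l_obs)}")
        if setup.lambda_obs is not None:
            lines.append(f"lambda_obs_nm = {_fmt(setup.lambda_obs)}")
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Canonical 8-species / 14-step template
# ---------------------------------------------------------------------------

#: The canonical branched-and-reversible template: eight species (the
#: reactant X and photoproducts Y1..Y7) interlinked by 14 unimolecular
#: steps (seven reversible pairs). X branches to Y1 and Y3; each branch
#: continues as a consecutive reversible chain.
SCHEME1_STEPS: dict[str, tuple[str, str]] = {
    "X->Y1": ("X", "Y1"),
    "Y1->X": ("Y1", "X"),
    "X->Y3": ("X", "Y3"),
    "Y3->X": ("Y3", "X"),
    "Y1->Y2": ("Y1", "Y2"),
    "Y2->Y1": ("Y2", "Y1"),
    "Y3->Y4": ("Y3", "Y4"),
    "Y4->Y3": ("Y4", "Y3"),
    "Y2->Y5": ("Y2", "Y5"),
    "Y5->Y2": ("Y5", "Y2"),
    "Y4->Y6": ("Y4", "Y6"),
    "Y6->Y4": ("Y6", "Y4"),
    "Y5->Y7": ("Y5", "Y7"),
    "Y7->Y5": ("Y7", "Y5"),
}


def scheme1_template(
    selection: set[str] | list[str] | tuple[str, ...],
    c0: float = 1.58e-5,
    epsilons: dict[str, float] | None = None,
    phis: dict[str, float] | None = None,
) -> Mechanism:
    """Build a sub-mechanism of the canonical 14-step template.

    Parameters
    ----------
    selection : collection of step labels
        Subset of :data:`SCHEME1_STEPS` keys, e.g. ``{"X->Y1", "Y1->X"}``.
        Must induce a connected mechanism containing the reactant X.
    c0 : float
        Initial reactant concentration, M.
    epsilons, phis : dict, optional
        Values per species name / step label. Missing epsilons default to
        0 and missing phis to 1.0 (placeholders to be filled by the caller).
    """
    selection = list(dict.fromkeys(selection))
    if not selection:
        raise MechanismError("empty step selection")
    unknown = [s for s in selection if s not in SCHEME1_STEPS]
    if unknown:
        raise MechanismError(f"unknown step label(s): {unknown}")
    endpoints = {e for lbl in selection for e in SCHEME1_STEPS[lbl]}
    if "X" not in endpoints:
        raise MechanismError("selection must include the reactant X")
    # connectivity of the selected step graph
    adj: dict[str, set[str]] = {n: set() for n in endpoints}
    for lbl in selection:
        a, b = SCHEME1_STEPS[lbl]
        adj[a].add(b)
        adj[b].add(a)
    seen = {"X"}
    queue = deque(seen)
    while queue:
        for nxt in adj[queue.popleft()]:
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    if seen != endpoints:
        raise MechanismError(f"disconnected selection: {sorted(endpoints - seen)} unreachable from X")

    epsilons = epsilons or {}
    phis = phis or {}
    order = ["X"] + sorted(endpoints - {"X"}, key=lambda n: int(n[1:]))
    species = tuple(
        Species(name=n, epsilon=float(epsilons.get(n, 0.0)), c0=c0 if n == "X" else 0.0) for n in order
    )
    steps = tuple(
        ReactionStep(source=SCHEME1_STEPS[lbl][0], target=SCHEME1_STEPS[lbl][1], phi=float(phis.get(lbl, 1.0)))
        for lbl in selection
    )
    return Mechanism(species=species, steps=steps)


def with_initial_concentration(m: Mechanism, c0: float) -> Mechanism:
    """Copy of ``m`` with the reactant's initial concentration replaced."""
    species = (replace(m.species[0], c0=c0),) + m.species[1:]
    return Mechanism(species=species, steps=m.steps, spectators=m.spectators)
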