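"""Circuit netlist model, ODE compilation, and the repressilator template.

A :class:`CircuitSpec` is a netlist: declared protein species (the ODE state),
gate nodes (one gene each, producing one species), constant sources (fixed
concentrations such as a logic-1 input) and optional external drives
(time-varying input signals).  :func:`compile_rhs` turns a validated netlist
into a plain ``f(t, y) -> dy/dt`` vector field built from the reduced gate
kinetics; :func:`cascade` composes netlists feed-forward, binding the free
inputs of a downstream stage to upstream species.

The repressilator template builds the canonical three-gene ring oscillator
(lacI -| tetR -| cI -| lacI) in which each protein represses the next gene,
sustaining oscillations whose period is tuned by a regulation coefficient chi.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Tuple

import numpy as np

from .hill_gates import GateKind, GateKinetics, HillInput, promoter_activity

__all__ = [
    "SpeciesDecl",
    "ConstantSource",
    "Regulator",
    "GateNode",
    "CircuitSpec",
    "RepressilatorSpec",
    "WiringError",
    "NamingError",
    "build_repressilator",
    "compile_rhs",
    "cascade",
    "validate",
    "square_wave",
]


class WiringError(ValueError):
    """An element of the netlist references a name that cannot be resolved,
    or a species has conflicting producers."""


class NamingError(ValueError):
    """Name collision when declaring or composing circuits."""


@dataclass(frozen=True)
class SpeciesDecl:
    """One protein species: a name and its initial concentration."""

    name: str
    initial: float = 0.0

    def __post_init__(self) -> None:
        if self.initial < 0:
            raise NamingError(f"initial concentration of {self.name!r} must be >= 0")


@dataclass(frozen=True)
class ConstantSource:
    """A fixed-concentration input, e.g. a logic-1 level held at 1.0."""

    id: str
    level: float

    def __post_init__(self) -> None:
        if self.level < 0:
            raise NamingError(f"source {self.id!r} level must be >= 0")


@dataclass(frozen=True)
class Regulator:
    """A gate input: the name of the signal it reads plus its Hill site."""

    source: str
    hill: HillInput


@dataclass(frozen=True)
class GateNode:
    """One gene: produces ``output`` under a promoter of kind ``kind``."""

    output: str
    kind: GateKind
    kinetics: GateKinetics
    regulators: Tuple[Regulator, ...]


@dataclass(frozen=True)
class CircuitSpec:
    """A named collection of species, gates, sources and external drives.

    Drives map a signal name to a callable ``t -> level``; they are runtime
    inputs and are not part of the ODE state.  Regulators may reference
    species, constant sources or drives.  State ordering in the compiled
    vector follows species declaration order.
    """

    name: str = "circuit"
    species: Tuple[SpeciesDecl, ...] = ()
    gates: Tuple[GateNode, ...] = ()
    sources: Tuple[ConstantSource, ...] = ()
    drives: Mapping[str, Callable[[float], float]] = field(default_factory=dict)

    @property
    def species_names(self) -> List[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise WiringError(f"unknown species {name!r} in circuit {self.name!r}")

    def with_drive(self, name: str, fn: Callable[[float], float]) -> "CircuitSpec":
        drives = dict(self.drives)
        drives[name] = fn
        return replace(self, drives=drives)

    def with_source(self, id: str, level: float) -> "CircuitSpec":
        return replace(self, sources=self.sources + (ConstantSource(id, level),))

    def validate(self) -> List[str]:
        return validate(self)


def validate(circuit: CircuitSpec) -> List[str]:
    """Check all netlist invariants; returns a list of diagnostics.

    An empty list means the circuit is well formed.  Each diagnostic names
    the offending element; no exception is raised.
    """
    diags: List[str] = []
    names = circuit.species_names
    seen: set = set()
    for n in names:
        if n in seen:
            diags.append(f"duplicate species name {n!r}")
        seen.add(n)
    for src in circuit.sources:
        if src.id in seen:
            diags.append(f"source id {src.id!r} collides with another name")
        seen.add(src.id)
    for dname in circuit.drives:
        if dname in seen:
            diags.append(f"drive name {dname!r} collides with another name")
        seen.add(dname)

    producers: Dict[str, int] = {}
    for gate in circuit.gates:
        if gate.output not in names:
            diags.append(f"gate output {gate.output!r} is not a declared species")
        producers[gate.output] = producers.get(gate.output, 0) + 1
        kind = GateKind(gate.kind)
        if len(gate.regulators) != kind.arity:
            diags.append(
                f"gate for {gate.output!r}: {kind.value} takes {kind.arity} "
                f"regulator(s), got {len(gate.regulators)}"
            )
        for reg in gate.regulators:
            if reg.source not in seen:
                diags.append(
                    f"gate for {gate.output!r}: regulator source {reg.source!r} "
                    "does not resolve to a species, source or drive"
                )
    for out, count in producers.items():
        if count > 1:
            diags.append(f"species {out!r} has {count} producing gates")
    for sp in circuit.species:
        if sp.name not in producers:
            diags.append(f"species {sp.name!r} has no producing gate")
    return diags


def compile_rhs(
    circuit: CircuitSpec,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile a validated circuit into a pure ODE vector field.

    The derivative of each species is assembled from its gate via the reduced
    kinetics ``rho * f - gamma * p + rho0``.  Regulator levels are clamped at
    zero before entering the Hill functions so that transient solver
    undershoot below zero cannot produce complex powers.

    Raises :class:`WiringError` if validation produces diagnostics.
    """
    diags = validate(circuit)
    if diags:
        raise WiringError("; ".join(diags))

    n = len(circuit.species)
    source_levels = {src.id: src.level for src in circuit.sources}
    drives = dict(circuit.drives)
    name_to_idx = {nm: i for i, nm in enumerate(circuit.species_names)}

    # Pre-resolve each regulator to a (tag, payload) accessor.
    compiled = []
    for gate in circuit.gates:
        getters = []
        for reg in gate.regulators:
            if reg.source in name_to_idx:
                getters.append(("state", name_to_idx[reg.source], reg.hill))
            elif reg.source in source_levels:
                getters.append(("const", source_levels[reg.source], reg.hill))
            else:
                getters.append(("drive", drives[reg.source], reg.hill))
        compiled.append(
            (name_to_idx[gate.output], GateKind(gate.kind), gate.kinetics, getters)
        )

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(n)
        for out, kind, kin, getters in compiled:
            regs = []
            for tag, payload, hill in getters:
                if tag == "state":
                    u = y[payload]
                elif tag == "const":
                    u = payload
                else:
                    u = payload(t)
                regs.append((max(float(u), 0.0), hill))
            f = promoter_activity(kind, regs)
            dy[out] = kin.rho * f - kin.gamma * y[out] + kin.rho0
        return dy

    return rhs


def cascade(
    upstream: CircuitSpec,
    downstream: CircuitSpec,
    wiring: Mapping[str, str] | None = None,
) -> CircuitSpec:
    """Feed-forward composition of two circuits.

    ``wiring`` maps a free input name used by downstream regulators to an
    upstream species (or source) name.  Species, gates, sources and drives
    are merged; because nothing upstream references the downstream stage, the
    upstream dynamics are unchanged by composition.

    Raises
    ------
    NamingError
        On species/source/drive name collisions.
    WiringError
        If a wiring target does not exist upstream.
    """
    wiring = dict(wiring or {})
    up_names = set(upstream.species_names) | {s.id for s in upstream.sources} | set(
        upstream.drives
    )
    for free, target in wiring.items():
        if target not in up_names:
            raise WiringError(f"wiring target {target!r} not found in upstream circuit")

    down_names = set(downstream.species_names) | {
        s.id for s in downstream.sources
    } | set(downstream.drives)
    clash = up_names & down_names
    if clash:
        raise NamingError(f"name collision in cascade: {sorted(clash)}")

    rewired_gates = []
    for gate in downstream.gates:
        regs = tuple(
            Regulator(wiring.get(r.source, r.source), r.hill) for r in gate.regulators
        )
        rewired_gates.append(dataclasses.replace(gate, regulators=regs))

    drives = dict(upstream.drives)
    drives.update(downstream.drives)
    return CircuitSpec(
        name=f"{upstream.name}+{downstream.name}",
        species=upstream.species + downstream.species,
        gates=upstream.gates + tuple(rewired_gates),
        sources=upstream.sources + downstream.sources,
        drives=drives,
    )


# ---------------------------------------------------------------------------
# Repressilator template
# ---------------------------------------------------------------------------

#: Default kinetic constants of the three-gene ring oscillator: each gene i is
#: repressed by its predecessor j through dp_i/dt = chi*(s/(1+p_j^n) - d*p_i).
_REPRESSILATOR_ORDER = ("p_lacI", "p_tetR", "p_cI")


@dataclass(frozen=True)
class RepressilatorSpec:
    """Parameters of the three-gene ring oscillator.

    chi is a dimensionless regulation coefficient that tunes the oscillation
    period.  Under the default ``chi_mode="rhs"`` it scales the whole right
    hand side (synthesis and decay alike), which rescales time: halving chi
    doubles the period while leaving amplitude and levels unchanged.  The
    alternative ``chi_mode="synthesis"`` scales synthesis only, which changes
    the balance of synthesis and decay (and can quench the oscillation).
    The "rhs" default is fixed by calibration: with chi=0.5 it reproduces the
    reference basal period of 32 s.
    """

    chi: float = 1.0
    synthesis: float = 0.6851
    decay: float = 0.233
    hill: HillInput = HillInput(K=1.0, n=4.0)
    initials: Tuple[float, float, float] = (0.7, 1.2, 1.7)
    chi_mode: str = "rhs"

    def __post_init__(self) -> None:
        if not self.chi > 0:
            raise NamingError(f"regulation coefficient chi must be > 0, got {self.chi}")
        if self.chi_mode not in ("rhs", "synthesis"):
            raise NamingError(f"chi_mode must be 'rhs' or 'synthesis', got {self.chi_mode!r}")


def build_repressilator(spec: RepressilatorSpec | None = None, **overrides) -> CircuitSpec:
    """Build the three-gene ring oscillator as a circuit of NOT gates.

    Keyword overrides (``chi=0.5`` etc.) are applied on top of ``spec`` or the
    defaults.  Species are declared in the order lacI, tetR, cI with the
    repression ring lacI -| tetR -| cI -| lacI.
    """
    spec = replace(spec or RepressilatorSpec(), **overrides) if overrides else (
        spec or RepressilatorSpec()
    )
    if spec.chi_mode == "rhs":
        kin = GateKinetics(rho=spec.chi * spec.synthesis, gamma=spec.chi * spec.decay)
    else:
        kin = GateKinetics(rho=spec.chi * spec.synthesis, gamma=spec.decay)
    repressor_of = {"p_lacI": "p_cI", "p_tetR": "p_lacI", "p_cI": "p_tetR"}
    species = tuple(
        SpeciesDecl(nm, init) for nm, init in zip(_REPRESSILATOR_ORDER, spec.initials)
    )
    gates = tuple(
        GateNode(
            output=nm,
            kind=GateKind.NOT,
            kinetics=kin,
            regulators=(Regulator(repressor_of[nm], spec.hill),),
        )
        for nm in _REPRESSILATOR_ORDER
    )
    return CircuitSpec(name="repressilator", species=species, gates=gates)


def square_wave(
    period: float,
    duty: float,
    high: float = 1.0,
    low: float = 0.0,
    rise: float = 0.3,
    start: float = 5.0,
) -> Callable[[float], float]:
    """Idealized periodic clock pulse for use as an external drive.

    A smoothed rectangular pulse of the given period and duty cycle with
    tanh-shaped edges of time scale ``rise`` (a hard discontinuity would
    defeat adaptive step control).  The first pulse begins at ``start``.
    """
    if not 0 < duty < 1:
        raise ValueError("duty must be in (0, 1)")
    width = duty * period
    pad = 3.0 * rise  # keep both tanh edges well inside one cycle

    def drive(t: float) -> float:
        ph = (t - start) % period
        edge_up = 0.5 * (1.0 + math.tanh((ph - pad) / rise))
        edge_dn = 0.5 * (1.0 + math.tanh((pad + width - ph) / rise))
        return low + (high - low) * edge_up * edge_dn

    return drive
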