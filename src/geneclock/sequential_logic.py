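"""Edge-triggered genetic JK flip-flops and synchronous frequency-divider counters.

A genetic JK flip-flop is six genes implementing a clocked bistable latch:

* rising-edge variant — four AND gates and two NOR gates::

      W = AND(K, CLK)    V = AND(J, CLK)
      R = AND(W, Q)      S = AND(V, Qbar)
      Q = NOR(R, Qbar)   Qbar = NOR(S, Q)

  where ``CLK`` is a narrow clock pulse (logic-high only briefly once per
  cycle), so the latch state can change only while the pulse is high —
  i.e. on the low-to-high transition of the clock.

* falling-edge variant — six NAND gates with the same wiring shape and the
  latch lines ``Q = NAND(S, Qbar)``, ``Qbar = NAND(R, Q)``; it is driven by
  a wide (high-most-of-the-time) pulse and becomes active in the brief
  low window, i.e. on the high-to-low transition.

Counters chain flip-flops sharing one clock.  A binary counter with delta
flip-flops divides the clock frequency by 2, 4, ..., 2^delta: ff1 has J=K
tied to logic 1 (toggle every pulse), ff2 is fed by Q1, and stages >= 3 are
fed by carry AND genes G_k.  A mod-3 counter uses two rising-edge flip-flops
plus one falling-edge flip-flop (on a complementary wide pulse) and an OR
output gene, giving one output cycle per three clock pulses.

Interconnect realization.  The counter equations wire Q outputs straight
into the next flip-flop's J/K inputs (``pJ2 = pK2 = pQ1``), i.e. the same
protein species regulates both latches.  In a continuous-kinetics
simulation this direct coupling has a race: the upstream Q collapses a
couple of seconds into the clock pulse (its own flip-flop is toggling), so
the downstream latch loses its drive before crossing its separatrix and
falls back — division by 2 succeeds but division by 4 and the mod-3 count
do not.  Passing ``buffered_wiring=True`` interposes one genetic Buffer per
flip-flop-to-flip-flop J/K link.  The Buffer's gene-expression delay (one
decay time, 1/gamma) lets the downstream stage read the pre-edge value of
the upstream output — the same mechanism the carry genes provide for
stages >= 3 — and restores exact 2x/4x/3x frequency division.  The default
(direct wiring) preserves the canonical counter structure and species
count.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Tuple

from .hill_gates import GateKind, GateKinetics, HillInput, promoter_activity
from .circuit_core import (
    CircuitSpec,
    ConstantSource,
    GateNode,
    Regulator,
    SpeciesDecl,
)

__all__ = [
    "FlipFlopParams",
    "CounterDesign",
    "build_jk_rising",
    "build_jk_falling",
    "build_binary_counter",
    "build_mod3_counter",
]

_FF_GENES = ("W", "V", "R", "S", "Q", "Qbar")


@dataclass(frozen=True)
class FlipFlopParams:
    """Kinetics and Hill sites for the six flip-flop genes.

    ``kinetics`` and ``hill`` apply to every gene unless overridden per gene
    (keys "W", "V", "R", "S", "Q", "Qbar").  Defaults mirror the reference
    counter parameterization: unit synthesis/decay rates, zero basal rate,
    K = 0.5, n = 4 for every gene.
    """

    kinetics: GateKinetics = GateKinetics(rho=1.0, gamma=1.0, rho0=0.0)
    hill: HillInput = HillInput(K=0.5, n=4.0)
    edge: str = "rising"
    per_gene_kinetics: Mapping[str, GateKinetics] = field(default_factory=dict)
    per_gene_hill: Mapping[str, HillInput] = field(default_factory=dict)

    def kin(self, gene: str) -> GateKinetics:
        return self.per_gene_kinetics.get(gene, self.kinetics)

    def site(self, gene: str) -> HillInput:
        return self.per_gene_hill.get(gene, self.hill)


def _build_jk(
    params: FlipFlopParams,
    j_src: str,
    k_src: str,
    clk_src: str,
    prefix: str,
    edge: str,
) -> CircuitSpec:
    """Six-gene flip-flop fragment; J/K/CLK references stay unresolved until
    the fragment is composed (via cascade wiring, drives or sources)."""
    if edge == "rising":
        latch_kind = GateKind.NOR
        gate_kind = GateKind.AND
        q_inputs = (f"{prefix}R", f"{prefix}Qbar")
        qbar_inputs = (f"{prefix}S", f"{prefix}Q")
    elif edge == "falling":
        latch_kind = GateKind.NAND
        gate_kind = GateKind.NAND
        q_inputs = (f"{prefix}S", f"{prefix}Qbar")
        qbar_inputs = (f"{prefix}R", f"{prefix}Q")
    else:
        raise ValueError(f"edge must be 'rising' or 'falling', got {edge!r}")

    wiring = {
        "W": (gate_kind, (k_src, clk_src)),
        "V": (gate_kind, (j_src, clk_src)),
        "R": (gate_kind, (f"{prefix}W", f"{prefix}Q")),
        "S": (gate_kind, (f"{prefix}V", f"{prefix}Qbar")),
        "Q": (latch_kind, q_inputs),
        "Qbar": (latch_kind, qbar_inputs),
    }
    # Seed a consistent latch state: Q low, Qbar at its maximal level.
    qbar_kin = params.kin("Qbar")
    initials = {"Qbar": qbar_kin.rho / qbar_kin.gamma + qbar_kin.rho0 / qbar_kin.gamma}
    species = tuple(
        SpeciesDecl(f"{prefix}{g}", initials.get(g, 0.0)) for g in _FF_GENES
    )
    gates = tuple(
        GateNode(
            output=f"{prefix}{g}",
            kind=wiring[g][0],
            kinetics=params.kin(g),
            regulators=tuple(Regulator(src, params.site(g)) for src in wiring[g][1]),
        )
        for g in _FF_GENES
    )
    return CircuitSpec(name=f"jk_{edge}[{prefix.rstrip('.')}]", species=species, gates=gates)


def build_jk_rising(
    params: Optional[FlipFlopParams] = None,
    j_src: str = "J",
    k_src: str = "K",
    clk_src: str = "CLK",
    prefix: str = "ff.",
) -> CircuitSpec:
    """Rising-edge-triggered JK flip-flop (4 AND + 2 NOR genes)."""
    return _build_jk(params or FlipFlopParams(), j_src, k_src, clk_src, prefix, "rising")


def build_jk_falling(
    params: Optional[FlipFlopParams] = None,
    j_src: str = "J",
    k_src: str = "K",
    clk_src: str = "CLK",
    prefix: str = "ff.",
) -> CircuitSpec:
    """Falling-edge-triggered JK flip-flop (six NAND genes)."""
    return _build_jk(params or FlipFlopParams(), j_src, k_src, clk_src, prefix, "falling")


def _merge(name: str, *parts: CircuitSpec, sources=(), extra_species=(), extra_gates=()) -> CircuitSpec:
    species: Tuple[SpeciesDecl, ...] = ()
    gates: Tuple[GateNode, ...] = ()
    for p in parts:
        species += p.species
        gates += p.gates
    return CircuitSpec(
        name=name,
        species=species + tuple(extra_species),
        gates=gates + tuple(extra_gates),
        sources=tuple(sources),
    )


def _interconnect(
    src: str,
    out: str,
    params: FlipFlopParams,
    src_initial: float,
) -> Tuple[SpeciesDecl, GateNode]:
    """One Buffer gene relaying ``src`` to ``out`` with delay 1/gamma."""
    kin = params.kinetics
    hill = params.hill
    f0 = promoter_activity(GateKind.BUFFER, [(src_initial, hill)])
    init = kin.rho / kin.gamma * f0 + kin.rho0 / kin.gamma
    decl = SpeciesDecl(out, init)
    gate = GateNode(
        output=out,
        kind=GateKind.BUFFER,
        kinetics=kin,
        regulators=(Regulator(src, hill),),
    )
    return decl, gate


def build_binary_counter(
    delta: int,
    params: Optional[FlipFlopParams] = None,
    clk_src: str = "clk",
    logic_one_level: float = 1.0,
    buffered_wiring: bool = False,
) -> CircuitSpec:
    """Synchronous binary counter: delta rising-edge flip-flops dividing the
    clock frequency by 2, 4, ..., 2^delta.

    ff1's J/K are tied to a logic-1 constant source, ff2 is fed by ff1.Q and
    flip-flop k >= 3 by the carry gene G_{k-2} = AND(previous feed, Q_{k-1}).
    ``clk_src`` is left as an external reference — bind it to a drive or
    cascade the counter after a clock-pulse circuit.  The outputs are
    ``ff1.Q`` (double period), ``ff2.Q`` (quadruple), ..., ``ff{delta}.Q``.

    With ``buffered_wiring=True`` the ff1.Q -> ff2 link goes through a relay
    Buffer gene (species ``jk2``); the carry genes already provide the
    equivalent delay for later stages.
    """
    if delta < 1:
        raise ValueError(f"delta must be a positive integer, got {delta}")
    params = params or FlipFlopParams()
    one = ConstantSource("one", logic_one_level)

    ffs: List[CircuitSpec] = []
    extra_species: List[SpeciesDecl] = []
    extra_gates: List[GateNode] = []

    feeds: List[str] = ["one"]  # J/K source per flip-flop, in order
    if delta >= 2:
        if buffered_wiring:
            decl, gate = _interconnect("ff1.Q", "jk2", params, src_initial=0.0)
            extra_species.append(decl)
            extra_gates.append(gate)
            feeds.append("jk2")
        else:
            feeds.append("ff1.Q")
    # Carry genes G1..G_{delta-2}: G_k = AND(feed_{k+1}, Q_{k+1}).
    for k in range(1, delta - 1):
        g_name = f"G{k}"
        extra_species.append(SpeciesDecl(g_name, 0.0))
        extra_gates.append(
            GateNode(
                output=g_name,
                kind=GateKind.AND,
                kinetics=params.kinetics,
                regulators=(
                    Regulator(feeds[k], params.hill),
                    Regulator(f"ff{k + 1}.Q", params.hill),
                ),
            )
        )
        feeds.append(g_name)

    for i in range(1, delta + 1):
        ffs.append(
            build_jk_rising(
                params,
                j_src=feeds[i - 1],
                k_src=feeds[i - 1],
                clk_src=clk_src,
                prefix=f"ff{i}.",
            )
        )
    return _merge(
        f"binary_counter_delta{delta}",
        *ffs,
        sources=(one,),
        extra_species=extra_species,
        extra_gates=extra_gates,
    )


def build_mod3_counter(
    params: Optional[FlipFlopParams] = None,
    clk_rise_src: str = "clk1",
    clk_fall_src: str = "clk2",
    logic_one_level: float = 1.0,
    buffered_wiring: bool = False,
) -> CircuitSpec:
    """Mod-3 counter: output gene G1 completes one cycle per three clock pulses.

    Two rising-edge flip-flops walk the two-bit state through the 3-cycle
    (Q1,Q2) = 00 -> 10 -> 01 -> 00 (J1 = Qbar2, J2 = Q1, K1 = K2 = 1); a
    falling-edge flip-flop driven by the complementary wide pulse copies Q2
    half a clock later (J3 = Q2, K3 = Qbar2); G1 = OR(Q2, Q3) then stays
    high for one full clock period out of three.

    ``clk_rise_src`` must be a narrow (low-to-high trigger) pulse and
    ``clk_fall_src`` the complementary wide (high-to-low trigger) pulse;
    both are external references.  ``buffered_wiring=True`` relays the four
    cross-couplings (Qbar2 -> J1, Q1 -> J2, Q2 -> J3, Qbar2 -> K3) through
    Buffer genes.
    """
    params = params or FlipFlopParams()
    one = ConstantSource("one", logic_one_level)
    qbar_init = params.kin("Qbar").rho / params.kin("Qbar").gamma

    extra_species: List[SpeciesDecl] = []
    extra_gates: List[GateNode] = []
    if buffered_wiring:
        links = {
            "j1": ("ff2.Qbar", qbar_init),
            "j2": ("ff1.Q", 0.0),
            "j3": ("ff2.Q", 0.0),
            "k3": ("ff2.Qbar", qbar_init),
        }
        for out, (src, src_init) in links.items():
            decl, gate = _interconnect(src, out, params, src_initial=src_init)
            extra_species.append(decl)
            extra_gates.append(gate)
        j1, j2, j3, k3 = "j1", "j2", "j3", "k3"
    else:
        j1, j2, j3, k3 = "ff2.Qbar", "ff1.Q", "ff2.Q", "ff2.Qbar"

    ff1 = build_jk_rising(params, j_src=j1, k_src="one", clk_src=clk_rise_src, prefix="ff1.")
    ff2 = build_jk_rising(params, j_src=j2, k_src="one", clk_src=clk_rise_src, prefix="ff2.")
    ff3 = build_jk_falling(params, j_src=j3, k_src=k3, clk_src=clk_fall_src, prefix="ff3.")

    extra_species.append(SpeciesDecl("G1", 0.0))
    extra_gates.append(
        GateNode(
            output="G1",
            kind=GateKind.OR,
            kinetics=params.kinetics,
            regulators=(
                Regulator("ff2.Q", params.hill),
                Regulator("ff3.Q", params.hill),
            ),
        )
    )
    return _merge(
        "mod3_counter",
        ff1,
        ff2,
        ff3,
        sources=(one,),
        extra_species=extra_species,
        extra_gates=extra_gates,
    )


@dataclass(frozen=True)
class CounterDesign:
    """Declarative counter description, used for document provenance and as a
    convenience constructor."""

    kind: str  # "binary" | "mod3"
    delta: Optional[int] = None
    params: FlipFlopParams = FlipFlopParams()
    buffered_wiring: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "mod3"):
            raise ValueError(f"counter kind must be 'binary' or 'mod3', got {self.kind!r}")
        if self.kind == "binary" and (self.delta is None or self.delta < 1):
            raise ValueError("binary counter requires delta >= 1")

    def build(
        self,
        clk_src: str = "clk",
        clk_fall_src: str = "clk2",
        logic_one_level: float = 1.0,
    ) -> CircuitSpec:
        if self.kind == "binary":
            return build_binary_counter(
                self.delta,
                self.params,
                clk_src=clk_src,
                logic_one_level=logic_one_level,
                buffered_wiring=self.buffered_wiring,
            )
        return build_mod3_counter(
            self.params,
            clk_rise_src=clk_src,
            clk_fall_src=clk_fall_src,
            logic_one_level=logic_one_level,
            buffered_wiring=self.buffered_wiring,
        )
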