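"""Design of Buffer-cascade waveform-shaping (PWM / clock-pulse) circuits.

A smooth genetic oscillation is reshaped into a near-square pulse train by
feeding it through a cascade of genetic Buffers.  Each Buffer's sigmoidal
steady-state curve acts as a soft comparator at its Hill constant K, so the
cascade repeatedly thresholds the waveform:

* The first stage's threshold ``K_1 = y_T`` selects the duty cycle: the
  output is logic-high for the fraction of each cycle the oscillation spends
  above ``y_T``.
* Every later stage thresholds at the half-maximal output of its
  predecessor, ``K_k = (rho_{k-1} + rho0_{k-1}) / (2 gamma_{k-1})``, so
  deviations from the logic levels shrink stage by stage provided each
  stage's operating-point gain ``rho n / (4 gamma K)`` exceeds 1.
* Because high thresholds converge slowly to the maximal level, a final
  compensation Buffer with a raised synthesis rate restores the nominal
  logic-high output level.

Threshold selection comes in two flavours.  For an ideal sinusoid
``y = A sin(w0 t + phi) + yd0`` the closed form ``y_T = yd0 + A cos(pi D)``
holds exactly.  Real oscillator waveforms are not sinusoidal, so an
empirical path computes the threshold as the time-quantile of a simulated
steady trace — the level exceeded for exactly the target fraction of each
cycle.  The shipped reference designs use fixed first-stage thresholds
(1.76 for the ~10% pulse, 0.6761 for the ~90% pulse) with five shaping
stages plus one compensation stage; the DC design uses three plus one.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .hill_gates import (
    GateKind,
    GateKinetics,
    HillInput,
    buffer_gain,
    promoter_activity,
)
from .circuit_core import CircuitSpec, GateNode, Regulator, SpeciesDecl, cascade
from .simulator import DEFAULT_DISCARD_FRACTION, SimulationTrace, steady_window
from .signal_analysis import _refined_peak_times

__all__ = [
    "ReferenceOscillation",
    "DutyCycleSpec",
    "ShaperStage",
    "ShaperDesign",
    "DesignError",
    "InsufficientDataError",
    "InfeasibleCompensationError",
    "analytic_threshold",
    "empirical_threshold",
    "design_cascade",
    "check_gain_condition",
    "compensation_rate",
    "with_compensation",
    "build_pwm_circuit",
    "d10_design",
    "d90_design",
    "dc_design",
]


class DesignError(ValueError):
    """A shaper design violates the stage-threshold recursion."""


class InsufficientDataError(ValueError):
    """A trace does not contain enough steady cycles for threshold estimation."""


class InfeasibleCompensationError(ValueError):
    """The compensation stage's logic-high input does not exceed its threshold."""


@dataclass(frozen=True)
class ReferenceOscillation:
    """Ideal sinusoidal reference ``y = A sin(2 pi t / T0 + phi) + yd0``."""

    A: float
    T0: float
    yd0: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.T0 > 0):
            raise ValueError("amplitude A and period T0 must be > 0")
        if self.yd0 < self.A:
            raise ValueError("base level yd0 must be >= A for a nonnegative signal")

    @property
    def omega0(self) -> float:
        return 2.0 * math.pi / self.T0

    def peak_time(self) -> float:
        """First time in [0, T0) at which the sinusoid peaks (w0 t + phi = pi/2)."""
        return ((0.5 * math.pi - self.phi) / self.omega0) % self.T0


@dataclass(frozen=True)
class DutyCycleSpec:
    """Target duty cycle D in (0, 1]: the logic-high fraction of each cycle."""

    D: float

    def __post_init__(self) -> None:
        if not 0 < self.D <= 1:
            raise ValueError(f"duty cycle must be in (0, 1], got {self.D}")

    def t_on(self, T0: float) -> float:
        return self.D * T0


@dataclass(frozen=True)
class ShaperStage:
    """One Buffer stage: its Hill site and kinetic rates."""

    hill: HillInput
    kinetics: GateKinetics = GateKinetics(rho=1.0, gamma=1.0, rho0=0.0)


@dataclass(frozen=True)
class ShaperDesign:
    """An ordered Buffer cascade implementing a target duty cycle.

    The first stage's Hill constant is the duty-cycle threshold; each later
    stage must threshold at its predecessor's half-maximal output level.  The
    last stage typically carries a raised synthesis rate (compensation).
    """

    stages: Tuple[ShaperStage, ...]
    input_species: str = "p_cI"

    def __post_init__(self) -> None:
        for k in range(1, len(self.stages)):
            prev = self.stages[k - 1]
            expected = (prev.kinetics.rho + prev.kinetics.rho0) / (2.0 * prev.kinetics.gamma)
            got = self.stages[k].hill.K
            if not math.isclose(got, expected, rel_tol=1e-9, abs_tol=1e-12):
                raise DesignError(
                    f"stage {k + 1} threshold {got} != half-maximal output "
                    f"{expected} of stage {k}"
                )

    @property
    def threshold_first(self) -> float:
        return self.stages[0].hill.K

    @property
    def compensation_rate_value(self) -> float:
        return self.stages[-1].kinetics.rho


def analytic_threshold(ref: ReferenceOscillation, duty: DutyCycleSpec) -> float:
    """Threshold on an ideal sinusoid exceeded for exactly fraction D of a cycle.

    Evaluating the sinusoid at the two instants ``t_h +/- T_on/2`` symmetric
    about its peak gives the single level ``y_T = yd0 + A cos(pi D)``:
    strictly decreasing in D, approaching ``yd0 + A`` as D -> 0 (a narrow
    rising-edge pulse), equal to the base level at D = 1/2, and ``yd0 - A``
    at D = 1.
    """
    return ref.yd0 + ref.A * math.cos(math.pi * duty.D)


def empirical_threshold(
    trace: SimulationTrace,
    signal: str,
    duty: DutyCycleSpec,
    discard_fraction: float = DEFAULT_DISCARD_FRACTION,
) -> float:
    """Threshold on a simulated waveform exceeded for fraction D of steady time.

    The (1 - D) time-quantile of the steady window — exact for any periodic
    waveform up to grid resolution, which makes it the right choice when the
    oscillator is not sinusoidal.  Requires at least three steady cycles.
    """
    w = steady_window(trace, discard_fraction)
    x = w[signal]
    if _refined_peak_times(w.times, x).size < 3:
        raise InsufficientDataError(
            f"signal {signal!r}: need >= 3 steady cycles for an empirical threshold"
        )
    return float(np.quantile(x, 1.0 - duty.D))


def design_cascade(
    threshold_first: float,
    stage_template: ShaperStage,
    M: int,
) -> ShaperDesign:
    """Build an M-stage cascade from a first threshold and a stage template.

    Stage 1 keeps the template's rates but thresholds at ``threshold_first``;
    stages 2..M threshold at the template's half-maximal output level (0.5
    for unit rates and zero basal rate).
    """
    if M < 2:
        raise DesignError("a shaping cascade needs at least 2 stages")
    kin = stage_template.kinetics
    n = stage_template.hill.n
    downstream_K = (kin.rho + kin.rho0) / (2.0 * kin.gamma)
    stages = [ShaperStage(HillInput(threshold_first, n), kin)]
    stages += [ShaperStage(HillInput(downstream_K, n), kin) for _ in range(M - 1)]
    return ShaperDesign(stages=tuple(stages))


def check_gain_condition(design: ShaperDesign) -> pd.DataFrame:
    """Operating-point gain of every stage, flagging gains <= 1.

    A stage with gain <= 1 does not amplify deviations from its threshold, so
    the cascade may fail to sharpen there; this is reported as a warning, not
    an error, because a high-threshold first stage can still select the duty
    cycle correctly while later stages do the sharpening.
    """
    rows = []
    for i, st in enumerate(design.stages, start=1):
        gain = buffer_gain(st.kinetics, st.hill)
        rows.append({"stage": i, "K": st.hill.K, "gain": gain, "ok": gain > 1.0})
    report = pd.DataFrame(rows)
    for _, row in report[~report["ok"]].iterrows():
        warnings.warn(
            f"shaper stage {int(row.stage)} gain {row.gain:.4g} <= 1 "
            f"(K={row.K:g}): this stage will not sharpen the waveform",
            stacklevel=2,
        )
    return report


def compensation_rate(
    design: ShaperDesign, input_high: float, target_high: float
) -> float:
    """Synthesis rate for a final Buffer that restores the logic-high level.

    Chooses rho so that the appended stage's steady output at logic-high
    input equals ``target_high``: ``rho = gamma * target_high / f_BUFFER(input_high)``
    (with zero basal rate).  Requires the logic-high input to exceed the
    stage threshold, else the stage would read its input as logic-low.
    """
    last = design.stages[-1]
    K_next = (last.kinetics.rho + last.kinetics.rho0) / (2.0 * last.kinetics.gamma)
    hill = HillInput(K_next, last.hill.n)
    if input_high <= K_next:
        raise InfeasibleCompensationError(
            f"logic-high input {input_high:g} does not exceed the compensation "
            f"stage threshold {K_next:g}"
        )
    f_high = promoter_activity(GateKind.BUFFER, [(input_high, hill)])
    return last.kinetics.gamma * target_high / f_high


def with_compensation(
    design: ShaperDesign, input_high: float, target_high: float = 1.0
) -> ShaperDesign:
    """Append the compensation Buffer implied by :func:`compensation_rate`."""
    last = design.stages[-1]
    rho = compensation_rate(design, input_high, target_high)
    K_next = (last.kinetics.rho + last.kinetics.rho0) / (2.0 * last.kinetics.gamma)
    stage = ShaperStage(
        HillInput(K_next, last.hill.n),
        GateKinetics(rho=rho, gamma=last.kinetics.gamma, rho0=0.0),
    )
    return ShaperDesign(stages=design.stages + (stage,), input_species=design.input_species)


def build_pwm_circuit(
    oscillator: CircuitSpec,
    tap: str,
    design: ShaperDesign,
    prefix: str = "p",
) -> CircuitSpec:
    """Wire a shaper design in series after an oscillator species.

    Stage k produces species ``p{k}``; stage 1 reads the tapped oscillator
    species, each later stage reads its predecessor.  An empty design returns
    the oscillator unchanged.
    """
    if tap not in oscillator.species_names:
        raise ValueError(f"tap species {tap!r} not found in oscillator")
    if not design.stages:
        return oscillator
    species = []
    gates = []
    input_name = "__shaper_in__"
    for k, st in enumerate(design.stages, start=1):
        out = f"{prefix}{k}"
        src = input_name if k == 1 else f"{prefix}{k - 1}"
        species.append(SpeciesDecl(out, 0.0))
        gates.append(
            GateNode(
                output=out,
                kind=GateKind.BUFFER,
                kinetics=st.kinetics,
                regulators=(Regulator(src, st.hill),),
            )
        )
    shaper = CircuitSpec(name="shaper", species=tuple(species), gates=tuple(gates))
    return cascade(oscillator, shaper, wiring={input_name: tap})


# ---------------------------------------------------------------------------
# Reference designs (five shaping stages + compensation; DC: three + one)
# ---------------------------------------------------------------------------

_UNIT_STAGE = ShaperStage(HillInput(0.5, 4.0), GateKinetics(1.0, 1.0, 0.0))


def _reference_design(threshold_first: float, comp_rho: float, shaping_stages: int) -> ShaperDesign:
    base = design_cascade(threshold_first, _UNIT_STAGE, shaping_stages)
    comp = ShaperStage(HillInput(0.5, 4.0), GateKinetics(comp_rho, 1.0, 0.0))
    return ShaperDesign(stages=base.stages + (comp,))


def d10_design() -> ShaperDesign:
    """Six-Buffer clock-pulse design targeting a narrow (~10% duty) pulse.

    First-stage threshold 1.76, four sharpening stages at K = 0.5, and a
    compensation stage with synthesis rate 1.0872.
    """
    return _reference_design(1.76, 1.0872, 5)


def d90_design() -> ShaperDesign:
    """Six-Buffer design targeting a wide (~90% duty) pulse.

    First-stage threshold 0.6761; compensation rate 1.1083.
    """
    return _reference_design(0.6761, 1.1083, 5)


def dc_design() -> ShaperDesign:
    """Four-Buffer rectifier producing a DC (100% duty) output.

    All thresholds 0.5; compensation rate 1.0851.
    """
    return _reference_design(0.5, 1.0851, 3)
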