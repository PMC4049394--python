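"""Promoter-activity functions and single-gene kinetics for genetic logic gates.

A genetic logic gate is a gene whose transcription is regulated by one or two
transcription-factor (TF) inputs through Hill-type promoter activity functions.
Seven gate types are supported:

====== ======= ==========================================================
kind   inputs  promoter activity f(u) with x_i = (u_i / K_i)^{n_i}
====== ======= ==========================================================
NOT    1       1 / (1 + x)                      (repressor input)
BUFFER 1       x / (1 + x)                      (activator input)
AND    2       x1 x2 / (1 + x1 + x2 + x1 x2)
OR     2       (x1 + x2 + x1 x2) / (1 + x1 + x2 + x1 x2)
XOR    2       (x1 + x2) / (1 + x1 + x2 + x1 x2)
NAND   2       (1 + x1 + x2) / (1 + x1 + x2 + x1 x2)
NOR    2       1 / (1 + x1 + x2 + x1 x2)
====== ======= ==========================================================

``K`` is the Hill constant (the input level at which a single-input gate is
half-maximal; it plays the role of a logic threshold) and ``n`` the Hill
coefficient (binding cooperativity; larger ``n`` gives a sharper switch).
All activities are dimensionless fractions in [0, 1], and the algebraic
complements hold exactly: ``f_NOT + f_BUFFER = 1``, ``f_NAND = 1 - f_AND``,
``f_NOR = 1 - f_OR`` and ``f_XOR = f_OR - f_AND``.

Gene expression itself comes in two resolutions.  The full two-stage model
tracks mRNA ``m`` and protein ``p``::

    dm/dt = alpha * f(u) - lambda * m + alpha0
    dp/dt = beta * m - gamma * p

Because mRNA is typically much shorter-lived than protein, the mRNA stage can
be adiabatically eliminated, giving the reduced one-stage protein model::

    dp/dt = rho * f(u) - gamma * p + rho0,   rho = alpha*beta/lambda,
                                             rho0 = alpha0*beta/lambda

Concentrations are treated as dimensionless arbitrary units and time is in
seconds; the worked examples throughout the package use ``n = 4``.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence, Tuple

__all__ = [
    "GateKind",
    "HillInput",
    "GateKinetics",
    "TranscriptionTranslationKinetics",
    "GateArityError",
    "KineticsDomainError",
    "promoter_activity",
    "reduced_gate_rhs",
    "full_gate_rhs",
    "reduce_kinetics",
    "buffer_steady_state",
    "buffer_gain",
]

# Hill ratios are capped here before forming products so that (u/K)^n never
# overflows; 1e150 squared is still a finite float and the resulting activity
# is correct to machine precision in the saturated limit.
_X_CAP = 1e150


class GateArityError(ValueError):
    """Raised when the number of regulators does not match the gate kind."""


class KineticsDomainError(ValueError):
    """Raised for parameter or input values outside the model's domain."""


class GateKind(str, enum.Enum):
    """The seven supported promoter-logic types."""

    NOT = "NOT"
    BUFFER = "BUFFER"
    AND = "AND"
    OR = "OR"
    XOR = "XOR"
    NAND = "NAND"
    NOR = "NOR"

    @property
    def arity(self) -> int:
        """Number of regulator inputs this gate kind takes (1 or 2)."""
        return 1 if self in (GateKind.NOT, GateKind.BUFFER) else 2


@dataclass(frozen=True)
class HillInput:
    """Hill constant and coefficient for one regulator binding site.

    Parameters
    ----------
    K : float
        Hill constant, in concentration units; must be > 0.  The input level
        at which the site is half-occupied — the gate's threshold.
    n : float
        Hill coefficient (dimensionless cooperativity); must be > 0.
        Non-integer values are accepted.
    """

    K: float
    n: float = 4.0

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise KineticsDomainError(f"Hill constant K must be > 0, got {self.K}")
        if not self.n > 0:
            raise KineticsDomainError(f"Hill coefficient n must be > 0, got {self.n}")


@dataclass(frozen=True)
class GateKinetics:
    """Reduced (protein-only) kinetic rates of a gate gene.

    rho is the maximal protein synthesis rate (concentration/time), gamma the
    protein decay rate (1/time) and rho0 the basal (leak) production rate.
    """

    rho: float
    gamma: float
    rho0: float = 0.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise KineticsDomainError(f"decay rate gamma must be > 0, got {self.gamma}")
        if self.rho < 0 or self.rho0 < 0:
            raise KineticsDomainError("synthesis rates rho, rho0 must be >= 0")


@dataclass(frozen=True)
class TranscriptionTranslationKinetics:
    """Two-stage (mRNA + protein) kinetic rates of a gate gene.

    alpha: maximal transcription rate; lam: mRNA decay rate; beta: translation
    rate per mRNA; gamma: protein decay rate; alpha0: basal transcription.
    """

    alpha: float
    lam: float
    beta: float
    gamma: float
    alpha0: float = 0.0

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise KineticsDomainError(f"mRNA decay rate lam must be > 0, got {self.lam}")
        if not self.gamma > 0:
            raise KineticsDomainError(f"decay rate gamma must be > 0, got {self.gamma}")
        if self.alpha < 0 or self.beta < 0 or self.alpha0 < 0:
            raise KineticsDomainError("rates alpha, beta, alpha0 must be >= 0")


def _hill_ratio(level: float, hill: HillInput) -> float:
    """(u/K)^n, evaluated by limit at u = 0 and capped against overflow."""
    if level < 0:
        raise KineticsDomainError(f"regulator level must be >= 0, got {level}")
    if level == 0.0:
        return 0.0
    try:
        x = math.pow(level / hill.K, hill.n)
    except OverflowError:
        return _X_CAP
    return min(x, _X_CAP)


def promoter_activity(
    kind: GateKind, regulators: Sequence[Tuple[float, HillInput]]
) -> float:
    """Evaluate the promoter activity f(u) of a gate, a fraction in [0, 1].

    Parameters
    ----------
    kind : GateKind
        The gate's logic type.
    regulators : sequence of (level, HillInput)
        One pair for NOT/BUFFER, two for the binary gates.  Levels are
        regulator (TF) concentrations and must be non-negative.

    Raises
    ------
    GateArityError
        If the regulator count does not match the gate kind's arity.
    KineticsDomainError
        If a regulator level is negative.
    """
    kind = GateKind(kind)
    if len(regulators) != kind.arity:
        raise GateArityError(
            f"{kind.value} gate takes {kind.arity} regulator(s), got {len(regulators)}"
        )
    if kind.arity == 1:
        x = _hill_ratio(*regulators[0])
        return 1.0 / (1.0 + x) if kind is GateKind.NOT else x / (1.0 + x)
    x1 = _hill_ratio(*regulators[0])
    x2 = _hill_ratio(*regulators[1])
    den = 1.0 + x1 + x2 + x1 * x2
    if kind is GateKind.AND:
        num = x1 * x2
    elif kind is GateKind.OR:
        num = x1 + x2 + x1 * x2
    elif kind is GateKind.XOR:
        num = x1 + x2
    elif kind is GateKind.NAND:
        num = 1.0 + x1 + x2
    else:  # NOR
        num = 1.0
    return num / den


def reduced_gate_rhs(
    kin: GateKinetics,
    kind: GateKind,
    regulators: Sequence[Tuple[float, HillInput]],
    p: float,
) -> float:
    """Time derivative of protein concentration in the reduced gate model.

    Returns ``rho * f(u) - gamma * p + rho0``.
    """
    if p < 0:
        raise KineticsDomainError(f"protein concentration must be >= 0, got {p}")
    f = promoter_activity(kind, regulators)
    return kin.rho * f - kin.gamma * p + kin.rho0


def full_gate_rhs(
    kin: TranscriptionTranslationKinetics,
    kind: GateKind,
    regulators: Sequence[Tuple[float, HillInput]],
    m: float,
    p: float,
) -> Tuple[float, float]:
    """Time derivatives (dm/dt, dp/dt) in the two-stage mRNA/protein model."""
    if m < 0 or p < 0:
        raise KineticsDomainError("concentrations m, p must be >= 0")
    f = promoter_activity(kind, regulators)
    dm = kin.alpha * f - kin.lam * m + kin.alpha0
    dp = kin.beta * m - kin.gamma * p
    return dm, dp


def reduce_kinetics(kin: TranscriptionTranslationKinetics) -> GateKinetics:
    """Adiabatic elimination of the mRNA stage.

    Maps the two-stage rates onto the reduced protein model so that both
    models share the same steady states: ``rho = alpha*beta/lam``,
    ``rho0 = alpha0*beta/lam``, ``gamma`` unchanged.
    """
    return GateKinetics(
        rho=kin.alpha * kin.beta / kin.lam,
        gamma=kin.gamma,
        rho0=kin.alpha0 * kin.beta / kin.lam,
    )


def buffer_steady_state(kin: GateKinetics, hill: HillInput, u: float) -> float:
    """Steady-state output of a Buffer gene at constant input ``u``.

    ``p_ss = (rho/gamma) * f_BUFFER(u) + rho0/gamma``.  The second term is the
    minimal level and ``rho/gamma`` the span between minimal and maximal
    levels; the output is half-maximal at ``u = K``, which is why the Hill
    constant acts as the stage's threshold.
    """
    f = promoter_activity(GateKind.BUFFER, [(u, hill)])
    return (kin.rho / kin.gamma) * f + kin.rho0 / kin.gamma


def buffer_gain(kin: GateKinetics, hill: HillInput) -> float:
    """Small-signal gain of a Buffer stage at its operating point ``u = K``.

    The slope of the steady-state input/output curve at the threshold:
    ``A = rho * n / (4 * gamma * K)``.  For a cascade of Buffers to sharpen a
    waveform, each stage's gain should exceed 1 so deviations from the
    threshold grow stage by stage; callers treat a gain <= 1 as a warning
    rather than an error.
    """
    return kin.rho * hill.n / (4.0 * kin.gamma * hill.K)
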