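"""Shared fixtures: reference oscillator and clock-pulse cascade traces.

Simulations are session-scoped — every metric test reads the same trace, so
the suite pays for each integration once.
"""
from __future__ import annotations

import numpy as np
import pytest

from geneclock import (
    RepressilatorSpec,
    SimulationTrace,
    SolverSettings,
    build_pwm_circuit,
    build_repressilator,
    d10_design,
    d90_design,
    dc_design,
    simulate,
)

#: Reference clock period of the chi=0.5 oscillator; oscillator tests measure
#: it rather than assume it, counter tests use it as the expected clock scale.
T0 = 32.3


@pytest.fixture(scope="session")
def rep_circuit():
    return build_repressilator(RepressilatorSpec(chi=0.5))


@pytest.fixture(scope="session")
def rep_trace(rep_circuit) -> SimulationTrace:
    return simulate(rep_circuit, SolverSettings(t_end=500.0))


def _cascade_trace(rep_circuit, design) -> SimulationTrace:
    circuit = build_pwm_circuit(rep_circuit, "p_cI", design)
    return simulate(circuit, SolverSettings(t_end=500.0))


@pytest.fixture(scope="session")
def d10_trace(rep_circuit) -> SimulationTrace:
    """Six-Buffer narrow-pulse cascade (first threshold 1.76) output trace."""
    return _cascade_trace(rep_circuit, d10_design())


@pytest.fixture(scope="session")
def d90_trace(rep_circuit) -> SimulationTrace:
    return _cascade_trace(rep_circuit, d90_design())


@pytest.fixture(scope="session")
def dc_trace(rep_circuit) -> SimulationTrace:
    return _cascade_trace(rep_circuit, dc_design())


@pytest.fixture(scope="session")
def sinusoid_trace() -> SimulationTrace:
    """Exact reference sinusoid 1.1731 + 0.63 sin(2 pi t / 32) on the default grid."""
    t = np.arange(0.0, 320.0, 0.01)
    x = 1.1731 + 0.63 * np.sin(2 * np.pi * t / 32.0)
    return SimulationTrace(times=t, values=x[:, None], species=["y"])


def digital_jk(q: bool, j: bool, k: bool) -> bool:
    """Four-state digital JK oracle: hold / reset / set / toggle."""
    if j and k:
        return not q
    if j:
        return True
    if k:
        return False
    return q
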